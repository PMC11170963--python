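"""Data model and TSV readers/writers shared by every analysis stage.

The package works on three in-memory containers:

``AbundanceTable``
    A non-negative feature x sample matrix (species relative abundances,
    gene RPKM, or raw counts) backed by a pandas DataFrame.
``CohortMetadata``
    Per-sample subject / arm / timepoint records plus host covariates and
    glycemic measures, encoding the paired pre/post design.
``PairedDesign``
    The materialised (subject, pre sample, post sample, arm) pairing for a
    chosen post-treatment day.

Tables live on disk as plain TSV with features in rows and samples in
columns (the usual metagenomics profile layout); metadata is one TSV row
per sample. Sample IDs are opaque strings — pairing always goes through
``subject_id`` + ``timepoint_day``, never through ID suffix parsing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "CohortMetadata",
    "PairedDesign",
    "SubjectPair",
    "TableKind",
    "CLINICAL_MEASURES",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "build_paired_design",
    "write_json",
]

TABLE_KINDS = ("relative_abundance", "rpkm", "counts")
TableKind = str

#: Glycemic measures carried per sample row (values at that sample's timepoint).
CLINICAL_MEASURES = ("hba1c", "fpg", "ppg", "homa_ir")

_REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "arm", "timepoint_day")
_COVARIATE_COLUMNS = ("age", "sex", "bmi")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what} IDs: {sorted(set(dups))}")


@dataclass
class AbundanceTable:
    """Feature x sample abundance matrix with validated identifiers.

    Parameters
    ----------
    data
        DataFrame with feature IDs as the index and sample IDs as columns.
        All entries must be finite and non-negative.
    kind
        One of ``relative_abundance``, ``rpkm`` or ``counts``. For
        ``relative_abundance`` each sample column is expected to sum to 1
        (within 1e-6) once :func:`microshift.diversity.to_relative` has
        been applied; raw input may arrive unnormalised.
    """

    data: pd.DataFrame
    kind: TableKind = "relative_abundance"

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}; expected one of {TABLE_KINDS}")
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite abundance at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance {values[bad[0], bad[1]]!r} at feature "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Matrix view, features in rows, samples in columns."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)].copy(), kind=self.kind)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy(dtype=float)


def read_abundance_table(path: str | Path, kind: TableKind = "relative_abundance") -> AbundanceTable:
    """Read a feature x sample TSV (header row of sample IDs, first column feature IDs).

    Raises
    ------
    ValueError
        On a negative or non-numeric body cell (the offending feature and
        sample are named) or on duplicate feature/sample identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        parsed = []
        for feat, cell in df[col].items():
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(f"{path}: missing value at feature {feat!r}, sample {col!r}")
            try:
                # python float() round-trips repr exactly (to_numeric may lose an ulp)
                parsed.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at feature {feat!r}, sample {col!r}"
                ) from None
        numeric[col] = parsed
    try:
        return AbundanceTable(numeric, kind=kind)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the table as TSV with a ``feature_id`` header cell.

    Floats are written with ``repr`` precision so that a write/read
    round-trip reproduces the matrix bit-for-bit.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        values = table.values
        for i, feat in enumerate(table.feature_ids):
            fh.write(feat + "\t" + "\t".join(repr(float(v)) for v in values[i]) + "\n")


@dataclass
class CohortMetadata:
    """Per-sample cohort metadata encoding the paired design.

    The backing DataFrame is indexed by ``sample_id`` and carries
    ``subject_id``, ``arm``, ``timepoint_day`` plus any of the covariate
    columns (``age``, ``sex``, ``bmi``) and clinical measures
    (:data:`CLINICAL_MEASURES`, valued at each sample's own timepoint).
    Missing covariate/clinical values are permitted (``NaN``) and reported
    by :meth:`missing_counts`; operations that need a measure drop the
    affected subjects and say how many.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject_id", "arm", "timepoint_day"):
            if col not in self.data.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        _check_unique(list(self.data.index), "sample")
        self.data = self.data.copy()
        self.data["timepoint_day"] = self.data["timepoint_day"].astype(int)
        if (self.data["timepoint_day"] < 0).any():
            raise ValueError("timepoint_day must be >= 0")
        pair_counts = self.data.groupby(["subject_id", "timepoint_day"]).size()
        dup = pair_counts[pair_counts > 1]
        if len(dup):
            raise ValueError(f"duplicated (subject, timepoint_day) rows: {list(dup.index)}")
        by_subject = self.data.groupby("subject_id")["timepoint_day"].agg(set)
        lacking = [s for s, days in by_subject.items() if 0 not in days]
        if lacking:
            raise ValueError(f"subjects lacking a day-0 (baseline) sample: {sorted(lacking)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def arms(self) -> list[str]:
        return sorted(self.data["arm"].unique())

    @property
    def timepoint_days(self) -> list[int]:
        return sorted(int(d) for d in self.data["timepoint_day"].unique())

    def samples_at(self, day: int, arm: str | None = None) -> list[str]:
        mask = self.data["timepoint_day"] == day
        if arm is not None:
            mask &= self.data["arm"] == arm
        return list(self.data.index[mask])

    def subject_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "subject_id"])

    def arm_of_subject(self, subject_id: str) -> str:
        rows = self.data[self.data["subject_id"] == subject_id]
        return str(rows["arm"].iloc[0])

    def missing_counts(self) -> dict[str, int]:
        """Number of missing (NaN) values per optional covariate/clinical column."""
        out = {}
        for col in (*_COVARIATE_COLUMNS, *CLINICAL_MEASURES):
            if col in self.data.columns:
                out[col] = int(self.data[col].isna().sum())
        return out

    def clinical_value(self, subject_id: str, measure: str, day: int) -> float:
        rows = self.data[(self.data["subject_id"] == subject_id) & (self.data["timepoint_day"] == day)]
        if rows.empty or measure not in rows.columns:
            return float("nan")
        return float(rows[measure].iloc[0])


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read per-sample metadata TSV (``NA`` encodes a missing value)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "arm": str},
                     na_values=["NA"], keep_default_na=True)
    for col in _REQUIRED_META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: metadata missing required column {col!r}")
    df = df.set_index("sample_id")
    try:
        return CohortMetadata(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    df = meta.data.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass(frozen=True)
class SubjectPair:
    subject_id: str
    pre_sample_id: str
    post_sample_id: str
    arm: str


@dataclass
class PairedDesign:
    """Pre/post sample pairing for one chosen post-treatment day.

    ``excluded_subjects`` lists subjects that lack either the baseline or
    the requested post-day sample and were dropped from the pairing.
    """

    post_day: int
    pairs: list[SubjectPair] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        subjects = [p.subject_id for p in self.pairs]
        _check_unique(subjects, "subject")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def arms(self) -> list[str]:
        return sorted({p.arm for p in self.pairs})

    def for_arm(self, arm: str) -> "PairedDesign":
        return PairedDesign(self.post_day, [p for p in self.pairs if p.arm == arm], [])

    def pre_sample_ids(self) -> list[str]:
        return [p.pre_sample_id for p in self.pairs]

    def post_sample_ids(self) -> list[str]:
        return [p.post_sample_id for p in self.pairs]

    def all_sample_ids(self) -> list[str]:
        return self.pre_sample_ids() + self.post_sample_ids()


def build_paired_design(meta: CohortMetadata, post_day: int) -> PairedDesign:
    """Pair each subject's day-0 sample with its sample at ``post_day``.

    Subjects lacking either timepoint are excluded and reported in
    ``excluded_subjects``. Requesting a day at which no sample exists in
    the whole cohort is an error listing the available days.
    """
    if post_day <= 0:
        raise ValueError("post_day must be > 0 (day 0 is the baseline)")
    days = meta.timepoint_days
    if post_day not in days:
        raise ValueError(f"no samples at day {post_day}; available days: {days}")
    pairs: list[SubjectPair] = []
    excluded: list[str] = []
    for subject in meta.subjects:
        rows = meta.data[meta.data["subject_id"] == subject]
        pre = rows.index[rows["timepoint_day"] == 0]
        post = rows.index[rows["timepoint_day"] == post_day]
        if len(pre) == 1 and len(post) == 1:
            pairs.append(SubjectPair(subject, str(pre[0]), str(post[0]), str(rows["arm"].iloc[0])))
        else:
            excluded.append(subject)
    return PairedDesign(post_day=post_day, pairs=pairs, excluded_subjects=excluded)


def write_json(obj: Mapping | Iterable, path: str | Path) -> None:
    """Serialize a result summary deterministically (sorted keys, repr floats)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
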