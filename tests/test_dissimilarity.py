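import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import distance as sp_distance

from microshift.core_io import AbundanceTable, CohortMetadata, build_paired_design
from microshift.dissimilarity import (
    METRICS,
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    fingerprint_assignment,
    hellinger,
    jensen_shannon,
    permanova,
    spearman_dissimilarity,
)


def _random_pair(rng, k=20, sparse=True):
    p = rng.lognormal(0, 1, k)
    q = rng.lognormal(0, 1, k)
    if sparse:
        p[rng.random(k) < 0.3] = 0
        q[rng.random(k) < 0.3] = 0
        if p.sum() == 0:
            p[0] = 1.0
        if q.sum() == 0:
            q[1] = 1.0
    return p / p.sum(), q / q.sum()


class TestMetricValues:
    def test_bray_curtis_example(self):
        assert bray_curtis([0.7, 0.3], [0.5, 0.5]) == pytest.approx(0.2)

    def test_hellinger_example(self):
        expected = math.sqrt(1 - math.sqrt(0.5))
        assert hellinger([1.0, 0.0], [0.5, 0.5]) == pytest.approx(expected, abs=1e-12)

    def test_boundary_identities(self):
        p = np.array([0.2, 0.3, 0.5])
        assert bray_curtis(p, p) == 0.0
        assert hellinger(p, p) == 0.0
        assert jensen_shannon(p, p) == 0.0
        assert spearman_dissimilarity([1.0, 2, 3], [2.0, 4, 6]) == pytest.approx(0.0)
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.5, 0.5])
        assert bray_curtis(a, b) == pytest.approx(1.0)
        assert hellinger(a, b) == pytest.approx(1.0)
        assert jensen_shannon(a, b) == pytest.approx(math.log(2), abs=1e-12)
        assert spearman_dissimilarity([1.0, 2, 3], [3.0, 2, 1]) == pytest.approx(1.0)

    def test_spearman_matches_rank_then_pearson(self, rng):
        for _ in range(20):
            p, q = _random_pair(rng, sparse=False)
            rho = np.corrcoef(stats.rankdata(p), stats.rankdata(q))[0, 1]
            assert spearman_dissimilarity(p, q) == pytest.approx((1 - rho) / 2, abs=1e-12)

    def test_jsd_matches_term_by_term_kl(self, rng):
        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * (np.log(a[mask]) - np.log(b[mask]))))

        for _ in range(20):
            p, q = _random_pair(rng)
            m = (p + q) / 2
            assert jensen_shannon(p, q) == pytest.approx(
                0.5 * kl(p, m) + 0.5 * kl(q, m), abs=1e-12
            )

    def test_bray_matches_scipy(self, rng):
        for _ in range(20):
            p, q = _random_pair(rng)
            assert bray_curtis(p, q) == pytest.approx(
                sp_distance.braycurtis(p, q), abs=1e-12
            )

    def test_range_and_symmetry_properties(self, rng):
        bounds = {"bray_curtis": 1.0, "hellinger": 1.0, "spearman": 1.0,
                  "jsd": math.log(2)}
        fns = {"bray_curtis": bray_curtis, "hellinger": hellinger,
               "spearman": spearman_dissimilarity, "jsd": jensen_shannon}
        for _ in range(200):
            p, q = _random_pair(rng)
            for name, fn in fns.items():
                d = fn(p, q)
                assert -1e-12 <= d <= bounds[name] + 1e-12
                assert d == pytest.approx(fn(q, p), abs=1e-12)

    def test_spearman_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman_dissimilarity([0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4])


class TestDistanceMatrix:
    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_looped_pairwise_calls(self, rng, metric):
        fns = {"bray_curtis": bray_curtis, "hellinger": hellinger,
               "spearman": spearman_dissimilarity, "jsd": jensen_shannon}
        raw = rng.lognormal(0, 1, (12, 6))
        raw[rng.random(raw.shape) < 0.2] = 0
        rel = raw / raw.sum(axis=0)
        t = AbundanceTable(pd.DataFrame(rel, index=[f"f{i}" for i in range(12)],
                                        columns=[f"s{j}" for j in range(6)]))
        dm = distance_matrix(t, metric)
        for i, j in itertools.combinations(range(6), 2):
            expected = fns[metric](rel[:, i], rel[:, j])
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_identical_samples_zero_distance(self):
        rel = np.tile(np.array([[0.2], [0.3], [0.5]]), (1, 2))
        t = AbundanceTable(pd.DataFrame(rel, index=list("abc"), columns=["s1", "s2"]))
        for metric in ("bray_curtis", "hellinger", "jsd"):
            assert distance_matrix(t, metric).values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_tsv_round_trip(self, tmp_path, small_table):
        dm = distance_matrix(small_table, "bray_curtis")
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path, metric="bray_curtis")
        np.testing.assert_allclose(back.values, dm.values, atol=1e-12)
        assert back.sample_ids == dm.sample_ids


def _independent_permanova_oracle(d2, labels):
    """SS decomposition and exact enumeration computed from first principles."""
    n = len(labels)
    labels = np.asarray(labels)

    def ss_for(lab):
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for lv in np.unique(lab):
            idx = np.nonzero(lab == lv)[0]
            ss_within += sum(
                d2[i, j] for i in idx for j in idx if i < j
            ) / len(idx)
        return ss_total, ss_within

    def f_for(lab):
        a = len(np.unique(lab))
        ss_total, ss_within = ss_for(lab)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total

    f_obs, r2 = f_for(labels)
    lv = np.unique(labels)
    k = int((labels == lv[0]).sum())
    count = total = 0
    for combo in itertools.combinations(range(n), k):
        lab = np.full(n, lv[1], dtype=object)
        lab[list(combo)] = lv[0]
        f, _ = f_for(lab)
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return r2, f_obs, count / total


class TestPermanova:
    def _dm(self, rng, n=6, sep=0.0):
        pts = rng.normal(0, 1, (n, 3))
        pts[: n // 2] += sep
        vals = sp_distance.squareform(sp_distance.pdist(pts))
        return DistanceMatrix([f"s{i}" for i in range(n)], "bray_curtis",
                              vals / (vals.max() + 1e-9))

    def test_duplicate_samples_give_zero_r2(self):
        vals = np.zeros((4, 4))
        dm = DistanceMatrix(["a", "b", "c", "d"], "bray_curtis", vals)
        labels = {"a": "pre", "b": "post", "c": "pre", "d": "post"}
        res = permanova(dm, labels, n_perm=19, seed=0)
        assert res.r_squared == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dm = self._dm(rng, n=6, sep=1.0)
        labels = {f"s{i}": ("pre" if i < 3 else "post") for i in range(6)}
        res = permanova(dm, labels, method="exact")
        r2, f, p = _independent_permanova_oracle(dm.values ** 2, [labels[s] for s in dm.sample_ids])
        assert res.r_squared == pytest.approx(r2, abs=1e-12)
        assert res.pseudo_f == pytest.approx(f, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_permutation_p_converges_to_exact(self):
        rng = np.random.default_rng(7)
        dm = self._dm(rng, n=8, sep=0.8)
        labels = {f"s{i}": ("pre" if i < 4 else "post") for i in range(8)}
        exact = permanova(dm, labels, method="exact").p_value
        approx = permanova(dm, labels, n_perm=4999, seed=11).p_value
        assert approx == pytest.approx(exact, abs=0.03)

    def test_r2_invariant_under_consistent_reordering(self, rng):
        dm = self._dm(rng, n=10, sep=0.5)
        labels = {f"s{i}": ("pre" if i % 2 else "post") for i in range(10)}
        base = permanova(dm, labels, n_perm=9, seed=0).r_squared
        order = list(rng.permutation(dm.sample_ids))
        dm2 = dm.subset(order)
        again = permanova(dm2, labels, n_perm=9, seed=0).r_squared
        assert again == pytest.approx(base, abs=1e-12)

    def test_separated_clusters_large_r2_floor_p(self, rng):
        dm = self._dm(rng, n=12, sep=20.0)
        labels = {f"s{i}": ("pre" if i < 6 else "post") for i in range(12)}
        res = permanova(dm, labels, n_perm=199, seed=0)
        assert res.r_squared > 0.5
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        dm = self._dm(rng, n=10, sep=1.0)
        labels = ["pre"] * 5 + ["post"] * 5
        ours = permanova(dm, dict(zip(dm.sample_ids, labels)), n_perm=999, seed=0)
        theirs = skbio_permanova(skbio.DistanceMatrix(dm.values, ids=dm.sample_ids),
                                 grouping=labels, permutations=999)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert ours.p_value == pytest.approx(theirs["p-value"], abs=0.05)

    def test_small_group_rejected(self):
        dm = self._dm(np.random.default_rng(0), n=4)
        labels = {"s0": "pre", "s1": "post", "s2": "post", "s3": "post"}
        with pytest.raises(ValueError, match="< 2 samples"):
            permanova(dm, labels, n_perm=9, seed=0)


class TestFingerprint:
    def _design(self, n):
        rows = [{"sample_id": f"S{i}_d{d}", "subject_id": f"S{i}", "arm": "a",
                 "timepoint_day": d} for i in range(n) for d in (0, 90)]
        meta = CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))
        return build_paired_design(meta, 90)

    def test_single_subject_degenerate(self):
        design = self._design(1)
        vals = np.array([[0.0, 0.1], [0.1, 0.0]])
        dm = DistanceMatrix(["S0_d0", "S0_d90"], "bray_curtis", vals)
        res = fingerprint_assignment(dm, design)
        assert res.accuracy == 1.0 and res.degenerate

    def test_tie_broken_lexicographically_and_flagged(self):
        design = self._design(2)
        ids = ["S0_d0", "S0_d90", "S1_d0", "S1_d90"]
        vals = np.zeros((4, 4))  # every distance ties at zero
        dm = DistanceMatrix(ids, "bray_curtis", vals)
        res = fingerprint_assignment(dm, design)
        rec = res.records.set_index("post_sample_id")
        assert rec.loc["S0_d90", "assigned_subject"] == "S0"
        assert rec.loc["S1_d90", "assigned_subject"] == "S0"  # lexicographic tie-break
        assert rec["tie"].all()

    def test_accuracy_counts_correct_assignments(self, null_cohort):
        species, _, meta, _ = null_cohort
        design = build_paired_design(meta, 90)
        dm = distance_matrix(species, "bray_curtis")
        res = fingerprint_assignment(dm, design)
        assert res.accuracy == res.records["correct"].mean()
        assert res.n_assessed == design.n_pairs
        assert (res.records["rank_of_true_baseline"] >= 1).all()

    def test_leave_self_out_candidate_pool(self, null_cohort):
        species, _, meta, _ = null_cohort
        design = build_paired_design(meta, 90)
        dm = distance_matrix(species, "bray_curtis")
        res = fingerprint_assignment(dm, design, candidates="all")
        # with intact fingerprints the own baseline dominates either way
        assert res.accuracy >= 0.9
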