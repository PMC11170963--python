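"""Baseline-microbiota prediction of treatment response.

The response of a subject on a glycemic measure (HbA1c, FPG, PPG,
HOMA-IR) is its percentage change, (post - pre) / pre * 100. Four
complementary analyses relate baseline microbial features to responses:

* a partial Spearman screen (rank, residualise on covariates, Pearson on
  residuals), with the significance rule |partial rho| > 0.3 AND p < 0.05;
* elastic-net feature selection followed by an ordinary least-squares
  refit whose R^2 is the reported variance explained;
* a median split into high responders (HR, percentage change strictly
  below the median — the greater reduction) and low responders (LR), with
  per-feature logistic odds ratios;
* generalized estimating equations (Gaussian family, identity link,
  exchangeable working correlation, robust errors) for longitudinal
  feature-clinical associations with subject clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "arm_response_dataset",
    "percent_change",
    "stratify_responders",
    "partial_spearman_screen",
    "count_significant_features",
    "elasticnet_variance_explained",
    "responder_logistic",
    "gee_longitudinal",
    "VarianceExplainedResult",
    "ResponderOddsResult",
    "GeeResult",
]


def arm_response_dataset(
    table,
    meta,
    arm: str,
    measure: str,
    post_day: int,
    pseudocount: float | str = "half-min",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, int]:
    """Assemble the per-subject response dataset for one arm and measure.

    Returns ``(features, response, covariates, n_dropped)`` where
    ``features`` holds baseline (day-0) CLR values (subjects x species),
    ``response`` the percentage change of the measure, and ``covariates``
    age, sex, BMI and the baseline measure. Subjects with a missing pre or
    post clinical value are dropped and counted in ``n_dropped``.
    """
    from .core_io import build_paired_design
    from .diversity import clr_transform

    design = build_paired_design(meta, post_day).for_arm(arm)
    if design.n_pairs == 0:
        raise ValueError(f"no pairs for arm {arm!r} at day {post_day}")
    clr = clr_transform(table, pseudocount=pseudocount)
    rows, resp, cov = {}, {}, {}
    n_dropped = 0
    for pair in design.pairs:
        pre = meta.clinical_value(pair.subject_id, measure, 0)
        post = meta.clinical_value(pair.subject_id, measure, post_day)
        meta_row = meta.data.loc[pair.pre_sample_id]
        covs = {
            "age": float(meta_row.get("age", np.nan)),
            "sex": str(meta_row.get("sex", "")),
            "bmi": float(meta_row.get("bmi", np.nan)),
            f"baseline_{measure}": pre,
        }
        if not np.isfinite(pre) or not np.isfinite(post) or pre == 0 or \
                not all(np.isfinite(v) for k, v in covs.items() if k != "sex"):
            n_dropped += 1
            continue
        rows[pair.subject_id] = clr[pair.pre_sample_id]
        resp[pair.subject_id] = percent_change(pre, post)
        cov[pair.subject_id] = covs
    features = pd.DataFrame(rows).T
    features.index.name = "subject_id"
    return (
        features,
        pd.Series(resp, name=measure),
        pd.DataFrame(cov).T,
        n_dropped,
    )


def percent_change(pre: float, post: float) -> float:
    """(post - pre) / pre * 100; errors on a zero baseline."""
    if pre == 0:
        raise ValueError("baseline (pre) value is zero; percentage change undefined")
    return (post - pre) / pre * 100.0


def stratify_responders(responses: pd.Series) -> pd.Series:
    """Median-split responses into HR (high responder) and LR classes.

    HR = percentage change strictly below the median (the greater
    reduction); values at or above the median, including exact-median
    ties, go to LR, which makes the split deterministic. Requires >= 4
    subjects and at least two distinct response values.
    """
    responses = responses.astype(float)
    if len(responses) < 4:
        raise ValueError("need >= 4 subjects for a median split")
    if responses.nunique() < 2:
        raise ValueError("all responses identical; no median split exists")
    med = float(responses.median())
    classes = pd.Series(np.where(responses < med, "HR", "LR"), index=responses.index)
    return classes


def _covariate_matrix(covariates: pd.DataFrame | None, index) -> np.ndarray | None:
    if covariates is None or covariates.shape[1] == 0:
        return None
    cov = covariates.loc[index].copy()
    for col in cov.columns:
        numeric = pd.to_numeric(cov[col], errors="coerce")
        if numeric.notna().all():
            cov[col] = numeric
        else:  # categorical column (e.g. sex) -> stable integer codes
            codes, _ = pd.factorize(cov[col].astype(str), sort=True)
            cov[col] = codes
    return cov.to_numpy(dtype=float)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, Z] by least squares."""
    design = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_spearman_screen(
    features: pd.DataFrame,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial Spearman correlation of each baseline feature with the response.

    ``features`` is subjects x features (e.g. baseline CLR values),
    ``response`` per-subject percentage change, ``covariates`` per-subject
    adjustment variables (age, sex, BMI, baseline measure; categorical
    columns are factorised). All variables — feature, response and the
    numeric covariates — are rank-transformed (mid-ranks); feature and
    response ranks are residualised on the covariate ranks by linear
    projection, and the partial rho is the Pearson correlation of the
    residuals with a t-test on n - 2 - #covariates degrees of freedom.
    Ranking the covariates too is what makes the adjustment remove any
    monotone confounding, not just linear. A feature is
    ``significant`` iff |rho| > rho_threshold (strict) AND p < alpha.
    Constant features are excluded with ``excluded=True``.
    """
    idx = response.index
    n = len(idx)
    k = 0 if covariates is None else covariates.shape[1]
    if n < k + 5:
        raise ValueError(f"need n >= #covariates + 5; have n={n}, k={k}")
    Z = _covariate_matrix(covariates, idx)
    if Z is not None:
        Z = np.column_stack([stats.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    y_rank = stats.rankdata(response.loc[idx].to_numpy(dtype=float))
    y_res = _residualize(y_rank, Z) if Z is not None else y_rank - y_rank.mean()
    df_t = n - 2 - k
    rows = []
    for feat in features.columns:
        x = features.loc[idx, feat].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append({"feature_id": feat, "partial_rho": np.nan, "p": np.nan,
                         "significant": False, "excluded": True})
            continue
        x_rank = stats.rankdata(x)
        x_res = _residualize(x_rank, Z) if Z is not None else x_rank - x_rank.mean()
        denom = np.sqrt((x_res ** 2).sum() * (y_res ** 2).sum())
        rho = float((x_res * y_res).sum() / denom) if denom > 0 else np.nan
        if not np.isfinite(rho) or abs(rho) >= 1.0:
            p = 0.0 if np.isfinite(rho) else np.nan
        else:
            t = rho * np.sqrt(df_t / (1.0 - rho ** 2))
            p = float(2 * stats.t.sf(abs(t), df_t))
        significant = bool(np.isfinite(rho) and abs(rho) > rho_threshold and p < alpha)
        rows.append({"feature_id": feat, "partial_rho": rho, "p": p,
                     "significant": significant, "excluded": False})
    return pd.DataFrame(rows)


def count_significant_features(screen: pd.DataFrame) -> int:
    """Number of screened features passing the significance rule."""
    if len(screen) == 0:
        return 0
    return int(screen["significant"].sum())


@dataclass
class VarianceExplainedResult:
    measure: str
    selected_features: list[str]
    r_squared: float          # in-sample R^2 of the OLS refit on selected features
    r_squared_cv: float       # cross-validated R^2 of the elastic net at its chosen penalty
    coefficients: dict[str, float] = field(default_factory=dict)
    alpha_chosen: float = float("nan")


def elasticnet_variance_explained(
    features: pd.DataFrame,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
    cv_folds: int = 5,
    seed: int | None = 0,
    l1_ratio: float = 0.5,
    penalty_rule: str = "1se",
    measure: str = "",
) -> VarianceExplainedResult:
    """Two-stage variance-explained estimate for one clinical measure.

    Stage 1: elastic net (mixing parameter ``l1_ratio``) with the penalty
    chosen by seeded ``cv_folds``-fold cross-validation selects features
    with non-zero coefficients. ``penalty_rule="1se"`` (default) takes the
    sparsest penalty whose CV error is within one standard error of the
    minimum — the usual guard against the dense selections (and inflated
    refit R^2) that the CV-minimum penalty produces; ``"min"`` uses the
    CV-minimum penalty itself. Stage 2: ordinary least squares of the
    response on the selected features; its in-sample R^2 is the headline
    number (an empty selection gives R^2 = 0). The elastic net's
    cross-validated R^2 at the chosen penalty is reported alongside. When
    covariates are supplied, response and features are first residualised
    on them (partialling out).
    """
    idx = response.index
    n = len(idx)
    if n < 20:
        raise ValueError(f"need n >= 20 subjects, got {n}")
    if cv_folds > n:
        raise ValueError(f"cv_folds={cv_folds} exceeds n={n}")
    X = features.loc[idx].to_numpy(dtype=float)
    y = response.loc[idx].to_numpy(dtype=float)
    Z = _covariate_matrix(covariates, idx)
    if Z is not None:
        y = _residualize(y, Z)
        X = np.column_stack([_residualize(X[:, j], Z) for j in range(X.shape[1])])
    # standardize features so the penalty treats them symmetrically
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    if penalty_rule not in ("1se", "min"):
        raise ValueError("penalty_rule must be '1se' or 'min'")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, max_iter=10000, alphas=100)
        enet.fit(Xs, y)
        mse_mean = enet.mse_path_.mean(axis=1)
        alpha_idx = int(np.argmin(np.abs(enet.alphas_ - enet.alpha_)))
        if penalty_rule == "1se":
            mse_se = enet.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_folds)
            limit = mse_mean[alpha_idx] + mse_se[alpha_idx]
            # alphas_ are sorted descending: the first within-1-SE alpha is the sparsest
            alpha_idx = int(np.nonzero(mse_mean <= limit)[0][0])
            from sklearn.linear_model import ElasticNet

            refit = ElasticNet(alpha=float(enet.alphas_[alpha_idx]),
                               l1_ratio=l1_ratio, max_iter=10000)
            refit.fit(Xs, y)
            coef = refit.coef_
        else:
            coef = enet.coef_
    chosen_alpha = float(enet.alphas_[alpha_idx])
    selected = [features.columns[j] for j in np.nonzero(coef)[0]]
    cv_mse = float(mse_mean[alpha_idx])
    var_y = float(np.var(y))
    r2_cv = 1.0 - cv_mse / var_y if var_y > 0 else 0.0
    if not selected:
        return VarianceExplainedResult(measure, [], 0.0, r2_cv, {}, chosen_alpha)
    cols = [list(features.columns).index(f) for f in selected]
    ols = LinearRegression().fit(Xs[:, cols], y)
    r2 = float(ols.score(Xs[:, cols], y))
    coefs = {f: float(c) for f, c in zip(selected, ols.coef_)}
    return VarianceExplainedResult(measure, selected, r2, r2_cv, coefs, chosen_alpha)


@dataclass
class ResponderOddsResult:
    feature_id: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    separated: bool = False

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.odds_ratio) and not self.separated)


def responder_logistic(
    feature: pd.Series,
    classes: pd.Series,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
) -> ResponderOddsResult:
    """Logistic regression of HR/LR class on one baseline feature.

    The outcome is HR = 1, LR = 0. With ``standardize=True`` the feature
    is scaled to unit SD so the odds ratio is per SD of baseline
    abundance; Wald 95% CI. Complete separation is detected and flagged
    (``separated=True`` with non-finite estimates) rather than reported as
    a huge finite OR.
    """
    idx = classes.index
    y = (classes.loc[idx] == "HR").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both HR and LR classes must be non-empty")
    x = feature.loc[idx].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("feature has zero variance")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=0)
    cols = [x]
    if covariates is not None:
        Z = _covariate_matrix(covariates, idx)
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
    X = sm.add_constant(np.column_stack(cols))
    name = str(feature.name) if feature.name is not None else "feature"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        return ResponderOddsResult(name, np.nan, np.nan, np.nan, np.nan, separated=True)
    # separation shows up as runaway coefficients / standard errors
    if not converged or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        return ResponderOddsResult(name, np.nan, np.nan, np.nan, np.nan, separated=True)
    return ResponderOddsResult(
        feature_id=name,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=p,
    )


@dataclass
class GeeResult:
    feature_id: str
    coefficient: float
    robust_se: float
    p: float
    converged: bool = True

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.coefficient) and np.isfinite(self.robust_se) and self.converged)


def gee_longitudinal(
    feature: pd.Series,
    clinical: pd.Series,
    subjects: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> GeeResult:
    """GEE association between a microbial feature and a clinical measure.

    Observations are sample-level (subjects repeated across timepoints);
    the clinical measure is regressed on the feature (plus covariates)
    with Gaussian family, identity link, exchangeable working correlation
    and robust (sandwich) standard errors clustered by subject. With one
    observation per subject this reduces to ordinary least squares.
    """
    idx = clinical.index
    x = feature.loc[idx].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("feature has zero variance")
    cols = [x]
    if covariates is not None:
        Z = _covariate_matrix(covariates, idx)
        cols.extend(Z[:, j] for j in range(Z.shape[1]))
    X = sm.add_constant(np.column_stack(cols))
    groups = subjects.loc[idx].to_numpy()
    name = str(feature.name) if feature.name is not None else "feature"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                clinical.loc[idx].to_numpy(dtype=float),
                X,
                groups=groups,
                family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            fit = model.fit()
    except Exception:
        return GeeResult(name, np.nan, np.nan, np.nan, converged=False)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    ok = np.isfinite(coef) and np.isfinite(se)
    return GeeResult(name, coef, se, p, converged=bool(ok))
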