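"""Group-level statistics: cluster permutation tests, Mantel test, regressions.

Covers the cohort-level questions around fingerprinting: do PSDs differ
between segments of the same sleep stage (cluster-level permutation test on
per-frequency repeated-measures F values), do the two fingerprinting methods
agree on between-subject dissimilarity structure (Mantel test), and what
predicts per-subject differentiability (OLS with muscle-artifact, sex, age
and cap-size terms, Eq-4 style), plus the cubic total-power-vs-age fit with
robust standard errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sct

from .containers import (
    ClusterResult,
    DataError,
    NoiseCovariate,
    PairedDistanceMatrix,
    RegressionResult,
)


# --------------------------------------------------------------------------
# cluster-level permutation test
# --------------------------------------------------------------------------

def _rm_f_per_bin(data: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F across segments, per frequency bin.

    ``data`` is (n_subjects, n_segments, n_freqs).  Subject main effects are
    removed; F = MS_segment / MS_error with the usual (S-1), (S-1)(n-1) dfs.
    """
    n, S, _ = data.shape
    grand = data.mean(axis=(0, 1))
    seg_mean = data.mean(axis=0)        # (S, F)
    subj_mean = data.mean(axis=1)       # (n, F)
    ss_seg = n * ((seg_mean - grand) ** 2).sum(axis=0)
    resid = data - subj_mean[:, None, :] - seg_mean[None, :, :] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df_seg = S - 1
    df_err = (S - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_seg / df_seg) / (ss_err / df_err)
    f = np.nan_to_num(f, nan=0.0, posinf=0.0)
    # identical segments leave only rounding error in ss_seg; force F to zero
    floor = 1e-12 * n * S * float(np.mean(data**2))
    f[ss_seg < floor] = 0.0
    return f


def _clusters_above(f: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Contiguous runs of suprathreshold bins with their F mass."""
    above = f > threshold
    out = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            out.append((i, j, float(f[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def cluster_permutation_test(
    psd_by_segment: np.ndarray,
    freqs: np.ndarray,
    d1: int | None = None,
    d2: float | None = None,
    alpha_cluster: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Do channel-averaged PSDs differ between segments of a stage?

    ``psd_by_segment`` is (n_subjects, n_segments, n_freqs), a paired design
    (every subject contributes every segment).  Per bin, a repeated-measures
    F is thresholded at the upper ``alpha_cluster`` quantile of F(d1, d2);
    contiguous suprathreshold bins form clusters scored by summed F.  The
    null distribution of the maximum cluster mass comes from within-subject
    permutations of segment labels; p = (#null >= observed + 1)/(n_perm + 1).

    By default d1 = n_segments - 1 and d2 = n_subjects, the reference
    convention; pass d2 = (S-1)(n-1) for the textbook error df.
    """
    data = np.asarray(psd_by_segment, dtype=float)
    if data.ndim != 3:
        raise ValueError("psd_by_segment must be (subjects, segments, freqs)")
    n, S, F = data.shape
    if S < 2:
        raise ValueError("need at least 2 segments")
    d1 = S - 1 if d1 is None else d1
    d2 = float(n) if d2 is None else d2
    threshold = float(sct.f.ppf(1.0 - alpha_cluster, d1, d2))

    observed = _clusters_above(_rm_f_per_bin(data), threshold)
    if not observed:
        return ClusterResult(clusters=[], threshold_f=threshold, dfs=(d1, d2), n_permutations=n_perm)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    idx = np.arange(S)
    for b in range(n_perm):
        perm = np.empty_like(data)
        for i in range(n):
            perm[i] = data[i, rng.permutation(idx)]
        clusters = _clusters_above(_rm_f_per_bin(perm), threshold)
        null_max[b] = max((c[2] for c in clusters), default=0.0)

    out = []
    for start, stop, mass in observed:
        p = (np.sum(null_max >= mass) + 1.0) / (n_perm + 1.0)
        out.append(
            {
                "bins": (int(start), int(stop)),
                "freqs_hz": (float(freqs[start]), float(freqs[stop - 1])),
                "mass": mass,
                "p": float(p),
            }
        )
    return ClusterResult(clusters=out, threshold_f=threshold, dfs=(d1, d2), n_permutations=n_perm)


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------

def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    D1: PairedDistanceMatrix | np.ndarray,
    D2: PairedDistanceMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test of association between two paired matrices.

    Matrices are symmetrized (mean of (i,j) and (j,i)) and the Pearson
    correlation of their off-diagonal upper triangles is computed.  The null
    permutes rows and columns of the second matrix jointly; the test is
    one-sided for positive association with p = (#r_perm >= r + 1)/(n_perm+1).
    """
    a = np.asarray(D1.values if isinstance(D1, PairedDistanceMatrix) else D1, dtype=float)
    b = np.asarray(D2.values if isinstance(D2, PairedDistanceMatrix) else D2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if (
        isinstance(D1, PairedDistanceMatrix)
        and isinstance(D2, PairedDistanceMatrix)
        and D1.subject_order != D2.subject_order
    ):
        raise ValueError("subject order mismatch between matrices")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 subjects")
    a_sym = 0.5 * (a + a.T)
    b_sym = 0.5 * (b + b.T)
    va = _offdiag_upper(a_sym)
    if va.std() == 0 or _offdiag_upper(b_sym).std() == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")

    def corr_with(perm_b: np.ndarray) -> float:
        vb = _offdiag_upper(perm_b)
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr_with(b_sym)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(b_sym[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return r_obs, float(p)


# --------------------------------------------------------------------------
# regressions
# --------------------------------------------------------------------------

def emg_noise_covariate(cohort: pd.DataFrame, seg1: str, seg2: str) -> NoiseCovariate:
    """Per-subject |log RMS_seg1 - log RMS_seg2| muscle-artifact covariate."""
    cols = (f"emg_rms_{seg1}", f"emg_rms_{seg2}")
    for c in cols:
        if c not in cohort.columns:
            raise KeyError(f"cohort table lacks column {c!r}")
    r1 = cohort[cols[0]].to_numpy(dtype=float)
    r2 = cohort[cols[1]].to_numpy(dtype=float)
    bad = cohort["subject_id"][(r1 <= 0) | (r2 <= 0)]
    if len(bad):
        raise DataError(f"non-positive EMG RMS for subjects: {list(bad)}")
    vals = pd.Series(np.abs(np.log(r1) - np.log(r2)), index=cohort["subject_id"], name="noise")
    return NoiseCovariate(values=vals, segments=(seg1, seg2))


def _result_from_fit(fit, formula: str) -> RegressionResult:
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    fit_stats = {
        "r_squared": fit.rsquared,
        "adj_r_squared": fit.rsquared_adj,
        "f_statistic": fit.fvalue,
        "f_pvalue": fit.f_pvalue,
        "df_model": fit.df_model,
        "df_resid": fit.df_resid,
        "resid_se": np.sqrt(fit.mse_resid),
        "n_obs": fit.nobs,
    }
    return RegressionResult(coefficients=coef, fit_stats=fit_stats, formula=formula)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        r = np.linalg.qr(x, mode="r")
        diag = np.abs(np.diag(r))
        aliased = [
            str(design.columns[j])
            for j in np.flatnonzero(diag < 1e-10 * max(float(diag.max()), 1.0))
        ]
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased or 'unknown'}")


def differentiability_regression(
    scores: pd.Series,
    cohort: pd.DataFrame,
    noise: NoiseCovariate,
    include_age_sex_interaction: bool = False,
) -> RegressionResult:
    """OLS of differentiability on noise, sex, age, cap and noise x sex.

    Sex is coded with F as reference and cap with the small cap as
    reference, matching the published table layout.  The age x sex
    interaction is added for N1-sleep models.
    """
    df = cohort.set_index("subject_id")[["age", "sex", "cap"]].copy()
    df["score"] = pd.Series(scores).reindex(df.index)
    df["noise"] = noise.values.reindex(df.index)
    df = df.dropna()
    for factor in ("sex", "cap"):
        if df[factor].nunique() < 2:
            raise ValueError(
                f"rank-deficient design; aliased term(s): [{factor!r}] "
                f"(single level {df[factor].iloc[0]!r} in the cohort)"
            )
    formula = (
        "score ~ noise + C(sex, Treatment('F')) + age + C(cap, Treatment('small')) "
        "+ noise:C(sex, Treatment('F'))"
    )
    if include_age_sex_interaction:
        formula += " + age:C(sex, Treatment('F'))"
    model = smf.ols(formula, data=df)
    _check_full_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    fit = model.fit()
    result = _result_from_fit(fit, formula)
    result.coefficients.index = [
        name.replace("C(sex, Treatment('F'))[T.M]", "sex[M]")
        .replace("C(cap, Treatment('small'))[T.FT]", "cap[FT]")
        for name in result.coefficients.index
    ]
    return result


def auc_age_regression(auc: np.ndarray, age: np.ndarray, degree: int = 3) -> RegressionResult:
    """Polynomial (default cubic) OLS of PSD area under the curve on age.

    Uses heteroskedasticity-robust (HC3) standard errors, since pediatric
    power levels are strongly heteroskedastic across age.
    """
    auc = np.asarray(auc, dtype=float)
    age = np.asarray(age, dtype=float)
    if auc.size <= degree + 1:
        raise ValueError("need more observations than polynomial terms")
    if np.unique(age).size <= degree:
        raise ValueError("degenerate age values for the requested degree")
    df = pd.DataFrame({"auc": auc, "age": age})
    terms = " + ".join(f"I(age**{d})" if d > 1 else "age" for d in range(1, degree + 1))
    formula = f"auc ~ {terms}"
    fit = smf.ols(formula, data=df).fit(cov_type="HC3")
    return _result_from_fit(fit, formula)


def artifact_age_regression(noise: NoiseCovariate, age: np.ndarray) -> RegressionResult:
    """Simple OLS of the muscle-artifact log-ratio covariate on age."""
    df = pd.DataFrame({"noise": noise.values.to_numpy(dtype=float), "age": np.asarray(age, float)})
    fit = smf.ols("noise ~ age", data=df).fit()
    return _result_from_fit(fit, "noise ~ age")


def age_groups(ages: pd.Series, n_groups: int = 10) -> pd.Series:
    """Equal-size age groups by rank; ties broken by subject id order."""
    order = ages.rank(method="first").astype(int) - 1
    return (order * n_groups // len(ages)).astype(int)
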