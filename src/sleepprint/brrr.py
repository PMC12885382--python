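"""Latent-noise Bayesian reduced-rank regression (BRRR).

The generative model for the standardized feature matrix Y (n x s) given the
one-hot subject design X (n x p) is

    Y = (X Psi + Omega) Gamma + E,

with per-subject latent coefficients Psi (p x k), latent noise Omega (n x k)
entering through the same projection Gamma (k x s) as the signal, and
independent Gaussian residuals E with feature-specific variances Sigma.  The
low-rank coefficient matrix Theta = Psi Gamma is the regression target; rank
k << p, s is enforced by a multiplicative gamma-process shrinkage prior on
the rows of Gamma.  Inference is a Gibbs sampler over the fully conjugate
conditionals, initialized from Fisher's linear discriminant.

Fit quality is summarized by the proportion of total variance explained,
PTVE = tr(Cov(X Psi Gamma)) / tr(Cov(Y)), which deliberately excludes the
latent noise term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .containers import FeatureMatrix, LatentProjection, SubjectDesign


@dataclass
class BRRRConfig:
    """Sampler settings; defaults follow the reference analysis.

    ``latent_noise_sd`` is the prior scale of Omega entries (variance 0.01 by
    default): latent noise is assumed small so that the subject covariates
    explain most of the shared-subspace variation.
    """

    K: int = 30
    n_iter: int = 1000
    burn_in: int = 500
    latent_noise_sd: float = 0.1
    shrinkage_a1: float = 2.1
    shrinkage_a2: float = 3.1
    psi_prior_sd: float = 1.0
    sigma_prior_shape: float = 1.0
    sigma_prior_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class BRRRPosterior:
    """Retained Gibbs draws, point estimates, and diagnostics."""

    draws: dict              # keys psi, omega, gamma, sigma -> (T, ...) arrays
    posterior_mean: dict     # keys psi, omega, gamma, sigma, theta
    ptve_trace: np.ndarray   # PTVE per retained draw
    config: BRRRConfig
    subject_order: list[str] = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return self.draws["gamma"].shape[0]


def init_lda(Y, X, K: int, ridge: float = 1e-6) -> np.ndarray:
    """Initial Gamma (K x s) from Fisher's linear discriminant of subjects.

    The generalized eigenproblem of between- vs within-subject scatter
    (small ridge on the within scatter) yields the top-K discriminant axes;
    the returned Gamma is the least-squares map from the discriminant scores
    Y W back to feature space, so its rows span the between-subject signal
    subspace.  When K exceeds the number of discriminant directions
    (subjects - 1), the remaining rows are filled with the top
    right-singular vectors of the subject-centered residual.
    """
    Y = np.asarray(Y.values if isinstance(Y, FeatureMatrix) else Y, dtype=float)
    X = np.asarray(X.values if isinstance(X, SubjectDesign) else X, dtype=float)
    n, s = Y.shape
    p = X.shape[1]
    counts = X.sum(axis=0)
    if np.any(counts < 2):
        raise ValueError("every subject needs at least 2 observations for LDA")
    means = (X.T @ Y) / counts[:, None]
    grand = Y.mean(axis=0)
    within = Y - X @ means
    Sw = within.T @ within
    centered_means = means - grand
    Sb = (centered_means * counts[:, None]).T @ centered_means
    tr = np.trace(Sw)
    Sw_reg = Sw + (ridge * tr / s if tr > 0 else ridge) * np.eye(s)
    if tr == 0:
        warnings.warn("singular within-subject scatter; ridge-regularized LDA solve")

    k_lda = min(K, p - 1, s)
    vals, vecs = sla.eigh(Sb, Sw_reg)
    weights = vecs[:, np.argsort(vals)[::-1][:k_lda]]  # s x k discriminant axes
    scores = (Y - grand) @ weights
    directions, *_ = np.linalg.lstsq(scores, Y - grand, rcond=None)
    if K > k_lda:
        _, _, vt = np.linalg.svd(within, full_matrices=False)
        extra = vt[: K - k_lda]
        directions = np.vstack([directions, extra])
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    return directions / np.maximum(norms, 1e-300)


def _sample_mvn_batch(A: np.ndarray, b: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) for a batch of precision matrices.

    ``A`` is (..., k, k), ``b`` and ``z`` are (..., k); uses batched Cholesky.
    """
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b[..., None])[..., 0]
    Lt = np.swapaxes(L, -1, -2)
    return mean + np.linalg.solve(Lt, z[..., None])[..., 0]


def gibbs_fit(Y, X, config: BRRRConfig) -> BRRRPosterior:
    """Fit the latent-noise BRRR by Gibbs sampling.

    Cycles conjugate full-conditional updates for Psi, Omega, Gamma (normal),
    Sigma (inverse gamma) and the gamma-process shrinkage weights, retaining
    the post-burn-in draws.  Reproducible given ``config.seed``.
    """
    subject_order = X.subject_order if isinstance(X, SubjectDesign) else []
    Yv = np.asarray(Y.values if isinstance(Y, FeatureMatrix) else Y, dtype=float)
    Xv = np.asarray(X.values if isinstance(X, SubjectDesign) else X, dtype=float)
    n, s = Yv.shape
    p = Xv.shape[1]
    k = config.K
    rng = np.random.default_rng(config.seed)

    counts = Xv.sum(axis=0)
    y_colvar_total = float(np.sum(np.var(Yv, axis=0, ddof=1)))
    if y_colvar_total <= 0:
        raise ValueError("Y has zero total variance; PTVE and the fit are undefined")

    # initialization: LDA projection, least-squares Psi, flat shrinkage
    gamma = init_lda(Yv, Xv, k)
    subj_means = (Xv.T @ Yv) / counts[:, None]
    psi = subj_means @ np.linalg.pinv(gamma)
    omega = np.zeros((n, k))
    sigma2 = np.maximum(np.var(Yv - Xv @ (psi @ gamma), axis=0), 1e-6)
    delta = np.ones(k)
    tau = np.cumprod(delta)

    sig_om2 = config.latent_noise_sd**2
    psi_prec = 1.0 / config.psi_prior_sd**2
    a_sig, b_sig = config.sigma_prior_shape, config.sigma_prior_rate
    a1, a2 = config.shrinkage_a1, config.shrinkage_a2

    n_keep = config.n_iter - config.burn_in
    draws = {
        "psi": np.empty((n_keep, p, k)),
        "omega": np.empty((n_keep, n, k)),
        "gamma": np.empty((n_keep, k, s)),
        "sigma": np.empty((n_keep, s)),
    }
    ptve_trace = np.empty(n_keep)
    eye_k = np.eye(k)

    for it in range(config.n_iter):
        inv_s2 = 1.0 / sigma2
        g_is = gamma * inv_s2            # k x s
        gsg = g_is @ gamma.T             # k x k

        # --- Psi | Gamma, Sigma with Omega marginalized out -------------
        # Collapsing Omega (Woodbury on C = Sigma + sig_om2 * Gamma' Gamma)
        # removes the slow Psi/Omega trade-off direction from the chain.
        a0 = gsg + eye_k / sig_om2                      # D^-1 + Gamma Sigma^-1 Gamma'
        cinv_gt = np.linalg.solve(a0.T, g_is).T / sig_om2   # s x k = C^-1 Gamma'
        g_marg = gamma @ cinv_gt                        # k x k = Gamma C^-1 Gamma'
        g_marg = 0.5 * (g_marg + g_marg.T)
        b_psi = (Xv.T @ Yv) @ cinv_gt                   # p x k
        z = rng.standard_normal((p, k))
        psi = np.empty((p, k))
        for nj in np.unique(counts):
            rows = counts == nj
            A = nj * g_marg + psi_prec * eye_k
            psi[rows] = _sample_mvn_batch(A, b_psi[rows], z[rows])

        # --- Omega | rest: shared precision across rows -----------------
        resid2 = Yv - Xv @ (psi @ gamma)
        A_om = gsg + eye_k / sig_om2
        b_om = resid2 @ g_is.T           # n x k
        omega = _sample_mvn_batch(A_om, b_om, rng.standard_normal((n, k)))

        # --- Gamma | rest: per-feature conjugate normal -----------------
        M = Xv @ psi + omega             # n x k
        mtm = M.T @ M
        mty = M.T @ Yv                   # k x s
        A_g = mtm[None, :, :] * inv_s2[:, None, None] + np.diag(tau)[None, :, :]
        b_g = (mty * inv_s2).T           # s x k
        gamma = _sample_mvn_batch(A_g, b_g, rng.standard_normal((s, k))).T

        # --- Sigma | rest: inverse gamma per feature --------------------
        ss = ((Yv - M @ gamma) ** 2).sum(axis=0)
        sigma2 = 1.0 / rng.gamma(a_sig + 0.5 * n, 1.0 / (b_sig + 0.5 * ss))
        if not np.all(np.isfinite(sigma2)) or np.any(sigma2 <= 0):
            bad = np.flatnonzero(~np.isfinite(sigma2) | (sigma2 <= 0))
            raise RuntimeError(
                f"divergent residual variance at iteration {it}: features {bad[:10].tolist()}, "
                f"max |gamma|={np.abs(gamma).max():.3g}, max |psi|={np.abs(psi).max():.3g}"
            )

        # --- multiplicative gamma-process shrinkage on Gamma rows -------
        ssq = (gamma**2).sum(axis=1)
        for h in range(k):
            tau_wo = tau / delta[h]
            shape = (a1 if h == 0 else a2) + 0.5 * s * (k - h)
            rate = 1.0 + 0.5 * np.sum(tau_wo[h:] * ssq[h:])
            delta[h] = rng.gamma(shape, 1.0 / rate)
            tau = np.cumprod(delta)

        if it >= config.burn_in:
            t = it - config.burn_in
            draws["psi"][t] = psi
            draws["omega"][t] = omega
            draws["gamma"][t] = gamma
            draws["sigma"][t] = sigma2
            fitted = Xv @ (psi @ gamma)
            ptve_trace[t] = np.sum(np.var(fitted, axis=0, ddof=1)) / y_colvar_total

    theta_mean = np.mean(
        np.einsum("tpk,tks->tps", draws["psi"], draws["gamma"]), axis=0
    )
    posterior_mean = {
        "psi": draws["psi"].mean(axis=0),
        "omega": draws["omega"].mean(axis=0),
        "gamma": draws["gamma"].mean(axis=0),
        "sigma": draws["sigma"].mean(axis=0),
        "theta": theta_mean,
    }
    return BRRRPosterior(
        draws=draws,
        posterior_mean=posterior_mean,
        ptve_trace=ptve_trace,
        config=config,
        subject_order=list(subject_order),
    )


def ptve(fit, Y, X) -> float:
    """Proportion of total variance explained by the rank-K mean X Psi Gamma.

    ``fit`` may be a BRRRPosterior (posterior means are used) or an explicit
    (Psi, Gamma) pair.  Latent noise is excluded by construction.
    """
    if isinstance(fit, BRRRPosterior):
        theta = fit.posterior_mean["theta"]  # mean of per-draw products
    else:
        psi, gamma = fit
        theta = psi @ gamma
    Yv = np.asarray(Y.values if isinstance(Y, FeatureMatrix) else Y, dtype=float)
    Xv = np.asarray(X.values if isinstance(X, SubjectDesign) else X, dtype=float)
    denom = np.sum(np.var(Yv, axis=0, ddof=1))
    if denom <= 0:
        raise ValueError("Y has zero total variance; PTVE undefined")
    fitted = Xv @ theta
    return float(np.sum(np.var(fitted, axis=0, ddof=1)) / denom)


def convergence_diagnostics(
    posterior: BRRRPosterior, n_entries: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Split R-hat and bulk/tail ESS for randomly sampled entries of Theta.

    The single retained chain is split into two halves (split-R-hat); entries
    with ESS below 100 are flagged per the usual rule of thumb.
    """
    T = posterior.n_draws
    if T < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    import arviz as az

    psi_d, gamma_d = posterior.draws["psi"], posterior.draws["gamma"]
    p, s = psi_d.shape[1], gamma_d.shape[2]
    rng = np.random.default_rng(seed)
    flat = rng.choice(p * s, size=min(n_entries, p * s), replace=False)
    ii, jj = np.unravel_index(flat, (p, s))

    series = np.einsum("tmk,tkm->tm", psi_d[:, ii, :], gamma_d[:, :, jj])  # (T, m)
    half = T // 2
    chains = np.stack([series[:half], series[half : 2 * half]])  # (2, half, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chains)
        rhat = np.asarray(az.rhat(ds)["x"], dtype=float)
        ess_bulk = np.asarray(az.ess(ds, method="bulk")["x"], dtype=float)
        ess_tail = np.asarray(az.ess(ds, method="tail")["x"], dtype=float)
    # a constant chain has no information: ESS undefined, flag it
    degenerate = series.std(axis=0) == 0
    ess_bulk[degenerate] = 0.0
    ess_tail[degenerate] = 0.0
    rhat[degenerate] = np.nan
    table = pd.DataFrame(
        {
            "row": ii,
            "col": jj,
            "rhat": rhat,
            "ess_bulk": ess_bulk,
            "ess_tail": ess_tail,
        }
    )
    table["flagged"] = (
        ~np.isfinite(table[["ess_bulk", "ess_tail"]]).all(axis=1)
        | (table["ess_bulk"] < 100)
        | (table["ess_tail"] < 100)
    )
    posterior.diagnostics = table
    return table


def project_latent(Y_new, gamma: np.ndarray, row_meta: pd.DataFrame | None = None) -> LatentProjection:
    """Project observations into the latent space: coords = Y @ pinv(Gamma).

    The right pseudo-inverse gives least-squares reconstruction coordinates;
    a rank-deficient Gamma falls back to the minimum-norm solution with a
    warning.
    """
    if isinstance(Y_new, FeatureMatrix):
        if row_meta is None:
            row_meta = Y_new.row_meta
        Yv = Y_new.values
    else:
        Yv = np.asarray(Y_new, dtype=float)
    if Yv.shape[1] != gamma.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: Y has {Yv.shape[1]}, Gamma has {gamma.shape[1]}"
        )
    if np.linalg.matrix_rank(gamma) < gamma.shape[0]:
        warnings.warn("Gamma is rank deficient; using the minimum-norm projection")
    coords = Yv @ np.linalg.pinv(gamma)
    if row_meta is None:
        row_meta = pd.DataFrame(
            {"subject_id": [""] * coords.shape[0], "segment_label": [""] * coords.shape[0]}
        )
    return LatentProjection(coords=coords, row_meta=row_meta.copy(), gamma_used=gamma)


def select_k_elbow(
    Y, X, k_grid: list[int], eval_fn, min_gain: float = 0.01
) -> tuple[int, pd.DataFrame]:
    """Sweep latent dimensions and pick the elbow of the success-rate curve.

    ``eval_fn(K)`` must return ``(success_rate, ptve)`` for a fit at that K
    (typically whole-data fingerprinting at reduced iterations).  The elbow
    is the smallest K whose success-rate gain over the previous grid point
    falls below ``min_gain`` (1 percentage point by default); if the curve
    keeps rising, the best-performing K is returned.
    """
    if not k_grid:
        raise ValueError("k_grid must not be empty")
    if sorted(k_grid) != list(k_grid):
        raise ValueError("k_grid must be sorted ascending")
    rows = []
    for k in k_grid:
        rate, tve = eval_fn(k)
        rows.append({"K": k, "success_rate": rate, "ptve": tve})
    curve = pd.DataFrame(rows)
    chosen = k_grid[int(np.argmax(curve["success_rate"]))]
    for i in range(1, len(k_grid)):
        if curve["success_rate"][i] - curve["success_rate"][i - 1] < min_gain:
            chosen = k_grid[i - 1]
            break
    return chosen, curve


def save_posterior(posterior: BRRRPosterior, path) -> None:
    """Serialize draws, point estimates and config to a portable .npz archive."""
    import json

    payload = {f"draws_{k}": v for k, v in posterior.draws.items()}
    payload |= {f"mean_{k}": v for k, v in posterior.posterior_mean.items()}
    payload["ptve_trace"] = posterior.ptve_trace
    payload["config_json"] = np.array(json.dumps(vars(posterior.config)))
    payload["subject_order"] = np.array(posterior.subject_order)
    np.savez_compressed(path, **payload)


def load_posterior(path) -> BRRRPosterior:
    import json

    with np.load(path, allow_pickle=False) as npz:
        config = BRRRConfig(**json.loads(str(npz["config_json"])))
        draws = {k[6:]: npz[k] for k in npz.files if k.startswith("draws_")}
        means = {k[5:]: npz[k] for k in npz.files if k.startswith("mean_")}
        return BRRRPosterior(
            draws=draws,
            posterior_mean=means,
            ptve_trace=npz["ptve_trace"],
            config=config,
            subject_order=[str(x) for x in npz["subject_order"]],
        )
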