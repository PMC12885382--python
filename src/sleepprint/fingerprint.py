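"""Subject identification from paired data segments ("fingerprinting").

Two routes are implemented.  The BRRR route projects each subject's two
segments into the fitted latent space and matches subjects by minimum L1
distance; the correlation route matches segments by maximum Pearson
correlation computed on the full feature vectors without any dimensionality
reduction.  Both produce an N x N paired matrix whose diagonal holds the
self pairs; the success rate is the fraction of subjects whose own second
segment is the nearest match to their first, and the differentiability
score is the per-subject Z-score of the self pair against that subject's
pairs with everyone else (sign-flipped for distances so that larger always
means more distinct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brrr import BRRRConfig, BRRRPosterior, gibbs_fit, project_latent, ptve
from .containers import (
    DataError,
    FeatureMatrix,
    FingerprintReport,
    LatentProjection,
    PairedDistanceMatrix,
    SubjectDesign,
)
from .features import zscore_features


def l1_distances(proj_a: LatentProjection, proj_b: LatentProjection,
                 subject_order: list[str] | None = None) -> PairedDistanceMatrix:
    """Pairwise L1 distances between two sets of latent coordinates."""
    a, b = proj_a.coords, proj_b.coords
    if a.shape[1] != b.shape[1]:
        raise ValueError("latent dimensions differ between projections")
    order_a = list(proj_a.row_meta["subject_id"])
    order_b = list(proj_b.row_meta["subject_id"])
    if order_a != order_b:
        raise ValueError("subject order mismatch between projections")
    values = np.abs(a[:, None, :] - b[None, :, :]).sum(axis=2)
    return PairedDistanceMatrix(
        values=values,
        kind="l1_distance",
        row_segments=tuple(sorted(set(proj_a.row_meta.get("segment_label", [])))),
        col_segments=tuple(sorted(set(proj_b.row_meta.get("segment_label", [])))),
        subject_order=subject_order or order_a,
    )


def correlation_similarities(
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    subject_order: list[str],
    row_segments: tuple = (),
    col_segments: tuple = (),
) -> PairedDistanceMatrix:
    """Pearson correlations between all pairs of feature-vector rows."""
    a = np.asarray(rows_a, dtype=float)
    b = np.asarray(rows_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("row blocks must have identical shapes")
    sd_a = a.std(axis=1)
    sd_b = b.std(axis=1)
    for name, sd in (("a", sd_a), ("b", sd_b)):
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DataError(f"zero-variance feature row(s) in block {name}: {bad.tolist()}")
    ac = (a - a.mean(axis=1, keepdims=True)) / sd_a[:, None]
    bc = (b - b.mean(axis=1, keepdims=True)) / sd_b[:, None]
    values = (ac @ bc.T) / a.shape[1]
    return PairedDistanceMatrix(
        values=np.clip(values, -1.0, 1.0),
        kind="pearson_similarity",
        row_segments=row_segments,
        col_segments=col_segments,
        subject_order=list(subject_order),
    )


def success_rate(matrix: PairedDistanceMatrix) -> FingerprintReport:
    """Nearest-match identification: argmin per row for distances, argmax
    for similarities; a subject is correct when the self column wins.

    Ties are broken toward the lowest column index with a warning.
    """
    matrix.validate()
    v = matrix.values
    best = np.argmin(v, axis=1) if matrix.kind == "l1_distance" else np.argmax(v, axis=1)
    extreme = np.min(v, axis=1) if matrix.kind == "l1_distance" else np.max(v, axis=1)
    n_ties = int(np.sum(np.sum(v == extreme[:, None], axis=1) > 1))
    if n_ties:
        warnings.warn(f"{n_ties} row(s) had tied best matches; lowest index kept")
    correct = best == np.arange(v.shape[0])
    scores = (
        differentiability(matrix) if v.shape[0] >= 3 else np.full(v.shape[0], np.nan)
    )
    return FingerprintReport(
        success_rate=float(correct.mean()),
        n_subjects=v.shape[0],
        per_subject_correct=correct,
        differentiability=scores,
        method="brrr" if matrix.kind == "l1_distance" else "correlation",
        train_segments=matrix.row_segments,
        test_segments=matrix.col_segments,
    )


def differentiability(matrix: PairedDistanceMatrix) -> np.ndarray:
    """Per-subject Z-score of the self pair against same-row other pairs.

    For L1 distances the score is negated so that a smaller self distance
    yields a larger (better) score; for Pearson similarities the sign is
    kept.  The mean and sample SD (ddof 1) are taken over the N-1
    off-diagonal entries of the subject's row.
    """
    v = matrix.values
    n = v.shape[0]
    if n < 3:
        raise ValueError("differentiability needs at least 3 subjects")
    off = ~np.eye(n, dtype=bool)
    others = v[off].reshape(n, n - 1)
    mu = others.mean(axis=1)
    sd = others.std(axis=1, ddof=1)
    zero_sd = sd == 0
    if np.any(zero_sd):
        warnings.warn(
            f"zero spread of other-pair statistics for {int(zero_sd.sum())} subject(s); NaN score"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.diag(v) - mu) / np.where(zero_sd, np.nan, sd)
    return -z if matrix.kind == "l1_distance" else z


def _segment_pair(fm: FeatureMatrix, labels: tuple[str, str] | None) -> tuple[str, str]:
    """Resolve the (a, b) segment labels used for the self pair.

    Defaults to the first two same-stage labels present; with mixed-stage
    training data this keeps the self pair within one stage.
    """
    if labels is not None:
        return labels
    seen = list(dict.fromkeys(fm.row_meta["segment_label"]))
    stages = fm.row_meta.drop_duplicates("segment_label").set_index("segment_label")["stage"]
    for stage in dict.fromkeys(stages[lab] for lab in seen):
        of_stage = [lab for lab in seen if stages[lab] == stage]
        if len(of_stage) >= 2:
            return of_stage[0], of_stage[1]
    raise DataError("no stage contributes two segment labels; specify the pair explicitly")


def brrr_distance_matrix(
    features_std: FeatureMatrix,
    gamma: np.ndarray,
    subject_order: list[str],
    pair: tuple[str, str],
) -> PairedDistanceMatrix:
    """Project the two paired segments with Gamma and take L1 distances."""
    lab_a, lab_b = pair
    rows_a = features_std.rows_of(lab_a, subject_order)
    rows_b = features_std.rows_of(lab_b, subject_order)
    proj_a = project_latent(rows_a, gamma,
                            pd.DataFrame({"subject_id": subject_order, "segment_label": lab_a}))
    proj_b = project_latent(rows_b, gamma,
                            pd.DataFrame({"subject_id": subject_order, "segment_label": lab_b}))
    mat = l1_distances(proj_a, proj_b, subject_order=subject_order)
    mat.row_segments, mat.col_segments = (lab_a,), (lab_b,)
    return mat


def correlation_distance_matrix(
    features: FeatureMatrix, subject_order: list[str], pair: tuple[str, str]
) -> PairedDistanceMatrix:
    lab_a, lab_b = pair
    return correlation_similarities(
        features.rows_of(lab_a, subject_order),
        features.rows_of(lab_b, subject_order),
        subject_order,
        row_segments=(lab_a,),
        col_segments=(lab_b,),
    )


def whole_data_fingerprint(
    features: FeatureMatrix,
    design: SubjectDesign,
    config: BRRRConfig,
    train_labels: list[str] | None = None,
    pair: tuple[str, str] | None = None,
    methods: tuple[str, ...] = ("brrr", "correlation"),
) -> dict[str, FingerprintReport]:
    """Fit on all subjects and fingerprint the training segments themselves.

    ``features`` must be unstandardized; Z-scoring happens here so that both
    routes see their canonical inputs (standardized for BRRR, raw relative
    bandpowers for correlation).
    """
    train = features.select_labels(train_labels) if train_labels else features
    pair = _segment_pair(train, pair)
    subject_order = design.subject_order
    out: dict[str, FingerprintReport] = {}
    if "brrr" in methods:
        train_std = zscore_features(train)
        x_rows = _design_for(train_std, subject_order)
        posterior = gibbs_fit(train_std, x_rows, config)
        mat = brrr_distance_matrix(train_std, posterior.posterior_mean["gamma"],
                                   subject_order, pair)
        report = success_rate(mat)
        report.ptve = ptve(posterior, train_std, x_rows)
        report.train_segments = tuple(dict.fromkeys(train.row_meta["segment_label"]))
        report.test_segments = pair
        out["brrr"] = report
    if "correlation" in methods:
        mat = correlation_distance_matrix(train, subject_order, pair)
        report = success_rate(mat)
        report.train_segments = pair
        report.test_segments = pair
        out["correlation"] = report
    return out


def _design_for(fm: FeatureMatrix, subject_order: list[str]) -> SubjectDesign:
    """One-hot design aligned to a feature matrix's rows."""
    col = {sid: j for j, sid in enumerate(subject_order)}
    x = np.zeros((fm.n_obs, len(subject_order)))
    for i, sid in enumerate(fm.row_meta["subject_id"]):
        x[i, col[sid]] = 1.0
    keep = x.sum(axis=0) > 0
    order = [sid for sid, k in zip(subject_order, keep) if k]
    return SubjectDesign(values=x[:, keep], subject_order=order)


@dataclass
class CVReport:
    """10-fold cross-validated fingerprinting summary."""

    per_fold: pd.DataFrame
    mean_success_rate: float
    sd_success_rate: float
    mean_train_ptve: float
    mean_success_rate_correlation: float | None = None


def crossval_fingerprint(
    features: FeatureMatrix,
    design: SubjectDesign,
    config: BRRRConfig,
    folds: int = 10,
    seed: int = 0,
    pair: tuple[str, str] | None = None,
    include_correlation: bool = True,
) -> CVReport:
    """Subject-level K-fold cross-validation of fingerprinting accuracy.

    Folds partition subjects.  Per fold, the model is fitted on the training
    subjects' rows (Z-scored on the training fold), test subjects' segment
    pairs are projected with the trained Gamma, and the success rate is
    computed among test subjects only.  Training PTVE is recorded per fold.
    """
    subjects = np.array(design.subject_order)
    if folds > len(subjects):
        raise ValueError("more folds than subjects")
    pair = _segment_pair(features, pair)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    assignments = np.array_split(perm, folds)
    rows = []
    for f, test_idx in enumerate(assignments):
        if len(test_idx) < 2:
            raise ValueError(f"fold {f} has fewer than 2 subjects")
        test_subjects = set(subjects[test_idx])
        is_test = features.row_meta["subject_id"].isin(test_subjects).to_numpy()
        train_fm = FeatureMatrix(
            values=features.values[~is_test],
            row_meta=features.row_meta.loc[~is_test].reset_index(drop=True),
            feature_names=features.feature_names,
        )
        test_fm = FeatureMatrix(
            values=features.values[is_test],
            row_meta=features.row_meta.loc[is_test].reset_index(drop=True),
            feature_names=features.feature_names,
        )
        train_std, test_std = zscore_features(train_fm, test_fm)
        x_train = _design_for(train_std, list(subjects))
        fold_config = BRRRConfig(**{**vars(config), "seed": config.seed + f})
        posterior = gibbs_fit(train_std, x_train, fold_config)
        test_order = [s for s in subjects if s in test_subjects]
        mat = brrr_distance_matrix(test_std, posterior.posterior_mean["gamma"],
                                   test_order, pair)
        rep = success_rate(mat)
        row = {
            "fold": f,
            "n_test_subjects": len(test_order),
            "success_rate": rep.success_rate,
            "train_ptve": ptve(posterior, train_std, x_train),
        }
        if include_correlation:
            corr_rep = success_rate(correlation_distance_matrix(test_fm, test_order, pair))
            row["success_rate_correlation"] = corr_rep.success_rate
        rows.append(row)
    table = pd.DataFrame(rows)
    return CVReport(
        per_fold=table,
        mean_success_rate=float(table["success_rate"].mean()),
        sd_success_rate=float(table["success_rate"].std(ddof=1)),
        mean_train_ptve=float(table["train_ptve"].mean()),
        mean_success_rate_correlation=(
            float(table["success_rate_correlation"].mean()) if include_correlation else None
        ),
    )


def generalize(
    fitted: BRRRPosterior,
    features_std: FeatureMatrix,
    latent_train_segments: tuple[str, ...],
    fingerprint_segments: tuple[str, str],
    subject_order: list[str],
) -> FingerprintReport:
    """Fingerprint new segment pairs in a latent space trained on others.

    ``features_std`` must be standardized with the training parameters.
    Overlap between training and fingerprinting segments is allowed but
    flagged with a warning.
    """
    overlap = set(latent_train_segments) & set(fingerprint_segments)
    if overlap:
        warnings.warn(f"fingerprint segments overlap training segments: {sorted(overlap)}")
    mat = brrr_distance_matrix(
        features_std, fitted.posterior_mean["gamma"], subject_order, fingerprint_segments
    )
    report = success_rate(mat)
    report.train_segments = tuple(latent_train_segments)
    report.test_segments = tuple(fingerprint_segments)
    return report


def sweep_cohort_size(
    features: FeatureMatrix,
    design: SubjectDesign,
    config: BRRRConfig,
    sizes: list[int],
    replicates: int = 3,
    seed: int = 0,
    pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Success rate of both methods as a function of cohort size.

    For each size, subjects are subsampled ``replicates`` times and both
    methods' whole-data success rates recorded.
    """
    subjects = np.array(design.subject_order)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(subjects):
            raise ValueError(f"size {size} exceeds available subjects ({len(subjects)})")
        for rep in range(replicates):
            chosen = set(rng.choice(subjects, size=size, replace=False)) \
                if size < len(subjects) else set(subjects)
            mask = features.row_meta["subject_id"].isin(chosen).to_numpy()
            sub_fm = FeatureMatrix(
                values=features.values[mask],
                row_meta=features.row_meta.loc[mask].reset_index(drop=True),
                feature_names=features.feature_names,
            )
            sub_design = _design_for(sub_fm, list(subjects))
            reports = whole_data_fingerprint(sub_fm, sub_design, config, pair=pair)
            for method, rep_out in reports.items():
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "method": method,
                        "success_rate": rep_out.success_rate,
                        "ptve": rep_out.ptve,
                    }
                )
    return pd.DataFrame(rows)


def plot_latent_tsne(projection: LatentProjection, ax=None, perplexity: float = 15.0, seed: int = 0):
    """Optional 2-D t-SNE view of the latent coordinates (untested helper)."""
    from sklearn.manifold import TSNE
    import matplotlib.pyplot as plt

    emb = TSNE(
        n_components=2, perplexity=min(perplexity, max(2, projection.coords.shape[0] - 2)),
        random_state=seed, init="pca",
    ).fit_transform(projection.coords)
    if ax is None:
        _, ax = plt.subplots()
    subjects = pd.Categorical(projection.row_meta["subject_id"]).codes
    ax.scatter(emb[:, 0], emb[:, 1], c=subjects, cmap="tab20", s=18)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax
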