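"""End-to-end orchestration: simulate -> features -> fit -> fingerprint -> stats.

``run_pipeline`` executes the stages requested by a RunConfig, writes every
artifact with provenance (config hash, seed, package version) and returns a
JSON-serializable report.  The report contains no timestamps, so identical
configs and seeds produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import SEGMENT_LABELS, FeatureMatrix, SubjectDesign
from .features import build_matrices, define_bands, extract_features, psd_auc, zscore_features
from .fingerprint import (
    brrr_distance_matrix,
    correlation_distance_matrix,
    crossval_fingerprint,
    differentiability,
    whole_data_fingerprint,
)
from .brrr import gibbs_fit, ptve, convergence_diagnostics
from .groupstats import (
    artifact_age_regression,
    auc_age_regression,
    cluster_permutation_test,
    differentiability_regression,
    emg_noise_covariate,
    mantel_test,
)
from .synthdata import generate_cohort, simulate_recording

log = logging.getLogger("sleepprint")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def simulate_stage(config: RunConfig):
    """Generate the cohort and extract features subject by subject."""
    specs, cohort = generate_cohort(
        config.cohort.n_subjects, config.cohort.seed, config.cohort.generator
    )
    bands = define_bands()
    segments = []
    auc_rows = []
    for spec in specs:
        rec = simulate_recording(spec, seed=config.cohort.seed)
        segs = extract_features(rec, bands)
        segments.extend(segs)
        for seg in segs:
            auc_rows.append(
                {"subject_id": spec.subject_id, "segment_label": seg.segment_label,
                 "auc": psd_auc(seg, bands)}
            )
        log.info("simulated and featurized %s (age %.1f y)", spec.subject_id, spec.age)
    features, design = build_matrices(segments, list(SEGMENT_LABELS), bands)
    return cohort, segments, features, design, pd.DataFrame(auc_rows)


def _stats_stage(config, cohort, segments, features, design, brrr_mat, corr_mat, reports):
    stats_cfg = config.stats
    seed = config.cohort.seed
    freqs = segments[0].freqs
    out = {}

    # per-stage cluster permutation tests on channel-averaged PSDs
    for stage, labels in (("N1", ["N1a", "N1b"]), ("N2", ["N2a", "N2b", "N2c", "N2d"])):
        by_subject = {}
        for seg in segments:
            if seg.segment_label in labels:
                by_subject.setdefault(seg.subject_id, {})[seg.segment_label] = seg.psd.mean(axis=0)
        cube = np.stack(
            [np.stack([by_subject[sid][lab] for lab in labels]) for sid in design.subject_order]
        )
        res = cluster_permutation_test(
            cube, freqs, alpha_cluster=stats_cfg.cluster_alpha,
            n_perm=stats_cfg.n_perm_cluster, seed=seed,
        )
        out[f"cluster_{stage}"] = {
            "threshold_f": res.threshold_f,
            "dfs": list(res.dfs),
            "clusters": res.clusters,
        }

    # Mantel agreement between the two dissimilarity structures
    r, p = mantel_test(
        brrr_mat.values, -corr_mat.values, n_perm=stats_cfg.n_perm_mantel, seed=seed
    )
    out["mantel_brrr_vs_correlation"] = {"r": r, "p": p}

    # differentiability regressions (Eq-4 style), one per method
    pair = tuple(config.fingerprint.pair)
    noise = emg_noise_covariate(cohort, *pair)
    n1_model = pair[0].startswith("N1")
    for method, rep in reports.items():
        scores = pd.Series(rep.differentiability, index=design.subject_order)
        reg = differentiability_regression(
            scores, cohort, noise, include_age_sex_interaction=n1_model
        )
        out[f"differentiability_regression_{method}"] = reg.to_dict()
    out["artifact_age_regression"] = artifact_age_regression(
        noise, cohort["age"].to_numpy()
    ).to_dict()
    return out


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the configured stages and persist artifacts plus a JSON report."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.cohort.seed,
        }
    }

    stage = "simulate"
    try:
        cohort, segments, features, design, auc_table = simulate_stage(config)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        feat_df = pd.DataFrame(features.values, columns=features.feature_names)
        pd.concat([features.row_meta, feat_df], axis=1).to_csv(
            outdir / "features.csv", index=False
        )
        report["cohort"] = {
            "n_subjects": int(len(cohort)),
            "median_age": float(cohort["age"].median()),
            "fraction_under_5y": float((cohort["age"] < 5).mean()),
        }

        stage = "fingerprint"
        fp_cfg = config.fingerprint
        reports = whole_data_fingerprint(
            features, design, config.brrr,
            train_labels=list(fp_cfg.train_segments),
            pair=tuple(fp_cfg.pair),
            methods=tuple(fp_cfg.methods),
        )
        report["fingerprint"] = {m: r.to_dict() for m, r in reports.items()}
        if fp_cfg.run_cv:
            cv = crossval_fingerprint(
                features.select_labels(list(fp_cfg.train_segments)), design, config.brrr,
                folds=fp_cfg.folds, seed=config.cohort.seed, pair=tuple(fp_cfg.pair),
            )
            report["crossval"] = {
                "mean_success_rate_brrr": cv.mean_success_rate,
                "sd_success_rate_brrr": cv.sd_success_rate,
                "mean_train_ptve": cv.mean_train_ptve,
                "mean_success_rate_correlation": cv.mean_success_rate_correlation,
            }

        stage = "stats"
        if config.stats.enabled:
            train = features.select_labels(list(fp_cfg.train_segments))
            train_std = zscore_features(train)
            from .fingerprint import _design_for

            x_rows = _design_for(train_std, design.subject_order)
            posterior = gibbs_fit(train_std, x_rows, config.brrr)
            if posterior.n_draws >= 100:
                diag = convergence_diagnostics(posterior, seed=config.cohort.seed)
                report["diagnostics"] = {
                    "max_rhat": float(np.nanmax(diag["rhat"])),
                    "min_ess_bulk": float(np.nanmin(diag["ess_bulk"])),
                    "min_ess_tail": float(np.nanmin(diag["ess_tail"])),
                    "n_flagged": int(diag["flagged"].sum()),
                }
            else:
                report["diagnostics"] = {"skipped": "fewer than 100 retained draws"}
            brrr_mat = brrr_distance_matrix(
                train_std, posterior.posterior_mean["gamma"],
                design.subject_order, tuple(fp_cfg.pair),
            )
            corr_mat = correlation_distance_matrix(
                train, design.subject_order, tuple(fp_cfg.pair)
            )
            report["stats"] = _stats_stage(
                config, cohort, segments, features, design, brrr_mat, corr_mat, reports
            )
            # cubic total-power-vs-age regression on the first N2 segment
            auc_first = auc_table[auc_table["segment_label"] == fp_cfg.pair[0]]
            merged = auc_first.merge(cohort[["subject_id", "age"]], on="subject_id")
            report["stats"]["auc_age_regression"] = auc_age_regression(
                merged["auc"].to_numpy(), merged["age"].to_numpy()
            ).to_dict()
    except Exception as exc:  # persist partial output, then surface the stage
        (outdir / "report_partial.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise PipelineError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "summary.txt").write_text(_summarize(report))
    return report


def _summarize(report: dict) -> str:
    lines = ["sleepprint run summary", "======================"]
    prov = report["provenance"]
    lines.append(f"package {prov['package_version']}  config {prov['config_hash']}  seed {prov['seed']}")
    if "cohort" in report:
        c = report["cohort"]
        lines.append(
            f"cohort: {c['n_subjects']} subjects, median age {c['median_age']:.1f} y, "
            f"{100 * c['fraction_under_5y']:.0f}% under 5 y"
        )
    for method, rep in report.get("fingerprint", {}).items():
        ptve_txt = "" if rep["ptve"] is None else f", PTVE {rep['ptve']:.2f}"
        lines.append(
            f"{method}: success rate {rep['success_rate']:.2f}, "
            f"mean differentiability {rep['mean_differentiability']:.2f}{ptve_txt}"
        )
    if "crossval" in report:
        cv = report["crossval"]
        lines.append(
            f"10-fold CV: BRRR {cv['mean_success_rate_brrr']:.2f} "
            f"(corr {cv['mean_success_rate_correlation']:.2f}), "
            f"train PTVE {cv['mean_train_ptve']:.2f}"
        )
    if "diagnostics" in report and "max_rhat" in report["diagnostics"]:
        d = report["diagnostics"]
        lines.append(
            f"MCMC: max R-hat {d['max_rhat']:.3f}, min bulk ESS {d['min_ess_bulk']:.0f}, "
            f"{d['n_flagged']} flagged entries"
        )
    if "stats" in report:
        m = report["stats"].get("mantel_brrr_vs_correlation")
        if m:
            lines.append(f"Mantel BRRR vs correlation: r = {m['r']:.2f}, p = {m['p']:.3g}")
    return "\n".join(lines) + "\n"
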