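"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pytest

from sleepprint.brrr import BRRRConfig, gibbs_fit
from sleepprint.containers import SEGMENT_LABELS
from sleepprint.features import build_matrices, extract_features
from sleepprint.synthdata import generate_cohort, simulate_from_brrr, simulate_recording

#: The moderate-noise recovery scenario: 40 subjects x 2 segments, 60
#: features, true rank 4, latent sd 0.1, residual sd 0.5.
RECOVERY_SCENARIO = dict(
    n_subjects=40, segments_per_subject=2, s=60, k_true=4, noise_scales=(0.1, 0.5)
)
RECOVERY_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def recovery_fits():
    """Three seeded simulations of the recovery scenario with full fits."""
    out = []
    for seed in RECOVERY_SEEDS:
        Y, X, truth = simulate_from_brrr(seed=seed, **RECOVERY_SCENARIO)
        post = gibbs_fit(Y, X, BRRRConfig(K=4, n_iter=1000, burn_in=500, seed=seed + 100))
        out.append((Y, X, truth, post))
    return out


@pytest.fixture(scope="session")
def raw_cohort():
    """A 12-subject raw-signal cohort run through the feature pipeline."""
    specs, cohort = generate_cohort(12, seed=4)
    segments = []
    for spec in specs:
        segments.extend(extract_features(simulate_recording(spec, seed=4)))
    features, design = build_matrices(segments, list(SEGMENT_LABELS))
    return {
        "specs": specs,
        "cohort": cohort,
        "segments": segments,
        "features": features,
        "design": design,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
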