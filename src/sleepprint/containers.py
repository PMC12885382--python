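"""Shared data containers for the sleep-EEG fingerprinting pipeline.

The analysis passes a small set of typed arrays between modules: simulated
recordings, per-epoch PSD segments, the response matrix ``Y`` of relative
bandpowers, the one-hot subject design ``X``, and paired distance matrices
used for identification.  Containers are plain dataclasses wrapping numpy
arrays plus pandas metadata so that every module can stay functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: 19-channel subset of the international 10-20 montage shared by all caps.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Canonical 60-s epoch labels: two from N1 sleep, four from N2 sleep.
SEGMENT_LABELS = ("N1a", "N1b", "N2a", "N2b", "N2c", "N2d")

STAGE_OF_LABEL = {lab: ("N1" if lab.startswith("N1") else "N2") for lab in SEGMENT_LABELS}

#: Start minute of each canonical epoch within the 900-s recording
#: (N1 occupies minutes 0-4, N2 minutes 5-14).  N2a/N2b are subsequent
#: minutes early in N2; N2c/N2d are subsequent minutes late in N2, so the
#: pair N2a+N2d probes segments far apart in time.
SEGMENT_MINUTES = {"N1a": 0, "N1b": 1, "N2a": 5, "N2b": 6, "N2c": 13, "N2d": 14}

SAMPLING_RATE = 250.0
RECORDING_SECONDS = 900.0
N1_SECONDS = 300.0


class DataError(ValueError):
    """Raised when input data violate a pipeline precondition."""


@dataclass
class SleepRecording:
    """A single subject's 900-s multichannel sleep EEG (microvolts)."""

    subject_id: str
    sampling_rate: float
    channels: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples)
    stage_annotation: list[tuple[float, float, str]]  # (onset s, duration s, stage)
    emg_rms_by_segment: dict[str, float] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    def validate(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise DataError(f"{self.subject_id}: data must be (channels, samples)")
        if abs(self.duration - RECORDING_SECONDS) > 1.0 / self.sampling_rate:
            raise DataError(
                f"{self.subject_id}: expected {RECORDING_SECONDS:.0f} s, got {self.duration:.1f} s"
            )


@dataclass
class PSDSegment:
    """Welch PSD of one 60-s epoch: ``psd`` is (channels, frequencies)."""

    subject_id: str
    segment_label: str
    stage: str
    freqs: np.ndarray
    psd: np.ndarray


@dataclass
class BandDefinition:
    """13 half-open frequency bands [low, high) with linearly growing widths."""

    edges: np.ndarray  # 14 boundaries

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def total_width(self) -> float:
        return float(self.edges[-1] - self.edges[0])

    def as_dict(self) -> dict:
        return {"edges_hz": [float(e) for e in self.edges]}


@dataclass
class FeatureMatrix:
    """Response matrix Y: rows are subject-epochs, columns relative bandpowers.

    Column ordering is channel-major: channel 1 bands 1-13, channel 2 bands
    1-13, ...  With 19 channels and 13 bands, s = 247.
    """

    values: np.ndarray  # (n, s)
    row_meta: pd.DataFrame  # columns: subject_id, segment_label, stage
    feature_names: list[str]
    standardized: bool = False
    standardization_params: Optional[tuple[np.ndarray, np.ndarray]] = None  # (mean, sd)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subject_ids(self) -> list[str]:
        """Unique subject ids in row order of first appearance."""
        return list(dict.fromkeys(self.row_meta["subject_id"]))

    def select_labels(self, labels: list[str]) -> "FeatureMatrix":
        """Subset rows to the given segment labels (row order preserved)."""
        mask = self.row_meta["segment_label"].isin(list(labels)).to_numpy()
        return replace(
            self,
            values=self.values[mask],
            row_meta=self.row_meta.loc[mask].reset_index(drop=True),
        )

    def rows_of(self, label: str, subject_order: list[str]) -> np.ndarray:
        """Rows carrying one segment label, ordered to match ``subject_order``."""
        sub = self.row_meta.index[self.row_meta["segment_label"] == label]
        by_subject = {self.row_meta.loc[i, "subject_id"]: i for i in sub}
        missing = [s for s in subject_order if s not in by_subject]
        if missing:
            raise DataError(f"segment {label!r} missing for subjects: {missing}")
        idx = [by_subject[s] for s in subject_order]
        return self.values[idx]


@dataclass
class SubjectDesign:
    """One-hot covariate matrix X linking observations to subjects."""

    values: np.ndarray  # (n, p) of 0/1
    subject_order: list[str]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if not np.array_equal(self.values.sum(axis=1), np.ones(self.values.shape[0])):
            raise DataError("design matrix rows must contain exactly one 1")


@dataclass
class GroundTruth:
    """Known generative parameters for recovery tests."""

    psi: np.ndarray    # (p, k)
    gamma: np.ndarray  # (k, s)
    omega: np.ndarray  # (n, k)
    sigma: np.ndarray  # (s,) residual variances

    @property
    def theta(self) -> np.ndarray:
        return self.psi @ self.gamma


@dataclass
class LatentProjection:
    """Observations projected into the k-dimensional latent space Y @ pinv(Gamma)."""

    coords: np.ndarray  # (n, k)
    row_meta: pd.DataFrame
    gamma_used: np.ndarray


@dataclass
class PairedDistanceMatrix:
    """Subject-by-subject statistic between one segment (rows) and another (cols).

    Entry (i, j) compares subject i's row-segment against subject j's
    column-segment; the diagonal holds the self pairs.
    """

    values: np.ndarray
    kind: str  # "l1_distance" | "pearson_similarity"
    row_segments: tuple[str, ...]
    col_segments: tuple[str, ...]
    subject_order: list[str]

    def validate(self) -> None:
        n = len(self.subject_order)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape must match subject order")
        if self.kind == "l1_distance" and np.any(self.values < 0):
            raise DataError("L1 distances must be non-negative")
        if self.kind == "pearson_similarity" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise DataError("Pearson similarities must lie in [-1, 1]")


@dataclass
class FingerprintReport:
    """Identification outcome for one fingerprinting task."""

    success_rate: float
    n_subjects: int
    per_subject_correct: np.ndarray
    differentiability: np.ndarray
    method: str  # "brrr" | "correlation"
    train_segments: tuple[str, ...] = ()
    test_segments: tuple[str, ...] = ()
    ptve: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "success_rate": float(self.success_rate),
            "n_subjects": int(self.n_subjects),
            "mean_differentiability": float(np.nanmean(self.differentiability)),
            "train_segments": list(self.train_segments),
            "test_segments": list(self.test_segments),
            "ptve": None if self.ptve is None else float(self.ptve),
        }


@dataclass
class RegressionResult:
    """OLS output shaped like the published regression tables."""

    coefficients: pd.DataFrame  # index term; columns estimate, se, t, ci_low, ci_high, p
    fit_stats: dict
    formula: str

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "coefficients": self.coefficients.to_dict(orient="index"),
            "fit_stats": {k: (None if v is None else float(v)) for k, v in self.fit_stats.items()},
        }


@dataclass
class NoiseCovariate:
    """Per-subject |log RMS_seg1 - log RMS_seg2| muscle-artifact covariate."""

    values: pd.Series  # index subject_id
    segments: tuple[str, str]


@dataclass
class ClusterResult:
    """Cluster-level permutation-test outcome over frequency bins."""

    clusters: list[dict]  # {"bins": (start, stop), "freqs_hz": (lo, hi), "mass": m, "p": p}
    threshold_f: float
    dfs: tuple[float, float]
    n_permutations: int

    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)
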