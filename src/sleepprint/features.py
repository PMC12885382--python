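"""Spectral feature extraction: band-pass, epoching, Welch PSDs, bandpowers.

Each recording is band-pass filtered to 1-45 Hz, cut into 60-s epochs, and
six canonical epochs (two N1, four N2) are retained.  Per epoch, a Welch PSD
(Hamming window, nfft = 1024 at 250 Hz, ~0.244 Hz resolution) is computed per
channel, and 13 relative bandpowers per channel form the feature vector of
length s = 19 x 13 = 247.  Relative power removes per-channel amplitude
scaling (e.g., skull-related), so features describe spectral *shape*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    CHANNELS_1020,
    SAMPLING_RATE,
    SEGMENT_LABELS,
    SEGMENT_MINUTES,
    STAGE_OF_LABEL,
    BandDefinition,
    DataError,
    FeatureMatrix,
    PSDSegment,
    SleepRecording,
    SubjectDesign,
)

EPOCH_SECONDS = 60.0
WELCH_NFFT = 1024
BANDPASS = (1.0, 45.0)

# 14 edges -> 13 bands; widths grow by exactly 0.2 Hz and sum to 41.6 Hz.
_BAND_EDGES = (1.0, 3.0, 5.2, 7.6, 10.2, 13.0, 16.0, 19.2, 22.6, 26.2, 30.0, 34.0, 38.2, 42.6)


def define_bands() -> BandDefinition:
    """The 13 analysis bands from 1 to 42.6 Hz with linearly widening widths."""
    return BandDefinition(edges=np.asarray(_BAND_EDGES))


@dataclass
class Epoch:
    """One 60-s multichannel epoch cut from a filtered recording."""

    subject_id: str
    segment_label: str
    stage: str
    data: np.ndarray  # (channels, samples)
    sampling_rate: float


def bandpass_filter(data: np.ndarray, sfreq: float) -> np.ndarray:
    """Zero-phase FIR band-pass at 1-45 Hz with 0.5 Hz transition bands."""
    import mne

    return mne.filter.filter_data(
        np.asarray(data, dtype=np.float64),
        sfreq=sfreq,
        l_freq=BANDPASS[0],
        h_freq=BANDPASS[1],
        l_trans_bandwidth=0.5,
        h_trans_bandwidth=0.5,
        fir_design="firwin",
        verbose="error",
    )


def bandpass_and_epoch(recording: SleepRecording) -> list[Epoch]:
    """Filter a 900-s recording and return the six canonical 60-s epochs.

    Epochs are labeled N1a, N1b (minutes 0 and 1 of the N1 block) and
    N2a, N2b, N2c, N2d (minutes 0, 1, 8, 9 of the N2 block), in
    chronological order.
    """
    recording.validate()
    sfreq = recording.sampling_rate
    n_epoch = int(EPOCH_SECONDS * sfreq)
    if recording.data.shape[1] < 15 * n_epoch:
        raise DataError(
            f"recording of subject {recording.subject_id!r} too short for 6 canonical epochs"
        )
    filtered = bandpass_filter(recording.data, sfreq)
    epochs = []
    for label in SEGMENT_LABELS:
        start = int(SEGMENT_MINUTES[label] * EPOCH_SECONDS * sfreq)
        epochs.append(
            Epoch(
                subject_id=recording.subject_id,
                segment_label=label,
                stage=STAGE_OF_LABEL[label],
                data=filtered[:, start : start + n_epoch],
                sampling_rate=sfreq,
            )
        )
    return epochs


def welch_psd(epoch: Epoch) -> PSDSegment:
    """Welch PSD of one 60-s epoch (Hamming window, nfft=1024, 50% overlap)."""
    if abs(epoch.sampling_rate - SAMPLING_RATE) > 1e-9:
        raise ValueError(f"expected sampling rate {SAMPLING_RATE} Hz, got {epoch.sampling_rate}")
    n_expected = int(EPOCH_SECONDS * SAMPLING_RATE)
    if epoch.data.shape[1] != n_expected:
        raise ValueError(f"expected {n_expected}-sample epochs, got {epoch.data.shape[1]}")
    freqs, psd = sps.welch(
        epoch.data,
        fs=SAMPLING_RATE,
        window="hamming",
        nperseg=WELCH_NFFT,
        noverlap=WELCH_NFFT // 2,
        nfft=WELCH_NFFT,
        detrend=False,
        axis=-1,
    )
    return PSDSegment(
        subject_id=epoch.subject_id,
        segment_label=epoch.segment_label,
        stage=epoch.stage,
        freqs=freqs,
        psd=psd,
    )


def _band_integrals(freqs: np.ndarray, psd: np.ndarray, bands: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of PSD rows over each band, with exact edge interpolation."""
    psd = np.atleast_2d(psd)
    out = np.empty((psd.shape[0], bands.n_bands))
    for b in range(bands.n_bands):
        lo, hi = bands.edges[b], bands.edges[b + 1]
        inside = (freqs > lo) & (freqs < hi)
        grid = np.concatenate(([lo], freqs[inside], [hi]))
        for c in range(psd.shape[0]):
            vals = np.interp(grid, freqs, psd[c])
            out[c, b] = np.trapezoid(vals, grid)
    return out


def relative_bandpower(segment: PSDSegment, bands: BandDefinition | None = None) -> np.ndarray:
    """Per-channel relative bandpowers, flattened channel-major (length 247).

    Band power is the trapezoidal integral of the PSD over [low, high);
    relative power divides by the sum of the 13 band powers of the same
    channel, so each channel's 13 values sum to one.
    """
    bands = bands or define_bands()
    if segment.freqs[0] > bands.edges[0] or segment.freqs[-1] < bands.edges[-1]:
        raise ValueError("PSD grid does not cover the 1-42.6 Hz analysis range")
    power = _band_integrals(segment.freqs, segment.psd, bands)
    totals = power.sum(axis=1)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        raise DataError(
            f"subject {segment.subject_id!r} segment {segment.segment_label!r}: "
            f"zero total power in channel(s) {dead.tolist()}"
        )
    return (power / totals[:, None]).ravel()


def psd_auc(segment: PSDSegment, bands: BandDefinition | None = None) -> float:
    """Area under the channel-averaged PSD over the 1-42.6 Hz analysis range."""
    bands = bands or define_bands()
    mean_psd = segment.psd.mean(axis=0, keepdims=True)
    lo, hi = bands.edges[0], bands.edges[-1]
    inside = (segment.freqs > lo) & (segment.freqs < hi)
    grid = np.concatenate(([lo], segment.freqs[inside], [hi]))
    vals = np.interp(grid, segment.freqs, mean_psd[0])
    return float(np.trapezoid(vals, grid))


def feature_names(channels=CHANNELS_1020, bands: BandDefinition | None = None) -> list[str]:
    bands = bands or define_bands()
    return [
        f"{ch}_band{b + 1:02d}_{bands.edges[b]:g}-{bands.edges[b + 1]:g}Hz"
        for ch in channels
        for b in range(bands.n_bands)
    ]


def build_matrices(
    segments: list[PSDSegment],
    segment_labels_used: list[str],
    bands: BandDefinition | None = None,
) -> tuple[FeatureMatrix, SubjectDesign]:
    """Assemble the response Y and one-hot design X from PSD segments.

    Rows are ordered by (subject, position of label in ``segment_labels_used``);
    every subject must contribute each requested label exactly once.
    """
    bands = bands or define_bands()
    wanted = [s for s in segments if s.segment_label in segment_labels_used]
    by_subject: dict[str, dict[str, PSDSegment]] = {}
    for seg in wanted:
        slot = by_subject.setdefault(seg.subject_id, {})
        if seg.segment_label in slot:
            raise DataError(
                f"duplicate segment {seg.segment_label!r} for subject {seg.subject_id!r}"
            )
        slot[seg.segment_label] = seg
    subject_order = sorted(by_subject)
    missing = {
        sid: sorted(set(segment_labels_used) - set(have))
        for sid, have in by_subject.items()
        if set(segment_labels_used) - set(have)
    }
    if missing:
        raise DataError(f"missing segments: {missing}")

    rows, meta = [], []
    for sid in subject_order:
        for label in segment_labels_used:
            seg = by_subject[sid][label]
            rows.append(relative_bandpower(seg, bands))
            meta.append((sid, label, seg.stage))
    values = np.vstack(rows)
    row_meta = pd.DataFrame(meta, columns=["subject_id", "segment_label", "stage"])
    n_channels = wanted[0].psd.shape[0]
    names = feature_names(channels=[f"ch{c:02d}" for c in range(n_channels)], bands=bands) \
        if n_channels != len(CHANNELS_1020) else feature_names(bands=bands)
    fm = FeatureMatrix(values=values, row_meta=row_meta, feature_names=names)

    design = np.zeros((len(rows), len(subject_order)))
    col = {sid: j for j, sid in enumerate(subject_order)}
    for i, (sid, _, _) in enumerate(meta):
        design[i, col[sid]] = 1.0
    return fm, SubjectDesign(values=design, subject_order=subject_order)


def extract_features(
    recording: SleepRecording, bands: BandDefinition | None = None
) -> list[PSDSegment]:
    """Recording -> six canonical PSD segments (band-pass, epoch, Welch)."""
    return [welch_psd(ep) for ep in bandpass_and_epoch(recording)]


def zscore_features(
    train: FeatureMatrix,
    apply_to: FeatureMatrix | None = None,
    eps: float = 1e-12,
) -> FeatureMatrix | tuple[FeatureMatrix, FeatureMatrix]:
    """Z-score columns of the training matrix; reuse its parameters elsewhere.

    Columns with zero variance get an ``eps`` floor on the SD (with a
    warning) so the transform stays finite.
    """
    if train.n_obs < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance feature column(s); using eps floor")
        sd = np.where(zero, eps, sd)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            values=(fm.values - mean) / sd,
            row_meta=fm.row_meta.copy(),
            feature_names=list(fm.feature_names),
            standardized=True,
            standardization_params=(mean, sd),
        )

    train_std = _apply(train)
    if apply_to is None:
        return train_std
    return train_std, _apply(apply_to)
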