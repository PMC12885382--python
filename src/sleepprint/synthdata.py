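"""Synthetic pediatric sleep-EEG cohorts and direct generative-model draws.

Two generators live here.  ``generate_cohort``/``simulate_recording`` build
raw 19-channel, 250 Hz, 900-s recordings whose spectra carry the structure
the analysis assumes: a 1/f^chi aperiodic background whose total power rises
then falls with age, an alpha-range peak drifting upward with maturation, a
12-15 Hz spindle peak that is stronger in N2 than in N1 sleep, per-segment
EMG-like high-frequency noise, and stable per-subject spectral
idiosyncrasies that make individuals identifiable.  ``simulate_from_brrr``
draws feature matrices directly from the latent-noise reduced-rank
regression model Y = (X Psi + Omega) Gamma + E with known parameters, for
parameter-recovery tests.

All randomness flows through numpy SeedSequences keyed by (cohort seed,
subject index), so per-subject parameters are reproducible independently of
cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CHANNELS_1020,
    SAMPLING_RATE,
    SEGMENT_LABELS,
    SEGMENT_MINUTES,
    FeatureMatrix,
    GroundTruth,
    SleepRecording,
    SubjectDesign,
)

_N_CHANNELS = len(CHANNELS_1020)
_MINUTES = 15
_MINUTE_SAMPLES = int(60 * SAMPLING_RATE)

#: Fixed EMG spatial profile: muscle activity loads mostly on fronto-temporal
#: electrodes.  Normalized below to unit mean-square.
_EMG_TOPO = np.array(
    [2.0, 2.0, 1.8, 1.2, 0.8, 1.2, 1.8, 1.6, 0.6, 0.4, 0.6, 1.6, 1.0, 0.5, 0.3, 0.5, 1.0, 0.6, 0.6]
)
_EMG_TOPO = _EMG_TOPO / np.sqrt(np.mean(_EMG_TOPO**2))


@dataclass
class Peak:
    """A Gaussian spectral bump with per-stage gain."""

    center: float      # Hz
    bandwidth: float   # Hz (Gaussian sd)
    amplitude: float   # PSD units at the peak, before channel profiles
    stage_gain: dict   # {"N1": g1, "N2": g2}


@dataclass
class SubjectSpec:
    """Everything needed to simulate one subject's recording."""

    subject_id: str
    age: float
    sex: str   # "F" | "M"
    cap: str   # "small" | "FT"
    aperiodic_offset: float     # log10 PSD at 1 Hz
    aperiodic_exponent: float
    peaks: list[Peak]
    channel_gain: np.ndarray            # (19,) multiplicative amplitude factors
    peak_channel_profile: np.ndarray    # (n_peaks, 19) per-peak spatial pattern
    emg_by_segment: dict                # canonical label -> target RMS (uV)
    emg_base: float                     # RMS scale for non-canonical minutes
    idiosyncrasy_seed: int
    wake_contamination: float = 0.0


@dataclass
class CohortConfig:
    """Generator parameters; defaults define the study conditions.

    Ages follow a right-skewed gamma (majority under 5 y); total power has an
    inverted-U age profile; the spindle peak grows with age and is always
    stronger in N2 than N1.  ``idiosyncrasy`` scales every stable per-subject
    deviation; setting it to zero (together with the age couplings, see
    ``exchangeable``) makes subjects statistically exchangeable.
    """

    # age distribution (years)
    age_shape: float = 1.15
    age_scale: float = 4.0
    age_min: float = 0.1
    age_max: float = 19.0
    # aperiodic background: log10 PSD offset with inverted-U age profile
    offset_base: float = 0.5
    offset_age_amp: float = 1.0
    offset_age_peak: float = 2.5
    exponent_base: float = 1.8
    exponent_age_slope: float = 0.35
    exponent_min: float = 0.8
    exponent_max: float = 2.0
    # spindle peak (12-15 Hz, N2 > N1 by construction)
    spindle_center: float = 13.5
    spindle_center_jitter: float = 0.8
    spindle_bw: float = 0.7
    spindle_amp: float = 6.0
    spindle_age_tau: float = 2.0
    spindle_n1_gain: tuple = (0.10, 0.35)
    # alpha-range peak drifting upward with age
    alpha_center_base: float = 6.0
    alpha_center_age_gain: float = 4.0
    alpha_center_jitter: float = 0.5
    alpha_bw: float = 1.2
    alpha_amp: float = 4.0
    # idiosyncrasy scales (all multiplied by `idiosyncrasy`)
    idiosyncrasy: float = 1.0
    channel_gain_sd: float = 0.25
    peak_channel_sd: float = 0.35
    peak_amp_sd: float = 0.30
    exponent_sd: float = 0.15
    offset_sd: float = 0.20
    # EMG artifact
    emg_level: float = 1.0
    emg_age_slope: float = -0.02
    emg_jitter_sd: float = 0.40
    wake_contamination: float = 0.0

    def exchangeable(self) -> "CohortConfig":
        """A null configuration: no idiosyncrasy, no age-linked spectra."""
        return replace(
            self,
            idiosyncrasy=0.0,
            offset_age_amp=0.0,
            exponent_age_slope=0.0,
            alpha_center_age_gain=0.0,
            spindle_age_tau=np.inf,
            emg_age_slope=0.0,
        )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _spindle_age_factor(age: float, tau: float) -> float:
    # grows from 0.25 toward 1 with maturation; constant when tau is inf
    return 0.25 + 0.75 * (0.0 if np.isinf(tau) else 1.0 - np.exp(-age / tau))


def generate_cohort(
    n_subjects: int, seed: int, config: CohortConfig | None = None
) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw a reproducible cohort of subject specs plus its covariate table.

    Returns the specs and a CohortTable with one row per subject: id, age,
    sex, cap size, and the target EMG RMS of each canonical segment.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    config = config or CohortConfig()
    idio = config.idiosyncrasy
    specs, rows = [], []
    for i in range(n_subjects):
        rng = _subject_rng(seed, i)
        sid = f"S{i + 1:04d}"
        age = float(
            np.clip(rng.gamma(config.age_shape, config.age_scale), config.age_min, config.age_max)
        )
        sex = "F" if rng.random() < 0.5 else "M"
        cap = "small" if age < 5.0 else "FT"

        a = age / config.offset_age_peak
        offset = (
            config.offset_base
            + config.offset_age_amp * a * np.exp(1.0 - a)
            + idio * config.offset_sd * rng.standard_normal()
        )
        exponent = float(
            np.clip(
                config.exponent_base
                - config.exponent_age_slope * np.log1p(age)
                + idio * config.exponent_sd * rng.standard_normal(),
                config.exponent_min,
                config.exponent_max,
            )
        )

        spindle_center = float(
            np.clip(
                config.spindle_center
                + idio * config.spindle_center_jitter * rng.standard_normal(),
                12.2,
                14.8,
            )
        )
        spindle_amp = (
            config.spindle_amp
            * _spindle_age_factor(age, config.spindle_age_tau)
            * np.exp(idio * config.peak_amp_sd * rng.standard_normal())
        )
        n1_gain = float(rng.uniform(*config.spindle_n1_gain))
        spindle = Peak(spindle_center, config.spindle_bw, spindle_amp, {"N1": n1_gain, "N2": 1.0})

        alpha_center = (
            config.alpha_center_base
            + config.alpha_center_age_gain * (1.0 - np.exp(-age / 4.0))
            + idio * config.alpha_center_jitter * rng.standard_normal()
        )
        alpha_amp = config.alpha_amp * np.exp(idio * config.peak_amp_sd * rng.standard_normal())
        alpha = Peak(float(alpha_center), config.alpha_bw, alpha_amp, {"N1": 1.0, "N2": 1.0})

        peaks = [alpha, spindle]
        channel_gain = np.exp(idio * config.channel_gain_sd * rng.standard_normal(_N_CHANNELS))
        peak_profile = np.exp(
            idio * config.peak_channel_sd * rng.standard_normal((len(peaks), _N_CHANNELS))
        )

        emg_base = config.emg_level * np.exp(config.emg_age_slope * age)
        emg_by_segment = {
            lab: float(emg_base * rng.lognormal(0.0, config.emg_jitter_sd))
            for lab in SEGMENT_LABELS
        }

        specs.append(
            SubjectSpec(
                subject_id=sid,
                age=age,
                sex=sex,
                cap=cap,
                aperiodic_offset=float(offset),
                aperiodic_exponent=exponent,
                peaks=peaks,
                channel_gain=channel_gain,
                peak_channel_profile=peak_profile,
                emg_by_segment=emg_by_segment,
                emg_base=float(emg_base),
                idiosyncrasy_seed=int(rng.integers(0, 2**31 - 1)),
                wake_contamination=config.wake_contamination,
            )
        )
        rows.append(
            {"subject_id": sid, "age": age, "sex": sex, "cap": cap}
            | {f"emg_rms_{lab}": emg_by_segment[lab] for lab in SEGMENT_LABELS}
        )
    return specs, pd.DataFrame(rows)


def _block_psd(spec: SubjectSpec, freqs: np.ndarray, stage: str, wake: bool) -> np.ndarray:
    """Target one-sided PSD (channels x freqs) for one 60-s block."""
    f_safe = np.maximum(freqs, 0.5)
    background = 10.0**spec.aperiodic_offset / f_safe**spec.aperiodic_exponent
    psd = np.tile(background, (_N_CHANNELS, 1))
    for p, peak in enumerate(spec.peaks):
        gain = peak.stage_gain.get(stage, 1.0) * (0.2 if wake else 1.0)
        bump = peak.amplitude * gain * np.exp(
            -((freqs - peak.center) ** 2) / (2.0 * peak.bandwidth**2)
        )
        psd += spec.peak_channel_profile[p][:, None] * bump[None, :]
    psd *= (spec.channel_gain**2)[:, None]
    psd[:, freqs == 0] = 0.0
    return psd


def simulate_recording(spec: SubjectSpec, seed: int) -> SleepRecording:
    """Simulate one 900-s recording by exact frequency-domain shaping.

    Each 60-s block is the inverse FFT of complex Gaussian spectra matching
    the block's target PSD (background + stage-gained peaks), plus a
    broadband 20-120 Hz EMG component scaled to the spec's per-segment RMS.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), spec.idiosyncrasy_seed)))
    freqs = np.fft.rfftfreq(_MINUTE_SAMPLES, 1.0 / SAMPLING_RATE)
    emg_band = (freqs >= 20.0) & (freqs <= 120.0)
    minute_to_label = {m: lab for lab, m in SEGMENT_MINUTES.items()}

    blocks = []
    emg_rms_by_segment = {}
    for minute in range(_MINUTES):
        stage = "N1" if minute * 60 < 300 else "N2"
        wake = bool(rng.random() < spec.wake_contamination)
        target = _block_psd(spec, freqs, stage, wake)
        scale = np.sqrt(target * SAMPLING_RATE * _MINUTE_SAMPLES / 4.0)
        z = rng.standard_normal((_N_CHANNELS, freqs.size)) + 1j * rng.standard_normal(
            (_N_CHANNELS, freqs.size)
        )
        spectrum = scale * z
        spectrum[:, 0] = 0.0
        spectrum[:, -1] = spectrum[:, -1].real
        neural = np.fft.irfft(spectrum, n=_MINUTE_SAMPLES, axis=1)

        label = minute_to_label.get(minute)
        target_rms = spec.emg_by_segment[label] if label else spec.emg_base
        if target_rms > 0:
            raw = rng.standard_normal((1, freqs.size)) + 1j * rng.standard_normal((1, freqs.size))
            raw[:, ~emg_band] = 0.0
            emg_wave = np.fft.irfft(raw, n=_MINUTE_SAMPLES, axis=1)[0]
            emg_wave /= np.sqrt(np.mean(emg_wave**2))
            emg = _EMG_TOPO[:, None] * (target_rms * emg_wave)[None, :]
            realized = float(np.sqrt(np.mean(emg**2)))
        else:
            emg = 0.0
            realized = 0.0
        if label:
            emg_rms_by_segment[label] = realized
        blocks.append(neural + emg)

    return SleepRecording(
        subject_id=spec.subject_id,
        sampling_rate=SAMPLING_RATE,
        channels=tuple(CHANNELS_1020),
        data=np.concatenate(blocks, axis=1),
        stage_annotation=[(0.0, 300.0, "N1"), (300.0, 600.0, "N2")],
        emg_rms_by_segment=emg_rms_by_segment,
    )


def simulate_from_brrr(
    n_subjects: int,
    segments_per_subject: int,
    s: int,
    k_true: int,
    noise_scales: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> tuple[FeatureMatrix, SubjectDesign, GroundTruth]:
    """Draw (Y, X, truth) directly from Y = (X Psi + Omega) Gamma + E.

    Psi entries are standard normal and Gamma entries N(0, 1/k_true), so the
    signal variance per feature is about one.  ``noise_scales`` is the pair
    (latent sd of Omega, residual sd of E).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if segments_per_subject < 2:
        raise ValueError("segments_per_subject must be at least 2")
    if k_true > min(n_subjects, s):
        raise ValueError(f"k_true={k_true} exceeds min(n_subjects, s)={min(n_subjects, s)}")
    latent_sd, residual_sd = noise_scales
    rng = np.random.default_rng(seed)

    p, n = n_subjects, n_subjects * segments_per_subject
    psi = rng.standard_normal((p, k_true))
    gamma = rng.standard_normal((k_true, s)) / np.sqrt(k_true)
    omega = latent_sd * rng.standard_normal((n, k_true))
    noise = residual_sd * rng.standard_normal((n, s))

    x = np.repeat(np.eye(p), segments_per_subject, axis=0)
    y = (x @ psi + omega) @ gamma + noise

    subject_order = [f"S{j + 1:04d}" for j in range(p)]
    row_meta = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_order, segments_per_subject),
            "segment_label": [f"seg{t + 1:02d}" for _ in range(p) for t in range(segments_per_subject)],
            "stage": "SIM",
        }
    )
    fm = FeatureMatrix(
        values=y, row_meta=row_meta, feature_names=[f"f{j:03d}" for j in range(s)]
    )
    design = SubjectDesign(values=x, subject_order=subject_order)
    truth = GroundTruth(
        psi=psi, gamma=gamma, omega=omega, sigma=np.full(s, residual_sd**2)
    )
    return fm, design, truth
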