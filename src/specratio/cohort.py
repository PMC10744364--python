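"""Synthetic resting-state EEG cohorts with lobar spectral group structure.

Each channel is a sum of independent band-limited noise processes — one per
canonical frequency band, with an RMS amplitude set by the channel's lobe —
plus a 1/f^beta broadband floor. Group structure enters multiplicatively:
patient (FTD) recordings scale frontal/temporal band amplitudes by
configurable factors whose default directions match the clinical picture
(frontal theta up, frontal and temporal alpha down, temporal gamma up).
Between-subject variability is a log-normal factor per (subject, lobe, band).

The generator emulates clean, already-preprocessed recordings: no blinks,
muscle artifacts, line noise, or nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EEGRecording, SubjectRecord, write_bids_cohort, write_edf, write_subject_table
from .montage import CHANNELS_1020, LobeMap
from .spectral import BAND_NAMES, BandScheme

__all__ = [
    "CovariateModel",
    "SyntheticCohortSpec",
    "band_limited_noise",
    "one_over_f_noise",
    "generate_subject_signal",
    "generate_cohort",
    "write_cohort",
]

LOBES = ("F", "T", "other")


def _lobe_band_matrix(values: dict[str, dict[str, float]] | None,
                      default: float) -> pd.DataFrame:
    mat = pd.DataFrame(default, index=list(LOBES), columns=list(BAND_NAMES), dtype=float)
    if values:
        for lobe, bands in values.items():
            for band, v in bands.items():
                mat.loc[lobe, band] = v
    return mat


# CTL baseline band RMS amplitudes (microvolt), typical of eyes-closed adult
# resting EEG: strong alpha, moderate slow activity, weak gamma.
DEFAULT_BASE_AMPLITUDE = {
    lobe: {"delta": 10.0, "theta": 7.0, "alpha": 12.0, "beta": 5.0, "gamma": 2.0}
    for lobe in LOBES
}

# FTD effect directions: frontal theta up, frontal/temporal alpha down,
# temporal gamma up; everything else unchanged. Non-frontal/temporal
# channels keep the CTL profile in both groups.
DEFAULT_FTD_MULTIPLIERS = {
    "F": {"theta": 1.3, "alpha": 0.75},
    "T": {"alpha": 0.7, "gamma": 1.25},
}


@dataclass
class CovariateModel:
    """Per-group demographic generators (age in years, MMSE 0-30)."""

    age_mean_ftd: float = 63.6
    age_sd_ftd: float = 8.2
    age_mean_ctl: float = 67.9
    age_sd_ctl: float = 5.4
    female_prop_ftd: float = 0.39
    female_prop_ctl: float = 0.38
    mmse_mean_ftd: float = 22.17
    mmse_sd_ftd: float = 8.22
    mmse_mean_ctl: float = 30.0
    mmse_sd_ctl: float = 0.0


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a synthetic EEG cohort.

    Parameters
    ----------
    n_ftd, n_ctl : int
        Group sizes (patients / controls).
    fs : float
        Sampling rate, Hz.
    duration : float
        Recording length per subject, seconds.
    channels : sequence of str
        Ordered 10-20 channel labels.
    base_amplitude : nested dict lobe -> band -> microvolt RMS
        Control-group band amplitudes; lobes 'F', 'T', 'other'.
    ftd_multipliers : nested dict lobe -> band -> factor
        Multiplicative FTD group effects on band amplitude.
    subject_sd : float
        Sigma of the log-normal per-(subject, lobe, band) amplitude factor.
    background_exponent : float
        Beta of the 1/f^beta broadband floor.
    background_scale : float or None
        RMS (microvolt) of the floor; None = 0.1 x mean base amplitude.
    covariates : CovariateModel
    seed : int
    """

    n_ftd: int = 23
    n_ctl: int = 29
    fs: float = 500.0
    duration: float = 600.0
    channels: tuple[str, ...] = CHANNELS_1020
    base_amplitude: dict = field(default_factory=lambda: DEFAULT_BASE_AMPLITUDE)
    ftd_multipliers: dict = field(default_factory=lambda: DEFAULT_FTD_MULTIPLIERS)
    subject_sd: float = 0.2
    background_exponent: float = 1.0
    background_scale: float | None = None
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0
    bands: BandScheme = field(default_factory=BandScheme)
    lobes: LobeMap = field(default_factory=LobeMap)
    dtype: str = "float64"  # float32 halves memory/FFT cost for large runs

    def __post_init__(self):
        if self.n_ftd < 1 or self.n_ctl < 1:
            raise ValueError("need at least one subject per group")
        top = max(hi for _, hi in self.bands.intervals.values())
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top} Hz)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self._base = _lobe_band_matrix(self.base_amplitude, np.nan)
        if self._base.isna().any().any():
            raise ValueError("base_amplitude must cover every (lobe, band) cell")
        self._mult = _lobe_band_matrix(self.ftd_multipliers, 1.0)
        # no FTD effect outside the analyzed lobes
        self._mult.loc["other"] = 1.0
        if (self._base.values < 0).any() or (self._mult.values < 0).any():
            raise ValueError("amplitudes and multipliers must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def background_rms(self) -> float:
        if self.background_scale is not None:
            return self.background_scale
        return 0.1 * float(self._base.values.mean())


def _normalize_rfft_unit_rms(coef: np.ndarray, n_samp: int) -> np.ndarray:
    """Scale rFFT coefficients so the inverse transform has exactly unit
    sample RMS (Parseval: n^2 RMS^2 = |c_0|^2 + 2 sum |c_k|^2 + |c_nyq|^2)."""
    w = np.full(coef.shape[-1], 2.0)
    w[0] = 1.0
    if n_samp % 2 == 0:
        w[-1] = 1.0
    energy = np.sum(w * np.abs(coef) ** 2, axis=-1, keepdims=True)
    energy[energy == 0] = 1.0
    return coef * (n_samp / np.sqrt(energy))


def _band_coefficients(band, fs, shape, rng, dtype="float64",
                       closed_low=True) -> np.ndarray:
    """Unit-RMS-normalized rFFT coefficients of band-limited Gaussian noise.

    ``closed_low=False`` excludes the exact lower-edge bin, so adjacent
    half-open bands occupy disjoint frequency bins.
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"invalid band ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValueError(
            f"band ({lo}, {hi}) Hz exceeds the Nyquist frequency {fs / 2} Hz"
        )
    n_samp = shape[-1]
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    mask = ((freqs >= lo) if closed_low else (freqs > lo)) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no spectral support for band ({lo}, {hi}) at n={n_samp}")
    cdtype = "complex64" if np.dtype(dtype) == np.float32 else "complex128"
    coef = np.zeros(shape[:-1] + (freqs.size,), dtype=cdtype)
    k = int(mask.sum())
    coef[..., mask] = rng.standard_normal(
        shape[:-1] + (k,), dtype=dtype
    ) + 1j * rng.standard_normal(shape[:-1] + (k,), dtype=dtype)
    return _normalize_rfft_unit_rms(coef, n_samp)


def _background_coefficients(beta, fs, shape, rng, f_min=0.5,
                             dtype="float64") -> np.ndarray:
    """Unit-RMS-normalized rFFT coefficients of 1/f^beta noise (no power
    below ``f_min``, matching band-passed preprocessed clinical EEG)."""
    n_samp = shape[-1]
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    amp = np.zeros(freqs.size, dtype=dtype)
    mask = freqs >= f_min
    amp[mask] = freqs[mask] ** (-beta / 2.0)
    coef = (
        rng.standard_normal(shape[:-1] + (freqs.size,), dtype=dtype)
        + 1j * rng.standard_normal(shape[:-1] + (freqs.size,), dtype=dtype)
    ) * amp
    return _normalize_rfft_unit_rms(coef, n_samp)


def band_limited_noise(band, fs, n, rng) -> np.ndarray:
    """Unit-RMS Gaussian noise strictly confined to a frequency band.

    Constructed in the frequency domain: i.i.d. complex Gaussian rFFT
    coefficients inside ``band`` (Hz), zero outside, normalized to exactly
    unit sample RMS and inverse-transformed. Accepts a leading shape for
    independent realizations, e.g.
    ``band_limited_noise((8, 13), 500, (19, 30000), rng)``.
    """
    shape = (n,) if np.isscalar(n) else tuple(n)
    coef = _band_coefficients(band, fs, shape, rng)
    return np.fft.irfft(coef, n=shape[-1], axis=-1)


def one_over_f_noise(beta, fs, n, rng, f_min=0.5) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^beta."""
    shape = (n,) if np.isscalar(n) else tuple(n)
    coef = _background_coefficients(beta, fs, shape, rng, f_min)
    return np.fft.irfft(coef, n=shape[-1], axis=-1)


def subject_amplitudes(spec: SyntheticCohortSpec, group: str, rng) -> pd.DataFrame:
    """Draw the (lobe x band) RMS amplitude matrix for one subject."""
    amps = spec._base.copy()
    if group == "FTD":
        amps = amps * spec._mult
    factors = np.exp(spec.subject_sd * rng.standard_normal(amps.shape))
    return amps * factors


def generate_subject_signal(spec: SyntheticCohortSpec, group: str, rng) -> EEGRecording:
    """Synthesize one subject's multichannel recording.

    Each channel is the sum over bands of amplitude x unit-RMS band noise
    (independent noise per channel, amplitude shared within a lobe) plus the
    1/f^beta floor.
    """
    if group not in ("FTD", "CTL"):
        raise ValueError(f"group must be FTD or CTL, got {group!r}")
    amps = subject_amplitudes(spec, group, rng)
    n_ch = len(spec.channels)
    n = spec.n_samples
    lobe_idx = [spec.lobes.lobe_of(ch) for ch in spec.channels]
    # accumulate in the frequency domain (each component exactly unit-RMS
    # normalized) and inverse-transform once
    cdtype = "complex64" if np.dtype(spec.dtype) == np.float32 else "complex128"
    coef = np.zeros((n_ch, n // 2 + 1), dtype=cdtype)
    first_band = spec.bands.names[0]
    for band, (lo, hi) in spec.bands.intervals.items():
        a = np.array([amps.loc[lobe, band] for lobe in lobe_idx], dtype=spec.dtype)
        if np.all(a == 0):
            continue  # skipping is deterministic: band order is fixed
        coef += a[:, None] * _band_coefficients(
            (lo, hi), spec.fs, (n_ch, n), rng, dtype=spec.dtype,
            closed_low=(band == first_band),
        )
    bg = spec.background_rms()
    if bg > 0:
        coef += bg * _background_coefficients(
            spec.background_exponent, spec.fs, (n_ch, n), rng, dtype=spec.dtype
        )
    data = np.fft.irfft(coef, n=n, axis=-1)
    return EEGRecording(data, spec.fs, list(spec.channels), reference="as-recorded")


def _draw_subject_record(spec, group, idx, rng) -> SubjectRecord:
    cov = spec.covariates
    if group == "FTD":
        age = rng.normal(cov.age_mean_ftd, cov.age_sd_ftd)
        sex = "F" if rng.random() < cov.female_prop_ftd else "M"
        mmse = rng.normal(cov.mmse_mean_ftd, cov.mmse_sd_ftd)
    else:
        age = rng.normal(cov.age_mean_ctl, cov.age_sd_ctl)
        sex = "F" if rng.random() < cov.female_prop_ctl else "M"
        mmse = rng.normal(cov.mmse_mean_ctl, cov.mmse_sd_ctl)
    mmse = int(round(min(30.0, max(0.0, mmse))))
    return SubjectRecord(
        subject_id=f"sub-{idx:03d}", group=group, age=round(age, 1), sex=sex, mmse=mmse
    )


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[list[EEGRecording], list[SubjectRecord]]:
    """Generate the full cohort: recordings and subject table.

    Deterministic under a fixed spec (seeded from ``spec.seed``); FTD
    subjects come first, then controls.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["FTD"] * spec.n_ftd + ["CTL"] * spec.n_ctl
    recordings, subjects = [], []
    for idx, group in enumerate(groups, start=1):
        subjects.append(_draw_subject_record(spec, group, idx, rng))
        recordings.append(generate_subject_signal(spec, group, rng))
    return recordings, subjects


def write_cohort(spec: SyntheticCohortSpec, out_dir, bids: bool = False) -> Path:
    """Generate and write a cohort as EDF files plus a TSV subject table.

    With ``bids=True`` uses the BIDS-style layout (sub-*/eeg/*.edf and
    participants.tsv); otherwise flat EDFs and subjects.tsv.
    """
    out_dir = Path(out_dir)
    recordings, subjects = generate_cohort(spec)
    if bids:
        write_bids_cohort(recordings, subjects, out_dir)
    else:
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, sub in zip(recordings, subjects):
            write_edf(rec, out_dir / f"{sub.subject_id}.edf")
        write_subject_table(subjects, out_dir / "subjects.tsv")
    return out_dir
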