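"""Band power estimation and inter-/intra-lobar power ratios.

The spectral estimator is Welch's method with a Hamming taper and 50%
segment overlap, zero-padded so that the frequency grid has a configurable
number of points per Hz ("steps per Hz"). At 500 Hz sampling the three
standard parameterizations decompose as:

====================  ========  ==========  ============
configuration          window    FFT length   overlap
====================  ========  ==========  ============
2 s / 10 steps per Hz    1000        5000         500
2 s /  5 steps per Hz    1000        2500         500
1 s / 10 steps per Hz     500        5000         250
====================  ========  ==========  ============

Band power is the mean of the one-sided power spectral density over the
grid points falling in the band; lobar power averages that over the lobe's
electrodes. The 65 power ratios pair every band of the frontal lobe with
every band of the temporal lobe (25) and every ordered unequal band pair
within each lobe (2 x 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording
from .montage import LobeMap

__all__ = [
    "BAND_NAMES",
    "BandScheme",
    "SpectralParams",
    "welch_psd",
    "band_power",
    "band_powers",
    "lobar_band_power",
    "cohort_band_powers",
    "power_ratios",
    "RATIO_NAMES",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

_EDGE_EPS = 1e-9


class InvalidBandError(ValueError):
    """Requested frequency band has no support on the spectrum grid."""


@dataclass(frozen=True)
class BandScheme:
    """Canonical EEG band edges (Hz), contiguous over 0.5-45 Hz.

    Intervals are half-open (low, high]; delta is closed at its lower edge:
    delta [0.5, 4], theta (4, 8], alpha (8, 13], beta (13, 30],
    gamma (30, 45].
    """

    edges: tuple[float, ...] = (0.5, 4.0, 8.0, 13.0, 30.0, 45.0)
    names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self):
        if len(self.edges) != len(self.names) + 1:
            raise ValueError("need one more edge than band names")
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("band edges must be strictly increasing")

    @property
    def intervals(self) -> dict[str, tuple[float, float]]:
        return {
            name: (lo, hi)
            for name, lo, hi in zip(self.names, self.edges, self.edges[1:])
        }

    def mask(self, freqs: np.ndarray, band: str) -> np.ndarray:
        """Boolean grid mask for a named band (lower edge exclusive except
        for the first band, upper edge inclusive)."""
        lo, hi = self.intervals[band]
        if band == self.names[0]:
            lower = freqs >= lo - _EDGE_EPS
        else:
            lower = freqs > lo + _EDGE_EPS
        return lower & (freqs <= hi + _EDGE_EPS)


@dataclass(frozen=True)
class SpectralParams:
    """FFT parameterization: window length (s) and frequency steps per Hz.

    The FFT length is ``steps_per_hz * fs`` samples (zero-padding beyond the
    window), giving a grid spacing of 1/steps_per_hz Hz; overlap is a
    fraction of the window (default 50%).
    """

    window_s: float = 2.0
    steps_per_hz: int = 10
    overlap: float = 0.5
    taper: str = "hamming"
    fs: float = 500.0

    def __post_init__(self):
        if self.window_s <= 0 or self.steps_per_hz < 1:
            raise ValueError("window_s and steps_per_hz must be positive")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.nfft < self.nperseg:
            raise ValueError(
                f"FFT length {self.nfft} shorter than window {self.nperseg}; "
                f"increase steps_per_hz or shorten the window"
            )

    @property
    def nperseg(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def nfft(self) -> int:
        return int(round(self.steps_per_hz * self.fs))

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.overlap))

    @property
    def df(self) -> float:
        """Frequency grid spacing, Hz."""
        return self.fs / self.nfft

    @property
    def label(self) -> str:
        w = f"{self.window_s:g}"
        return f"{w}s-{self.steps_per_hz}"


def welch_psd(x, params: SpectralParams):
    """One-sided Welch power spectral density on the zero-padded grid.

    Parameters
    ----------
    x : array, (..., n_samples)
        Signal(s) in microvolts; the PSD is computed along the last axis.
    params : SpectralParams

    Returns
    -------
    freqs : array (n_freqs,)
        Grid of spacing ``1/steps_per_hz`` Hz from 0 to Nyquist.
    psd : array (..., n_freqs)
        Density in microvolt^2/Hz; integrates (sum x grid spacing) to the
        detrended signal's mean power.
    """
    x = np.asarray(x)
    if x.dtype.kind != "f":
        x = x.astype(float)
    if x.shape[-1] < params.nperseg:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than one window "
            f"({params.nperseg} samples)"
        )
    nperseg, nfft = params.nperseg, params.nfft
    step = nperseg - params.noverlap
    win = sps.get_window(params.taper, nperseg).astype(x.dtype)
    # all segments in one strided view, one batched FFT (equivalent to
    # scipy.signal.welch with detrend='constant', scaling='density')
    n_seg = (x.shape[-1] - nperseg) // step + 1
    segs = np.lib.stride_tricks.sliding_window_view(x, nperseg, axis=-1)[
        ..., ::step, :
    ][..., :n_seg, :]
    segs = segs - segs.mean(axis=-1, keepdims=True)
    segs *= win
    spec = np.fft.rfft(segs, n=nfft, axis=-1)
    psd = (spec.real**2 + spec.imag**2).mean(axis=-2)
    psd /= params.fs * (win**2).sum()
    psd[..., 1:] *= 2.0
    if nfft % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / params.fs)
    return freqs, psd


def band_power(freqs, psd, band, scheme: BandScheme | None = None):
    """Average spectral power in one band: mean PSD over in-band grid points.

    ``band`` is a band name from the scheme or an explicit (low, high]
    interval in Hz.
    """
    scheme = scheme or BandScheme()
    freqs = np.asarray(freqs)
    if isinstance(band, str):
        mask = scheme.mask(freqs, band)
        lo, hi = scheme.intervals[band]
    else:
        lo, hi = band
        mask = (freqs > lo + _EDGE_EPS) & (freqs <= hi + _EDGE_EPS)
    if not mask.any():
        raise InvalidBandError(
            f"band ({lo}, {hi}] Hz has no grid points in "
            f"[{freqs.min():g}, {freqs.max():g}] Hz"
        )
    return np.asarray(psd)[..., mask].mean(axis=-1)


def band_powers(freqs, psd, scheme: BandScheme | None = None) -> dict[str, np.ndarray]:
    """All named band powers of a spectrum (or stack of spectra)."""
    scheme = scheme or BandScheme()
    return {name: band_power(freqs, psd, name, scheme) for name in scheme.names}


def lobar_band_power(rec: EEGRecording, params: SpectralParams,
                     lobemap: LobeMap | None = None,
                     scheme: BandScheme | None = None) -> pd.Series:
    """Frontal and temporal band powers for one recording.

    Returns a Series indexed 'F-delta' ... 'T-gamma' (10 values): the mean
    over the lobe's electrodes of each electrode's band power.
    """
    lobemap = lobemap or LobeMap()
    scheme = scheme or BandScheme()
    missing = [
        ch for ch in sorted(lobemap.frontal | lobemap.temporal)
        if ch not in rec.labels
    ]
    if missing:
        raise ValueError(f"recording is missing lobar electrodes: {missing}")
    if abs(rec.fs - params.fs) > 1e-9:
        params = SpectralParams(
            params.window_s, params.steps_per_hz, params.overlap, params.taper, rec.fs
        )
    out = {}
    for lobe in ("F", "T"):
        chans = lobemap.electrodes(lobe)
        idx = [rec.labels.index(ch) for ch in chans]
        freqs, psd = welch_psd(rec.data[idx], params)
        for name in scheme.names:
            out[f"{lobe}-{name}"] = float(band_power(freqs, psd, name, scheme).mean())
    return pd.Series(out)


def cohort_band_powers(recordings, subjects, params: SpectralParams,
                       lobemap: LobeMap | None = None,
                       scheme: BandScheme | None = None) -> pd.DataFrame:
    """BandPowerTable: subjects x 10 (lobe, band) absolute average powers."""
    rows = {
        sub.subject_id: lobar_band_power(rec, params, lobemap, scheme)
        for rec, sub in zip(recordings, subjects)
    }
    return pd.DataFrame(rows).T.rename_axis("subject_id")


def decimate_grid(freqs, psd, factor: int):
    """Exact coarse-grid spectrum from an oversampled one.

    A Welch spectrum zero-padded to ``k * steps_per_hz`` points per Hz,
    subsampled at every ``k``-th bin, is *identical* to the spectrum
    computed directly at ``steps_per_hz`` (the padded DFT evaluated at bins
    ``k*j`` coincides with the shorter-padding DFT, the window and segment
    layout being equal). Useful to derive, e.g., the 2 s/5 parameterization
    from a single 2 s/10 pass.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return freqs[::factor], np.asarray(psd)[..., ::factor]


def cohort_band_powers_multi(recordings, subjects, params_list,
                             lobemap: LobeMap | None = None,
                             scheme: BandScheme | None = None
                             ) -> dict[SpectralParams, pd.DataFrame]:
    """Band-power tables for several FFT parameterizations in one pass.

    Parameterizations sharing window, overlap and taper whose FFT lengths
    divide a finer one are derived exactly from the finest pass via
    :func:`decimate_grid` instead of a separate Welch run.
    """
    lobemap = lobemap or LobeMap()
    scheme = scheme or BandScheme()
    params_list = list(params_list)
    # map each parameterization to the finest compatible "parent"
    parents: dict[SpectralParams, SpectralParams] = {}
    for p in params_list:
        parent = p
        for q in params_list:
            if (
                q.nperseg == p.nperseg
                and q.noverlap == p.noverlap
                and q.taper == p.taper
                and q.nfft % p.nfft == 0
                and q.nfft >= parent.nfft
            ):
                parent = q
        parents[p] = parent
    chans = lobemap.electrodes("F") + lobemap.electrodes("T")
    n_front = len(lobemap.electrodes("F"))
    out: dict[SpectralParams, dict] = {p: {} for p in params_list}
    for rec, sub in zip(recordings, subjects):
        missing = [ch for ch in chans if ch not in rec.labels]
        if missing:
            raise ValueError(f"recording is missing lobar electrodes: {missing}")
        idx = [rec.labels.index(ch) for ch in chans]
        cache = {}
        for parent in set(parents.values()):
            cache[parent] = welch_psd(rec.data[idx], parent)
        for p in params_list:
            freqs, psd = cache[parents[p]]
            if parents[p] is not p:
                freqs, psd = decimate_grid(freqs, psd, parents[p].nfft // p.nfft)
            row = {}
            for name in scheme.names:
                bp = band_power(freqs, psd, name, scheme)
                row[f"F-{name}"] = float(bp[:n_front].mean())
                row[f"T-{name}"] = float(bp[n_front:].mean())
            out[p][sub.subject_id] = pd.Series(row)
    return {
        p: pd.DataFrame(rows).T.rename_axis("subject_id")
        for p, rows in out.items()
    }


def _ratio_names(bands=BAND_NAMES) -> list[str]:
    names = [f"F-{bi}/T-{bj}" for bi in bands for bj in bands]
    names += [f"F-{bi}/F-{bj}" for bi in bands for bj in bands if bi != bj]
    names += [f"T-{bi}/T-{bj}" for bi in bands for bj in bands if bi != bj]
    return names


#: the 65 ratio column names: 25 inter-lobar F/T + 20 F/F + 20 T/T
RATIO_NAMES = tuple(_ratio_names())


def power_ratios(bpt: pd.DataFrame) -> pd.DataFrame:
    """RatioTable: all 65 inter-/intra-lobar band-power ratios.

    Cells with a zero denominator become NaN (flagged missing, excluded
    downstream).
    """
    cols = {}
    for name in RATIO_NAMES:
        num, den = name.split("/")
        numerator = bpt[num].to_numpy(dtype=float)
        denominator = bpt[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(denominator > 0, numerator / denominator, np.nan)
        cols[name] = vals
    out = pd.DataFrame(cols, index=bpt.index)
    return out
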