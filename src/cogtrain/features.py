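"""Neurophysiological feature extraction.

Spectral power (Welch / periodogram), band-integrated power, phase-locking
value connectivity, theta-gamma phase-amplitude coupling (Kullback-Leibler
modulation index), the training-induced plasticity index (percent change in
band power), and the modified Beer-Lambert estimate of oxygenated
hemoglobin change for near-infrared intensity series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal import hilbert

from .signals import SignalFrame

logger = logging.getLogger(__name__)

__all__ = ["BandPowerSpectrum", "PhaseSeries", "NIRSParams", "compute_psd",
           "band_power", "plv", "modulation_index", "theta_gamma_coupling",
           "tipi", "delta_hbo2", "band_power_table"]


@dataclass
class BandPowerSpectrum:
    """Power spectral density per channel plus named band aggregates.

    psd is channels x frequencies in µV²/Hz; band_power maps band name to
    a per-channel µV² vector.
    """

    freqs: np.ndarray
    psd: np.ndarray
    fs: float
    window_name: str
    nperseg: int
    channel_labels: tuple[str, ...] = ()
    band_power: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.psd = np.atleast_2d(self.psd)
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def total_power(self) -> np.ndarray:
        """Integrated power over the whole estimated range, per channel."""
        return np.trapezoid(self.psd, self.freqs, axis=-1)


@dataclass
class PhaseSeries:
    """Instantaneous phases, trials x samples, wrapped to (-pi, pi]."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.phases, dtype=float))
        self.phases = np.angle(np.exp(1j * p))  # wrap

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]


@dataclass
class NIRSParams:
    """Modified Beer-Lambert coefficients (natural-log convention)."""

    alpha_coeff: float
    beta_coeff: float
    I0: float
    dHbR: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")


def compute_psd(frame: SignalFrame, window_name: str = "hann",
                nperseg: int | None = None,
                overlap: float = 0.5) -> BandPowerSpectrum:
    """Averaged modified-periodogram PSD estimate of a frame.

    Defaults to Hann windows of 2 s with 50% overlap.  With a rectangular
    full-length window this reduces to the plain periodogram, for which
    the integrated power equals the time-domain variance (Parseval).
    """
    if nperseg is None:
        nperseg = min(frame.n_samples, int(2 * frame.fs))
    if nperseg > frame.n_samples:
        raise ValueError(f"nperseg={nperseg} exceeds sample count "
                         f"{frame.n_samples}")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    window = "boxcar" if window_name == "rectangular" else window_name
    freqs, psd = sps.welch(frame.data, fs=frame.fs, window=window,
                           nperseg=nperseg,
                           noverlap=int(overlap * nperseg),
                           detrend="constant", axis=-1)
    return BandPowerSpectrum(freqs=freqs, psd=psd, fs=frame.fs,
                             window_name=window_name, nperseg=nperseg,
                             channel_labels=frame.channel_labels)


def band_power(spectrum: BandPowerSpectrum, f_low: float, f_high: float,
               name: str | None = None) -> np.ndarray:
    """Trapezoidal integral of the PSD over [f_low, f_high], per channel.

    Band edges are linearly interpolated onto the frequency grid, which
    makes the integral exactly additive over adjacent bands.  When
    ``name`` is given the result is also cached in ``spectrum.band_power``.
    """
    if f_low >= f_high:
        raise ValueError(f"inverted band ({f_low}, {f_high})")
    freqs = spectrum.freqs
    if f_low < freqs[0] - 1e-9 or f_high > freqs[-1] + 1e-9:
        raise ValueError(f"band ({f_low}, {f_high}) outside spectrum range "
                         f"[{freqs[0]}, {freqs[-1]}]")
    f_low = max(f_low, freqs[0])
    f_high = min(f_high, freqs[-1])
    inner = (freqs > f_low) & (freqs < f_high)
    grid = np.concatenate(([f_low], freqs[inner], [f_high]))
    out = np.empty(spectrum.psd.shape[0])
    for c in range(spectrum.psd.shape[0]):
        vals = np.interp(grid, freqs, spectrum.psd[c])
        out[c] = np.trapezoid(vals, grid)
    if name is not None:
        spectrum.band_power[name] = out
    return out


def plv(x: PhaseSeries, y: PhaseSeries, pooled: bool = False) -> np.ndarray | float:
    """Phase-locking value |mean over trials of exp(i(phi_x - phi_y))|.

    Returns one value per time point (the trial axis is averaged), or a
    single pooled value over trials and time when ``pooled=True`` or when
    only one trial is present (logged, as trial-resolved locking is then
    unavailable).
    """
    if x.phases.shape != y.phases.shape:
        raise ValueError(f"shape mismatch {x.phases.shape} vs "
                         f"{y.phases.shape}")
    d = np.exp(1j * (x.phases - y.phases))
    if pooled or x.n_trials == 1:
        if x.n_trials == 1 and not pooled:
            logger.info("plv: single trial, pooling across time")
        return float(np.abs(d.mean()))
    return np.abs(d.mean(axis=0))


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = 18) -> float:
    """Kullback-Leibler modulation index of phase-amplitude coupling.

    Bins the amplitude by phase, normalises the binned means to a
    distribution P, and returns KL(P || uniform) / log(n_bins): 0 for
    amplitude independent of phase, 1 for amplitude concentrated in a
    single phase bin.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase/amplitude length mismatch")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(np.angle(np.exp(1j * phase)), edges) - 1,
                  0, n_bins - 1)
    means = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = amplitude[sel].mean()
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    return kl / np.log(n_bins)


def _bandpass_analytic(x: np.ndarray, band: tuple[float, float], fs: float,
                       order: int = 4) -> np.ndarray:
    """Zero-phase band-pass followed by the analytic signal.  Filter
    order is fixed (4th-order Butterworth, applied forward-backward)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return hilbert(sps.sosfiltfilt(sos, x))


def theta_gamma_coupling(frame: SignalFrame,
                         phase_band: tuple[float, float] = (4.0, 8.0),
                         amp_band: tuple[float, float] = (30.0, 50.0),
                         n_bins: int = 18) -> np.ndarray:
    """Phase-amplitude coupling strength per channel.

    Extracts the phase-band analytic phase and the amplitude-band analytic
    envelope (4th-order zero-phase Butterworth + Hilbert) and returns the
    KL modulation index per channel.  Requires at least 10 phase-band
    cycles of recording.
    """
    nyq = frame.fs / 2
    if phase_band[1] > nyq or amp_band[1] > nyq:
        raise ValueError("band above Nyquist")
    if frame.duration_s * phase_band[0] < 10:
        raise ValueError(
            f"recording too short: {frame.duration_s:.2f} s holds fewer "
            f"than 10 cycles of the {phase_band[0]} Hz phase band")
    out = np.empty(frame.data.shape[0])
    for c, x in enumerate(frame.data):
        ph = np.angle(_bandpass_analytic(x, phase_band, frame.fs))
        am = np.abs(_bandpass_analytic(x, amp_band, frame.fs))
        out[c] = modulation_index(ph, am, n_bins)
    return out


def tipi(psd_pre: np.ndarray | float, psd_post: np.ndarray | float
         ) -> np.ndarray | float:
    """Training-induced plasticity index: percent change in spectral
    power, 100 * (post - pre) / pre.  Requires pre > 0."""
    pre = np.asarray(psd_pre, dtype=float)
    post = np.asarray(psd_post, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("psd_pre must be > 0")
    out = 100.0 * (post - pre) / pre
    return float(out) if out.ndim == 0 else out


def delta_hbo2(I_t: np.ndarray, params: NIRSParams) -> np.ndarray:
    """Oxygenated-hemoglobin concentration change from a light-intensity
    series via the modified Beer-Lambert law (natural log):
    alpha * ln(I0 / I(t)) - beta * dHbR(t)."""
    I_t = np.asarray(I_t, dtype=float)
    if np.any(I_t <= 0):
        raise ValueError("intensities must be > 0")
    return (params.alpha_coeff * np.log(params.I0 / I_t)
            - params.beta_coeff * np.asarray(params.dHbR, dtype=float))


def band_power_table(spectrum: BandPowerSpectrum,
                     bands: dict[str, tuple[float, float]],
                     profile: str = "") -> pd.DataFrame:
    """Tidy feature table: (profile, channel, band, metric, value)."""
    rows = []
    labels = spectrum.channel_labels or tuple(
        f"ch{i}" for i in range(spectrum.psd.shape[0]))
    for band, (lo, hi) in bands.items():
        bp = band_power(spectrum, lo, hi, name=band)
        for ch, v in zip(labels, bp):
            rows.append({"profile": profile, "channel": ch, "band": band,
                         "metric": "band_power", "value": v})
    return pd.DataFrame(rows)
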