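"""Band-structured synthetic EEG and auxiliary physiological streams.

The EEG generator builds each channel as a sum of narrow-band oscillators
(amplitude-modulated sinusoids whose instantaneous frequency drifts slowly
inside the band) on top of 1/f^k broadband background noise, with the
0.5-50 Hz content of scalp EEG, 500 Hz sampling, and a controlled
signal-to-noise ratio.  Oscillator and noise components are rescaled to
their exact realized target powers, so the produced frame's band powers
and SNR are measurable properties of the data, not nominal labels.

SNR here is defined as total oscillatory-component power over total
broadband-noise power (10 log10 scale); the definition is recorded in the
frame metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .profiles import SubjectProfile

logger = logging.getLogger(__name__)

__all__ = ["SignalFrame", "BandSpec", "EEGSynthSpec", "synth_eeg",
           "synth_physio", "estimate_snr", "default_bands",
           "DEFAULT_CHANNELS", "PHYSIO_RATES", "frame_to_csv"]

#: 10-20 electrode labels of the regions tracked by the neural-marker
#: benchmark.
DEFAULT_CHANNELS = ("Fz", "F3", "F4", "Pz", "Cz", "Oz", "T7", "T8")

#: Sampling rate (Hz) per auxiliary modality, matching the hardware
#: configuration the simulator emulates.
PHYSIO_RATES = {"gsr": 100.0, "heart_rate": 500.0, "emg": 2000.0}

#: Frequency support of the generated EEG content.
CONTENT_BAND = (0.5, 50.0)


@dataclass
class SignalFrame:
    """One multichannel, uniformly sampled signal stream.

    ``data`` is channels x samples (µV for EEG); ``meta`` carries
    generation provenance such as realized component powers.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count != label count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class BandSpec:
    """One oscillatory band: name, edges in Hz, and target power in µV²."""

    name: str
    f_low: float
    f_high: float
    target_power: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band edges ({self.f_low}, {self.f_high})")
        if self.target_power < 0:
            raise ValueError("target_power must be >= 0")


@dataclass
class EEGSynthSpec:
    """EEG generation parameters.

    snr_db is the ratio of total band-oscillator power to total broadband
    noise power; noise_exponent is the 1/f^k spectral slope of the
    background; channel_lag_s shifts each successive channel's oscillators
    so cross-channel phase relations are nontrivial.
    """

    bands: list[BandSpec]
    snr_db: float = 35.0
    fs: float = 500.0
    duration_s: float = 10.0
    noise_exponent: float = 1.0
    channel_lag_s: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        for b in self.bands:
            if b.f_high > self.fs / 2:
                raise ValueError(
                    f"band {b.name} upper edge {b.f_high} Hz above Nyquist")


def default_bands() -> list[BandSpec]:
    """Theta/alpha/beta oscillators with benchmark-scale powers (µV²)."""
    return [BandSpec("theta", 4.0, 8.0, 12.4),
            BandSpec("alpha", 8.0, 13.0, 19.8),
            BandSpec("beta", 13.0, 30.0, 15.4)]


def _smooth_noise(rng: np.random.Generator, n: int, cutoff_hz: float,
                  fs: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian noise (slow modulation source)."""
    x = rng.standard_normal(n)
    sos = sps.butter(2, max(cutoff_hz, 1e-3), btype="low", fs=fs,
                     output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _band_noise(rng: np.random.Generator, n: int, f_lo: float, f_hi: float,
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise with flat spectrum on [f_lo, f_hi].

    Built by Fourier-domain shaping (circularly stationary), which avoids
    the edge transients a very-low-frequency time-domain filter would
    leave at the record boundaries.
    """
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size))
    mask = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    x = np.fft.irfft(np.where(mask, spec, 0.0), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_oscillator(rng: np.random.Generator, band: BandSpec, n: int,
                     fs: float) -> np.ndarray:
    """AM sinusoid with instantaneous frequency drifting inside the band,
    rescaled to unit power."""
    f_c = 0.5 * (band.f_low + band.f_high)
    half_bw = 0.5 * (band.f_high - band.f_low)
    # slow frequency drift confined well inside the band so AM sidebands
    # stay within the edges
    drift = _band_noise(rng, n, 1.0 / max(n / fs, 4.0), 0.2, fs)
    drift = np.clip(drift / 2.5, -1.0, 1.0)
    f_inst = f_c + 0.6 * half_bw * drift
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    # band-pass (0.3-1.5 Hz) amplitude modulation: no ultra-slow power
    # wander, so windowed spectral estimates track the sample variance
    env = 1.0 + 0.25 * _band_noise(rng, n, 0.3, 1.5, fs)
    env = np.clip(env, 0.05, None)
    x = env * np.sin(phase)
    x -= x.mean()
    return x / x.std()


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float,
                      band: tuple[float, float] = CONTENT_BAND) -> np.ndarray:
    """Unit-power noise with a 1/f^exponent spectrum restricted to
    ``band`` (Fourier-domain shaping of white noise)."""
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size))
    amp = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    amp[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=n)
    x -= x.mean()
    return x / x.std()


def synth_eeg(profile: SubjectProfile | None, spec: EEGSynthSpec,
              channels: tuple[str, ...] = DEFAULT_CHANNELS) -> SignalFrame:
    """Generate a multichannel EEG frame with exact realized band powers
    and SNR.

    Each band oscillator is normalised so its realized (sample) power
    equals ``target_power``; per-channel noise is scaled so realized
    oscillator-power / noise-power matches ``snr_db``.  Successive
    channels receive a lag of ``channel_lag_s`` on the shared oscillators,
    giving reproducible nontrivial cross-channel phase structure.
    Deterministic under ``spec.seed``.
    """
    if not channels:
        raise ValueError("channels must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    lag = int(round(spec.channel_lag_s * spec.fs))
    base = {b.name: _band_oscillator(rng, b, n, spec.fs) for b in spec.bands}
    snr_ratio = 10.0 ** (spec.snr_db / 10.0)

    data = np.empty((len(channels), n))
    sig_power = np.empty(len(channels))
    noise_power = np.empty(len(channels))
    band_power_realized: dict[str, np.ndarray] = {
        b.name: np.empty(len(channels)) for b in spec.bands}
    for c in range(len(channels)):
        total_sig = np.zeros(n)
        for b in spec.bands:
            comp = np.roll(base[b.name], c * lag)
            comp = comp - comp.mean()
            comp *= np.sqrt(b.target_power) / comp.std()
            band_power_realized[b.name][c] = float(np.var(comp))
            total_sig += comp
        p_sig = float(np.var(total_sig))
        noise = _one_over_f_noise(rng, n, spec.fs, spec.noise_exponent)
        noise *= np.sqrt(p_sig / snr_ratio)
        p_noise = float(np.var(noise))
        x = total_sig + noise
        data[c] = x - x.mean()
        sig_power[c] = p_sig
        noise_power[c] = p_noise
    realized_snr = 10 * np.log10(sig_power / noise_power)
    meta = {
        "kind": "eeg",
        "snr_definition": "total oscillator power / total 1/f noise power",
        "snr_db_target": spec.snr_db,
        "snr_db_realized": realized_snr,
        "signal_power": sig_power,
        "noise_power": noise_power,
        "band_power_realized": band_power_realized,
        "noise_exponent": spec.noise_exponent,
        "seed": spec.seed,
    }
    return SignalFrame(data=data, fs=spec.fs, channel_labels=tuple(channels),
                       meta=meta)


def synth_physio(profile: SubjectProfile | None, modality: str,
                 duration_s: float, seed: int = 0) -> SignalFrame:
    """Generate an auxiliary physiological stream.

    gsr: tonic skin conductance (µS, within 0.01-100) with slow drift and
    sparse phasic responses, 100 Hz.  heart_rate: beats-per-minute series
    with respiratory-band variability, 500 Hz.  emg: burst-modulated
    band-limited surface EMG (µV), 2000 Hz.
    """
    if modality not in PHYSIO_RATES:
        raise ValueError(f"unknown modality {modality!r}; "
                         f"expected one of {sorted(PHYSIO_RATES)}")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    fs = PHYSIO_RATES[modality]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if modality == "gsr":
        tonic = rng.uniform(2.0, 15.0)
        drift = 0.5 * _smooth_noise(rng, n, 0.05, fs)
        x = tonic + drift
        n_events = rng.poisson(0.2 * duration_s)
        for _ in range(n_events):
            onset = rng.uniform(0, duration_s)
            amp = rng.uniform(0.1, 1.5)
            rise, decay = 0.75, 2.0
            dt = t - onset
            scr = np.where(dt > 0,
                           amp * (1 - np.exp(-np.maximum(dt, 0) / rise))
                           * np.exp(-np.maximum(dt, 0) / decay), 0.0)
            x += scr
        x = np.clip(x, 0.01, 100.0)
    elif modality == "heart_rate":
        base = rng.uniform(60.0, 85.0)
        rsa = 2.5 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        lf = 1.5 * _smooth_noise(rng, n, 0.1, fs)
        x = base + rsa + lf
        x = np.clip(x, 30.0, 220.0)
    else:  # emg
        white = rng.standard_normal(n)
        f_hi = min(450.0, 0.45 * fs)
        sos = sps.butter(4, [20.0, f_hi], btype="bandpass", fs=fs,
                         output="sos")
        carrier = sps.sosfiltfilt(sos, white)
        carrier /= carrier.std()
        burst = np.clip(_smooth_noise(rng, n, 1.0, fs), 0, None)
        x = 50.0 * (0.2 + burst) * carrier
    return SignalFrame(data=x[None, :], fs=fs, channel_labels=(modality,),
                       meta={"kind": modality, "seed": seed})


def estimate_snr(frame: SignalFrame, signal_bands: list[BandSpec],
                 nperseg: int | None = None) -> float:
    """Spectral SNR estimate: in-band power over out-of-band power, dB.

    Bins are partitioned between the union of ``signal_bands`` and its
    complement, so swapping the band/noise roles negates the estimate.
    Returns ``inf`` (logged) when the out-of-band power is zero.
    """
    if frame.n_samples == 0:
        raise ValueError("empty frame")
    nperseg = nperseg or min(frame.n_samples, int(2 * frame.fs))
    freqs, psd = sps.welch(frame.data, fs=frame.fs, nperseg=nperseg,
                           axis=-1, detrend="constant")
    mask = np.zeros_like(freqs, dtype=bool)
    for b in signal_bands:
        mask |= (freqs >= b.f_low) & (freqs <= b.f_high)
    p_in = float(psd[:, mask].sum())
    p_out = float(psd[:, ~mask].sum())
    if p_out <= 1e-12 * p_in:
        # denominator zero up to numerical spectral-leakage floor
        logger.warning("estimate_snr: zero out-of-band power, SNR infinite")
        return float("inf")
    if p_in == 0.0:
        logger.warning("estimate_snr: zero in-band power, SNR -infinite")
        return float("-inf")
    return float(10 * np.log10(p_in / p_out))


def frame_to_csv(frame: SignalFrame, path) -> None:
    """Write a frame as long-format CSV (time_s, channel, value)."""
    t = frame.times
    rows = pd.DataFrame({
        "time_s": np.tile(t, frame.data.shape[0]),
        "channel": np.repeat(frame.channel_labels, frame.n_samples),
        "value": frame.data.ravel(),
    })
    rows.to_csv(path, index=False)
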