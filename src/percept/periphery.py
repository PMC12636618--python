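"""Cochleagram front-ends: waveform -> model input representation.

A bank of FIR gammatone filters with ERB-spaced characteristic frequencies,
followed by half-wave rectification, power-law compression (exponent 0.3),
lowpass filtering to emulate the upper limit of auditory-nerve phase
locking, and downsampling with a Kaiser-windowed-sinc resampler. Two
presets mirror the two tasks: a binaural localization front-end
(40 channels, 40 Hz–20 kHz, ~3.79 kHz lowpass, 8 kHz output, middle 1 s of
a 1.5 s input → 2×40×8000) and a monaural pitch front-end (100 channels,
60 Hz–16 kHz, 3 kHz lowpass, 20 kHz output, middle 50 ms of 150 ms →
100×1000). The two presets apply compression and lowpass in different
orders, selected by ``stage_order``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, upfirdn

__all__ = [
    "PeripheryConfig", "Cochleagram", "erb", "erb_number", "inverse_erb_number",
    "erb_spaced_cfs", "gammatone_fir", "cochleagram",
    "localization_preset", "pitch_preset",
    "toy_localization_preset", "toy_pitch_preset",
]


# Glasberg & Moore ERB formulas
def erb(f):
    """Equivalent rectangular bandwidth (Hz) at frequency f (Hz)."""
    return 24.7 * (0.00437 * np.asarray(f, dtype=float) + 1.0)


def erb_number(f):
    """ERB-number (Cam) scale value at frequency f (Hz)."""
    return 21.4 * np.log10(0.00437 * np.asarray(f, dtype=float) + 1.0)


def inverse_erb_number(n):
    """Frequency (Hz) at ERB-number n."""
    return (10.0 ** (np.asarray(n, dtype=float) / 21.4) - 1.0) / 0.00437


@dataclass(frozen=True)
class ResamplerParams:
    """Kaiser-windowed-sinc resampler settings."""

    width: int = 64
    rolloff: float = 0.94759
    beta: float = 14.76965


@dataclass(frozen=True)
class PeripheryConfig:
    n_channels: int
    cf_min: float
    cf_max: float
    fir_duration: float            # seconds; gammatone impulse response length
    lowpass_cutoff: float | None   # Hz; None = resampler anti-alias cutoff
    output_rate: int               # Hz
    crop_duration: float           # seconds
    native_rate: int               # Hz; inputs are resampled here first
    stage_order: str = "compress_then_lowpass"
    compression_exponent: float = 0.3
    resampler: ResamplerParams = field(default_factory=ResamplerParams)

    def __post_init__(self):
        if not 0 < self.cf_min < self.cf_max:
            raise ValueError("require 0 < cf_min < cf_max")
        if self.stage_order not in ("compress_then_lowpass", "lowpass_then_compress"):
            raise ValueError(f"unknown stage_order {self.stage_order!r}")
        n_keep = self.crop_duration * self.output_rate
        if abs(n_keep - round(n_keep)) > 1e-9:
            raise ValueError("crop_duration * output_rate must be integral")


@dataclass
class Cochleagram:
    """Peripheral representation: [ears ×] channels × time, all values >= 0."""

    data: np.ndarray
    cfs: np.ndarray
    rate: float

    @property
    def binaural(self) -> bool:
        return self.data.ndim == 3

    def save_h5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            d = f.create_dataset("cochleagram", data=self.data)
            d.attrs["rate"] = self.rate
            f.create_dataset("cfs", data=self.cfs)

    @classmethod
    def load_h5(cls, path) -> "Cochleagram":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(data=f["cochleagram"][...], cfs=f["cfs"][...],
                       rate=float(f["cochleagram"].attrs["rate"]))


def localization_preset() -> PeripheryConfig:
    """Binaural localization front-end (2 × 40 × 8000 for 1.5 s stereo input)."""
    return PeripheryConfig(
        n_channels=40, cf_min=40.0, cf_max=20000.0, fir_duration=0.025,
        lowpass_cutoff=None, output_rate=8000, crop_duration=1.0,
        native_rate=48000, stage_order="compress_then_lowpass")


def pitch_preset() -> PeripheryConfig:
    """Monaural pitch front-end (100 × 1000 for 150 ms mono input)."""
    return PeripheryConfig(
        n_channels=100, cf_min=60.0, cf_max=16000.0, fir_duration=0.05,
        lowpass_cutoff=3000.0, output_rate=20000, crop_duration=0.05,
        native_rate=48000, stage_order="lowpass_then_compress")


def toy_localization_preset() -> PeripheryConfig:
    """Reduced binaural front-end for minutes-scale CPU training.

    16 channels, 16 kHz native rate, 400 Hz output envelope rate,
    0.25 s crop: 2 × 16 × 100 per scene. The envelope rate discards binaural
    fine structure, so the trainable cue set is dominated by interaural
    level differences plus monaural spectra — sufficient for the
    qualitative uncertainty phenomena the toy experiments probe.
    """
    return PeripheryConfig(
        n_channels=16, cf_min=300.0, cf_max=7000.0, fir_duration=0.02,
        lowpass_cutoff=None, output_rate=400, crop_duration=0.25,
        native_rate=16000, stage_order="compress_then_lowpass")


def toy_pitch_preset() -> PeripheryConfig:
    """Reduced monaural front-end for minutes-scale CPU training (30 × 150)."""
    return PeripheryConfig(
        n_channels=30, cf_min=80.0, cf_max=6000.0, fir_duration=0.03,
        lowpass_cutoff=3000.0, output_rate=3000, crop_duration=0.05,
        native_rate=16000, stage_order="lowpass_then_compress")


def erb_spaced_cfs(n: int, fmin: float, fmax: float) -> np.ndarray:
    """n characteristic frequencies uniform on the ERB-number scale.

    First equals fmin, last equals fmax, strictly increasing.
    """
    if n < 2 or not 0 < fmin < fmax:
        raise ValueError("require n >= 2 and 0 < fmin < fmax")
    nums = np.linspace(erb_number(fmin), erb_number(fmax), n)
    cfs = inverse_erb_number(nums)
    cfs[0], cfs[-1] = fmin, fmax
    return cfs


def gammatone_fir(cf: float, rate: float, duration: float) -> np.ndarray:
    """4th-order gammatone impulse response, peak-gain normalized at cf.

    h(t) = t^3 exp(−2π b t) cos(2π cf t), b = 1.019 ERB(cf), truncated to
    ``duration`` seconds.
    """
    if cf >= rate / 2:
        raise ValueError(f"cf {cf} Hz is at or above Nyquist ({rate / 2} Hz)")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    b = 1.019 * float(erb(cf))
    h = t ** 3 * np.exp(-2.0 * np.pi * b * t) * np.cos(2.0 * np.pi * cf * t)
    # normalize magnitude response to 1 at cf
    resp = np.exp(-2j * np.pi * cf * np.arange(n) / rate)
    h = h / np.abs(np.dot(h, resp))
    return h


def _kaiser_sinc_kernel(up: int, down: int, sr_in: float, cutoff: float,
                        params: ResamplerParams) -> tuple[np.ndarray, int]:
    """FIR interpolation kernel for upfirdn; returns (taps, half_length)."""
    sr_up = sr_in * up
    f_c = min(cutoff, sr_up / 2 * 0.999) / (sr_up / 2.0)
    half = int(math.ceil(params.width / f_c))
    half = int(math.ceil(half / down) * down)  # keep delay an integer at sr_out
    n = np.arange(-half, half + 1)
    taps = f_c * np.sinc(f_c * n) * np.kaiser(2 * half + 1, params.beta) * up
    return taps, half


def resample_kaiser(x: np.ndarray, sr_in: int, sr_out: int,
                    cutoff: float | None = None,
                    params: ResamplerParams = ResamplerParams(),
                    axis: int = -1) -> np.ndarray:
    """Resample along ``axis`` with a Kaiser-windowed-sinc filter.

    ``cutoff`` defaults to rolloff × min(sr_in, sr_out)/2, i.e. the
    anti-alias cutoff; an explicit cutoff lowpasses at that frequency
    while resampling.
    """
    if sr_in == sr_out and cutoff is None:
        return np.asarray(x, dtype=float)
    g = math.gcd(int(sr_in), int(sr_out))
    up, down = int(sr_out) // g, int(sr_in) // g
    if cutoff is None:
        cutoff = params.rolloff * min(sr_in, sr_out) / 2.0
    taps, half = _kaiser_sinc_kernel(up, down, sr_in, cutoff, params)
    y = upfirdn(taps, np.asarray(x, dtype=float), up=up, down=down, axis=axis)
    start = half // down
    n_out = int(math.ceil(x.shape[axis] * up / down))
    sl = [slice(None)] * y.ndim
    sl[axis] = slice(start, start + n_out)
    out = y[tuple(sl)]
    if out.shape[axis] < n_out:  # pad tail if the filter ran off the end
        pad = [(0, 0)] * y.ndim
        pad[axis] = (0, n_out - out.shape[axis])
        out = np.pad(out, pad)
    return out


def _lowpass_fir(x: np.ndarray, rate: float, cutoff: float,
                 params: ResamplerParams) -> np.ndarray:
    taps, half = _kaiser_sinc_kernel(1, 1, rate, cutoff, params)
    y = fftconvolve(x, taps[None, :] if x.ndim == 2 else taps, mode="full",
                    axes=-1)
    return y[..., half:half + x.shape[-1]]


def cochleagram(waveform: np.ndarray, rate: int,
                config: PeripheryConfig) -> Cochleagram:
    """Convert a waveform to its cochleagram under ``config``.

    ``waveform``: (n,) mono or (2, n) stereo; returns (channels, time) or
    (ears, channels, time). Stages: gammatone filterbank → half-wave
    rectification → compression and lowpass in ``stage_order`` →
    Kaiser-sinc downsampling → center crop.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    if w.ndim != 2 or w.shape[0] not in (1, 2):
        raise ValueError("waveform must be (n,) mono or (2, n) stereo")
    if rate != config.native_rate:
        w = resample_kaiser(w, rate, config.native_rate,
                            params=config.resampler)
    n_native = w.shape[-1]
    n_out_full = int(math.ceil(n_native * config.output_rate / config.native_rate))
    n_keep = int(round(config.crop_duration * config.output_rate))
    if n_out_full < n_keep:
        need = config.crop_duration * config.native_rate / config.output_rate \
            * config.output_rate
        raise ValueError(
            f"input too short: need at least {config.crop_duration:g} s "
            f"({int(need)} samples at {config.native_rate} Hz) after processing, "
            f"got {n_native / config.native_rate:g} s")

    cfs = erb_spaced_cfs(config.n_channels, config.cf_min, config.cf_max)
    kernels = np.stack([gammatone_fir(cf, config.native_rate, config.fir_duration)
                        for cf in cfs])
    ears = []
    for ear in w:
        sub = fftconvolve(ear[None, :], kernels, mode="full", axes=-1)
        sub = sub[:, :n_native]
        sub = np.maximum(sub, 0.0)                      # half-wave rectify
        if config.stage_order == "compress_then_lowpass":
            sub = sub ** config.compression_exponent
            sub = resample_kaiser(sub, config.native_rate, config.output_rate,
                                  cutoff=config.lowpass_cutoff,
                                  params=config.resampler)
        else:
            sub = _lowpass_fir(sub, config.native_rate,
                               config.lowpass_cutoff, config.resampler)
            sub = np.maximum(sub, 0.0) ** config.compression_exponent
            sub = resample_kaiser(sub, config.native_rate, config.output_rate,
                                  params=config.resampler)
        sub = np.maximum(sub, 0.0)                      # clip filter ringing
        start = (sub.shape[-1] - n_keep) // 2
        ears.append(sub[:, start:start + n_keep])
    data = np.stack(ears) if len(ears) == 2 else ears[0]
    return Cochleagram(data=data, cfs=cfs, rate=float(config.output_rate))
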