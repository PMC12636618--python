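"""Seeded synthesis of stimuli and toy binaural scenes.

Everything the virtual experiments and the desk-scale training runs need:
tones, narrowband/broadband noises, harmonic complexes with controlled
harmonic ranges and phases, trapezoidal spectral filtering, threshold-
equalizing masking noise, level/SNR arithmetic, and a lawful toy binaural
spatializer (Woodworth interaural time differences, frequency-dependent
interaural level differences, a single elevation-dependent high-frequency
pinna notch, and a subtle rear spectral cue — preserving the front/back
ambiguity structure of real heads without a room simulator).

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .periphery import erb

__all__ = [
    "AudioClip", "SceneSpec", "SpeakerGrid", "pure_tone", "jitter_frequency",
    "narrowband_noise", "broadband_noise", "harmonic_complex",
    "trapezoid_spectral_filter", "masking_noise_ten",
    "component_level_above_threshold", "set_level", "set_rms", "mix_at_snr",
    "toy_spatialize", "speaker_grid", "multi_speaker_noise",
    "dbspl_to_rms", "render_toy_scene", "toy_localization_dataset",
    "toy_pitch_dataset",
]

SPEED_OF_SOUND = 343.0      # m/s
HEAD_RADIUS = 0.0875        # m
# software mapping of absolute presentation level: 65 dB SPL <-> RMS 0.05
_REF_SPL, _REF_RMS = 65.0, 0.05


def dbspl_to_rms(level_db_spl: float) -> float:
    """Digital RMS corresponding to a nominal sound pressure level."""
    return _REF_RMS * 10.0 ** ((level_db_spl - _REF_SPL) / 20.0)


@dataclass
class AudioClip:
    waveform: np.ndarray
    rate: int
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.waveform.shape[-1] / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.waveform ** 2)))


@dataclass(frozen=True)
class SceneSpec:
    """A toy binaural training scene: target kind + location + noise floor."""

    target_kind: str            # "broadband" | "bandpass" | "tone"
    azimuth_deg: float
    elevation_deg: float
    snr_db: float
    seed: int
    target_params: tuple = ()


@dataclass(frozen=True)
class SpeakerGrid:
    positions: tuple            # of (azimuth_deg, elevation_deg)

    def __len__(self):
        return len(self.positions)


def _ramp_envelope(n: int, rate: int, ramp_ms: float, shape: str) -> np.ndarray:
    env = np.ones(n)
    nr = int(round(ramp_ms * 1e-3 * rate))
    if nr <= 0:
        return env
    nr = min(nr, n // 2)
    r = np.linspace(0.0, 1.0, nr, endpoint=False)
    if shape == "hann":
        r = np.sin(0.5 * np.pi * r) ** 2
    elif shape != "linear":
        raise ValueError(f"unknown ramp shape {shape!r}")
    env[:nr] = r
    env[n - nr:] = r[::-1]
    return env


def pure_tone(freq: float, duration: float = 0.75, ramp_ms: float = 250.0,
              ramp_shape: str = "linear", rate: int = 44100,
              phase: float = 0.0) -> AudioClip:
    """Sinusoid with on/off ramps; unit amplitude before leveling."""
    if freq >= rate / 2:
        raise ValueError("frequency must be below Nyquist")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w = np.sin(2 * np.pi * freq * t + phase)
    w *= _ramp_envelope(n, rate, ramp_ms, ramp_shape)
    return AudioClip(w, rate, meta={"kind": "tone", "freq": freq})


def jitter_frequency(freq: float, range_octaves: float = 0.5,
                     seed: int = 0) -> float:
    """Uniform log-frequency jitter over a total range of ``range_octaves``
    centered on ``freq`` (i.e. ±range/2 octaves)."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    rng = np.random.default_rng(seed)
    return float(freq * 2.0 ** rng.uniform(-range_octaves / 2, range_octaves / 2))


def narrowband_noise(cf: float, bandwidth_octaves: float = 1.0, order: int = 4,
                     duration: float = 0.75, rate: int = 44100, seed: int = 0,
                     ramp_ms: float = 250.0) -> AudioClip:
    """White noise through a Butterworth bandpass centered (log) on cf."""
    lo = cf * 2.0 ** (-bandwidth_octaves / 2)
    hi = cf * 2.0 ** (bandwidth_octaves / 2)
    if not 0 < lo < hi < rate / 2:
        raise ValueError("band must lie within (0, Nyquist)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    w = rng.normal(size=n)
    sos = butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    w = sosfilt(sos, w)
    w *= _ramp_envelope(n, rate, ramp_ms, "linear")
    return AudioClip(w, rate, meta={"kind": "narrowband", "cf": cf,
                                    "band": (lo, hi)})


def broadband_noise(duration: float = 0.75, rate: int = 44100, seed: int = 0,
                    low_cut: float | None = None, high_cut: float | None = None,
                    ramp_ms: float = 250.0) -> AudioClip:
    """Broadband noise with randomized band edges.

    Unless given explicitly, the lower cutoff is drawn uniformly from
    [20, 60] Hz and the upper from [8, 16] kHz.
    """
    rng = np.random.default_rng(seed)
    if low_cut is None:
        low_cut = rng.uniform(20.0, 60.0)
    if high_cut is None:
        high_cut = rng.uniform(8000.0, 16000.0)
    high_cut = min(high_cut, rate / 2 * 0.99)
    n = int(round(duration * rate))
    w = rng.normal(size=n)
    sos = butter(4, [low_cut, high_cut], btype="bandpass", fs=rate, output="sos")
    w = sosfilt(sos, w)
    w *= _ramp_envelope(n, rate, ramp_ms, "linear")
    return AudioClip(w, rate, meta={"kind": "broadband",
                                    "band": (low_cut, high_cut)})


def harmonic_complex(f0: float, harmonics: range | tuple,
                     phase_mode: str = "sine", duration: float = 0.1,
                     rate: int = 44100, seed: int = 0,
                     ramp_ms: float = 10.0) -> AudioClip:
    """Equal-amplitude harmonic complex tone.

    ``harmonics``: iterable of harmonic numbers (e.g. range(1, 11));
    ``phase_mode``: sine | cosine | random | alternating (sine/cosine for
    odd/even partial order, producing envelope periodicity at 2·f0 when
    only high-numbered harmonics are audible).
    """
    harmonics = list(harmonics)
    if not harmonics or f0 * max(harmonics) >= rate / 2:
        raise ValueError("harmonics must be nonempty and below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w = np.zeros(n)
    for j, h in enumerate(harmonics):
        if phase_mode == "sine":
            ph = 0.0
        elif phase_mode == "cosine":
            ph = np.pi / 2
        elif phase_mode == "random":
            ph = rng.uniform(0, 2 * np.pi)
        elif phase_mode == "alternating":
            ph = 0.0 if j % 2 == 0 else np.pi / 2
        else:
            raise ValueError(f"unknown phase_mode {phase_mode!r}")
        w += np.sin(2 * np.pi * h * f0 * t + ph)
    w *= _ramp_envelope(n, rate, ramp_ms, "linear")
    return AudioClip(w, rate, meta={"kind": "harmonic", "f0": f0,
                                    "harmonics": tuple(harmonics),
                                    "phase_mode": phase_mode})


def trapezoid_spectral_filter(clip: AudioClip, passband: tuple,
                              slope_db_per_octave: float = 50.0) -> AudioClip:
    """Trapezoidal spectral filter: flat in the passband, linear-in-log-f
    rolloff of ``slope_db_per_octave`` outside; applied by FFT multiply."""
    f_lo, f_hi = passband
    if not 0 < f_lo < f_hi:
        raise ValueError("invalid passband")
    n = clip.waveform.shape[-1]
    spec = np.fft.rfft(clip.waveform)
    freqs = np.fft.rfftfreq(n, 1.0 / clip.rate)
    gain_db = np.zeros_like(freqs)
    with np.errstate(divide="ignore"):
        below = freqs < f_lo
        gain_db[below] = -slope_db_per_octave * np.log2(f_lo / freqs[below])
        above = freqs > f_hi
        gain_db[above] = -slope_db_per_octave * np.log2(freqs[above] / f_hi)
    gain = 10.0 ** (gain_db / 20.0)
    gain[freqs == 0] = 0.0
    out = np.fft.irfft(spec * gain, n=n)
    return AudioClip(out, clip.rate, meta={**clip.meta,
                                           "trapezoid": (f_lo, f_hi)})


def masking_noise_ten(duration: float, rate: int,
                      reference_level_db: float = -30.0,
                      seed: int = 0) -> AudioClip:
    """Threshold-equalizing noise: equal power per ERB across frequency.

    White noise is spectrally shaped with amplitude ∝ 1/sqrt(ERB(f)), so
    the power falling in any 1-ERB-wide band is constant — the
    operational core of threshold-equalizing noise, used here to mask
    cochlear distortion products. ``reference_level_db`` (dB re full
    scale) sets the noise power within the 1-ERB band at 1 kHz.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    w = rng.normal(size=n)
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = 1.0 / np.sqrt(erb(np.maximum(freqs, 1.0)))
    shape[freqs == 0] = 0.0
    out = np.fft.irfft(spec * shape, n=n)
    clip = AudioClip(out, rate, meta={"kind": "ten"})
    # calibrate: measure current power in the ERB band at 1 kHz
    p = _band_power(clip, 1000.0)
    target_p = 10.0 ** (reference_level_db / 10.0)
    clip.waveform *= np.sqrt(target_p / p)
    clip.meta["reference_level_db"] = reference_level_db
    return clip


def _band_power(clip: AudioClip, freq: float) -> float:
    """Noise power within the 1-ERB band around ``freq`` (periodogram)."""
    n = clip.waveform.shape[-1]
    spec = np.abs(np.fft.rfft(clip.waveform)) ** 2 / n ** 2
    spec[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / clip.rate)
    half = float(erb(freq)) / 2.0
    band = (freqs >= freq - half) & (freqs <= freq + half)
    return float(spec[band].sum())


def component_level_above_threshold(noise: AudioClip, margin_db: float = 10.0,
                                    probe_freq: float = 1000.0) -> float:
    """Component level (dB re full scale) ``margin_db`` above the masked
    threshold of a probe tone in ``noise``.

    The masked threshold is approximated as the level at which the probe's
    power equals the noise power within the 1-ERB band at the probe
    frequency (power ratio 0 dB in the auditory filter).
    """
    p = _band_power(noise, probe_freq)
    return 10.0 * np.log10(p) + margin_db


def set_rms(clip: AudioClip, rms: float) -> AudioClip:
    cur = clip.rms
    if cur == 0:
        return AudioClip(clip.waveform.copy(), clip.rate, dict(clip.meta))
    return AudioClip(clip.waveform * (rms / cur), clip.rate, dict(clip.meta))


def set_level(clip: AudioClip, level_db: float) -> AudioClip:
    """Scale to an RMS of 10^(level_db/20) re full scale (RMS 1.0)."""
    return set_rms(clip, 10.0 ** (level_db / 20.0))


def mix_at_snr(target: AudioClip, background: AudioClip,
               snr_db: float) -> AudioClip:
    """Add background to target at the stated SNR (RMS ratio, pre-mix);
    the target's level is preserved."""
    if target.rate != background.rate:
        raise ValueError("sampling rates differ")
    nb, nt = background.waveform.shape[-1], target.waveform.shape[-1]
    bg = background.waveform[..., :nt] if nb >= nt else np.pad(
        background.waveform, [(0, 0)] * (background.waveform.ndim - 1)
        + [(0, nt - nb)])
    t_rms, b_rms = target.rms, float(np.sqrt(np.mean(bg ** 2)))
    scale = t_rms / (b_rms * 10.0 ** (snr_db / 20.0)) if b_rms > 0 else 0.0
    return AudioClip(target.waveform + scale * bg, target.rate,
                     {**target.meta, "snr_db": snr_db})


# ---------------------------------------------------------------------------
# Toy binaural spatialization
# ---------------------------------------------------------------------------

def _lateral_angle_deg(azimuth_deg: float) -> float:
    """Lateral angle: azimuth folded onto [−90°, 90°] (front/back share it)."""
    az = (azimuth_deg + 180.0) % 360.0 - 180.0
    if az > 90.0:
        return 180.0 - az
    if az < -90.0:
        return -180.0 - az
    return az


def woodworth_itd(lateral_deg: float, head_radius: float = HEAD_RADIUS) -> float:
    """Woodworth spherical-head ITD (seconds): (r/c)(λ + sin λ)."""
    lam = np.deg2rad(abs(lateral_deg))
    return float(np.sign(lateral_deg) * head_radius / SPEED_OF_SOUND
                 * (lam + np.sin(lam)))


def _ild_db(freqs: np.ndarray, lateral_deg: float) -> np.ndarray:
    """Frequency-dependent interaural level difference (dB, right − left).

    Grows with |lateral angle| (∝ sin λ, so spatial sensitivity is highest
    at the midline) and with frequency (head shadow is a high-frequency
    effect): ILD = 20 · sin λ · f/(f + 1500 Hz) dB.
    """
    lam = np.deg2rad(lateral_deg)
    return 20.0 * np.sin(lam) * freqs / (freqs + 1500.0)


def toy_spatialize(clip: AudioClip, azimuth_deg: float, elevation_deg: float,
                   head_radius: float = HEAD_RADIUS) -> AudioClip:
    """Render a mono clip as a binaural pair with lawful toy cues.

    Cues: Woodworth ITD applied as a fractional delay (split across ears);
    ILD per :func:`_ild_db`; an elevation-dependent spectral notch
    (center 6 kHz + 50 Hz/deg, −15 dB) as a stand-in pinna cue; rear
    sources additionally receive a high-frequency shelf (−8 dB above
    ~3.5 kHz). Front and back locations on a cone of confusion share ITD
    and ILD exactly, so front/back is resolvable only through the
    high-frequency spectral cue — broadband sounds can exploit it,
    low-frequency or narrowband sounds cannot, preserving the real-world
    front/back ambiguity structure.
    """
    if clip.waveform.ndim != 1:
        raise ValueError("toy_spatialize expects a mono clip")
    n = clip.waveform.shape[0]
    spec = np.fft.rfft(clip.waveform)
    freqs = np.fft.rfftfreq(n, 1.0 / clip.rate)
    lat = _lateral_angle_deg(azimuth_deg)
    itd = woodworth_itd(lat, head_radius)
    ild = _ild_db(freqs, lat)
    # positive lateral angle = source on the right: right ear leads & is louder
    phase = np.exp(-1j * np.pi * freqs * itd)       # half delay each ear
    right = spec * np.conj(phase) * 10.0 ** (+ild / 40.0)
    left = spec * phase * 10.0 ** (-ild / 40.0)
    notch_fc = 6000.0 + 50.0 * elevation_deg
    with np.errstate(divide="ignore"):
        logf = np.log2(np.maximum(freqs, 1.0) / notch_fc)
    notch = 10.0 ** (-15.0 / 20.0 * np.exp(-logf ** 2 / (2 * 0.15 ** 2)))
    az = (azimuth_deg + 180.0) % 360.0 - 180.0
    if abs(az) > 90.0:
        shelf = 10.0 ** (-8.0 / 20.0 / (1.0 + np.exp(-(freqs - 3500.0) / 400.0)))
    else:
        shelf = 1.0
    gain = notch * shelf
    out = np.stack([np.fft.irfft(left * gain, n=n),
                    np.fft.irfft(right * gain, n=n)])
    return AudioClip(out, clip.rate, {**clip.meta, "azimuth_deg": azimuth_deg,
                                      "elevation_deg": elevation_deg})


def speaker_grid(kind: str) -> SpeakerGrid:
    """Standard loudspeaker layouts used by the experiments.

    array133: azimuths −90..90° (10° steps) × elevations −20..40° (10°);
    grid504: the training/classification grid (5° az × 10° el);
    frontal19: azimuths −90..90° at elevation 0;
    semicircle18: azimuths 0..180° (10° steps) omitting the ambiguous 90°.
    """
    if kind == "array133":
        pos = [(a, e) for a in range(-90, 100, 10) for e in range(-20, 50, 10)]
    elif kind == "grid504":
        pos = [(a, e) for a in range(0, 360, 5) for e in range(0, 70, 10)]
    elif kind == "frontal19":
        pos = [(a, 0) for a in range(-90, 100, 10)]
    elif kind == "semicircle18":
        pos = [(a, 0) for a in range(0, 190, 10) if a != 90]
    else:
        raise ValueError(f"unknown speaker grid {kind!r}")
    return SpeakerGrid(positions=tuple(pos))


def multi_speaker_noise(width_speakers: int, center_az: float,
                        duration: float = 0.75, rate: int = 44100,
                        seed: int = 0, spacing_deg: float = 10.0,
                        ramp_ms: float = 125.0) -> list[tuple[AudioClip, float]]:
    """Independent white-noise tokens at adjacent azimuths (source-width
    stimuli); width must be odd so a true center exists."""
    if width_speakers not in (1, 3, 5, 7):
        raise ValueError("width_speakers must be one of 1, 3, 5, 7")
    rng = np.random.default_rng(seed)
    half = (width_speakers - 1) // 2
    out = []
    n = int(round(duration * rate))
    for i in range(-half, half + 1):
        w = rng.normal(size=n)
        w *= _ramp_envelope(n, rate, ramp_ms, "linear")
        out.append((AudioClip(w, rate, meta={"kind": "white"}),
                    center_az + i * spacing_deg))
    return out


# ---------------------------------------------------------------------------
# Toy training scenes and datasets
# ---------------------------------------------------------------------------

def _pink_tilt(clip: AudioClip, corner_hz: float = 100.0) -> AudioClip:
    """Impose a 1/f power tilt (flat below ``corner_hz``) on a mono clip."""
    spec = np.fft.rfft(clip.waveform)
    freqs = np.fft.rfftfreq(clip.waveform.size, 1.0 / clip.rate)
    gain = 1.0 / np.sqrt(np.maximum(freqs, corner_hz) / corner_hz)
    out = np.fft.irfft(spec * gain, n=clip.waveform.size)
    return AudioClip(out, clip.rate, dict(clip.meta))


def render_toy_scene(spec: SceneSpec, rate: int = 16000,
                     duration: float = 0.45) -> AudioClip:
    """Render one binaural training scene at desk scale.

    The target (broadband noise, band-limited noise, or a tone) is
    spatialized at the labeled direction; a diffuse background (ten
    independent pink-noise sources at random azimuths) is added at the
    scene's SNR; the binaural result is RMS-normalized to 0.1. Summing
    many weak sources makes the background approximate a diffuse field:
    no single background source is localizable as a competing object and
    the net interaural contrast of the background is small, so the
    scene's interaural cues are attributable to the target. The 1/f
    spectral tilt mimics ambient real-world noise and keeps a
    spectrally flat target separable from the background — with a flat
    background, a level-normalized broadband target near the midline is
    indistinguishable from a background-dominated scene whose target is
    elsewhere, and the readout (correctly) reports a diffuse posterior
    for the whole stimulus class.
    """
    rng = np.random.default_rng(spec.seed)
    kind = spec.target_kind
    if kind == "broadband":
        tgt = broadband_noise(duration, rate, seed=int(rng.integers(2 ** 31)),
                              low_cut=50.0, high_cut=rate / 2 * 0.9,
                              ramp_ms=20.0)
    elif kind == "bandpass":
        cf, bw = spec.target_params
        tgt = narrowband_noise(cf, bw, duration=duration, rate=rate,
                               seed=int(rng.integers(2 ** 31)), ramp_ms=20.0)
    elif kind == "tone":
        (freq,) = spec.target_params
        tgt = pure_tone(freq, duration, ramp_ms=20.0, rate=rate,
                        phase=rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    bin_t = toy_spatialize(set_rms(tgt, 0.05), spec.azimuth_deg,
                           spec.elevation_deg)
    bg = np.zeros_like(bin_t.waveform)
    for _ in range(10):
        src = broadband_noise(duration, rate, seed=int(rng.integers(2 ** 31)),
                              low_cut=50.0, high_cut=rate / 2 * 0.9,
                              ramp_ms=5.0)
        src = _pink_tilt(src)
        sp = toy_spatialize(set_rms(src, 0.05), rng.uniform(0, 360),
                            rng.uniform(0, 40))
        bg += sp.waveform
    mixed = mix_at_snr(AudioClip(bin_t.waveform, rate, dict(bin_t.meta)),
                       AudioClip(bg, rate), spec.snr_db)
    return set_rms(mixed, 0.1)


def sample_scene_specs(n: int, seed: int, rate: int = 16000,
                       az_step: float = 5.0, el_values=(0, 10, 20, 30, 40, 50, 60),
                       snr_range=(-15.0, 30.0)) -> list[SceneSpec]:
    """Draw toy training-scene specifications.

    Target mix: 50% band-limited noise (bandwidth 0.5–4 octaves, emulating
    the bandpass augmentation of naturalistic corpora), 25% broadband
    noise, 25% pure tones; azimuth on the 5° grid, elevation on the 10°
    grid, SNR uniform over ``snr_range`` dB.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        u = rng.random()
        if u < 0.5:
            cf = float(np.exp(rng.uniform(np.log(400.0), np.log(5000.0))))
            bw = float(rng.uniform(0.5, 4.0))
            bw = min(bw, 2 * np.log2(rate / 2 * 0.95 / cf), 2 * np.log2(cf / 60))
            kind, params = "bandpass", (cf, max(bw, 0.3))
        elif u < 0.75:
            kind, params = "broadband", ()
        else:
            freq = float(np.exp(rng.uniform(np.log(400.0), np.log(6000.0))))
            kind, params = "tone", (freq,)
        specs.append(SceneSpec(
            target_kind=kind,
            azimuth_deg=float(rng.integers(0, int(360 / az_step)) * az_step),
            elevation_deg=float(rng.choice(el_values)),
            snr_db=float(rng.uniform(*snr_range)),
            seed=int(rng.integers(2 ** 31)),
            target_params=params))
    return specs


def toy_localization_dataset(n: int, seed: int, periphery_config=None,
                             rate: int = 16000):
    """n labeled toy scenes run through the toy periphery -> LabeledScene
    list (import-cycle-free lazy imports)."""
    from .model_core import LabeledScene
    from .periphery import cochleagram, toy_localization_preset
    from .distributions import SphericalLocation
    cfg = periphery_config or toy_localization_preset()
    scenes = []
    for spec in sample_scene_specs(n, seed, rate=rate):
        clip = render_toy_scene(spec, rate=rate)
        coch = cochleagram(clip.waveform, rate, cfg)
        scenes.append(LabeledScene(
            cochleagram=coch.data,
            label=SphericalLocation.from_degrees(spec.azimuth_deg,
                                                 spec.elevation_deg)))
    return scenes


def toy_pitch_dataset(n: int, seed: int, periphery_config=None,
                      rate: int = 16000, f0_range=(80.0, 1000.0),
                      snr_range=(-10.0, 10.0)):
    """n labeled pitch excerpts: harmonic complexes / tones in noise, with
    the log-f0 label; run through the toy pitch periphery."""
    from .model_core import LabeledScene
    from .periphery import cochleagram, toy_pitch_preset
    cfg = periphery_config or toy_pitch_preset()
    rng = np.random.default_rng(seed)
    duration = 0.15
    scenes = []
    for _ in range(n):
        f0 = float(np.exp(rng.uniform(np.log(f0_range[0]), np.log(f0_range[1]))))
        u = rng.random()
        if u < 0.25:
            tgt = pure_tone(f0, duration, ramp_ms=10.0, rate=rate,
                            phase=rng.uniform(0, 2 * np.pi))
        else:
            hmax = int(min(12, rate / 2 * 0.9 / f0))
            lo = int(rng.integers(1, max(2, hmax - 2)))
            hi = int(min(hmax, lo + int(rng.integers(3, 10))))
            tgt = harmonic_complex(f0, range(lo, hi + 1), phase_mode="random",
                                   duration=duration, rate=rate,
                                   seed=int(rng.integers(2 ** 31)))
        noise = broadband_noise(duration, rate, seed=int(rng.integers(2 ** 31)),
                                low_cut=50.0, high_cut=rate / 2 * 0.9,
                                ramp_ms=5.0)
        mixed = mix_at_snr(set_rms(tgt, 0.05), noise,
                           float(rng.uniform(*snr_range)))
        coch = cochleagram(set_rms(mixed, 0.1).waveform, rate, cfg)
        scenes.append(LabeledScene(cochleagram=coch.data, label=float(np.log(f0))))
    return scenes
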