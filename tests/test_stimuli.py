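import numpy as np
import pytest
from scipy.stats import kstest

from percept import stimuli as st


def _band_db(w, rate, a, b):
    spec = np.abs(np.fft.rfft(w)) ** 2
    fr = np.fft.rfftfreq(w.size, 1.0 / rate)
    m = (fr >= a) & (fr < b)
    return 10 * np.log10(spec[m].mean())


def test_pure_tone_samples_and_ramp():
    clip = st.pure_tone(600.0, 0.75, ramp_ms=250.0, rate=44100)
    assert clip.waveform.size == int(0.75 * 44100)
    spec = np.abs(np.fft.rfft(clip.waveform))
    fr = np.fft.rfftfreq(clip.waveform.size, 1 / 44100)
    assert abs(fr[np.argmax(spec)] - 600.0) <= fr[1]
    # linear 250 ms ramp: envelope 0.5 at t = 125 ms
    i = int(0.125 * 44100)
    seg = clip.waveform[i - 40:i + 40]
    assert np.abs(seg).max() == pytest.approx(0.5, abs=0.01)


def test_pure_tone_rejects_above_nyquist():
    with pytest.raises(ValueError):
        st.pure_tone(30000.0, 0.1, rate=44100)


def test_jitter_bounds_uniform_and_deterministic():
    f = 2000.0
    vals = np.array([st.jitter_frequency(f, 0.5, s) for s in range(10000)])
    assert np.all(vals >= f * 2 ** -0.25) and np.all(vals <= f * 2 ** 0.25)
    stat = kstest(np.log2(vals / f), "uniform", args=(-0.25, 0.5)).pvalue
    assert stat > 0.01
    assert st.jitter_frequency(f, 0.5, 7) == st.jitter_frequency(f, 0.5, 7)


def test_narrowband_power_in_band():
    clip = st.narrowband_noise(2000.0, 1.0, order=4, duration=1.0,
                               rate=44100, seed=3, ramp_ms=10)
    spec = np.abs(np.fft.rfft(clip.waveform)) ** 2
    fr = np.fft.rfftfreq(clip.waveform.size, 1 / 44100)
    band = (fr >= 2000 * 2 ** -0.5) & (fr <= 2000 * 2 ** 0.5)
    assert spec[band].sum() / spec.sum() >= 0.90


def test_narrowband_seeds_uncorrelated():
    a = st.narrowband_noise(2000.0, duration=0.5, rate=44100, seed=1)
    b = st.narrowband_noise(2000.0, duration=0.5, rate=44100, seed=2)
    r = np.corrcoef(a.waveform, b.waveform)[0, 1]
    assert abs(r) < 0.05


def test_broadband_cutoffs_and_flatness():
    lows, highs = [], []
    for s in range(400):
        clip = st.broadband_noise(0.05, 44100, seed=s)
        lo, hi = clip.meta["band"]
        lows.append(lo)
        highs.append(hi)
    assert min(lows) >= 20 and max(lows) <= 60
    assert min(highs) >= 8000 and max(highs) <= 16000
    clip = st.broadband_noise(2.0, 44100, seed=9, ramp_ms=10)
    lo, hi = clip.meta["band"]
    mids = np.geomspace(2 * lo, hi / 2, 8)
    levels = [_band_db(clip.waveform, 44100, a, b)
              for a, b in zip(mids[:-1], mids[1:])]
    assert max(levels) - min(levels) < 6.0    # +-3 dB about the mean


def test_broadband_deterministic():
    a = st.broadband_noise(0.1, 44100, seed=5)
    b = st.broadband_noise(0.1, 44100, seed=5)
    assert np.array_equal(a.waveform, b.waveform)


def test_harmonic_spectra():
    clip = st.harmonic_complex(200.0, range(1, 11), "sine", 0.5, 44100)
    spec = np.abs(np.fft.rfft(clip.waveform))
    fr = np.fft.rfftfreq(clip.waveform.size, 1 / 44100)
    peaks = fr[spec > spec.max() * 0.1]
    assert peaks.min() > 150 and peaks.max() < 2100
    # magnitude spectrum invariant to phase mode
    r = st.harmonic_complex(200.0, range(1, 11), "random", 0.5, 44100, seed=4)
    sr = np.abs(np.fft.rfft(r.waveform))
    interior = slice(2000, -2000)   # ignore ramp-dominated spectral skirts
    assert np.allclose(np.sort(sr)[-10:], np.sort(spec)[-10:], rtol=0.05)


def test_alternating_phase_envelope_2f0():
    f0 = 100.0
    clip = st.harmonic_complex(f0, range(18, 31), "alternating", 0.5, 44100,
                               ramp_ms=5)
    env = np.abs(clip.waveform)
    from scipy.signal import fftconvolve
    env = fftconvolve(env, np.ones(50) / 50, mode="same")
    ac = np.correlate(env - env.mean(), env - env.mean(), "full")
    ac = ac[ac.size // 2:]
    lag_f0 = int(round(44100 / f0))
    lag_2f0 = int(round(44100 / (2 * f0)))
    assert ac[lag_2f0 - 5:lag_2f0 + 6].max() > 0.5 * ac[0]


def test_trapezoid_slope_and_cascade():
    rng = np.random.default_rng(1)
    clip = st.AudioClip(rng.normal(size=2 ** 16), 44100)
    f = st.trapezoid_spectral_filter(clip, (1000.0, 2000.0), 50.0)
    drop = _band_db(f.waveform, 44100, 480, 520) - \
        _band_db(clip.waveform, 44100, 480, 520)
    assert drop == pytest.approx(-50.0, abs=1.5)
    ff = st.trapezoid_spectral_filter(f, (1000.0, 2000.0), 50.0)
    drop2 = _band_db(ff.waveform, 44100, 480, 520) - \
        _band_db(clip.waveform, 44100, 480, 520)
    assert drop2 == pytest.approx(-100.0, abs=2.5)
    # in-band tone RMS preserved
    tone = st.pure_tone(1500.0, 0.2, ramp_ms=5, rate=44100)
    ft = st.trapezoid_spectral_filter(tone, (1000.0, 2000.0))
    assert ft.rms == pytest.approx(tone.rms, rel=0.01)


def test_ten_constant_power_per_erb():
    ten = st.masking_noise_ten(2.0, 44100, -30.0, seed=2)
    freqs = np.geomspace(100, 10000, 9)
    powers = [10 * np.log10(st._band_power(ten, f)) for f in freqs]
    assert max(powers) - min(powers) < 4.0    # +-2 dB
    assert 10 * np.log10(st._band_power(ten, 1000.0)) == pytest.approx(-30.0,
                                                                       abs=0.1)


def test_component_margin_additivity():
    ten = st.masking_noise_ten(0.5, 44100, -30.0, seed=3)
    assert st.component_level_above_threshold(ten, 20.0) - \
        st.component_level_above_threshold(ten, 10.0) == pytest.approx(10.0)


def test_set_level_and_mix_at_snr(rng):
    clip = st.AudioClip(rng.normal(size=44100), 44100)
    leveled = st.set_rms(clip, 0.1)
    assert leveled.rms == pytest.approx(0.1, abs=1e-6)
    bg = st.AudioClip(rng.normal(size=44100), 44100)
    mix0 = st.mix_at_snr(leveled, bg, 0.0)
    added = mix0.waveform - leveled.waveform
    assert np.sqrt((added ** 2).mean()) == pytest.approx(0.1, abs=1e-6)
    mix6 = st.mix_at_snr(leveled, bg, 6.02)
    added6 = mix6.waveform - leveled.waveform
    assert np.sqrt((added ** 2).mean()) / np.sqrt((added6 ** 2).mean()) == \
        pytest.approx(2.0, abs=1e-3)


def test_spatialize_itd_midline_and_woodworth():
    clip = st.broadband_noise(0.3, 48000, seed=1, high_cut=15000, ramp_ms=5)
    mid = st.toy_spatialize(clip, 0.0, 0.0)
    l, r = mid.waveform
    xc = np.correlate(r, l, "full")
    lag = np.argmax(xc) - (l.size - 1)
    assert abs(lag) <= 1
    side = st.toy_spatialize(clip, 90.0, 0.0)
    l, r = side.waveform
    xc = np.correlate(r, l, "full")
    lag = np.argmax(xc) - (l.size - 1)
    expect = st.HEAD_RADIUS / st.SPEED_OF_SOUND * (np.pi / 2 + 1) * 48000
    assert abs(abs(lag) - expect) <= 2


def test_spatialize_mirror_symmetry():
    clip = st.broadband_noise(0.2, 16000, seed=4, high_cut=7000, ramp_ms=5)
    a = st.toy_spatialize(clip, 35.0, 10.0).waveform
    b = st.toy_spatialize(clip, -35.0, 10.0).waveform
    assert np.allclose(a, b[::-1], atol=1e-6)


def test_front_back_share_interaural_cues():
    clip = st.narrowband_noise(500.0, duration=0.2, rate=16000, seed=5,
                               ramp_ms=5)
    front = st.toy_spatialize(clip, 40.0, 0.0).waveform
    back = st.toy_spatialize(clip, 140.0, 0.0).waveform
    # at low frequencies (below the rear shelf) front and back match
    assert np.allclose(front, back, atol=1e-3)


def test_speaker_grids():
    assert len(st.speaker_grid("array133")) == 133
    assert len(st.speaker_grid("grid504")) == 504
    assert len(st.speaker_grid("frontal19")) == 19
    semi = st.speaker_grid("semicircle18")
    assert len(semi) == 18
    assert all(az != 90 for az, _ in semi.positions)
    for kind in ("array133", "grid504", "frontal19", "semicircle18"):
        pos = st.speaker_grid(kind).positions
        assert len(set(pos)) == len(pos)
    with pytest.raises(ValueError):
        st.speaker_grid("bogus")


def test_multi_speaker_noise():
    toks = st.multi_speaker_noise(7, 0.0, duration=1.0, rate=16000, seed=6)
    assert [az for _, az in toks] == [-30, -20, -10, 0, 10, 20, 30]
    for i in range(len(toks)):
        for j in range(i + 1, len(toks)):
            r = np.corrcoef(toks[i][0].waveform, toks[j][0].waveform)[0, 1]
            assert abs(r) < 0.05
    assert len(st.multi_speaker_noise(1, 0.0, rate=16000, seed=1)) == 1
    with pytest.raises(ValueError):
        st.multi_speaker_noise(4, 0.0)


def test_scene_reproducible():
    spec = st.SceneSpec("bandpass", 120.0, 20.0, 5.0, 99, (1500.0, 1.0))
    a = st.render_toy_scene(spec)
    b = st.render_toy_scene(spec)
    assert np.array_equal(a.waveform, b.waveform)
    assert a.rms == pytest.approx(0.1, abs=1e-9)
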