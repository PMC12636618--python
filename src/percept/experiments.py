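"""Virtual psychophysics: run the experimental protocols on a model.

Protocols implemented (model side): absolute localization of controlled
stimuli with confidence bets (7 conditions × 19 azimuths), front/back
discrimination with bets (4 conditions × 18 azimuths × 5 elevations),
uncertainty-based stimulus screening (percentile selection), and pitch
discrimination of tone pairs with posterior-variance confidence.

A "model" is anything mapping a cochleagram array to a predicted mixture
(e.g. ``NetworkModel.predict_mixture`` or the NetworkModel itself); stub
callables work for testing. Trial tables are pandas DataFrames; bets are
assigned only after experiment-level pooling of the uncertainty column.
Every table is exactly reproducible from (model, protocol config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stimuli as st
from .confidence import assign_bets
from .periphery import cochleagram, toy_localization_preset, toy_pitch_preset
from .posterior_tools import (
    binary_entropy_bits, circular_histogram, constrained_map_f0,
    fold_to_frontal, histogram_mode, hpd_width, mode_local_variance,
)
from .distributions import sample_von_mises_mixture

__all__ = [
    "TrialRecord", "run_exp3", "run_exp4", "screen_by_uncertainty",
    "run_exp6", "EXP3_CONDITIONS", "EXP4_CONDITIONS", "EXP6_STIMULUS_TYPES",
]

# 7 conditions: broadband noise + {narrowband noise, pure tone} × {600, 2000, 4000 Hz}
EXP3_CONDITIONS = (
    ("broadband", None),
    ("narrowband", 600.0), ("narrowband", 2000.0), ("narrowband", 4000.0),
    ("tone", 600.0), ("tone", 2000.0), ("tone", 4000.0),
)
# 4 conditions: broadband noise + pure tones at 600/2000/4000 Hz
EXP4_CONDITIONS = (
    ("broadband", None), ("tone", 600.0), ("tone", 2000.0), ("tone", 4000.0),
)
# 5 pitch stimulus types: (name, harmonic range or None, phase mode)
EXP6_STIMULUS_TYPES = (
    ("pure_tone", None, None),
    ("low_harm", (1, 10), "sine"),
    ("mid_harm", (8, 17), "sine"),
    ("high_harm_sine", (18, 30), "sine"),
    ("high_harm_rand", (18, 30), "random"),
)


# per-participant trial counts of the human protocols (for structural checks);
# exp1 used 160 natural sounds × 7 speaker locations
PROTOCOL_TRIAL_COUNTS = {
    "exp1": 160 * 7,
    "exp3": len(EXP3_CONDITIONS) * 19 * 3,
    "exp4": len(EXP4_CONDITIONS) * 18 * 5,
    "exp6": len(EXP6_STIMULUS_TYPES) * 6 * 2 * 5,
}


@dataclass(frozen=True)
class TrialRecord:
    """One virtual trial; tables are built from lists of these."""

    experiment: str
    condition: str
    stimulus: dict
    true_label: tuple
    response: float | str
    uncertainty: float
    seed: int
    correct: bool | None = None


def _predict_fn(model):
    """Normalize a model to a callable (cochleagram_data, trial_info) -> mixture.

    Accepts a NetworkModel (uses predict_mixture), a one-argument callable
    over the cochleagram, or a two-argument callable that also receives a
    trial-info dict (useful for stub models in tests).
    """
    import inspect
    if getattr(model, "trained", True) is False:
        raise ValueError(
            "model has not been trained; train it (or load a trained "
            "checkpoint) before running virtual experiments")
    fn = model.predict_mixture if hasattr(model, "predict_mixture") else model
    try:
        n_par = len(inspect.signature(fn).parameters)
    except (TypeError, ValueError):
        n_par = 1
    if n_par >= 2:
        return fn
    return lambda data, info: fn(data)


def _wrap_deg(a):
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def _loc_posterior_summaries(mixture, seed: int, n: int = 5000,
                             fold_frontal: bool = False):
    """One sampling pass -> (map_az, map_el, hpd50_az, p_front).

    With ``fold_frontal`` the azimuthal samples are reflected onto the
    frontal hemifield before the MAP estimate (frontal-arc response
    protocols). The HPD width and ``p_front`` always come from the raw
    samples: front/back ambiguity is part of the model's uncertainty even
    when the response scale cannot express it.
    """
    samples = np.rad2deg(sample_von_mises_mixture(mixture, n, seed))
    az_mass, az_centers = circular_histogram(samples[:, 0])
    el_mass, el_centers = circular_histogram(samples[:, 1])
    if fold_frontal:
        fold_mass, fold_centers = circular_histogram(
            fold_to_frontal(samples[:, 0]))
        map_az = histogram_mode(fold_mass, fold_centers)
    else:
        map_az = histogram_mode(az_mass, az_centers)
    map_el = histogram_mode(el_mass, el_centers)
    width = hpd_width(az_mass, 0.5)
    p_front = float(np.mean(np.abs(_wrap_deg(samples[:, 0])) <= 90.0))
    return map_az, map_el, width, p_front


def _make_loc_stimulus(kind: str, cf, rng: np.random.Generator, rate: int,
                       duration: float, jitter_octaves: float):
    seed = int(rng.integers(2 ** 31))
    if kind == "broadband":
        clip = st.broadband_noise(duration, rate, seed=seed,
                                  high_cut=min(16000.0, rate / 2 * 0.9))
        return clip, {"kind": kind}
    cf_j = st.jitter_frequency(cf, jitter_octaves, int(rng.integers(2 ** 31)))
    if kind == "narrowband":
        return (st.narrowband_noise(cf_j, 1.0, duration=duration, rate=rate,
                                    seed=seed),
                {"kind": kind, "cf_nominal": cf, "cf": cf_j})
    if kind == "tone":
        return (st.pure_tone(cf_j, duration, rate=rate,
                             phase=rng.uniform(0, 2 * np.pi)),
                {"kind": kind, "cf_nominal": cf, "cf": cf_j})
    raise ValueError(f"unknown stimulus kind {kind!r}")


def _render_and_predict(predict, clip, az, el, periphery, info):
    spatial = st.toy_spatialize(st.set_rms(clip, 0.05), az, el)
    normed = st.set_rms(spatial, 0.1)
    coch = cochleagram(normed.waveform, clip.rate, periphery)
    return predict(coch.data, info)


def run_exp3(model, repeats: int = 3, seed: int = 0, periphery=None,
             rate: int = 16000, duration: float = 0.75,
             jitter_octaves: float = 0.5, conditions=EXP3_CONDITIONS,
             azimuths=None) -> pd.DataFrame:
    """Absolute localization with bets: conditions × frontal azimuths × repeats.

    Defaults: 7 conditions × 19 azimuths (−90°..90°, 10° steps) × 3
    repeats = 399 rows. Elevation drawn per trial from {0..40}° in 10°
    steps. Response = Monte Carlo MAP azimuth; uncertainty = 50% HPD width
    of the azimuthal posterior; bets assigned over the whole table.
    """
    predict = _predict_fn(model)
    periphery = periphery or toy_localization_preset()
    if azimuths is None:
        azimuths = [a for a, _ in st.speaker_grid("frontal19").positions]
    ss = np.random.SeedSequence(seed)
    rows = []
    for (kind, cf) in conditions:
        for az in azimuths:
            for rep in range(repeats):
                trial_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2 ** 31)
                rng = np.random.default_rng(trial_seed)
                el = float(rng.choice([0, 10, 20, 30, 40]))
                clip, meta = _make_loc_stimulus(kind, cf, rng, rate, duration,
                                                jitter_octaves)
                info = {**meta, "azimuth_deg": float(az),
                        "elevation_deg": el}
                mixture = _render_and_predict(predict, clip, az, el,
                                              periphery, info)
                map_az, map_el, width, _ = _loc_posterior_summaries(
                    mixture, trial_seed, fold_frontal=True)
                err = abs(float(_wrap_deg(map_az - az)))
                rows.append(dict(
                    experiment="exp3", condition=f"{kind}_{int(cf)}" if cf
                    else kind, kind=kind, cf=cf if cf else np.nan,
                    azimuth_true=float(az), elevation_true=el, repeat=rep,
                    azimuth_resp=map_az, elevation_resp=map_el,
                    abs_error=err, uncertainty=width, seed=trial_seed))
    table = pd.DataFrame(rows)
    table["bet"] = assign_bets(table["uncertainty"].to_numpy())
    return table


def run_exp4(model, repeats: int = 1, seed: int = 0, periphery=None,
             rate: int = 16000, duration: float = 0.75,
             conditions=EXP4_CONDITIONS, azimuths=None,
             elevations=(0, 10, 20, 30, 40)) -> pd.DataFrame:
    """Front/back discrimination with bets.

    Defaults: 4 conditions × 18 azimuths (0..180° omitting 90°) × 5
    elevations = 360 rows per repeat block. Response = hemifield with the
    larger posterior mass; uncertainty = binary front/back entropy. The
    ``position`` column (0–80°) pairs each azimuth with its cone-of-
    confusion partner for analysis.
    """
    predict = _predict_fn(model)
    periphery = periphery or toy_localization_preset()
    if azimuths is None:
        azimuths = [a for a, _ in st.speaker_grid("semicircle18").positions]
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep in range(repeats):
        for (kind, cf) in conditions:
            for az in azimuths:
                for el in elevations:
                    trial_seed = int(
                        ss.spawn(1)[0].generate_state(1)[0] % 2 ** 31)
                    rng = np.random.default_rng(trial_seed)
                    clip, meta = _make_loc_stimulus(kind, cf, rng, rate,
                                                    duration, 0.5)
                    info = {**meta, "azimuth_deg": float(az),
                            "elevation_deg": float(el)}
                    mixture = _render_and_predict(predict, clip, az, el,
                                                  periphery, info)
                    _, _, _, p_front = _loc_posterior_summaries(
                        mixture, trial_seed)
                    truly_front = az < 90
                    resp_front = p_front >= 0.5
                    rows.append(dict(
                        experiment="exp4", condition=f"{kind}_{int(cf)}" if cf
                        else kind, kind=kind, cf=cf if cf else np.nan,
                        azimuth_true=float(az), elevation_true=float(el),
                        position=float(az if az < 90 else 180 - az),
                        repeat=rep, truly_front=truly_front,
                        resp_front=bool(resp_front), p_front=p_front,
                        correct=bool(resp_front == truly_front),
                        uncertainty=binary_entropy_bits(p_front),
                        seed=trial_seed))
    table = pd.DataFrame(rows)
    table["bet"] = assign_bets(table["uncertainty"].to_numpy())
    return table


def screen_by_uncertainty(table: pd.DataFrame, low_pct: float = 5.0,
                          high_pct: float = 95.0, k: int = 10,
                          stimulus_col: str = "stimulus_id",
                          uncertainty_col: str = "uncertainty"):
    """Select the k stimuli centered on two uncertainty percentiles.

    Uncertainty is first averaged per stimulus over all its rows
    (elevations, repeats, models); stimuli are then ranked, and the k
    ranks centered on each percentile position are returned
    (low-uncertainty list, high-uncertainty list). Deliberately avoids
    the extremes, and guarantees disjoint lists.
    """
    means = table.groupby(stimulus_col)[uncertainty_col].mean()
    n = len(means)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} distinct stimuli")
    if 2 * k > n - 2:
        raise ValueError(f"cannot select two disjoint lists of {k} from {n} "
                         "while excluding the extreme stimuli")
    order = means.sort_values(kind="stable").index.to_list()
    # ranks 0 and n-1 (the single lowest/highest-uncertainty stimuli) are
    # excluded from both windows
    first, last = 1, n - 1 - k

    def window(pct):
        center = int(round(pct / 100.0 * (n - 1)))
        lo = min(max(first, center - (k - 1) // 2), last)
        return lo, lo + k
    lo1, hi1 = window(low_pct)
    lo2, hi2 = window(high_pct)
    if hi1 > lo2:                       # disjointness: push windows apart
        overlap = hi1 - lo2
        lo1 = max(first, lo1 - overlap)
        hi1 = lo1 + k
        lo2 = max(hi1, lo2)
        hi2 = lo2 + k
    return order[lo1:hi1], order[lo2:hi2]


def _exp6_stimulus(stim_type, f0: float, max_f0: float, rate: int,
                   duration: float, seed: int,
                   noise_level_db: float = -30.0) -> st.AudioClip:
    """Synthesize one pitch stimulus in threshold-equalizing noise."""
    name, harm, phase = stim_type
    rng = np.random.default_rng(seed)
    noise = st.masking_noise_ten(duration, rate, noise_level_db,
                                 int(rng.integers(2 ** 31)))
    if name == "pure_tone":
        # tones set 20 dB above the masked-audibility level in the noise
        level = st.component_level_above_threshold(noise, 20.0, f0)
        tone = st.set_level(st.pure_tone(f0, duration, ramp_ms=10.0, rate=rate,
                                         phase=rng.uniform(0, 2 * np.pi)),
                            level)
        return st.AudioClip(tone.waveform + noise.waveform, rate,
                            {"kind": name, "f0": f0})
    lo_h, hi_h = harm
    hi_h = min(hi_h, int(rate / 2 * 0.95 / f0))
    comp = st.harmonic_complex(f0, range(lo_h, hi_h + 1), phase,
                               duration=duration, rate=rate,
                               seed=int(rng.integers(2 ** 31)), ramp_ms=10.0)
    # passband edges tied to the harmonic numbers at the larger trial f0
    comp = st.trapezoid_spectral_filter(comp, (lo_h * max_f0, hi_h * max_f0))
    # each component 10 dB above the 1 kHz masked-audibility level
    comp_level = st.component_level_above_threshold(noise, 10.0, 1000.0)
    n_comp = hi_h - lo_h + 1
    comp = st.set_level(comp, comp_level + 10.0 * np.log10(n_comp))
    return st.AudioClip(comp.waveform + noise.waveform, rate,
                        {"kind": name, "f0": f0})


def run_exp6(model, f0_diff_grid=None, nominal_f0s=(150.0, 300.0),
             n_targets: int = 121, stimulus_types=EXP6_STIMULUS_TYPES,
             seed: int = 0, periphery=None, rate: int = 44100,
             duration: float = 0.15, mc_samples: int = 5000) -> pd.DataFrame:
    """Pitch discrimination of target/probe pairs.

    For each stimulus type, nominal f0, target f0 (``n_targets`` uniformly
    spaced over ±6% of nominal) and f0 difference, the probe is shifted up
    or down at random; the response is "probe higher" iff the constrained
    MAP f0 of the probe exceeds that of the target. Uncertainty = mean of
    the two mode-local posterior variances. Bets assigned over the table.
    """
    predict = _predict_fn(model)
    periphery = periphery or toy_pitch_preset()
    if f0_diff_grid is None:
        f0_diff_grid = np.round(np.arange(1, 31) * 0.2, 10)   # 0.2..6 %f0
    ss = np.random.SeedSequence(seed)
    rows = []
    for stim_type in stimulus_types:
        for nominal in nominal_f0s:
            targets = nominal * (1.0 + np.linspace(-0.06, 0.06, n_targets))
            for f0_t in targets:
                for diff in f0_diff_grid:
                    trial_seed = int(
                        ss.spawn(1)[0].generate_state(1)[0] % 2 ** 31)
                    rng = np.random.default_rng(trial_seed)
                    up = bool(rng.random() < 0.5)
                    f0_p = f0_t * (1.0 + (diff / 100.0) * (1 if up else -1))
                    max_f0 = max(f0_t, f0_p)
                    ests, mlvs = [], []
                    for f0 in (f0_t, f0_p):
                        clip = _exp6_stimulus(stim_type, f0, max_f0, rate,
                                              duration,
                                              int(rng.integers(2 ** 31)))
                        coch = cochleagram(st.set_rms(clip, 0.1).waveform,
                                           rate, periphery)
                        mix = predict(coch.data,
                                      {"kind": stim_type[0], "f0": f0,
                                       "nominal_f0": nominal})
                        ests.append(constrained_map_f0(
                            mix, nominal, n=mc_samples,
                            seed=int(rng.integers(2 ** 31))))
                        mlvs.append(mode_local_variance(mix))
                    resp_higher = ests[1] > ests[0]
                    rows.append(dict(
                        experiment="exp6", condition=stim_type[0],
                        nominal_f0=nominal, f0_target=f0_t, f0_probe=f0_p,
                        f0_diff_pct=float(diff), probe_up=up,
                        map_target=ests[0], map_probe=ests[1],
                        resp_higher=bool(resp_higher),
                        correct=bool(resp_higher == up),
                        uncertainty=float(np.mean(mlvs)), seed=trial_seed))
    table = pd.DataFrame(rows)
    table["bet"] = assign_bets(table["uncertainty"].to_numpy())
    return table
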