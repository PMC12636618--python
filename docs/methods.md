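# Methods and conventions

This document records the scientific conventions the package commits to,
and the reasoning behind the desk-scale ("toy") design choices. Everything
here is implemented and unit-tested; file references point at the module
that owns each definition.

## Coordinates and units

- Azimuth: degrees (or radians internally), 0° straight ahead, positive to
  the listener's right, wrapped to (−180°, 180°]. The front hemifield is
  |az| ≤ 90°; the boundary counts as front (the protocols omit ±90° where
  it matters).
- Elevation: degrees above the horizontal plane.
- Pitch is estimated as s = ln f0 (natural-log Hz), bounded to [3, 10]
  (≈20 Hz – 22 kHz). The f0 analysis range is 80–1000 Hz discretized into
  700 bins of 1/16 semitone (≈0.36% per bin) — `posterior_tools.log_f0_bin_edges`.
- Audio is float waveform at native rates; levels are RMS re full scale
  (1.0), with 65 dB SPL conventionally mapped to RMS 0.05
  (`stimuli.dbspl_to_rms`). Binaural scenes are RMS-normalized to 0.1.

## Mixture readouts (`distributions`, `model_core`)

Location readout: a K=5 mixture of bivariate von Mises components with
independent azimuth/elevation factors,

    p(az, el) = Σ_k α_k vM(az; μ_k1, κ_k1) vM(el; μ_k2, κ_k2).

Pitch readout: a K=5 Gaussian mixture over s = ln f0. Constraint
transforms applied to raw network outputs:

- weights: softmax;
- circular means: atan2(tanh u, tanh v);
- concentrations: hard clip to [1, 512] ("relux"). κ = 512 corresponds to
  a circular variance of ≈1/512 ≈ 0.002 rad²;
- pitch means: clip to [3, 10]; variances: softplus + 1e−9.

`log_i0` (log modified Bessel I₀, needed by the von Mises normalizer) uses
the Abramowitz–Stegun piecewise polynomials with the switch at κ = 3.75,
accurate to <1e−4 against a converged power series.

Training minimizes the exact negative log-likelihood (a strictly proper
scoring rule — the reason the readout learns *calibrated* uncertainty) via
a small NumPy reverse-mode autodiff. One training-dynamics refinement: the
hard clip has zero gradient outside its bounds, so a concentration
pre-activation pushed below the lower bound early in training could never
recover ("dying-clamp"). The constraint therefore uses a straight-through
backward pass that admits only gradients pointing back into the interval
(`_autodiff.clip_straight_through`); forward values are unchanged.

Interaural mirror augmentation doubles each batch with ear-swapped
cochleagrams and negated azimuths (`model_core.mirror_scene`).

Multiple trained instantiations can be pooled into a
`model_core.MixtureEnsemble`, whose posterior is the equal-weight
average of the member posteriors (component concatenation). Ensemble
posteriors widen where the members disagree, so pooled confidence
reflects estimate instability as well as each member's own reported
spread — at desk scale this matters: a single small MDN reproduces the
growth of localization *error* toward the interaural axis but
under-reports the corresponding growth in spread, while ensemble
disagreement recovers it. The toy localization study
(`demo.toy_localization_study`) therefore evaluates a two-member
ensemble.

## Cochleagrams (`periphery`)

Gammatone FIR filterbank on an ERB-number-spaced center-frequency grid
(ERB(f) = 24.7(0.00437 f + 1)), half-wave rectification, power-law
compression (exponent 0.3), lowpass envelope extraction, and Kaiser-sinc
resampling (width 64, rolloff 0.94759, β = 14.77). The localization preset
orders compression before the envelope lowpass; the pitch preset lowpasses
before compressing. Full-scale presets produce 2×40×8000 (binaural) and
100×1000 (pitch) arrays; the toy presets produce 2×16×100 and 30×150 so
that training fits in minutes on one CPU.

## Posterior → decision → confidence (`posterior_tools`, `confidence`)

- MAP estimates: 5000 Monte-Carlo samples from the mixture, histogrammed
  at 1° (or 1/16-semitone) resolution; the modal bin wins (midline-nearest,
  lowest-index tiebreak).
- Localization uncertainty: width of the 50% highest-posterior-density
  region of the azimuthal histogram, computed circularly.
- Front/back confidence: binary entropy of the posterior front-hemifield
  mass.
- Pitch decisions: MAP constrained to ±1 octave around the nominal f0
  (upper edge excluded); pitch uncertainty is the posterior variance
  within a one-octave window around the mode.
- Frontal folding: when a protocol restricts responses to the frontal arc
  (absolute localization), azimuth samples are reflected across the
  interaural axis onto the front hemifield before taking the MAP
  (`fold_to_frontal`) — the response a subject can give. The HPD width is
  still computed on the raw azimuthal posterior: front/back ambiguity is
  part of the model's uncertainty even when the response scale cannot
  express it.
- Bets: trial uncertainties are ranked (descending, stable); rank quantiles
  i/(N−1) are mapped through the CDF of the discrete Gaussian bet prior
  (0.0545, 0.2442, 0.4026, 0.2442, 0.0545) to bets 5…1, so bet proportions
  reproduce the prior and larger uncertainty never earns a larger bet.

## Toy binaural world (`stimuli`)

A full head-related transfer function simulator is out of scope; the toy
spatializer supplies *lawful* cues at desk scale:

- ITD: Woodworth τ(λ) = (r/c)(λ + sin λ), head radius 0.0875 m, applied as
  a phase ramp (fractional delay), split ± between ears.
- ILD: 20 sin(λ) · f/(f + 1500) dB, split ± between ears — increases with
  laterality and frequency.
- Elevation: a single spectral notch (−15 dB, σ = 0.15 oct) moving up from
  6 kHz at 50 Hz/deg — a stand-in pinna cue.
- Front/back: rendered identically except a rear high-frequency shelf
  (−8 dB above ≈3.5 kHz), preserving the real-world front/back ambiguity
  structure: interaural cues are shared across the cone of confusion, so
  only sounds with high-frequency energy (broadband, high narrowband) can
  be disambiguated front from back.

Training scenes place one target (50% bandpass noise, 25% broadband, 25%
tone) on a 5° azimuth grid with elevation in {0…60}°, superimposed on a
diffuse background at an SNR drawn from U(−15, +30) dB. The background
sums ten independent pink-noise (1/f) sources at random azimuths: with
many weak sources no single background source is localizable as a
competing object and the background's net interaural contrast is small,
so the scene's interaural cues are attributable to the target. The 1/f
tilt matters: real ambient noise is low-frequency weighted, and because
scenes are RMS-normalized a spectrally *flat* background would make a
clean broadband target near the midline indistinguishable from a
background-dominated scene whose target is elsewhere — the calibrated
readout then (correctly, for that world) reports diffuse posteriors for
the entire broadband class, inverting the paper's
broadband-is-most-certain ordering. With a spectrally distinct
background the target remains identifiable at all SNRs and the
orderings emerge — see the qualitative posterior-structure test.

## Virtual experiments (`experiments`)

- exp3 — absolute localization: 7 conditions (broadband; narrowband noise
  and pure tones at 600/2000/4000 Hz, ±0.5-octave jitter) × 19 frontal
  azimuths × 3 repeats = 399 trials; random elevation in {0…40}°; response
  is the frontally folded MAP azimuth; uncertainty is the 50% HPD width of
  the raw azimuthal posterior; bets are assigned over the whole table.
- exp4 — front/back: 4 conditions × 18 azimuths (0–180° omitting 90°) × 5
  elevations = 360 trials; response is the hemifield with more posterior
  mass; uncertainty is the front/back entropy; the `position` column pairs
  cone-of-confusion partners.
- screening — per-stimulus mean uncertainty, ranked; the k stimuli centered
  on the 5th and 95th percentiles, excluding the single most extreme
  stimulus at each end; disjoint lists guaranteed.
- exp6 — f0 discrimination: five stimulus types (pure tone; filtered
  harmonic complexes with low/mid/high harmonics, sine or random phase) in
  threshold-equalizing noise (components 10 dB above masked threshold,
  tones 20 dB); target vs probe at ±Δ%; response is whichever stimulus has
  the higher constrained MAP f0; uncertainty is the mean of the two
  mode-local variances.

## Psychometrics (`psychometrics`)

d′ with 1/(2n) rate clipping; cumulative-normal psychometric fits
p(Δ) = 0.5 + 0.5 Φ((ln Δ − m)/s) with 70.7%-correct thresholds capped at
100% and degeneracy flags; percentile bootstrap (1024 resamples);
split-half (parity) reliability with Spearman–Brown correction; attenuation-
corrected correlations r/√(rxx·ryy); within-experiment z-scoring before
pooled human–model correlation; paired Δr one-tailed bootstrap tests.

## Reproducibility

Every generator is a pure function of its arguments and a seed; a single
top-level seed derives named module seeds via `SeedSequence` spawning
(`io.derive_seeds`); CLI runs write a manifest with the config snapshot,
derived seeds, package versions, and SHA-256 digests of inputs and
outputs.
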