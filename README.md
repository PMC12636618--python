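# percept

Stimulus-computable models of perceptual uncertainty for auditory
psychophysics: mixture-density-network readouts over sound location and
fundamental frequency, a gammatone cochleagram front end, posterior →
confidence extraction, and virtual psychophysical experiments with
post-decision wagers.

The package lets you synthesize auditory scenes, pass them through a
cochlear front end, train a network that outputs a full posterior
distribution (a von Mises mixture over azimuth/elevation, or a Gaussian
mixture over log-f0), convert that posterior into decisions and graded
confidence bets, run experiment protocols on the trained model, and
analyze the resulting trial tables with standard psychometric statistics.

## Modules

| Module | Contents |
| --- | --- |
| `percept.distributions` | `VonMisesMixture`, `GaussianMixture1D`, constraint transforms (softmax weights, `atan2(tanh·)` circular means, bounded concentrations, softplus variances), log-densities with a stable `log_i0`, mixture sampling, JSON round-trip |
| `percept.periphery` | Gammatone FIR cochleagrams: ERB-spaced filterbanks, half-wave rectification, power-law compression, lowpass envelope extraction, Kaiser-sinc resampling; full-scale and toy presets |
| `percept.nnet` / `percept._autodiff` | Minimal layer stack (conv, pooling, batch norm, dropout, Adam) on a NumPy autodiff |
| `percept.model_core` | `NetworkModel` (backbone + mixture readout), NLL training with interaural mirror augmentation, LR schedule, checkpointing, ensembles |
| `percept.posterior_tools` | Monte-Carlo MAP estimates, circular histograms, 50% highest-posterior-density widths, front/back entropy, frontal folding, octave-constrained f0 MAP, mode-local variance |
| `percept.confidence` | Discrete Gaussian bet prior and the rank/inverse-CDF mapping from uncertainty to 1–5 bets |
| `percept.stimuli` | Tones, narrowband/broadband noises, harmonic complexes, threshold-equalizing noise, trapezoid spectral filters, SNR mixing, a toy binaural spatializer (Woodworth ITD, frequency-dependent ILD, elevation notch, rear shelf), speaker grids, scene synthesis and toy training corpora |
| `percept.experiments` | Virtual protocols: absolute localization with bets (exp3), front/back judgments (exp4), uncertainty-based stimulus screening, f0 discrimination (exp6) |
| `percept.psychometrics` | Absolute-error summaries, MAD precision, d′ with clipping, cumulative-normal psychometric fits and thresholds, bootstrap CIs, split-half reliability, Spearman–Brown, attenuation-corrected correlations, paired Δr tests |
| `percept.io` / `percept.cli` | WAV/CSV/YAML/HDF5 plumbing, seed derivation, run manifests, and the `percept` command-line tool |

## Quick start

Train a toy localization model and run a virtual experiment:

```python
import percept as pc

scenes = pc.toy_localization_dataset(800, seed=1)
model = pc.NetworkModel(scenes[0].cochleagram.shape,
                        readout="von_mises_mixture", hidden=(128, 64))
pc.train(model, scenes, pc.TrainConfig(max_epochs=20, mirror_augment=True))

table = pc.run_exp3(model, seed=2)       # 399-trial localization protocol
print(table[["condition", "azimuth_true", "azimuth_resp",
             "uncertainty", "bet"]].head())
```

Several trained instantiations can be pooled with
`pc.MixtureEnsemble([model_a, model_b])`, whose posterior is the
equal-weight average of the members'; `pc.toy_localization_study(seed=0)`
runs the full train-and-evaluate pipeline on a two-member ensemble and
returns the headline posterior-width summaries (~10 min on one CPU).

Check that model confidence is calibrated on a task with known
input-dependent noise:

```python
from percept.demo import calibration_demo
report = calibration_demo(seed=0)
print(report["spread_correlation"], report["hpd50_coverage"])
```

Command line (each run writes a manifest with config, seeds and digests):

```bash
percept synth --experiment exp3 --out stim/ --seed 1
percept train --task localization --out model.npz --n-scenes 400 --epochs 6
percept run-exp --exp 3 --model model.npz --out trials.csv
percept demo-calibration --out calibration.json
```

## Testing

```bash
python -m pytest            # unit + property tests
python scripts/acceptance.py --seed 0 --out acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion; the
model-training criterion trains a toy model from scratch and takes several
minutes, the rest run in seconds.

See `docs/methods.md` for the scientific conventions (coordinate systems,
density parameterizations, uncertainty summaries, protocol definitions)
and the reasoning behind the toy-scale design choices.
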