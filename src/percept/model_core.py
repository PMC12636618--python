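"""Trainable models: configurable backbone, mixture readout heads, objectives.

A :class:`NetworkModel` maps a cochleagram (or any fixed-shape input) to a
latent vector z via a small convolutional/MLP backbone, then through three
readout heads to the parameters of a predictive distribution:

* ``von_mises_mixture`` — weights (softmax), circular means
  (atan2 of tanh-squashed sine/cosine pairs), concentrations (bounded
  rectifier in [1, 512]) over (azimuth, elevation);
* ``gaussian_mixture`` — weights, means bounded to [3, 10] log-Hz,
  variances (softplus + 1e−9) over s = log f0;
* ``categorical`` — a plain softmax over a discrete location grid, the
  classification baseline whose cross-entropy objective is known to yield
  overconfident posteriors.

Training minimizes the mean negative log-likelihood (a strictly proper
scoring rule) with Adam under a linear-warmup / plateau / multiplicative-
decay learning-rate schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from . import nnet
from ._autodiff import Tensor
from .distributions import (
    DEFAULT_BOUNDS, GaussianMixture1D, LOG_2PI, ReadoutBounds,
    SphericalLocation, VonMisesMixture, log_i0, wrap_angle,
)

__all__ = [
    "NetworkModel", "TrainConfig", "LabeledScene", "TrainResult",
    "MixtureEnsemble", "nll_loss", "cross_entropy_loss",
    "location_grid_504",
    "nearest_grid_bin", "mirror_scene", "train", "train_ensemble",
    "lr_schedule",
]

READOUTS = ("von_mises_mixture", "gaussian_mixture", "categorical")


@dataclass
class LabeledScene:
    """One training pair: input representation + ground-truth label."""

    cochleagram: np.ndarray
    label: SphericalLocation | float


@dataclass
class TrainConfig:
    lr: float = 0.001
    warmup_fraction: float = 0.2
    decay_fraction: float = 0.2
    decay_gamma: float = 0.9
    batch_size: int = 64
    max_epochs: int = 5
    seed: int = 0
    patience_epochs: int = 1
    min_rel_improvement: float = 1e-4
    mirror_augment: bool = False

    def __post_init__(self):
        if not (0 <= self.warmup_fraction <= 1 and 0 <= self.decay_fraction <= 1
                and self.warmup_fraction + self.decay_fraction <= 1):
            raise ValueError("warmup/decay fractions must lie in [0,1], sum <= 1")


def pitch_train_config(**kw) -> TrainConfig:
    """Pitch-task training defaults (shorter warmup, gentler decay)."""
    kw.setdefault("warmup_fraction", 0.1)
    kw.setdefault("decay_fraction", 0.2)
    kw.setdefault("decay_gamma", 0.99)
    kw.setdefault("batch_size", 128)
    kw.setdefault("max_epochs", 25)
    return TrainConfig(**kw)


def lr_schedule(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear warmup -> plateau -> per-step multiplicative decay."""
    warmup = int(round(cfg.warmup_fraction * total_steps))
    decay_start = total_steps - int(round(cfg.decay_fraction * total_steps))
    if warmup > 0 and step < warmup:
        return cfg.lr * step / warmup
    if step >= decay_start:
        return cfg.lr * cfg.decay_gamma ** (step - decay_start + 1)
    return cfg.lr


def location_grid_504() -> np.ndarray:
    """The discrete location grid of the classification baseline.

    72 azimuths (0–355° in 5° steps) × 7 elevations (0–60° in 10° steps)
    = 504 bins, azimuth-major order. Returns an array of (az, el) degrees.
    """
    az = np.arange(0, 360, 5)
    el = np.arange(0, 70, 10)
    return np.array([(a, e) for a in az for e in el], dtype=float)


def nearest_grid_bin(azimuth_deg: float, elevation_deg: float,
                     grid: np.ndarray) -> int:
    """Index of the grid bin nearest a location (circular azimuth metric)."""
    daz = np.abs(wrap_angle(np.deg2rad(grid[:, 0] - azimuth_deg)))
    de = np.abs(np.deg2rad(grid[:, 1] - elevation_deg))
    return int(np.argmin(daz ** 2 + de ** 2))


def mirror_scene(scene: LabeledScene) -> LabeledScene:
    """Interaural mirror augmentation: swap ears, reflect azimuth.

    Azimuth (0–360° convention) maps to (360° − az) mod 360°; elevation is
    unchanged. An involution: mirror(mirror(s)) == s.
    """
    if scene.cochleagram.ndim != 3 or scene.cochleagram.shape[0] != 2:
        raise ValueError("mirror augmentation requires a binaural cochleagram")
    loc = scene.label
    if not isinstance(loc, SphericalLocation):
        raise ValueError("mirror augmentation requires a spherical label")
    return LabeledScene(cochleagram=scene.cochleagram[::-1].copy(),
                        label=SphericalLocation(-loc.azimuth, loc.elevation))


class NetworkModel:
    """Backbone + readout. See module docstring for readout kinds.

    ``conv_blocks``: sequence of (out_channels, (kh, kw), (ph, pw)) conv
    stages, each followed by ReLU, 2×2-ish max pooling and batch norm;
    ``hidden``: sizes of fully connected layers after flattening.
    """

    def __init__(self, input_shape: tuple, readout: str = "von_mises_mixture",
                 K: int = 5, hidden: tuple = (64,), conv_blocks: tuple = (),
                 pool: tuple = (2, 2), dropout: float = 0.0, n_bins: int = 504,
                 bounds: ReadoutBounds = DEFAULT_BOUNDS, seed: int = 0):
        if readout not in READOUTS:
            raise ValueError(f"unknown readout {readout!r}")
        self.config = dict(input_shape=tuple(input_shape), readout=readout, K=K,
                           hidden=tuple(hidden),
                           conv_blocks=tuple(tuple(b) for b in conv_blocks),
                           pool=tuple(pool), dropout=dropout, n_bins=n_bins,
                           seed=seed)
        self.readout_kind = readout
        self.K, self.bounds, self.n_bins = K, bounds, n_bins
        self.grid = location_grid_504() if n_bins == 504 else None
        rng = np.random.default_rng(seed)

        layers: list[nnet.Layer] = []
        shape = tuple(input_shape)
        if conv_blocks:
            if len(shape) == 2:          # monaural (C_freq, T): add channel axis
                shape = (1,) + shape
            c, h, w = shape
            for (c_out, kernel, padding) in conv_blocks:
                layers.append(nnet.Conv2d(c, c_out, tuple(kernel), rng,
                                          padding=tuple(padding)))
                h = h + 2 * padding[0] - kernel[0] + 1
                w = w + 2 * padding[1] - kernel[1] + 1
                layers.append(nnet.ReLU())
                ph = pool[0] if h >= pool[0] else 1
                pw = pool[1] if w >= pool[1] else 1
                layers.append(nnet.MaxPool2d((ph, pw)))
                h, w = h // ph, w // pw
                layers.append(nnet.BatchNorm(c_out))
                c = c_out
            shape = (c, h, w)
        layers.append(nnet.Flatten())
        n_feat = int(np.prod(shape))
        for n_hidden in hidden:
            layers.append(nnet.Linear(n_feat, n_hidden, rng))
            layers.append(nnet.ReLU())
            if dropout > 0:
                layers.append(nnet.Dropout(dropout, np.random.default_rng(
                    rng.integers(2 ** 31))))
            n_feat = n_hidden
        self.backbone = nnet.Sequential(*layers)

        if readout == "von_mises_mixture":
            self.head_weights = nnet.Linear(n_feat, K, rng)
            self.head_means = nnet.Linear(n_feat, K * 4, rng)   # (u,v) × 2 dims
            self.head_spread = nnet.Linear(n_feat, K * 2, rng)
        elif readout == "gaussian_mixture":
            self.head_weights = nnet.Linear(n_feat, K, rng)
            self.head_means = nnet.Linear(n_feat, K, rng)
            # bias start inside [3,10] so relux gradients are alive at init
            self.head_means.bias.data += rng.uniform(
                bounds.mean_lb_logf0 + 0.5, bounds.mean_ub_logf0 - 0.5, size=K)
            self.head_spread = nnet.Linear(n_feat, K, rng)
        else:
            self.head_weights = nnet.Linear(n_feat, n_bins, rng)
            self.head_means = self.head_spread = None
        self.trained = False

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = list(self.backbone.parameters())
        for head in (self.head_weights, self.head_means, self.head_spread):
            if head is not None:
                ps.extend(head.parameters())
        return ps

    # -- forward -------------------------------------------------------
    def _check_shape(self, x: np.ndarray):
        expect = self.config["input_shape"]
        if tuple(x.shape[1:]) != tuple(expect):
            raise ValueError(f"input shape {x.shape[1:]} does not match "
                             f"model input shape {expect}")

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        """Batched forward pass; returns constrained parameter tensors."""
        x = np.asarray(x, dtype=np.float64)
        self._check_shape(x)
        if self.config["conv_blocks"] and x.ndim == 3:
            x = x[:, None]                      # (N, 1, C, T)
        z = self.backbone(Tensor(x), train=train)
        n = x.shape[0]
        K, b = self.K, self.bounds
        logits = self.head_weights(z)
        if self.readout_kind == "categorical":
            return {"logits": logits}
        if self.readout_kind == "von_mises_mixture":
            uv = self.head_means(z).reshape(n, K, 2, 2)
            means = ad.atan2(ad.tanh(uv[:, :, :, 0]), ad.tanh(uv[:, :, :, 1]))
            conc = ad.clip_straight_through(
                self.head_spread(z).reshape(n, K, 2), b.conc_lb, b.conc_ub)
            return {"logits": logits, "means": means, "concentrations": conc}
        means = ad.clip_straight_through(self.head_means(z), b.mean_lb_logf0,
                                         b.mean_ub_logf0)
        variances = ad.softplus(self.head_spread(z)) + b.var_epsilon
        return {"logits": logits, "means": means, "variances": variances}

    def predict_mixture(self, cochleagram) -> VonMisesMixture | GaussianMixture1D | np.ndarray:
        """Single-input evaluation-mode forward, returning a mixture object
        (or a categorical probability vector for the softmax baseline)."""
        data = cochleagram.data if hasattr(cochleagram, "data") else cochleagram
        out = self.forward(np.asarray(data)[None], train=False)
        logits = ad.value(out["logits"])[0]
        w = np.exp(logits - logits.max())
        w /= w.sum()
        if self.readout_kind == "categorical":
            return w
        if self.readout_kind == "von_mises_mixture":
            return VonMisesMixture(weights=w, means=ad.value(out["means"])[0],
                                   concentrations=ad.value(out["concentrations"])[0],
                                   bounds=self.bounds)
        return GaussianMixture1D(weights=w, means=ad.value(out["means"])[0],
                                 variances=ad.value(out["variances"])[0],
                                 bounds=self.bounds)

    # -- persistence ---------------------------------------------------
    def save(self, path):
        arrays = nnet.flatten_params(self.parameters())
        arrays.update({f"state.{k}": v
                       for k, v in self.backbone.state_arrays().items()})
        np.savez(path, config=json.dumps(self.config),
                 trained=np.array(self.trained), **arrays)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with np.load(path, allow_pickle=False) as f:
            cfg = json.loads(str(f["config"]))
            model = cls(**cfg)
            nnet.load_params(model.parameters(), {k: f[k] for k in f.files
                                                  if k.startswith("param")})
            model.backbone.load_state_arrays(
                {k[len("state."):]: f[k] for k in f.files
                 if k.startswith("state.")})
            if "trained" in f.files:
                model.trained = bool(f["trained"])
        return model


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def _log_softmax(logits):
    return logits - ad.logsumexp(logits, axis=-1, keepdims=True)


def vm_batch_log_likelihood(out: dict, labels: np.ndarray):
    """Per-example log-likelihood under the von Mises mixture head.

    ``labels``: (N, 2) radians. Log-sum-exp over components of
    log α_k + Σ_i [κ cos(θ_i − μ_i) − log 2π − log I0(κ)].
    """
    theta = np.asarray(labels, dtype=float)[:, None, :]   # (N,1,2)
    logw = _log_softmax(out["logits"])                    # (N,K)
    kappa = out["concentrations"]
    per_dim = kappa * ad.cos(theta - out["means"]) - LOG_2PI - log_i0(kappa)
    comp = logw + per_dim.sum(axis=2)
    return ad.logsumexp(comp, axis=1)


def gm_batch_log_likelihood(out: dict, labels: np.ndarray):
    """Per-example log-likelihood under the Gaussian mixture head;
    ``labels``: (N,) values of s = log f0."""
    s = np.asarray(labels, dtype=float)[:, None]
    logw = _log_softmax(out["logits"])
    var = out["variances"]
    comp = logw - 0.5 * LOG_2PI - 0.5 * ad.log(var) \
        - (s - out["means"]) ** 2 / (2.0 * var)
    return ad.logsumexp(comp, axis=1)


def _labels_array(scenes, readout: str) -> np.ndarray:
    if readout == "von_mises_mixture":
        return np.array([[s.label.azimuth, s.label.elevation] for s in scenes])
    return np.array([float(s.label) for s in scenes])


def nll_loss(scenes: list[LabeledScene], model: NetworkModel,
             train: bool = False):
    """Mean negative log-likelihood of a batch under the model's mixture."""
    x = np.stack([s.cochleagram for s in scenes])
    out = model.forward(x, train=train)
    labels = _labels_array(scenes, model.readout_kind)
    if model.readout_kind == "von_mises_mixture":
        ll = vm_batch_log_likelihood(out, labels)
    elif model.readout_kind == "gaussian_mixture":
        ll = gm_batch_log_likelihood(out, labels)
    else:
        raise ValueError("nll_loss requires a mixture readout; "
                         "use cross_entropy_loss for the categorical head")
    loss = -(ll.mean())
    if not np.isfinite(ad.value(loss)):
        raise FloatingPointError("non-finite NLL; inspect labels/parameters")
    return loss


def cross_entropy_loss(scenes: list[LabeledScene], model: NetworkModel,
                       train: bool = False, warn_off_grid: bool = True):
    """Mean cross-entropy of true location bins under the categorical head.

    Labels off the 504-bin grid are snapped to the nearest bin.
    """
    import warnings
    x = np.stack([s.cochleagram for s in scenes])
    out = model.forward(x, train=train)
    idx = []
    for s in scenes:
        loc = s.label
        az, el = loc.azimuth_deg % 360.0, loc.elevation_deg
        k = nearest_grid_bin(az, el, model.grid)
        if warn_off_grid and (abs(model.grid[k, 0] - az) % 360 > 1e-6
                              or abs(model.grid[k, 1] - el) > 1e-6):
            warnings.warn(f"label ({az:.1f}, {el:.1f})° off grid; snapped to "
                          f"bin {k}", RuntimeWarning, stacklevel=2)
        idx.append(k)
    logp = _log_softmax(out["logits"])
    picked = logp[(np.arange(len(scenes)), np.array(idx))]
    return -(picked.mean())


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    loss_trace: list = field(default_factory=list)     # per-step mean NLL
    lr_trace: list = field(default_factory=list)
    epoch_losses: list = field(default_factory=list)
    stopped_early: bool = False
    diverged: bool = False


def train(model: NetworkModel, scenes: list[LabeledScene],
          cfg: TrainConfig, loss_fn=None) -> TrainResult:
    """Train ``model`` on ``scenes`` under ``cfg``; returns the loss trace.

    All randomness (shuffling) flows from ``cfg.seed``. Early stopping
    triggers when the epoch-mean loss improves by less than
    ``min_rel_improvement`` relatively over ``patience_epochs`` epochs.
    On divergence (non-finite loss) the last finite parameter state is
    restored and the result is flagged.
    """
    if not scenes:
        raise ValueError("empty dataset")
    if loss_fn is None:
        loss_fn = cross_entropy_loss if model.readout_kind == "categorical" \
            else nll_loss
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = nnet.Adam(params)
    n = len(scenes)
    steps_per_epoch = max(1, n // cfg.batch_size)
    total_steps = steps_per_epoch * cfg.max_epochs
    result = TrainResult()
    best, stale = np.inf, 0
    snapshot = [p.data.copy() for p in params]
    step = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            batch = [scenes[i] for i in order[b * cfg.batch_size:
                                              (b + 1) * cfg.batch_size]]
            if cfg.mirror_augment:
                batch = batch + [mirror_scene(s) for s in batch]
            lr = lr_schedule(step, total_steps, cfg)
            try:
                loss = loss_fn(batch, model, train=True)
            except FloatingPointError:
                for p, s in zip(params, snapshot):
                    p.data[...] = s
                result.diverged = True
                return result
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            lv = float(ad.value(loss))
            result.loss_trace.append(lv)
            result.lr_trace.append(lr)
            epoch_losses.append(lv)
            step += 1
        snapshot = [p.data.copy() for p in params]
        epoch_mean = float(np.mean(epoch_losses))
        result.epoch_losses.append(epoch_mean)
        if best - epoch_mean < cfg.min_rel_improvement * abs(best):
            stale += 1
            if stale >= cfg.patience_epochs:
                result.stopped_early = True
                break
        else:
            stale = 0
        best = min(best, epoch_mean)
    model.trained = True
    return result


class MixtureEnsemble:
    """Equal-weight ensemble of trained mixture-readout models.

    The ensemble posterior is the average of the member posteriors,
    realized exactly by concatenating the members' mixture components
    with weights divided by the member count. Ensemble posteriors widen
    where the members disagree, so their spread reflects both each
    member's reported uncertainty and the instability of the estimate
    itself — confidence is read from several trained instantiations
    rather than a single network.
    """

    def __init__(self, models):
        if not models:
            raise ValueError("ensemble needs at least one model")
        kinds = {m.readout_kind for m in models}
        if len(kinds) != 1:
            raise ValueError(f"mixed readout kinds {kinds}")
        if "categorical" in kinds:
            raise ValueError("categorical readouts have no mixture to pool")
        self.models = list(models)
        self.readout_kind = kinds.pop()

    @property
    def trained(self) -> bool:
        return all(getattr(m, "trained", True) for m in self.models)

    def predict_mixture(self, cochleagram):
        parts = [m.predict_mixture(cochleagram) for m in self.models]
        weights = np.concatenate([p.weights / len(parts) for p in parts])
        means = np.concatenate([p.means for p in parts])
        if self.readout_kind == "von_mises_mixture":
            return VonMisesMixture(
                weights=weights, means=means,
                concentrations=np.concatenate(
                    [p.concentrations for p in parts]))
        return GaussianMixture1D(
            weights=weights, means=means,
            variances=np.concatenate([p.variances for p in parts]))


def train_ensemble(model_factory, scenes: list[LabeledScene],
                   cfg: TrainConfig, n_models: int = 5,
                   base_seed: int = 0) -> list[NetworkModel]:
    """Train ``n_models`` instances from different seeds (virtual subjects).

    ``model_factory(seed)`` must build a fresh model; each instance trains
    with its own data-order seed derived from ``base_seed``.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_models) % (2 ** 31)
    models = []
    for s in seeds:
        m = model_factory(int(s))
        c = TrainConfig(**{**asdict(cfg), "seed": int(s)})
        train(m, scenes, c)
        models.append(m)
    return models
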