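import numpy as np
import pytest

from percept import _autodiff as ad
from percept import model_core as mc
from percept.distributions import SphericalLocation


def test_location_grid_504_structure():
    grid = mc.location_grid_504()
    assert grid.shape == (504, 2)
    assert len({(a, e) for a, e in grid}) == 504
    assert set(np.unique(grid[:, 1])) == {0., 10., 20., 30., 40., 50., 60.}


def test_nearest_grid_bin_wraps():
    grid = mc.location_grid_504()
    i = mc.nearest_grid_bin(358.0, 0.0, grid)
    assert tuple(grid[i]) == (0.0, 0.0)       # 358 is nearer 0 than 355
    j = mc.nearest_grid_bin(92.6, 31.0, grid)
    assert tuple(grid[j]) == (95.0, 30.0)


def test_mirror_scene_involution(rng):
    scene = mc.LabeledScene(
        cochleagram=rng.normal(size=(2, 4, 6)),
        label=SphericalLocation.from_degrees(40.0, 20.0))
    m = mc.mirror_scene(scene)
    assert m.label.azimuth_deg == pytest.approx(-40.0)
    assert np.allclose(m.cochleagram[0], scene.cochleagram[1])
    mm = mc.mirror_scene(m)
    assert mm.label.azimuth_deg == pytest.approx(40.0)
    assert np.allclose(mm.cochleagram, scene.cochleagram)


def test_mirror_requires_binaural(rng):
    with pytest.raises(ValueError):
        mc.mirror_scene(mc.LabeledScene(cochleagram=rng.normal(size=(4, 6)),
                                        label=SphericalLocation(0, 0)))


def test_lr_schedule_shape():
    cfg = mc.TrainConfig(lr=0.001, warmup_fraction=0.2, decay_fraction=0.2,
                         decay_gamma=0.9)
    total = 100
    lrs = [mc.lr_schedule(s, total, cfg) for s in range(total)]
    assert lrs[0] == 0.0
    assert lrs[10] == pytest.approx(0.001 * 10 / 20)
    assert lrs[50] == pytest.approx(0.001)
    assert lrs[80] == pytest.approx(0.001 * 0.9)
    assert lrs[99] == pytest.approx(0.001 * 0.9 ** 20)


def test_pitch_train_config_defaults():
    cfg = mc.pitch_train_config()
    assert cfg.warmup_fraction == 0.1
    assert cfg.decay_gamma == 0.99
    assert cfg.batch_size == 128


def _vm_model(seed=0):
    return mc.NetworkModel((2, 4, 10), readout="von_mises_mixture", K=3,
                           hidden=(16,), seed=seed)


def test_forward_constraint_ranges(rng):
    model = _vm_model()
    out = model.forward(rng.normal(size=(5, 2, 4, 10)))
    conc = ad.value(out["concentrations"])
    means = ad.value(out["means"])
    assert conc.shape == (5, 3, 2)
    assert np.all(conc >= 1.0) and np.all(conc <= 512.0)
    assert np.all(np.abs(means) <= np.pi)

    gm = mc.NetworkModel((3, 7), readout="gaussian_mixture", K=4,
                         hidden=(8,), seed=1)
    out2 = gm.forward(rng.normal(size=(5, 3, 7)))
    m2 = ad.value(out2["means"])
    v2 = ad.value(out2["variances"])
    assert np.all(m2 >= 3.0) and np.all(m2 <= 10.0)
    assert np.all(v2 >= 1e-9)


def test_predict_mixture_weights_simplex(rng):
    model = _vm_model()
    mix = model.predict_mixture(rng.normal(size=(2, 4, 10)))
    assert mix.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_input_shape_check(rng):
    model = _vm_model()
    with pytest.raises(ValueError):
        model.forward(rng.normal(size=(5, 2, 4, 11)))


def test_save_load_roundtrip(tmp_path, rng):
    model = _vm_model(3)
    x = rng.normal(size=(2, 2, 4, 10))
    before = ad.value(model.forward(x)["means"])
    p = tmp_path / "m.npz"
    model.save(p)
    loaded = mc.NetworkModel.load(p)
    after = ad.value(loaded.forward(x)["means"])
    assert np.allclose(before, after)
    assert loaded.trained is False


def test_trained_flag_persists(tmp_path, rng):
    model = _vm_model(4)
    scenes = [mc.LabeledScene(cochleagram=rng.normal(size=(2, 4, 10)),
                              label=SphericalLocation.from_degrees(
                                  float(rng.integers(0, 360)), 0.0))
              for _ in range(8)]
    mc.train(model, scenes, mc.TrainConfig(max_epochs=1, batch_size=4,
                                           mirror_augment=False))
    assert model.trained
    p = tmp_path / "m.npz"
    model.save(p)
    assert mc.NetworkModel.load(p).trained


def test_training_reduces_loss_gaussian(rng):
    # 1-D regression with constant noise: loss should drop substantially
    xs = rng.random(256)
    ys = 5.0 + 2.0 * xs + 0.1 * rng.normal(size=256)
    scenes = [mc.LabeledScene(cochleagram=np.array([[x]]), label=float(y))
              for x, y in zip(xs, ys)]
    model = mc.NetworkModel((1, 1), readout="gaussian_mixture", K=2,
                            hidden=(16,), seed=0)
    res = mc.train(model, scenes, mc.TrainConfig(max_epochs=20, batch_size=32,
                                                 mirror_augment=False,
                                                 patience_epochs=3))
    assert res.epoch_losses[-1] < res.epoch_losses[0] - 0.3
    assert not res.diverged


def test_training_deterministic(rng):
    xs = rng.random(64)
    ys = 5.0 + xs
    scenes = [mc.LabeledScene(cochleagram=np.array([[x]]), label=float(y))
              for x, y in zip(xs, ys)]

    def run():
        m = mc.NetworkModel((1, 1), readout="gaussian_mixture", K=2,
                            hidden=(8,), seed=5)
        mc.train(m, scenes, mc.TrainConfig(max_epochs=3, batch_size=16,
                                           mirror_augment=False, seed=5))
        return ad.value(m.forward(np.array([[[0.5]]]))["means"])
    assert np.array_equal(run(), run())


def test_cross_entropy_loss_matches_manual(rng):
    grid = mc.location_grid_504()
    model = mc.NetworkModel((2, 4, 10), readout="categorical", n_bins=504,
                            hidden=(8,), seed=2)
    scenes = [mc.LabeledScene(cochleagram=rng.normal(size=(2, 4, 10)),
                              label=SphericalLocation.from_degrees(45.0, 20.0))]
    loss = float(ad.value(mc.cross_entropy_loss(scenes, model, train=False)))
    out = model.forward(scenes[0].cochleagram[None], train=False)
    logits = ad.value(out["logits"])[0]
    logp = logits - np.log(np.exp(logits - logits.max()).sum()) - logits.max()
    bin_i = mc.nearest_grid_bin(45.0, 20.0, grid)
    assert loss == pytest.approx(-logp[bin_i], abs=1e-9)


def test_train_ensemble_distinct(rng):
    xs = rng.random(32)
    scenes = [mc.LabeledScene(cochleagram=np.array([[x]]), label=5.0 + x)
              for x in xs]

    def factory(seed):
        return mc.NetworkModel((1, 1), readout="gaussian_mixture", K=2,
                               hidden=(8,), seed=seed)
    models = mc.train_ensemble(factory, scenes,
                               mc.TrainConfig(max_epochs=2, batch_size=16,
                                              mirror_augment=False),
                               n_models=2, base_seed=11)
    a = ad.value(models[0].forward(np.array([[[0.5]]]))["means"])
    b = ad.value(models[1].forward(np.array([[[0.5]]]))["means"])
    assert not np.allclose(a, b)
    assert all(m.trained for m in models)


def test_mixture_ensemble_pools_components(rng):
    models = []
    for seed in (3, 4):
        m = mc.NetworkModel((2, 4, 10), readout="von_mises_mixture", K=3,
                            hidden=(8,), seed=seed)
        m.trained = True
        models.append(m)
    ens = mc.MixtureEnsemble(models)
    x = rng.normal(size=(2, 4, 10))
    pooled = ens.predict_mixture(x)
    parts = [m.predict_mixture(x) for m in models]
    assert pooled.weights.size == 6
    assert pooled.weights.sum() == pytest.approx(1.0, abs=1e-12)
    # pooled density is the average of member densities
    from percept.distributions import vm_mixture_logpdf
    pt = np.array([0.3, -0.2])
    dens = np.exp(vm_mixture_logpdf(pt, pooled))
    avg = np.mean([np.exp(vm_mixture_logpdf(pt, p)) for p in parts])
    assert dens == pytest.approx(avg, rel=1e-10)


def test_mixture_ensemble_rejects_mixed_kinds():
    a = mc.NetworkModel((1, 1), readout="gaussian_mixture", K=2, hidden=(4,),
                        seed=0)
    b = mc.NetworkModel((2, 4, 10), readout="von_mises_mixture", K=2,
                        hidden=(4,), seed=0)
    with pytest.raises(ValueError, match="mixed"):
        mc.MixtureEnsemble([a, b])
    with pytest.raises(ValueError, match="at least one"):
        mc.MixtureEnsemble([])
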