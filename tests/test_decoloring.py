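"""Feature construction, LU baseline, and learned estimators."""

import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from milsd.decoloring import (
    EstimatorConfig,
    LinearUnmixer,
    SaturationNeuralNet,
    SaturationRandomForest,
    extract_samples,
    l1_normalize,
    linear_unmixing,
    train_estimator,
    predict,
)
from milsd.fluence import IlluminationGeometry, simulate_stack
from milsd.phantoms import TubeSpec, rasterize_optics
from milsd.spectra import ChromophoreMixture, WavelengthGrid, bundled_endmembers, \
    mixture_mu_a


def uncolored_dataset(n, rng, family="sulfate", grid=None):
    """Forward-mixing oracle: L1-normalized mixture spectra with phi == 1
    (no spectral coloring)."""
    grid = grid or WavelengthGrid()
    e1, e0 = (e.asarray() for e in bundled_endmembers(family, grid))
    sats = rng.uniform(0, 1, n)
    vfs = rng.uniform(0.2, 1.0, n)
    X = vfs[:, None] * (sats[:, None] * e1 + (1 - sats[:, None]) * e0)
    return l1_normalize(X), sats


@pytest.fixture(scope="module")
def small_stack():
    grid = WavelengthGrid(tuple(np.arange(680.0, 981.0, 60.0)))
    tubes = [TubeSpec((15.0, 4.0), 0.5, 0.25), TubeSpec((22.0, 7.0), 0.5, 0.75)]
    ph = rasterize_optics(tubes, ChromophoreMixture(0.4, 0.01), grid=grid,
                          extent_mm=(40.0, 20.0), pitch_mm=0.3)
    return simulate_stack(ph, IlluminationGeometry(), backend="diffusion")


class TestL1Normalize:
    def test_simple_example(self):
        assert np.allclose(l1_normalize(np.array([1.0, 3.0])), [0.25, 0.75])

    def test_scale_invariance(self):
        s = np.array([0.2, 1.4, 0.9])
        assert np.allclose(l1_normalize(3.7 * s), l1_normalize(s))

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            l1_normalize(np.zeros(4))


class TestExtractSamples:
    def test_milsd_width_and_mirror_doubles_count(self, small_stack):
        plain = extract_samples(small_stack, mode="milsd")
        aug = extract_samples(small_stack, mode="milsd", augment_mirror=True)
        n_wl = small_stack.n_wavelengths
        assert plain.features.shape[1] == 4 * n_wl
        assert len(aug) == 2 * len(plain)
        # each 16-block sums to one
        blocks = plain.features.reshape(len(plain), 4, n_wl)
        assert np.allclose(blocks.sum(axis=2), 1.0)

    def test_mirror_reverses_illumination_blocks(self, small_stack):
        aug = extract_samples(small_stack, mode="milsd", augment_mirror=True)
        n = len(aug) // 2
        n_wl = small_stack.n_wavelengths
        orig = aug.features[:n].reshape(n, 4, n_wl)
        mirr = aug.features[n:].reshape(n, 4, n_wl)
        assert np.array_equal(mirr, orig[:, ::-1, :])

    def test_lsd_mode_mean_spectrum(self, small_stack):
        ds = extract_samples(small_stack, mode="lsd", augment_mirror=True)
        assert ds.features.shape[1] == small_stack.n_wavelengths
        assert np.allclose(ds.features.sum(axis=1), 1.0)
        # augmentation is a no-op for the averaged-illumination mode
        assert len(ds) == (small_stack.phantom.labels > 0).sum() - ds.n_dropped

    def test_labels_follow_tube_ground_truth(self, small_stack):
        ds = extract_samples(small_stack, mode="milsd")
        sats = small_stack.phantom.tube_saturations
        assert set(np.round(np.unique(ds.labels), 6)) <= set(np.round(sats, 6))
        for tube_id in (1, 2):
            rows = ds.provenance[:, 2] == tube_id
            assert np.allclose(ds.labels[rows], sats[tube_id - 1])

    def test_gamma_amplitude_invariance(self, small_stack):
        # multiplying every voxel's spectra by its own Gamma * A factor
        # leaves the features unchanged (normalization removes it)
        rng = np.random.default_rng(0)
        scale = rng.uniform(0.5, 2.0, small_stack.H.shape[2:])
        scaled = type(small_stack)(
            H=small_stack.H * scale[None, None], phantom=small_stack.phantom,
            backend=small_stack.backend)
        a = extract_samples(small_stack, mode="milsd")
        b = extract_samples(scaled, mode="milsd")
        assert np.allclose(a.features, b.features, rtol=1e-12)


class TestLinearUnmixing:
    def test_exact_recovery_without_coloring(self):
        ems = bundled_endmembers("sulfate")
        spec = l1_normalize(mixture_mu_a(ChromophoreMixture(0.3, 0.77)))
        assert linear_unmixing(spec, ems) == pytest.approx(0.30, abs=1e-6)

    def test_pure_endmember_returns_one(self):
        ems = bundled_endmembers("hemoglobin")
        got = linear_unmixing(l1_normalize(ems[0].asarray()), ems)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_colored_deep_tube_spectrum_has_error(self, small_stack):
        # spectral coloring makes LU err on a deep tube of a fixed instance
        ds = extract_samples(small_stack, mode="lsd")
        ems = bundled_endmembers("sulfate", small_stack.phantom.grid)
        deep = ds.provenance[:, 2] == 2
        est = LinearUnmixer(ems).fit().predict(ds.features[deep])
        assert np.median(np.abs(est - ds.labels[deep])) > 0.005

    def test_degenerate_fit_is_flagged_not_zero(self):
        E = np.zeros((4, 2))
        E[0, 0] = E[1, 1] = 1.0
        with pytest.warns(RuntimeWarning):
            out = linear_unmixing(np.array([0.0, 0.0, 0.5, 0.5]), E)
        assert np.isnan(out)

    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            LinearUnmixer(np.ones((4, 2))).predict(np.ones((1, 4)))


class TestRandomForest:
    def test_constant_label_training(self):
        rng = np.random.default_rng(1)
        X, _ = uncolored_dataset(200, rng)
        rf = SaturationRandomForest(mode="lsd", random_state=0)
        rf.fit(X, np.full(len(X), 0.7))
        assert np.allclose(rf.predict(X[:20]), 0.7, atol=1e-9)

    def test_uncolored_recovery_below_one_pp(self):
        rng = np.random.default_rng(2)
        X, y = uncolored_dataset(3000, rng)
        Xt, yt = uncolored_dataset(500, rng)
        rf = SaturationRandomForest(mode="lsd", random_state=0).fit(X, y)
        err = np.abs(rf.predict(Xt) - yt) * 100
        assert np.median(err) < 1.0

    def test_train_error_not_worse_than_holdout(self):
        rng = np.random.default_rng(3)
        X, y = uncolored_dataset(1000, rng)
        Xt, yt = uncolored_dataset(400, rng)
        rf = SaturationRandomForest(mode="lsd", random_state=0).fit(X, y)
        e_train = np.median(np.abs(rf.predict(X) - y))
        e_test = np.median(np.abs(rf.predict(Xt) - yt))
        assert e_train <= e_test

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X, y = uncolored_dataset(300, rng)
        p1 = SaturationRandomForest(mode="lsd", random_state=9).fit(X, y).predict(X)
        p2 = SaturationRandomForest(mode="lsd", random_state=9).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_width_mismatch_rejected(self):
        rf = SaturationRandomForest(mode="milsd")
        with pytest.raises(ValueError):
            rf.fit(np.ones((5, 16)), np.ones(5))

    def test_predictions_clipped_and_empty_ok(self):
        rng = np.random.default_rng(5)
        X, y = uncolored_dataset(100, rng)
        rf = SaturationRandomForest(mode="lsd", random_state=0).fit(X, y)
        p = rf.predict(X)
        assert np.all((p >= 0) & (p <= 1))
        assert rf.predict(np.empty((0, 16))).size == 0

    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            SaturationRandomForest().predict(np.ones((1, 64)))


class TestNeuralNet:
    def test_architecture_widths(self):
        rng = np.random.default_rng(6)
        for mode, d_in in (("lsd", 16), ("milsd", 64)):
            X = rng.uniform(size=(50, d_in))
            X = X / X.sum(axis=1, keepdims=True)
            nn = SaturationNeuralNet(mode=mode, epochs=1).fit(X, rng.uniform(size=50))
            shapes = [w.shape for w in nn.coefs_]
            hid = 2 * d_in
            assert shapes == [(d_in, hid)] + [(hid, hid)] * 3 + [(hid, 1)]
            assert nn.hidden_layer_sizes_ == (hid,) * 4

    def test_loss_decreases_during_training(self):
        rng = np.random.default_rng(7)
        X, y = uncolored_dataset(2000, rng)
        nn = SaturationNeuralNet(mode="lsd", epochs=30, random_state=0)
        nn.fit(X, y)
        assert nn.loss_curve_[-1] < nn.loss_curve_[0]

    def test_learns_uncolored_mapping(self):
        rng = np.random.default_rng(8)
        X, y = uncolored_dataset(4000, rng)
        Xt, yt = uncolored_dataset(500, rng)
        nn = SaturationNeuralNet(mode="lsd", epochs=60, batch_size=256,
                                 random_state=0).fit(X, y)
        err = np.abs(nn.predict(Xt) - yt) * 100
        assert np.median(err) < 5.0

    def test_predictions_in_unit_interval(self):
        rng = np.random.default_rng(9)
        X, y = uncolored_dataset(200, rng)
        nn = SaturationNeuralNet(mode="lsd", epochs=2, random_state=0).fit(X, y)
        p = nn.predict(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_unfitted_rejected(self):
        with pytest.raises(NotFittedError):
            SaturationNeuralNet().predict(np.ones((1, 64)))


class TestWrappers:
    def test_train_and_predict_roundtrip(self, small_stack):
        ds = extract_samples(small_stack, mode="milsd", augment_mirror=True)
        cfg = EstimatorConfig(kind="rf", mode="milsd", seed=0,
                              n_wavelengths=small_stack.n_wavelengths)
        est = train_estimator(ds, cfg)
        p = predict(est, ds)
        assert p.shape == (len(ds),)
        assert np.all((p >= 0) & (p <= 1))

    def test_mode_mismatch_rejected(self, small_stack):
        ds = extract_samples(small_stack, mode="lsd")
        with pytest.raises(ValueError):
            train_estimator(ds, EstimatorConfig(kind="rf", mode="milsd"))
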