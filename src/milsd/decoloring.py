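"""Feature construction and saturation estimators.

The estimation target is the saturation fraction (sO2, or its sulfate
analogue rCu) of a tube voxel from its absorbed-energy spectra.  Because
the optoacoustic signal is S = Gamma * A * H with Gamma (Grueneisen) and
A (reconstruction amplitude) wavelength-independent per voxel, dividing
each spectrum by its L1 norm removes both factors exactly:
normalized signal spectra equal normalized absorbed-energy spectra.
Estimators therefore consume L1-normalized features only:

* LSD     — the mean spectrum over all illumination positions, then
            L1-normalized (16 features on the default grid).
* MI-LSD  — each illumination's spectrum L1-normalized separately, then
            concatenated in illumination order (4 x 16 = 64 features).

Mirror augmentation appends every MI-LSD sample with the illumination
order reversed, exploiting the lateral symmetry of the line-array
geometry; it doubles the MI-LSD sample count and is a no-op for LSD.

Three estimators are provided as scikit-learn compatible regressors:
``LinearUnmixer`` (the model-free nonnegative least-squares baseline),
``SaturationRandomForest`` and ``SaturationNeuralNet``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import NotFittedError

from .fluence import AbsorbedEnergyStack
from .spectra import EndmemberSpectrum

__all__ = [
    "LabeledSpectraSet",
    "EstimatorConfig",
    "l1_normalize",
    "extract_samples",
    "linear_unmixing",
    "LinearUnmixer",
    "SaturationRandomForest",
    "SaturationNeuralNet",
    "train_estimator",
    "predict",
]


def l1_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Divide a nonnegative spectrum by its L1 norm (output sums to 1)."""
    s = np.asarray(spectrum, dtype=float)
    total = s.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot L1-normalize a spectrum with nonpositive sum")
    return s / total


@dataclass
class LabeledSpectraSet:
    """Per-voxel feature matrix with ground-truth saturation labels.

    ``provenance`` rows are (volume id, flat voxel index, tube id);
    ``n_dropped`` counts voxels discarded for an all-zero spectrum.
    """

    features: np.ndarray  # (n_samples, 16) lsd or (n_samples, 64) milsd
    labels: np.ndarray  # (n_samples,) in [0, 1]
    provenance: np.ndarray  # (n_samples, 3) int
    mode: str
    n_wavelengths: int
    n_illuminations: int
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def concatenate(cls, parts: list["LabeledSpectraSet"]) -> "LabeledSpectraSet":
        if not parts:
            raise ValueError("no parts to concatenate")
        first = parts[0]
        return cls(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=np.concatenate([p.provenance for p in parts]),
            mode=first.mode,
            n_wavelengths=first.n_wavelengths,
            n_illuminations=first.n_illuminations,
            n_dropped=sum(p.n_dropped for p in parts),
        )


def extract_samples(
    stack: AbsorbedEnergyStack,
    mode: str = "milsd",
    augment_mirror: bool = False,
    joint_normalization: bool = False,
    sort_by_norm: bool = False,
    volume_id: int = 0,
) -> LabeledSpectraSet:
    """Extract one labeled sample per tube voxel of an absorbed-energy stack.

    ``mode='lsd'`` averages the spectra over the illumination positions
    first and then L1-normalizes; ``mode='milsd'`` L1-normalizes each
    illumination's spectrum separately and concatenates them in
    illumination order.  ``joint_normalization`` instead divides the
    whole MI block stack by its total L1 norm, preserving
    inter-illumination amplitude ratios (off by default).
    ``sort_by_norm`` orders the illumination blocks by decreasing raw L1
    norm before normalization (off by default).  Voxels with an
    unusable all-zero spectrum are dropped and counted.
    """
    if mode not in ("lsd", "milsd"):
        raise ValueError(f"unknown mode {mode!r}")
    labels_map = stack.phantom.labels
    mask = labels_map > 0
    if not mask.any():
        raise ValueError("stack has no tube-labeled voxels")
    tube_ids = labels_map[mask]
    flat_idx = np.flatnonzero(mask.ravel())
    sats = stack.phantom.tube_saturations[tube_ids - 1]
    n_ill, n_wl = stack.H.shape[:2]

    # (n_voxels, n_ill, n_wl)
    V = stack.H[:, :, mask].transpose(2, 0, 1)

    if mode == "lsd":
        mean_spec = V.mean(axis=1)
        sums = mean_spec.sum(axis=1)
        keep = sums > 0
        feats = mean_spec[keep] / sums[keep, None]
    else:
        block_sums = V.sum(axis=2)  # (n_voxels, n_ill)
        keep = np.all(block_sums > 0, axis=1)
        Vk = V[keep]
        if sort_by_norm:
            order = np.argsort(-block_sums[keep], axis=1)
            Vk = np.take_along_axis(Vk, order[:, :, None], axis=1)
        if joint_normalization:
            feats = Vk / Vk.sum(axis=(1, 2))[:, None, None]
        else:
            feats = Vk / Vk.sum(axis=2, keepdims=True)
        feats = feats.reshape(len(Vk), n_ill * n_wl)

    labels = sats[keep]
    prov = np.column_stack([
        np.full(keep.sum(), volume_id, dtype=np.int64),
        flat_idx[keep],
        tube_ids[keep].astype(np.int64),
    ])
    n_dropped = int((~keep).sum())

    if augment_mirror and mode == "milsd":
        mirrored = feats.reshape(-1, n_ill, n_wl)[:, ::-1, :].reshape(feats.shape)
        feats = np.concatenate([feats, mirrored])
        labels = np.concatenate([labels, labels])
        prov = np.concatenate([prov, prov])

    return LabeledSpectraSet(
        features=feats, labels=labels, provenance=prov, mode=mode,
        n_wavelengths=n_wl, n_illuminations=n_ill, n_dropped=n_dropped)


def _endmember_matrix(endmembers) -> np.ndarray:
    if isinstance(endmembers, np.ndarray):
        E = endmembers
    else:
        if len(endmembers) != 2:
            raise ValueError("linear unmixing needs exactly two endmembers")
        E = np.column_stack([e.asarray() if isinstance(e, EndmemberSpectrum) else
                             np.asarray(e, float) for e in endmembers])
    if E.ndim != 2 or E.shape[1] != 2:
        raise ValueError("endmember matrix must be (n_wavelengths, 2)")
    return E


def linear_unmixing(spectrum: np.ndarray, endmembers) -> float:
    """Nonnegative least-squares unmixing of one spectrum onto two
    endmembers (oxygenated-like first); returns c_oxy / (c_oxy + c_deoxy)
    clipped to [0, 1], or NaN (with a warning) if both coefficients
    vanish."""
    E = _endmember_matrix(endmembers)
    s = np.asarray(spectrum, dtype=float)
    if s.shape != (E.shape[0],):
        raise ValueError("spectrum and endmembers must share a wavelength grid")
    coef, _ = nnls(E, s)
    total = coef.sum()
    if total <= 0:
        warnings.warn("linear unmixing degenerate: both coefficients zero",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.clip(coef[0] / total, 0.0, 1.0))


class LinearUnmixer(RegressorMixin, BaseEstimator):
    """Model-free LU baseline as a scikit-learn style regressor.

    ``fit`` only records the endmember matrix (there is nothing to
    learn); ``predict`` unmixes each row of X independently.
    """

    def __init__(self, endmembers=None):
        self.endmembers = endmembers

    def fit(self, X=None, y=None):
        if self.endmembers is None:
            raise ValueError("LinearUnmixer requires endmembers")
        self.endmembers_ = _endmember_matrix(self.endmembers)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "endmembers_"):
            raise NotFittedError("LinearUnmixer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.empty(0)
        out = np.empty(len(X))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for i, row in enumerate(X):
                out[i] = linear_unmixing(row, self.endmembers_)
        return out


class _WidthCheckMixin:
    def _expected_width(self) -> int:
        if self.mode == "lsd":
            return self.n_wavelengths
        if self.mode == "milsd":
            return self.n_illuminations * self.n_wavelengths
        raise ValueError(f"unknown mode {self.mode!r}")

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_samples, n_features)")
        if X.shape[1] != self._expected_width():
            raise ValueError(
                f"feature width {X.shape[1]} does not match mode {self.mode!r} "
                f"(expected {self._expected_width()})")
        return X


class SaturationRandomForest(_WidthCheckMixin, RegressorMixin, BaseEstimator):
    """Random-forest spectral-decoloring regressor (100 trees, depth 30)."""

    def __init__(self, mode="milsd", n_estimators=100, max_depth=30,
                 n_wavelengths=16, n_illuminations=4, random_state=None,
                 n_jobs=None):
        self.mode = mode
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.n_wavelengths = n_wavelengths
        self.n_illuminations = n_illuminations
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            random_state=self.random_state, n_jobs=self.n_jobs)
        self.forest_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "forest_"):
            raise NotFittedError("SaturationRandomForest is not fitted")
        X = self._check_X(X)
        if len(X) == 0:
            return np.empty(0)
        return np.clip(self.forest_.predict(X), 0.0, 1.0)


class SaturationNeuralNet(_WidthCheckMixin, RegressorMixin, BaseEstimator):
    """Feedforward spectral-decoloring network.

    Four hidden layers of twice the input width (32 for LSD, 128 for
    MI-LSD), leaky-ReLU activations, optional inverted dropout, trained
    with plain minibatch SGD on a mean-squared-error loss for 100 epochs
    at batch size 1e5 (capped at the dataset size) under the schedule
    lr(epoch) = 1e-2 * 0.9^(epoch/2), epoch counted from zero.
    """

    def __init__(self, mode="milsd", hidden_layers=4, width_factor=2,
                 negative_slope=0.01, dropout=0.0, epochs=100,
                 batch_size=100_000, lr0=1e-2, lr_decay=0.9,
                 standardize=True, n_wavelengths=16, n_illuminations=4,
                 random_state=None):
        self.mode = mode
        self.hidden_layers = hidden_layers
        self.width_factor = width_factor
        self.negative_slope = negative_slope
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.standardize = standardize
        self.n_wavelengths = n_wavelengths
        self.n_illuminations = n_illuminations
        self.random_state = random_state

    # -- internals ---------------------------------------------------
    def _leaky(self, z):
        return np.where(z > 0, z, self.negative_slope * z)

    def _leaky_grad(self, z):
        return np.where(z > 0, 1.0, self.negative_slope)

    def _forward(self, X, rng=None):
        """Returns (pre-activations, activations); applies inverted
        dropout on hidden activations when an rng is given."""
        zs, acts = [], [X]
        a = X
        n_layers = len(self.coefs_)
        for li, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + b
            zs.append(z)
            if li < n_layers - 1:
                a = self._leaky(z)
                if rng is not None and self.dropout > 0:
                    keep = rng.random(a.shape) >= self.dropout
                    a = a * keep / (1.0 - self.dropout)
            else:
                a = z
            acts.append(a)
        return zs, acts

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)
        if self.standardize:
            # internal affine preprocessing: L1-normalized spectra live on a
            # tiny per-feature scale, which conditions SGD badly
            self.feature_mean_ = X.mean(axis=0)
            self.feature_scale_ = np.maximum(X.std(axis=0), 1e-12)
        else:
            self.feature_mean_ = np.zeros(X.shape[1])
            self.feature_scale_ = np.ones(X.shape[1])
        X = (X - self.feature_mean_) / self.feature_scale_
        d_in = X.shape[1]
        hidden = self.width_factor * d_in
        sizes = [d_in] + [hidden] * self.hidden_layers + [1]
        self.hidden_layer_sizes_ = tuple([hidden] * self.hidden_layers)
        self.coefs_ = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                                  size=(sizes[i], sizes[i + 1]))
                       for i in range(len(sizes) - 1)]
        self.intercepts_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

        n = len(X)
        batch = min(self.batch_size, n)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            lr = self.lr0 * self.lr_decay ** (epoch / 2.0)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb = X[idx], y[idx]
                zs, acts = self._forward(xb, rng=rng)
                pred = acts[-1].ravel()
                err = pred - yb
                losses.append(float(np.mean(err ** 2)))
                delta = (2.0 * err / len(idx))[:, None]
                for li in range(len(self.coefs_) - 1, -1, -1):
                    gW = acts[li].T @ delta
                    gb = delta.sum(axis=0)
                    if li > 0:
                        delta = (delta @ self.coefs_[li].T) * \
                            self._leaky_grad(zs[li - 1])
                    self.coefs_[li] -= lr * gW
                    self.intercepts_[li] -= lr * gb
            self.loss_curve_.append(float(np.mean(losses)))
        self.n_features_in_ = d_in
        return self

    def predict(self, X):
        if not hasattr(self, "coefs_"):
            raise NotFittedError("SaturationNeuralNet is not fitted")
        X = self._check_X(X)
        if len(X) == 0:
            return np.empty(0)
        X = (X - self.feature_mean_) / self.feature_scale_
        _, acts = self._forward(X, rng=None)
        return np.clip(acts[-1].ravel(), 0.0, 1.0)


@dataclass(frozen=True)
class EstimatorConfig:
    """Which estimator to build and with what hyperparameters."""

    kind: str = "rf"  # {"rf", "nn"}
    mode: str = "milsd"  # {"lsd", "milsd"}
    n_trees: int = 100
    max_depth: int = 30
    hidden_layers: int = 4
    dropout: float = 0.0
    epochs: int = 100
    batch_size: int = 100_000
    n_wavelengths: int = 16
    n_illuminations: int = 4
    seed: int | None = None

    def build(self):
        common = dict(mode=self.mode, n_wavelengths=self.n_wavelengths,
                      n_illuminations=self.n_illuminations,
                      random_state=self.seed)
        if self.kind == "rf":
            return SaturationRandomForest(
                n_estimators=self.n_trees, max_depth=self.max_depth, **common)
        if self.kind == "nn":
            return SaturationNeuralNet(
                hidden_layers=self.hidden_layers, dropout=self.dropout,
                epochs=self.epochs, batch_size=self.batch_size, **common)
        raise ValueError(f"unknown estimator kind {self.kind!r}")


def train_estimator(train: LabeledSpectraSet, cfg: EstimatorConfig):
    """Build the configured estimator and fit it on a labeled set."""
    if cfg.mode != train.mode:
        raise ValueError(
            f"estimator mode {cfg.mode!r} does not match dataset mode {train.mode!r}")
    est = cfg.build()
    est.fit(train.features, train.labels)
    return est


def predict(estimator, samples: LabeledSpectraSet) -> np.ndarray:
    """Saturation estimates in [0, 1] for every sample of a labeled set."""
    return estimator.predict(samples.features)
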