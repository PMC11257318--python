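"""From-scratch Rocket regressor and naive forecasting baselines.

Rocket transforms each multichannel observation window with a large bank of
random dilated convolutional kernels, pools every kernel's output into two
features (PPV, the proportion of positive values, and the maximum), and maps
the pooled features to the glucose target with closed-form ridge regression.
Kernels are never learned: length is drawn from {7, 9, 11}, weights are
mean-centred Gaussians over a random channel subset, bias is uniform on
[-1, 1], and dilation is sampled on an exponential scale so kernels see the
window at many time scales.

Estimators follow the scikit-learn contract (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and compose with
sklearn model selection; the module-level functions (``generate_kernels``,
``apply_kernels``, ``fit_ridge``) expose the individual steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._fast import apply_kernels_nb

KERNEL_LENGTHS = (7, 9, 11)


@dataclass
class KernelSet:
    """A sampled bank of random dilated convolution kernels (flat arrays)."""

    lengths: np.ndarray       # (K,)
    dilations: np.ndarray     # (K,)
    paddings: np.ndarray      # (K,)
    biases: np.ndarray        # (K,)
    ch_offsets: np.ndarray    # (K+1,) offsets into channel_idx
    channel_idx: np.ndarray   # flat channel indices
    w_offsets: np.ndarray     # (K+1,) offsets into weights
    weights: np.ndarray       # flat, mean-centred per channel
    n_channels: int
    series_len: int

    def __len__(self) -> int:
        return len(self.lengths)


def generate_kernels(
    num_kernels: int,
    n_channels: int,
    series_len: int,
    rng: np.random.Generator,
    lengths: tuple[int, ...] = KERNEL_LENGTHS,
    max_channels: int = 9,
) -> KernelSet:
    """Sample a seeded kernel bank.

    Dilation is ``floor(2**a)`` with ``a ~ U[0, log2((T-1)/(l-1))]`` so every
    kernel's span fits the window; zero-padding of half the span is applied
    with probability 1/2.
    """
    if series_len < max(lengths) + 1:
        raise ValueError(f"series too short for kernels: need > {max(lengths)} samples")
    K = int(num_kernels)
    if K < 1:
        raise ValueError("num_kernels must be >= 1")
    ls = np.empty(K, dtype=np.int64)
    ds = np.empty(K, dtype=np.int64)
    pads = np.empty(K, dtype=np.int64)
    biases = np.empty(K, dtype=np.float64)
    n_sel = np.empty(K, dtype=np.int64)
    ch_lists, w_lists = [], []
    hi_ch = min(n_channels, max_channels)
    for k in range(K):
        l = int(rng.choice(lengths))
        m = int(rng.integers(1, hi_ch + 1))
        chans = np.sort(rng.choice(n_channels, size=m, replace=False))
        w = rng.standard_normal((m, l))
        w -= w.mean(axis=1, keepdims=True)
        b = rng.uniform(-1.0, 1.0)
        a = rng.uniform(0.0, np.log2((series_len - 1) / (l - 1)))
        d = int(np.floor(2.0**a))
        pad = ((l - 1) * d) // 2 if rng.integers(0, 2) == 1 else 0
        ls[k], ds[k], pads[k], biases[k], n_sel[k] = l, d, pad, b, m
        ch_lists.append(chans.astype(np.int64))
        w_lists.append(w.ravel())
    ch_offsets = np.concatenate([[0], np.cumsum(n_sel)]).astype(np.int64)
    w_offsets = np.concatenate([[0], np.cumsum(n_sel * ls)]).astype(np.int64)
    return KernelSet(
        ls, ds, pads, biases, ch_offsets,
        np.concatenate(ch_lists), w_offsets, np.concatenate(w_lists),
        n_channels, series_len,
    )


def apply_kernels(X: np.ndarray, kernels: KernelSet) -> np.ndarray:
    """Transform windows (n, C, T) into the 2K-column feature matrix."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (n_windows, n_channels, T)")
    if X.shape[1] != kernels.n_channels:
        raise ValueError(
            f"channel mismatch: kernels sampled for {kernels.n_channels} channels, "
            f"got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    return apply_kernels_nb(
        X, kernels.lengths, kernels.dilations, kernels.paddings, kernels.biases,
        kernels.ch_offsets, kernels.channel_idx, kernels.w_offsets, kernels.weights,
    )


# ---------------------------------------------------------------------------
# ridge on pooled features


@dataclass
class RidgeResult:
    coef: np.ndarray
    intercept: float
    alpha: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray


def _standardize(F: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    # zero-variance features come out identically zero
    return (F - mean) / scale


def _ridge_solve_svd(Z: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Coefficients of (Z'Z + aI) b = Z'y for every alpha, via one SVD."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uty = U.T @ yc
    return np.stack([(Vt.T * (s / (s**2 + a))) @ uty for a in alphas])


def _inner_blocks(n: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Chronological contiguous validation blocks for inner model selection."""
    blocks = np.array_split(np.arange(n), k)
    folds = []
    for b in blocks:
        tr = np.setdiff1d(np.arange(n), b)
        if len(tr) and len(b):
            folds.append((tr, b))
    return folds


def fit_ridge(
    features: np.ndarray,
    targets: np.ndarray,
    alphas=(1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0),
    n_inner_folds: int = 3,
) -> RidgeResult:
    """Closed-form ridge with the penalty chosen by inner-fold validation RMSE.

    Features are standardised with training statistics (zero-variance columns
    pass through as zeros); the intercept is the training-target mean.
    """
    F = np.asarray(features, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if F.ndim != 2 or len(F) != len(y):
        raise ValueError("features must be 2-D with one row per target")
    if len(y) < 2:
        raise ValueError("need at least 2 samples to fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    alphas = np.asarray(sorted(alphas), dtype=np.float64)

    def stats(Fi):
        mean = Fi.mean(axis=0)
        scale = Fi.std(axis=0)
        # zero-variance features pass through as zeros; near-constant features
        # are floored rather than blown up when the test fold drifts
        scale = np.maximum(scale, 1e-2 * (1.0 + np.abs(mean)))
        scale[Fi.std(axis=0) == 0] = 1.0
        return mean, scale

    best_alpha = float(alphas[0])
    if len(alphas) > 1 and len(y) >= 4:
        errs = np.zeros(len(alphas))
        for tr, va in _inner_blocks(len(y), n_inner_folds):
            m, sc = stats(F[tr])
            Ztr = _standardize(F[tr], m, sc)
            Zva = _standardize(F[va], m, sc)
            ybar = y[tr].mean()
            B = _ridge_solve_svd(Ztr, y[tr] - ybar, alphas)
            preds = ybar + Zva @ B.T
            errs += np.sqrt(((preds - y[va][:, None]) ** 2).mean(axis=0))
        best_alpha = float(alphas[int(np.argmin(errs))])

    mean, scale = stats(F)
    Z = _standardize(F, mean, scale)
    ybar = float(y.mean())
    coef = _ridge_solve_svd(Z, y - ybar, np.array([best_alpha]))[0]
    return RidgeResult(coef, ybar, best_alpha, mean, scale)


# ---------------------------------------------------------------------------
# estimators


class RocketRegressor(BaseEstimator, RegressorMixin):
    """Random convolutional kernel regression for glucose forecasting.

    Parameters
    ----------
    num_kernels : int
        Size of the random kernel bank. 10000 is a desk-scale default; the
        best published setting for this task uses 100000.
    alphas : tuple of float
        Candidate ridge penalties, selected by inner-fold validation RMSE.
    n_inner_folds : int
        Chronological contiguous inner validation blocks.
    random_state : int or None
        Seeds the kernel sampling; identical seed + data give bit-identical
        predictions.
    """

    #: the experiment runner min-max-scales inputs for estimators with this flag
    requires_scaled_input = True

    def __init__(
        self,
        num_kernels: int = 10000,
        kernel_lengths: tuple[int, ...] = KERNEL_LENGTHS,
        alphas: tuple[float, ...] = tuple(float(a) for a in np.logspace(-3, 3, 10)),
        n_inner_folds: int = 3,
        max_channels: int = 9,
        random_state: int | None = None,
    ):
        self.num_kernels = num_kernels
        self.kernel_lengths = kernel_lengths
        self.alphas = alphas
        self.n_inner_folds = n_inner_folds
        self.max_channels = max_channels
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, T)")
        rng = np.random.default_rng(self.random_state)
        self.kernels_ = generate_kernels(
            self.num_kernels, X.shape[1], X.shape[2], rng,
            tuple(self.kernel_lengths), self.max_channels,
        )
        F = apply_kernels(X, self.kernels_)
        res = fit_ridge(F, y, self.alphas, self.n_inner_folds)
        self.coef_ = res.coef
        self.intercept_ = res.intercept
        self.alpha_ = res.alpha
        self.feature_mean_ = res.feature_mean
        self.feature_scale_ = res.feature_scale
        self.n_channels_ = X.shape[1]
        self.series_len_ = X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        """Pooled (PPV, max) features under the fitted kernel bank."""
        if not hasattr(self, "kernels_"):
            raise ValueError("RocketRegressor is not fitted")
        return apply_kernels(np.asarray(X, dtype=np.float64), self.kernels_)

    def predict(self, X) -> np.ndarray:
        F = self.transform(X)
        Z = _standardize(F, self.feature_mean_, self.feature_scale_)
        return self.intercept_ + Z @ self.coef_


class PersistenceForecaster(BaseEstimator, RegressorMixin):
    """Predict the last observed glucose value in the window (naive baseline)."""

    requires_scaled_input = False

    def __init__(self, glucose_channel: int = 0):
        self.glucose_channel = glucose_channel

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] <= self.glucose_channel:
            raise ValueError("X must be (n, C, T) with the glucose channel present")
        self.n_channels_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X[:, self.glucose_channel, -1]


class ARForecaster(BaseEstimator, RegressorMixin):
    """Ordinary least squares on the window's last ``order`` CGM ticks."""

    requires_scaled_input = False

    def __init__(self, order: int = 2, glucose_channel: int = 0, tick_seconds: int = 300):
        self.order = order
        self.glucose_channel = glucose_channel
        self.tick_seconds = tick_seconds

    def _design(self, X: np.ndarray) -> np.ndarray:
        T = X.shape[2]
        lags = [T - 1 - k * self.tick_seconds for k in range(self.order)]
        if lags[-1] < 0:
            raise ValueError("window shorter than requested AR order")
        cols = [X[:, self.glucose_channel, i] for i in lags]
        return np.column_stack([np.ones(X.shape[0])] + cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        A = self._design(X)
        self.coef_, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.n_channels_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self._design(np.asarray(X, dtype=np.float64)) @ self.coef_


# ---------------------------------------------------------------------------
# serialization: JSON header + flat binary coefficient block


_ARRAY_FIELDS = (
    "lengths", "dilations", "paddings", "biases",
    "ch_offsets", "channel_idx", "w_offsets", "weights",
)


def save_rocket(model: RocketRegressor, path) -> None:
    """Round-trippable dump; reloading reproduces predictions bit-exactly."""
    if not hasattr(model, "kernels_"):
        raise ValueError("cannot save an unfitted model")
    ks = model.kernels_
    arrays = {f"kernel_{f}": getattr(ks, f) for f in _ARRAY_FIELDS}
    arrays.update(
        coef=model.coef_, feature_mean=model.feature_mean_,
        feature_scale=model.feature_scale_,
    )
    header = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "alpha": model.alpha_,
        "intercept": model.intercept_,
        "n_channels": model.n_channels_,
        "series_len": model.series_len_,
        "arrays": [],
    }
    blob = bytearray()
    for name, arr in arrays.items():
        arr = np.ascontiguousarray(arr)
        header["arrays"].append(
            {"name": name, "dtype": arr.dtype.str, "shape": list(arr.shape),
             "offset": len(blob), "nbytes": arr.nbytes}
        )
        blob += arr.tobytes()
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n\x00")
        fh.write(bytes(blob))


def load_rocket(path) -> RocketRegressor:
    raw = Path(path).read_bytes()
    sep = raw.index(b"\n\x00")
    header = json.loads(raw[:sep].decode())
    blob = raw[sep + 2:]
    arrays = {}
    for spec in header["arrays"]:
        a = np.frombuffer(
            blob, dtype=np.dtype(spec["dtype"]),
            count=int(np.prod(spec["shape"])) if spec["shape"] else 1,
            offset=spec["offset"],
        ).reshape(spec["shape"])
        arrays[spec["name"]] = a.copy()
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in header["params"].items()}
    model = RocketRegressor(**params)
    model.kernels_ = KernelSet(
        *[arrays[f"kernel_{f}"] for f in _ARRAY_FIELDS],
        header["n_channels"], header["series_len"],
    )
    model.coef_ = arrays["coef"]
    model.feature_mean_ = arrays["feature_mean"]
    model.feature_scale_ = arrays["feature_scale"]
    model.alpha_ = header["alpha"]
    model.intercept_ = header["intercept"]
    model.n_channels_ = header["n_channels"]
    model.series_len_ = header["series_len"]
    return model
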