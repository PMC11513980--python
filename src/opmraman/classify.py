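"""Microplastic identification from Raman spectra.

Rule-based selection of training spectra (peak counting in two
fingerprint regimes), spectral preprocessing (detrend, mean-subtract,
max-normalize, crop), a small 1D convolutional network over five classes
(PS, PMMA, PA6, agarose, dish), and score-weighted false-color
rendering of classified maps.

The network is the minimal architecture that the task requires — one
convolution layer with 64 filters of kernel size 3, ReLU, max pooling
(size 2), flatten and a dense softmax — trained with Adam on
cross-entropy.  It is implemented directly on numpy (im2col
convolution), which keeps training deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _sig

from .errors import DegenerateSignalError, InvalidInputError
from .types import Spectrum

__all__ = [
    "SelectionRule",
    "DEFAULT_SELECTION_RULES",
    "ClassifierConfig",
    "Conv1dClassifier",
    "select_training_spectra",
    "preprocess_for_cnn",
    "train_classifier",
    "nearest_mean_classifier",
    "render_classification",
]

CLASSES = ("PS", "PMMA", "PA6", "agarose", "dish")


@dataclass(frozen=True)
class SelectionRule:
    """Accept a spectrum as training data when enough peaks are found.

    Peaks are counted in two fingerprint regimes (defaults 700-1850 and
    2700-3200 cm^-1); acceptance requires at least ``min_peaks1`` in the
    first and ``min_peaks2`` in the second.
    """

    class_name: str
    min_peaks1: int
    min_peaks2: int
    regime1: tuple = (700.0, 1850.0)
    regime2: tuple = (2700.0, 3200.0)

    def __post_init__(self):
        if self.min_peaks1 < 0 or self.min_peaks2 < 0:
            raise InvalidInputError("peak counts must be >= 0")
        if not (self.regime1[1] <= self.regime2[0]
                or self.regime2[1] <= self.regime1[0]):
            raise InvalidInputError("regimes must be disjoint")


DEFAULT_SELECTION_RULES = {
    "PS": SelectionRule("PS", 3, 2),
    "PMMA": SelectionRule("PMMA", 4, 1),
    "PA6": SelectionRule("PA6", 3, 1),
}


def _count_peaks(shifts, values, window, prominence_sigma=3.0, smooth_width=5):
    v = np.convolve(values, np.ones(smooth_width) / smooth_width, mode="same")
    d = np.diff(values)
    noise = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    floor = prominence_sigma * max(noise, 1e-12)
    idx, _ = _sig.find_peaks(v, prominence=floor)
    lo, hi = window
    return int(np.sum((shifts[idx] >= lo) & (shifts[idx] <= hi)))


def select_training_spectra(spectra: Sequence[Spectrum], rule: SelectionRule,
                            prominence_sigma=3.0, smooth_width=5):
    """Filter spectra by the two-regime peak-count rule.

    Each spectrum is smoothed (moving average, default width 5 bins) and
    local maxima above a 3-sigma prominence floor are counted in each
    regime; accepted spectra are returned labeled with the rule's class.
    Monotone in the peak counts: adding peaks never flips accept to
    reject.
    """
    accepted = []
    for sp in spectra:
        n1 = _count_peaks(sp.shifts, sp.intensities, rule.regime1,
                          prominence_sigma, smooth_width)
        n2 = _count_peaks(sp.shifts, sp.intensities, rule.regime2,
                          prominence_sigma, smooth_width)
        if n1 >= rule.min_peaks1 and n2 >= rule.min_peaks2:
            accepted.append(Spectrum(sp.shifts.copy(), sp.intensities.copy(),
                                     label=rule.class_name))
    return accepted


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training protocol of the spectrum classifier."""

    n_filters: int = 64
    kernel_size: int = 3
    n_conv_layers: int = 1
    classes: tuple = CLASSES
    train_fraction: float = 0.8
    epochs: int = 500
    crop_window: tuple = (560.0, 3360.0)   # cm^-1
    grid_step: float = 20.0                # cm^-1
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidInputError("train fraction must be in (0, 1)")
        if self.n_conv_layers != 1:
            raise InvalidInputError("only the single-conv-layer network is defined")


def preprocess_for_cnn(spectrum: Spectrum, cfg: ClassifierConfig = None):
    """Feature vector: detrend -> subtract mean -> max-normalize -> crop.

    The least-squares linear trend is removed, the mean subtracted, the
    result divided by its maximum absolute value and cropped to the
    configured window (141 bins for the default 560-3360 cm^-1 at
    20 cm^-1).  Scale-invariant: multiplying the input by k > 0 leaves
    the output unchanged.  All-zero (or trend-only) spectra cannot be
    normalized and are rejected.
    """
    cfg = cfg or ClassifierConfig()
    v = _sig.detrend(spectrum.intensities.astype(float))
    v = v - v.mean()
    mx = np.abs(v).max()
    if mx <= 1e-12 * max(np.abs(spectrum.intensities).max(), 1.0) or mx == 0.0:
        raise DegenerateSignalError("spectrum has no structure after detrending")
    v = v / mx
    lo, hi = cfg.crop_window
    m = (spectrum.shifts >= lo - 1e-9) & (spectrum.shifts <= hi + 1e-9)
    if not m.any():
        raise InvalidInputError("crop window not covered by the spectrum")
    return v[m]


def _one_hot(labels, n):
    out = np.zeros((len(labels), n))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class Conv1dClassifier:
    """1-conv-layer CNN: conv(k=3, 64 filters) -> ReLU -> max pool (2)
    -> flatten -> dense softmax.  Trained with Adam on cross-entropy.

    The pooling keeps positional information at half resolution — Raman
    classes are distinguished by *where* their peaks sit, so the feature
    map cannot be pooled globally.
    """

    POOL = 2

    def __init__(self, cfg: ClassifierConfig, n_features: Optional[int] = None):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k, f, nc = cfg.kernel_size, cfg.n_filters, len(cfg.classes)
        if n_features is None:
            lo, hi = cfg.crop_window
            n_features = int(round((hi - lo) / cfg.grid_step)) + 1
        lp = (n_features - k + 1) // self.POOL
        self._lp = lp
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / k), size=(k, f)).astype(np.float32)
        self.b1 = np.zeros(f, dtype=np.float32)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / (lp * f)),
                             size=(lp * f, nc)).astype(np.float32)
        self.b2 = np.zeros(nc, dtype=np.float32)
        self._rng = rng

    # -- forward pieces -------------------------------------------------
    @staticmethod
    def _im2col(X, k):
        # X: (n, L) -> (n, L-k+1, k) view
        n, L = X.shape
        s0, s1 = X.strides
        return np.lib.stride_tricks.as_strided(
            X, shape=(n, L - k + 1, k), strides=(s0, s1, s1), writeable=False
        )

    def _forward(self, X):
        k, f = self.cfg.kernel_size, self.cfg.n_filters
        n = len(X)
        cols = self._im2col(np.ascontiguousarray(X, dtype=np.float32), k)  # (n, L', k)
        lp = self._lp
        z1 = (cols.reshape(-1, k) @ self.W1).reshape(n, -1, f) + self.b1
        a1 = np.maximum(z1, 0.0)
        a0 = a1[:, 0:lp * self.POOL:2]
        a2 = a1[:, 1:lp * self.POOL:2]
        right = a2 > a0                                     # (n, lp, f)
        flat = np.where(right, a2, a0).reshape(n, lp * f)
        logits = flat @ self.W2 + self.b2
        return cols, z1, right, flat, logits

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_scores(self, X):
        """Softmax class scores, rows summing to one."""
        X = np.asarray(X, dtype=np.float32)
        return self._softmax(self._forward(X)[-1])

    def predict(self, X):
        return self.predict_scores(X).argmax(axis=1)

    # -- training -------------------------------------------------------
    def fit(self, X, y, epochs=None, verbose=False):
        cfg = self.cfg
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        n = len(X)
        Y = _one_hot(y, len(cfg.classes)).astype(np.float32)
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        t = 0
        history = []
        epochs = cfg.epochs if epochs is None else epochs
        for ep in range(epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb, Yb = X[idx], Y[idx]
                b = len(idx)
                k, f, lp = cfg.kernel_size, cfg.n_filters, self._lp
                cols, z1, right, flat, logits = self._forward(Xb)
                P = self._softmax(logits)
                dlogits = (P - Yb) / b
                gW2 = flat.T @ dlogits
                gb2 = dlogits.sum(axis=0)
                dflat = (dlogits @ self.W2.T).reshape(b, lp, f)
                dz1 = np.zeros_like(z1)
                dz1[:, 0:lp * self.POOL:2] = np.where(right, 0.0, dflat)
                dz1[:, 1:lp * self.POOL:2] = np.where(right, dflat, 0.0)
                dz1 *= z1 > 0
                gW1 = cols.reshape(-1, k).T @ dz1.reshape(-1, f)
                gb1 = dz1.sum(axis=(0, 1))
                grads = [gW1, gb1, gW2, gb2]
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1m
                    mi += (1 - b1m) * g
                    vi *= b2m
                    vi += (1 - b2m) * g * g
                    mhat = mi / (1 - b1m**t)
                    vhat = vi / (1 - b2m**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if verbose and (ep + 1) % max(1, epochs // 10) == 0:
                acc = float((self.predict(X) == y).mean())
                history.append((ep + 1, acc))
        return history


def _stratified_split(y, train_fraction, rng):
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        k = int(round(train_fraction * len(idx)))
        if k == 0 or k == len(idx):
            raise InvalidInputError(
                f"class {c} would be absent from one split"
            )
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return (np.array(sorted(train_idx)), np.array(sorted(test_idx)))


def train_classifier(spectra: Sequence[Spectrum],
                     cfg: ClassifierConfig = None,
                     epochs=None) -> Tuple[Conv1dClassifier, dict]:
    """Preprocess, split, and train the CNN; returns (model, metrics).

    Spectra must carry labels from ``cfg.classes``.  The data are
    shuffled and split per class (stratified 80/20 by default) with the
    config seed, trained for ``cfg.epochs``, and evaluated on the
    held-out fraction.  Metrics include held-out accuracy and the
    per-class confusion matrix (rows = truth, columns = prediction).
    """
    cfg = cfg or ClassifierConfig()
    labels = [sp.label for sp in spectra]
    missing = {l for l in labels} - set(cfg.classes)
    if missing:
        raise InvalidInputError(f"unknown class labels: {sorted(missing)}")
    if len(set(labels)) < 2:
        raise InvalidInputError("need at least two classes to train")
    class_to_idx = {c: i for i, c in enumerate(cfg.classes)}
    X = np.stack([preprocess_for_cnn(sp, cfg) for sp in spectra])
    y = np.array([class_to_idx[l] for l in labels])
    rng = np.random.default_rng(cfg.seed)
    tr, te = _stratified_split(y, cfg.train_fraction, rng)
    model = Conv1dClassifier(cfg)
    history = model.fit(X[tr], y[tr], epochs=epochs)
    pred = model.predict(X[te])
    nc = len(cfg.classes)
    conf = np.zeros((nc, nc), dtype=int)
    for yt, yp in zip(y[te], pred):
        conf[yt, yp] += 1
    metrics = {
        "test_accuracy": float((pred == y[te]).mean()),
        "train_accuracy": float((model.predict(X[tr]) == y[tr]).mean()),
        "confusion": conf,
        "n_train": len(tr),
        "n_test": len(te),
        "history": history,
    }
    return model, metrics


def nearest_mean_classifier(X_train, y_train):
    """Independent baseline: classify by nearest class-mean feature vector."""
    classes = np.unique(y_train)
    means = np.stack([X_train[y_train == c].mean(axis=0) for c in classes])

    def predict(X):
        d = ((np.asarray(X)[:, None, :] - means[None]) ** 2).sum(axis=2)
        return classes[d.argmin(axis=1)]

    return predict


def render_classification(total_intensity, scores, class_names=CLASSES):
    """Score-weighted false-color map of a classified field.

    ``scores`` has shape (ny, nx, 5) with nonnegative per-class scores
    (softmax probabilities); the total scattering intensity I is routed
    to R = I*(s_PS + g), G = I*(s_PMMA + g), B = I*(s_PA6 + g) with
    g = (s_agarose + s_dish)/3, then the image is jointly scaled to
    [0, 1].  Pure agarose/dish pixels come out gray, zero intensity
    black.
    """
    I = np.asarray(total_intensity, dtype=float)
    S = np.asarray(scores, dtype=float)
    if S.shape[:-1] != I.shape or S.shape[-1] != len(class_names):
        raise InvalidInputError("scores must be (ny, nx, n_classes)")
    if np.any(S < 0):
        raise InvalidInputError("scores must be nonnegative")
    idx = {c: i for i, c in enumerate(class_names)}
    g = (S[..., idx["agarose"]] + S[..., idx["dish"]]) / 3.0
    rgb = np.stack([I * (S[..., idx["PS"]] + g),
                    I * (S[..., idx["PMMA"]] + g),
                    I * (S[..., idx["PA6"]] + g)], axis=-1)
    mx = rgb.max()
    return rgb / mx if mx > 0 else rgb
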