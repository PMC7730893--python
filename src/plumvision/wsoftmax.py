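"""Weight-biased softmax (w-softmax) loss.

A negative-focused margin loss for the final fully connected layer.  All
class weight vectors are L2-normalised; for a sample of true class ``c`` each
negative class weight ``w_i`` is pulled toward the positive one before the
softmax is taken:

    w_i' = (gamma * w_c + w_i) / ||gamma * w_c + w_i||,   i != c

so the negative logits ``w_i' . x`` rise, the training loss grows, and the
learned decision boundaries widen.  ``gamma = 0`` recovers the standard
softmax cross-entropy (on unit-normalised weights); ``gamma -> inf`` drives
every biased negative weight onto ``w_c``.

Weights are stored as rows: ``W[k]`` is the d-dimensional weight vector of
class ``k``.  The bias is recomputed from the current weights at every
forward pass, so the weights themselves train under the loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClassifierWeights", "normalize_rows", "bias_negative_weights",
           "wsoftmax_probabilities", "wsoftmax_loss", "WSoftmaxLoss",
           "softmax_cross_entropy"]

_EPS_DEGENERATE = 1e-12


@dataclass
class ClassifierWeights:
    """Unit-normalised class weight matrix with a designated positive class.

    W: (C, d) matrix, one row per class; c: positive class index;
    gamma: non-negative bias strength.
    """

    W: np.ndarray
    c: int
    gamma: float = 1.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be a (C, d) matrix")
        if not (0 <= self.c < self.W.shape[0]):
            raise ValueError(f"positive class index {self.c} out of range")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def normalize_rows(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=np.float64)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if np.any(norms < _EPS_DEGENERATE):
        raise ValueError("cannot normalise a zero weight vector")
    return W / norms


def bias_negative_weights(cw: ClassifierWeights) -> np.ndarray:
    """Biased, re-normalised weight matrix W'.

    Row ``c`` is unchanged; every other row i becomes
    (gamma*w_c + w_i)/||gamma*w_c + w_i||.  Input rows must be unit norm.
    """
    W, c, gamma = cw.W, cw.c, cw.gamma
    if not np.allclose(np.linalg.norm(W, axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of W must be unit-normalised before biasing")
    b = gamma * W[c][None, :] + W
    norms = np.linalg.norm(b, axis=1)
    norms[c] = gamma + 1.0  # (gamma+1) w_c normalises back to w_c exactly
    if np.any(norms < _EPS_DEGENERATE):
        raise ValueError(
            "degenerate bias: gamma*w_c + w_i vanishes (antipodal weights)")
    out = b / norms[:, None]
    out[c] = W[c]
    return out


def wsoftmax_probabilities(x: np.ndarray, cw: ClassifierWeights) -> np.ndarray:
    """Class probabilities for feature x under the biased weights.

    With unit-norm rows, ||x|| cos(theta_k) = w_k . x, so this is a softmax
    over [w_c . x] + [w_j' . x for j != c].
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature vector")
    Wb = bias_negative_weights(cw)
    z = Wb @ x
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _forward(X: np.ndarray, labels: np.ndarray, W: np.ndarray, gamma: float,
             guard: bool = False):
    """Vectorised forward over a batch; returns (loss, cache).

    With ``guard`` set, a biased negative logit is never allowed to fall
    below the corresponding unbiased one.  The two coincide whenever
    gamma * (w_c . x) >= (||gamma w_c + w_i|| - 1) * (w_i . x), which holds
    throughout the loss's intended operating regime (positive-class cosine
    positive); the guard only removes a degenerate optimum in which every
    cosine is driven equally negative and the loss vanishes without the
    classes separating.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    C, d = W.shape
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError("label out of range")
    Vn = np.linalg.norm(W, axis=1)
    if np.any(Vn < _EPS_DEGENERATE):
        raise ValueError("cannot normalise a zero weight vector")
    U = W / Vn[:, None]
    # b[n, k] = gamma * u_{c_n} + u_k ; for k = c_n this is (gamma+1) u_c,
    # which renormalises to u_c, so the positive logit needs no special case.
    B = gamma * U[labels][:, None, :] + U[None, :, :]
    norms = np.linalg.norm(B, axis=2)
    if np.any(norms < _EPS_DEGENERATE):
        raise ValueError(
            "degenerate bias: gamma*w_c + w_i vanishes (antipodal weights)")
    Wb = B / norms[:, :, None]
    zb = np.einsum("nkd,nd->nk", Wb, X)
    n = X.shape[0]
    if guard:
        zr = X @ U.T
        use_biased = zb >= zr
        use_biased[np.arange(n), labels] = True
        z = np.where(use_biased, zb, zr)
    else:
        use_biased = np.ones_like(zb, dtype=bool)
        z = zb
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    P = e / e.sum(axis=1, keepdims=True)
    loss = -np.log(P[np.arange(n), labels]).mean()
    return loss, (X, labels, U, Vn, Wb, norms, zb, P, use_biased)


def wsoftmax_loss(X: np.ndarray, labels, W: np.ndarray, gamma: float,
                  guard: bool = False) -> float:
    """Mean w-softmax loss of a batch (forward only).

    X: (n, d) features; labels: (n,) class indices; W: (C, d) weight matrix,
    rows unit-normalised (any non-zero rows are accepted and normalised).
    """
    loss, _ = _forward(np.atleast_2d(X), np.atleast_1d(labels), W, gamma,
                       guard=guard)
    return float(loss)


class WSoftmaxLoss:
    """Trainable w-softmax loss: forward caches what backward needs.

    backward returns (dX, dW) — gradients of the mean loss with respect to
    the features and the *raw* (pre-normalisation) weight matrix.  ``guard``
    enables the negative-bias floor described in ``_forward``; it is off by
    default so the bare formula is what this class computes, and turned on
    by the trainer.
    """

    def __init__(self, gamma: float = 1.0, guard: bool = False):
        if gamma < 0:
            raise ValueError("gamma must be non-negative")
        self.gamma = gamma
        self.guard = guard
        self._cache = None

    def forward(self, X: np.ndarray, labels: np.ndarray, W: np.ndarray) -> float:
        loss, cache = _forward(X, labels, W, self.gamma, guard=self.guard)
        self._cache = cache
        return float(loss)

    def backward(self) -> tuple[np.ndarray, np.ndarray]:
        X, labels, U, Vn, Wb, norms, zb, P, use_biased = self._cache
        n, C = P.shape
        G = P.copy()
        G[np.arange(n), labels] -= 1.0
        G /= n
        Gb = G * use_biased            # gradient through the biased branch
        Gr = G * (~use_biased)         # gradient through the unbiased branch
        dX = np.einsum("nk,nkd->nd", Gb, Wb) + Gr @ U
        # through w' = b/||b||:  d b = g * (x - z w') / ||b||
        A = (Gb / norms)[:, :, None] * (X[:, None, :] - zb[:, :, None] * Wb)
        dU = A.sum(axis=0) + Gr.T @ X
        # u_c additionally enters every b_k with coefficient gamma
        np.add.at(dU, labels, self.gamma * A.sum(axis=1))
        # through u = v/||v||: project out the radial component
        dW = (dU - (dU * U).sum(axis=1, keepdims=True) * U) / Vn[:, None]
        self._cache = None
        return dX, dW


def softmax_cross_entropy(X: np.ndarray, labels: np.ndarray,
                          W: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Plain softmax cross-entropy on logits W @ x; returns (loss, dX, dW)."""
    X = np.asarray(X, dtype=np.float64)
    z = X @ W.T
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    P = e / e.sum(axis=1, keepdims=True)
    n = X.shape[0]
    loss = float(-np.log(P[np.arange(n), labels]).mean())
    G = P.copy()
    G[np.arange(n), labels] -= 1.0
    G /= n
    return loss, G @ W, G.T @ X
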