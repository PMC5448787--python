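"""Extreme learning machines for image classification, vector and tensor flavored.

A classic ELM is a single-hidden-layer feedforward network whose input weights
are drawn at random and frozen; only the output weights are learned, by a
Moore-Penrose pseudoinverse solve of ``H beta = T`` with one-hot targets T.

The tensor variant (TELM) replaces the random input map with the truncated
mode-2 / mode-3 factor matrices of the higher-order SVD of the training image
tensor ``Gamma`` (samples x rows x cols).  Each image x is projected to
``U2' x U3`` (shape n1 x n2), vectorized in mode-1-unfolding order, passed
through a sigmoid, and linearly decoded by beta.  The sample mode is never
projected.  This keeps the 2D structure of the images in the hidden layer and
needs no randomness at all.

Tensor primitives (`unfold`, `refold`, `mode_product`, `hosvd_factors`) follow
the standard mode-q unfolding convention in which the remaining indices are
enumerated in row-major order; modes are numbered from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid

from .errors import InvalidArgumentError

__all__ = [
    "unfold",
    "refold",
    "mode_product",
    "hosvd_factors",
    "one_hot",
    "TELMModel",
    "ELMModel",
    "train_telm",
    "predict_telm",
    "train_elm",
    "predict_elm",
]

#: Relative singular-value cutoff of the Moore-Penrose solve.
PINV_RCOND = 1e-10


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-q unfolding (1-based): rows index mode q, columns enumerate the
    remaining indices in row-major order (earlier modes vary slowest)."""
    a = np.asarray(tensor)
    if not 1 <= mode <= a.ndim:
        raise InvalidArgumentError(f"mode must be in 1..{a.ndim}, got {mode}")
    return np.moveaxis(a, mode - 1, 0).reshape(a.shape[mode - 1], -1)


def refold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given full shape."""
    if not 1 <= mode <= len(shape):
        raise InvalidArgumentError(f"mode must be in 1..{len(shape)}, got {mode}")
    rest = tuple(s for i, s in enumerate(shape) if i != mode - 1)
    a = np.asarray(matrix).reshape((shape[mode - 1],) + rest)
    return np.moveaxis(a, 0, mode - 1)


def mode_product(tensor: np.ndarray, B: np.ndarray, mode: int) -> np.ndarray:
    """Mode-q product: contract mode q of the tensor with the columns of B."""
    a = np.asarray(tensor)
    B = np.asarray(B)
    if not 1 <= mode <= a.ndim:
        raise InvalidArgumentError(f"mode must be in 1..{a.ndim}, got {mode}")
    if B.ndim != 2 or B.shape[1] != a.shape[mode - 1]:
        raise InvalidArgumentError(
            f"matrix shape {B.shape} incompatible with tensor mode {mode} "
            f"of size {a.shape[mode - 1]}")
    new_shape = list(a.shape)
    new_shape[mode - 1] = B.shape[0]
    return refold(B @ unfold(a, mode), mode, tuple(new_shape))


def hosvd_factors(gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/column factor matrices of a (samples x I1 x I2) training tensor.

    U2 and U3 are the left singular matrices of the mode-2 and mode-3
    unfoldings; the sample mode is left unprojected.
    """
    a = np.asarray(gamma, dtype=float)
    if a.ndim != 3:
        raise InvalidArgumentError(f"training tensor must be order 3, got order {a.ndim}")
    u2 = np.linalg.svd(unfold(a, 2), full_matrices=False)[0]
    u3 = np.linalg.svd(unfold(a, 3), full_matrices=False)[0]
    return u2, u3


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    t = np.zeros((len(labels), len(classes)))
    idx = np.searchsorted(classes, labels)
    t[np.arange(len(labels)), idx] = 1.0
    return t


@dataclass
class TELMModel:
    """Truncated HOSVD projections plus pseudoinverse-learned output weights."""

    U2: np.ndarray  # I1 x n1, column-orthonormal
    U3: np.ndarray  # I2 x n2, column-orthonormal
    beta: np.ndarray  # (n1*n2) x m
    classes: np.ndarray

    @property
    def hidden_width(self) -> int:
        return self.U2.shape[1] * self.U3.shape[1]


@dataclass
class ELMModel:
    """Random-input-weight baseline network."""

    alpha: np.ndarray  # (n+1) x n_hidden
    beta: np.ndarray  # n_hidden x m
    classes: np.ndarray
    seed: int


def train_telm(images: np.ndarray, labels: np.ndarray, n1: int = 18,
               n2: int = 15) -> TELMModel:
    """Fit a TELM on a stack of equally-shaped 2D images.

    Defaults n1=18, n2=15 give a hidden layer of width 270.
    """
    gamma = np.asarray(images, dtype=float)
    if gamma.ndim != 3:
        raise InvalidArgumentError(f"expected (N, I1, I2) image stack, got shape {gamma.shape}")
    _, i1, i2 = gamma.shape
    if not (1 <= n1 <= i1) or not (1 <= n2 <= i2):
        raise InvalidArgumentError(
            f"truncation ({n1}, {n2}) exceeds image dimensions ({i1}, {i2})")
    u2, u3 = hosvd_factors(gamma)
    if n1 > u2.shape[1] or n2 > u3.shape[1]:
        raise InvalidArgumentError("truncation exceeds the rank of the training tensor")
    u2t, u3t = u2[:, :n1], u3[:, :n2]
    z = mode_product(mode_product(gamma, u2t.T, 2), u3t.T, 3)
    h = sigmoid(unfold(z, 1))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    beta = np.linalg.pinv(h, rcond=PINV_RCOND) @ one_hot(labels, classes)
    return TELMModel(U2=u2t, U3=u3t, beta=beta, classes=classes)


def _telm_hidden(model: TELMModel, images: np.ndarray) -> np.ndarray:
    # per-image projection U2' x U3 flattened row-major, which coincides with
    # the mode-1 unfolding order of the batch tensor path
    z = np.einsum("ab,nac,cd->nbd", model.U2, images, model.U3)
    return sigmoid(z.reshape(images.shape[0], -1))


def predict_telm(model: TELMModel, image: np.ndarray):
    """Class scores and argmax label(s); ties go to the smallest class index.

    Accepts a single (I1, I2) image or an (N, I1, I2) batch.
    """
    a = np.asarray(image, dtype=float)
    single = a.ndim == 2
    if single:
        a = a[None]
    if a.ndim != 3 or a.shape[1] != model.U2.shape[0] or a.shape[2] != model.U3.shape[0]:
        raise InvalidArgumentError(
            f"image shape {np.asarray(image).shape} incompatible with model "
            f"({model.U2.shape[0]}, {model.U3.shape[0]})")
    scores = _telm_hidden(model, a) @ model.beta
    labels = model.classes[np.argmax(scores, axis=1)]
    if single:
        return scores[0], labels[0]
    return scores, labels


def _augment(x: np.ndarray) -> np.ndarray:
    return np.hstack([x, np.ones((x.shape[0], 1))])


def train_elm(x: np.ndarray, labels: np.ndarray, n_hidden: int,
              seed: int = 0) -> ELMModel:
    """Fit a classic ELM on row vectors; alpha ~ Uniform[-1, 1], seeded."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(-1.0, 1.0, size=(x.shape[1] + 1, n_hidden))
    h = sigmoid(_augment(x) @ alpha)
    classes = np.unique(labels)
    beta = np.linalg.pinv(h, rcond=PINV_RCOND) @ one_hot(labels, classes)
    return ELMModel(alpha=alpha, beta=beta, classes=classes, seed=seed)


def predict_elm(model: ELMModel, x: np.ndarray):
    """Class scores and argmax label(s) for row vector(s)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] + 1 != model.alpha.shape[0]:
        raise InvalidArgumentError(
            f"input length {x2.shape[1]} incompatible with model ({model.alpha.shape[0] - 1})")
    scores = sigmoid(_augment(x2) @ model.alpha) @ model.beta
    labels = model.classes[np.argmax(scores, axis=1)]
    if single:
        return scores[0], labels[0]
    return scores, labels
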