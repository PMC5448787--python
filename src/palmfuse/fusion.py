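"""Discriminant-driven fusion of multiband BIMF stacks.

Each multispectral sample is represented by a matrix ``V`` of shape
``(n_pixels, n_bands * K)`` whose columns are the vectorized,
illumination-compensated BIMFs of every band (band-major, level-minor).  A
fused image is a linear combination ``F = V @ phi`` of those columns.

The fusion coefficients ``phi`` are learned on training samples by maximizing
a contribution-weighted Fisher ratio

    phi = argmax  (phi' D phi) / (phi' D_w phi),

where D and D_w are between-/within-class scatter matrices of the per-sample
matrices, each sample weighted by a contribution factor mu in [0, 1]: samples
buried inside their class (all k nearest neighbors same-class) get mu = 0,
samples on a class border (all k nearest neighbors other-class) get mu = 1,
with a Gaussian-of-distance interpolation in between.  The maximizer is the
leading generalized eigenvector of (D, D_w).  Setting mu = 1 everywhere
recovers the classic Fisher criterion; phi = 1 recovers the plain sum rule.

Pairwise distances entering the contribution factor are Frobenius distances
divided by the mean k-nearest-neighbor distance of the training set, so that
the Gaussian spread ``delta`` is expressed on a data-independent scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidArgumentError, NoDiscriminativeInformationError
from .fabemd import CompensatedBIMFs

__all__ = [
    "BANDS",
    "BIMFFeatureMatrix",
    "ContributionWeights",
    "FusionModel",
    "FusedImage",
    "build_feature_matrix",
    "contribution_factors",
    "scatter_matrices",
    "solve_fusion_coefficients",
    "fuse",
    "sum_rule_model",
    "sum_rule_baseline",
    "classic_fisher_baseline",
    "fit_weighted_fisher",
]

#: Canonical band order of the imaging protocol.
BANDS = ("blue", "green", "red", "nir")


@dataclass(frozen=True)
class BIMFFeatureMatrix:
    """Stacked vectorized BIMFs of one sample: shape (n_pixels, n_bands*K)."""

    V: np.ndarray
    shape: tuple[int, int]
    label: int
    K: int
    bands: tuple[str, ...] = BANDS
    sample_index: int | None = None

    def band_subset(self, bands: Sequence[str]) -> "BIMFFeatureMatrix":
        """Restrict the columns to a subset of bands (order preserved as given)."""
        cols = []
        for b in bands:
            if b not in self.bands:
                raise InvalidArgumentError(f"band {b!r} not present in {self.bands}")
            start = self.bands.index(b) * self.K
            cols.extend(range(start, start + self.K))
        return BIMFFeatureMatrix(V=self.V[:, cols], shape=self.shape, label=self.label,
                                 K=self.K, bands=tuple(bands), sample_index=self.sample_index)


@dataclass(frozen=True)
class ContributionWeights:
    mu: np.ndarray
    k: int
    delta: float
    distance_scale: float


@dataclass
class FusionModel:
    """Learned fusion direction plus the hyperparameters that produced it."""

    phi: np.ndarray
    K: int
    eigenvalue: float | None = None
    ridge: float = 0.0
    hyperparams: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "phi": [float(x) for x in self.phi],
                "K": self.K,
                "eigenvalue": None if self.eigenvalue is None else float(self.eigenvalue),
                "ridge": float(self.ridge),
                "hyperparams": self.hyperparams,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FusionModel":
        d = json.loads(text)
        return cls(phi=np.asarray(d["phi"], dtype=float), K=int(d["K"]),
                   eigenvalue=d.get("eigenvalue"), ridge=float(d.get("ridge", 0.0)),
                   hyperparams=dict(d.get("hyperparams", {})))


@dataclass(frozen=True)
class FusedImage:
    F: np.ndarray
    label: int


def _band_levels(entry) -> list[np.ndarray]:
    if isinstance(entry, CompensatedBIMFs):
        return entry.adjusted
    return list(entry)


def build_feature_matrix(sample: Mapping[str, object], K: int,
                         bands: Sequence[str] = BANDS, label: int = -1,
                         sample_index: int | None = None) -> BIMFFeatureMatrix:
    """Stack the compensated BIMFs of every band into one pixel-by-column matrix.

    ``sample`` maps band name -> :class:`CompensatedBIMFs` (or a plain list of
    K arrays).  Columns are ordered band-major (order of ``bands``),
    level-minor; pixels are flattened row-major.
    """
    bands = tuple(bands)
    missing = [b for b in bands if b not in sample]
    if missing:
        raise InvalidArgumentError(f"sample is missing bands {missing}")
    shape = None
    cols = []
    for b in bands:
        levels = _band_levels(sample[b])
        if len(levels) != K:
            raise InvalidArgumentError(
                f"band {b!r} has {len(levels)} BIMF levels, expected K={K}")
        for s in levels:
            s = np.asarray(s, dtype=float)
            if shape is None:
                shape = s.shape
            elif s.shape != shape:
                raise InvalidArgumentError(
                    f"BIMF shape {s.shape} differs from {shape} in band {b!r}")
            cols.append(s.ravel(order="C"))
    return BIMFFeatureMatrix(V=np.column_stack(cols), shape=shape, label=label,
                             K=K, bands=bands, sample_index=sample_index)


def contribution_factors(samples: Sequence[BIMFFeatureMatrix], k: int = 6,
                         delta: float = 5.0,
                         distance_scale: float | None = None) -> ContributionWeights:
    """Per-sample border weights from the class mix of the k nearest neighbors.

    mu_j = sum over other-class neighbors of exp(-d^2/delta^2) divided by the
    same sum over all k neighbors; distances are Frobenius norms divided by
    ``distance_scale`` (default: mean k-NN distance of the set).
    """
    n = len(samples)
    if not 0 < k < n:
        raise InvalidArgumentError(f"k must satisfy 0 < k < n_samples={n}, got {k}")
    if delta <= 0:
        raise InvalidArgumentError(f"delta must be positive, got {delta}")
    labels = np.asarray([s.label for s in samples])
    X = np.stack([s.V.ravel() for s in samples])
    dist = squareform(pdist(X))
    np.fill_diagonal(dist, np.inf)
    neighbors = np.argsort(dist, axis=1, kind="stable")[:, :k]
    nn_dist = np.take_along_axis(dist, neighbors, axis=1)
    if distance_scale is None:
        distance_scale = float(nn_dist.mean())
    if distance_scale <= 0:
        distance_scale = 1.0
    weights = np.exp(-((nn_dist / distance_scale) ** 2) / delta**2)
    other = labels[neighbors] != labels[:, None]
    mu = (weights * other).sum(axis=1) / weights.sum(axis=1)
    return ContributionWeights(mu=mu, k=k, delta=delta, distance_scale=distance_scale)


def scatter_matrices(samples: Sequence[BIMFFeatureMatrix],
                     mu: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Contribution-weighted total and within-class scatter matrices.

    The global and class means are unweighted; mu weights only the outer
    products.  ``mu=None`` means uniform weights (classic Fisher).
    """
    n = len(samples)
    labels = np.asarray([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise InvalidArgumentError("need at least 2 classes for a Fisher criterion")
    if mu is None:
        mu = np.ones(n)
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (n,):
        raise InvalidArgumentError(f"mu must have shape ({n},), got {mu.shape}")
    p = samples[0].V.shape[1]
    vbar = np.mean([s.V for s in samples], axis=0)
    D = np.zeros((p, p))
    for w, s in zip(mu, samples):
        diff = s.V - vbar
        D += w * (diff.T @ diff)
    Dw = np.zeros((p, p))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        cbar = np.mean([samples[i].V for i in idx], axis=0)
        for i in idx:
            diff = samples[i].V - cbar
            Dw += mu[i] * (diff.T @ diff)
    # enforce exact symmetry against accumulation round-off
    return 0.5 * (D + D.T), 0.5 * (Dw + Dw.T)


def solve_fusion_coefficients(D: np.ndarray, Dw: np.ndarray,
                              ridge: float | None = None, K: int | None = None,
                              hyperparams: dict | None = None) -> FusionModel:
    """Leading generalized eigenvector of (D, D_w + ridge*I), unit-norm.

    The default ridge is ``1e-6 * trace(D_w)/p`` (or 1e-6 when D_w is zero),
    which keeps the pencil definite when interior samples nullify D_w.  The
    sign is fixed so the largest-magnitude entry is positive.
    """
    D = np.asarray(D, dtype=float)
    Dw = np.asarray(Dw, dtype=float)
    if D.shape != Dw.shape or D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidArgumentError("D and D_w must be square matrices of equal shape")
    if not np.any(D):
        raise NoDiscriminativeInformationError(
            "between-class scatter is zero; no fusion direction can be learned")
    p = D.shape[0]
    if ridge is None:
        tr = float(np.trace(Dw))
        ridge = 1e-6 * (tr / p if tr > 0 else 1.0)
    evals, evecs = linalg.eigh(D, Dw + ridge * np.eye(p))
    phi = evecs[:, -1]
    phi = phi / np.linalg.norm(phi)
    if phi[np.argmax(np.abs(phi))] < 0:
        phi = -phi
    return FusionModel(phi=phi, K=K if K is not None else p // len(BANDS),
                       eigenvalue=float(evals[-1]), ridge=float(ridge),
                       hyperparams=dict(hyperparams or {}))


def fuse(sample: BIMFFeatureMatrix, model: FusionModel,
         rescale: bool = True) -> FusedImage:
    """Project a sample onto the fusion direction and reshape to an image.

    With ``rescale=True`` (the default used downstream) the fused image is
    min-max normalized to [0, 1]; a constant projection maps to zeros.
    """
    phi = np.asarray(model.phi, dtype=float)
    if sample.V.shape[1] != phi.shape[0]:
        raise InvalidArgumentError(
            f"feature matrix has {sample.V.shape[1]} columns but phi has length {phi.shape[0]}")
    f = (sample.V @ phi).reshape(sample.shape)
    if rescale:
        lo, hi = f.min(), f.max()
        f = (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)
    return FusedImage(F=f, label=sample.label)


def sum_rule_model(n_cols: int, K: int | None = None) -> FusionModel:
    """Equal-weight fusion: phi = all-ones (the sum-rule baseline)."""
    return FusionModel(phi=np.ones(n_cols), K=K if K is not None else n_cols // len(BANDS),
                       hyperparams={"rule": "sum"})


def sum_rule_baseline(sample: BIMFFeatureMatrix, rescale: bool = True) -> FusedImage:
    return fuse(sample, sum_rule_model(sample.V.shape[1], sample.K), rescale=rescale)


def classic_fisher_baseline(samples: Sequence[BIMFFeatureMatrix],
                            ridge: float | None = None) -> FusionModel:
    """Fisher-criterion fusion: uniform contribution weights."""
    D, Dw = scatter_matrices(samples, mu=None)
    model = solve_fusion_coefficients(D, Dw, ridge=ridge, K=samples[0].K,
                                      hyperparams={"rule": "fisher"})
    return model


def fit_weighted_fisher(samples: Sequence[BIMFFeatureMatrix], k: int = 6,
                        delta: float = 5.0, ridge: float | None = None,
                        distance_scale: float | None = None) -> FusionModel:
    """Weighted-Fisher fusion: contribution factors drive the scatter weights."""
    cw = contribution_factors(samples, k=k, delta=delta, distance_scale=distance_scale)
    D, Dw = scatter_matrices(samples, mu=cw.mu)
    model = solve_fusion_coefficients(
        D, Dw, ridge=ridge, K=samples[0].K,
        hyperparams={"rule": "wfisher", "k": k, "delta": delta,
                     "distance_scale": cw.distance_scale})
    return model
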