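"""Fast and adaptive bidimensional empirical mode decomposition (FABEMD).

FABEMD decomposes a 2D intensity image into a small number of bidimensional
intrinsic mode functions (BIMFs) plus a residue,

    I = S_1 + S_2 + ... + S_K + R,

where finer oscillatory scales come first and the residue carries the smooth
trend.  Unlike spline-based BEMD, the upper and lower envelopes are estimated
with MAX / MIN order-statistics filters whose square window size is derived
from the spacing of the local extrema of the current source signal, followed
by an arithmetic-mean smoothing of the same window.  Each level extracts

    S_i = J_i - (U_Ei + L_Ei) / 2,        J_{i+1} = (U_Ei + L_Ei) / 2,

with J_1 = I, so the additive reconstruction holds exactly by telescoping.

For images acquired under uneven lighting the residue approximates the
multiplicative illumination field; dividing every BIMF by a smoothed residue
(`compensate`) cancels smooth multiplicative shading and yields
illumination-stable detail layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateExtremaError, InvalidArgumentError

__all__ = [
    "ExtremaMaps",
    "WindowSelection",
    "EnvelopePair",
    "BIMFDecomposition",
    "CompensatedBIMFs",
    "find_extrema",
    "adjacent_distances",
    "window_selection",
    "select_window_size",
    "order_statistics_envelopes",
    "estimate_envelopes",
    "decompose",
    "smooth_residue",
    "compensate",
]

#: Hard bounds on the order-statistics filter window.
WINDOW_MIN = 3
WINDOW_MAX = 69


@dataclass(frozen=True)
class ExtremaMaps:
    """Boolean maps of strict local maxima and minima of one source signal."""

    maxima: np.ndarray
    minima: np.ndarray

    @property
    def n_maxima(self) -> int:
        return int(self.maxima.sum())

    @property
    def n_minima(self) -> int:
        return int(self.minima.sum())


@dataclass(frozen=True)
class WindowSelection:
    """Outcome of the adjacent-extrema window-size rule."""

    d_adj_max: np.ndarray
    d_adj_min: np.ndarray
    gross_size: float
    final_size: int
    mode: str


@dataclass(frozen=True)
class EnvelopePair:
    """Upper and lower envelope surfaces of one source signal."""

    upper: np.ndarray
    lower: np.ndarray


@dataclass(frozen=True)
class BIMFDecomposition:
    """Ordered BIMFs plus residue; ``sum(bimfs) + residue`` equals the source."""

    bimfs: list[np.ndarray]
    residue: np.ndarray
    window_sizes: list[int]
    source_shape: tuple[int, int]

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for s in self.bimfs:
            out += s
        return out


@dataclass(frozen=True)
class CompensatedBIMFs:
    """Illumination-compensated BIMFs and the smoothed residue that divided them."""

    adjusted: list[np.ndarray]
    smooth_residue: np.ndarray
    eps: float = 1e-5
    smoothing_window: int = 10


def _as_image(image: np.ndarray) -> np.ndarray:
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise InvalidArgumentError(f"expected a 2D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("image contains non-finite values")
    return a


def find_extrema(image: np.ndarray, window: int = 3) -> ExtremaMaps:
    """Locate strict local maxima and minima over a square detection window.

    A pixel is a maximum iff its value exceeds every *other* pixel in the
    ``window x window`` neighborhood clipped to the image (neighbors outside
    the image are neglected); minima are symmetric.  Ties never qualify.
    """
    a = _as_image(image)
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError(f"detection window must be odd and >= 3, got {window}")
    footprint = np.ones((window, window), dtype=bool)
    footprint[window // 2, window // 2] = False
    neigh_max = ndimage.maximum_filter(a, footprint=footprint, mode="constant", cval=-np.inf)
    neigh_min = ndimage.minimum_filter(a, footprint=footprint, mode="constant", cval=np.inf)
    return ExtremaMaps(maxima=a > neigh_max, minima=a < neigh_min)


def adjacent_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to its nearest *other* point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise DegenerateExtremaError("need at least 2 extrema to measure adjacent distances")
    dists, _ = cKDTree(pts).query(pts, k=2)
    return dists[:, 1]


def _nearest_odd(x: float) -> int:
    # largest odd integer <= x (valid for x >= 1); ties between the two
    # surrounding odd integers round upward.
    lower = int(math.floor((x - 1.0) / 2.0)) * 2 + 1
    upper = lower + 2
    return lower if (x - lower) < (upper - x) else upper


def window_selection(maxima_points: np.ndarray, minima_points: np.ndarray,
                     mode: str = "d1") -> WindowSelection:
    """Derive the order-statistics filter window from adjacent-extrema spacing.

    The gross size is the min (``d1``) or max (``d2``) of the two minimal
    adjacent-extrema distances, rounded to the nearest odd integer (ties up)
    and clamped to [3, 69].
    """
    if mode not in ("d1", "d2"):
        raise InvalidArgumentError(f"mode must be 'd1' or 'd2', got {mode!r}")
    d_max = adjacent_distances(maxima_points)
    d_min = adjacent_distances(minima_points)
    pair = (float(d_max.min()), float(d_min.min()))
    gross = min(pair) if mode == "d1" else max(pair)
    final = min(max(_nearest_odd(max(gross, 1.0)), WINDOW_MIN), WINDOW_MAX)
    return WindowSelection(d_adj_max=d_max, d_adj_min=d_min, gross_size=gross,
                           final_size=final, mode=mode)


def select_window_size(maxima_points: np.ndarray, minima_points: np.ndarray,
                       mode: str = "d1") -> int:
    return window_selection(maxima_points, minima_points, mode).final_size


def _clipped_mean(a: np.ndarray, window: int) -> np.ndarray:
    """Arithmetic-mean filter dividing by the number of in-image window pixels.

    For an even window the extra row/column extends toward larger indices.
    """
    h, w = a.shape
    lo = (window - 1) // 2
    hi = window // 2
    cs = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=cs[1:, 1:])
    r0 = np.clip(np.arange(h) - lo, 0, h)
    r1 = np.clip(np.arange(h) + hi + 1, 0, h)
    c0 = np.clip(np.arange(w) - lo, 0, w)
    c1 = np.clip(np.arange(w) + hi + 1, 0, w)
    total = (cs[np.ix_(r1, c1)] - cs[np.ix_(r0, c1)]
             - cs[np.ix_(r1, c0)] + cs[np.ix_(r0, c0)])
    counts = np.outer(r1 - r0, c1 - c0)
    return total / counts


def order_statistics_envelopes(source: np.ndarray, w_en: int) -> EnvelopePair:
    """Raw MAX/MIN filtered envelopes (pre-smoothing); upper >= source >= lower."""
    a = _as_image(source)
    # replicate padding only duplicates in-window edge pixels, so this equals
    # the max/min over the window clipped to the image
    upper = ndimage.maximum_filter(a, size=w_en, mode="nearest")
    lower = ndimage.minimum_filter(a, size=w_en, mode="nearest")
    return EnvelopePair(upper=upper, lower=lower)


def estimate_envelopes(source: np.ndarray, w_en: int) -> EnvelopePair:
    """Order-statistics envelopes followed by a same-window mean smoothing."""
    if w_en % 2 == 0 or not (WINDOW_MIN <= w_en <= WINDOW_MAX):
        raise InvalidArgumentError(f"w_en must be odd in [{WINDOW_MIN}, {WINDOW_MAX}], got {w_en}")
    raw = order_statistics_envelopes(source, w_en)
    return EnvelopePair(upper=_clipped_mean(raw.upper, w_en),
                        lower=_clipped_mean(raw.lower, w_en))


def decompose(image: np.ndarray, K: int = 4, mode: str = "d1",
              detection_window: int = 3) -> BIMFDecomposition:
    """Extract K BIMFs and a residue from a 2D image.

    The filter window is re-derived at every level from the extrema of the
    current source signal.  If a level has fewer than two maxima or minima the
    shifting stops early: the remaining BIMFs are zero and the residue is the
    current source, so the additive reconstruction always holds.
    """
    a = _as_image(image)
    if K < 1:
        raise InvalidArgumentError(f"K must be >= 1, got {K}")
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise InvalidArgumentError(f"image must be at least 3x3, got {a.shape}")

    current = a.copy()
    bimfs: list[np.ndarray] = []
    windows: list[int] = []
    for _ in range(K):
        ext = find_extrema(current, detection_window)
        if ext.n_maxima < 2 or ext.n_minima < 2:
            break
        w_en = select_window_size(np.argwhere(ext.maxima), np.argwhere(ext.minima), mode)
        env = estimate_envelopes(current, w_en)
        mean_env = 0.5 * (env.upper + env.lower)
        bimfs.append(current - mean_env)
        windows.append(w_en)
        current = mean_env
    while len(bimfs) < K:
        bimfs.append(np.zeros_like(a))
        windows.append(WINDOW_MIN)
    return BIMFDecomposition(bimfs=bimfs, residue=current, window_sizes=windows,
                             source_shape=a.shape)


def smooth_residue(residue: np.ndarray, window: int = 10) -> np.ndarray:
    """Average-filter the residue into a smooth illumination estimate."""
    a = _as_image(residue)
    if window < 1:
        raise InvalidArgumentError(f"window must be >= 1, got {window}")
    if window == 1:
        return a.copy()
    return _clipped_mean(a, window)


def compensate(bimfs: list[np.ndarray], smooth_res: np.ndarray, eps: float = 1e-5,
               smoothing_window: int = 10) -> CompensatedBIMFs:
    """Divide every BIMF elementwise by the smoothed residue.

    Where ``|R_s| < eps`` the denominator is replaced by ``eps`` so the
    division never blows up on (near-)zero illumination estimates.
    """
    if eps <= 0:
        raise InvalidArgumentError(f"eps must be positive, got {eps}")
    rs = _as_image(smooth_res)
    denom = np.where(np.abs(rs) >= eps, rs, eps)
    adjusted = []
    for s in bimfs:
        s = np.asarray(s, dtype=float)
        if s.shape != rs.shape:
            raise InvalidArgumentError(
                f"BIMF shape {s.shape} does not match residue shape {rs.shape}")
        adjusted.append(s / denom)
    return CompensatedBIMFs(adjusted=adjusted, smooth_residue=rs, eps=eps,
                            smoothing_window=smoothing_window)


def decompose_and_compensate(image: np.ndarray, K: int = 4, mode: str = "d1",
                             smoothing_window: int = 10, eps: float = 1e-5,
                             apply_compensation: bool = True) -> CompensatedBIMFs:
    """Convenience path: decompose, smooth the residue, compensate.

    With ``apply_compensation=False`` the raw BIMFs are returned unchanged
    (the smoothed residue is still reported).
    """
    dec = decompose(image, K=K, mode=mode)
    rs = smooth_residue(dec.residue, smoothing_window)
    if not apply_compensation:
        return CompensatedBIMFs(adjusted=[s.copy() for s in dec.bimfs],
                                smooth_residue=rs, eps=eps,
                                smoothing_window=smoothing_window)
    return compensate(dec.bimfs, rs, eps=eps, smoothing_window=smoothing_window)
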