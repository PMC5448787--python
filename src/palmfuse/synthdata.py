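"""Synthetic multispectral palm-like datasets.

Real multispectral palm images consist of dark curvilinear structure (principal
lines, wrinkles, ridges) on a bright skin background, captured at Blue, Green,
Red and NIR bands that are co-registered by construction; the longer
wavelengths additionally pick up subcutaneous vein patterns.  This module
emulates exactly those properties with random smooth strokes:

* all identities share one global layout of principal lines (real palms carry
  their principal lines in roughly the same places); each identity (class)
  perturbs that layout and adds its own minor wrinkles, and the resulting
  stroke set is shared by all four bands, scaled by a per-band contrast gain;
* extra lower-contrast, wider "vein" strokes appear only in Red and NIR,
  again as class-specific perturbations of a common layout;
* within-class variation is a small common translation plus additive noise;
* test images can be corrupted by a smooth multiplicative uneven-illumination
  field (linear gradient or Gaussian bump) of controllable strength, mirroring
  the way shading enters real acquisitions.

Everything is driven by one seed through per-purpose substreams, so a given
spec reproduces the dataset bit for bit; training instances and test instances
are independent draws, and toggling the illumination settings changes only the
illumination, not the underlying test images.

The strokes are statistical stand-ins, not anatomical renderings: they provide
class-discriminative correlated multiband texture, which is all the
decomposition/fusion/classification chain consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .io import MultispectralSample, save_image, write_manifest

__all__ = [
    "SyntheticDatasetSpec",
    "IlluminationField",
    "generate_identity_template",
    "sample_instance",
    "make_illumination_field",
    "apply_illumination",
    "generate_dataset",
    "write_dataset",
]

BANDS = ("blue", "green", "red", "nir")

# rng substream tags
_TAG_TEMPLATE, _TAG_INSTANCE, _TAG_ILLUM, _TAG_LAYOUT = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full recipe for one reproducible dataset."""

    n_classes: int = 10
    train_per_class: int = 6
    test_per_class: int = 6
    image_size: int = 64
    n_principal: int = 3             # principal lines, shared global layout
    n_lines: int = 4                 # class-specific minor wrinkles
    class_offset_sd: float = 2.0     # px perturbation of the global layout per class
    line_width_range: tuple[float, float] = (1.4, 2.8)  # gaussian sigma, px
    line_amplitude_range: tuple[float, float] = (0.35, 0.6)
    wrinkle_width_range: tuple[float, float] = (1.0, 2.0)
    wrinkle_amplitude_range: tuple[float, float] = (0.12, 0.22)
    vein_n_lines: int = 3
    vein_width_range: tuple[float, float] = (2.0, 4.0)
    vein_amplitude_range: tuple[float, float] = (0.12, 0.25)
    band_gains: tuple[float, float, float, float] = (1.0, 0.95, 0.85, 0.8)
    background: float = 0.85
    jitter_translation: float = 2.5  # max |shift| per axis, px
    jitter_noise_sd: float = 0.04
    illumination: str = "none"  # none | linear | gaussian_bump
    illumination_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.train_per_class, self.test_per_class,
               self.image_size, self.n_lines) < 1:
            raise InvalidArgumentError("all counts must be positive")
        if self.illumination not in ("none", "linear", "gaussian_bump"):
            raise InvalidArgumentError(f"unknown illumination {self.illumination!r}")
        if not 0.0 <= self.illumination_strength <= 0.9:
            raise InvalidArgumentError("illumination strength must be in [0, 0.9]")


@dataclass(frozen=True)
class IlluminationField:
    """Smooth positive multiplicative field with mean 1."""

    field: np.ndarray
    kind: str
    strength: float


def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, *key])


def _stroke_params(size: int, rng: np.random.Generator) -> np.ndarray:
    """Control points (p0, p1, p2) of one random quadratic Bezier stroke."""
    m = 0.1 * size
    p0 = rng.uniform(m, size - m, 2)
    p2 = rng.uniform(m, size - m, 2)
    mid = 0.5 * (p0 + p2)
    perp = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
    norm = np.linalg.norm(perp)
    if norm > 0:
        perp = perp / norm
    p1 = mid + perp * rng.uniform(-0.3, 0.3) * size
    return np.stack([p0, p1, p2])


def _render_stroke(params: np.ndarray, size: int, width: float) -> np.ndarray:
    """Rasterize a quadratic Bezier stroke, max-normalized to 1."""
    p0, p1, p2 = params
    t = np.linspace(0.0, 1.0, 6 * size)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    canvas = np.zeros((size, size))
    ij = np.clip(np.round(pts).astype(int), 0, size - 1)
    canvas[ij[:, 0], ij[:, 1]] = 1.0
    canvas = ndimage.gaussian_filter(canvas, width)
    peak = canvas.max()
    return canvas / peak if peak > 0 else canvas


def _global_layout(spec: SyntheticDatasetSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-line and vein stroke layouts shared by every identity."""
    rng = _rng(seed, _TAG_LAYOUT)
    principal = np.stack([_stroke_params(spec.image_size, rng)
                          for _ in range(spec.n_principal)])
    veins = np.stack([_stroke_params(spec.image_size, rng)
                      for _ in range(spec.vein_n_lines)])
    return principal, veins


def generate_identity_template(class_id: int, spec: SyntheticDatasetSpec,
                               seed: int | None = None) -> dict[str, np.ndarray]:
    """Per-band base images of one identity.

    Identity = class-specific perturbation of the shared principal-line and
    vein layouts plus a few private minor wrinkles.  Blue/Green/Red/NIR share
    the same line pattern scaled by the band gains; Red and NIR additionally
    carry the vein pattern.
    """
    seed = spec.seed if seed is None else seed
    principal_layout, vein_layout = _global_layout(spec, seed)
    rng = _rng(seed, _TAG_TEMPLATE, class_id)
    size = spec.image_size
    lines = np.zeros((size, size))
    for params in principal_layout:
        amp = rng.uniform(*spec.line_amplitude_range)
        width = rng.uniform(*spec.line_width_range)
        jittered = params + rng.normal(0.0, spec.class_offset_sd, params.shape)
        lines += amp * _render_stroke(jittered, size, width)
    for _ in range(spec.n_lines):
        amp = rng.uniform(*spec.wrinkle_amplitude_range)
        width = rng.uniform(*spec.wrinkle_width_range)
        lines += amp * _render_stroke(_stroke_params(size, rng), size, width)
    veins = np.zeros((size, size))
    for params in vein_layout:
        amp = rng.uniform(*spec.vein_amplitude_range)
        width = rng.uniform(*spec.vein_width_range)
        jittered = params + rng.normal(0.0, spec.class_offset_sd, params.shape)
        veins += amp * _render_stroke(jittered, size, width)
    out = {}
    for band, gain in zip(BANDS, spec.band_gains):
        img = spec.background - gain * lines
        if band in ("red", "nir"):
            img = img - veins
        out[band] = np.clip(img, 0.0, 1.0)
    return out


def sample_instance(template: dict[str, np.ndarray], spec: SyntheticDatasetSpec,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One within-class draw: a shared sub-pixel translation plus pixel noise.

    The translation is identical across bands (the acquisition leaves bands
    co-registered); the additive noise is independent per band.
    """
    shift = rng.uniform(-spec.jitter_translation, spec.jitter_translation, 2) \
        if spec.jitter_translation > 0 else np.zeros(2)
    out = {}
    for band in BANDS:
        img = template[band]
        if np.any(shift):
            img = ndimage.shift(img, shift, order=1, mode="nearest")
        if spec.jitter_noise_sd > 0:
            img = img + rng.normal(0.0, spec.jitter_noise_sd, img.shape)
        out[band] = np.clip(img, 0.0, 1.0)
    return out


def make_illumination_field(size: int, kind: str, strength: float,
                            rng: np.random.Generator | int = 0) -> IlluminationField:
    """Smooth multiplicative shading field with mean exactly 1.

    ``linear`` ramps along a random direction through the image center;
    ``gaussian_bump`` is a randomly centered Gaussian highlight/shadow.
    Values stay within [1 - strength, 1 + strength].
    """
    if not 0.0 <= strength <= 0.9:
        raise InvalidArgumentError("strength must be in [0, 0.9]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if kind == "none" or strength == 0.0:
        return IlluminationField(field=np.ones((size, size)), kind="none", strength=0.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    if kind == "linear":
        theta = rng.uniform(0, 2 * np.pi)
        dev = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    elif kind == "gaussian_bump":
        by, bx = rng.uniform(0.2 * size, 0.8 * size, 2)
        sigma = rng.uniform(0.25, 0.4) * size
        dev = np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sigma**2))
        if rng.uniform() < 0.5:
            dev = -dev  # shadow instead of highlight
    else:
        raise InvalidArgumentError(f"unknown illumination kind {kind!r}")
    dev = dev - dev.mean()
    peak = np.abs(dev).max()
    field = 1.0 + strength * dev / peak if peak > 0 else np.ones((size, size))
    return IlluminationField(field=field, kind=kind, strength=strength)


def apply_illumination(image: np.ndarray, field: IlluminationField | np.ndarray) -> np.ndarray:
    f = field.field if isinstance(field, IlluminationField) else field
    return np.clip(np.asarray(image, dtype=float) * f, 0.0, 1.0)


def generate_dataset(spec: SyntheticDatasetSpec
                     ) -> tuple[list[MultispectralSample], list[MultispectralSample]]:
    """Build (train, test) sample lists.

    Training samples are clean; test samples are fresh within-class draws,
    multiplied by a per-sample illumination field when the spec asks for one.
    The illumination substream is separate from the jitter substream, so two
    specs differing only in illumination share identical underlying test
    images.
    """
    train, test = [], []
    for cls in range(spec.n_classes):
        template = generate_identity_template(cls, spec)
        for j in range(spec.train_per_class):
            rng = _rng(spec.seed, _TAG_INSTANCE, cls, 0, j)
            bands = sample_instance(template, spec, rng)
            train.append(MultispectralSample(bands=bands, label=cls,
                                             sample_id=f"c{cls:03d}_train{j:02d}",
                                             split="train"))
        for j in range(spec.test_per_class):
            rng = _rng(spec.seed, _TAG_INSTANCE, cls, 1, j)
            bands = sample_instance(template, spec, rng)
            if spec.illumination != "none" and spec.illumination_strength > 0:
                illum_rng = _rng(spec.seed, _TAG_ILLUM, cls, j)
                fld = make_illumination_field(spec.image_size, spec.illumination,
                                              spec.illumination_strength, illum_rng)
                bands = {b: apply_illumination(img, fld) for b, img in bands.items()}
            test.append(MultispectralSample(bands=bands, label=cls,
                                            sample_id=f"c{cls:03d}_test{j:02d}",
                                            split="test"))
    return train, test


def write_dataset(train: list[MultispectralSample], test: list[MultispectralSample],
                  out_dir: str | Path) -> Path:
    """Write PNGs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in [*train, *test]:
        for band, img in sample.bands.items():
            rel = f"{sample.sample_id}_{band}.png"
            save_image(out_dir / rel, img)
            rows.append({"sample_id": sample.sample_id, "label": sample.label,
                         "band": band, "split": sample.split, "path": rel})
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
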