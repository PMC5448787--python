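"""Image and manifest I/O.

Datasets are exchanged as a directory of single-band grayscale images plus a
manifest CSV with columns ``sample_id, label, band, split, path``.  Images are
read as floating intensities on the unit scale: 8-bit values are divided by
255, 16-bit by 65535, floating images are taken as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["MultispectralSample", "load_image", "save_image",
           "load_manifest", "write_manifest"]

MANIFEST_COLUMNS = ["sample_id", "label", "band", "split", "path"]


@dataclass
class MultispectralSample:
    """One labeled sample: a dict of co-registered single-band images."""

    bands: dict[str, np.ndarray]
    label: int
    sample_id: str = ""
    split: str = ""


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float64 intensities in [0, 1]."""
    a = np.asarray(iio.imread(Path(path)))
    if a.ndim == 3:  # collapse an accidental RGB to luminance-ish mean
        a = a.mean(axis=2)
    if a.dtype == np.uint8:
        return a.astype(float) / 255.0
    if a.dtype == np.uint16:
        return a.astype(float) / 65535.0
    return a.astype(float)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a unit-scale image as 16-bit grayscale PNG."""
    a = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(a * 65535).astype(np.uint16))


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def load_manifest(path: str | Path, split: str | None = None,
                  bands: tuple[str, ...] | None = None) -> list[MultispectralSample]:
    """Group manifest rows into :class:`MultispectralSample` records.

    Raises a descriptive error naming the sample and band when a configured
    band image is missing or unreadable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidArgumentError(f"manifest {path} lacks columns {missing_cols}")
    if split is not None:
        df = df[df["split"] == split]
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        have = {str(r.band): r for r in grp.itertuples()}
        wanted = bands if bands is not None else tuple(sorted(have))
        images = {}
        for b in wanted:
            if b not in have:
                raise IOError(f"sample {sid!r} is missing band {b!r} in manifest {path}")
            img_path = Path(have[b].path)
            if not img_path.is_absolute():
                img_path = path.parent / img_path
            if not img_path.exists():
                raise IOError(f"sample {sid!r}, band {b!r}: image file not found: {img_path}")
            images[b] = load_image(img_path)
        labels = set(grp["label"])
        if len(labels) != 1:
            raise InvalidArgumentError(f"sample {sid!r} has conflicting labels {labels}")
        samples.append(MultispectralSample(bands=images, label=int(grp["label"].iloc[0]),
                                           sample_id=str(sid),
                                           split=str(grp["split"].iloc[0])))
    return samples
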