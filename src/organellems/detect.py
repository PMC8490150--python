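"""Label-free vesicle detection in grayscale microscopy images.

Vesicles appear as small dark (brightfield) or bright (digitally inverted)
blobs against a roughly uniform background.  Detection is a global threshold
(Otsu by default), 8-connected component labeling, a diameter window filter,
and intensity-weighted centroids for sub-pixel targeting accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure
from skimage.filters import threshold_otsu

from .fixtures import ImageFixture

__all__ = ["ObjectTable", "BinaryMask", "threshold_objects", "make_mask", "filter_objects", "read_image"]

_COLUMNS = [
    "id",
    "row_px",
    "col_px",
    "area_px2",
    "mean_intensity",
    "eq_diam_px",
    "eccentricity",
    "accepted",
]


@dataclass
class ObjectTable:
    """Detected vesicle candidates.

    ``df`` has one row per object (columns: id, row_px, col_px, area_px2,
    mean_intensity, eq_diam_px, eccentricity, accepted); ``pixels`` maps each
    object id to its (rows, cols) pixel index arrays so masks can be
    reconstructed exactly.
    """

    df: pd.DataFrame
    pixels: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.df):
            if self.df["id"].duplicated().any():
                raise ValueError("object ids must be unique")
            if (self.df["area_px2"] <= 0).any():
                raise ValueError("object areas must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def accepted(self) -> pd.DataFrame:
        return self.df[self.df["accepted"]]

    def centroids(self, accepted_only: bool = True) -> np.ndarray:
        d = self.accepted if accepted_only else self.df
        return d[["row_px", "col_px"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.df[_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObjectTable":
        df = pd.read_csv(path)
        missing = set(_COLUMNS) - {"eccentricity"} - set(df.columns)
        if missing:
            raise ValueError(f"object table missing columns: {sorted(missing)}")
        return cls(df=df)


@dataclass
class BinaryMask:
    """Binary image: object pixels at the dtype maximum, background at 0."""

    pixels: np.ndarray
    foreground_value: int

    def __post_init__(self) -> None:
        vals = np.unique(self.pixels)
        if not set(vals.tolist()) <= {0, self.foreground_value}:
            raise ValueError("mask must contain only 0 and foreground_value")

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG into a 2-D float array."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        img = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        img = iio.imread(p)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse RGB
        img = img.mean(axis=2)
    return img


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, ImageFixture):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def threshold_objects(
    image,
    polarity: str = "dark",
    min_diameter: float = 2.0,
    max_diameter: float = 40.0,
    threshold: float | None = None,
) -> ObjectTable:
    """Segment vesicle candidates with a global threshold.

    Parameters
    ----------
    image : 2-D array or ImageFixture
    polarity : 'dark' for dark-on-bright brightfield vesicles, 'bright' for
        inverted images.
    min_diameter, max_diameter : equivalent-diameter window in pixels;
        components outside it are discarded.
    threshold : manual global threshold; default is Otsu's.

    A blank/constant image yields an empty table with a warning rather than
    an exception.  Centroids are intensity-weighted (contrast relative to
    the background side of the threshold), 0-based, origin at the top-left
    pixel center.
    """
    if min_diameter >= max_diameter:
        raise ValueError("min_diameter must be < max_diameter")
    if polarity not in ("dark", "bright"):
        raise ValueError(f"unknown polarity {polarity!r}")
    img = _as_pixels(image)
    if img.size == 0:
        raise ValueError("empty image")

    empty = ObjectTable(
        df=pd.DataFrame(columns=_COLUMNS).astype({"accepted": bool}),
        pixels={},
        image_shape=img.shape,
    )
    if np.ptp(img) == 0:
        warnings.warn("constant image: no contrast, returning empty object table")
        return empty

    thr = float(threshold_otsu(img)) if threshold is None else float(threshold)
    fg = img < thr if polarity == "dark" else img > thr
    if not fg.any():
        warnings.warn("threshold found no foreground pixels")
        return empty

    labels = measure.label(fg, connectivity=2)  # 8-connectivity
    # weight by contrast so centroids are pulled toward the blob core
    weight = (img.max() - img) if polarity == "dark" else img
    props = measure.regionprops(labels, intensity_image=weight)

    rows, pixmap = [], {}
    oid = 0
    for p in props:
        if not (min_diameter <= p.equivalent_diameter_area <= max_diameter):
            continue
        wr, wc = p.centroid_weighted
        if not np.isfinite(wr):  # all-zero weights: fall back to unweighted
            wr, wc = p.centroid
        coords = p.coords
        rows.append(
            {
                "id": oid,
                "row_px": float(wr),
                "col_px": float(wc),
                "area_px2": float(p.area),
                "mean_intensity": float(img[coords[:, 0], coords[:, 1]].mean()),
                "eq_diam_px": float(p.equivalent_diameter_area),
                "eccentricity": float(p.eccentricity),
                "accepted": True,
            }
        )
        pixmap[oid] = (coords[:, 0].copy(), coords[:, 1].copy())
        oid += 1
    if not rows:
        return empty
    return ObjectTable(df=pd.DataFrame(rows), pixels=pixmap, image_shape=img.shape)


def make_mask(
    image_shape: tuple[int, int],
    objects: ObjectTable,
    dtype=np.uint16,
) -> BinaryMask:
    """Rasterize accepted objects at the dtype's maximum over a zero field."""
    fg = int(np.iinfo(dtype).max)
    out = np.zeros(image_shape, dtype=dtype)
    for oid in objects.accepted["id"]:
        if oid not in objects.pixels:
            raise ValueError(f"object {oid} has no stored pixel coordinates")
        rr, cc = objects.pixels[oid]
        if len(rr) and (rr.max() >= image_shape[0] or cc.max() >= image_shape[1]):
            raise ValueError(f"object {oid} lies outside image_shape")
        out[rr, cc] = fg
    return BinaryMask(pixels=out, foreground_value=fg)


def filter_objects(
    objects: ObjectTable,
    rules: Sequence[str | Callable[[pd.DataFrame], "pd.Series"]] = (),
    manual_removals: Iterable[int] = (),
) -> ObjectTable:
    """Update the ``accepted`` flag by morphology rules and manual removals.

    ``rules`` are pandas expressions over the table columns (e.g.
    ``"eccentricity < 0.9"``) or callables returning a boolean Series; an
    object stays accepted only if it satisfies every rule.  Rows are never
    deleted, preserving the audit trail.  Unknown ids in
    ``manual_removals`` raise a ``KeyError`` naming the id.
    """
    df = objects.df.copy()
    keep = df["accepted"].to_numpy(copy=True)
    for rule in rules:
        ok = df.eval(rule) if isinstance(rule, str) else rule(df)
        keep &= np.asarray(ok, dtype=bool)
    ids = set(df["id"].tolist())
    for rid in manual_removals:
        if rid not in ids:
            raise KeyError(f"unknown object id: {rid}")
        keep &= (df["id"] != rid).to_numpy()
    df["accepted"] = keep
    return ObjectTable(df=df, pixels=dict(objects.pixels), image_shape=objects.image_shape)
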