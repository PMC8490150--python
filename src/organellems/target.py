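"""Pixel→stage registration and laser-safe target-list generation.

Object centroids found in the microscopy image are mapped to mass
spectrometer stage coordinates by a point-based affine registration fitted
to fiducial pairs, then pruned by a distance filter so that no two targets
sit closer than the laser-spot-safe spacing (200 µm by default for a 100 µm
laser footprint): every member of a too-close pair is removed, guaranteeing
that each acquisition samples a single organelle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import ObjectTable

__all__ = [
    "RegistrationModel",
    "TargetList",
    "fit_registration",
    "apply_distance_filter",
    "distance_filter_mask",
    "export_targets",
    "read_fiducials",
]


@dataclass
class RegistrationModel:
    """2-D affine map from pixel (row, col) to stage (x, y) in µm.

    stage = A @ (row, col) + t, six free parameters.
    """

    A: np.ndarray  # (2, 2)
    t: np.ndarray  # (2,)
    fiducials: pd.DataFrame
    rms_residual: float  # µm

    def pixel_to_stage(self, pts_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_px, dtype=float))
        return pts @ self.A.T + self.t

    def stage_to_pixel(self, pts_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        return (pts - self.t) @ np.linalg.inv(self.A).T


def read_fiducials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"px_row", "px_col", "stage_x_um", "stage_y_um"}
    if not need <= set(df.columns):
        raise ValueError(f"fiducial CSV must have columns {sorted(need)}")
    return df


def fit_registration(fiducials) -> RegistrationModel:
    """Least-squares affine fit to ≥3 non-collinear fiducial pairs.

    ``fiducials`` is a DataFrame with columns px_row, px_col, stage_x_um,
    stage_y_um, or a sequence of ((row, col), (x, y)) pairs.  The fit is
    exact (residual ≤ 1e-9 µm) when the pairs derive from an affine map.
    """
    if isinstance(fiducials, pd.DataFrame):
        df = fiducials
    else:
        df = pd.DataFrame(
            [
                {
                    "px_row": p[0][0],
                    "px_col": p[0][1],
                    "stage_x_um": p[1][0],
                    "stage_y_um": p[1][1],
                }
                for p in fiducials
            ]
        )
    if len(df) < 3:
        raise ValueError(f"need at least 3 fiducial pairs, got {len(df)}")
    px = df[["px_row", "px_col"]].to_numpy(dtype=float)
    st = df[["stage_x_um", "stage_y_um"]].to_numpy(dtype=float)
    centered = px - px.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("fiducials are collinear in pixel space; affine fit is degenerate")
    # solve on centered coordinates for numerical conditioning (stage
    # offsets are often 1e4-1e5 µm), then recover the offset
    px_mean, st_mean = px.mean(axis=0), st.mean(axis=0)
    design = np.column_stack([px - px_mean, np.ones(len(px))])
    coef, *_ = np.linalg.lstsq(design, st - st_mean, rcond=None)  # (3, 2)
    A = coef[:2].T
    t = st_mean + coef[2] - A @ px_mean
    resid = px @ A.T + t - st
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationModel(A=A, t=t, fiducials=df.copy(), rms_residual=rms)


def distance_filter_mask(points: np.ndarray, min_spacing: float) -> np.ndarray:
    """Boolean keep-mask: True where the nearest neighbor is ≥ min_spacing.

    Symmetric removal: both members of any pair strictly closer than
    ``min_spacing`` are dropped (a distance exactly equal to the spacing is
    kept).  Backed by a k-d tree, so it is exact and fast for large n.
    """
    if min_spacing <= 0:
        raise ValueError("min_spacing must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    if n < 2:
        return keep
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=min_spacing, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        close = pairs[d < min_spacing]  # strict "closer than"
        keep[close.ravel()] = False
    return keep


def apply_distance_filter(
    points, min_spacing: float = 200.0, mode: str = "symmetric"
) -> np.ndarray:
    """Return the points surviving the minimum-spacing filter, order preserved.

    ``mode='symmetric'`` (default) removes every point with any neighbor
    strictly closer than ``min_spacing``; ``mode='greedy'`` keeps the first
    point of each close pair in input order instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if mode == "symmetric":
        return pts[distance_filter_mask(pts, min_spacing)]
    if mode == "greedy":
        keep: list[int] = []
        kept_pts: list[np.ndarray] = []
        for i, p in enumerate(pts):
            if all(np.linalg.norm(p - q) >= min_spacing for q in kept_pts):
                keep.append(i)
                kept_pts.append(p)
        return pts[keep]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TargetList:
    """Stage-coordinate targets with provenance back to image objects."""

    entries: pd.DataFrame  # columns: object_id, x_um, y_um
    spot_diameter: float = 100.0  # µm
    min_spacing: float = 200.0  # µm

    def __post_init__(self) -> None:
        pts = self.entries[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts) >= 2:
            tree = cKDTree(pts)
            d, _ = tree.query(pts, k=2)
            if d[:, 1].min() < self.min_spacing:
                raise ValueError(
                    "target list violates min_spacing: nearest pair at "
                    f"{d[:, 1].min():.3f} µm < {self.min_spacing} µm"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)

    def to_point_list(self, path: str | Path) -> None:
        """Plain 'x y' per line, for instrument import."""
        with open(path, "w") as fh:
            for _, r in self.entries.iterrows():
                fh.write(f"{r.x_um:.3f} {r.y_um:.3f}\n")


def export_targets(
    objects: ObjectTable,
    model: RegistrationModel,
    min_spacing: float = 200.0,
    spot_diameter: float = 100.0,
) -> TargetList:
    """Transform accepted objects to stage µm and apply the distance filter.

    The returned table keeps each target's source object id so spectra can
    later be matched back to image crops of the individual vesicles.
    """
    acc = objects.accepted
    if len(acc) == 0:
        warnings.warn("no accepted objects: exporting an empty target list")
        return TargetList(
            entries=pd.DataFrame(columns=["object_id", "x_um", "y_um"]),
            spot_diameter=spot_diameter,
            min_spacing=min_spacing,
        )
    stage = model.pixel_to_stage(acc[["row_px", "col_px"]].to_numpy(dtype=float))
    keep = distance_filter_mask(stage, min_spacing)
    entries = pd.DataFrame(
        {
            "object_id": acc["id"].to_numpy()[keep],
            "x_um": stage[keep, 0],
            "y_um": stage[keep, 1],
        }
    )
    return TargetList(entries=entries, spot_diameter=spot_diameter, min_spacing=min_spacing)
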