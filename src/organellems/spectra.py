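"""Spectral preprocessing: peak picking, internal calibration, alignment.

Each single-organelle spectrum is reduced to a centroided peak list (local
maxima passing a signal-to-noise and a relative-intensity threshold, with
sub-grid apex refinement), optionally recalibrated against internal
calibrant peaks of known exact mass, and finally aligned across spectra by
nonuniform ppm-gap binning into a spectra × features intensity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "PeakList",
    "CalibrationModel",
    "PeakMatrix",
    "pick_peaks",
    "calibrate",
    "align_bins",
    "read_mzml",
    "read_calibrants",
]


@dataclass
class PeakList:
    """Centroided peaks of one spectrum (m/z ascending)."""

    spectrum_id: str
    peaks: pd.DataFrame  # columns: mz, intensity, snr
    base_peak_intensity: float
    calibrated: bool = False
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks["intensity"].to_numpy()


@dataclass
class CalibrationModel:
    """Linear m/z recalibration m_corr = a * m_obs + b.

    With ≥2 matched calibrants both gain and offset drift are corrected;
    with a single match only a multiplicative (constant-ppm) correction is
    applied.  ``matched`` lists calibrants found within the search window;
    ``unmatched`` names the ones that were not.
    """

    calibrants: pd.DataFrame  # name, mz (theoretical)
    matched: pd.DataFrame  # name, theoretical_mz, observed_mz
    a: float
    b: float
    residuals_ppm: np.ndarray
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def read_mzml(path: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read (id, m/z, intensity) for each spectrum in an mzML file.

    Uses pyteomics when its mzML backend is importable; otherwise falls
    back to a small lxml parser covering plain base64 binary arrays
    (32/64-bit floats, zlib or uncompressed) — the subset this package
    writes.
    """
    try:
        from pyteomics import mzml as _mzml

        out = []
        with _mzml.MzML(str(path)) as reader:
            for sp in reader:
                out.append((sp["id"], sp["m/z array"], sp["intensity array"]))
        return out
    except Exception:
        return _read_mzml_minimal(path)


def _read_mzml_minimal(path: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    import base64
    import zlib

    from lxml import etree

    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    tree = etree.parse(str(path))
    out = []
    for sp in tree.iterfind(".//m:spectrum", ns):
        arrays: dict[str, np.ndarray] = {}
        for bda in sp.iterfind(".//m:binaryDataArray", ns):
            accs = {cv.get("accession") for cv in bda.iterfind("m:cvParam", ns)}
            dtype = "<f8" if "MS:1000523" in accs else "<f4"
            raw = base64.b64decode(bda.findtext("m:binary", "", ns))
            if "MS:1000574" in accs:  # zlib compression
                raw = zlib.decompress(raw)
            arr = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accs:
                arrays["mz"] = arr
            elif "MS:1000515" in accs:
                arrays["intensity"] = arr
        if {"mz", "intensity"} <= arrays.keys():
            out.append((sp.get("id", ""), arrays["mz"], arrays["intensity"]))
    return out


def read_calibrants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"name", "mz"} <= set(df.columns):
        raise ValueError("calibrants CSV must have columns: name, mz")
    return df


def _refine_apex(
    mz: np.ndarray, inten: np.ndarray, i: int, half_width: int = 3
) -> tuple[float, float]:
    """Parabolic apex interpolation around grid index ``i``.

    Fits a least-squares parabola to the log intensities of up to
    ``2*half_width + 1`` grid points centered on the maximum (a Gaussian
    peak is exactly quadratic in log space, so the fit is unbiased while
    averaging grid-point noise).  Falls back to the classic 3-point plain
    parabola when the log fit is unusable (nonpositive points, or no
    concave apex).
    """
    n = len(mz)
    lo = max(i - half_width, 0)
    hi = min(i + half_width + 1, n)
    x = mz[lo:hi] - mz[i]
    y = inten[lo:hi]
    if len(x) >= 3 and y.min() > 0:
        L = np.log(y)
        coef = np.polynomial.polynomial.polyfit(x, L, 2)  # c0 + c1 x + c2 x^2
        c0, c1, c2 = coef
        if c2 < 0:
            dx = -c1 / (2.0 * c2)
            half_span = 0.5 * (mz[min(i + 1, n - 1)] - mz[max(i - 1, 0)])
            if abs(dx) <= max(half_span, 1e-12):
                return float(mz[i] + dx), float(np.exp(c0 - c1**2 / (4.0 * c2)))
    # 3-point plain parabola fallback
    if i == 0 or i == n - 1:
        return float(mz[i]), float(inten[i])
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(mz[i]), float(y1)
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    return float(mz[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    spectrum_id: str = "",
    snr_min: float = 5.0,
    rel_int_min: float = 0.0001,
    noise_window: int = 101,
) -> PeakList:
    """Centroid a profile spectrum.

    A local maximum is retained when (i) its baseline-subtracted height is
    at least ``snr_min`` times the local noise and (ii) its raw height is
    strictly greater than ``rel_int_min`` of the base peak.  The local
    baseline is the running median over ``noise_window`` grid points and the
    noise is 1.4826 × the running median absolute deviation over the same
    window.  Apex m/z and height are refined by parabolic interpolation
    of the log intensities around the maximum.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) != len(intensity):
        raise ValueError("mz and intensity must have equal length")
    if len(mz) > 1 and not np.all(np.diff(mz) > 0):
        raise ValueError("mz must be strictly increasing")
    empty = PeakList(
        spectrum_id=spectrum_id,
        peaks=pd.DataFrame(columns=["mz", "intensity", "snr"]),
        base_peak_intensity=0.0,
    )
    if len(mz) == 0 or not intensity.any():
        return empty

    base = float(intensity.max())
    # reflect padding: edge windows reuse interior values instead of
    # replicating the end point (which collapses the MAD at the borders)
    med = ndimage.median_filter(intensity, size=noise_window, mode="reflect")
    mad = ndimage.median_filter(np.abs(intensity - med), size=noise_window, mode="reflect")
    sigma = 1.4826 * mad

    cand, _ = signal.find_peaks(intensity)
    if len(cand) == 0:
        return empty
    height = intensity[cand] - med[cand]
    sig = sigma[cand]
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sig > 0, height / sig, np.where(height > 0, np.inf, 0.0))
    keep = (snr >= snr_min) & (intensity[cand] > rel_int_min * base)
    rows = []
    for i, s in zip(cand[keep], snr[keep]):
        apex_mz, apex_h = _refine_apex(mz, intensity, int(i))
        rows.append((apex_mz, apex_h, float(s)))
    df = pd.DataFrame(rows, columns=["mz", "intensity", "snr"]).sort_values("mz")
    return PeakList(
        spectrum_id=spectrum_id,
        peaks=df.reset_index(drop=True),
        base_peak_intensity=base,
    )


def calibrate(
    peaklist: PeakList,
    calibrants: pd.DataFrame,
    search_ppm: float = 50.0,
) -> tuple[CalibrationModel, PeakList]:
    """Internal calibration against known exact masses.

    Each calibrant is matched to the nearest picked peak within
    ``search_ppm``.  With ≥2 matches a linear model m_corr = a·m_obs + b is
    least-squares fitted; with one match a constant-ppm (multiplicative)
    correction is used.  With zero matches the spectrum is returned
    unchanged, flagged uncalibrated, with a warning recorded (the pipeline
    keeps such spectra, as for analyses run without internal calibrants).
    """
    cal = calibrants.reset_index(drop=True)
    obs = peaklist.mz
    matched_rows, unmatched = [], []
    for _, row in cal.iterrows():
        theo = float(row["mz"])
        if len(obs) == 0:
            unmatched.append(str(row["name"]))
            continue
        j = int(np.argmin(np.abs(obs - theo)))
        ppm = (obs[j] - theo) / theo * 1e6
        if abs(ppm) <= search_ppm:
            matched_rows.append(
                {"name": row["name"], "theoretical_mz": theo, "observed_mz": float(obs[j])}
            )
        else:
            unmatched.append(str(row["name"]))
    matched = pd.DataFrame(matched_rows, columns=["name", "theoretical_mz", "observed_mz"])

    if len(matched) == 0:
        msg = (
            f"spectrum {peaklist.spectrum_id!r}: no calibrant matched within "
            f"{search_ppm} ppm; calibration skipped"
        )
        warnings.warn(msg)
        model = CalibrationModel(
            calibrants=cal,
            matched=matched,
            a=1.0,
            b=0.0,
            residuals_ppm=np.empty(0),
            unmatched=unmatched,
        )
        out = PeakList(
            spectrum_id=peaklist.spectrum_id,
            peaks=peaklist.peaks.copy(),
            base_peak_intensity=peaklist.base_peak_intensity,
            calibrated=False,
            warnings=peaklist.warnings + [msg],
        )
        return model, out

    if len(matched) == 1:
        a = matched["theoretical_mz"].iloc[0] / matched["observed_mz"].iloc[0]
        b = 0.0
    else:
        x = matched["observed_mz"].to_numpy()
        y = matched["theoretical_mz"].to_numpy()
        design = np.column_stack([x, np.ones_like(x)])
        (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
        a, b = float(a), float(b)
    pred = a * matched["observed_mz"].to_numpy() + b
    residuals_ppm = (pred - matched["theoretical_mz"].to_numpy()) / matched[
        "theoretical_mz"
    ].to_numpy() * 1e6
    model = CalibrationModel(
        calibrants=cal,
        matched=matched,
        a=float(a),
        b=float(b),
        residuals_ppm=residuals_ppm,
        unmatched=unmatched,
    )
    corrected = peaklist.peaks.copy()
    corrected["mz"] = a * corrected["mz"].to_numpy() + b
    out = PeakList(
        spectrum_id=peaklist.spectrum_id,
        peaks=corrected,
        base_peak_intensity=peaklist.base_peak_intensity,
        calibrated=True,
        warnings=list(peaklist.warnings),
    )
    return model, out


@dataclass
class PeakMatrix:
    """Spectra × aligned-feature intensity matrix.

    ``values[i, j]`` is the intensity of feature j in spectrum i (0 when
    absent); ``feature_mz`` holds each feature's representative m/z (the
    intensity-weighted mean of its member peaks), ascending.
    """

    values: np.ndarray  # (n_spectra, n_features)
    spectrum_ids: list[str]
    feature_mz: np.ndarray
    mz_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.feature_mz) > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z must be ascending")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict(self, lo: float, hi: float) -> "PeakMatrix":
        """Keep features with representative m/z in [lo, hi]."""
        sel = (self.feature_mz >= lo) & (self.feature_mz <= hi)
        return PeakMatrix(
            values=self.values[:, sel],
            spectrum_ids=list(self.spectrum_ids),
            feature_mz=self.feature_mz[sel],
            mz_window=(lo, hi),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.spectrum_ids, name="spectrum_id"),
            columns=[f"{m:.6f}" for m in self.feature_mz],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            spectrum_ids=[str(i) for i in df.index],
            feature_mz=np.array([float(c) for c in df.columns]),
        )


def align_bins(
    peaklists: Sequence[PeakList],
    gap_ppm: float = 5.0,
    mz_window: tuple[float, float] | None = None,
) -> PeakMatrix:
    """Nonuniform-bin alignment of peak lists into a feature matrix.

    All peaks are pooled and sorted by m/z; a new bin starts wherever the
    gap between adjacent pooled peaks exceeds ``gap_ppm`` of the local m/z
    (single-linkage 1-D clustering, so bin widths adapt to the local peak
    density).  Each spectrum contributes at most one intensity per bin (the
    maximum, if it has several member peaks).  Features whose
    representative m/z falls outside ``mz_window`` (inclusive) are dropped.
    """
    ids = [pl.spectrum_id for pl in peaklists]
    all_mz, all_int, all_src = [], [], []
    for si, pl in enumerate(peaklists):
        all_mz.append(pl.mz)
        all_int.append(pl.intensity)
        all_src.append(np.full(len(pl), si, dtype=int))
    if not all_mz or sum(map(len, all_mz)) == 0:
        return PeakMatrix(
            values=np.zeros((len(ids), 0)),
            spectrum_ids=ids,
            feature_mz=np.empty(0),
            mz_window=mz_window,
        )
    pool_mz = np.concatenate(all_mz)
    pool_int = np.concatenate(all_int)
    pool_src = np.concatenate(all_src)
    order = np.argsort(pool_mz, kind="stable")
    pool_mz, pool_int, pool_src = pool_mz[order], pool_int[order], pool_src[order]

    gaps = np.diff(pool_mz)
    local = 0.5 * (pool_mz[:-1] + pool_mz[1:])
    new_bin = gaps > gap_ppm * 1e-6 * local
    bin_id = np.concatenate([[0], np.cumsum(new_bin)])
    n_bins = int(bin_id[-1]) + 1

    rep = np.zeros(n_bins)
    for b in range(n_bins):
        sel = bin_id == b
        w = pool_int[sel]
        rep[b] = np.average(pool_mz[sel], weights=w) if w.sum() > 0 else pool_mz[sel].mean()

    values = np.zeros((len(ids), n_bins))
    np.maximum.at(values, (pool_src, bin_id), pool_int)

    if mz_window is not None:
        lo, hi = mz_window
        sel = (rep >= lo) & (rep <= hi)
        rep, values = rep[sel], values[:, sel]
    order = np.argsort(rep)
    return PeakMatrix(
        values=values[:, order],
        spectrum_ids=ids,
        feature_mz=rep[order],
        mz_window=mz_window,
    )
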