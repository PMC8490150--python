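"""Synthetic microscopy images and single-vesicle mass spectra.

The generator emulates the data the pipeline consumes: dark (or bright)
blob-like vesicles scattered on a noisy brightfield background, and
high-resolution single-organelle spectra built from isotope-free Gaussian
peaks with per-spectrum uniform ppm calibration drift, log-normal intensity
jitter and additive baseline noise.  Ground truth (blob centroids and radii,
per-spectrum peak lists, planted class and cluster labels) is returned with
every fixture so downstream modules can be scored against it.

All randomness flows through ``FixtureConfig.seed``; an identical config
yields byte-identical fixtures.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FixtureConfig",
    "ImageFixture",
    "SpectrumFixture",
    "PlacementError",
    "make_image",
    "make_spectra",
    "write_image",
    "write_spectrum_txt",
    "read_spectrum_txt",
    "write_mzml",
    "write_image_truth",
    "write_spectra_truth",
    "DEFAULT_PEAK_SETS",
    "DEFAULT_CLUSTER_PEAKS",
]


class PlacementError(RuntimeError):
    """Raised when the requested blob count cannot be placed at the
    configured minimum spacing."""


# Default planted chemistry.  Peak positions are synthetic stand-ins chosen
# inside the peptide/lipid m/z region the pipeline analyses; the two tallest
# peptide-like peaks double as internal calibrants in calibration tests.
DEFAULT_PEAK_SETS: dict[str, tuple[tuple[float, float], ...]] = {
    "DCV": (
        (760.5851, 400.0),
        (782.5670, 300.0),
        (806.5672, 250.0),
        (1221.6878, 800.0),
        (1396.7225, 700.0),
    ),
    "LV": (
        (512.5032, 350.0),
        (630.4941, 400.0),
        (725.5563, 350.0),
        (852.7702, 300.0),
        (970.8021, 300.0),
        (1080.8533, 250.0),
    ),
}

# Three planted vesicle subpopulations that share the class backbone above but
# differ in five marker peaks each (mirrors distinct prohormone-processing
# signatures within one morphological vesicle type).
DEFAULT_CLUSTER_PEAKS: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    "DCV": {
        "c1": (
            (520.3402, 300.0),
            (610.1855, 350.0),
            (703.5748, 300.0),
            (915.4633, 250.0),
            (1120.5521, 300.0),
        ),
        "c2": (
            (545.3527, 300.0),
            (655.4712, 350.0),
            (745.5021, 300.0),
            (960.5148, 250.0),
            (1175.6033, 300.0),
        ),
        "c3": (
            (575.3719, 300.0),
            (680.4803, 350.0),
            (820.5411, 300.0),
            (1005.5322, 250.0),
            (1251.6620, 300.0),
        ),
    },
}


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic slide and its spectra.

    Image side: ``n_objects`` radially symmetric Gaussian blobs of radius
    drawn from ``radius_range`` (px) are placed on a background of mean
    ``background_mean`` with additive Gaussian noise ``noise_sd``; blob depth
    is ``vesicle_contrast`` times the background.  Placement enforces
    ``min_separation_um`` between centers (a laser-spacing-equivalent guard
    against overlapping blobs).

    Spectrum side: each spectrum is the sum of Gaussian peaks (sigma
    ``peak_sigma_mz`` Da) on the grid ``mz_window`` at ``mz_step`` Da.  Peak
    heights are log-normally jittered with coefficient of variation
    ``intensity_cv`` (mean-preserving), all peak positions of one spectrum
    share a uniform ppm drift drawn from ``drift_ppm_range``, and Gaussian
    baseline noise of sd ``spectrum_noise_sd`` is added.
    """

    # image
    n_objects: int = 50
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0  # µm per pixel
    vesicle_contrast: float = 0.5  # blob depth as fraction of background
    background_mean: float = 100.0
    noise_sd: float = 1.0  # image noise, intensity units (1% of background)
    radius_range: tuple[float, float] = (2.0, 4.0)  # px
    min_separation_um: float = 30.0
    polarity: str = "dark"  # dark-on-bright brightfield default
    # spectra
    n_spectra_per_class: int = 50
    peak_set_per_class: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_SETS)
    )
    cluster_peaks: Mapping[str, Mapping[str, Sequence[tuple[float, float]]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLUSTER_PEAKS.items()}
    )
    mz_window: tuple[float, float] = (450.0, 1450.0)
    mz_step: float = 0.01  # Da
    peak_sigma_mz: float = 0.04  # Da
    intensity_cv: float = 0.3
    drift_ppm_range: tuple[float, float] = (-5.0, 5.0)
    spectrum_noise_sd: float = 0.1
    spectrum_baseline_mean: float = 1.0  # keeps noisy baselines positive
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.vesicle_contrast < 1.0):
            raise ValueError("vesicle_contrast must lie in (0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def with_(self, **kwargs) -> "FixtureConfig":
        return replace(self, **kwargs)


@dataclass
class ImageFixture:
    """A rendered slide image plus its ground truth."""

    pixels: np.ndarray  # 2-D float32, nonnegative
    pixel_size: float  # µm per pixel
    truth_centroids: np.ndarray  # (n, 2) float (row, col) px
    truth_radii: np.ndarray  # (n,) px

    def __post_init__(self) -> None:
        nrow, ncol = self.pixels.shape
        if len(self.truth_centroids) and (
            self.truth_centroids[:, 0].max() >= nrow
            or self.truth_centroids[:, 1].max() >= ncol
            or self.truth_centroids.min() < 0
        ):
            raise ValueError("truth centroids must lie inside the image")


@dataclass
class SpectrumFixture:
    """One synthetic single-vesicle spectrum plus its ground truth."""

    spectrum_id: str
    mz: np.ndarray  # ascending
    intensity: np.ndarray  # nonnegative baseline noise is clipped at 0
    truth_peaks: list[tuple[float, float]]  # (true m/z, realized height)
    drift_ppm: float
    class_label: str
    cluster_label: str


# ---------------------------------------------------------------------------
# image generation


def _place_centers(
    rng: np.random.Generator, config: FixtureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement with a hard minimum spacing and edge margin."""
    nrow, ncol = config.image_shape
    min_sep_px = config.min_separation_um / config.pixel_size
    rmin, rmax = config.radius_range
    margin = 3.0 * rmax + 1.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = max(2000, 2000 * config.n_objects)
    tries = 0
    while len(centers) < config.n_objects:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {config.n_objects} objects at "
                f"{config.min_separation_um} µm spacing in a "
                f"{nrow}x{ncol} px image ({len(centers)} placed)"
            )
        r = rng.uniform(margin, nrow - margin)
        c = rng.uniform(margin, ncol - margin)
        if centers:
            d = np.hypot(
                np.array([p[0] for p in centers]) - r,
                np.array([p[1] for p in centers]) - c,
            )
            if d.min() < min_sep_px:
                continue
        centers.append((r, c))
        radii.append(rng.uniform(rmin, rmax))
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


def make_image(config: FixtureConfig) -> ImageFixture:
    """Render ``config.n_objects`` Gaussian blobs on a noisy background.

    Blobs are radially symmetric with sigma = radius / 2, dark on bright by
    default (``config.polarity='bright'`` inverts them, for digitally
    inverted images).  Identical configs give bit-identical pixels.
    """
    rng = np.random.default_rng(config.seed)
    nrow, ncol = config.image_shape
    if config.n_objects > 0:
        centers, radii = _place_centers(rng, config)
    else:
        centers = np.empty((0, 2), dtype=float)
        radii = np.empty((0,), dtype=float)

    img = np.full((nrow, ncol), config.background_mean, dtype=np.float64)
    depth = config.vesicle_contrast * config.background_mean
    sign = -1.0 if config.polarity == "dark" else 1.0
    for (r0, c0), rad in zip(centers, radii):
        sigma = rad / 2.0
        ext = int(np.ceil(4 * sigma)) + 1
        r_lo, r_hi = int(np.floor(r0)) - ext, int(np.floor(r0)) + ext + 1
        c_lo, c_hi = int(np.floor(c0)) - ext, int(np.floor(c0)) + ext + 1
        rr = np.arange(max(r_lo, 0), min(r_hi, nrow))
        cc = np.arange(max(c_lo, 0), min(c_hi, ncol))
        d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
        img[np.ix_(rr, cc)] += sign * depth * np.exp(-d2 / (2.0 * sigma**2))

    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return ImageFixture(
        pixels=img.astype(np.float32),
        pixel_size=config.pixel_size,
        truth_centroids=centers,
        truth_radii=radii,
    )


# ---------------------------------------------------------------------------
# spectrum generation


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative jitter with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def make_spectra(config: FixtureConfig) -> list[SpectrumFixture]:
    """Generate ``n_spectra_per_class`` spectra for every configured class.

    Within a class, spectra are assigned round-robin to that class's planted
    subpopulations (clusters); a spectrum carries its class backbone peaks
    plus its cluster's marker peaks.  Raises ``ValueError`` if any configured
    peak m/z falls outside ``mz_window``.
    """
    if not config.peak_set_per_class:
        raise ValueError("peak_set_per_class must be nonempty")
    lo, hi = config.mz_window
    if not np.isfinite(config.drift_ppm_range).all():
        raise ValueError("drift_ppm_range must be finite")
    for cls, peaks in config.peak_set_per_class.items():
        if len(peaks) == 0:
            raise ValueError(f"class {cls!r} has an empty peak set")
        for mz0, _ in list(peaks) + [
            p for cl in config.cluster_peaks.get(cls, {}).values() for p in cl
        ]:
            if not (lo < mz0 < hi):
                raise ValueError(
                    f"peak m/z {mz0} of class {cls!r} lies outside the "
                    f"configured window ({lo}, {hi})"
                )

    rng = np.random.default_rng(config.seed + 1)
    grid = np.arange(lo, hi + 0.5 * config.mz_step, config.mz_step)
    out: list[SpectrumFixture] = []
    dlo, dhi = config.drift_ppm_range
    for cls in config.peak_set_per_class:
        clusters = list(config.cluster_peaks.get(cls, {}).keys()) or [cls]
        for i in range(config.n_spectra_per_class):
            cluster = clusters[i % len(clusters)]
            peaks = list(config.peak_set_per_class[cls])
            if cluster != cls:
                peaks += list(config.cluster_peaks[cls][cluster])
            true_mz = np.array([p[0] for p in peaks])
            base_h = np.array([p[1] for p in peaks])
            heights = base_h * _lognormal_factor(rng, config.intensity_cv, len(peaks))
            drift = rng.uniform(dlo, dhi)
            obs_mz = true_mz * (1.0 + drift * 1e-6)
            inten = np.full_like(grid, config.spectrum_baseline_mean)
            s = config.peak_sigma_mz
            for m, h in zip(obs_mz, heights):
                j0 = np.searchsorted(grid, m - 6 * s)
                j1 = np.searchsorted(grid, m + 6 * s)
                seg = grid[j0:j1]
                inten[j0:j1] += h * np.exp(-((seg - m) ** 2) / (2 * s**2))
            if config.spectrum_noise_sd > 0:
                inten += rng.normal(0.0, config.spectrum_noise_sd, size=grid.shape)
                np.clip(inten, 0.0, None, out=inten)
            out.append(
                SpectrumFixture(
                    spectrum_id=f"{cls}_{i:04d}",
                    mz=grid.copy(),
                    intensity=inten,
                    truth_peaks=list(zip(true_mz.tolist(), heights.tolist())),
                    drift_ppm=float(drift),
                    class_label=cls,
                    cluster_label=cluster,
                )
            )
    return out


# ---------------------------------------------------------------------------
# writers


def write_image(fix: ImageFixture, path: str | Path) -> None:
    tifffile.imwrite(str(path), fix.pixels)


def write_image_truth(fix: ImageFixture, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(len(fix.truth_radii)),
            "row_px": fix.truth_centroids[:, 0] if len(fix.truth_radii) else [],
            "col_px": fix.truth_centroids[:, 1] if len(fix.truth_radii) else [],
            "radius_px": fix.truth_radii,
        }
    )
    df.to_csv(path, index=False)


def write_spectrum_txt(spec: SpectrumFixture, path: str | Path) -> None:
    """Two-column whitespace-delimited (m/z, intensity) text."""
    np.savetxt(path, np.column_stack([spec.mz, spec.intensity]), fmt="%.6f %.6f")


def read_spectrum_txt(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, ndmin=2)
    return arr[:, 0], arr[:, 1]


def write_spectra_truth(specs: Sequence[SpectrumFixture], path: str | Path) -> None:
    rows = []
    for s in specs:
        for mz0, h in s.truth_peaks:
            rows.append(
                {
                    "spectrum_id": s.spectrum_id,
                    "true_mz": mz0,
                    "true_height": h,
                    "class": s.class_label,
                    "cluster": s.cluster_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _b64_f64(values: np.ndarray, compress: bool) -> tuple[str, int]:
    raw = struct.pack(f"<{len(values)}d", *values.astype(np.float64))
    if compress:
        raw = zlib.compress(raw)
    enc = base64.b64encode(raw).decode("ascii")
    return enc, len(enc)


def write_mzml(
    specs: Sequence[SpectrumFixture], path: str | Path, compress: bool = True
) -> None:
    """Write spectra as a minimal mzML 1.1.0 document.

    Arrays are 64-bit little-endian, zlib-compressed by default, base64
    encoded; spectra are MS1 profile scans.  The output is readable by
    pyteomics.mzml.
    """
    from lxml import etree

    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(
        f"{{{NS}}}mzML", nsmap={None: NS}, version="1.1.0", id="organellems-fixture"
    )
    cvlist = etree.SubElement(root, f"{{{NS}}}cvList", count="1")
    etree.SubElement(
        cvlist,
        f"{{{NS}}}cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, f"{{{NS}}}run", id="run1")
    slist = etree.SubElement(
        run, f"{{{NS}}}spectrumList", count=str(len(specs)), defaultDataProcessingRef="dp1"
    )

    def cv(parent, accession, name, value=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name}
        if value is not None:
            attrs["value"] = str(value)
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    comp_acc = ("MS:1000574", "zlib compression") if compress else (
        "MS:1000576",
        "no compression",
    )
    for idx, s in enumerate(specs):
        sp = etree.SubElement(
            slist,
            f"{{{NS}}}spectrum",
            index=str(idx),
            id=f"scan={idx} id={s.spectrum_id}",
            defaultArrayLength=str(len(s.mz)),
        )
        cv(sp, "MS:1000579", "MS1 spectrum")
        cv(sp, "MS:1000511", "ms level", 1)
        cv(sp, "MS:1000128", "profile spectrum")
        bal = etree.SubElement(sp, f"{{{NS}}}binaryDataArrayList", count="2")
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            enc, n = _b64_f64(np.asarray(arr), compress)
            bda = etree.SubElement(
                bal, f"{{{NS}}}binaryDataArray", encodedLength=str(n)
            )
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, comp_acc[0], comp_acc[1])
            cv(bda, acc, name)
            b = etree.SubElement(bda, f"{{{NS}}}binary")
            b.text = enc
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
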