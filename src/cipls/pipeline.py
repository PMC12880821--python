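"""Analysis stages: tissue segmentation, ROI statistics, two-wavelength
``DeltaDOCP`` differencing, and depth-trend tables.

The imaging experiment produces, per sample and per wavelength (617 and
850 nm), a DOCP map and a pseudo-intensity image.  The tissue region is
bright against the surrounding agarose gel, so segmentation is an automatic
bimodal threshold on pseudo-intensity plus morphological cleanup (the
delineation method is explicit config; a manually drawn mask can be
imported instead).  ROI statistics are the arithmetic mean and population SD
of DOCP over the mask.  The two-wavelength difference

    DeltaDOCP = DOCP(617 nm) - DOCP(850 nm)

cancels wavelength-independent surface contributions (reflection,
roughness); its trend against the top healthy-layer thickness T1 is the
depth signal, while the cancer-layer thickness T2 contributes an order of
magnitude less (the sensitivity ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _gray_closing, disk

__all__ = [
    "SegmentationError",
    "TissueMask",
    "ROISummary",
    "TrendTable",
    "segment_tissue",
    "load_mask",
    "roi_stats",
    "delta_docp",
    "build_trend",
    "sensitivity_ratio",
    "monotone_direction",
]


class SegmentationError(RuntimeError):
    """Tissue segmentation could not produce a usable mask."""


@dataclass(frozen=True)
class TissueMask:
    """Boolean tissue raster at channel resolution, with provenance."""

    mask: np.ndarray
    method: str = "otsu"
    threshold: Optional[float] = None
    closing_radius: int = 2

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {m.shape}")
        if not m.any():
            raise SegmentationError("tissue mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROISummary:
    """Mean +/- SD of DOCP over the tissue ROI for one sample and wavelength.

    ``sd`` is the population standard deviation (divide by n); the error
    bars are descriptive scatter within the ROI, not a standard error.
    """

    sample_id: str
    wavelength_nm: float
    t1_mm: float
    t2_mm: float
    mean_docp: float
    sd_docp: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd_docp < 0:
            raise ValueError("SD must be non-negative")
        if self.n_pixels <= 0:
            raise ValueError("pixel count must be positive")


@dataclass(frozen=True)
class TrendTable:
    """Per-sample mean DOCP at both wavelengths plus the DeltaDOCP column,
    sorted by the swept thickness (T1 at fixed T2, or T2 at fixed T1)."""

    sweep: str  # "T1" or "T2"
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.sweep not in ("T1", "T2"):
            raise ValueError(f"sweep must be 'T1' or 'T2', got {self.sweep!r}")
        col = self.swept_column
        vals = self.table[col].to_numpy()
        if not (np.diff(vals) > 0).all():
            raise ValueError(f"{col} must be strictly increasing across rows")

    @property
    def swept_column(self) -> str:
        return "t1_mm" if self.sweep == "T1" else "t2_mm"

    @property
    def swept_values(self) -> np.ndarray:
        return self.table[self.swept_column].to_numpy()

    @property
    def delta_docp_means(self) -> np.ndarray:
        return self.table["delta_docp"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")


def segment_tissue(
    pseudo_s0: np.ndarray,
    closing_radius: int = 2,
    threshold: Optional[float] = None,
) -> TissueMask:
    """Segment the bright tissue region from the dark agarose background.

    Default method: automatic bimodal (Otsu) threshold on the
    pseudo-intensity image, morphological closing with a disk of
    ``closing_radius`` pixels, keep the largest connected component, fill
    holes.  Pass ``threshold`` to override the automatic split.

    Raises :class:`SegmentationError` on a constant image or when the mask
    comes out empty.
    """
    img = np.asarray(pseudo_s0, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    finite = np.isfinite(img)
    if not finite.any() or np.nanmax(img) == np.nanmin(img):
        raise SegmentationError("constant (or empty) image cannot be segmented")
    thr = float(threshold_otsu(img[finite])) if threshold is None else float(threshold)
    mask = img > thr
    if closing_radius > 0:
        mask = _gray_closing(mask, disk(closing_radius)).astype(bool)
    labels, n = ndi.label(mask)
    if n == 0:
        raise SegmentationError("no foreground component after thresholding")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    return TissueMask(mask=mask, method="otsu" if threshold is None else "manual",
                      threshold=thr, closing_radius=closing_radius)


def load_mask(path) -> TissueMask:
    """Import a manually drawn tissue mask from a raster file (PNG/TIFF).

    Nonzero pixels are tissue.  Mirrors the hand-drawn ROI workflow; the
    provenance records the source file.
    """
    from pathlib import Path

    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raster = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        raster = iio.imread(p)
    raster = np.asarray(raster)
    if raster.ndim == 3:  # collapse color/alpha channels
        raster = raster[..., :3].max(axis=-1)
    return TissueMask(mask=raster > 0, method=f"manual-import:{p.name}",
                      threshold=None, closing_radius=0)


def roi_stats(docp_map: np.ndarray, mask, valid: Optional[np.ndarray] = None):
    """Arithmetic mean and population SD of a DOCP map over a tissue mask.

    Pixels flagged invalid by the DOCP estimator (NaN, or ``valid`` False)
    are excluded.  Returns ``(mean, sd, n)``; raises if no valid pixel
    remains.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    d = np.asarray(docp_map, dtype=float)
    if d.shape != m.shape:
        raise ValueError(f"map shape {d.shape} != mask shape {m.shape}")
    sel = m & np.isfinite(d)
    if valid is not None:
        sel &= np.asarray(valid, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no valid pixels under the mask")
    vals = d[sel]
    return float(vals.mean()), float(vals.std(ddof=0)), n


def _xcorr_shift(a: np.ndarray, b: np.ndarray) -> tuple:
    """Integer-pixel translation of ``b`` relative to ``a`` by FFT
    cross-correlation of the finite-valued parts."""
    a0 = np.nan_to_num(a - np.nanmean(a))
    b0 = np.nan_to_num(b - np.nanmean(b))
    corr = np.fft.irfft2(np.fft.rfft2(a0) * np.conj(np.fft.rfft2(b0)), s=a0.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for p, size in zip(peak, a0.shape):
        shift.append(p - size if p > size // 2 else p)
    return tuple(int(s) for s in shift)


def delta_docp(
    map_617: np.ndarray,
    map_850: np.ndarray,
    registration: str = "none",
):
    """Pixelwise ``DeltaDOCP = DOCP(617 nm) - DOCP(850 nm)``.

    The scene is static under sequential acquisition, so the default is no
    registration; ``registration="xcorr"`` first aligns the 850 nm map to
    the 617 nm map by integer-pixel cross-correlation.  Output is NaN
    wherever either input is invalid.  Returns ``(delta_map, shift)``.
    """
    a = np.asarray(map_617, dtype=float)
    b = np.asarray(map_850, dtype=float)
    if registration not in ("none", "xcorr"):
        raise ValueError(f"unknown registration mode {registration!r}")
    if a.shape != b.shape:
        raise ValueError(
            f"map shapes differ ({a.shape} vs {b.shape}) and no resampling "
            "registration is implemented"
        )
    shift = (0, 0)
    if registration == "xcorr":
        shift = _xcorr_shift(a, b)
        b = np.roll(b, shift, axis=(0, 1))
    return a - b, shift


def build_trend(summaries: Sequence[ROISummary], sweep: str) -> TrendTable:
    """Assemble per-wavelength ROI summaries into a depth-trend table.

    ``summaries`` must contain, for each sample, one row per wavelength
    (617 and 850 nm) sharing the fixed thickness; the swept thickness must
    be unique across samples.  The DeltaDOCP column is the difference of the
    per-wavelength ROI means (mean(617) - mean(850)); rows are sorted by the
    swept thickness.
    """
    if sweep not in ("T1", "T2"):
        raise ValueError(f"sweep must be 'T1' or 'T2', got {sweep!r}")
    if not summaries:
        raise ValueError("no summaries given")
    rows = {}
    for s in summaries:
        rows.setdefault(s.sample_id, {})[round(s.wavelength_nm)] = s
    records = []
    for sid, by_wl in sorted(rows.items()):
        if set(by_wl) != {617, 850}:
            raise ValueError(
                f"sample {sid!r} needs both wavelengths, has {sorted(by_wl)}"
            )
        a, b = by_wl[617], by_wl[850]
        if (a.t1_mm, a.t2_mm) != (b.t1_mm, b.t2_mm):
            raise ValueError(f"sample {sid!r} thickness metadata disagrees")
        records.append(
            {
                "sample_id": sid,
                "t1_mm": a.t1_mm,
                "t2_mm": a.t2_mm,
                "mean_docp_617": a.mean_docp,
                "sd_docp_617": a.sd_docp,
                "n_617": a.n_pixels,
                "mean_docp_850": b.mean_docp,
                "sd_docp_850": b.sd_docp,
                "n_850": b.n_pixels,
                "delta_docp": a.mean_docp - b.mean_docp,
            }
        )
    df = pd.DataFrame.from_records(records)
    swept = "t1_mm" if sweep == "T1" else "t2_mm"
    fixed = "t2_mm" if sweep == "T1" else "t1_mm"
    if df[fixed].nunique() != 1:
        raise ValueError(f"{fixed} must be fixed across a {sweep} sweep")
    if df[swept].duplicated().any():
        raise ValueError(f"duplicate {swept} values in {sweep} sweep")
    df = df.sort_values(swept, kind="mergesort").reset_index(drop=True)
    return TrendTable(sweep=sweep, table=df)


def sensitivity_ratio(t1_table: TrendTable, t2_table: TrendTable) -> float:
    """Ratio of DeltaDOCP variation ranges: range over the T2 sweep divided
    by range over the T1 sweep (range = max - min of the mean-DeltaDOCP
    column).  Small values mean the depth of the cancer layer (T1) moves the
    signal far more than its volume (T2)."""
    for t in (t1_table, t2_table):
        if len(t.table) < 2:
            raise ValueError("each trend table needs at least 2 rows")
    r1 = float(np.ptp(t1_table.delta_docp_means))
    r2 = float(np.ptp(t2_table.delta_docp_means))
    if r1 == 0:
        raise ZeroDivisionError("T1 sweep has zero DeltaDOCP range")
    return r2 / r1


def monotone_direction(values: Sequence[float]) -> int:
    """Strict sign test over successive differences of a sorted-trend column:
    +1 if strictly increasing, -1 if strictly decreasing, 0 otherwise."""
    d = np.diff(np.asarray(values, dtype=float))
    if len(d) == 0:
        return 0
    if (d > 0).all():
        return 1
    if (d < 0).all():
        return -1
    return 0
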