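"""Image qualification, cell segmentation and per-image peak statistics.

Clinical FLIM acquisitions of exfoliated cells are unusable when bright
non-cellular debris dominates the field or neutrophils blanket the cells;
such images are filtered out before analysis.  Qualified images are
segmented with an Otsu-threshold pipeline (dilate, drop small components,
fill holes) and summarised by the modal values of their masked tm and a2
distributions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .containers import LifetimeMaps

__all__ = ["QCConfig", "CellMask", "ImageSummary", "SegmentationError",
           "otsu_segment", "refine_mask", "smooth_maps", "qc_qualify",
           "peak_statistics"]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)
_SPECKLE_MAX_AREA = 25          # px; components this small count as clutter
_SPECKLE_INTENSITY_FACTOR = 2.0  # times the masked median intensity


class SegmentationError(ValueError):
    """No meaningful threshold / no pixels to summarise."""


@dataclass(frozen=True)
class QCConfig:
    """Operational cutoffs for image qualification.

    The underlying rules are qualitative (debris brighter than cells,
    neutrophil clutter, too little cell area); these numeric defaults are
    package choices, all overridable.
    """

    max_noncell_intensity_ratio: float = 1.5
    max_clutter_coverage: float = 0.3
    min_cell_pixels: int = 500

    def __post_init__(self) -> None:
        if self.max_noncell_intensity_ratio <= 0:
            raise ValueError("max_noncell_intensity_ratio must be positive")
        if not 0.0 <= self.max_clutter_coverage <= 1.0:
            raise ValueError("max_clutter_coverage must lie in [0, 1]")


@dataclass
class CellMask:
    """Binary cell-region mask with 8-connected component labels."""

    mask: np.ndarray
    components: np.ndarray       # int labels, 0 = background
    areas: dict                  # label -> pixel count

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.components.shape:
            raise ValueError("mask and components must share a shape")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def n_components(self) -> int:
        return len(self.areas)


@dataclass
class ImageSummary:
    peak_tm_ps: float
    peak_a2_pct: float
    n_valid_pixels: int


def otsu_segment(intensity: np.ndarray) -> np.ndarray:
    """Foreground pixels above the Otsu threshold (256-bin histogram)."""
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.min() == intensity.max():
        raise SegmentationError("constant image: no threshold separates it")
    # float input pins the threshold search to a 256-bin histogram
    # (integer input would make skimage bin per integer value)
    thr = threshold_otsu(intensity, nbins=256)
    return intensity > thr


def refine_mask(binary: np.ndarray, min_area_px: int = 100,
                dilate_radius_px: int = 1) -> CellMask:
    """Dilate, drop small components, fill holes — in that fixed order."""
    binary = np.asarray(binary, dtype=bool)
    if dilate_radius_px > 0:
        binary = ndimage.binary_dilation(binary,
                                         structure=disk(dilate_radius_px))
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n:
        areas = ndimage.sum_labels(np.ones_like(binary, dtype=np.int64),
                                   labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area_px) + 1
        binary = np.isin(labels, keep)
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    areas = {}
    if n:
        counts = ndimage.sum_labels(np.ones_like(binary, dtype=np.int64),
                                    labels, index=np.arange(1, n + 1))
        areas = {int(i + 1): int(c) for i, c in enumerate(counts)}
    return CellMask(mask=binary, components=labels, areas=areas)


def _masked_median3(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """3x3 median restricted to mask pixels; off-mask neighbors excluded.

    Off-mask window entries sort to +inf; the median of the n in-mask
    entries is read off the sorted window directly.
    """
    ny, nx = values.shape
    padded = np.full((ny + 2, nx + 2), np.inf)
    padded[1:-1, 1:-1] = np.where(mask, values, np.inf)
    windows = np.stack([padded[1 + dy:1 + dy + ny, 1 + dx:1 + dx + nx]
                        for dy in (-1, 0, 1) for dx in (-1, 0, 1)])
    windows.sort(axis=0)
    n = np.isfinite(windows).sum(axis=0)
    nn = np.maximum(n, 1)
    rows, cols = np.indices((ny, nx))
    lo = windows[(nn - 1) // 2, rows, cols]
    hi = windows[nn // 2, rows, cols]
    out = values.copy()
    inside = mask & (n > 0)
    out[inside] = 0.5 * (lo + hi)[inside]
    return out


def smooth_maps(maps: LifetimeMaps, mask: CellMask) -> LifetimeMaps:
    """3x3 median smoothing of tm and a2 inside the mask; intensity untouched."""
    if maps.shape != mask.mask.shape:
        raise ValueError("maps and mask dimensions disagree")
    m = mask.mask & maps.valid
    return LifetimeMaps(
        tm_ps=_masked_median3(maps.tm_ps, m),
        a2_frac=_masked_median3(maps.a2_frac, m),
        t2_ps=maps.t2_ps.copy(),
        intensity=maps.intensity.copy(),
        valid=maps.valid.copy(),
        t1_ps=maps.t1_ps,
        meta={**maps.meta, "smoothed": "median3"},
    )


def qc_qualify(maps: LifetimeMaps, mask: CellMask,
               config: QCConfig | None = None) -> tuple[bool, list]:
    """Apply the data-filtering rules; returns (qualified, failed reasons)."""
    config = QCConfig() if config is None else config
    if maps.shape != mask.mask.shape:
        raise ValueError("maps and mask dimensions disagree")
    reasons: list[str] = []
    m = mask.mask
    intensity = maps.intensity

    if mask.area < config.min_cell_pixels:
        reasons.append(
            f"cell area {mask.area} px below minimum {config.min_cell_pixels}")

    if m.any() and (~m).any():
        on = float(np.percentile(intensity[m], 99))
        off = float(np.percentile(intensity[~m], 99))
        if on > 0 and off / on > config.max_noncell_intensity_ratio:
            reasons.append(
                "non-cell intensity ratio "
                f"{off / on:.2f} exceeds {config.max_noncell_intensity_ratio}")

    if mask.area > 0:
        med = float(np.median(intensity[m]))
        bright = m & (intensity > _SPECKLE_INTENSITY_FACTOR * max(med, 1e-12))
        labels, n = ndimage.label(bright, structure=_EIGHT_CONN)
        if n:
            areas = ndimage.sum_labels(np.ones_like(bright, dtype=np.int64),
                                       labels, index=np.arange(1, n + 1))
            speckle_px = int(areas[areas < _SPECKLE_MAX_AREA].sum())
            coverage = speckle_px / mask.area
            if coverage > config.max_clutter_coverage:
                reasons.append(
                    f"speckle clutter covers {coverage:.2f} of the mask "
                    f"(limit {config.max_clutter_coverage})")
    return (len(reasons) == 0, reasons)


def peak_statistics(maps: LifetimeMaps, mask: CellMask,
                    tm_bin_ps: float = 20.0,
                    a2_bin_pct: float = 1.0) -> ImageSummary:
    """Modal bin centers of the masked tm and a2 distributions.

    Histograms are anchored at zero with the given bin widths; ties go to
    the lower bin.
    """
    sel = mask.mask & maps.valid
    n = int(sel.sum())
    if n == 0:
        raise SegmentationError("no valid masked pixels to summarise")
    peak_tm = _histogram_mode(maps.tm_ps[sel], tm_bin_ps)
    peak_a2 = _histogram_mode(maps.a2_frac[sel] * 100.0, a2_bin_pct)
    return ImageSummary(peak_tm_ps=peak_tm, peak_a2_pct=peak_a2,
                        n_valid_pixels=n)


def _histogram_mode(values: np.ndarray, bin_width: float) -> float:
    idx = np.floor(values / bin_width).astype(np.int64)
    bins, counts = np.unique(idx, return_counts=True)
    best = bins[np.argmax(counts)]          # first max = lowest bin on ties
    return float((best + 0.5) * bin_width)
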