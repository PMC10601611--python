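"""Scalar per-cell intensity statistics.

Four readouts, each computed inside a segmented cell mask:

* mean cellular fluorescence;
* *patchiness* — the standard deviation of in-cell pixel intensities divided
  by the *total* (summed) cell fluorescence. Punctate signal concentrates
  variance, so patchiness rises with induction of a low-abundance transcript
  even when the total signal is swamped by diffuse autofluorescence. Note it
  is a normalized SD, not a coefficient of variation, so it carries a
  1/area scale and is only comparable across cells of similar size imaged
  with identical settings;
* plasma-membrane *band* signal — the fluorescence in a 0.2 µm-wide band
  drawn immediately outside the thylakoid region (the ImageJ Make Band
  analogue), as a mean and as a fraction of the whole-cell-plus-band total;
* polar:equatorial ratio — mean intensity in the two polar caps over the
  mean in the remaining mid-cell region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image import CellImage
from .segmentation import CellRecord

log = logging.getLogger(__name__)

__all__ = [
    "CellStats",
    "RegionError",
    "mean_cell_intensity",
    "patchiness",
    "thylakoid_region",
    "membrane_band",
    "polar_equatorial_ratio",
    "cell_stats",
    "stats_to_dataframe",
]


class RegionError(ValueError):
    """Raised when a measurement region is degenerate (empty band/caps)."""


@dataclass
class CellStats:
    cell_label: int
    channel: str
    mean_intensity: float
    patchiness: float
    band_mean: float
    band_fraction: float
    polar_equatorial_ratio: float
    area_px: int


def mean_cell_intensity(image: CellImage, cell: CellRecord, channel: str) -> float:
    """Arithmetic mean of in-mask intensities."""
    return float(image.channel(channel)[cell.mask].mean())


def patchiness(image: CellImage, cell: CellRecord, channel: str) -> float:
    """Normalized SD: sample SD of in-mask pixels / summed in-mask intensity.

    Zero for a uniform cell; grows as a fixed total signal concentrates into
    fewer, brighter foci. Errors on zero total fluorescence.
    """
    vals = image.channel(channel)[cell.mask]
    total = float(vals.sum())
    if total <= 0:
        raise ValueError(f"cell {cell.label}: zero total fluorescence in {channel!r}")
    return float(vals.std(ddof=1)) / total


def thylakoid_region(
    image: CellImage, cell: CellRecord, channel: str = "thylakoid"
) -> np.ndarray:
    """Threshold the pigment channel inside the cell to select the shell."""
    arr = image.channel(channel)
    vals = arr[cell.mask]
    if np.ptp(vals) == 0:
        raise RegionError(f"cell {cell.label}: constant pigment channel")
    thr = threshold_otsu(vals)
    return cell.mask & (arr > thr)


def membrane_band(
    image: CellImage,
    cell: CellRecord,
    thylakoid_mask: np.ndarray,
    channel: str,
    band_width_um: float = 0.2,
) -> tuple[float, float]:
    """Quantify fluorescence in a band drawn around the thylakoid region.

    The band is every pixel within ``band_width_um`` (Euclidean distance,
    rounded half-up at the µm→px conversion) *outward* of the thylakoid
    region — the plasma-membrane zone. The region is hole-filled first so the
    band never extends inward into the central cytoplasm, whose signal would
    otherwise contaminate a plasma-membrane estimate. Returns
    ``(band_mean, band_fraction)`` where the fraction is the band sum over
    the whole-cell-plus-band sum.

    Raises
    ------
    RegionError
        If the thylakoid mask or the resulting band is empty (e.g. the
        region touches the image border).
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be positive")
    if not thylakoid_mask.any():
        raise RegionError(f"cell {cell.label}: empty thylakoid region")
    band_px = math.floor(band_width_um * 1000 / image.pixel_size_nm + 0.5)
    filled = ndi.binary_fill_holes(thylakoid_mask)
    dist = ndi.distance_transform_edt(~filled)
    band = (dist > 0) & (dist <= band_px)
    if not band.any():
        raise RegionError(f"cell {cell.label}: empty membrane band")
    arr = image.channel(channel)
    band_sum = float(arr[band].sum())
    total = float(arr[cell.mask | band].sum())
    band_mean = float(arr[band].mean())
    if total <= 0:
        raise RegionError(f"cell {cell.label}: zero total signal in {channel!r}")
    return band_mean, band_sum / total


def polar_regions(cell: CellRecord, polar_cap_fraction: float = 0.2):
    """Split the mask into polar caps and the equatorial remainder.

    Caps are the pixels whose projection onto the long axis falls in the
    outer ``polar_cap_fraction`` of the cell's projected extent at either
    end. The two regions partition the mask exactly.
    """
    if not 0 < polar_cap_fraction < 0.5:
        raise ValueError("polar_cap_fraction must be in (0, 0.5)")
    coords = np.argwhere(cell.mask).astype(float)
    d = np.array([np.cos(cell.orientation), np.sin(cell.orientation)])
    s = (coords - np.asarray(cell.centroid)) @ d
    lo, hi = s.min(), s.max()
    extent = hi - lo
    cap = extent * polar_cap_fraction
    in_caps = (s <= lo + cap) | (s >= hi - cap)
    polar = np.zeros_like(cell.mask)
    equatorial = np.zeros_like(cell.mask)
    idx = coords.astype(int)
    polar[idx[in_caps, 0], idx[in_caps, 1]] = True
    equatorial[idx[~in_caps, 0], idx[~in_caps, 1]] = True
    return polar, equatorial


def polar_equatorial_ratio(
    image: CellImage,
    cell: CellRecord,
    channel: str,
    polar_cap_fraction: float = 0.2,
) -> float:
    """Mean polar-cap intensity / mean equatorial intensity.

    Returns ``inf`` when the equatorial mean is zero but the polar mean is
    not (all signal at the poles); raises :class:`RegionError` when either
    region is empty (degenerate geometry).
    """
    polar, equatorial = polar_regions(cell, polar_cap_fraction)
    if not polar.any() or not equatorial.any():
        raise RegionError(f"cell {cell.label}: degenerate polar/equatorial regions")
    arr = image.channel(channel)
    p = float(arr[polar].mean())
    e = float(arr[equatorial].mean())
    if e == 0:
        if p == 0:
            raise RegionError(f"cell {cell.label}: zero signal in both regions")
        log.warning("cell %d: zero equatorial signal; ratio diverges", cell.label)
        return float("inf")
    return p / e


def cell_stats(
    image: CellImage,
    cell: CellRecord,
    channel: str,
    thylakoid_mask: np.ndarray | None = None,
    band_width_um: float = 0.2,
    polar_cap_fraction: float = 0.2,
) -> CellStats:
    """All scalar metrics for one cell and channel (band stats NaN on failure)."""
    if thylakoid_mask is None:
        try:
            thylakoid_mask = thylakoid_region(image, cell)
        except (RegionError, KeyError):
            thylakoid_mask = np.zeros_like(cell.mask)
    try:
        band_mean, band_frac = membrane_band(
            image, cell, thylakoid_mask, channel, band_width_um
        )
    except RegionError as exc:
        log.warning("%s; band stats set to NaN", exc)
        band_mean, band_frac = float("nan"), float("nan")
    try:
        ratio = polar_equatorial_ratio(image, cell, channel, polar_cap_fraction)
    except RegionError as exc:
        log.warning("%s; ratio set to NaN", exc)
        ratio = float("nan")
    return CellStats(
        cell_label=cell.label,
        channel=channel,
        mean_intensity=mean_cell_intensity(image, cell, channel),
        patchiness=patchiness(image, cell, channel),
        band_mean=band_mean,
        band_fraction=band_frac,
        polar_equatorial_ratio=ratio,
        area_px=cell.area_px,
    )


def stats_to_dataframe(stats: list[CellStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_label": s.cell_label,
                "channel": s.channel,
                "mean_intensity": s.mean_intensity,
                "patchiness": s.patchiness,
                "band_mean": s.band_mean,
                "band_fraction": s.band_fraction,
                "polar_equatorial_ratio": s.polar_equatorial_ratio,
                "area_px": s.area_px,
            }
            for s in stats
        ],
        columns=[
            "cell_label", "channel", "mean_intensity", "patchiness",
            "band_mean", "band_fraction", "polar_equatorial_ratio", "area_px",
        ],
    )
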