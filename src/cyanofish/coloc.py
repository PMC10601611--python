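"""Pearson colocalization at Costes' automatic threshold.

Colocalization of two fluorescence channels is quantified per cell by the
Pearson product-moment correlation of paired pixel intensities: 1 means
perfect correlation, -1 perfect anti-correlation, 0 uncorrelated signals.
The background/signal split is chosen automatically by Costes' procedure:
fit b = m*a + c by least squares, then lower a candidate threshold T_A from
the top of channel a's range (with T_B = m*T_A + c) until the pixels *below
both* thresholds are no longer positively correlated. The correlation is then
computed on the above-threshold pixel set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image import CellImage
from .segmentation import CellRecord

log = logging.getLogger(__name__)

__all__ = ["ColocResult", "CostesResult", "pearson", "costes_threshold", "coloc_per_cell"]


@dataclass
class CostesResult:
    """Costes threshold pair with the regression line and status flags."""

    t_a: float
    t_b: float
    slope: float
    intercept: float
    all_retained: bool = False  # scan never found r <= 0; minima returned
    anticorrelated: bool = False  # regression slope <= 0; minima returned


@dataclass
class ColocResult:
    cell_label: int
    channels: tuple[str, str]
    r_pearson: float
    costes_thresholds: tuple[float, float]
    n_pixels_used: int


def pearson(a, b) -> float:
    """Pearson correlation of paired pixel values.

    Raises ``ValueError`` on unequal lengths, fewer than two pixels, or a
    constant input vector (correlation undefined).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("pixel vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant channel")
    return float(stats.pearsonr(a, b).statistic)


def _below_r(a, b, t_a, t_b) -> float | None:
    """Correlation of the sub-threshold set, or None where undefined."""
    sel = (a < t_a) & (b < t_b)
    if sel.sum() < 2:
        return None
    aa, bb = a[sel], b[sel]
    if np.ptp(aa) == 0 or np.ptp(bb) == 0:
        return None
    return float(stats.pearsonr(aa, bb).statistic)


def _orthogonal_fit(a, b) -> tuple[float, float]:
    """Total-least-squares line through the pixel cloud (PCA major axis)."""
    cov = np.cov(a, b)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("orthogonal fit degenerate: vertical major axis")
    m = v[1] / v[0]
    return float(m), float(b.mean() - m * a.mean())


def costes_threshold(a, b, regression: str = "ols") -> CostesResult:
    """Costes' automatic threshold pair for two channels.

    Scans candidate T_A downward over the distinct observed intensities of
    channel a (exact for integer images), with T_B tied to the least-squares
    line b = m*a + c (``regression='orthogonal'`` switches to a total-least-
    squares fit), and returns the highest pair at which the correlation
    of pixels below both thresholds is <= 0. An undefined sub-threshold
    correlation (too few or constant pixels) is not admissible and the scan
    continues. If no candidate qualifies, the channel minima are returned
    (every pixel retained above threshold) with ``all_retained`` set; a
    non-positive regression slope short-circuits to the same fallback with
    ``anticorrelated`` set.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Costes threshold undefined for a constant channel")
    if regression == "ols":
        m, c = np.polyfit(a, b, 1)
    elif regression == "orthogonal":
        m, c = _orthogonal_fit(a, b)
    else:
        raise ValueError("regression must be 'ols' or 'orthogonal'")
    if m <= 0:
        log.warning("costes_threshold: channels anticorrelated (slope %.3g)", m)
        return CostesResult(float(a.min()), float(b.min()), float(m), float(c),
                            all_retained=True, anticorrelated=True)
    for t_a in np.unique(a)[::-1]:
        t_b = m * t_a + c
        r = _below_r(a, b, t_a, t_b)
        if r is not None and r <= 0:
            return CostesResult(float(t_a), float(t_b), float(m), float(c))
    log.info("costes_threshold: no sub-threshold anticorrelation; retaining all pixels")
    return CostesResult(float(a.min()), float(b.min()), float(m), float(c),
                        all_retained=True)


def coloc_per_cell(
    image: CellImage,
    cells: list[CellRecord],
    ch1: str,
    ch2: str,
    pixel_set: str = "above",
    min_pixels: int = 10,
) -> list[ColocResult]:
    """Per-cell Pearson correlation at Costes' threshold.

    For every cell not touching the image border, thresholds are computed
    from the in-mask pixels of the two channels; the correlation is then
    taken over in-mask pixels with ``a >= T_A or b >= T_B``
    (``pixel_set='above'``) or over all in-mask pixels (``pixel_set='all'``).
    Cells with fewer than ``min_pixels`` retained pixels, or where the
    correlation is undefined, are skipped with a logged reason.
    """
    if pixel_set not in ("above", "all"):
        raise ValueError("pixel_set must be 'above' or 'all'")
    log.info("coloc_per_cell: %s vs %s, pixel_set=%s", ch1, ch2, pixel_set)
    arr1 = image.channel(ch1)
    arr2 = image.channel(ch2)
    results: list[ColocResult] = []
    for cell in sorted(cells, key=lambda c: c.label):
        if cell.touches_border:
            log.debug("cell %d: touches border, excluded", cell.label)
            continue
        a = arr1[cell.mask]
        b = arr2[cell.mask]
        try:
            thr = costes_threshold(a, b)
        except ValueError as exc:
            log.warning("cell %d: %s; skipped", cell.label, exc)
            continue
        if pixel_set == "above":
            sel = (a >= thr.t_a) | (b >= thr.t_b)
        else:
            sel = np.ones(a.shape, dtype=bool)
        if sel.sum() < min_pixels:
            log.warning(
                "cell %d: only %d above-threshold pixels (< %d); skipped",
                cell.label, int(sel.sum()), min_pixels,
            )
            continue
        try:
            r = pearson(a[sel], b[sel])
        except ValueError as exc:
            log.warning("cell %d: %s; skipped", cell.label, exc)
            continue
        results.append(
            ColocResult(
                cell_label=cell.label,
                channels=(ch1, ch2),
                r_pearson=r,
                costes_thresholds=(thr.t_a, thr.t_b),
                n_pixels_used=int(sel.sum()),
            )
        )
    return results


def coloc_to_dataframe(results: list[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_label": r.cell_label,
                "ch1": r.channels[0],
                "ch2": r.channels[1],
                "r_pearson": r.r_pearson,
                "T_A": r.costes_thresholds[0],
                "T_B": r.costes_thresholds[1],
                "n_pixels_used": r.n_pixels_used,
            }
            for r in results
        ],
        columns=["cell_label", "ch1", "ch2", "r_pearson", "T_A", "T_B", "n_pixels_used"],
    )
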