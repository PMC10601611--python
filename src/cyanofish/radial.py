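"""Short-axis radial profiling and focus localization.

For each cell, an 8-pixel-wide line across the short axis (through the
centroid) yields a per-channel intensity profile. The two thylakoid peaks on
that profile define a normalized radial coordinate u: the cell center maps
to 0 and the peaks to -0.5 and +0.5, i.e. the peak-to-peak distance is the
unit of length. This compensates for variable cell width and makes radial
positions comparable across cells. Profiles are then linearly interpolated
onto a common u-grid, and punctate FISH/GFP signals are localized and
expressed in u.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import argrelextrema

from .image import CellImage
from .segmentation import CellRecord

log = logging.getLogger(__name__)

__all__ = [
    "AxisProfile",
    "FocusCall",
    "ProfileError",
    "extract_profile",
    "resample_profile",
    "localize_foci",
    "classify_focus",
    "foci_to_dataframe",
]


class ProfileError(ValueError):
    """Raised when a usable two-peak thylakoid profile cannot be built."""


@dataclass
class AxisProfile:
    """Short-axis profile of one cell.

    ``positions_px`` are signed transverse offsets t from the centroid along
    the short axis (px). ``tm_peaks_px`` are the two thylakoid-peak positions
    in the same coordinate (left < right, sub-pixel refined). u is affine in
    t with u(left peak) = -0.5 and u(right peak) = +0.5.
    """

    cell_label: int
    positions_px: np.ndarray
    intensity_by_channel: dict[str, np.ndarray]
    tm_peaks_px: tuple[float, float]
    line_width_px: int
    u_grid: np.ndarray | None = None
    resampled: dict[str, np.ndarray] | None = None

    @property
    def peak_distance_px(self) -> float:
        return self.tm_peaks_px[1] - self.tm_peaks_px[0]

    @property
    def center_px(self) -> float:
        return 0.5 * (self.tm_peaks_px[0] + self.tm_peaks_px[1])

    def u_of(self, t_px) -> np.ndarray:
        """Map signed transverse offsets (px) to the normalized coordinate."""
        return (np.asarray(t_px, dtype=float) - self.center_px) / self.peak_distance_px

    @property
    def u_positions(self) -> np.ndarray:
        return self.u_of(self.positions_px)

    @property
    def n_interp(self) -> int | None:
        return None if self.u_grid is None else len(self.u_grid)


@dataclass
class FocusCall:
    """One detected punctate signal, localized in the cell's u coordinate."""

    cell_label: int
    channel: str
    u: float
    peak_intensity: float
    position_px: tuple[float, float]
    compartment: str = ""


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-pixel peak position by local parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def extract_profile(
    image: CellImage,
    cell: CellRecord,
    line_width_px: int = 8,
    thylakoid_channel: str = "thylakoid",
) -> AxisProfile:
    """Sample all channels along the cell's short axis through the centroid.

    Intensities are averaged over ``line_width_px`` parallel lines offset
    along the long axis. The two thylakoid peaks are the highest local maxima
    on either side of the centroid (ties resolved outward); a parabolic
    refinement gives sub-pixel positions.

    Raises
    ------
    ProfileError
        If fewer than two thylakoid local maxima are found — the cell should
        be excluded, with the reason logged.
    """
    theta = cell.orientation
    d = np.array([np.cos(theta), np.sin(theta)])  # long axis
    n = np.array([-d[1], d[0]])  # short axis
    # half-extent of the sampling line: a bit beyond the cell half-width
    coords = np.argwhere(cell.mask).astype(float)
    t_all = (coords - np.asarray(cell.centroid)) @ n
    t_max = float(np.abs(t_all).max()) + 2.0
    positions = np.arange(-np.ceil(t_max), np.ceil(t_max) + 1.0)

    offsets = np.arange(line_width_px, dtype=float)
    offsets -= offsets.mean()  # centered along the long axis
    c0 = np.asarray(cell.centroid)

    profiles: dict[str, np.ndarray] = {}
    for name, arr in image.channels.items():
        acc = np.zeros(len(positions))
        for off in offsets:
            pts = c0 + off * d[None, :] * 1.0 + positions[:, None] * n[None, :]
            acc += ndi.map_coordinates(
                arr, [pts[:, 0], pts[:, 1]], order=1, mode="nearest"
            )
        profiles[name] = acc / line_width_px

    tm = profiles.get(thylakoid_channel)
    if tm is None:
        tm = image.channel(thylakoid_channel)  # raises KeyError with detail
    (maxima,) = argrelextrema(tm, np.greater_equal, order=2)
    # drop plateaux duplicates and flat ends
    maxima = [i for i in maxima if 0 < i < len(tm) - 1]
    left = [i for i in maxima if positions[i] < 0]
    right = [i for i in maxima if positions[i] > 0]
    if not left or not right:
        msg = (
            f"cell {cell.label}: found {len(left)} left / {len(right)} right "
            "thylakoid maxima; need one on each side of the centroid"
        )
        log.warning(msg)
        raise ProfileError(msg)

    def pick(side, outward_sign):
        best = max(side, key=lambda i: (tm[i], outward_sign * positions[i]))
        return _parabolic_refine(tm, best) + positions[0]

    t_left = pick(left, -1)
    t_right = pick(right, +1)
    if not t_left < t_right:
        raise ProfileError(f"cell {cell.label}: thylakoid peaks not ordered")
    return AxisProfile(
        cell_label=cell.label,
        positions_px=positions,
        intensity_by_channel=profiles,
        tm_peaks_px=(t_left, t_right),
        line_width_px=line_width_px,
    )


def resample_profile(
    profile: AxisProfile, n_interp: int = 101, u_max: float = 0.75
) -> AxisProfile:
    """Linearly interpolate all channels onto a fixed u-grid.

    The grid has ``n_interp`` points between u = -0.5 and u = +0.5 (the two
    thylakoid peaks) and extends symmetrically to ±``u_max`` with the same
    spacing, so every cell contributes the same number of points between its
    peaks regardless of its width in pixels.
    """
    if n_interp < 2:
        raise ValueError("n_interp must be >= 2")
    du = 1.0 / (n_interp - 1)
    n_ext = int(np.floor((u_max - 0.5) / du + 1e-9))
    grid = np.arange(-(n_interp // 2) - n_ext, (n_interp - 1) - (n_interp // 2) + n_ext + 1) * du
    u_samples = profile.u_positions
    resampled = {
        name: np.interp(grid, u_samples, vals)
        for name, vals in profile.intensity_by_channel.items()
    }
    profile.u_grid = grid
    profile.resampled = resampled
    return profile


def localize_foci(
    image: CellImage,
    cell: CellRecord,
    profile: AxisProfile,
    channel: str,
    k_mad: float = 5.0,
    min_distance_px: int = 7,
    mode: str = "all-foci",
) -> list[FocusCall]:
    """Detect punctate signals in one channel and localize them in u.

    Foci are 2-D local maxima inside the cell mask whose intensity exceeds
    the in-cell median by ``k_mad`` times the median absolute deviation.
    The channel should retain its diffuse background (detect before baseline
    subtraction): the median/MAD statistics are robust to punctate signal but
    collapse once the background has been subtracted and floored at zero.
    ``min_distance_px`` should be at least the blurred focus half-width so
    that noise ripples on one focus do not register as several calls. Each
    focus position (sub-pixel, intensity-weighted over a 3x3 window) is
    projected onto the cell's short axis and normalized by the cell's
    thylakoid peak-to-peak distance, so its u is directly comparable to the
    profile's coordinate. ``mode='global-peak'`` keeps only the brightest
    focus per cell (the single profile-peak reading).
    """
    if mode not in ("all-foci", "global-peak"):
        raise ValueError("mode must be 'all-foci' or 'global-peak'")
    from skimage.feature import peak_local_max

    arr = image.channel(channel)
    vals = arr[cell.mask]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    if mad == 0:
        # a zero-floored (background-subtracted) cell collapses the MAD and
        # with it any robust noise scale; detection must run on the channel
        # before baseline subtraction
        if np.ptp(vals) == 0:
            return []
        log.warning(
            "cell %d: zero MAD in %r (already background-subtracted?); "
            "detect on the unsubtracted channel instead", cell.label, channel,
        )
        mad = float(np.percentile(vals, 84.13) - med)
        if mad == 0:
            return []
    thr = med + k_mad * mad
    masked = np.where(cell.mask, arr, -np.inf)
    peaks = peak_local_max(
        masked, min_distance=min_distance_px, threshold_abs=thr, exclude_border=False
    )

    theta = cell.orientation
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    c0 = np.asarray(cell.centroid)

    calls: list[FocusCall] = []
    for r, c in peaks:
        # intensity-weighted sub-pixel refinement in a 3x3 window
        r0, r1 = max(0, r - 1), min(arr.shape[0], r + 2)
        c0w, c1w = max(0, c - 1), min(arr.shape[1], c + 2)
        win = np.clip(arr[r0:r1, c0w:c1w] - thr, 0, None)
        if win.sum() > 0:
            rr, cc = np.mgrid[r0:r1, c0w:c1w]
            pr = float((rr * win).sum() / win.sum())
            pc = float((cc * win).sum() / win.sum())
        else:
            pr, pc = float(r), float(c)
        t_off = float((np.array([pr, pc]) - c0) @ n)
        u = float(profile.u_of(t_off))
        calls.append(
            FocusCall(
                cell_label=cell.label,
                channel=channel,
                u=u,
                peak_intensity=float(arr[r, c]),
                position_px=(pr, pc),
            )
        )
    if mode == "global-peak" and calls:
        calls = [max(calls, key=lambda f: f.peak_intensity)]
    return calls


def classify_focus(u: float, tm_halfwidth: float = 0.1) -> str:
    """Assign a focus to a radial compartment.

    ``central``: |u| < 0.5 - tm_halfwidth (central cytoplasm);
    ``thylakoid``: within 0.5 ± tm_halfwidth of the shell peak;
    ``beyond``: |u| > 0.5 + tm_halfwidth (plasma-membrane side).
    """
    if tm_halfwidth <= 0:
        raise ValueError("tm_halfwidth must be positive")
    au = abs(u)
    if au < 0.5 - tm_halfwidth:
        return "central"
    if au <= 0.5 + tm_halfwidth:
        return "thylakoid"
    return "beyond"


def foci_to_dataframe(calls: list[FocusCall], tm_halfwidth: float = 0.1) -> pd.DataFrame:
    rows = []
    for f in calls:
        rows.append(
            {
                "cell_label": f.cell_label,
                "channel": f.channel,
                "u": f.u,
                "compartment": f.compartment or classify_focus(f.u, tm_halfwidth),
                "peak_intensity": f.peak_intensity,
                "row": f.position_px[0],
                "col": f.position_px[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_label", "channel", "u", "compartment", "peak_intensity", "row", "col"],
    )
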