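"""Synthetic fluorescence micrographs of rod-shaped cyanobacteria.

Renders 2-D confocal-style fields of spherocylindrical cells with a
peripheral thylakoid shell, punctate FISH/GFP foci at controlled normalized
radial positions, diffuse in-cell background, Gaussian optical blur, and
photon/readout noise — together with the exact ground truth (cell poses,
true focus coordinates, per-compartment signal fractions) needed to validate
every downstream metric.

Geometry and coordinates
------------------------
A cell is a 2-D spherocylinder: a rectangle of width ``W`` capped by two
semicircles, total tip-to-tip length ``L``. Its local frame has a
longitudinal coordinate ``s`` (0 at the centroid) and a signed transverse
coordinate ``t``. The thylakoid shell is a Gaussian ridge in the distance to
the centerline segment, peaking at ``shell_radius_frac * W/2``.

The normalized radial coordinate ``u`` places the cell center at 0 and the
two thylakoid-ridge peaks at ±0.5, i.e. ``u = t / (2 * d_peak)`` — the
peak-to-peak distance is the unit of length, matching how measured profiles
are normalized downstream.

Rendering is flux-preserving: each shell and each focus is normalized to sum
exactly to its configured flux on the pixel grid before blur and noise are
applied, so noiseless totals are exact bookkeeping quantities.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .image import CellImage

log = logging.getLogger(__name__)

__all__ = [
    "PigmentChannel",
    "FocusChannel",
    "SimConfig",
    "CellPose",
    "GroundTruth",
    "SimulationError",
    "simulate_field",
    "simulate_condition_pair",
    "sample_u",
]


class SimulationError(RuntimeError):
    """Raised when a field cannot be generated under the given config."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PigmentChannel:
    """Thylakoid-autofluorescence channel (PC or Chl analogue).

    ``shell_flux`` is the *total* shell signal per cell in counts;
    ``interior_flux_per_px`` is a diffuse pigment level inside the whole
    cell, as real pigment fluorescence is not strictly membrane-confined.
    """

    shell_flux: float = 2.0e6
    shell_sigma_u: float = 0.06  # ridge width, u units
    interior_flux_per_px: float = 60.0

    kind: str = field(default="pigment", init=False, repr=False)


@dataclass
class FocusChannel:
    """Punctate channel (FISH or GFP analogue) with diffuse background.

    ``position_model`` controls the distribution of the true normalized
    radial coordinate ``u`` of foci; see :func:`sample_u`. ``flux_median``
    is the per-focus total signal (log-normal across foci). ``polar_enrichment``
    multiplies the diffuse background inside the two polar caps (fraction
    ``polar_cap_fraction`` of the cell length at each end).
    """

    n_foci: int | tuple[int, int] = (2, 5)
    position_model: object = "central"
    flux_median: float = 9.0e4
    flux_sigma_log: float = 0.3
    focus_sigma_nm: float = 60.0
    background_per_px: float = 80.0
    polar_enrichment: float = 1.0
    polar_cap_fraction: float = 0.2
    min_focus_separation_px: float = 14.0

    kind: str = field(default="foci", init=False, repr=False)


def _default_channels() -> dict:
    return {"thylakoid": PigmentChannel(), "fish": FocusChannel()}


@dataclass
class SimConfig:
    """Full description of one synthetic field.

    Invariants: ``pixel_size_nm > 0``; sampled widths below sampled lengths;
    shell compartment radii in (0, 1]; a fixed seed makes the output
    bit-identical.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 24.0
    n_cells: int = 10
    cell_length_um: tuple[float, float] = (2.5, 3.5)
    cell_width_um: tuple[float, float] = (0.9, 1.1)
    shell_radius_frac: float = 0.7  # ridge peak, fraction of half-width
    shell_inner_u: float = 0.4  # compartment boundaries in |u|
    shell_outer_u: float = 0.6
    channels: dict = field(default_factory=_default_channels)
    psf_sigma_nm: float = 100.0
    noise_gain: float | None = 1.0  # photons per count; None = no shot noise
    read_noise_sd: float = 3.0  # counts; 0 = off
    crosstalk: float = 0.0  # optional bleed of thylakoid into focus channels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.cell_width_um[1] >= self.cell_length_um[0]:
            raise ValueError("cell widths must be below cell lengths")
        if not (0 < self.shell_inner_u < self.shell_outer_u <= 1):
            raise ValueError("compartment radii must satisfy 0 < inner < outer <= 1")
        if not (0 < self.shell_radius_frac < 1):
            raise ValueError("shell_radius_frac must be in (0, 1)")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name, spec in d["channels"].items():
            spec["kind"] = self.channels[name].kind
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        chans = {}
        for name, spec in d.get("channels", {}).items():
            spec = dict(spec)
            kind = spec.pop("kind", "foci")
            if kind == "pigment":
                chans[name] = PigmentChannel(**spec)
            else:
                if isinstance(spec.get("n_foci"), list):
                    spec["n_foci"] = tuple(spec["n_foci"])
                if isinstance(spec.get("position_model"), list):
                    spec["position_model"] = tuple(spec["position_model"])
                chans[name] = FocusChannel(**spec)
        if chans:
            d["channels"] = chans
        for key in ("image_size", "cell_length_um", "cell_width_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class CellPose:
    """True pose of one simulated cell (pixel units unless suffixed)."""

    label: int
    center: tuple[float, float]  # (row, col)
    theta: float  # long-axis angle, radians in [0, pi)
    length_um: float
    width_um: float

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([np.cos(self.theta), np.sin(self.theta)])  # (dr, dc)
        n = np.array([-d[1], d[0]])
        return d, n

    def pole_points(self, pixel_size_nm: float) -> tuple[tuple, tuple]:
        d, _ = self.axes()
        half = self.length_um * 1000 / pixel_size_nm / 2
        c = np.asarray(self.center)
        p1, p2 = c - half * d, c + half * d
        return (tuple(p1), tuple(p2))


@dataclass
class GroundTruth:
    """Simulator annotation tables.

    ``cells``: one row per cell (label, center, angle, size, poles).
    ``foci``: one row per rendered focus (owning cell, channel, u_true,
    s offset in px, absolute position, flux).
    ``fractions``: per cell and channel, the true fraction of (pre-blur)
    signal in the central cytoplasm (|u| < inner), the thylakoid shell
    (inner ≤ |u| ≤ outer), and the plasma-membrane band (|u| > outer).
    """

    cells: pd.DataFrame
    foci: pd.DataFrame
    fractions: pd.DataFrame

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.csv", index=False)
        self.foci.to_csv(outdir / "truth_foci.csv", index=False)
        self.fractions.to_csv(outdir / "truth_fractions.csv", index=False)


_EMPTY_CELLS = [
    "label", "row", "col", "theta", "length_um", "width_um",
    "pole1_row", "pole1_col", "pole2_row", "pole2_col",
]
_EMPTY_FOCI = ["cell_label", "channel", "u_true", "s_px", "row", "col", "flux"]
_EMPTY_FRAC = ["cell_label", "channel", "frac_central", "frac_shell", "frac_band"]


# ---------------------------------------------------------------------------
# focus position models
# ---------------------------------------------------------------------------


def sample_u(model, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sample ``n`` true normalized radial coordinates from a position model.

    Models
    ------
    ``"central"``
        Truncated normal, sd 0.12, support |u| <= 0.3 — foci in the central
        cytoplasm.
    ``"membrane"``
        |u| uniform on (0.5, 0.68), random sign — foci at or beyond the
        thylakoid shell, toward the plasma membrane.
    ``"uniform"``
        u uniform on (-0.7, 0.7).
    ``("uniform", lo, hi)`` / ``("uniform_abs", lo, hi)``
        Uniform on u, or on |u| with a random sign.
    ``("fixed", u0)``
        All foci at exactly u0.
    ``("mixture", p, model_a, model_b)``
        Each focus from model_a with probability p, else model_b.
    """
    if isinstance(model, str):
        if model == "central":
            out = rng.normal(0.0, 0.12, size=4 * n + 16)
            out = out[np.abs(out) <= 0.3]
            while out.size < n:  # pragma: no cover - vanishingly rare
                out = np.concatenate([out, rng.normal(0.0, 0.12, size=4 * n)])
                out = out[np.abs(out) <= 0.3]
            return out[:n]
        if model == "membrane":
            mag = rng.uniform(0.5, 0.68, size=n)
            return mag * rng.choice([-1.0, 1.0], size=n)
        if model == "uniform":
            return rng.uniform(-0.7, 0.7, size=n)
        raise ValueError(f"unknown position model {model!r}")
    kind = model[0]
    if kind == "uniform":
        return rng.uniform(model[1], model[2], size=n)
    if kind == "uniform_abs":
        mag = rng.uniform(model[1], model[2], size=n)
        return mag * rng.choice([-1.0, 1.0], size=n)
    if kind == "fixed":
        return np.full(n, float(model[1]))
    if kind == "mixture":
        _, p, a, b = model
        pick = rng.random(n) < p
        ua = sample_u(a, rng, n)
        ub = sample_u(b, rng, n)
        return np.where(pick, ua, ub)
    raise ValueError(f"unknown position model {model!r}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between 2-D segments p1-p2 and q1-q2."""

    def point_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        tt = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + tt * ab)))

    p1, p2, q1, q2 = map(np.asarray, (p1, p2, q1, q2))
    d1, d2 = p2 - p1, q2 - q1
    r = p1 - q1
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    b, c = d1 @ d2, d1 @ r
    denom = a * e - b * b
    if denom > 1e-12:
        s = np.clip((b * f - c * e) / denom, 0, 1)
    else:
        s = 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    t = np.clip(t, 0, 1)
    # refine endpoints (standard clamped closest-approach)
    cand = [
        point_seg(p1, q1, q2), point_seg(p2, q1, q2),
        point_seg(q1, p1, p2), point_seg(q2, p1, p2),
        float(np.linalg.norm((p1 + s * d1) - (q1 + t * d2))),
    ]
    return min(cand)


def _cell_crop(shape, pose: CellPose, pixel_size_nm, margin_px) -> tuple[slice, slice]:
    half = pose.length_um * 1000 / pixel_size_nm / 2 + margin_px
    r0 = int(max(0, np.floor(pose.center[0] - half)))
    r1 = int(min(shape[0], np.ceil(pose.center[0] + half) + 1))
    c0 = int(max(0, np.floor(pose.center[1] - half)))
    c1 = int(min(shape[1], np.ceil(pose.center[1] + half) + 1))
    return slice(r0, r1), slice(c0, c1)


def _local_coords(pose: CellPose, rows: slice, cols: slice):
    """Return (s, t) local coordinates in px for a crop window."""
    rr, cc = np.mgrid[rows, cols]
    d, n = pose.axes()
    dr = rr - pose.center[0]
    dc = cc - pose.center[1]
    s = dr * d[0] + dc * d[1]
    t = dr * n[0] + dc * n[1]
    return s, t


def cell_mask_from_pose(pose: CellPose, shape, pixel_size_nm) -> np.ndarray:
    """Boolean full-frame mask of the true spherocylinder."""
    rows, cols = _cell_crop(shape, pose, pixel_size_nm, 2)
    s, t = _local_coords(pose, rows, cols)
    L = pose.length_um * 1000 / pixel_size_nm
    W = pose.width_um * 1000 / pixel_size_nm
    h = (L - W) / 2
    rho = np.hypot(np.maximum(np.abs(s) - h, 0.0), t)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = rho <= W / 2
    return mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _place_cells(config: SimConfig, rng: np.random.Generator) -> list[CellPose]:
    px = config.pixel_size_nm
    poses: list[CellPose] = []
    max_attempts = 1000 * max(config.n_cells, 1)
    attempts = 0
    gap_px = 3.0
    while len(poses) < config.n_cells:
        if attempts >= max_attempts:
            raise SimulationError(
                f"could not place {config.n_cells} non-overlapping cells in a "
                f"{config.image_size} field after {max_attempts} attempts; "
                "the requested cell density is too high"
            )
        attempts += 1
        L = rng.uniform(*config.cell_length_um)
        W = rng.uniform(*config.cell_width_um)
        theta = rng.uniform(0, np.pi)
        L_px, W_px = L * 1000 / px, W * 1000 / px
        margin = L_px / 2 + 3
        if 2 * margin >= min(config.image_size):
            raise SimulationError(
                "image too small to host a cell: increase image_size or "
                "shrink cell_length_um"
            )
        r = rng.uniform(margin, config.image_size[0] - margin)
        c = rng.uniform(margin, config.image_size[1] - margin)
        pose = CellPose(len(poses) + 1, (r, c), theta, L, W)
        d, _ = pose.axes()
        h = (L_px - W_px) / 2
        p1 = np.array([r, c]) - h * d
        p2 = np.array([r, c]) + h * d
        ok = True
        for other in poses:
            od, _ = other.axes()
            oL = other.length_um * 1000 / px
            oW = other.width_um * 1000 / px
            oh = (oL - oW) / 2
            q1 = np.asarray(other.center) - oh * od
            q2 = np.asarray(other.center) + oh * od
            if _segment_distance(p1, p2, q1, q2) < (W_px + oW) / 2 + gap_px:
                ok = False
                break
        if ok:
            poses.append(pose)
    return poses


def _render_pigment(canvas, pose, spec: PigmentChannel, config, zone_sums):
    px = config.pixel_size_nm
    rows, cols = _cell_crop(canvas.shape, pose, px, 4)
    s, t = _local_coords(pose, rows, cols)
    L = pose.length_um * 1000 / px
    W = pose.width_um * 1000 / px
    h = (L - W) / 2
    rho = np.hypot(np.maximum(np.abs(s) - h, 0.0), t)
    d_peak = config.shell_radius_frac * W / 2
    sigma_d = spec.shell_sigma_u * 2 * d_peak
    inside = rho <= W / 2
    ridge = np.exp(-((rho - d_peak) ** 2) / (2 * sigma_d**2))
    ridge[rho > W / 2 + 3 * sigma_d] = 0.0
    total = ridge.sum()
    contrib = np.zeros_like(ridge)
    if total > 0:
        contrib += ridge * (spec.shell_flux / total)
    contrib += inside * spec.interior_flux_per_px
    canvas[rows, cols] += contrib
    u_abs = rho / (2 * d_peak)
    zone_sums["central"] += float(contrib[u_abs < config.shell_inner_u].sum())
    zone_sums["shell"] += float(
        contrib[(u_abs >= config.shell_inner_u) & (u_abs <= config.shell_outer_u)].sum()
    )
    zone_sums["band"] += float(contrib[u_abs > config.shell_outer_u].sum())


def _render_focus(canvas, pos, flux, sigma_px):
    r0, c0 = pos
    half = int(np.ceil(5 * sigma_px)) + 1
    rows = slice(max(0, int(r0) - half), min(canvas.shape[0], int(r0) + half + 1))
    cols = slice(max(0, int(c0) - half), min(canvas.shape[1], int(c0) + half + 1))
    rr, cc = np.mgrid[rows, cols]
    g = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2)))
    total = g.sum()
    if total > 0:
        canvas[rows, cols] += g * (flux / total)


def _render_focus_channel(canvas, pose, spec: FocusChannel, config, rng, zone_sums):
    """Render background + foci for one cell; returns focus records."""
    px = config.pixel_size_nm
    rows, cols = _cell_crop(canvas.shape, pose, px, 4)
    s, t = _local_coords(pose, rows, cols)
    L = pose.length_um * 1000 / px
    W = pose.width_um * 1000 / px
    h = (L - W) / 2
    rho = np.hypot(np.maximum(np.abs(s) - h, 0.0), t)
    inside = rho <= W / 2
    d_peak = config.shell_radius_frac * W / 2

    # diffuse background, optionally enriched in the polar caps
    bg = inside * spec.background_per_px
    if spec.polar_enrichment != 1.0:
        caps = inside & (np.abs(s) > L / 2 - spec.polar_cap_fraction * L)
        bg = bg + caps * spec.background_per_px * (spec.polar_enrichment - 1.0)
    canvas[rows, cols] += bg
    u_abs = rho / (2 * d_peak)
    zone_sums["central"] += float(bg[u_abs < config.shell_inner_u].sum())
    zone_sums["shell"] += float(
        bg[(u_abs >= config.shell_inner_u) & (u_abs <= config.shell_outer_u)].sum()
    )
    zone_sums["band"] += float(bg[u_abs > config.shell_outer_u].sum())

    # foci
    if isinstance(spec.n_foci, (tuple, list)):
        n = int(rng.integers(spec.n_foci[0], spec.n_foci[1] + 1))
    else:
        n = int(spec.n_foci)
    d, nvec = pose.axes()
    sigma_px = spec.focus_sigma_nm / px
    records = []
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(200):
            u = float(sample_u(spec.position_model, rng, 1)[0])
            t_off = u * 2 * d_peak
            if abs(t_off) > W / 2 - 1:  # keep focus center inside the cell
                continue
            s_max = max(h * 0.9, 1.0)
            s_off = float(rng.uniform(-s_max, s_max))
            pos = np.asarray(pose.center) + s_off * d + t_off * nvec
            if placed and min(
                np.linalg.norm(pos - q) for q in placed
            ) < spec.min_focus_separation_px:
                continue
            break
        else:
            log.warning(
                "cell %d: could not place focus %d with the requested "
                "separation; skipping", pose.label, len(placed) + 1,
            )
            continue
        flux = float(
            rng.lognormal(mean=np.log(spec.flux_median), sigma=spec.flux_sigma_log)
        )
        _render_focus(canvas, pos, flux, sigma_px)
        placed.append(pos)
        records.append(
            {"u_true": u, "s_px": s_off, "row": pos[0], "col": pos[1], "flux": flux}
        )
        au = abs(u)
        if au < config.shell_inner_u:
            zone_sums["central"] += flux
        elif au <= config.shell_outer_u:
            zone_sums["shell"] += flux
        else:
            zone_sums["band"] += flux
    return records


def simulate_field(
    config: SimConfig, cells: list[CellPose] | None = None
) -> tuple[CellImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Parameters
    ----------
    config
        Scene description; ``config.seed`` fixes all randomness.
    cells
        Optional explicit cell poses (bypasses random non-overlapping
        placement — used e.g. to force touching cells).

    Returns
    -------
    (CellImage, GroundTruth)
        PSF blur and noise are applied after noiseless compositing; the
        ground-truth tables refer to the pre-blur scene.
    """
    rng = np.random.default_rng(config.seed)
    if cells is None:
        poses = _place_cells(config, rng) if config.n_cells > 0 else []
    else:
        poses = cells

    canvases = {name: np.zeros(config.image_size) for name in config.channels}
    foci_rows, frac_rows = [], []
    for pose in poses:
        for name, spec in config.channels.items():
            zone = {"central": 0.0, "shell": 0.0, "band": 0.0}
            if spec.kind == "pigment":
                _render_pigment(canvases[name], pose, spec, config, zone)
            else:
                recs = _render_focus_channel(
                    canvases[name], pose, spec, config, rng, zone
                )
                for rec in recs:
                    foci_rows.append({"cell_label": pose.label, "channel": name, **rec})
            tot = sum(zone.values())
            if tot > 0:
                frac_rows.append(
                    {
                        "cell_label": pose.label,
                        "channel": name,
                        "frac_central": zone["central"] / tot,
                        "frac_shell": zone["shell"] / tot,
                        "frac_band": zone["band"] / tot,
                    }
                )

    # optional pigment bleed-through into focus channels (single coefficient)
    if config.crosstalk > 0:
        pigment = [n for n, s in config.channels.items() if s.kind == "pigment"]
        if pigment:
            bleed = config.crosstalk * canvases[pigment[0]]
            for name, spec in config.channels.items():
                if spec.kind == "foci":
                    canvases[name] += bleed

    psf_px = config.psf_sigma_nm / config.pixel_size_nm
    for name in canvases:
        if psf_px > 0:
            canvases[name] = ndi.gaussian_filter(canvases[name], psf_px)
        if config.noise_gain is not None and config.noise_gain > 0:
            g = config.noise_gain
            canvases[name] = rng.poisson(canvases[name] * g).astype(float) / g
        if config.read_noise_sd > 0:
            canvases[name] = canvases[name] + rng.normal(
                0.0, config.read_noise_sd, size=canvases[name].shape
            )

    image = CellImage(canvases, pixel_size_nm=config.pixel_size_nm, bit_depth=12)
    cell_rows = []
    for pose in poses:
        (p1r, p1c), (p2r, p2c) = pose.pole_points(config.pixel_size_nm)
        cell_rows.append(
            {
                "label": pose.label,
                "row": pose.center[0],
                "col": pose.center[1],
                "theta": pose.theta,
                "length_um": pose.length_um,
                "width_um": pose.width_um,
                "pole1_row": p1r, "pole1_col": p1c,
                "pole2_row": p2r, "pole2_col": p2c,
            }
        )
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows, columns=_EMPTY_CELLS),
        foci=pd.DataFrame(foci_rows, columns=_EMPTY_FOCI),
        fractions=pd.DataFrame(frac_rows, columns=_EMPTY_FRAC),
    )
    return image, truth


def simulate_condition_pair(
    config: SimConfig, shift: float
) -> tuple[tuple[CellImage, GroundTruth], tuple[CellImage, GroundTruth]]:
    """Render an uninduced/induced pair of fields.

    Field A draws all foci from the central-cytoplasm model. Field B draws a
    ``shift`` fraction from the membrane model (|u_true| >= 0.5) and the rest
    from the central model — the two-condition contrast the radial pipeline
    is meant to detect.
    """
    if not 0 <= shift <= 1:
        raise ValueError("shift must be in [0, 1]")
    seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)

    def with_model(model, seed):
        chans = {}
        for name, spec in config.channels.items():
            if spec.kind == "foci":
                chans[name] = replace(spec, position_model=model)
            else:
                chans[name] = replace(spec)
        return replace(config, channels=chans, seed=int(seed))

    cfg_a = with_model("central", seeds[0])
    cfg_b = with_model(("mixture", shift, "membrane", "central"), seeds[1])
    return simulate_field(cfg_a), simulate_field(cfg_b)
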