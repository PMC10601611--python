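"""Short-axis profiles, the normalized coordinate u, and focus localization."""

import numpy as np
import pytest

from cyanofish import (
    SimConfig,
    classify_focus,
    extract_profile,
    localize_foci,
    preprocess,
    resample_profile,
    segment_cells,
    simulate_field,
)
from cyanofish.radial import AxisProfile, ProfileError
from cyanofish.simulate import FocusChannel, PigmentChannel

from conftest import match_cells


def simulate_segment(cfg):
    img, truth = simulate_field(cfg)
    blurred = preprocess(img)
    cells = segment_cells(blurred)
    return img, truth, blurred, cells


@pytest.fixture(scope="module")
def noiseless_cell():
    cfg = SimConfig(n_cells=1, seed=8, noise_gain=None, read_noise_sd=0.0)
    img, truth, blurred, cells = simulate_segment(cfg)
    return cfg, truth, blurred, cells[0]


class TestExtractProfile:
    def test_peaks_at_true_shell_positions(self, noiseless_cell):
        cfg, truth, blurred, cell = noiseless_cell
        prof = extract_profile(blurred, cell)
        row = truth.cells.iloc[0]
        d_peak = cfg.shell_radius_frac * row.width_um * 1000 / cfg.pixel_size_nm / 2
        assert prof.tm_peaks_px[0] == pytest.approx(-d_peak, abs=1.0)
        assert prof.tm_peaks_px[1] == pytest.approx(+d_peak, abs=1.0)
        # u at the peaks is exactly -/+ 0.5 by construction
        assert prof.u_of(prof.tm_peaks_px[0]) == pytest.approx(-0.5)
        assert prof.u_of(prof.tm_peaks_px[1]) == pytest.approx(+0.5)

    def test_centroid_maps_to_zero_for_symmetric_cell(self, noiseless_cell):
        _, _, blurred, cell = noiseless_cell
        prof = extract_profile(blurred, cell)
        assert abs(prof.u_of(0.0)) <= 0.02

    def test_normalization_divisor_tracks_cell_width(self):
        # shell rendered with peak-to-peak 0.8 um -> divisor ~ 0.8 um / pixel
        width = 0.8 / 0.7  # shell at 0.7 of the half-width
        cfg = SimConfig(
            n_cells=1, seed=6, noise_gain=None, read_noise_sd=0.0,
            cell_width_um=(width, width), cell_length_um=(3.0, 3.0),
        )
        _, _, blurred, cells = simulate_segment(cfg)
        prof = extract_profile(blurred, cells[0])
        assert prof.peak_distance_px == pytest.approx(800 / 24.0, abs=1.5)

    def test_too_few_peaks_raises(self):
        cfg = SimConfig(
            n_cells=1, seed=6, noise_gain=None, read_noise_sd=0.0,
            channels={"thylakoid": PigmentChannel(shell_flux=0.0,
                                                  interior_flux_per_px=100.0)},
        )
        _, _, blurred, cells = simulate_segment(cfg)
        with pytest.raises(ProfileError, match="maxima"):
            extract_profile(blurred, cells[0])


def synthetic_profile(intensity):
    positions = np.arange(-20.0, 21.0)
    return AxisProfile(
        cell_label=1,
        positions_px=positions,
        intensity_by_channel={"fish": np.asarray(intensity, dtype=float)},
        tm_peaks_px=(-10.0, 10.0),
        line_width_px=8,
    )


class TestResampleProfile:
    def test_linear_ramp_is_exact(self):
        positions = np.arange(-20.0, 21.0)
        prof = synthetic_profile(2.0 * positions + 5.0)
        resample_profile(prof, n_interp=101)
        # u = t / 20 -> intensity = 40 u + 5, exactly, under linear interpolation
        assert np.allclose(prof.resampled["fish"], 40.0 * prof.u_grid + 5.0)
        between = (prof.u_grid >= -0.5) & (prof.u_grid <= 0.5)
        assert between.sum() == 101

    def test_identity_on_target_grid(self):
        prof = synthetic_profile(np.sin(np.arange(41)))
        resample_profile(prof, n_interp=101)
        first = prof.resampled["fish"].copy()
        # feeding the resampled values back through the same grid changes nothing
        prof2 = AxisProfile(1, prof.u_grid * 20.0,
                            {"fish": first}, (-10.0, 10.0), 8)
        resample_profile(prof2, n_interp=101)
        assert np.allclose(prof2.resampled["fish"], first)

    def test_values_bounded_by_originals(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 9, 41)
        prof = synthetic_profile(vals)
        resample_profile(prof, n_interp=51)
        assert prof.resampled["fish"].min() >= vals.min() - 1e-12
        assert prof.resampled["fish"].max() <= vals.max() + 1e-12

    def test_common_grid_across_cells(self, segmented_field):
        _, blurred, _, cells = segmented_field
        grids = []
        for cell in cells[:3]:
            prof = resample_profile(extract_profile(blurred, cell), n_interp=101)
            grids.append(prof.u_grid)
        for g in grids[1:]:
            assert np.array_equal(g, grids[0])

    def test_invalid_n_interp(self):
        with pytest.raises(ValueError):
            resample_profile(synthetic_profile(np.ones(41)), n_interp=1)


class TestLocalizeFoci:
    def _recovery(self, model, seed):
        cfg = SimConfig(
            n_cells=4, seed=seed, image_size=(512, 512),
            channels={"thylakoid": PigmentChannel(),
                      "fish": FocusChannel(n_foci=2, position_model=model)},
        )
        img, truth, blurred, cells = simulate_segment(cfg)
        calls = []
        for cell in cells:
            if cell.touches_border:
                continue
            prof = extract_profile(blurred, cell)
            calls += localize_foci(blurred, cell, prof, "fish")
        return truth, calls

    def test_central_focus_recovered_near_zero(self):
        truth, calls = self._recovery(("fixed", 0.0), seed=21)
        assert len(calls) >= 6
        assert all(abs(c.u) <= 0.05 for c in calls)

    def test_membrane_foci_recovered_beyond_half(self):
        truth, calls = self._recovery(("uniform_abs", 0.6, 0.65), seed=22)
        assert len(calls) >= 6
        assert all(abs(c.u) >= 0.5 for c in calls)

    def test_zero_signal_channel_empty(self, noiseless_cell):
        _, _, blurred, cell = noiseless_cell
        img = blurred.copy()
        img.channels["fish"] = np.zeros(img.shape)
        prof = extract_profile(img, cell)
        assert localize_foci(img, cell, prof, "fish") == []

    def test_intensity_scale_invariance(self, segmented_field):
        _, blurred, _, cells = segmented_field
        cell = next(c for c in cells if not c.touches_border)
        prof = extract_profile(blurred, cell)
        calls1 = localize_foci(blurred, cell, prof, "fish")
        scaled = blurred.copy()
        for name in scaled.channels:
            scaled.channels[name] = scaled.channels[name] * 5.0
        prof_s = extract_profile(scaled, cell)
        calls2 = localize_foci(scaled, cell, prof_s, "fish")
        assert len(calls1) == len(calls2) > 0
        for c1, c2 in zip(calls1, calls2):
            assert c1.u == pytest.approx(c2.u, abs=1e-9)

    def test_global_peak_mode_returns_brightest(self, segmented_field):
        _, blurred, _, cells = segmented_field
        cell = next(c for c in cells if not c.touches_border)
        prof = extract_profile(blurred, cell)
        all_calls = localize_foci(blurred, cell, prof, "fish")
        top = localize_foci(blurred, cell, prof, "fish", mode="global-peak")
        if all_calls:
            assert len(top) == 1
            assert top[0].peak_intensity == max(c.peak_intensity for c in all_calls)


@pytest.mark.parametrize(
    "u, halfwidth, expected",
    [
        (0.0, 0.1, "central"),
        (0.5, 0.1, "thylakoid"),
        (-0.5, 0.1, "thylakoid"),
        (0.39, 0.1, "central"),
        (0.41, 0.1, "thylakoid"),
        (0.7, 0.1, "beyond"),
        (-0.75, 0.2, "beyond"),
    ],
)
def test_classify_focus(u, halfwidth, expected):
    assert classify_focus(u, halfwidth) == expected


def test_classify_focus_requires_positive_halfwidth():
    with pytest.raises(ValueError):
        classify_focus(0.0, 0.0)
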