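"""Per-cell intensity statistics: patchiness, band, polar ratio, mean."""

import numpy as np
import pytest

from cyanofish import (
    CellImage,
    SimConfig,
    mean_cell_intensity,
    membrane_band,
    patchiness,
    polar_equatorial_ratio,
    preprocess,
    segment_cells,
    simulate_field,
    thylakoid_region,
)
from cyanofish.metrics import RegionError, polar_regions
from cyanofish.segmentation import CellRecord
from cyanofish.simulate import CellPose, FocusChannel, PigmentChannel, cell_mask_from_pose

from conftest import match_cells


def square_cell(arr):
    """A CellRecord covering the whole array (synthetic unit-test geometry)."""
    mask = np.ones(arr.shape, dtype=bool)
    return CellRecord(
        label=1, mask=mask, centroid=((arr.shape[0] - 1) / 2, (arr.shape[1] - 1) / 2),
        orientation=0.0, length_um=arr.shape[0] * 0.024, width_um=arr.shape[1] * 0.024,
        pole_points=((0.0, 0.0), (float(arr.shape[0] - 1), 0.0)), touches_border=True,
    )


def noiseless_cells(seed, fish_spec, n_cells=2, psf=0.0, interior=0.0):
    cfg = SimConfig(
        n_cells=n_cells, seed=seed, psf_sigma_nm=psf, noise_gain=None,
        read_noise_sd=0.0,
        channels={"thylakoid": PigmentChannel(interior_flux_per_px=interior),
                  "fish": fish_spec},
    )
    img, truth = simulate_field(cfg)
    cells = segment_cells(img)
    return cfg, img, truth, cells


class TestPatchiness:
    def test_constant_cell_is_zero(self):
        arr = np.full((10, 10), 4.0)
        img = CellImage({"fish": arr})
        assert patchiness(img, square_cell(arr), "fish") == 0.0

    def test_single_bright_pixel_oracle(self):
        # 100 pixels, one of value 10: SD(ddof=1) = 1, sum = 10 -> 0.1
        # (frozen from a direct evaluation of the formula on the vector)
        arr = np.zeros((10, 10))
        arr[0, 0] = 10.0
        img = CellImage({"fish": arr})
        assert patchiness(img, square_cell(arr), "fish") == pytest.approx(0.1)

    def test_concentration_increases_patchiness(self):
        # same total signal in 2 foci vs 10 foci: fewer foci -> patchier
        total = 6.0e5
        vals = {}
        for n in (10, 2):
            spec = FocusChannel(n_foci=n, flux_median=total / n, flux_sigma_log=0.0,
                                background_per_px=0.0, position_model="uniform",
                                min_focus_separation_px=10.0)
            cfg, img, truth, cells = noiseless_cells(31, spec, n_cells=1, psf=50.0)
            assert len(truth.foci) == n  # all foci must actually render
            vals[n] = patchiness(img, cells[0], "fish")
        assert vals[2] > vals[10]

    def test_scale_invariance_and_permutation(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(1, 9, (8, 8))
        img = CellImage({"fish": arr})
        cell = square_cell(arr)
        p = patchiness(img, cell, "fish")
        img2 = CellImage({"fish": 7.0 * arr})
        assert patchiness(img2, cell, "fish") == pytest.approx(p, rel=1e-12)
        shuffled = arr.ravel().copy()
        rng.shuffle(shuffled)
        img3 = CellImage({"fish": shuffled.reshape(arr.shape)})
        assert patchiness(img3, cell, "fish") == pytest.approx(p, rel=1e-12)

    def test_zero_total_errors(self):
        arr = np.zeros((5, 5))
        with pytest.raises(ValueError):
            patchiness(CellImage({"fish": arr}), square_cell(arr), "fish")


class TestMeanCellIntensity:
    def test_constant_and_mixture(self):
        arr = np.full((6, 6), 3.0)
        img = CellImage({"fish": arr})
        assert mean_cell_intensity(img, square_cell(arr), "fish") == 3.0
        arr2 = np.zeros((6, 6))
        arr2[:3] = 8.0
        img2 = CellImage({"fish": arr2})
        assert mean_cell_intensity(img2, square_cell(arr2), "fish") == 4.0

    def test_matches_rendered_flux(self):
        spec = FocusChannel(n_foci=2, background_per_px=0.0)
        cfg, img, truth, cells = noiseless_cells(33, spec, n_cells=1)
        cell = cells[0]
        # noiseless mean inside the true cell envelope tracks flux / area
        expected = img.channel("fish")[cell.mask].sum() / cell.area_px
        assert mean_cell_intensity(img, cell, "fish") == pytest.approx(expected)


class TestMembraneBand:
    def test_band_geometry(self):
        # 0.2 um at 24 nm pixels -> 8-px-thick band, disjoint from the region
        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 28:36] = True
        arr = np.ones((64, 64))
        img = CellImage({"fish": arr})
        cell = square_cell(arr)
        _, frac = membrane_band(img, cell, mask, "fish")
        from scipy import ndimage as ndi

        dist = ndi.distance_transform_edt(~mask)
        band = (dist > 0) & (dist <= 8)
        assert frac == pytest.approx(arr[band].sum() / arr.sum())
        assert not (band & mask).any()
        assert dist[band].max() <= 8

    def test_zero_outside_region_gives_zero_fraction(self):
        spec = FocusChannel(n_foci=0, background_per_px=0.0)
        cfg, img, truth, cells = noiseless_cells(35, FocusChannel(
            n_foci=2, background_per_px=0.0, position_model=("fixed", 0.5)),
            n_cells=1)
        cell = cells[0]
        tm = thylakoid_region(img, cell)
        img.channels["fish"] = np.where(tm, img.channel("fish"), 0.0)
        _, frac = membrane_band(img, cell, tm, "fish")
        assert frac == 0.0

    def test_ground_truth_fraction_recovered(self):
        # blur-free, noiseless: measured band fraction matches the true
        # fraction of focus flux placed beyond the thylakoid shell
        spec = FocusChannel(
            n_foci=6, background_per_px=0.0, focus_sigma_nm=30.0,
            position_model=("mixture", 0.4, ("uniform_abs", 0.63, 0.68), "central"),
        )
        cfg, img, truth, cells = noiseless_cells(31, spec, n_cells=6)
        matched = match_cells(cfg, truth, cells, img.shape)
        for lbl, cell in matched.items():
            tm = thylakoid_region(img, cell)
            _, frac = membrane_band(img, cell, tm, "fish")
            true_frac = truth.fractions.query(
                "cell_label == @lbl and channel == 'fish'"
            ).frac_band.iloc[0]
            assert frac == pytest.approx(true_frac, abs=0.05)

    def test_empty_region_errors(self):
        arr = np.ones((16, 16))
        img = CellImage({"fish": arr})
        with pytest.raises(RegionError):
            membrane_band(img, square_cell(arr), np.zeros((16, 16), bool), "fish")


class TestPolarEquatorial:
    def test_uniform_channel_gives_one(self):
        spec = FocusChannel(n_foci=0, background_per_px=80.0)
        cfg, img, truth, cells = noiseless_cells(41, spec, n_cells=1)
        assert polar_equatorial_ratio(img, cells[0], "fish") == pytest.approx(1.0, abs=0.1)

    def test_regions_partition_mask(self):
        spec = FocusChannel(n_foci=0, background_per_px=80.0)
        cfg, img, truth, cells = noiseless_cells(41, spec, n_cells=1)
        polar, equatorial = polar_regions(cells[0])
        assert not (polar & equatorial).any()
        assert np.array_equal(polar | equatorial, cells[0].mask)

    def test_twofold_enrichment_recovered(self):
        spec = FocusChannel(n_foci=0, background_per_px=100.0, polar_enrichment=2.0)
        cfg, img, truth, cells = noiseless_cells(42, spec, n_cells=3, psf=50.0)
        for cell in cells:
            ratio = polar_equatorial_ratio(img, cell, "fish")
            assert ratio == pytest.approx(2.0, abs=0.2)

    def test_all_signal_in_caps_diverges(self):
        spec = FocusChannel(n_foci=0, background_per_px=80.0)
        cfg, img, truth, cells = noiseless_cells(43, spec, n_cells=1)
        cell = cells[0]
        polar, equatorial = polar_regions(cell)
        img.channels["fish"] = np.where(polar, 50.0, 0.0)
        assert polar_equatorial_ratio(img, cell, "fish") == np.inf

    def test_bad_cap_fraction(self):
        spec = FocusChannel(n_foci=0, background_per_px=80.0)
        cfg, img, truth, cells = noiseless_cells(44, spec, n_cells=1)
        with pytest.raises(ValueError):
            polar_equatorial_ratio(img, cells[0], "fish", polar_cap_fraction=0.6)
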