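import logging

import numpy as np
import pytest

from cyanofish import SimConfig, preprocess, segment_cells, simulate_field
from cyanofish.simulate import CellPose, cell_mask_from_pose

logging.getLogger("cyanofish").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_field():
    """One default simulated field (seed 1) with its ground truth."""
    cfg = SimConfig(seed=1)
    image, truth = simulate_field(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def segmented_field(default_field):
    cfg, image, truth = default_field
    blurred = preprocess(image)
    cells = segment_cells(blurred)
    return cfg, blurred, truth, cells


def true_masks(cfg, truth, shape):
    """Ground-truth spherocylinder masks keyed by cell label."""
    out = {}
    for _, row in truth.cells.iterrows():
        pose = CellPose(
            int(row.label), (row.row, row.col), row.theta, row.length_um, row.width_um
        )
        out[int(row.label)] = cell_mask_from_pose(pose, shape, cfg.pixel_size_nm)
    return out


def match_cells(cfg, truth, cells, shape):
    """Map truth label -> best-overlap CellRecord."""
    masks = true_masks(cfg, truth, shape)
    return {
        lbl: max(cells, key=lambda c: int((c.mask & tmask).sum()))
        for lbl, tmask in masks.items()
    }


def angular_difference(a: float, b: float) -> float:
    """Smallest angle between two axial (mod pi) orientations, radians."""
    return abs((a - b + np.pi / 2) % np.pi - np.pi / 2)
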