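"""Shared fixtures: small simulated plates and rendered wells."""

from __future__ import annotations

import numpy as np
import pytest

from orgscreen.config import DrugSpec, SimulationConfig, make_plate_map
from orgscreen.synthetic import render_well_stack, simulate_plate


@pytest.fixture(scope="session")
def vehicle_plate():
    """Four vehicle wells, 96x96 field, two frames: cheap render source."""
    cfg = SimulationConfig(
        seed=7, image_size_px=(96, 96), seeding_density=4, n_timepoints=2,
        init_area_um2=2000.0, plate_format=96,
    )
    pmap = make_plate_map(4, 0, [], plate_format=96)
    truth = simulate_plate(cfg, pmap)
    return cfg, pmap, truth


@pytest.fixture(scope="session")
def rendered_well(vehicle_plate):
    cfg, pmap, truth = vehicle_plate
    images, tmasks = render_well_stack(truth, "A01")
    return cfg, truth, images, tmasks


@pytest.fixture(scope="session")
def titration_plate():
    """Cytotoxic 10-point titration with controls, 5 frames, 160 px field."""
    spec = DrugSpec(
        "drugA", tuple(np.logspace(-8.5, -4, 10)), ec50_true=1e-6,
        hill_true=1.0, mode="cytotoxic",
    )
    cfg = SimulationConfig(
        seed=3, image_size_px=(160, 160), seeding_density=8, n_timepoints=5,
        drug_panel=(spec,),
    )
    pmap = make_plate_map(3, 3, [spec], replicates=1)
    truth = simulate_plate(cfg, pmap)
    return cfg, pmap, truth, spec


@pytest.fixture(scope="session")
def training_pairs():
    """50 (brightfield, fluorescence ground truth) pairs for network training."""
    from orgscreen.segmentation import fluorescence_ground_truth

    cfg = SimulationConfig(
        seed=7, image_size_px=(96, 96), seeding_density=4, n_timepoints=2,
        init_area_um2=2000.0, plate_format=96,
    )
    pmap = make_plate_map(25, 0, [], plate_format=96)
    truth = simulate_plate(cfg, pmap)
    pairs = []
    for well in pmap.wells:
        images, _ = render_well_stack(truth, well)
        for t in range(images.n_frames):
            gt = fluorescence_ground_truth(images.blue[t], images.green[t])
            pairs.append((images.bf[t], gt))
    return pairs


@pytest.fixture(scope="session")
def trained_model(training_pairs):
    from orgscreen.fcn import train_seg_model

    return train_seg_model(training_pairs, epochs=8, seed=0)
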