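import numpy as np
import pandas as pd
import pytest

import simscape as sc
import simscape.synthetic as syn


@pytest.fixture(scope="session")
def ref_ions():
    return sc.load_reference_ions()


@pytest.fixture(scope="session")
def ref_frame():
    """Bundled panel with published means, fold changes, trends and q."""
    return syn.reference_table()


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down geometry (32x32 px) with two animals per group."""
    return sc.StudyDesign(
        image_width_px=32, image_height_px=32, seed=11,
        animals_per_group={"LEAN": 2, "P1": 2, "P2": 2},
    )


@pytest.fixture(scope="session")
def noise_off():
    return sc.NoiseModel(tic_cv=0, texture_cv=0, counting_noise=False)


@pytest.fixture(scope="session")
def noise_free_table(ref_ions, small_design, noise_off):
    """Animal-level peak table from a fully deterministic study."""
    table, _ = sc.images_to_peak_table(
        sc.iter_study(small_design, ref_ions, noise_off, animal_cv=0.0),
        ref_ions,
    )
    return sc.aggregate_replicates(table)


@pytest.fixture(scope="session")
def noisy_table(ref_ions):
    """Animal-level peak table from one default-noise 32x32 study."""
    design = sc.StudyDesign(image_width_px=32, image_height_px=32, seed=0)
    table, _ = sc.images_to_peak_table(
        sc.iter_study(design, ref_ions), ref_ions
    )
    return sc.aggregate_replicates(table)


@pytest.fixture
def tiny_table():
    """Hand-built two-ion peak table for unit tests."""
    meta = pd.DataFrame({
        "sample_id": ["a1", "a2", "b1", "b2", "c1", "c2"],
        "group": ["LEAN", "LEAN", "P1", "P1", "P2", "P2"],
        "animal": ["a1", "a2", "b1", "b2", "c1", "c2"],
    }).set_index("sample_id")
    values = pd.DataFrame(
        {
            100.0: [1e-3, 1.2e-3, 2e-3, 2.2e-3, 1.5e-3, 1.6e-3],
            200.0: [3e-3, 3.1e-3, 1e-3, 1.1e-3, 2e-3, 2.1e-3],
        },
        index=meta.index,
    )
    ions = pd.DataFrame(
        {"mz": [100.0, 200.0],
         "annotation": ["amino ion", "lipid ion"],
         "ion_class": ["amino_acid", "lipid"]},
    ).set_index("mz")
    return sc.PeakTable(meta=meta, values=values, ions=ions)
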