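import numpy as np
import pandas as pd
import pytest

import glomkit as gk
from glomkit.io import GLOM_INDEX_COLUMNS, write_label_mask, write_table
from glomkit.types import CELL_COLUMNS


@pytest.fixture(scope="session")
def small_glomerulus() -> gk.LabeledGlomerulus:
    spec = gk.GlomerulusSpec(
        lesion_type="NOA", tuft_radius_px=40, mesangial_fraction_target=0.25,
        cell_counts={"mesangial": 20, "endothelial": 20, "podocyte": 20},
    )
    return gk.generate_glomerulus(spec, seed=123)


@pytest.fixture(scope="session")
def big_cohort() -> gk.Cohort:
    """500-patient cohort shared by monotonicity / trend tests."""
    return gk.generate_cohort(gk.CohortSpec(n_patients=500, seed=101))


@pytest.fixture(scope="session")
def pipeline_dataset(tmp_path_factory):
    """A small simulated image dataset laid out for run_pipeline."""
    data = tmp_path_factory.mktemp("pipeline_data")
    cohort = gk.generate_cohort(gk.CohortSpec(n_patients=15, seed=3))
    ss = np.random.SeedSequence(42)
    idx, cells = [], []
    children = ss.spawn(len(cohort.patients))
    for (_, row), child in zip(cohort.patients.iterrows(), children):
        gloms = gk.generate_patient_glomeruli(
            row.true_class, 8, int(child.generate_state(1)[0]), tuft_radius_px=30,
        )
        for j, g in enumerate(gloms):
            gid = f"G{j:03d}"
            fname = f"{row.patient_id}_{gid}.png"
            write_label_mask(data / fname, g.mask)
            idx.append((row.patient_id, gid, g.lesion_type, fname, g.pixel_size_um))
            for _, c in g.cells.iterrows():
                cells.append((row.patient_id, gid, c.cell_type, c.row, c.col))
    write_table(data / "glomeruli.csv", pd.DataFrame(idx, columns=list(GLOM_INDEX_COLUMNS)))
    write_table(data / "cells.csv",
                pd.DataFrame(cells, columns=["patient_id", "glom_id", *CELL_COLUMNS]))
    write_table(data / "classes.csv",
                cohort.patients[["patient_id", "true_class"]]
                .rename(columns={"true_class": "rps_class"}))
    write_table(data / "visits.csv", cohort.visits)
    return data
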