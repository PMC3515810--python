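import numpy as np
import pandas as pd
import pytest

import translocscreen as ts


@pytest.fixture(scope="session")
def small_acq():
    return ts.AcquisitionSpec(field_width_px=192, field_height_px=192,
                              fields_per_well=1)


@pytest.fixture(scope="session")
def noiseless():
    return ts.NoiseModel.noiseless()


@pytest.fixture
def sample_entry():
    return ts.WellSpec("B02", 1, 1, "S01", "sample", 100.0, "S01")


def make_wells_frame(group_values: dict[str, list[float]],
                     classes: dict[str, str] | None = None,
                     doses: dict[str, float] | None = None) -> pd.DataFrame:
    """Well-summary frame from per-group value lists (vehicle = 'DMSO')."""
    classes = classes or {}
    doses = doses or {}
    rows = []
    i = 0
    for label, vals in group_values.items():
        cls = classes.get(label,
                          "vehicle" if label == "DMSO" else "sample")
        for v in vals:
            rows.append({"well_id": f"W{i:03d}", "row": i // 12, "col": i % 12,
                         "treatment_label": label, "treatment_class": cls,
                         "dose": doses.get(label, 0.0),
                         "n_cells_kept": 100, "mean_nc_ratio": v,
                         "sd": 0.1, "sem": 0.01, "usable": True,
                         "normalized_translocation": v})
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def wells_factory():
    return make_wells_frame
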