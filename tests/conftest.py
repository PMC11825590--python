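import numpy as np
import pandas as pd
import pytest

from pmprofile import builtin_layout
from pmprofile.plates import CompoundAnnotation, PlateLayout, WellAddress


@pytest.fixture(scope="session")
def layout():
    """The full builtin synthetic 8-plate layout."""
    return builtin_layout()


@pytest.fixture(scope="session")
def m8_wells(layout):
    return layout.wells_for_plate("PM-M8")


def make_summaries(values_by_sample: dict[str, np.ndarray], wells) -> pd.DataFrame:
    """Long summary table (sample_id, plate, well, value, log_value) from
    per-sample value vectors aligned with ``wells``."""
    rows = []
    for sid, vals in values_by_sample.items():
        for addr, v in zip(wells, np.asarray(vals, float)):
            rows.append(
                {"sample_id": sid, "plate": addr.plate, "well": addr.well, "value": 10.0**v, "log_value": v}
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_layout():
    """Four-well partial layout with one concentration series."""
    entries = {
        WellAddress("PM-M5", "A02"): CompoundAnnotation("Sodium chloride", "ion", "S1", 2),
        WellAddress("PM-M5", "A03"): CompoundAnnotation("Sodium chloride", "ion", "S1", 1),
        WellAddress("PM-M5", "A04"): CompoundAnnotation("Sodium chloride", "ion", "S1", 3),
        WellAddress("PM-M2", "H02"): CompoundAnnotation("Glu-Trp", "dipeptide"),
    }
    return PlateLayout(entries)
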