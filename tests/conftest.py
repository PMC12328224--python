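import numpy as np
import pandas as pd
import pytest

from mechanotypes.data_model import MEASUREMENT_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """A minimal valid measurement table: 2 pairs x 3 cells of area."""
    rows = []
    for line, sub, vals in [
        ("A1", "Glass", (100.0, 200.0, 300.0)),
        ("B2", "500Pa_Coll", (50.0, 60.0, 70.0)),
    ]:
        for i, v in enumerate(vals):
            rows.append((line, sub, "area", f"c{i}", v))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


@pytest.fixture
def tiny_meta_csv(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text(
        "cell_line,tissue,malignant\n"
        "A1,breast,true\n"
        "B2,breast,false\n"
        "C3,lung,true\n"
    )
    return p
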