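"""Substrate-sensitivity ratios and cancer-vs-normal contrasts.

Builds a small synthetic panel in which one cell line doubles its area
median when the substrate stiffens from 500 Pa to 30 kPa while a second
line is insensitive, plus a same-tissue cancer/normal pair differing on
glass.  Reports median ratios across the 11 substrate alterations with
two-sided permutation p-values (BH-adjusted within feature x alteration
panels) and the within-substrate median-difference contrasts.

Run from the repository root:  python analysis/06_sensitivity.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mechanotypes.data_model import MEASUREMENT_COLUMNS, CellLineMeta
from mechanotypes.sensitivity import cancer_vs_normal_table, substrate_sensitivity_table
from mechanotypes.synthetic import ClassSpec

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)
rng = np.random.default_rng(SEED)

def pair_rows(line, substrate, median, n=40, sigma=0.3):
    cls = ClassSpec(0, "lognormal", (np.log(median), sigma))
    return [(line, substrate, "area", f"c{i}", v)
            for i, v in enumerate(cls.sample(n, rng))]

rows = []
# RESP doubles its median on stiff substrate; FLAT does not
for sub, med in [("500Pa_Coll", 300.0), ("30kPa_Coll", 600.0), ("Glass", 650.0)]:
    rows += pair_rows("RESP", sub, med)
for sub in ("500Pa_Coll", "30kPa_Coll", "Glass"):
    rows += pair_rows("FLAT", sub, 400.0)
# same-tissue cancer/normal pair measured on glass
rows += pair_rows("TUM", "Glass", 250.0)
rows += pair_rows("NORM", "Glass", 520.0)
table = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))

sens = substrate_sensitivity_table(table, ["area"], min_n=25, n_perm=10000, seed=SEED)
sens.to_csv(OUT / "substrate_sensitivity.csv", index=False)
print("substrate alterations with n >= 25 on both substrates:")
cols = ["cell_line", "alteration", "ratio", "p_raw", "p_adj", "stars"]
print(sens[cols].round(4).to_string(index=False))

meta = {
    "TUM": CellLineMeta("TUM", "pancreas", True),
    "NORM": CellLineMeta("NORM", "pancreas", False),
    "RESP": CellLineMeta("RESP", "breast", True),
    "FLAT": CellLineMeta("FLAT", "breast", True),
}
cvn = cancer_vs_normal_table(table, meta, ["area"], min_n=25, n_perm=10000, seed=SEED)
cvn.to_csv(OUT / "cancer_vs_normal.csv", index=False)
print("\nwithin-substrate cancer vs normal (same tissue):")
print(cvn[["cancer_line", "normal_line", "substrate", "median_diff",
           "p_adj", "stars"]].round(4).to_string(index=False))
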