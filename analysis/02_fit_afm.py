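"""Fit the Hertz sphere model to the simulated force curves.

Raw curves carry a 150-nm pre-contact baseline: the contact point is located
by the two-segment residual search, the curve is re-referenced, and Young's
modulus is fit closed-form over the first 500 nm of indentation.  Each
indentation site becomes one stiffness record.

Run after 01_simulate.py:  python analysis/02_fit_afm.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mechanotypes.afm import (
    aggregate_stiffness,
    align_at_contact,
    curves_from_frame,
    detect_contact_point,
    fit_hertz,
)

DATA = Path("results/data")
samples = pd.read_csv(DATA / "force_curves.csv")
sidecar = pd.read_csv(DATA / "force_curves_probes.csv")
curves = curves_from_frame(samples, sidecar)

rows = []
for line in sorted({c.cell_id.split("_")[0] for c in curves}):
    fits = []
    for c in (c for c in curves if c.cell_id.startswith(line)):
        aligned = align_at_contact(c, detect_contact_point(c))
        fits.append(fit_hertz(aligned, poisson=0.5, window_nm=500.0))
    substrate = "Glass" if line.endswith("0") else "30kPa_Coll"
    stiff = aggregate_stiffness(fits, line, substrate)
    rows.append(stiff)
    print(
        f"{line}: {len(stiff)} indentations, median E = "
        f"{np.median(stiff['value']):.0f} Pa (per-site values kept separate)"
    )

out = pd.concat(rows, ignore_index=True)
out.to_csv(DATA / "measurements_stiffness.csv", index=False)
print(f"wrote {len(out)} stiffness records")
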