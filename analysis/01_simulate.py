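"""Simulate every input of the mechanophenotyping study at desk scale.

Generates (i) a single-cell area table with four planted mechanotype
classes, (ii) the heavy-tailed outlier variant used for the W1-vs-KS
contrast, (iii) persistent-random-walk trajectories for three motility
conditions, and (iv) Hertz force curves (10 cells x 3 sites) for two
stiffness conditions.  Everything is seeded and lands under results/data/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import json
import sys
from pathlib import Path

import pandas as pd

from mechanotypes.afm import curves_to_frame
from mechanotypes.synthetic import (
    CurveSpec,
    WalkSpec,
    default_area_design,
    outlier_contrast_design,
    simulate_force_curve,
    simulate_measurements,
    simulate_trajectories,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

# planted 4-class area table
table, labels = simulate_measurements(default_area_design(seed=SEED))
table.to_csv(OUT / "measurements_area.csv", index=False)
json.dump(
    {f"{l}|{s}": c for (l, s), c in labels.items()},
    open(OUT / "planted_labels_area.json", "w"), indent=2,
)
print(f"area table: {len(table)} cells, {len(labels)} pairs, 4 planted classes")

# outlier-contrast variant
otable, olabels = simulate_measurements(outlier_contrast_design(seed=SEED))
otable.to_csv(OUT / "measurements_outlier.csv", index=False)
json.dump(
    {f"{l}|{s}": c for (l, s), c in olabels.items()},
    open(OUT / "planted_labels_outlier.json", "w"), indent=2,
)
print(f"outlier table: {len(olabels)} pairs (one heavy-tailed outlier pair)")

# trajectories: persistent, intermediate, and erratic walkers
walks = [
    WalkSpec(mean_speed=0.9, turn_sd=0.3, n_tracks=40, duration=180.0,
             cell_line="SYNW0", substrate="Glass", seed=SEED),
    WalkSpec(mean_speed=0.5, turn_sd=0.8, n_tracks=40, duration=180.0,
             cell_line="SYNW1", substrate="30kPa_Coll", seed=SEED + 1),
    WalkSpec(mean_speed=0.3, turn_sd=1.6, n_tracks=40, duration=120.0,
             cell_line="SYNW2", substrate="500Pa_Coll", seed=SEED + 2),
]
traj = pd.concat([simulate_trajectories(w) for w in walks], ignore_index=True)
traj.to_csv(OUT / "trajectories.csv", index=False)
n_tracks = traj.groupby(["cell_line", "track_id"]).ngroups
print(f"trajectories: {n_tracks} tracks over {len(walks)} conditions "
      f"(5-min interval, 2-3 h)")

# force curves: 2 conditions x 10 cells x 3 indentation sites
curves = []
for cond, (line, E) in enumerate({"SYNA0": 800.0, "SYNA1": 2400.0}.items()):
    for cell in range(10):
        for loc in range(3):
            s = SEED * 1000 + cond * 100 + cell * 3 + loc
            curves.append(
                simulate_force_curve(
                    CurveSpec(E_true=E, noise_sd=2e-11, contact_offset=150.0, seed=s),
                    curve_id=f"{line}_c{cell}_l{loc}",
                    cell_id=f"{line}_c{cell}",
                    location_id=f"l{loc}",
                )
            )
samples, sidecar = curves_to_frame(curves)
samples.to_csv(OUT / "force_curves.csv", index=False)
sidecar.to_csv(OUT / "force_curves_probes.csv", index=False)
print(f"force curves: {len(curves)} (true E = 800 and 2400 Pa)")
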