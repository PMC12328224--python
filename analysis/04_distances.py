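"""Pairwise distribution distances between cell line-substrate pairs.

Builds eligible pair samples (n >= 25 cells) for the planted area table and
the outlier variant, then computes full Wasserstein-1 and KS distance
matrices.  The printed summary contrasts the scales of the two metrics —
KS is bounded by 1 while W1 grows with how far apart the distributions are.

Run after 01_simulate.py:  python analysis/04_distances.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mechanotypes.data_model import extract_pair_samples
from mechanotypes.distances import pairwise_distances

DATA = Path("results/data")
OUT = Path("results")

for stem in ("area", "outlier"):
    table = pd.read_csv(DATA / f"measurements_{stem}.csv")
    samples = extract_pair_samples(table, "area", min_n=25)
    for metric in ("wasserstein1", "ks"):
        dm = pairwise_distances(samples, metric=metric)
        dm.to_frame().to_csv(OUT / f"distances_{stem}_{metric}.csv")
        off = dm.D[np.triu_indices(dm.n, 1)]
        print(
            f"{stem}/{metric}: {dm.n} pairs, distances "
            f"median {np.median(off):.3g}, max {off.max():.3g}"
        )
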