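"""Consensus clustering of distance matrices into mechanotype classes.

Two analyses: (i) recovery of the four planted area classes from the W1
matrix — PAC/CHI select k, average-linkage of 1-M assigns classes, item
consensus flags boundary cases; (ii) the outlier contrast — the same
pipeline run on W1 and on KS distances for the heavy-tailed-outlier design,
showing that W1 isolates the outlier pair as its own class while the
bounded KS metric folds it into a bulk class.

Run after 01_simulate.py:  python analysis/05_mechanotypes.py [seed]
"""

import json
import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from mechanotypes.consensus import ClusteringConfig, discover_mechanotypes, mechanotype_report
from mechanotypes.data_model import extract_pair_samples
from mechanotypes.distances import pairwise_distances

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/data")
OUT = Path("results")
CFG = ClusteringConfig(k_range=tuple(range(2, 10)), subsample_rate=0.8,
                       n_reps=200, seed=SEED)

# --- planted-class recovery on W1 ----------------------------------------
table = pd.read_csv(DATA / "measurements_area.csv")
labels = {tuple(k.split("|")): v
          for k, v in json.load(open(DATA / "planted_labels_area.json")).items()}
samples = extract_pair_samples(table, "area", min_n=25)
dm = pairwise_distances(samples, metric="wasserstein1")
res = discover_mechanotypes(dm, CFG)
res.selection.per_k.to_csv(OUT / "model_selection_area.csv", index=False)
report, kdes = mechanotype_report(res.membership, samples)
report.to_csv(OUT / "membership_area.csv", index=False)
kde_frames = [
    pd.DataFrame({"grid": kde.grid, "density": kde.density, "class_id": cls})
    for cls, kde in kdes.items()
]
pd.concat(kde_frames, ignore_index=True).to_csv(OUT / "class_kde_area.csv", index=False)

planted = [labels[p] for p in res.membership.labels]
ari = adjusted_rand_score(planted, res.membership.assigned)
print(f"planted area classes: selected k = {res.selection.k_optimal}, "
      f"ARI vs planted = {ari:.3f}, "
      f"boundary cases = {int(res.membership.is_boundary.sum())}")
print(res.selection.per_k.round(4).to_string(index=False))

# --- W1 vs KS on the heavy-tailed outlier design -------------------------
otable = pd.read_csv(DATA / "measurements_outlier.csv")
olabels = {tuple(k.split("|")): v
           for k, v in json.load(open(DATA / "planted_labels_outlier.json")).items()}
out_pair = next(p for p, c in olabels.items() if c == 99)
osamples = extract_pair_samples(otable, "area", min_n=25)
for metric in ("wasserstein1", "ks"):
    dmo = pairwise_distances(osamples, metric=metric)
    reso = discover_mechanotypes(dmo, CFG)
    reso.membership.to_frame().to_csv(OUT / f"membership_outlier_{metric}.csv", index=False)
    i = reso.membership.labels.index(out_pair)
    mates = int((reso.membership.assigned == reso.membership.assigned[i]).sum())
    verdict = "isolated as its own class" if mates == 1 else \
        f"merged into a class of {mates} pairs"
    print(f"outlier design / {metric}: k = {reso.selection.k_optimal}, "
          f"outlier pair {verdict}")
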