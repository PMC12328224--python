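"""Consensus clustering of distribution distances into mechanotypes.

A *mechanotype* is a phenotypic class of cell line-substrate pairs whose
single-feature value distributions resemble each other.  Classes are found
by consensus clustering: k-medoids (PAM) is run on many random subsamples of
the pairwise distance matrix, and the consensus index

    M_ij = (# subsamples where i and j clustered together)
           / (# subsamples where i and j were drawn together)

records how stably two pairs co-cluster.  The cluster count k is chosen by
the proportion of ambiguous clustering (PAC — the fraction of consensus
indices that are neither confidently together, > 0.9, nor confidently apart,
< 0.1) together with the Calinski-Harabasz pseudo-F (between-cluster
separation over within-cluster dispersion computed from squared distances):
good k has low PAC and high CHI.  Final classes come from average-linkage
agglomerative clustering of 1 - M; each pair is assigned to the class with
its highest item consensus (mean consensus with the class members), and
pairs whose best item consensus falls below 0.8 are flagged as boundary
cases straddling their top two classes.

PAM uses a deterministic BUILD + steepest-descent SWAP, so the subsample
draws are the only source of randomness and a seed reproduces every run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringConfig:
    k_range: tuple[int, ...] = tuple(range(2, 10))
    subsample_rate: float = 0.8
    n_reps: int = 1000
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    boundary_threshold: float = 0.8
    select_eps: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.subsample_rate <= 1:
            raise InputError("subsample_rate must lie in (0, 1]")
        if not self.pac_bounds[0] < self.pac_bounds[1]:
            raise InputError("pac_bounds must be (lower, upper) with lower < upper")
        if not 0 < self.boundary_threshold <= 1:
            raise InputError("boundary_threshold must lie in (0, 1]")


# ---------------------------------------------------------------------------
# PAM (partition around medoids) on a precomputed distance matrix
# ---------------------------------------------------------------------------

def pam_cluster(D: np.ndarray, n_clusters: int, seed: int | None = None):
    """PAM on a precomputed distance matrix.

    BUILD greedily seeds medoids (first medoid minimises total distance, each
    next maximises cost reduction), then SWAP applies the best
    (medoid, non-medoid) exchange until no exchange lowers the total cost.
    Fully deterministic — ties break on the lowest index — so ``seed`` is
    accepted only for interface symmetry with stochastic clusterers.

    Returns ``(labels, medoids)``: labels in 0..k-1 (label = rank of the
    owning medoid), medoid indices into D.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    k = int(n_clusters)
    if k > n:
        raise InputError(f"n_clusters={k} exceeds number of items {n}")
    if k < 1:
        raise InputError("n_clusters must be >= 1")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        d_nearest = np.minimum(d_nearest, D[c])

    medoids_arr = np.asarray(sorted(medoids))
    idx = np.arange(n)
    while True:
        dm = D[medoids_arr]                       # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        nearest = order[0]
        d1 = dm[nearest, idx]
        d2 = dm[order[1], idx] if k > 1 else np.full(n, np.inf)
        cost = d1.sum()
        non_medoids = np.setdiff1d(idx, medoids_arr, assume_unique=False)
        if non_medoids.size == 0:
            break
        best = None
        best_cost = cost
        for mi in range(k):
            d_wo = np.where(nearest == mi, d2, d1)   # distances if medoid mi removed
            cand = np.minimum(d_wo[None, :], D[non_medoids])
            cand_costs = cand.sum(axis=1)
            j = int(np.argmin(cand_costs))
            if cand_costs[j] < best_cost - 1e-12:
                best_cost = float(cand_costs[j])
                best = (mi, int(non_medoids[j]))
        if best is None:
            break
        mi, h = best
        medoids_arr = np.asarray(sorted(np.r_[np.delete(medoids_arr, mi), h]))

    dm = D[medoids_arr]
    nearest = np.argmin(dm, axis=0)
    nearest[medoids_arr] = np.arange(k)            # a medoid belongs to itself
    return nearest.astype(int), medoids_arr


# ---------------------------------------------------------------------------
# consensus matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusMatrix:
    labels: tuple[tuple[str, str], ...]
    M: np.ndarray = field(repr=False)
    cosample_counts: np.ndarray = field(repr=False)
    k: int = 0

    @property
    def n(self) -> int:
        return len(self.labels)


def consensus_run(
    D_labels: tuple[tuple[str, str], ...],
    D: np.ndarray,
    cfg: ClusteringConfig,
) -> dict[int, ConsensusMatrix]:
    """Subsampled-PAM consensus matrices for every k in ``cfg.k_range``.

    Each repetition draws ``floor(rate * n)`` items without replacement,
    clusters the induced submatrix with PAM, and accumulates co-cluster and
    co-sample counts.  Entries never co-sampled (vanishingly rare at the
    default 1000 reps x 0.8 rate) are warned about and treated as zero
    consensus.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 4:
        raise InputError("consensus clustering needs at least 4 items")
    m = int(np.floor(cfg.subsample_rate * n))
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.k_range))
    out: dict[int, ConsensusMatrix] = {}
    for child, k in zip(children, cfg.k_range):
        rng = np.random.default_rng(child)
        conn = np.zeros((n, n))
        counts = np.zeros((n, n))
        for _ in range(cfg.n_reps):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels, _ = pam_cluster(D[np.ix_(idx, idx)], k)
            eq = (labels[:, None] == labels[None, :]).astype(float)
            sub = np.ix_(idx, idx)
            conn[sub] += eq
            counts[sub] += 1.0
        never = counts == 0
        np.fill_diagonal(never, False)
        if never.any():
            warnings.warn(
                f"k={k}: {int(never.sum()) // 2} item pairs never co-sampled; "
                "their consensus is reported as 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(counts > 0, conn / np.where(counts > 0, counts, 1.0), 0.0)
        np.fill_diagonal(M, 1.0)
        out[k] = ConsensusMatrix(labels=tuple(D_labels), M=M, cosample_counts=counts, k=k)
    return out


# ---------------------------------------------------------------------------
# model selection: PAC and CHI
# ---------------------------------------------------------------------------

def pac(cm: ConsensusMatrix, bounds: tuple[float, float] = (0.1, 0.9)) -> float:
    """Proportion of ambiguous clustering: fraction of upper-triangle
    consensus indices strictly between the bounds."""
    lo, hi = bounds
    iu = np.triu_indices(cm.n, k=1)
    vals = cm.M[iu]
    return float(np.mean((vals > lo) & (vals < hi))) if vals.size else 0.0


def chi(D: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz pseudo-F from squared pairwise distances.

    W = sum_c (1 / 2 n_c) sum_{i,j in c} d_ij^2 ;  T = (1 / 2n) sum_{i,j} d_ij^2
    B = T - W ;  CHI = (B / (k-1)) / (W / (n-k)).  W = 0 (all within-cluster
    distances zero) is reported as inf.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise InputError("CHI needs >= 2 clusters")
    D2 = D**2
    W = 0.0
    for c in uniq:
        members = labels == c
        n_c = int(members.sum())
        if n_c == 0:
            raise InputError("empty cluster")
        W += D2[np.ix_(members, members)].sum() / (2.0 * n_c)
    T = D2.sum() / (2.0 * n)
    B = T - W
    if W <= 0:
        return float("inf")
    return float((B / (k - 1)) / (W / (n - k)))


@dataclass(frozen=True)
class ModelSelection:
    per_k: pd.DataFrame            # columns k, pac, chi
    k_optimal: int
    rule: str


def select_k(per_k: pd.DataFrame, eps: float = 0.02) -> ModelSelection:
    """Choose k with low PAC and high CHI.

    Among candidate k whose PAC is within ``eps`` of the minimum PAC, take
    the one with maximal CHI (smallest k on an exact CHI tie).
    """
    if len(per_k) < 2:
        raise InputError("need >= 2 candidate cluster counts")
    df = per_k.sort_values("k").reset_index(drop=True)
    min_pac = df["pac"].min()
    cand = df[df["pac"] <= min_pac + eps]
    best = cand.sort_values(["chi", "k"], ascending=[False, True]).iloc[0]
    rule = (
        f"min-PAC with CHI tie-break: candidates PAC <= {min_pac:.4f} + {eps}, "
        f"argmax CHI"
    )
    return ModelSelection(per_k=df, k_optimal=int(best["k"]), rule=rule)


# ---------------------------------------------------------------------------
# final membership and boundary handling
# ---------------------------------------------------------------------------

def hierarchical_labels(M: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomerative clustering of 1 - M cut at k clusters."""
    dist = 1.0 - np.asarray(M, dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


@dataclass(frozen=True)
class MembershipResult:
    labels: tuple[tuple[str, str], ...]
    assigned: np.ndarray                 # class id per pair, 0..k-1
    item_consensus: np.ndarray = field(repr=False)   # n x k
    is_boundary: np.ndarray = field(repr=False)
    boundary_classes: tuple          # per pair: (top, second) when boundary else None
    k: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (line, sub) in enumerate(self.labels):
            rows.append(
                {
                    "cell_line": line,
                    "substrate": sub,
                    "assigned_class": int(self.assigned[i]),
                    "item_consensus_max": float(self.item_consensus[i].max()),
                    "is_boundary": bool(self.is_boundary[i]),
                    "boundary_classes": (
                        "|".join(map(str, self.boundary_classes[i]))
                        if self.boundary_classes[i] is not None
                        else ""
                    ),
                }
            )
        return pd.DataFrame(rows)


def final_membership(cm: ConsensusMatrix, k_optimal: int, cfg: ClusteringConfig) -> MembershipResult:
    """Assign each pair to the class with its highest item consensus.

    Classes come from average-linkage clustering of 1 - M at ``k_optimal``.
    Item consensus of item i for class C is the mean of M_ij over members
    j of C other than i itself (1.0 for a singleton class containing only i).
    A pair whose best item consensus is below the boundary threshold is a
    boundary case, viewed as belonging to either of its top two classes.
    """
    M = cm.M
    n = cm.n
    base = hierarchical_labels(M, k_optimal)
    classes = np.unique(base)
    k = classes.size
    ic = np.zeros((n, k))
    for ci, c in enumerate(classes):
        members = np.flatnonzero(base == c)
        for i in range(n):
            others = members[members != i]
            ic[i, ci] = M[i, others].mean() if others.size else 1.0
    assigned_idx = np.argmax(ic, axis=1)
    best = ic[np.arange(n), assigned_idx]
    is_boundary = best < cfg.boundary_threshold
    boundary_classes = []
    for i in range(n):
        if is_boundary[i] and k >= 2:
            top2 = np.argsort(ic[i])[::-1][:2]
            boundary_classes.append((int(classes[top2[0]]), int(classes[top2[1]])))
        else:
            boundary_classes.append(None)
    return MembershipResult(
        labels=cm.labels,
        assigned=classes[assigned_idx],
        item_consensus=ic,
        is_boundary=is_boundary,
        boundary_classes=tuple(boundary_classes),
        k=k,
    )


# ---------------------------------------------------------------------------
# end-to-end mechanotype discovery for one feature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanotypeResult:
    consensus_by_k: dict
    selection: ModelSelection
    membership: MembershipResult


def discover_mechanotypes(dm, cfg: ClusteringConfig) -> MechanotypeResult:
    """Full stack: consensus matrices -> PAC/CHI -> k -> membership.

    ``dm`` is a :class:`~mechanotypes.distances.DistanceMatrix`.
    """
    consensus_by_k = consensus_run(dm.labels, dm.D, cfg)
    rows = []
    for k, cm in consensus_by_k.items():
        labels_k = hierarchical_labels(cm.M, k)
        rows.append({"k": k, "pac": pac(cm, cfg.pac_bounds), "chi": chi(dm.D, labels_k)})
    selection = select_k(pd.DataFrame(rows), eps=cfg.select_eps)
    membership = final_membership(consensus_by_k[selection.k_optimal], selection.k_optimal, cfg)
    return MechanotypeResult(
        consensus_by_k=consensus_by_k, selection=selection, membership=membership
    )


def mechanotype_report(membership: MembershipResult, samples) -> tuple[pd.DataFrame, dict]:
    """Per-pair class table plus per-class pooled KDEs.

    Boundary pairs keep their class label in the table but are excluded from
    the pooled values feeding each class KDE, so the characteristic densities
    describe confident members only.
    """
    from .distances import class_kde

    by_pair = {s.pair_id: s for s in samples}
    rows = []
    pooled: dict[int, list] = {}
    for i, pair in enumerate(membership.labels):
        s = by_pair.get(pair)
        med = float(np.median(s.values)) if s is not None else np.nan
        cls = int(membership.assigned[i])
        rows.append(
            {
                "cell_line": pair[0],
                "substrate": pair[1],
                "assigned_class": cls,
                "median": med,
                "n": s.n if s is not None else 0,
                "is_boundary": bool(membership.is_boundary[i]),
            }
        )
        if s is not None and not membership.is_boundary[i]:
            pooled.setdefault(cls, []).append(s.values)
    kdes = {
        cls: class_kde(np.concatenate(vals))
        for cls, vals in sorted(pooled.items())
        if np.unique(np.concatenate(vals)).size >= 2
    }
    return pd.DataFrame(rows), kdes
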