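"""Substrate-sensitivity ratios and permutation statistics.

Phenotypic sensitivity of a cell line to a substrate alteration is the ratio
of the median feature values on the two substrates (e.g. 30 kPa Coll / 500 Pa
Coll).  Eleven named alterations cover stiffness changes, hyaluronic-acid
substitution, ligand swaps and the jump to glass.  Significance of a ratio
differing from 1 (or, for within-substrate cancer-vs-normal contrasts, of a
median difference from 0) is assessed with a two-sided permutation test on
the pooled single-cell values, and p-values are Benjamini-Hochberg adjusted
within presentation families (one family per feature x alteration panel by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import PairSample
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Alteration:
    """A named substrate change: ratio = median(numerator) / median(denominator)."""

    name: str
    numerator_substrate: str
    denominator_substrate: str


#: The 11 substrate alterations considered.
ALTERATIONS: tuple[Alteration, ...] = (
    Alteration("30k-500Pa Coll", "30kPa_Coll", "500Pa_Coll"),
    Alteration("30k-500Pa FN", "30kPa_FN", "500Pa_FN"),
    Alteration("HA-500Pa Coll", "HA_Coll", "500Pa_Coll"),
    Alteration("HA-500Pa FN", "HA_FN", "500Pa_FN"),
    Alteration("HA Coll-FN", "HA_Coll", "HA_FN"),
    Alteration("500Pa Coll-FN", "500Pa_Coll", "500Pa_FN"),
    Alteration("30kPa Coll-FN", "30kPa_Coll", "30kPa_FN"),
    Alteration("30kPa-HA Coll", "30kPa_Coll", "HA_Coll"),
    Alteration("30kPa-HA FN", "30kPa_FN", "HA_FN"),
    Alteration("Glass-30kPa Coll", "Glass", "30kPa_Coll"),
    Alteration("Glass-30kPa FN", "Glass", "30kPa_FN"),
)


def median_ratio(numerator: PairSample, denominator: PairSample) -> float:
    """Ratio of sample medians; the substrate-sensitivity measure."""
    num = float(np.median(numerator.values))
    den = float(np.median(denominator.values))
    if den == 0:
        raise InputError("denominator median is zero; ratio undefined")
    return num / den


def _permutation_p(x, y, statistic, n_perm: int, rng: np.random.Generator) -> float:
    """Generic two-sided permutation p with the plus-one correction.

    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm); never exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_obs = statistic(x, y)
    # sorting makes the permutation schedule depend only on the pooled
    # multiset, so p(x, y) == p(y, x) for equal group sizes under one seed
    pooled = np.sort(np.concatenate([x, y]))
    nx = x.size
    perms = np.tile(pooled, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    mx = np.median(perms[:, :nx], axis=1)
    my = np.median(perms[:, nx:], axis=1)
    t_perm = statistic.from_medians(mx, my)
    return float((1 + np.sum(t_perm >= t_obs - 1e-15)) / (1 + n_perm))


class _RatioStat:
    """|log median ratio|; falls back to |median difference| when a median
    is non-positive (log undefined)."""

    def __init__(self):
        self.fallback = False

    def __call__(self, x, y):
        mx, my = np.median(x), np.median(y)
        if mx <= 0 or my <= 0:
            self.fallback = True
            logger.warning("non-positive median; using |median difference| statistic")
            return abs(mx - my)
        return abs(np.log(mx / my))

    def from_medians(self, mx, my):
        if self.fallback:
            return np.abs(mx - my)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.abs(np.log(mx / my))
        # permuted medians can be non-positive even when observed ones are not
        bad = ~np.isfinite(out)
        if bad.any():
            out[bad] = np.inf
        return out


class _DiffStat:
    def __call__(self, x, y):
        return abs(np.median(x) - np.median(y))

    def from_medians(self, mx, my):
        return np.abs(mx - my)


def permutation_test_ratio(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation test of the median ratio differing from 1.

    The statistic is |log(median(x) / median(y))|, symmetric in direction, so
    ratios above and below 1 are treated alike.  Labels are permuted over the
    pooled sample preserving group sizes.
    """
    if len(x) == 0 or len(y) == 0:
        raise InputError("samples must be non-empty")
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    return _permutation_p(x, y, _RatioStat(), n_perm, rng)


def permutation_test_diff(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation test of the median difference from 0."""
    if len(x) == 0 or len(y) == 0:
        raise InputError("samples must be non-empty")
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    return _permutation_p(x, y, _DiffStat(), n_perm, rng)


def adjust_bh(p_values: pd.Series | np.ndarray, family: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, applied within each family."""
    p = np.asarray(p_values, dtype=float)
    out = np.empty_like(p)
    fam = np.zeros(p.size) if family is None else np.asarray(family)
    for f in np.unique(fam):
        m = fam == f
        out[m] = multipletests(p[m], method="fdr_bh")[1]
    return out


def significance_stars(p_adj: float) -> str:
    """Star marks: '***' p<0.01, '**' p<0.05, '*' p<0.1, '' otherwise."""
    if p_adj < 0.01:
        return "***"
    if p_adj < 0.05:
        return "**"
    if p_adj < 0.1:
        return "*"
    return ""


def substrate_sensitivity_table(
    table: pd.DataFrame,
    features: list[str],
    min_n: int = 25,
    n_perm: int = 10000,
    seed: int = 0,
    alterations: tuple[Alteration, ...] = ALTERATIONS,
) -> pd.DataFrame:
    """Per-(cell line, alteration, feature) sensitivity ratios with p-values.

    A ratio is computed only when both substrates carry at least ``min_n``
    measurements of the feature for that cell line; other combinations are
    skipped and logged.  BH families are (feature, alteration) panels.
    """
    from .data_model import extract_pair_samples

    ss = np.random.SeedSequence(seed)
    rows = []
    for feature in features:
        samples = {s.pair_id: s for s in extract_pair_samples(table, feature, min_n=min_n)}
        lines = sorted({line for line, _ in samples})
        for alt in alterations:
            for line in lines:
                num = samples.get((line, alt.numerator_substrate))
                den = samples.get((line, alt.denominator_substrate))
                if num is None or den is None:
                    logger.info(
                        "skipping %s / %s / %s: n < %d on at least one substrate",
                        line, feature, alt.name, min_n,
                    )
                    continue
                sub_seed = int(ss.generate_state(1)[0] % (2**31))
                ss = ss.spawn(1)[0]
                p = permutation_test_ratio(num.values, den.values, n_perm=n_perm, seed=sub_seed)
                rows.append(
                    {
                        "cell_line": line,
                        "feature": feature,
                        "alteration": alt.name,
                        "ratio": median_ratio(num, den),
                        "n_num": num.n,
                        "n_den": den.n,
                        "p_raw": p,
                        "family_id": f"{feature}|{alt.name}",
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_bh(out["p_raw"].to_numpy(), out["family_id"].to_numpy())
        out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out


def cancer_vs_normal_table(
    table: pd.DataFrame,
    meta: dict,
    features: list[str],
    min_n: int = 25,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-substrate contrasts of every cancer line against every normal
    line of the same tissue, as median differences with permutation p-values.

    BH families are (feature, substrate, tissue) panels.
    """
    from .data_model import extract_pair_samples

    normals = {m.name: m for m in meta.values() if not m.malignant}
    cancers = {m.name: m for m in meta.values() if m.malignant}
    ss = np.random.SeedSequence(seed)
    rows = []
    for feature in features:
        samples = {s.pair_id: s for s in extract_pair_samples(table, feature, min_n=min_n)}
        for nname, nmeta in sorted(normals.items()):
            for cname, cmeta in sorted(cancers.items()):
                if cmeta.tissue != nmeta.tissue:
                    continue
                for substrate in sorted({sub for _, sub in samples}):
                    cs = samples.get((cname, substrate))
                    ns = samples.get((nname, substrate))
                    if cs is None or ns is None:
                        continue
                    sub_seed = int(ss.generate_state(1)[0] % (2**31))
                    ss = ss.spawn(1)[0]
                    p = permutation_test_diff(cs.values, ns.values, n_perm=n_perm, seed=sub_seed)
                    rows.append(
                        {
                            "cancer_line": cname,
                            "normal_line": nname,
                            "tissue": cmeta.tissue,
                            "substrate": substrate,
                            "feature": feature,
                            "median_diff": float(np.median(cs.values) - np.median(ns.values)),
                            "p_raw": p,
                            "family_id": f"{feature}|{substrate}|{cmeta.tissue}",
                        }
                    )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = adjust_bh(out["p_raw"].to_numpy(), out["family_id"].to_numpy())
        out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out
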