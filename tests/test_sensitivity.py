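"""Median ratios, permutation tests and Benjamini-Hochberg adjustment."""

import numpy as np
import pandas as pd
import pytest

from mechanotypes.data_model import MEASUREMENT_COLUMNS, PairSample
from mechanotypes.errors import InputError
from mechanotypes.sensitivity import (
    ALTERATIONS,
    adjust_bh,
    cancer_vs_normal_table,
    median_ratio,
    permutation_test_diff,
    permutation_test_ratio,
    significance_stars,
    substrate_sensitivity_table,
)


def bh_oracle(p):
    """Textbook step-up BH: p_(i) * m / i with running minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def sample(line, sub, values):
    return PairSample(line, sub, "area", np.asarray(values, dtype=float))


class TestMedianRatio:
    def test_basic_ratio(self):
        num = sample("A", "30kPa_Coll", [150.0, 200.0, 250.0])
        den = sample("A", "500Pa_Coll", [90.0, 100.0, 110.0])
        assert median_ratio(num, den) == pytest.approx(2.0)

    def test_identical_samples_unity(self):
        s = sample("A", "Glass", [1.0, 2.0, 3.0])
        assert median_ratio(s, s) == 1.0

    def test_alteration_catalogue_has_eleven_contrasts(self):
        assert len(ALTERATIONS) == 11
        assert len({a.name for a in ALTERATIONS}) == 11


class TestPermutationTests:
    def test_identical_constant_samples_p_one(self):
        x = np.full(10, 5.0)
        assert permutation_test_ratio(x, x, n_perm=200, seed=0) == 1.0
        assert permutation_test_diff(x, x, n_perm=200, seed=0) == 1.0

    def test_fully_separated_samples_tiny_p(self, rng):
        x = rng.uniform(1.0, 2.0, 30)
        y = rng.uniform(10.0, 11.0, 30)
        assert permutation_test_ratio(x, y, n_perm=10000, seed=1) <= 0.001
        assert permutation_test_diff(x, y, n_perm=10000, seed=1) <= 0.001

    def test_p_never_zero(self, rng):
        x = rng.uniform(1, 2, 20)
        y = rng.uniform(100, 101, 20)
        for fn in (permutation_test_ratio, permutation_test_diff):
            assert fn(x, y, n_perm=500, seed=2) >= 1 / 501

    def test_seed_determinism(self, rng):
        x, y = rng.lognormal(0, 1, 25), rng.lognormal(0.3, 1, 25)
        p1 = permutation_test_ratio(x, y, n_perm=1000, seed=7)
        p2 = permutation_test_ratio(x, y, n_perm=1000, seed=7)
        assert p1 == p2

    def test_symmetry_under_shared_seed(self, rng):
        x, y = rng.lognormal(0, 1, 30), rng.lognormal(0.5, 1, 30)
        assert permutation_test_diff(x, y, n_perm=1000, seed=3) == permutation_test_diff(
            y, x, n_perm=1000, seed=3
        )

    def test_power_increases_with_effect_size(self, rng):
        rates = []
        for shift in (1.0, 1.3, 1.8):
            hits = 0
            for t in range(60):
                x = rng.lognormal(0.0, 0.5, 30)
                y = shift * rng.lognormal(0.0, 0.5, 30)
                if permutation_test_ratio(x, y, n_perm=300, seed=t) < 0.05:
                    hits += 1
            rates.append(hits / 60)
        assert rates[0] <= rates[1] <= rates[2] + 1e-9
        assert rates[2] > rates[0]

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            permutation_test_ratio([], [1.0], n_perm=100, seed=0)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_all_equal_stay_equal(self):
        out = adjust_bh(np.full(5, 0.02))
        np.testing.assert_allclose(out, 0.02)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    def test_rejection_sets_match_oracle(self, rng):
        for _ in range(30):
            p = rng.uniform(0, 0.2, 25)
            for alpha in (0.01, 0.05, 0.1):
                np.testing.assert_array_equal(
                    adjust_bh(p) <= alpha, bh_oracle(p) <= alpha
                )

    def test_families_adjusted_independently(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        fam = np.array(["a", "a", "b", "b"])
        out = adjust_bh(p, fam)
        np.testing.assert_allclose(out[:2], bh_oracle(p[:2]))
        np.testing.assert_allclose(out[2:], bh_oracle(p[2:]))


class TestStars:
    @pytest.mark.parametrize(
        "p,mark", [(0.005, "***"), (0.03, "**"), (0.08, "*"), (0.5, "")]
    )
    def test_threshold_mapping(self, p, mark):
        assert significance_stars(p) == mark


def build_table(spec):
    """spec: {(line, substrate): (n, median_scale)} lognormal area values."""
    rng = np.random.default_rng(0)
    rows = []
    for (line, sub), (n, scale) in spec.items():
        for i, v in enumerate(rng.lognormal(np.log(scale), 0.2, n)):
            rows.append((line, sub, "area", f"c{i}", v))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


class TestSensitivityTables:
    def test_pairs_below_min_n_skipped(self):
        table = build_table(
            {
                ("A", "30kPa_Coll"): (30, 200.0),
                ("A", "500Pa_Coll"): (24, 100.0),  # below n >= 25 on one side
                ("B", "30kPa_Coll"): (30, 200.0),
                ("B", "500Pa_Coll"): (30, 100.0),
            }
        )
        out = substrate_sensitivity_table(table, ["area"], min_n=25, n_perm=200, seed=0)
        assert set(out["cell_line"]) == {"B"}
        row = out.iloc[0]
        assert row["alteration"] == "30k-500Pa Coll"
        assert row["ratio"] == pytest.approx(2.0, rel=0.2)
        assert 0 < row["p_raw"] <= 1 and 0 < row["p_adj"] <= 1

    def test_cancer_vs_normal_same_tissue_only(self, tiny_meta_csv):
        from mechanotypes.data_model import read_metadata

        meta = read_metadata(tiny_meta_csv)  # A1 breast cancer, B2 breast normal, C3 lung cancer
        table = build_table(
            {
                ("A1", "Glass"): (30, 300.0),
                ("B2", "Glass"): (30, 100.0),
                ("C3", "Glass"): (30, 100.0),
            }
        )
        out = cancer_vs_normal_table(table, meta, ["area"], min_n=25, n_perm=500, seed=0)
        assert len(out) == 1  # only A1 (cancer) vs B2 (normal), both breast
        row = out.iloc[0]
        assert (row["cancer_line"], row["normal_line"]) == ("A1", "B2")
        assert row["median_diff"] > 0
        assert row["p_adj"] < 0.05
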