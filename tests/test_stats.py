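import math

import numpy as np
import pandas as pd
import pytest

from subflux.stats import (
    collapse_probes,
    fdr_select,
    growth_rate_from_doubling,
    intersect_platforms,
    one_sided_p,
    reaction_h_values,
    spearman_scores,
    ttest_scores,
)

from conftest import simple_model


def score_table(p_values, statistics=None, undefined=None):
    n = len(p_values)
    return pd.DataFrame(
        {
            "statistic": statistics if statistics is not None else [1.0] * n,
            "p_value": p_values,
            "undefined": undefined if undefined is not None else [False] * n,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestGrowthRate:
    def test_identity_point(self):
        assert growth_rate_from_doubling(math.log(2)) == pytest.approx(1.0)

    def test_24h_doubling(self):
        assert growth_rate_from_doubling(24.0) == pytest.approx(
            math.log(2) / 24, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            growth_rate_from_doubling(bad)


class TestSpearman:
    def make(self, values, phen):
        samples = [f"s{i}" for i in range(len(phen))]
        expr = pd.DataFrame([values], index=["g"], columns=samples)
        return expr, pd.Series(phen, index=samples)

    def test_perfect_monotone_gives_rho_one(self):
        expr, phen = self.make([1, 4, 9, 16, 25, 36], [1, 2, 3, 4, 5, 6])
        s = spearman_scores(expr, phen)
        assert s.loc["g", "statistic"] == pytest.approx(1.0)
        assert s.loc["g", "p_value"] == pytest.approx(0.0, abs=1e-12)

    def test_antitone_gives_rho_minus_one(self):
        expr, phen = self.make([6, 5, 4, 3, 2, 1], [1, 2, 3, 4, 5, 6])
        assert spearman_scores(expr, phen).loc["g", "statistic"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_undefined(self):
        expr, phen = self.make([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])
        s = spearman_scores(expr, phen)
        assert bool(s.loc["g", "undefined"])
        assert fdr_select(s, q=0.05) == set()

    def test_matches_scipy_with_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        phen_vals = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        samples = [f"s{i}" for i in range(30)]
        expr = pd.DataFrame(
            np.round(rng.standard_normal((10, 30)), 1), columns=samples
        )
        phen = pd.Series(phen_vals, index=samples)
        got = spearman_scores(expr, phen)
        for g in expr.index:
            rho, p = spearmanr(expr.loc[g], phen_vals)
            assert got.loc[g, "statistic"] == pytest.approx(rho, abs=1e-12)
            assert got.loc[g, "p_value"] == pytest.approx(p, rel=1e-6)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(20)]
        expr = pd.DataFrame(rng.standard_normal((4, 20)), columns=samples)
        phen = pd.Series(rng.uniform(0.5, 2.0, 20), index=samples)
        base = spearman_scores(expr, phen)
        warped = spearman_scores(np.exp(expr), phen**3)
        pd.testing.assert_frame_equal(base, warped)

    def test_too_few_samples_rejected(self):
        expr, phen = self.make([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_scores(expr, phen)


class TestTTest:
    def make(self, case, ctrl):
        vals = np.asarray(list(case) + list(ctrl), dtype=float)[None, :]
        samples = [f"s{i}" for i in range(vals.shape[1])]
        expr = pd.DataFrame(vals, index=["g"], columns=samples)
        groups = pd.Series(
            ["deceased"] * len(case) + ["survivor"] * len(ctrl), index=samples
        )
        return expr, groups

    def test_equal_means_gives_zero_t(self):
        expr, groups = self.make([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        s = ttest_scores(expr, groups)
        assert s.loc["g", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc["g", "p_value"] == pytest.approx(1.0)

    def test_sign_positive_when_higher_in_cases(self):
        expr, groups = self.make([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert ttest_scores(expr, groups).loc["g", "statistic"] > 0

    def test_one_constant_group_stays_finite(self):
        expr, groups = self.make([2.0, 2.0, 2.0], [1.0, 3.0, 2.5])
        s = ttest_scores(expr, groups)
        assert np.isfinite(s.loc["g", "statistic"])

    def test_planted_effect_beats_background(self):
        rng = np.random.default_rng(17)
        n_each = 20
        samples = [f"s{i}" for i in range(2 * n_each)]
        groups = pd.Series(
            ["deceased"] * n_each + ["survivor"] * n_each, index=samples
        )
        X = rng.standard_normal((50, 2 * n_each))
        X[0, :n_each] += 2.0  # planted gene, higher in deceased
        expr = pd.DataFrame(X, columns=samples)
        s = ttest_scores(expr, groups)
        assert s.iloc[0]["p_value"] < s.iloc[1:]["p_value"].median()

    def test_small_group_rejected(self):
        expr, groups = self.make([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            ttest_scores(expr, groups)


class TestFdrSelect:
    def test_hand_bh_example(self):
        # BH thresholds i*q/m = .0125, .025, .0375, .05: largest passing rank 2
        s = score_table([0.001, 0.02, 0.04, 0.9])
        assert fdr_select(s, q=0.05, direction="two_sided") == {"g0", "g1"}

    def test_all_null_empty(self):
        s = score_table([1.0, 1.0, 1.0])
        assert fdr_select(s, q=0.05) == set()

    def test_selection_monotone_in_q(self):
        rng = np.random.default_rng(9)
        s = score_table(rng.uniform(0, 0.2, 50).tolist())
        assert fdr_select(s, q=0.01) <= fdr_select(s, q=0.05)

    def test_positive_direction_restricts_sign(self):
        s = score_table([0.002, 0.002], statistics=[2.5, -2.5])
        assert fdr_select(s, q=0.05, direction="positive") == {"g0"}
        assert fdr_select(s, q=0.05, direction="negative") == {"g1"}

    def test_empty_table(self):
        assert fdr_select(score_table([]), q=0.05) == set()


class TestIntersection:
    def test_disjoint(self):
        assert intersect_platforms({"a"}, {"b"}) == set()

    def test_identical(self):
        assert intersect_platforms({"a", "b"}, {"a", "b"}) == {"a", "b"}

    def test_probe_mapping_with_planted_overlap(self):
        # platform A probes pa_*, platform B probes pb_*; 40% shared genes
        id_map = {f"pa_{i}": f"gene{i}" for i in range(10)}
        id_map |= {f"pb_{i}": f"gene{i}" for i in range(10)}
        sel_a = {f"pa_{i}" for i in range(5)}
        sel_b = {f"pb_{i}" for i in range(3, 8)}
        assert intersect_platforms(sel_a, sel_b, id_map) == {
            "gene3",
            "gene4",
        }

    def test_collapse_probes_takes_min_p(self):
        scores = score_table([0.5, 0.01, 0.2], statistics=[1, 2, 3])
        collapsed = collapse_probes(scores, {"g0": "G", "g1": "G", "g2": "H"})
        assert collapsed.loc["G", "p_value"] == pytest.approx(0.01)
        assert collapsed.loc["H", "p_value"] == pytest.approx(0.2)


class TestHValues:
    def test_single_gene_h(self):
        model = simple_model(
            {"R1": {"A": -1, "B": 1}}, gprs={"R1": "g0"}
        )
        scores = score_table([0.02], statistics=[3.0])  # one-sided 0.01
        h = reaction_h_values(scores, model, direction="positive")
        assert h.h("R1") == pytest.approx(0.99)
        assert h.table.loc["R1", "contributing_gene"] == "g0"

    def test_no_gpr_unscored(self):
        model = simple_model({"R1": {"A": -1, "B": 1}})
        h = reaction_h_values(score_table([0.01]), model)
        assert h.h("R1") == 0.0
        assert not bool(h.table.loc["R1", "scored"])

    def test_min_p_rule_over_isozymes(self):
        model = simple_model(
            {"R1": {"A": -1, "B": 1}}, gprs={"R1": "g0 or g1"}
        )
        scores = score_table([1.0, 0.002], statistics=[2.0, 2.0])
        h = reaction_h_values(scores, model, direction="positive")
        assert h.h("R1") == pytest.approx(1 - 0.001)

    def test_discordant_sign_scores_low(self):
        model = simple_model({"R1": {"A": -1, "B": 1}}, gprs={"R1": "g0"})
        scores = score_table([0.02], statistics=[-3.0])
        h = reaction_h_values(scores, model, direction="positive")
        assert h.h("R1") == pytest.approx(1 - 0.99)

    def test_one_sided_p_conventions(self):
        s = score_table([0.1, 0.1], statistics=[1.0, -1.0])
        pos = one_sided_p(s, "positive")
        assert pos.tolist() == pytest.approx([0.05, 0.95])
        assert one_sided_p(s, "two_sided").tolist() == pytest.approx([0.1, 0.1])
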