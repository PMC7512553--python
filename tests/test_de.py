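"""NB differential expression: normalization oracles, dispersion recovery,
test calibration, and the three-gate consensus rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tpscan import de, synth


def two_group_design():
    return synth.StudyDesign(bacteria=("OP50", "PAO1"), generations=("F1",), seed=0)


GROUPS = np.array([0, 0, 0, 1, 1, 1])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile([[10], [40], [7]], (1, 4)))
        assert de.size_factors_median_of_ratios(m) == pytest.approx([1, 1, 1, 1])

    def test_scale_equivariance(self):
        col = np.random.default_rng(0).poisson(50, size=300) + 1
        doubled = pd.DataFrame({0: col, 1: col, 2: col * 2, 3: col})
        sf = de.size_factors_median_of_ratios(doubled)
        assert sf[2] / sf[0] == pytest.approx(2.0, rel=1e-9)

    def test_matches_step_by_step_hand_implementation(self, rng):
        m = pd.DataFrame(rng.negative_binomial(10, 0.1, size=(200, 6)))
        got = de.size_factors_median_of_ratios(m)
        # independent spreadsheet-style implementation
        arr = m.to_numpy(float)
        keep = (arr > 0).all(axis=1)
        sub = arr[keep]
        geo = np.exp(np.log(sub).mean(axis=1))
        want = [np.median(sub[:, j] / geo) for j in range(6)]
        assert got == pytest.approx(want)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile([[10], [40], [7], [100]], (1, 3)))
        assert de.tmm_factors(m) == pytest.approx([1, 1, 1])

    def test_geometric_mean_is_one(self, rng):
        m = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(400, 5)))
        f = de.tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_trim_excludes_extreme_feature(self):
        # 21 equal features plus one 4x-inflated feature in sample 2; the
        # 30% M-trim removes the inflated feature, so the factor comes from
        # the remaining features alone: it must exactly undo the library-size
        # difference the outlier created (2200 vs 2500)
        counts = np.full((21, 2), 100)
        counts = np.vstack([counts, [[100, 400]]])
        f = de.tmm_factors(pd.DataFrame(counts), m_trim=0.30, a_trim=0.0)
        assert f[1] / f[0] == pytest.approx(2200 / 2500, rel=1e-9)

    def test_all_zero_sample_raises(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            de.tmm_factors(m)


class TestDispersion:
    def test_poisson_data_gives_near_zero(self):
        m = synth.simulate_count_matrix(
            [f"f{i}" for i in range(10_000)], two_group_design(),
            baseline_mean=100, dispersion=0.0, seed=5,
        )
        phi = de.estimate_dispersion(m, GROUPS, method="moments_pooled")
        assert np.median(phi) < 0.01

    def test_recovers_planted_dispersion(self):
        m = synth.simulate_count_matrix(
            [f"f{i}" for i in range(8_000)], two_group_design(),
            baseline_mean=200, dispersion=0.2, seed=6,
        )
        phi = de.estimate_dispersion(m, GROUPS, method="moments_pooled")
        assert 0.15 < np.median(phi) < 0.25

    def test_constant_counts_give_zero(self):
        m = pd.DataFrame(np.full((5, 6), 42))
        phi = de.estimate_dispersion(m, GROUPS, method="moments_pooled")
        assert phi == pytest.approx(np.zeros(5))

    def test_single_replicate_raises(self):
        m = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            de.estimate_dispersion(m, [0, 1, 1])


class TestWald:
    def test_identical_groups_are_null(self):
        m = pd.DataFrame(np.tile([[100], [50]], (1, 6)))
        res = de.nb_wald_test(m, GROUPS, np.ones(6), np.full(2, 0.1))
        assert res["log2fc"].to_numpy() == pytest.approx([0, 0])
        assert (res["p"] > 0.99).all()

    def test_all_zero_feature(self):
        m = pd.DataFrame(np.zeros((1, 6)))
        res = de.nb_wald_test(m, GROUPS, np.ones(6), np.zeros(1))
        assert res["log2fc"].iloc[0] == 0 and res["p"].iloc[0] == 1

    def test_power_at_planted_effect(self):
        """log2fc=+2, phi=0.05, 3v3, mean 200 -> p < 0.05 in >= 90% of sims."""
        hits = 0
        design = two_group_design()
        for seed in range(200):
            m = synth.simulate_count_matrix(
                ["f"], design, baseline_mean=200, dispersion=0.05,
                planted_log2fc={"f": {"PAO1_F1": 2.0}}, seed=seed,
            )
            sf = np.ones(6)
            res = de.nb_wald_test(m, GROUPS, sf, np.array([0.05]))
            hits += res["p"].iloc[0] < 0.05
        assert hits >= 180


class TestExact:
    def test_symmetric_counts_give_p_one(self):
        m = pd.DataFrame([[7, 7, 7, 7, 7, 7]])
        res = de.nb_exact_test(m, GROUPS, np.ones(6), 0.1)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_phi_zero_reduces_to_binomial_split(self):
        # one group sums to 5, the other to 0; equal library sizes
        p = de._exact_nb_pvalue(5, 0, 3, 3, 0.0)
        k = np.arange(6)
        f = stats.binom.pmf(k, 5, 0.5)
        want = f[f <= f[5] * (1 + 1e-10)].sum()
        assert p == pytest.approx(want)

    def test_p_monotone_in_planted_effect(self):
        design = two_group_design()
        pvals = []
        for lfc in (0.5, 1.5, 3.0):
            m = synth.simulate_count_matrix(
                ["f"] + [f"n{i}" for i in range(60)], design, baseline_mean=100,
                dispersion=0.05, planted_log2fc={"f": {"PAO1_F1": lfc}}, seed=3,
            )
            res = de.nb_exact_test(m, GROUPS, de.tmm_factors(m), 0.05)
            pvals.append(res["p"].loc["f"])
        assert pvals[0] > pvals[1] > pvals[2]


class TestBh:
    def test_matches_brute_force(self, rng):
        p = rng.random(500) ** 2
        got = de.benjamini_hochberg(p)
        # independent BH: sort, scale by n/rank, enforce monotonicity
        n = len(p)
        order = np.argsort(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        monotone = np.minimum.accumulate(scaled[::-1])[::-1]
        want = np.empty(n)
        want[order] = np.minimum(monotone, 1)
        assert got == pytest.approx(want)


class TestConsensus:
    @pytest.mark.parametrize(
        "lfc,padj_a,p_b,want",
        [
            (2.0, 0.01, 0.01, "up"),
            (0.9, 0.001, 0.001, "ns"),   # fold-change gate
            (2.0, 0.06, 0.01, "ns"),     # method-A gate
            (2.0, 0.01, 0.06, "ns"),     # method-B gate
            (-2.0, 0.01, 0.01, "down"),
            (-0.9, 0.001, 0.001, "ns"),
        ],
    )
    def test_three_gate_rule(self, lfc, padj_a, p_b, want):
        table = pd.DataFrame({"log2fc": [lfc], "padj_a": [padj_a], "p_b": [p_b]})
        assert de.consensus_call(table).iloc[0] == want

    def test_missing_method_raises(self):
        with pytest.raises(ValueError, match="p_b"):
            de.consensus_call(pd.DataFrame({"log2fc": [1.0], "padj_a": [0.01]}))


class TestCalibrationAndRecovery:
    def test_null_type_one_error_in_band(self):
        """Raw method-A rejection at 0.05 stays near nominal under the null."""
        m = synth.simulate_count_matrix(
            [f"f{i}" for i in range(5_000)], two_group_design(),
            baseline_mean=100, dispersion=0.1, seed=42,
        )
        table = de.run_two_group(m, GROUPS)
        rej = (table["p_a"] < 0.05).mean()
        assert 0.03 <= rej <= 0.07
        assert (table["call"] != "ns").mean() < 0.01

    def test_direction_always_matches_planted_sign(self):
        design = two_group_design()
        lfc = {f"f{i}": {"PAO1_F1": 2.0 if i % 2 else -2.0} for i in range(40)}
        m = synth.simulate_count_matrix(
            [f"f{i}" for i in range(400)], design, baseline_mean=200,
            dispersion=0.05, planted_log2fc=lfc, seed=11,
        )
        table = de.run_two_group(m, GROUPS)
        for i in range(40):
            call = table.loc[f"f{i}", "call"]
            if call != "ns":
                assert call == ("up" if i % 2 else "down")

    def test_scale_invariance_of_calls(self):
        design = two_group_design()
        lfc = {"f0": {"PAO1_F1": 2.0}}
        m = synth.simulate_count_matrix(
            [f"f{i}" for i in range(300)], design, baseline_mean=150,
            dispersion=0.05, planted_log2fc=lfc, seed=13,
        )
        scaled = m.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        sf0 = de.size_factors_median_of_ratios(m)
        sf1 = de.size_factors_median_of_ratios(scaled)
        # relative to the other samples, the scaled sample's factor grows ~3x
        assert (sf1[0] / sf1[1]) / (sf0[0] / sf0[1]) == pytest.approx(3, rel=0.05)
        t1 = de.run_two_group(m, GROUPS)
        t2 = de.run_two_group(scaled, GROUPS)
        assert t1.loc["f0", "call"] == t2.loc["f0", "call"] == "up"
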