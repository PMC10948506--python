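"""Inferential-machinery tests, each against an independent oracle where one
exists: exhaustive sign-flip enumeration, brute-force BH, pingouin's
repeated-measures ANOVA, and hand-computed rank statistics."""

import numpy as np
import pandas as pd
import pytest

from numadapt.stats import (
    adaptation_percentage,
    bonferroni_posthoc,
    cell_means,
    fdr_bh,
    paired_permutation_test,
    rm_anova_gg,
    spearman_correlation,
)


class TestPairedPermutation:
    def test_identical_conditions_give_p_one(self):
        a = np.arange(6.0)
        t, p = paired_permutation_test(a, a.copy(), seed=0)
        assert t == 0.0
        assert p == 1.0

    def test_small_n_uses_exhaustive_enumeration(self):
        # n = 5: 2^5 = 32 sign patterns; p must be an exact multiple of 1/32
        rng = np.random.default_rng(3)
        a = rng.normal(size=5) + 1.0
        b = rng.normal(size=5)
        _, p = paired_permutation_test(a, b, n_permutations=15000, seed=0)
        assert (p * 32) == pytest.approx(round(p * 32), abs=1e-12)

    def test_monte_carlo_matches_exhaustive_within_error(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=5) + 0.8
        b = rng.normal(size=5)
        _, p_exact = paired_permutation_test(a, b, n_permutations=100000, seed=0)
        # force the Monte-Carlo path with a budget below 2^5... not possible
        # (2^5 = 32 <= any sensible budget); use n = 14 instead
        a = np.concatenate([a, a, a[:4]])
        b = np.concatenate([b, b, b[:4]])
        _, p_exh = paired_permutation_test(a, b, n_permutations=2**14, seed=0)
        _, p_mc = paired_permutation_test(a, b, n_permutations=9999, seed=1)
        se = np.sqrt(p_exh * (1 - p_exh) / 9999)
        assert abs(p_mc - p_exh) < 4 * se + 2e-4

    def test_type_one_error_rate_near_nominal(self):
        # independent replicate experiments as feature columns, independent
        # sign-flip batches to decorrelate the rate estimate
        rng = np.random.default_rng(11)
        rates = []
        for batch in range(5):
            a = rng.normal(size=(16, 200))
            b = rng.normal(size=(16, 200))
            _, p = paired_permutation_test(a, b, n_permutations=999, seed=batch)
            rates.append(np.mean(p <= 0.05))
        rate = np.mean(rates)
        assert 0.035 <= rate <= 0.065

    def test_invariant_to_common_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        _, p1 = paired_permutation_test(a, b, seed=0)
        _, p2 = paired_permutation_test(a + 7.5, b + 7.5, seed=0)
        np.testing.assert_allclose(p1, p2)

    def test_rejects_unpaired_or_tiny_inputs(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(1), np.ones(1))


class TestFdrBH:
    def test_single_p_is_identity(self):
        adj, mask = fdr_bh(np.array([0.03]), 0.05)
        assert adj[0] == pytest.approx(0.03)
        assert mask[0]

    def test_hand_computed_step_up(self):
        adj, mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert mask.all()

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=30)
            adj, _ = fdr_bh(p, 0.05)
            order = np.argsort(p)
            m = len(p)
            brute = np.empty(m)
            for rank_idx, i in enumerate(order):
                js = np.arange(rank_idx, m)
                brute[i] = min(1.0, np.min(m * p[order][js] / (js + 1)))
            np.testing.assert_allclose(adj, brute, atol=1e-12)

    def test_mask_is_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        _, mask = fdr_bh(p, 0.05)
        p2 = p.copy()
        p2[p2.argmax()] = 0.0
        _, mask2 = fdr_bh(p2, 0.05)
        assert set(np.flatnonzero(mask)) <= set(np.flatnonzero(mask2))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]))


def _balanced_table(rng, n=12, effect_a=0.0):
    rows = []
    for s in range(n):
        base = rng.normal()
        for a in ("High", "Low"):
            for b in (14, 16, 18, 20, 22):
                rows.append(
                    (s, a, b, base + rng.normal() + effect_a * (a == "High"))
                )
    return pd.DataFrame(
        rows, columns=["participant", "adaptation", "numerosity", "value"]
    )


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        table = _balanced_table(rng, effect_a=0.5)
        res = rm_anova_gg(table)
        eff = res["Adaptation"]
        assert eff["eps"] == 1.0
        wide = table.pivot_table(
            index="participant", columns="adaptation", values="value"
        )
        t, p = sps.ttest_rel(wide["High"], wide["Low"])
        assert eff["F"] == pytest.approx(t**2, rel=1e-10)
        assert eff["p"] == pytest.approx(p, rel=1e-10)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        # exchangeable errors: sphericity holds, so GG epsilon ~ 1 (the
        # estimator has a known downward small-sample bias, hence the slack)
        rng = np.random.default_rng(1)
        eps_vals = []
        for _ in range(20):
            table = _balanced_table(rng, n=40)
            eps_vals.append(rm_anova_gg(table)["Numerosity"]["eps"])
        assert np.mean(eps_vals) > 0.85

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        for _ in range(3):
            table = _balanced_table(rng, effect_a=0.3)
            mine = rm_anova_gg(table)
            ref = pg.rm_anova(
                data=table,
                dv="value",
                within=["adaptation", "numerosity"],
                subject="participant",
                correction=True,
                detailed=True,
            ).set_index("Source")
            for effect, source in [
                ("Adaptation", "adaptation"),
                ("Numerosity", "numerosity"),
                ("Adaptation x Numerosity", "adaptation * numerosity"),
            ]:
                assert mine[effect]["F"] == pytest.approx(
                    ref.loc[source, "F"], abs=1e-6
                )
                assert mine[effect]["eps"] == pytest.approx(
                    ref.loc[source, "eps"], abs=1e-6
                )
                assert mine[effect]["p"] == pytest.approx(
                    ref.loc[source, "p_GG_corr"], abs=1e-6
                )
                assert mine[effect]["df1"] == ref.loc[source, "ddof1"]
                assert mine[effect]["df2"] == ref.loc[source, "ddof2"]

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(0)
        table = _balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing cell"):
            rm_anova_gg(table)


class TestBonferroni:
    def test_single_comparison_unadjusted(self, rng):
        table = _balanced_table(np.random.default_rng(0), effect_a=1.0)
        res = bonferroni_posthoc(table, [(("High", 14), ("Low", 14))])
        assert res["p_adj"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])

    def test_adjustment_multiplies_and_caps(self):
        table = _balanced_table(np.random.default_rng(0))
        res = bonferroni_posthoc(table)
        assert len(res) == 5
        np.testing.assert_allclose(
            res["p_adj"], np.minimum(1.0, res["p_raw"] * 5)
        )


class TestAdaptationPercentage:
    def _behavior(self, est_high, est_low):
        rows = []
        for p in range(2):
            for n in (14, 16, 18, 20, 22):
                for t in range(3):
                    rows.append((p, 0, t, "High", n, est_high(n)))
                    rows.append((p, 0, t, "Low", n, est_low(n)))
        return pd.DataFrame(
            rows,
            columns=[
                "participant", "block", "trial", "adaptation",
                "true_numerosity", "estimate",
            ],
        )

    def test_identical_conditions_give_zero(self):
        behavior = self._behavior(lambda n: n, lambda n: n)
        assert adaptation_percentage(behavior)["overall"] == 0.0

    def test_fifteen_percent_case(self):
        # at every numerosity: Low = 1.075 n, High = 0.925 n -> 15%
        behavior = self._behavior(lambda n: 0.925 * n, lambda n: 1.075 * n)
        res = adaptation_percentage(behavior)
        assert res["overall"] == pytest.approx(15.0, abs=1e-9)
        np.testing.assert_allclose(res["per_numerosity"], 15.0)

    def test_empty_cell_rejected(self):
        behavior = self._behavior(lambda n: n, lambda n: n)
        behavior = behavior[behavior["adaptation"] == "High"]
        with pytest.raises(ValueError):
            adaptation_percentage(behavior)


class TestSpearman:
    def test_perfect_monotonicity(self):
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_rank_example(self):
        # d^2 = (1,1,1,1): rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_antisymmetry_under_reversal(self):
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 4, 5, 2]
        rho1, _ = spearman_correlation(x, y)
        rho2, _ = spearman_correlation(x, [-v for v in y])
        assert rho1 == pytest.approx(-rho2)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


def test_cell_means_collapses_trials():
    rows = [
        (0, 0, 0, "High", 14, 10),
        (0, 0, 1, "High", 14, 12),
        (0, 0, 2, "Low", 14, 20),
    ]
    behavior = pd.DataFrame(
        rows,
        columns=[
            "participant", "block", "trial", "adaptation",
            "true_numerosity", "estimate",
        ],
    )
    cells = cell_means(behavior)
    assert set(cells.columns) == {"participant", "adaptation", "numerosity", "value"}
    high = cells[cells["adaptation"] == "High"]["value"].iloc[0]
    assert high == 11.0
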