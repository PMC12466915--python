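import itertools

import numpy as np
import pandas as pd
import pytest

from pcss.assays import (
    SEX_EFFECT_CATEGORIES,
    analyze_sex_effects,
    anova_genotype_sex,
    classify_sex_effect,
    cox_interaction,
    knockdown_sex_bias_tests,
    logrank_test,
    mean_survival,
    qpcr_relative_expression,
    survival_log2fc,
)
from pcss.simulate import simulate_assay, simulate_qpcr


def flies(times, sex="F", group="control", events=None):
    return pd.DataFrame(
        {
            "line": "L",
            "sex": sex,
            "group": group,
            "time": list(times),
            "event": events if events is not None else [True] * len(times),
        }
    )


class TestMeanSurvival:
    def test_arithmetic_mean_all_events(self):
        assert mean_survival(flies([10, 20, 30])) == pytest.approx(20.0)
        assert mean_survival(flies([48])) == pytest.approx(48.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mean_survival(flies([]))

    def test_censoring_uses_km_restricted_mean(self):
        # times 2, 4+, 6: S = 1 on [0,2), 2/3 on [2,6), 0 after
        # area to t=6: 2*1 + 4*(2/3) = 4.6667
        df = flies([2, 4, 6], events=[True, False, True])
        assert mean_survival(df) == pytest.approx(2 + 4 * 2 / 3, abs=1e-9)

    def test_all_event_mean_equals_km_area(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(50, 40)
        df = flies(t)
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        kmf = KaplanMeierFitter().fit(t, np.ones_like(t))
        assert mean_survival(df) == pytest.approx(
            restricted_mean_survival_time(kmf, t=t.max()), abs=1e-8
        )


class TestLogrank:
    def test_identical_groups_null(self):
        a = flies([10, 20, 30, 40])
        chi2, p = logrank_test(a, a.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_disjoint_ranges_highly_significant(self, rng):
        a = flies(rng.uniform(1, 10, 20))
        b = flies(rng.uniform(50, 60, 20))
        _, p = logrank_test(a, b)
        assert p < 1e-4

    def test_matches_hand_computed_observed_minus_expected(self):
        # groups A: deaths at 1, 3, 5; B: deaths at 2, 4, 6 (all distinct)
        a, b = flies([1, 3, 5]), flies([2, 4, 6])
        chi2, p = logrank_test(a, b)
        # independent hand computation over the six risk sets
        times = [(1, "A"), (2, "B"), (3, "A"), (4, "B"), (5, "A"), (6, "B")]
        na, nb, O, E, V = 3, 3, 0.0, 0.0, 0.0
        for _, grp in times:
            n = na + nb
            if n > 1:
                O += 1.0 if grp == "A" else 0.0
                E += na / n
                V += (na * nb) / (n * n)
            if grp == "A":
                na -= 1
            else:
                nb -= 1
        chi2_hand = (O - E) ** 2 / V
        assert chi2 == pytest.approx(chi2_hand, rel=1e-9)


class TestLog2FC:
    @pytest.mark.parametrize(
        "kd,ctl,expected",
        [(87.4, 74.2, 0.24), (107.52, 93.38, 0.20)],
    )
    def test_reported_fold_changes(self, kd, ctl, expected):
        assert round(survival_log2fc(kd, ctl), 2) == expected

    def test_antisymmetry_and_zero(self):
        assert survival_log2fc(50, 80) == pytest.approx(-survival_log2fc(80, 50))
        assert survival_log2fc(64.2, 64.2) == 0.0

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            survival_log2fc(0.0, 10.0)


class TestCoxInteraction:
    def test_sex_swap_negates_interaction(self):
        df = simulate_assay(-0.8, 0.4, n_per_cell=60, seed=3)
        fit = cox_interaction(df)
        swapped = df.assign(sex=df["sex"].map({"F": "M", "M": "F"}))
        fit_sw = cox_interaction(swapped)
        assert fit.beta[2] == pytest.approx(-fit_sw.beta[2], abs=1e-6)

    def test_opposite_effects_detected(self):
        df = simulate_assay(-1.0, 1.0, n_per_cell=100, seed=5)
        fit = cox_interaction(df)
        assert fit.converged
        assert fit.p_wald[2] < 0.01

    def test_empty_cell_errors(self):
        df = simulate_assay(0, 0, n_per_cell=10, seed=1)
        df = df[~((df["sex"] == "M") & (df["group"] == "knockdown"))]
        with pytest.raises(ValueError, match="sex=M"):
            cox_interaction(df)


class TestAnova:
    def test_balanced_fixture_matches_hand_sums_of_squares(self):
        # classic balanced 2x2 with n=2 per cell
        rows = []
        data = {
            ("control", "F"): [10.0, 12.0],
            ("control", "M"): [20.0, 22.0],
            ("knockdown", "F"): [14.0, 16.0],
            ("knockdown", "M"): [30.0, 32.0],
        }
        for (g, s), ts in data.items():
            for t in ts:
                rows.append({"line": "L", "sex": s, "group": g, "time": t, "event": True})
        table = anova_genotype_sex(pd.DataFrame(rows))
        # hand computation: cell means 11,21,15,31; grand 19.5
        # SS_genotype = 2*2*((13-19.5)^2+(26-19.5)^2)? -> use marginal means
        # genotype means: ctl 16, kd 23 -> SS_g = 4*(16-19.5)^2*2 = 98
        # sex means: F 13, M 26 -> SS_s = 4*(13-19.5)^2*2 = 338
        # interaction: cells - additive: SS_i = 2*sum((cell - g - s + grand)^2) = 18
        # residual SS = 2 per cell * 4 = 8, df=4 -> MSE = 2
        assert table.loc["C(genotype)", "F"] == pytest.approx(98 / 2)
        assert table.loc["C(sex)", "F"] == pytest.approx(338 / 2)
        assert table.loc["C(genotype):C(sex)", "F"] == pytest.approx(18 / 2)

    def test_zero_interaction_by_construction(self):
        rows = []
        for g, ge in (("control", 0.0), ("knockdown", 5.0)):
            for s, se in (("F", 0.0), ("M", 10.0)):
                for e in (-1.0, 1.0):
                    rows.append({"line": "L", "sex": s, "group": g,
                                 "time": 30 + ge + se + e, "event": True})
        table = anova_genotype_sex(pd.DataFrame(rows))
        assert table.loc["C(genotype):C(sex)", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_unbalanced_matches_projection_oracle(self, rng):
        rows = []
        sizes = {("control", "F"): 5, ("control", "M"): 8,
                 ("knockdown", "F"): 6, ("knockdown", "M"): 3}
        for (g, s), n in sizes.items():
            for t in rng.normal(50 + 5 * (g == "knockdown") + 10 * (s == "M"), 4, n):
                rows.append({"line": "L", "sex": s, "group": g, "time": t, "event": True})
        df = pd.DataFrame(rows)
        table = anova_genotype_sex(df)
        # type-II SS for the interaction: SSR(main) - SSR(full) via lstsq
        g = (df["group"] == "knockdown").to_numpy(float)
        s = (df["sex"] == "M").to_numpy(float)
        y = df["time"].to_numpy()
        X_main = np.column_stack([np.ones_like(g), g, s])
        X_full = np.column_stack([X_main, g * s])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        ss_int = rss(X_main) - rss(X_full)
        assert table.loc["C(genotype):C(sex)", "sum_sq"] == pytest.approx(ss_int, rel=1e-9)


class TestClassification:
    def test_published_antagonistic_example(self):
        # knockdown raises female survival, lowers male survival, both significant
        cat = classify_sex_effect(0.002, 0.06, 3.9e-12, -0.23, p_interaction=0.001)
        assert cat == "antagonistic"

    def test_no_effect(self):
        assert classify_sex_effect(0.4, 0.1, 0.3, 0.2, 0.5) == "no_effect"

    def test_male_biased_enhanced_walkthrough(self):
        cat = classify_sex_effect(0.01, 0.10, 0.02, 0.30, p_interaction=0.01)
        assert cat == "male_biased_enhanced"

    def test_sex_specific_ignores_interaction(self):
        assert (
            classify_sex_effect(0.01, -0.2, 0.5, 0.3, p_interaction=0.001)
            == "female_specific_weakened"
        )

    def test_consistent_when_interaction_not_significant(self):
        assert (
            classify_sex_effect(0.01, 0.2, 0.01, 0.4, p_interaction=0.5)
            == "consistent_enhanced"
        )

    def test_inconsistent_zero_fold_change_flagged(self):
        with pytest.raises(ValueError):
            classify_sex_effect(0.01, 0.0, 0.5, 0.1, 0.5)

    def test_totality_over_discrete_patterns(self):
        """Every (state_F, state_M, interaction, larger-sex) pattern maps to
        exactly one category: 3 x 3 x 2 x 2 = 36 patterns."""
        states = {"nonsig": (0.5, 0.1), "sig_up": (0.01, 0.1), "sig_down": (0.01, -0.1)}
        seen = set()
        for (sf, (pf, ff)), (sm, (pm, fm)), p_int, bigger_f in itertools.product(
            states.items(), states.items(), (0.01, 0.5), (True, False)
        ):
            scale_f = 3.0 if bigger_f else 1.0
            scale_m = 1.0 if bigger_f else 3.0
            cat = classify_sex_effect(pf, ff * scale_f, pm, fm * scale_m, p_int)
            assert cat in SEX_EFFECT_CATEGORIES
            seen.add(cat)
        # the grid exercises every category except the weakened-biased pair's
        # complement; at minimum all specific/antagonistic/consistent appear
        assert {"no_effect", "antagonistic", "consistent_enhanced",
                "consistent_weakened", "female_specific_enhanced",
                "male_specific_weakened", "male_biased_enhanced",
                "female_biased_weakened"} <= seen


class TestAnalyzeSexEffects:
    def test_end_to_end_antagonistic_gene(self):
        df = simulate_assay(-1.0, 1.0, n_per_cell=100, seed=42, line="geneX")
        res = analyze_sex_effects(df)
        assert res.loc[0, "category"] == "antagonistic"
        assert res.loc[0, "log2fc_f"] > 0 > res.loc[0, "log2fc_m"]
        assert res.loc[0, "q"] < 0.05


class TestQpcr:
    def test_no_knockdown_is_unity(self):
        df = simulate_qpcr(1.0, noise_sd=0.0, seed=0)
        _, mean_rel = qpcr_relative_expression(df, sex="F")
        assert mean_rel == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        df = simulate_qpcr(0.5, noise_sd=0.0, seed=0)
        _, mean_rel = qpcr_relative_expression(df, sex="M")
        assert mean_rel == pytest.approx(0.5)

    def test_hand_computed_ddct(self):
        rows = []
        for grp, dcts in (("control", [4.0, 4.2, 3.8]), ("knockdown", [6.0, 6.4, 5.6])):
            for i, dct in enumerate(dcts, 1):
                for tech in (1, 2):
                    rows.append({"gene": "g", "sex": "F", "group": grp,
                                 "bio_rep": f"b{i}", "tech_rep": f"t{tech}",
                                 "ct_target": 18 + dct, "ct_reference": 18.0})
        rel, mean_rel = qpcr_relative_expression(pd.DataFrame(rows))
        # ddCt per kd replicate: 2.0, 2.4, 1.6 -> 2^-x = .25, .1895, .3299
        assert rel == pytest.approx([2 ** -2.0, 2 ** -2.4, 2 ** -1.6])
        assert mean_rel == pytest.approx(np.mean([2 ** -2.0, 2 ** -2.4, 2 ** -1.6]))


class TestKnockdownSexBias:
    def _expr(self, gene_vals):
        rows = []
        for gene, (fvals, mvals) in gene_vals.items():
            for i, v in enumerate(fvals, 1):
                rows.append({"gene": gene, "sex": "F", "bio_rep": f"b{i}", "rel_expr": v})
            for i, v in enumerate(mvals, 1):
                rows.append({"gene": gene, "sex": "M", "bio_rep": f"b{i}", "rel_expr": v})
        return pd.DataFrame(rows)

    def test_identical_sexes_null(self):
        expr = self._expr({f"g{i}": ([0.3, 0.4], [0.3, 0.4]) for i in range(4)})
        cats, genes = knockdown_sex_bias_tests(
            expr, pd.Series({f"g{i}": "antagonistic" for i in range(4)})
        )
        assert cats.loc[0, "p"] == pytest.approx(1.0)
        assert (genes["p"] == 1.0).all()

    def test_four_pair_t_matches_closed_form(self):
        vals = {"g1": ([0.30], [0.20]), "g2": ([0.41], [0.25]),
                "g3": ([0.35], [0.33]), "g4": ([0.50], [0.31])}
        expr = self._expr(vals)
        cats, _ = knockdown_sex_bias_tests(
            expr, pd.Series({g: "c" for g in vals})
        )
        diffs = np.array([0.10, 0.16, 0.02, 0.19])
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        assert cats.loc[0, "t"] == pytest.approx(t_hand, rel=1e-9)

    def test_planted_shift_detected(self, rng):
        gene_vals = {}
        for i in range(10):
            base = rng.uniform(0.2, 0.5)
            f = base + rng.normal(0, 0.02, 3)
            m = base - 0.04 + rng.normal(0, 0.02, 3)  # shift = 2 within-gene SD
            gene_vals[f"g{i}"] = (list(f), list(m))
        cats, genes = knockdown_sex_bias_tests(
            self._expr(gene_vals), pd.Series({f"g{i}": "male_biased" for i in range(10)})
        )
        assert cats.loc[0, "p"] < 0.05

    def test_single_gene_category_skipped(self):
        expr = self._expr({"g1": ([0.3, 0.4], [0.2, 0.25])})
        cats, genes = knockdown_sex_bias_tests(expr, pd.Series({"g1": "solo"}))
        assert len(cats) == 0
        assert len(genes) == 1
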