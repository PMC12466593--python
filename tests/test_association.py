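"""Fixed-effects genotype+sex model, pairwise contrasts and letter displays."""

import itertools

import numpy as np
import pytest

from snptrait import (
    DegenerateDesignError,
    Locus,
    PairwiseComparison,
    SampleRecord,
    TraitModelSpec,
    ValidationError,
    analyze_trait,
    compact_letter_display,
    fit_trait_model,
    pairwise_genotype_comparisons,
)

LOC = Locus("L", "A", "C")
CLASS_CALL = {"hom_ref": "AA", "het": "AC", "hom_alt": "CC"}


def make_records(classes, sexes, ys, trait="w"):
    return [
        SampleRecord(
            f"s{i}", sex, calls={LOC.id: CLASS_CALL[k]}, traits={trait: float(y)}
        )
        for i, (k, sex, y) in enumerate(zip(classes, sexes, ys))
    ]


def balanced_design(cell_means, reps=4):
    """Fully crossed genotype x sex data with exact cell means, no noise."""
    classes, sexes, ys = [], [], []
    for (klass, sex), mu in cell_means.items():
        classes += [klass] * reps
        sexes += [sex] * reps
        ys += [mu] * reps
    return make_records(classes, sexes, ys)


SPEC = TraitModelSpec("w", LOC)


class TestFitTraitModel:
    def test_additive_zero_noise_recovers_effects_exactly(self):
        mu, g_het, g_alt, s_m = 100.0, 40.0, 60.0, 80.0
        cells = {
            (k, s): mu
            + {"hom_ref": 0.0, "het": g_het, "hom_alt": g_alt}[k]
            + (s_m if s == "M" else 0.0)
            for k in CLASS_CALL
            for s in "FM"
        }
        fit = fit_trait_model(balanced_design(cells), SPEC)
        assert fit.coefficients["Intercept"] == pytest.approx(mu, abs=1e-9)
        assert fit.coefficients["genotype[het]"] == pytest.approx(g_het, abs=1e-9)
        assert fit.coefficients["genotype[hom_alt]"] == pytest.approx(g_alt, abs=1e-9)
        assert fit.coefficients["sex[M]"] == pytest.approx(s_m, abs=1e-9)
        assert fit.mse == pytest.approx(0.0, abs=1e-16)

    def test_coefficients_match_normal_equations_oracle(self):
        """OLS solution equals a brute-force solve of X'X b = X'y."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(10, 31)
            classes = rng.choice(list(CLASS_CALL), size=n)
            sexes = rng.choice(["F", "M"], size=n)
            if len(set(classes)) < 2 or len(set(sexes)) < 2:
                continue
            ys = rng.normal(100, 20, size=n)
            recs = make_records(classes, sexes, ys)
            try:
                fit = fit_trait_model(recs, SPEC)
            except DegenerateDesignError:
                continue
            levels = fit.genotype_levels
            X = np.column_stack(
                [np.ones(n)]
                + [(classes == lv).astype(float) for lv in levels[1:]]
                + [(sexes == "M").astype(float)]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ ys)
            got = [fit.coefficients[name] for name in fit.param_names]
            assert got == pytest.approx(list(beta), abs=1e-8)

    def test_balanced_partial_f_equals_classical_anova_f(self):
        """With equal cell sizes the partial genotype F is the classical one."""
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        classes = ["hom_ref", "het", "hom_alt"] * 20
        sexes = (["F"] * 3 + ["M"] * 3) * 10
        ys = rng.normal(100, 10, size=60) + np.where(np.array(classes) == "het", 5, 0)
        fit = fit_trait_model(make_records(classes, sexes, ys), SPEC)
        df = pd.DataFrame({"y": ys, "g": classes, "s": sexes})
        table = anova_lm(smf.ols("y ~ C(g) + C(s)", data=df).fit())
        assert fit.genotype_F == pytest.approx(table.loc["C(g)", "F"], rel=1e-9)
        assert fit.genotype_p == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-9)

    def test_parameter_recovery_on_simulated_cohort(self):
        from snptrait.synthetic import (
            CohortSpec,
            LocusSimSpec,
            TraitSimSpec,
            simulate_cohort,
        )

        spec = CohortSpec(
            n_female=133,
            n_male=43,
            loci=(LocusSimSpec(LOC, p_ref=0.5, inbreeding_f=0.0),),
            traits=(TraitSimSpec("w", 1400.0, (0.0, 40.0, 60.0), 80.0, 200.0),),
            seed=20240915,
        )
        cohort = simulate_cohort(spec)
        fit = fit_trait_model(cohort.records, SPEC)
        # each estimate within 3 of its standard error from the truth
        idx = {name: i for i, name in enumerate(fit.param_names)}
        ses = np.sqrt(np.diag(fit.cov_params))
        for name, truth in [
            ("genotype[het]", 40.0),
            ("genotype[hom_alt]", 60.0),
            ("sex[M]", 80.0),
        ]:
            assert abs(fit.coefficients[name] - truth) < 3 * ses[idx[name]]

    def test_single_genotype_level_raises(self):
        recs = make_records(["hom_ref"] * 10, ["F", "M"] * 5, range(10))
        with pytest.raises(DegenerateDesignError, match="genotype"):
            fit_trait_model(recs, SPEC)

    def test_single_sex_level_raises(self):
        recs = make_records(["hom_ref", "het"] * 5, ["F"] * 10, range(10))
        with pytest.raises(DegenerateDesignError, match="sex"):
            fit_trait_model(recs, SPEC)


class TestPairwiseComparisons:
    def test_two_group_lsd_identity_with_f_test(self):
        """With two genotype groups the single contrast p equals the F-test p."""
        rng = np.random.default_rng(5)
        classes = rng.choice(["hom_ref", "het"], size=40)
        sexes = rng.choice(["F", "M"], size=40)
        ys = rng.normal(50, 5, size=40)
        fit = fit_trait_model(make_records(classes, sexes, ys), SPEC)
        (comp,) = pairwise_genotype_comparisons(fit, method="lsd")
        assert comp.p_raw == pytest.approx(fit.genotype_p, rel=1e-9)
        assert comp.p_adj == comp.p_raw

    def test_bonferroni_is_m_times_raw(self):
        rng = np.random.default_rng(6)
        classes = rng.choice(list(CLASS_CALL), size=90)
        sexes = rng.choice(["F", "M"], size=90)
        ys = rng.normal(50, 5, size=90)
        fit = fit_trait_model(make_records(classes, sexes, ys), SPEC)
        comps = pairwise_genotype_comparisons(fit, method="bonferroni")
        for c in comps:
            assert c.p_adj == pytest.approx(min(1.0, 3 * c.p_raw))
            assert c.p_adj >= c.p_raw

    def test_tukey_not_more_liberal_than_lsd(self):
        rng = np.random.default_rng(7)
        classes = rng.choice(list(CLASS_CALL), size=90)
        sexes = rng.choice(["F", "M"], size=90)
        ys = rng.normal(50, 5, size=90)
        fit = fit_trait_model(make_records(classes, sexes, ys), SPEC)
        lsd = pairwise_genotype_comparisons(fit, method="lsd")
        tukey = pairwise_genotype_comparisons(fit, method="tukey")
        for a, b in zip(lsd, tukey):
            assert b.p_adj >= a.p_raw - 1e-12

    def test_shifted_group_detected(self):
        """A group shifted by 5 pooled SDs is significant against both others."""
        rng = np.random.default_rng(8)
        classes = ["hom_ref"] * 30 + ["het"] * 30 + ["hom_alt"] * 30
        sexes = ["F", "M"] * 45
        ys = rng.normal(100, 5, size=90)
        ys[:30] += 25.0  # 5 pooled SDs
        fit = fit_trait_model(make_records(classes, sexes, ys), SPEC)
        comps = pairwise_genotype_comparisons(fit, method="lsd")
        hits = [c for c in comps if "hom_ref" in c.pair]
        assert len(hits) == 2 and all(c.p_adj < 0.01 for c in hits)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(9)
        classes = rng.choice(list(CLASS_CALL), size=30)
        fit = fit_trait_model(
            make_records(classes, ["F", "M"] * 15, rng.normal(0, 1, 30) + 10), SPEC
        )
        with pytest.raises(ValidationError):
            pairwise_genotype_comparisons(fit, method="duncan")


def fake_comparisons(pvals: dict[tuple[str, str], float]) -> list[PairwiseComparison]:
    return [
        PairwiseComparison(
            pair=pair, diff=0.0, se=1.0, t=0.0, df=10, p_raw=p, p_adj=p, method="lsd"
        )
        for pair, p in pvals.items()
    ]


class TestCompactLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        comps = fake_comparisons(
            {("hom_ref", "het"): 0.9, ("hom_ref", "hom_alt"): 0.5, ("het", "hom_alt"): 0.7}
        )
        disp = compact_letter_display(
            comps, {"hom_ref": 3.0, "het": 2.0, "hom_alt": 1.0}, alpha=0.05
        )
        assert set(disp.letters.values()) == {"a"}

    def test_one_group_split_off(self):
        """het/hom_alt higher and equivalent, hom_ref below both: a, a, b."""
        comps = fake_comparisons(
            {
                ("hom_ref", "het"): 0.01,
                ("hom_ref", "hom_alt"): 0.02,
                ("het", "hom_alt"): 0.60,
            }
        )
        means = {"hom_ref": 1171.67, "het": 1230.11, "hom_alt": 1255.39}
        disp = compact_letter_display(comps, means, alpha=0.05)
        assert disp.letters == {"hom_alt": "a", "het": "a", "hom_ref": "b"}

    def test_intermediate_group_bridges(self):
        """Only the extremes differ: b, ab, a ordered by mean."""
        comps = fake_comparisons(
            {
                ("hom_ref", "het"): 0.30,
                ("hom_ref", "hom_alt"): 0.03,
                ("het", "hom_alt"): 0.40,
            }
        )
        means = {"hom_ref": 22.12, "het": 23.17, "hom_alt": 23.74}
        disp = compact_letter_display(comps, means, alpha=0.05)
        assert disp.letters == {"hom_alt": "a", "het": "ab", "hom_ref": "b"}

    def test_upper_case_display(self):
        comps = fake_comparisons(
            {("hom_ref", "het"): 0.001, ("hom_ref", "hom_alt"): 0.002, ("het", "hom_alt"): 0.9}
        )
        disp = compact_letter_display(
            comps, {"hom_ref": 5.96, "het": 7.06, "hom_alt": 6.99}, alpha=0.01, case="upper"
        )
        assert disp.letters == {"het": "A", "hom_alt": "A", "hom_ref": "B"}

    def test_incomplete_comparison_set_rejected(self):
        comps = fake_comparisons({("hom_ref", "het"): 0.5})
        with pytest.raises(ValidationError):
            compact_letter_display(
                comps, {"hom_ref": 1, "het": 2, "hom_alt": 3}, alpha=0.05
            )

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_sharing_invariant_on_random_p_matrices(self, k):
        """Two groups share a letter iff their pairwise p >= alpha (200 draws)."""
        rng = np.random.default_rng(100 + k)
        groups = [f"g{i}" for i in range(k)]
        for _ in range(200):
            pvals = {
                pair: float(rng.uniform())
                for pair in itertools.combinations(groups, 2)
            }
            means = {g: float(rng.normal()) for g in groups}
            disp = compact_letter_display(fake_comparisons(pvals), means, alpha=0.05)
            for (a, b), p in pvals.items():
                share = bool(set(disp.letters[a]) & set(disp.letters[b]))
                assert share == (p >= 0.05), (pvals, disp.letters)

    def test_highest_mean_gets_letter_a(self):
        rng = np.random.default_rng(17)
        groups = ["g0", "g1", "g2", "g3"]
        for _ in range(50):
            pvals = {
                pair: float(rng.uniform()) for pair in itertools.combinations(groups, 2)
            }
            means = {g: float(rng.normal()) for g in groups}
            disp = compact_letter_display(fake_comparisons(pvals), means, alpha=0.3)
            top = max(means, key=means.get)
            assert "a" in disp.letters[top]


class TestSummary:
    def test_constant_trait_summary(self):
        classes = ["hom_ref", "het", "hom_alt"] * 6
        sexes = ["F", "M"] * 9
        recs = make_records(classes, sexes, [100.0] * 18)
        summary = analyze_trait(recs, SPEC)
        for lv in summary.genotype_levels:
            assert summary.cell(lv) == "100.00 ± 0.00 ^Aa^"
        assert sum(summary.ns.values()) == 18

    def test_raw_means_and_letters_on_simulated_cohort(self):
        from snptrait.synthetic import (
            CohortSpec,
            LocusSimSpec,
            TraitSimSpec,
            simulate_cohort,
        )

        spec = CohortSpec(
            n_female=133,
            n_male=43,
            loci=(LocusSimSpec(LOC, p_ref=0.5, inbreeding_f=0.0),),
            traits=(TraitSimSpec("w", 1400.0, (0.0, 50.0, 50.0), 80.0, 150.0),),
            seed=5,
        )
        cohort = simulate_cohort(spec)
        summary = analyze_trait(cohort.records, SPEC)
        truth = {"hom_ref": 0.0, "het": 50.0, "hom_alt": 50.0}
        sex_mix = 43 / 176 * 80.0  # marginal sex contribution to raw means
        for lv in summary.genotype_levels:
            n = summary.ns[lv]
            assert abs(
                summary.means[lv] - (1400.0 + truth[lv] + sex_mix)
            ) < 3 * 170.0 / np.sqrt(n)

    def test_single_level_propagates_degenerate_error(self):
        recs = make_records(["het"] * 8, ["F", "M"] * 4, range(8))
        with pytest.raises(DegenerateDesignError):
            analyze_trait(recs, SPEC)
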