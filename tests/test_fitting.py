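"""Poisson ML fitting, likelihood-ratio and Wald tests, model selection."""

import numpy as np
import pytest
from scipy import stats

import agreemod as am
from agreemod.fitting import DivergentParameterError

from conftest import random_table


def closed_form_independence(table):
    """Textbook product-of-marginals fitted counts for any K."""
    n = table.n
    mu = np.full(table.counts.shape, float(n))
    for k, rater in enumerate(table.raters):
        shape = [1] * table.n_raters
        shape[k] = table.n_categories
        mu = mu * (table.margin(rater) / n).reshape(shape)
    return mu.reshape(-1)


class TestIndependenceOracle:
    @pytest.mark.parametrize("n_raters,n_categories", [(2, 2), (2, 3), (3, 3)])
    def test_fitted_counts_match_closed_form(self, rng, n_raters, n_categories):
        for _ in range(10):
            t = random_table(rng, n_raters, n_categories, n=300)
            res = am.fit(t, am.make_spec("independence", t.raters, t.categories))
            expected = closed_form_independence(t)
            assert np.allclose(res.fitted_counts, expected, atol=1e-8)
            y = t.flat().astype(float)
            mask = y > 0
            g2 = 2 * np.sum(y[mask] * np.log(y[mask] / expected[mask]))
            assert res.deviance == pytest.approx(g2, abs=1e-8)

    def test_exact_independence_table_has_zero_deviance(self):
        counts = np.outer([10, 20, 30], [2, 3, 5])  # rank-1 table
        t = am.ContingencyTable(["a", "b"], ["x", "y", "z"], counts)
        res = am.fit(t, am.make_spec("independence", t.raters, t.categories))
        assert res.deviance == pytest.approx(0.0, abs=1e-10)


class TestAgainstStatsmodels:
    """Independent cross-check: statsmodels Poisson GLM on the same design."""

    @pytest.mark.parametrize("name", ["homogeneous", "nonhomogeneous"])
    def test_coefficients_and_ses_match(self, rng, name):
        import statsmodels.api as sm

        t = random_table(rng, 2, 3, n=400)
        spec = am.make_spec(name, t.raters, t.categories)
        res = am.fit(t, spec, agreement_coding="indicator")
        sm_fit = sm.GLM(
            t.flat().astype(float),
            res.design.X,
            family=sm.families.Poisson(),
        ).fit()
        assert np.allclose(res.coefficients, sm_fit.params, atol=1e-6)
        assert np.allclose(res.se, sm_fit.bse, atol=1e-6)
        assert res.deviance == pytest.approx(sm_fit.deviance, abs=1e-6)


class TestRenexConsensusFits:
    """The bundled 2-rater table reproduces the published ladder."""

    def test_ladder_deviances(self, renex_table):
        for name, g2, df in [
            ("independence", 138.55, 4),
            ("homogeneous", 21.38, 3),
            ("nonhomogeneous", 0.16, 1),
        ]:
            res = am.fit(renex_table, am.make_spec(name, renex_table.raters,
                                                   renex_table.categories))
            assert res.deviance == pytest.approx(g2, abs=0.02)
            assert res.residual_df == df

    def test_nonhomogeneous_coefficients(self, renex_table):
        spec = am.make_spec("nonhomogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        expected = {
            "agree(RENEX*consensus)[non-obstructed]": (1.57, 0.30),
            "agree(RENEX*consensus)[equivocal]": (-0.28, 0.31),
            "agree(RENEX*consensus)[obstructed]": (1.82, 0.36),
        }
        for label, (est, se) in expected.items():
            assert res.coef(label) == pytest.approx(est, abs=0.01)
            assert res.coef_se(label) == pytest.approx(se, abs=0.01)
        assert res.coef_p("agree(RENEX*consensus)[equivocal]") == pytest.approx(
            0.37, abs=0.01
        )

    def test_indicator_coding_doubles_agreement_scale(self, renex_table):
        spec = am.make_spec("nonhomogeneous", renex_table.raters, renex_table.categories)
        eff = am.fit(renex_table, spec, agreement_coding="effects")
        ind = am.fit(renex_table, spec, agreement_coding="indicator")
        lab = "agree(RENEX*consensus)[obstructed]"
        assert ind.coef(lab) == pytest.approx(2 * eff.coef(lab), abs=1e-6)
        assert ind.deviance == pytest.approx(eff.deviance, abs=1e-8)


class TestMomentConditions:
    def test_fitted_margins_and_agreement_totals(self, rng):
        t = random_table(rng, 2, 3, n=500)
        spec = am.make_spec("nonhomogeneous", t.raters, t.categories)
        res = am.fit(t, spec)
        assert res.fitted_counts.sum() == pytest.approx(t.n, abs=1e-6)
        assert (res.fitted_counts > 0).all()
        mu = res.fitted_counts.reshape(t.counts.shape)
        for rater in t.raters:
            k = t.raters.index(rater)
            other = tuple(i for i in range(2) if i != k)
            assert np.allclose(mu.sum(axis=other), t.margin(rater), atol=1e-6)
        for c in range(3):
            assert mu[c, c] == pytest.approx(t.counts[c, c], abs=1e-6)


class TestCodingInvariance:
    def test_agreement_estimates_and_deviance(self, rng):
        for _ in range(5):
            t = random_table(rng, 2, 3, n=400)
            spec = am.make_spec("nonhomogeneous", t.raters, t.categories)
            ref = am.fit(t, spec, main_coding="reference")
            stz = am.fit(t, spec, main_coding="sum_to_zero")
            assert ref.deviance == pytest.approx(stz.deviance, abs=1e-6)
            for lab in ref.design.label_strings():
                if lab.startswith("agree("):
                    assert ref.coef(lab) == pytest.approx(stz.coef(lab), abs=1e-6)
                    assert ref.coef_se(lab) == pytest.approx(stz.coef_se(lab), abs=1e-6)


def test_category_permutation_equivariance(rng):
    t = random_table(rng, 2, 3, n=300)
    perm = [2, 0, 1]
    permuted = am.ContingencyTable(
        t.raters,
        tuple(t.categories[i] for i in perm),
        t.counts[np.ix_(perm, perm)],
    )
    spec_a = am.make_spec("nonhomogeneous", t.raters, t.categories)
    spec_b = am.make_spec("nonhomogeneous", t.raters, permuted.categories)
    fit_a = am.fit(t, spec_a)
    fit_b = am.fit(permuted, spec_b)
    assert fit_a.deviance == pytest.approx(fit_b.deviance, abs=1e-8)
    for cat in t.categories:
        lab = f"agree(r0*r1)[{cat}]"
        assert fit_a.coef(lab) == pytest.approx(fit_b.coef(lab), abs=1e-8)


def test_divergent_agreement_pattern_is_named(renex_table):
    counts = renex_table.counts.copy()
    counts[1, 1] = 0  # no observed agreement on the equivocal category
    t = am.ContingencyTable(renex_table.raters, renex_table.categories, counts)
    spec = am.make_spec("nonhomogeneous", t.raters, t.categories)
    with pytest.raises(DivergentParameterError, match=r"equivocal"):
        am.fit(t, spec)


class TestLikelihoodRatio:
    def test_ladder_differences(self, renex_table):
        specs = {
            name: am.fit(renex_table, am.make_spec(name, renex_table.raters,
                                                   renex_table.categories))
            for name in ("independence", "homogeneous", "nonhomogeneous")
        }
        lrt1 = am.likelihood_ratio_test(specs["independence"], specs["homogeneous"])
        assert lrt1.statistic == pytest.approx(138.55 - 21.38, abs=0.05)
        assert lrt1.df == 1
        lrt2 = am.likelihood_ratio_test(specs["homogeneous"], specs["nonhomogeneous"])
        assert lrt2.statistic == pytest.approx(21.38 - 0.16, abs=0.05)
        assert lrt2.df == 2
        assert lrt2.p_value < 0.001

    def test_identical_specs_degenerate(self, renex_table):
        spec = am.make_spec("homogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        with pytest.raises(ValueError, match="degenerate"):
            am.likelihood_ratio_test(res, res)

    def test_non_nested_rejected(self, rng):
        t = random_table(rng, 4, 3, n=3000)
        pn = am.fit(t, am.make_spec("pairwise_nonhomogeneous", t.raters, t.categories))
        tn = am.fit(t, am.make_spec("threeway_nonhomogeneous", t.raters, t.categories))
        with pytest.raises(ValueError, match="not nested"):
            am.likelihood_ratio_test(pn, tn)

    def test_deviance_nonincreasing_along_ladder(self, rng):
        t = random_table(rng, 2, 3, n=250)
        devs = [
            am.fit(t, am.make_spec(name, t.raters, t.categories)).deviance
            for name in ("independence", "homogeneous", "nonhomogeneous")
        ]
        assert devs[0] >= devs[1] >= devs[2] >= 0


class TestWald:
    def test_single_parameter_equals_z_squared(self, renex_table):
        spec = am.make_spec("nonhomogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        lab = "agree(RENEX*consensus)[non-obstructed]"
        w = am.wald_linear_test(res, {lab: 1.0})
        z = res.coef(lab) / res.coef_se(lab)
        assert w.statistic == pytest.approx(z**2, rel=1e-10)
        assert w.df == 1

    def test_all_zero_constraint_rejected(self, renex_table):
        spec = am.make_spec("homogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        with pytest.raises(ValueError, match="all-zero"):
            am.wald_linear_test(res, {"agree(RENEX*consensus)": 0.0})

    def test_dependent_rows_rejected(self, renex_table):
        spec = am.make_spec("nonhomogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        row = {"agree(RENEX*consensus)[equivocal]": 1.0}
        with pytest.raises(ValueError, match="linearly dependent"):
            am.wald_linear_test(res, [row, row])


class TestNamedEquivalenceTests:
    def test_pairwise_emits_nine_results(self):
        cfg = am.preset_renex_panel(n_subjects=20_000, seed=11)
        res = am.fit(am.sample_table(cfg), cfg.spec)
        tests = am.named_equivalence_tests(res, "RENEX")
        assert len(tests) == 9
        names = {(t.name, t.category) for t in tests}
        assert len(names) == 9
        assert all(t.df == (1 if t.name == "experts_vs_cad" else 2) for t in tests)

    def test_threeway_emits_three_results(self, rng):
        spec = am.make_spec(
            "threeway_nonhomogeneous",
            ("expert1", "expert2", "expert3", "RENEX"),
            ("non-obstructed", "equivocal", "obstructed"),
        )
        coeffs = am.calibrate_main_effects(
            spec,
            {str(l): 0.5 for l in am.build_design(spec).labels if l.kind == "agreement"},
            np.array([0.59, 0.16, 0.25]),
        )
        cfg = am.GeneratorConfig(spec, coeffs, n_subjects=20_000, seed=5)
        res = am.fit(am.sample_table(cfg), spec)
        tests = am.named_equivalence_tests(res, "RENEX")
        assert len(tests) == 3
        assert all(t.name == "experts_vs_cad" and t.df == 1 for t in tests)

    def test_wrong_spec_rejected(self, renex_table):
        spec = am.make_spec("nonhomogeneous", renex_table.raters, renex_table.categories)
        res = am.fit(renex_table, spec)
        with pytest.raises(ValueError, match="pairwise_nonhomogeneous"):
            am.named_equivalence_tests(res, "RENEX")

    def test_detects_deflated_cad_agreement(self):
        """Power: CAD pair strengths deflated by 1.0 at n=20,000 are flagged
        by the experts-vs-cad test at alpha=0.01 in >90% of replicates."""
        spec = am.make_spec(
            "pairwise_nonhomogeneous",
            ("expert1", "expert2", "expert3", "RENEX"),
            ("non-obstructed", "equivocal", "obstructed"),
        )
        design = am.build_design(spec)
        agreement = {}
        for lab in design.labels:
            if lab.kind != "agreement":
                continue
            base = {"non-obstructed": 1.0, "equivocal": 0.2, "obstructed": 0.8}[
                lab.category
            ]
            agreement[str(lab)] = base - (1.0 if "RENEX" in lab.raters else 0.0)
        coeffs = am.calibrate_main_effects(spec, agreement, np.array([0.59, 0.16, 0.25]))
        n_reps, rejections = 200, 0
        seeds = np.random.SeedSequence(77).spawn(n_reps)
        for ss in seeds:
            cfg = am.GeneratorConfig(spec, coeffs, n_subjects=20_000, seed=0)
            table = am.sample_table(cfg, seed=ss)
            res = am.fit(table, spec)
            tests = [
                t
                for t in am.named_equivalence_tests(res, "RENEX")
                if t.name == "experts_vs_cad" and t.category == "non-obstructed"
            ]
            rejections += tests[0].p_value < 0.01
        assert rejections / n_reps > 0.9


class TestModelLadder:
    def test_selects_nonhomogeneous_on_renex_table(self, renex_table):
        ladder = am.run_model_ladder(renex_table)
        assert ladder.selected_name == "nonhomogeneous"
        assert ladder.adequate
        rung = ladder.rungs[-1]
        assert rung.deviance == pytest.approx(0.16, abs=0.02)
        assert rung.df == 1
        assert rung.p_value == pytest.approx(0.69, abs=0.01)
        assert [r.adequate for r in ladder.rungs] == [False, False, True]

    def test_exact_independence_selects_independence(self):
        counts = np.outer([10, 20, 30], [2, 3, 5])
        t = am.ContingencyTable(["a", "b"], ["x", "y", "z"], counts)
        ladder = am.run_model_ladder(t)
        assert ladder.selected_name == "independence"
        assert ladder.selected.deviance == pytest.approx(0.0, abs=1e-8)

    def test_large_n_pairwise_generator_selects_pairwise_nonhomogeneous(self):
        cfg = am.preset_renex_panel(n_subjects=20_000, seed=9)
        table = am.sample_table(cfg)
        ladder = am.run_model_ladder(
            table,
            ("independence", "pairwise_homogeneous", "pairwise_nonhomogeneous"),
        )
        assert ladder.selected_name == "pairwise_nonhomogeneous"

    def test_non_nested_ladder_rejected(self, renex_table):
        with pytest.raises(ValueError, match="not nested"):
            am.run_model_ladder(renex_table, ("nonhomogeneous", "independence"))
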