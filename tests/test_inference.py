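"""Stage-2 inference: indicators, permutation p-values, interaction, balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mica import inference, preprocess, synthio, univariate
from mica.containers import COVARIATES, MODIFIER, OUTCOME, CohortTable, MicaError


@pytest.fixture(scope="module")
def big_cohort():
    """Balanced-modifier cohort (2,500/stratum) with the planted 2-taxon clique."""
    cfg = synthio.fixture_config(seed=17, n_samples=5_000, modifier_prevalence=0.5,
                                 missing_rate=0.0)
    table, cohort = synthio.simulate_cohort(cfg)
    cohort = preprocess.add_transformed_outcome(cohort)
    ind = inference.clique_indicator(table, ["ASV0000", "ASV0001"], "pair")
    return table, cohort, ind


class TestCliqueIndicator:
    def test_bounds_for_two_member_clique(self, fixture_cohort):
        _, table, _ = fixture_cohort
        ind = inference.clique_indicator(table, ["ASV0000", "ASV0001"])
        assert set(ind.unique()) <= {0, 1, 2}
        assert ind.max() == 2  # planted joint presence guarantees full counts

    def test_bounds_for_four_member_clique(self, fixture_cohort):
        _, table, _ = fixture_cohort
        members = ["ASV0002", "ASV0003", "ASV0004", "ASV0005"]
        ind = inference.clique_indicator(table, members)
        assert set(ind.unique()) <= {0, 1, 2, 3, 4}

    def test_no_members_present_counts_zero(self):
        df = pd.DataFrame({"A": [0.0, 0.5], "B": [0.0, 0.5]}, index=["S0", "S1"])
        from mica.containers import AbundanceTable
        ind = inference.clique_indicator(AbundanceTable(df), ["A", "B"])
        assert ind.tolist() == [0, 2]

    def test_unknown_member_rejected(self, fixture_cohort):
        _, table, _ = fixture_cohort
        with pytest.raises(MicaError):
            inference.clique_indicator(table, ["ASV0000", "NOPE"])


class TestCliqueAssociation:
    def test_recovers_stratum_slopes(self, big_cohort):
        _, cohort, ind = big_cohort
        ins = inference.clique_association(cohort, ind, "insecure", permute=False)
        sec = inference.clique_association(cohort, ind, "secure", permute=False)
        assert ins.beta == pytest.approx(0.29, abs=0.03)
        assert sec.beta == pytest.approx(0.05, abs=0.03)

    def test_delegates_to_ols(self, big_cohort):
        _, cohort, ind = big_cohort
        res = inference.clique_association(cohort, ind, "secure", permute=False)
        mask = cohort.stratum_mask("secure").to_numpy()
        design = cohort.data.loc[mask, COVARIATES].astype(float)
        design.insert(0, "clique", ind.to_numpy()[mask].astype(float))
        oracle = univariate.ols_fit(cohort.data.loc[mask, OUTCOME].to_numpy(),
                                    design, "clique")
        assert res.beta == pytest.approx(oracle.beta, abs=1e-10)

    def test_constant_indicator_rejected(self, big_cohort):
        _, cohort, _ = big_cohort
        flat = pd.Series(np.ones(cohort.n_samples), index=cohort.sample_ids, name="flat")
        with pytest.raises(MicaError):
            inference.clique_association(cohort, flat, "secure", permute=False)


class TestPermutationP:
    def _null_fit(self, seed, n=80, n_perm=2_000):
        rng = np.random.default_rng(seed)
        design = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        y = rng.normal(size=n)
        return y, design

    def test_floor_never_zero(self):
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"x": rng.normal(size=100)})
        y = 5 * design["x"].to_numpy() + rng.normal(0, 0.1, 100)
        res = inference.permutation_p(y, design, "x", n_permutations=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501)

    def test_agrees_with_t_test_under_gaussian_null(self):
        import statsmodels.api as sm

        y, design = self._null_fit(7)
        res = inference.permutation_p(y, design, "x", n_permutations=2_000, seed=2)
        fit = sm.OLS(y, sm.add_constant(design.to_numpy())).fit()
        p_t = fit.pvalues[1]
        tol = 2 * np.sqrt(p_t * (1 - p_t) / 2_000)
        assert abs(res.p_value - p_t) < tol + 1e-3

    def test_invariant_to_covariate_column_order(self):
        y, design = self._null_fit(11)
        p1 = inference.permutation_p(y, design, "x", n_permutations=500, seed=3).p_value
        p2 = inference.permutation_p(y, design[["z", "x"]], "x",
                                     n_permutations=500, seed=3).p_value
        assert p1 == p2

    def test_reproducible_given_seed(self):
        y, design = self._null_fit(13)
        p1 = inference.permutation_p(y, design, "x", n_permutations=500, seed=4).p_value
        p2 = inference.permutation_p(y, design, "x", n_permutations=500, seed=4).p_value
        assert p1 == p2


class TestCrossStratumValidation:
    def test_effect_in_both_strata_validates(self):
        cfg = synthio.fixture_config(seed=21, n_samples=4_000, modifier_prevalence=0.5,
                                     missing_rate=0.0)
        cfg.cliques[0].effect_by_stratum = {0: 0.25, 1: 0.25}
        table, cohort = synthio.simulate_cohort(cfg)
        cohort = preprocess.add_transformed_outcome(cohort)
        ind = inference.clique_indicator(table, ["ASV0000", "ASV0001"], "pair")
        disc = inference.clique_association(cohort, ind, "insecure", permute=False)
        val = inference.cross_stratum_validate(cohort, ind, "insecure",
                                               n_permutations=500, seed=5)
        assert disc.ci_low > 0
        assert val.ci_low > 0
        assert val.stratum == "secure"
        assert val.term == "pair"

    def test_null_stratum_shows_no_effect(self, big_cohort):
        # secure-stratum truth is 0.05; a clique planted only in the insecure
        # stratum stays near zero when validated in a null stratum
        cfg = synthio.fixture_config(seed=23, n_samples=4_000, modifier_prevalence=0.5,
                                     missing_rate=0.0)
        cfg.cliques[0].effect_by_stratum = {0: 0.0, 1: 0.29}
        table, cohort = synthio.simulate_cohort(cfg)
        cohort = preprocess.add_transformed_outcome(cohort)
        ind = inference.clique_indicator(table, ["ASV0000", "ASV0001"], "pair")
        val = inference.cross_stratum_validate(cohort, ind, "insecure",
                                               n_permutations=500, seed=5)
        assert abs(val.beta) < 2 * val.se


class TestInteraction:
    def test_difference_of_slopes(self, big_cohort):
        _, cohort, ind = big_cohort
        res = inference.interaction_test(cohort, ind, n_permutations=500, seed=5)
        assert res.beta == pytest.approx(0.24, abs=0.04)

    def test_equal_slopes_give_null_interaction(self):
        cfg = synthio.fixture_config(seed=27, n_samples=3_000, modifier_prevalence=0.5,
                                     missing_rate=0.0)
        cfg.cliques[0].effect_by_stratum = {0: 0.15, 1: 0.15}
        table, cohort = synthio.simulate_cohort(cfg)
        cohort = preprocess.add_transformed_outcome(cohort)
        ind = inference.clique_indicator(table, ["ASV0000", "ASV0001"], "pair")
        res = inference.interaction_test(cohort, ind, n_permutations=500, seed=6)
        assert abs(res.beta) < 2 * res.se

    def test_stratified_and_interaction_algebra(self, big_cohort):
        # beta_insecure ~ beta_secure + interaction within 2 SE
        _, cohort, ind = big_cohort
        ins = inference.clique_association(cohort, ind, "insecure", permute=False)
        sec = inference.clique_association(cohort, ind, "secure", permute=False)
        inter = inference.interaction_test(cohort, ind, n_permutations=1, seed=0)
        assert ins.beta - sec.beta == pytest.approx(inter.beta, abs=2 * inter.se)


class TestBalanceDiagnostics:
    def _cohort(self, n=600, confounded=False, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.normal(60, 10, n)
        expose_p = 1 / (1 + np.exp(-(age - 60) / 5)) if confounded else np.full(n, 0.5)
        exposed = rng.random(n) < expose_p
        data = pd.DataFrame({
            "cognitive_score": rng.integers(0, 4, n),
            MODIFIER: rng.integers(0, 2, n),
            "age": age, "bmi": rng.normal(31, 5, n), "fiber_g": rng.gamma(4, 5, n),
            "female": rng.integers(0, 2, n), "race_other": rng.integers(0, 2, n),
            "pet_owner": rng.integers(0, 2, n), "ever_smoker": rng.integers(0, 2, n),
            "antibiotics": rng.integers(0, 2, n),
        }, index=[f"S{i}" for i in range(n)])
        ind = pd.Series(exposed.astype(int), index=data.index, name="clique")
        return CohortTable(data), ind

    def test_identical_groups_have_zero_smd(self):
        cohort, _ = self._cohort()
        # duplicate every sample once exposed, once unexposed
        doubled = CohortTable(pd.concat([cohort.data, cohort.data.set_index(
            cohort.data.index + "_b")]))
        ind = pd.Series([1] * cohort.n_samples + [0] * cohort.n_samples,
                        index=doubled.data.index)
        table = inference.balance_diagnostics(doubled, ind)
        assert np.allclose(table["smd_before"], 0.0, atol=1e-12)

    def test_one_sd_shift_gives_unit_smd(self):
        cohort, ind = self._cohort(seed=2)
        sd = cohort.data["bmi"].std(ddof=1)
        cohort.data.loc[ind == 1, "bmi"] += sd
        table = inference.balance_diagnostics(cohort, ind)
        smd = table.set_index("covariate").loc["bmi", "smd_before"]
        assert smd == pytest.approx(1.0, abs=0.15)  # pooled-SD denominator

    def test_subclassification_improves_balance(self):
        cohort, ind = self._cohort(confounded=True, seed=3)
        table = inference.balance_diagnostics(cohort, ind)
        assert table["smd_after"].abs().mean() < table["smd_before"].abs().mean()

    def test_degenerate_exposure_rejected(self):
        cohort, _ = self._cohort()
        allon = pd.Series(np.ones(cohort.n_samples, dtype=int), index=cohort.data.index)
        with pytest.raises(MicaError):
            inference.balance_diagnostics(cohort, allon)
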