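import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from carabidfa import asymmetry as a
from carabidfa import synthetic as syn
from carabidfa.synthetic import TraitSpec
from carabidfa.traits import assess_measurement_error

from conftest import one_species_cohort


class TestSignedRelativeAsymmetry:
    def test_symmetric_input_zero(self):
        assert a.signed_relative_asymmetry(2.0, 2.0) == 0.0

    def test_hand_evaluated(self):
        assert a.signed_relative_asymmetry(1.1, 0.9) == pytest.approx(0.2)

    def test_side_swap_antisymmetry(self):
        assert a.signed_relative_asymmetry(0.9, 1.1) == pytest.approx(-0.2)

    def test_degenerate_zero_sum_is_nan(self):
        assert np.isnan(a.signed_relative_asymmetry(0.0, 0.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.001, 1000))
    def test_antisymmetry_and_scale_invariance(self, R, L, k):
        s = a.signed_relative_asymmetry(R, L)
        assert a.signed_relative_asymmetry(L, R) == pytest.approx(-s, abs=1e-12)
        assert a.signed_relative_asymmetry(k * R, k * L) == pytest.approx(
            s, rel=1e-9, abs=1e-12)


class TestCorrectedFA:
    def test_identical_s_all_zero(self):
        idx = a.corrected_fa(pd.Series([0.3] * 8))
        assert np.allclose(idx.values, 0.0)
        assert idx.da_term == pytest.approx(0.3)

    def test_hand_arithmetic_two_individuals(self):
        idx = a.corrected_fa(pd.Series([0.1, -0.1]), min_n=2)
        assert np.allclose(sorted(idx.values), [-0.1, 0.1])
        assert idx.da_term == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=5, max_size=40))
    def test_cohort_sum_always_zero(self, values):
        idx = a.corrected_fa(pd.Series(values))
        assert abs(idx.values.sum()) < 1e-12

    def test_below_minimum_n_raises(self):
        with pytest.raises(ValueError, match="below minimum"):
            a.corrected_fa(pd.Series([0.1, 0.2]))

    def test_unit_rescaling_invariance(self, small_individuals):
        spec = TraitSpec("a2", fa_sd=0.01, me_sd=0.002)
        meas = syn.simulate_bilateral(small_individuals, spec, seed=31)
        tab_mm = a.asymmetry_table(small_individuals, meas, "a2")
        meas_cm = meas.assign(value=meas["value"] / 10.0)  # mm -> cm
        tab_cm = a.asymmetry_table(small_individuals, meas_cm, "a2")
        assert np.allclose(tab_mm["s"], tab_cm["s"])
        fa_mm = a.corrected_fa(tab_mm["s"]).values
        fa_cm = a.corrected_fa(tab_cm["s"]).values
        assert np.allclose(fa_mm, fa_cm)

    def test_da_test_on_corrected_values_degenerate(self):
        """Guard: the DA t-test must run on uncorrected s — on the corrected
        index it is identically ~0 and can never flag."""
        rng = np.random.default_rng(5)
        s = pd.Series(rng.normal(0.3, 0.05, 40))  # strong DA
        t_raw, p_raw, flag_raw = a.test_directional_asymmetry(s)
        assert flag_raw
        fa = a.corrected_fa(s).values
        t_c, p_c, flag_c = a.test_directional_asymmetry(fa)
        assert abs(t_c) < 1e-8 and not flag_c


class TestGates:
    def test_da_test_type_i_calibrated(self):
        rej = 0
        for i in range(500):
            s = np.random.default_rng(i).normal(0, 0.02, 50)
            rej += a.test_directional_asymmetry(s)[2]
        assert 0.03 <= rej / 500 <= 0.07

    def test_da_power_at_effect_size_one(self):
        """delta = sigma at n = 50: noncentral-t power ~ 1."""
        flagged = 0
        for i in range(100):
            s = np.random.default_rng(2000 + i).normal(0.02, 0.02, 50)
            flagged += a.test_directional_asymmetry(s)[2]
        # oracle: power = P(|T'| > t_crit), T' noncentral t, ncp = sqrt(50)
        ncp = np.sqrt(50)
        tcrit = stats.t.ppf(0.975, 49)
        power = stats.nct.sf(tcrit, 49, ncp) + stats.nct.cdf(-tcrit, 49, ncp)
        assert power > 0.99
        assert flagged / 100 >= 0.99

    def test_da_all_zero_not_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t_, p, flag = a.test_directional_asymmetry(np.zeros(20))
        assert not flag and p == 1.0

    def test_antisymmetry_mixture_flagged(self):
        """+-a mixture: excess kurtosis ~ -2; flagged in >= 95% at n=60."""
        hits, kurts = 0, []
        for i in range(100):
            rng = np.random.default_rng(3000 + i)
            s = rng.choice([-0.05, 0.05], 60) + rng.normal(0, 0.005, 60)
            k, p, flag = a.test_antisymmetry(s)
            hits += flag
            kurts.append(k)
        assert hits / 100 >= 0.95
        assert np.mean(kurts) == pytest.approx(-2.0, abs=0.25)

    def test_antisymmetry_gaussian_calibrated(self):
        rej = 0
        for i in range(500):
            s = np.random.default_rng(4000 + i).normal(0, 0.02, 60)
            rej += a.test_antisymmetry(s)[2]
        assert rej / 500 <= 0.07

    def test_antisymmetry_small_n_no_verdict(self):
        with pytest.warns(UserWarning, match="n < 10"):
            k, p, flag = a.test_antisymmetry(np.random.default_rng(0).normal(size=8))
        assert not flag and np.isnan(p)

    def test_size_dependence_calibrated_and_powered(self):
        rej = 0
        for i in range(300):
            rng = np.random.default_rng(5000 + i)
            body = rng.normal(5, 0.5, 60)
            d = np.abs(rng.normal(0, 0.02, 60))
            rej += a.test_size_dependence(d, body)[2]
        assert 0.02 <= rej / 300 <= 0.08
        # injected slope from the archetype card
        hits = 0
        for i in range(100):
            rng = np.random.default_rng(6000 + i)
            body = rng.normal(5, 0.5, 60)
            z = (body - body.mean()) / body.std()
            d = np.abs(rng.normal(0, 0.012, 60) * (1 + 0.6 * z))
            hits += a.test_size_dependence(d, body)[2]
        assert hits / 100 >= 0.90

    def test_size_dependence_all_zero_diff(self):
        rng = np.random.default_rng(1)
        f, p, flag = a.test_size_dependence(np.zeros(30), rng.normal(5, 0.5, 30))
        assert f == 0.0 and not flag

    def test_constant_body_size_warns(self):
        with pytest.warns(UserWarning, match="constant body size"):
            _, _, flag = a.test_size_dependence(np.abs(np.random.default_rng(0)
                                                       .normal(size=20)),
                                                np.full(20, 5.0))
        assert not flag


class TestClassification:
    def _assessment(self, **flags):
        from carabidfa.traits import MEAssessment
        me = MEAssessment("sp", "a2", 40, 1, 1, 1, 0.1, 10.0, 0.001, 5.0,
                          verdict=flags.get("me", "resolvable"))
        da = (2.0, 0.01 if flags.get("da") else 0.5, bool(flags.get("da")))
        anti = (-1.0, 0.01 if flags.get("anti") else 0.5, bool(flags.get("anti")))
        size = (3.0, 0.01 if flags.get("size") else 0.5, bool(flags.get("size")))
        return a.classify_trait(me, da, anti, size, n=40, species="sp", trait="a2")

    def test_all_negative_true_fa(self):
        res = self._assessment()
        assert res.verdict == "true_FA" and res.usable_for_fa

    def test_da_beats_size(self):
        res = self._assessment(da=True, size=True)
        assert res.verdict == "DA" and not res.usable_for_fa
        assert res.needs_size_covariate

    def test_me_beats_everything(self):
        res = self._assessment(me="ME_dominated", da=True, anti=True)
        assert res.verdict == "ME_dominated"

    def test_anti_beats_da(self):
        res = self._assessment(da=True, anti=True)
        assert res.verdict == "antisymmetry"

    def test_size_only_usable_with_covariate(self):
        res = self._assessment(size=True)
        assert res.verdict == "size_dependent"
        assert res.usable_for_fa and res.needs_size_covariate

    def test_archetype_recovery_smoke(self):
        """Small-scale verdict recovery; the full 5 x 200 experiment runs in
        the acceptance suite."""
        correct = total = 0
        for rep in range(30):
            for label, ind, meas in syn.make_archetype_suite(7000 + rep, 60):
                gates = a.gate_traits(ind, meas)
                total += 1
                correct += gates.loc[0, "verdict"] == label
        assert correct / total >= 0.85


class TestFAModels:
    def test_treatment_lmm_detects_inflated_clearing(self):
        """50% FA-sd inflation in the clearing at n ~ 60/group is detected
        in >= 80% of replicates."""
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            ind = syn.simulate_individuals(10, seed=8000 + i)  # 360 inds
            ind = ind.groupby("treatment", group_keys=False).apply(
                lambda g: g.iloc[:60]).reset_index(drop=True)
            rng = np.random.default_rng(8000 + i)
            n = len(ind)
            sd = np.where(ind["treatment"] == "clearing", 0.018, 0.012)
            s = rng.normal(0, sd)
            d = pd.DataFrame({
                "fa": np.abs(s - s.mean()),
                "treatment": ind["treatment"], "month": ind["month"],
                "individual_id": ind["individual_id"],
            })
            lmm, _, _ = a.fit_treatment_lmm(d)
            p = lmm.wald_table.set_index("term").loc["C(treatment)", "p"]
            hits += p < 0.05
        assert hits / n_rep >= 0.80

    def test_treatment_lmm_null_calibrated(self):
        ps = []
        for i in range(100):
            rng = np.random.default_rng(9000 + i)
            ind = syn.simulate_individuals(3, seed=9000 + i)
            s = rng.normal(0, 0.012, len(ind))
            d = pd.DataFrame({"fa": np.abs(s - s.mean()),
                              "treatment": ind["treatment"],
                              "month": ind["month"],
                              "individual_id": ind["individual_id"]})
            lmm, _, _ = a.fit_treatment_lmm(d)
            ps.append(lmm.wald_table.set_index("term").loc["C(treatment)", "p"])
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.10

    def test_tukey_identical_groups(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(0, 0.01, 60))
        d = pd.DataFrame({
            "fa": np.tile(base, 3) + rng.normal(0, 1e-7, 180),
            "treatment": np.repeat(["clearing", "control", "ecotone"], 60),
            "month": np.tile(np.arange(1, 7).repeat(10), 3),
            "individual_id": [f"i{k}" for k in range(180)],
        })
        _, _, contrasts = a.fit_treatment_lmm(d)
        assert (contrasts["p_tukey"] > 0.95).all()

    def test_interaction_models_stages_and_levene(self):
        ind, meas = one_species_cohort(TraitSpec("a2", fa_sd=0.012,
                                                 me_sd=0.002), n=72, seed=17)
        tab = a.fa_model_table(ind, meas, "a2", ind["species"].iloc[0])
        res = a.fit_interaction_models(tab)
        assert set(res["stages"]) == {"wing_sex", "treatment_wing", "full"}
        assert res["stages"]["full"] is not None
        assert 0 <= res["levene_p"] <= 1

    def test_levene_equal_variance_calibrated(self):
        rej = 0
        for i in range(300):
            rng = np.random.default_rng(11_000 + i)
            groups = [rng.normal(0, 1, 30) for _ in range(4)]
            rej += stats.levene(*groups, center="median")[1] < 0.05
        assert 0.02 <= rej / 300 <= 0.08

    def test_sex_specific_fa_detected(self):
        """Injected male FA inflation surfaces in the final-stage sex term."""
        hits = 0
        for i in range(30):
            ind = syn.simulate_individuals(6, seed=12_000 + i)
            rng = np.random.default_rng(12_000 + i)
            sd = np.where(ind["sex"] == "M", 0.022, 0.012)
            s = rng.normal(0, sd)
            d = pd.DataFrame({
                "fa": np.abs(s - s.mean()), "sex": ind["sex"],
                "treatment": ind["treatment"],
                "wing_morph_num": ind["wing_morph_code"].astype(float),
            })
            res = a.fit_interaction_models(d)
            full = res["stages"]["full"]
            hits += full.loc["C(sex)", "PR(>F)"] < 0.05
        assert hits / 30 >= 0.80


class TestConcordance:
    def test_identical_rankings_w_one(self):
        base = np.arange(1, 11, dtype=float)
        m = pd.DataFrame({"t1": base, "t2": base * 2, "t3": base + 5})
        W, chi2, p = a.kendall_w(m)
        assert W == pytest.approx(1.0)
        assert p < 0.01

    def test_two_reversed_rankings_w_zero(self):
        base = np.arange(1, 9, dtype=float)
        m = pd.DataFrame({"t1": base, "t2": base[::-1]})
        W, _, _ = a.kendall_w(m)
        assert W == pytest.approx(0.0, abs=1e-12)

    def test_matches_friedman_chi2(self):
        """Independent scipy oracle: Friedman chi-square == m(n-1)W for
        untied data (judges as blocks)."""
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        W, chi2, _ = a.kendall_w(m)
        # Friedman's treatments are the ranked subjects (rows); the traits
        # act as blocks
        fr = stats.friedmanchisquare(*[m.loc[i] for i in m.index])
        assert chi2 == pytest.approx(fr.statistic, rel=1e-10)

    def test_random_rankings_rarely_significant(self):
        rej = 0
        for i in range(100):
            m = pd.DataFrame(np.random.default_rng(i).normal(size=(30, 3)))
            rej += a.kendall_w(m)[2] < 0.05
        assert rej / 100 <= 0.12

    def test_bonferroni_and_minimum_traits(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        res = a.kendall_concordance(m, n_species_tested=4)
        assert res["p_bonferroni"] >= res["p"]
        with pytest.raises(ValueError, match="at least 3"):
            a.kendall_concordance(m[["a", "b"]])


class TestEnvBGLM:
    def test_injected_litter_effect_recovered(self, community_tables):
        comm, env, _ = community_tables
        ind = syn.simulate_individuals(4, seed=33)
        spec = TraitSpec("a2", fa_sd=0.012, me_sd=0.002)
        meas = syn.simulate_bilateral(ind, spec, seed=33)
        tab = a.fa_model_table(ind, meas, "a2", ind["species"].iloc[0])
        tab["sample_id"] = tab["site_id"].astype(str) + "-m" + tab["month"].astype(str)
        litter = env.set_index("sample_id")["litter"]
        lz = (litter - litter.mean()) / litter.std()
        rng = np.random.default_rng(33)
        tab["fa"] = (0.02 + 0.01 * tab["sample_id"].map(lz).fillna(0)
                     + rng.normal(0, 0.004, len(tab)))
        post = a.fit_env_bglm(tab, env, seed=4, iterations=2000)
        row = post.table.loc["litter"]
        assert row["prob_direction"] >= 0.95 and row["mean"] > 0

    def test_join_and_diagnostics(self, community_tables):
        comm, env, _ = community_tables
        ind = syn.simulate_individuals(2, seed=44)
        meas = syn.simulate_bilateral(ind, TraitSpec("a2", fa_sd=0.012,
                                                     me_sd=0.002), seed=44)
        tab = a.fa_model_table(ind, meas, "a2", ind["species"].iloc[0])
        post = a.fit_env_bglm(tab, env, seed=1, iterations=1000)
        fixed = post.table[post.table["kind"] == "fixed"]
        assert set(a.ENV_PREDICTORS) <= set(fixed.index)
        assert post.rhat_threshold == 1.2
        assert 0 <= post.pareto_k_good_pct <= 100
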