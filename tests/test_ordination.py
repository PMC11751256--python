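import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import eig, inv

from carabidfa import ordination as o
from carabidfa import synthetic as syn
from carabidfa.synthetic import CommunitySpec


def brute_force_cca_eigenvalues(Y, X, Z=None):
    """Direct generalized-eigenproblem solution of (partial) CCA.

    Independent of the package's SVD-of-projection path: builds the weighted
    cross-product matrices explicitly and calls a dense eigensolver.
    """
    Yv = np.asarray(Y, float)
    total = Yv.sum()
    P = Yv / total
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    def wcenter(M):
        return (M - r @ M) * np.sqrt(r)[:, None]
    Xw = wcenter(np.asarray(X, float))
    if Z is not None and np.asarray(Z).size:
        Zw = wcenter(np.asarray(Z, float))
        Hz = Zw @ inv(Zw.T @ Zw) @ Zw.T
        Q = Q - Hz @ Q
        Xw = Xw - Hz @ Xw
    Sxx = Xw.T @ Xw
    Sxq = Xw.T @ Q
    M = inv(Sxx) @ Sxq @ Sxq.T
    w = np.real(eig(M)[0])
    w = np.sort(w[w > 1e-12])[::-1]
    return w


class TestTransform:
    def test_log_of_zero_is_zero(self):
        Y = pd.DataFrame([[0.0, 4.0], [2.0, 1.0]], columns=["a", "b"])
        out = o.transform_abundances(Y, log=True, downweight=False)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(np.log(5))

    def test_equal_frequencies_downweight_identity(self):
        Y = pd.DataFrame(np.ones((4, 3)))
        out = o.transform_abundances(Y, log=False, downweight=True)
        pd.testing.assert_frame_equal(out, Y.astype(float))

    def test_downweight_rule_hand_evaluated(self):
        """25 samples, f_max = 25 => threshold 5; a species present in 2
        samples gets weight 2/5 = 0.4; a species at the threshold is
        untouched."""
        Y = pd.DataFrame(0.0, index=range(25), columns=["common", "rare", "edge"])
        Y["common"] = 1.0
        Y.loc[:1, "rare"] = 1.0
        Y.loc[:4, "edge"] = 1.0
        out = o.transform_abundances(Y, log=False, downweight=True)
        assert out.loc[0, "rare"] == pytest.approx(0.4)
        assert out.loc[0, "edge"] == pytest.approx(1.0)
        assert out.loc[0, "common"] == pytest.approx(1.0)

    def test_all_zero_matrix_fatal(self):
        with pytest.raises(ValueError, match="all-zero"):
            o.transform_abundances(pd.DataFrame(np.zeros((3, 3))))


class TestPCCA:
    def test_eigenvalues_match_brute_force_oracle(self, toy_community):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=5)}, index=toy_community.index)
        fit = o.fit_pcca(toy_community, X, None)
        oracle = brute_force_cca_eigenvalues(toy_community, X)
        assert np.allclose(fit.eigenvalues, oracle[: len(fit.eigenvalues)],
                           atol=1e-8)

    def test_partial_eigenvalues_match_oracle(self, toy_community):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=5)}, index=toy_community.index)
        Z = pd.DataFrame({"z": rng.normal(size=5)}, index=toy_community.index)
        fit = o.fit_pcca(toy_community, X, Z)
        oracle = brute_force_cca_eigenvalues(toy_community, X, Z)
        assert np.allclose(fit.eigenvalues, oracle[: len(fit.eigenvalues)],
                           atol=1e-8)

    def test_matches_skbio_cca(self, toy_community):
        """Independent library cross-check on the unpartialled case."""
        from skbio.stats.ordination import cca as skcca
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=5), "w": rng.normal(size=5)},
                         index=toy_community.index)
        fit = o.fit_pcca(toy_community, X, None)
        sk = skcca(toy_community, X)
        k = len(fit.eigenvalues)
        assert np.allclose(fit.eigenvalues, sk.eigvals.values[:k], atol=1e-8)

    def test_empty_covariables_equals_plain_cca(self, toy_community):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.normal(size=5)}, index=toy_community.index)
        a = o.fit_pcca(toy_community, X, None)
        b = o.fit_pcca(toy_community, X, pd.DataFrame(index=toy_community.index))
        assert np.allclose(a.eigenvalues, b.eigenvalues)
        assert a.explained_fraction == pytest.approx(b.explained_fraction)

    def test_partialling_cannot_increase_constrained_inertia(self):
        comm, env, _ = syn.simulate_community(CommunitySpec(), seed=5)
        Yt = o.transform_abundances(comm)
        X = env[["herbs"]]
        Z = env[["air_temp"]]
        with_z = o.fit_pcca(Yt, X, Z)
        without = o.fit_pcca(Yt, X, None)
        assert with_z.constrained_inertia <= without.constrained_inertia + 1e-12

    def test_eigenvalues_sorted_in_unit_interval(self, community_tables):
        comm, env, _ = community_tables
        fit = o.fit_pcca(o.transform_abundances(comm),
                         env[["herbs", "litter"]], env[["air_temp"]])
        e = fit.eigenvalues
        assert np.all(np.diff(e) <= 1e-12)
        assert np.all((e >= 0) & (e < 1))

    def test_aliased_constraint_dropped_with_warning(self, toy_community):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5)
        X = pd.DataFrame({"x": x, "x2": 2 * x}, index=toy_community.index)
        with pytest.warns(UserWarning, match="aliased"):
            fit = o.fit_pcca(toy_community, X, None)
        assert fit.rank_constraints == 1


class TestRestrictedPermutations:
    def test_zero_shift_reproduces_identity(self):
        blocks = np.array(["a"] * 4 + ["b"] * 4)
        rng_zero = np.random.default_rng(0)

        class FakeRng:
            def integers(self, n):
                return 0
        idx = o._cyclic_shift_indices(blocks, FakeRng())
        assert np.array_equal(idx, np.arange(8))

    def test_block_of_length_T_has_T_orderings(self):
        blocks = np.array(["a"] * 5)
        rng = np.random.default_rng(0)
        seen = {tuple(o._cyclic_shift_indices(blocks, rng)) for _ in range(400)}
        assert len(seen) == 5  # cyclic group order

    def test_p_value_on_lattice(self, community_tables):
        comm, env, _ = community_tables
        blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
        f, p = o.restricted_permutation_test(
            o.transform_abundances(comm), env[["herbs"]], None, blocks,
            n_perm=99, seed=0)
        assert f > 0
        assert p in {k / 100 for k in range(1, 101)}

    def test_null_rejection_rate_calibrated(self):
        """No env-species association: rejection at alpha = .05 in [.03, .07]
        (150 replicates; the full 500-replicate calibration runs in the
        acceptance suite)."""
        rej = 0
        n_rep = 150
        for i in range(n_rep):
            spec = CommunitySpec(association=0.0, n_species=8,
                                 abundance_scale=10)
            comm, env, _ = syn.simulate_community(spec, seed=10_000 + i)
            blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
            _, p = o.restricted_permutation_test(
                comm, env[["herbs"]], None, blocks, n_perm=99, seed=i)
            rej += p <= 0.05
        assert 0.02 <= rej / n_rep <= 0.09  # wider band at 150 reps


class TestForwardSelection:
    def test_single_candidate_equals_marginal(self, community_tables):
        comm, env, _ = community_tables
        Yt = o.transform_abundances(comm)
        blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
        cand = env[["herbs"]]
        tab = o.forward_select(Yt, cand, None, blocks, n_perm=49, seed=0)
        fit = o.fit_pcca(Yt, cand, None)
        assert tab.loc[0, "conditional_explained_pct"] == pytest.approx(
            100 * fit.explained_fraction, abs=1e-8)

    def test_duplicate_candidate_has_zero_conditional_effect(self, community_tables):
        comm, env, _ = community_tables
        Yt = o.transform_abundances(comm)
        blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
        cand = pd.DataFrame({"herbs": env["herbs"], "herbs_copy": env["herbs"]})
        tab = o.forward_select(Yt, cand, None, blocks, n_perm=49, seed=0)
        assert tab.loc[1, "conditional_explained_pct"] == pytest.approx(0, abs=1e-8)

    def test_adjusted_p_not_below_raw(self, community_tables):
        comm, env, _ = community_tables
        Yt = o.transform_abundances(comm)
        blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
        cand = env[["herbs", "litter", "soil_moisture"]]
        tab = o.forward_select(Yt, cand, None, blocks, n_perm=49, seed=1)
        assert (tab["p_adj"] >= tab["p"] - 1e-12).all()

    def test_driving_gradient_selected_first(self):
        """When composition follows the latent open-habitat gradient, herbs
        (its strongest env correlate) wins the first selection step nearly
        always."""
        first = []
        for i in range(40):
            spec = CommunitySpec(association=1.5, n_species=12)
            comm, env, _ = syn.simulate_community(spec, seed=500 + i)
            Yt = o.transform_abundances(comm)
            blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
            cand = env[["herbs", "soil_moisture", "air_temp"]]
            tab = o.forward_select(Yt, cand, None, blocks, n_perm=9, seed=i)
            first.append(tab.loc[0, "variable"])
        assert np.mean([f == "herbs" for f in first]) >= 0.9


class TestTraitSummaries:
    def test_cwm_single_species(self):
        Y = pd.DataFrame({"a": [3.0, 1.0]}, index=["s1", "s2"])
        cwm = o.compute_cwm(Y, pd.Series({"a": 2.5}))
        assert (cwm == 2.5).all()

    def test_cwm_hand_weighted(self):
        Y = pd.DataFrame([[1.0, 3.0]], columns=["a", "b"])
        cwm = o.compute_cwm(Y, pd.Series({"a": 0.0, "b": 1.0}))
        assert cwm.iloc[0] == pytest.approx(0.75)

    def test_cwm_constant_trait_and_bounds(self, toy_community):
        vals = pd.Series(0.7, index=toy_community.columns)
        assert np.allclose(o.compute_cwm(toy_community, vals), 0.7)
        rng = np.random.default_rng(0)
        vals2 = pd.Series(rng.uniform(0, 5, toy_community.shape[1]),
                          index=toy_community.columns)
        cwm = o.compute_cwm(toy_community, vals2)
        assert (cwm >= vals2.min() - 1e-12).all()
        assert (cwm <= vals2.max() + 1e-12).all()

    def test_cwm_zero_abundance_sample_missing(self):
        Y = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], columns=["a", "b"])
        cwm = o.compute_cwm(Y, pd.Series({"a": 1.0, "b": 2.0}))
        assert np.isnan(cwm.iloc[0]) and cwm.iloc[1] == pytest.approx(1.5)

    def test_raoq_single_species_zero(self):
        Y = pd.DataFrame({"a": [5.0]})
        D = pd.DataFrame(0.0, index=["a"], columns=["a"])
        assert o.compute_raoq(Y, D).iloc[0] == 0.0

    def test_raoq_brute_force_double_sum(self, toy_community):
        rng = np.random.default_rng(8)
        n = toy_community.shape[1]
        A = rng.uniform(0, 1, (n, n))
        D = pd.DataFrame((A + A.T) / 2, index=toy_community.columns,
                         columns=toy_community.columns)
        np.fill_diagonal(D.values, 0.0)
        q = o.compute_raoq(toy_community, D)
        # brute-force double sum, sample by sample
        for s in toy_community.index:
            p = toy_community.loc[s] / toy_community.loc[s].sum()
            expect = sum(D.loc[i, j] * p[i] * p[j]
                         for i in D.index for j in D.columns)
            assert q[s] == pytest.approx(expect, abs=1e-12)

    def test_raoq_simpson_identity(self):
        """With all between-species distances 1, Q = 1 - sum p_i^2."""
        Y = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], columns=["a", "b"])
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        q = o.compute_raoq(Y, D)
        assert q.iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert q.iloc[1] == pytest.approx(1 - (0.25 ** 2 + 0.75 ** 2), abs=1e-12)

    def test_raoq_equal_abundance_closed_form(self):
        for n in (2, 5, 9):
            Y = pd.DataFrame([np.ones(n)], columns=[f"s{i}" for i in range(n)])
            D = pd.DataFrame(1.0 - np.eye(n), index=Y.columns, columns=Y.columns)
            assert o.compute_raoq(Y, D).iloc[0] == pytest.approx(1 - 1 / n,
                                                                 abs=1e-12)

    def test_raoq_asymmetric_distance_fatal(self):
        Y = pd.DataFrame([[1.0, 1.0]], columns=["a", "b"])
        D = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            o.compute_raoq(Y, D)


class TestPassiveProjection:
    @pytest.fixture
    def fitted(self, community_tables):
        comm, env, _ = community_tables
        return o.fit_pcca(o.transform_abundances(comm),
                          env[["herbs", "litter"]], None)

    def test_axis_score_projects_onto_own_axis(self, fitted):
        v = fitted.site_scores["CCA1"]
        proj = o.project_supplementary(fitted, v.rename("v"))
        assert abs(proj.loc["v", "CCA1"]) > 10 * abs(proj.loc["v", "CCA2"])

    def test_negated_axis_flips_sign(self, fitted):
        v = -fitted.site_scores["CCA2"]
        proj = o.project_supplementary(fitted, v.rename("v"))
        assert proj.loc["v", "CCA2"] < 0

    def test_constant_vector_zero_arrow(self, fitted):
        v = pd.Series(3.0, index=fitted.site_scores.index, name="const")
        with pytest.warns(UserWarning, match="constant"):
            proj = o.project_supplementary(fitted, v)
        assert np.allclose(proj.loc["const"], 0.0)
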