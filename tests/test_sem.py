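import numpy as np
import pandas as pd
import pytest

from richscape import sem
from richscape import simulate as sim


def manual_path_model(coeffs, resid=0.5):
    """PathModel shell with prescribed standardized coefficients."""
    keys = {"C~A": "g_ca", "C~T": "g_ct", "S~A": "g_sa", "S~T": "g_st",
            "R~T": "b_t", "R~C": "b_c", "R~S": "b_s", "R~A": "b_a"}
    coefficients = {k: coeffs.get(v, 0.0) for k, v in keys.items()}
    return sem.PathModel(coefficients=coefficients,
                         se={k: 0.01 for k in coefficients},
                         ci95={k: (0, 0) for k in coefficients},
                         resid_var={"C": resid, "S": resid, "R": resid},
                         n=1000, exog_cov=np.eye(2))


COEF_KEY = {"C~A": "g_ca", "C~T": "g_ct", "S~A": "g_sa", "S~T": "g_st",
            "R~T": "b_t", "R~C": "b_c", "R~S": "b_s", "R~A": "b_a"}


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(0)
    idx = {g: rng.normal(size=2000) for g in
           ("climate", "soil", "terrain", "anthropogenic")}
    cols, groups = {}, {}
    for g, v in idx.items():
        for i in range(2):
            name = f"{g[:3]}{i}"
            cols[name] = 0.9 * v + 0.44 * rng.normal(size=2000)
            groups[name] = g
    return pd.DataFrame(cols), groups, idx


@pytest.fixture(scope="module")
def fitted():
    df = sim.simulate_structural_data({}, 5000, seed=2)
    idx = sem.indices_from_table(df)
    return idx, sem.fit_path_model(idx)


class TestIndices:
    def test_single_variable_group_equals_standardized_variable(self):
        rng = np.random.default_rng(1)
        cols = {g[:3]: rng.normal(2.0, 5.0, 500) for g in
                ("climate", "soil", "terrain", "anthropogenic")}
        groups = {g[:3]: g for g in ("climate", "soil", "terrain",
                                     "anthropogenic")}
        table = pd.DataFrame(cols)
        resp = rng.normal(size=500)
        for method in ("pc1", "mean"):
            idx = sem.build_indices(table, groups, resp, method=method)
            z = (table["cli"] - table["cli"].mean()) / table["cli"].std(ddof=0)
            assert np.allclose(idx.data["C"], z, atol=1e-8)

    def test_pc1_recovers_generating_group_index(self, small_table):
        table, groups, idx_true = small_table
        rng = np.random.default_rng(2)
        indices = sem.build_indices(table, groups, rng.normal(size=len(table)),
                                    method="pc1")
        for var, g in [("C", "climate"), ("S", "soil"), ("T", "terrain"),
                       ("A", "anthropogenic")]:
            r = np.corrcoef(indices.data[var], idx_true[g])[0, 1]
            assert abs(r) >= 0.9

    def test_anchor_sign_alignment(self, small_table):
        table, groups, idx_true = small_table
        rng = np.random.default_rng(3)
        resp = rng.normal(size=len(table))
        idx = sem.build_indices(table, groups, resp, method="pc1")
        for g, load in idx.loadings.items():
            assert load.iloc[0] > 0  # anchor (first member) loads positively

    def test_perfectly_correlated_pair_reduces_to_the_variable(self):
        rng = np.random.default_rng(4)
        base = {g: rng.normal(size=300) for g in
                ("climate", "soil", "terrain", "anthropogenic")}
        cols = {}
        groups = {}
        for g, v in base.items():
            cols[f"{g[:3]}a"] = v
            cols[f"{g[:3]}b"] = 2.0 * v + 1.0  # r = 1 with the first
            groups[f"{g[:3]}a"] = groups[f"{g[:3]}b"] = g
        idx = sem.build_indices(pd.DataFrame(cols), groups,
                                rng.normal(size=300), method="pc1")
        z = (base["climate"] - base["climate"].mean()) / base["climate"].std()
        assert np.allclose(idx.data["C"], z, atol=1e-8)


class TestPathModel:
    def test_recovery_of_generating_coefficients(self, fitted):
        _, model = fitted
        for key, name in COEF_KEY.items():
            assert model.coefficients[key] == pytest.approx(
                sim.DEFAULT_STRUCTURAL[name], abs=0.05)

    def test_estimates_match_normal_equations_oracle(self, fitted):
        idx, model = fitted
        z = idx.data
        for endog, preds in sem.EQUATIONS.items():
            X = np.column_stack([np.ones(len(z))] +
                                [z[p].to_numpy() for p in preds])
            beta = np.linalg.solve(X.T @ X, X.T @ z[endog].to_numpy())
            for j, p in enumerate(preds, start=1):
                assert model.coefficients[f"{endog}~{p}"] == pytest.approx(
                    beta[j], abs=1e-10)

    def test_invariance_to_affine_rescaling_of_inputs(self):
        df = sim.simulate_structural_data({}, 2000, seed=3)
        m1 = sem.fit_path_model(sem.indices_from_table(df))
        df2 = df.copy()
        df2["T"] = 100.0 * df2["T"] - 7.0
        df2["R"] = 0.01 * df2["R"] + 3.0
        m2 = sem.fit_path_model(sem.indices_from_table(df2))
        for k in m1.coefficients:
            assert m1.coefficients[k] == pytest.approx(m2.coefficients[k],
                                                       abs=1e-10)

    def test_null_coefficients_rarely_exceed_2p5_se(self):
        n_flagged, total = 0, 0
        for rep in range(200):
            df = sim.simulate_structural_data(
                {k: 0 for k in sim.STRUCTURAL_KEYS}, 1000, seed=40_000 + rep,
                noise_sd={"climate": 1, "soil": 1, "richness": 1})
            m = sem.fit_path_model(sem.indices_from_table(df))
            for k, est in m.coefficients.items():
                total += 1
                if abs(est) >= 2.5 * m.se[k]:
                    n_flagged += 1
        assert n_flagged / total <= 0.05

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=500)
        df = pd.DataFrame({"T": t, "A": 2 * t, "C": rng.normal(size=500),
                           "S": rng.normal(size=500), "R": rng.normal(size=500)})
        with pytest.raises(ValueError, match="collinear"):
            sem.fit_path_model(sem.indices_from_table(df))

    def test_bootstrap_cis_bracket_the_estimates(self):
        df = sim.simulate_structural_data({}, 2000, seed=6)
        m = sem.fit_path_model(sem.indices_from_table(df), bootstrap=100, seed=0)
        for k, (lo, hi) in m.bootstrap_ci95.items():
            assert lo <= m.coefficients[k] <= hi


class TestEffects:
    def test_zero_mediation_makes_total_equal_direct(self):
        model = manual_path_model({"b_t": 0.3, "b_c": 0.2, "b_s": -0.1,
                                   "b_a": 0.4})
        eff = sem.effects_decomposition(model)
        for p in eff.direct:
            assert eff.indirect[p] == 0.0
            assert eff.total[p] == eff.direct[p]

    def test_reported_coefficient_set_reproduces_path_product_rule(self):
        # standardized path coefficients of a published driver analysis
        coeffs = {"g_ct": -0.3624, "g_ca": 0.1558, "g_st": 0.1162,
                  "g_sa": -0.0319, "b_t": 0.2597, "b_c": 0.0548,
                  "b_s": -0.0986, "b_a": 0.3469}
        eff = sem.effects_decomposition(manual_path_model(coeffs))
        expect_ind_t = coeffs["g_ct"] * coeffs["b_c"] + coeffs["g_st"] * coeffs["b_s"]
        assert eff.indirect["T"] == pytest.approx(expect_ind_t, abs=1e-12)
        assert eff.total["T"] == pytest.approx(coeffs["b_t"] + expect_ind_t,
                                               abs=1e-12)
        expect_ind_a = coeffs["g_ca"] * coeffs["b_c"] + coeffs["g_sa"] * coeffs["b_s"]
        assert eff.total["A"] == pytest.approx(coeffs["b_a"] + expect_ind_a,
                                               abs=1e-12)

    def test_path_products_equal_reduced_form_matrix_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            coeffs = {k: rng.uniform(-0.6, 0.6) for k in sim.STRUCTURAL_KEYS}
            model = manual_path_model(coeffs)
            eff = sem.effects_decomposition(model)
            TE = sem.total_effects_matrix(model)
            r = sem.VARS.index("R")
            for p in eff.total:
                assert eff.total[p] == pytest.approx(
                    TE[r, sem.VARS.index(p)], abs=1e-12)

    def test_total_is_direct_plus_indirect_identically(self):
        rng = np.random.default_rng(8)
        coeffs = {k: rng.uniform(-0.5, 0.5) for k in sim.STRUCTURAL_KEYS}
        eff = sem.effects_decomposition(manual_path_model(coeffs))
        for p in eff.total:
            assert eff.total[p] == pytest.approx(
                eff.direct[p] + eff.indirect[p], abs=1e-12)


class TestFitIndices:
    def test_true_model_fits_cleanly_at_large_n(self):
        df = sim.simulate_structural_data({}, 100_000, seed=9)
        idx = sem.indices_from_table(df)
        model = sem.fit_path_model(idx)
        fi = sem.fit_indices(idx, model)
        assert fi.cfi >= 0.99
        assert 0 <= fi.nfi <= 1 and 0 <= fi.gfi <= 1

    def test_dropping_a_true_path_worsens_chi_square(self):
        df = sim.simulate_structural_data({}, 20_000, seed=10)
        idx = sem.indices_from_table(df)
        model = sem.fit_path_model(idx)
        full = sem.fit_indices(idx, model)
        # force the anthropogenic -> richness path (truth 0.3469) to zero
        model.coefficients["R~A"] = 0.0
        resid = (idx.data["R"] - sum(
            model.coefficients[f"R~{p}"] * idx.data[p]
            for p in sem.EQUATIONS["R"]))
        model.resid_var["R"] = float(np.mean((resid - resid.mean()) ** 2))
        broken = sem.fit_indices(idx, model)
        assert broken.chi_square > full.chi_square

    def test_independence_baseline_on_independent_data(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(20_000, 5)), columns=sem.VARS)
        idx = sem.indices_from_table(df)
        model = sem.fit_path_model(idx)
        fi = sem.fit_indices(idx, model)
        # baseline chi-square near its dof when everything is independent
        assert fi.baseline_chi_square < 3 * fi.baseline_df
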