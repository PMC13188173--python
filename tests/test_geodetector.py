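import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import anova_q_oracle
from richscape import geodetector as gd
from richscape import simulate as sim
from richscape.grids import EnvStack, RasterGrid


def strata_from_labels(labels, name="x"):
    return gd.StrataMap(labels=np.asarray(labels), method="given", k=0,
                        source=(name,))


class TestDiscretize:
    def test_jenks_classes_on_two_clusters(self):
        sm = gd.discretize(np.array([1.0, 2.0, 8.0, 9.0]), "jenks", k=2)
        assert sm.labels.tolist() == [1, 1, 2, 2]

    def test_quantile_classes_are_balanced(self):
        sm = gd.discretize(np.arange(100.0), "quantile", k=5)
        counts = np.bincount(sm.labels)[1:]
        assert counts.min() >= 19 and counts.max() <= 21

    def test_directional_classes_wrap_north(self):
        deg = np.array([0.0, 90.0, 180.0, 270.0, 350.0])
        sm = gd.discretize(deg, "directional", k=4)
        assert sm.labels[0] == sm.labels[4]  # 0 and 350 are both "north"
        assert len(set(sm.labels.tolist())) == 4

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            gd.discretize(np.ones(10), "jenks", k=2)


class TestFactorQ:
    def test_piecewise_constant_response_gives_q_one(self):
        labels = np.repeat([1, 2, 3], 10)
        y = np.repeat([0.0, 5.0, 9.0], 10)
        assert gd.factor_q(y, strata_from_labels(labels)).q == pytest.approx(1.0)

    def test_equal_strata_means_give_q_zero(self):
        y = np.tile([1.0, 2.0, 3.0], 4)
        labels = np.repeat([1, 2, 3, 4], 3)
        assert gd.factor_q(y, strata_from_labels(labels)).q == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_two_pass_anova_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        labels = rng.integers(1, 6, 200)
        q = gd.factor_q(y, strata_from_labels(labels)).q
        assert q == pytest.approx(anova_q_oracle(y, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_invariance_of_q(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=60)
        labels = rng.integers(1, 5, 60)
        sm = strata_from_labels(labels)
        q1 = gd.factor_q(y, sm).q
        q2 = gd.factor_q(3.5 * y - 11.0, sm).q
        assert q1 == pytest.approx(q2, abs=1e-10)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gd.factor_q(np.ones(10), strata_from_labels(np.repeat([1, 2], 5)))


class TestInteraction:
    def test_self_overlay_is_idempotent(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=300)
        labels = rng.integers(1, 5, 300)
        sm = strata_from_labels(labels)
        res = gd.interaction_q(y, sm, sm)
        assert res.q == pytest.approx(gd.factor_q(y, sm).q, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_refinement_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=120)
        a = strata_from_labels(rng.integers(1, 4, 120), "a")
        b = strata_from_labels(rng.integers(1, 4, 120), "b")
        q_ab = gd.interaction_q(y, a, b).q
        assert q_ab >= max(gd.factor_q(y, a).q, gd.factor_q(y, b).q) - 1e-12

    def test_xor_response_is_nonlinear_enhance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 2000)
        b = rng.integers(0, 2, 2000)
        y = (a ^ b).astype(float) + rng.normal(0, 0.1, 2000)
        res = gd.interaction_q(y, strata_from_labels(a + 1, "a"),
                               strata_from_labels(b + 1, "b"))
        qa = gd.factor_q(y, strata_from_labels(a + 1)).q
        qb = gd.factor_q(y, strata_from_labels(b + 1)).q
        assert res.q > qa + qb
        assert res.interaction_class == "nonlinear-enhance"

    def test_additive_independent_factors_classified_enhance_bivariate(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 5000)
        b = rng.integers(0, 3, 5000)
        y = a + b + rng.normal(0, 0.5, 5000)
        res = gd.interaction_q(y, strata_from_labels(a + 1, "a"),
                               strata_from_labels(b + 1, "b"))
        assert res.interaction_class in ("bi-enhance", "nonlinear-enhance",
                                         "independent")


@pytest.fixture(scope="module")
def env():
    cfg = sim.LandscapeConfig(shape=(60, 60), corr_range=3.0, seed=5)
    env, truth = sim.gen_env_stack(cfg)
    return env, truth


class TestGroupStrata:
    def test_single_member_group_matches_its_own_strata(self, env):
        stack, _ = env
        name = stack.group_members("terrain")[0]
        solo = gd.discretize(stack.pixel_table[name].to_numpy(), "jenks", k=3,
                             name=name)
        grp = gd.group_strata(stack, [name], k=3, min_count=1, directional=())
        assert np.array_equal(solo.labels, grp.labels)

    def test_overlay_size_bound_and_refinement(self, env):
        stack, truth = env
        members = stack.group_members("soil")[:2]
        grp = gd.group_strata(stack, members, k=3, min_count=1, directional=())
        assert grp.n_strata <= 9
        y = truth.index_fields["soil"].values.ravel()
        q_group = gd.factor_q(y, grp).q
        for m in members:
            sm = gd.discretize(stack.pixel_table[m].to_numpy(), "jenks", k=3)
            assert q_group >= gd.factor_q(y, sm).q - 1e-12

    def test_small_strata_are_merged(self, env):
        stack, _ = env
        members = stack.group_members("anthropogenic")
        grp = gd.group_strata(stack, members, k=3, min_count=10, directional=())
        counts = np.bincount(grp.labels)[1:]
        assert counts[counts > 0].min() >= 10


class TestGroupInteractionTable:
    def test_generating_groups_dominate_the_matrix(self):
        # response from the climate and anthropogenic indices only
        cfg = sim.LandscapeConfig(
            shape=(60, 60), corr_range=3.0, seed=6,
            structural={**{k: 0 for k in sim.STRUCTURAL_KEYS},
                        "b_c": 0.7, "b_a": 0.7})
        env, truth = sim.gen_env_stack(cfg)
        rich = sim.gen_richness_response(env, truth)
        flat = env.pixel_table.index.to_numpy()
        y = rich.continuous.ravel()[flat]
        tables = gd.group_interaction_table(y, env, per_factor_k=4, group_k=3)
        for mode, M in tables.items():
            assert np.allclose(M.to_numpy(), M.to_numpy().T, equal_nan=True)
        comb = tables["combined"]
        off = comb.where(~np.eye(len(comb), dtype=bool))
        assert off.max().idxmax() in ("anthropogenic", "climate")
        assert off["anthropogenic"]["climate"] == off.max().max()

    def test_singleton_groups_make_both_modes_agree(self):
        cfg = sim.LandscapeConfig(
            shape=(50, 50), corr_range=2.0, seed=7,
            group_sizes={"climate": 1, "soil": 1, "terrain": 1,
                         "anthropogenic": 1})
        env, truth = sim.gen_env_stack(cfg)
        rich = sim.gen_richness_response(env, truth)
        y = rich.continuous.ravel()[env.pixel_table.index.to_numpy()]
        tables = gd.group_interaction_table(y, env, per_factor_k=3, group_k=3,
                                            min_count=1, directional=())
        a, b = tables["combined"], tables["mean-pairwise"]
        off_diag = ~np.eye(len(a), dtype=bool)
        assert np.allclose(a.to_numpy()[off_diag], b.to_numpy()[off_diag])


class TestSignificance:
    def test_perfect_stratification_attains_the_floor_p(self):
        labels = np.repeat([1, 2], 50)
        y = np.repeat([0.0, 1.0], 50)
        p = gd.q_significance(y, strata_from_labels(labels), n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_null_strata_rarely_significant(self):
        rng = np.random.default_rng(8)
        n_sig = 0
        cases = 20
        for i in range(cases):
            y = rng.normal(size=150)
            sm = strata_from_labels(rng.integers(1, 5, 150))
            if gd.q_significance(y, sm, n_perm=99, seed=i) <= 0.05:
                n_sig += 1
        assert n_sig <= 2  # ~90% of null cases stay non-significant

    def test_seeded_and_reproducible(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=100)
        sm = strata_from_labels(rng.integers(1, 4, 100))
        assert gd.q_significance(y, sm, 99, seed=5) == \
            gd.q_significance(y, sm, 99, seed=5)
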