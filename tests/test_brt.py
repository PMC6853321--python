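"""Boosted-regression-tree screening: fitting, importance, interactions, PD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pooltrend as pt
from pooltrend import brt
from pooltrend.synthetic import (
    AGE_GROUPS,
    GENDERS,
    PERIODS,
    GenerativeParams,
    PooledObservation,
    ValidationError,
)


def obs_from_fn(design, fn, rng=None, noise=0.0):
    out = []
    for c in design:
        for _ in range(c.n_pools):
            v = fn(c.age_group, c.gender, c.period)
            if noise:
                v += rng.normal(0, noise)
            out.append(
                PooledObservation.from_log("HCB", c.age_group, c.gender, c.period, float(v), c.pool_size)
            )
    return out


class TestFit:
    def test_constant_response_makes_no_splits(self, design):
        obs = obs_from_fn(design, lambda a, g, p: 2.5)
        fit = pt.fit_brt(obs, shrinkage=0.5, max_trees=20, split_seed=0)
        assert fit.n_trees == 0
        assert np.allclose(fit.cell_table(), 2.5)
        with pytest.raises(brt.UndefinedImportanceError):
            pt.relative_importance(fit)

    def test_noiseless_signal_is_recovered(self, design):
        effects = dict(zip(AGE_GROUPS, [0.0, 0.5, 1.0, 1.5, 2.0]))
        obs = obs_from_fn(design, lambda a, g, p: 1.0 + effects[a])
        fit = pt.fit_brt(obs, shrinkage=1.0, max_trees=100, tree_depth=3, split_seed=1)
        assert pt.brt_rmse(fit, "test") <= 1e-6
        assert pt.brt_rmse(fit, "train") <= 1e-6

    def test_loss_trace_non_increasing(self, brt_fit_planted):
        assert np.all(np.diff(brt_fit_planted.loss_trace) <= 1e-9)

    def test_half_split_is_balanced_and_disjoint(self, brt_fit_planted):
        tr, te = brt_fit_planted.train_indices, brt_fit_planted.test_indices
        assert abs(len(tr) - len(te)) <= 1
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == len(brt_fit_planted.y)

    def test_split_is_seed_reproducible(self, planted_interaction_data):
        f1 = pt.fit_brt(planted_interaction_data, max_trees=5, split_seed=9)
        f2 = pt.fit_brt(planted_interaction_data, max_trees=5, split_seed=9)
        assert np.array_equal(f1.train_indices, f2.train_indices)
        assert np.array_equal(f1.cell_table(), f2.cell_table())

    def test_input_validation(self, design):
        obs = obs_from_fn(design, lambda a, g, p: 1.0)
        with pytest.raises(ValidationError):
            pt.fit_brt(obs[:1])
        with pytest.raises(ValidationError):
            pt.fit_brt(obs, shrinkage=0.0)
        with pytest.raises(ValidationError):
            pt.fit_brt(obs, shrinkage=1.5)


class TestImportance:
    def test_sums_to_100(self, brt_fit_planted):
        imp = pt.relative_importance(brt_fit_planted)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())

    def test_single_active_predictor_takes_all(self, design):
        effects = dict(zip(AGE_GROUPS, [0.0, 0.4, 0.8, 1.2, 1.6]))
        obs = obs_from_fn(design, lambda a, g, p: effects[a])
        fit = pt.fit_brt(obs, shrinkage=1.0, max_trees=50, split_seed=0)
        imp = pt.relative_importance(fit)
        assert imp["age_group"] == pytest.approx(100.0, abs=1e-9)
        assert imp["gender"] == 0.0 and imp["period"] == 0.0

    def test_null_response_importance_bounded(self, design):
        # pure-noise response: no predictor should dominate on average
        means = {p: [] for p in brt.PREDICTORS}
        n_ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            obs = obs_from_fn(design, lambda a, g, p: 0.0, rng=rng, noise=1.0)
            fit = pt.fit_brt(obs, shrinkage=0.05, max_trees=100, split_seed=seed, patience=10)
            try:
                imp = pt.relative_importance(fit)
            except brt.UndefinedImportanceError:
                continue
            n_ok += 1
            for k, v in imp.items():
                means[k].append(v)
        assert n_ok >= 10
        for k in brt.PREDICTORS:
            assert np.mean(means[k]) < 60.0


class TestInteractions:
    def test_stumps_are_exactly_additive(self, planted_interaction_data):
        fit = pt.fit_brt(planted_interaction_data, shrinkage=0.1, max_trees=300, tree_depth=1, split_seed=0)
        for strength in pt.interaction_table(fit).values():
            assert strength <= 1e-12

    def test_additive_truth_scores_near_zero(self):
        design = pt.make_design(2, 100)
        age_eff = dict(zip(AGE_GROUPS, [0.0, 0.3, 0.6, 0.9, 1.2]))
        per_eff = dict(zip(PERIODS, [0.0, -0.1, -0.2, -0.3, -0.4]))
        obs = obs_from_fn(design, lambda a, g, p: 2.0 + age_eff[a] + per_eff[p])
        fit = pt.fit_brt(obs, shrinkage=1.0, max_trees=400, tree_depth=3, split_seed=2)
        for strength in pt.interaction_table(fit).values():
            assert strength <= 1e-6

    def test_symmetric_in_pair_order(self, brt_fit_planted):
        s1 = pt.interaction_strength(brt_fit_planted, ("age_group", "period"))
        s2 = pt.interaction_strength(brt_fit_planted, ("period", "age_group"))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_planted_interaction_ranks_first(self, brt_fit_planted):
        tab = pt.interaction_table(brt_fit_planted)
        assert max(tab, key=tab.get) == ("age_group", "period")

    def test_unknown_predictor_rejected(self, brt_fit_planted):
        with pytest.raises(ValidationError):
            pt.interaction_strength(brt_fit_planted, ("age_group", "bmi"))


class TestPartialDependence:
    def test_weighted_mean_effect_is_zero(self, brt_fit_planted):
        Xtr = brt_fit_planted.X[brt_fit_planted.train_indices]
        for j, pred in enumerate(brt.PREDICTORS):
            eff = pt.partial_dependence(brt_fit_planted, pred)
            levels = {"age_group": AGE_GROUPS, "gender": GENDERS, "period": PERIODS}[pred]
            w = np.bincount(Xtr[:, j], minlength=len(levels)) / len(Xtr)
            assert float(np.dot(list(eff.values()), w)) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_age_effect_recovered(self, design):
        alpha = np.tile(np.array([1.0, 1.5, 2.0, 2.5, 3.0])[:, None], (1, 2))
        obs = pt.simulate_dataset(design, GenerativeParams(2, sigma=0.0, alpha_ag=alpha), seed=0)
        fit = pt.fit_brt(obs, shrinkage=1.0, max_trees=100, split_seed=0)
        eff = pt.partial_dependence(fit, "age_group")
        vals = [eff[a] for a in AGE_GROUPS]
        assert np.all(np.diff(vals) > 0)

    def test_unknown_predictor_rejected(self, brt_fit_planted):
        with pytest.raises(ValidationError):
            pt.partial_dependence(brt_fit_planted, "weight")


class TestRmse:
    def test_zero_when_predictions_exact(self, design):
        effects = dict(zip(GENDERS, [0.0, 1.0]))
        obs = obs_from_fn(design, lambda a, g, p: effects[g])
        fit = pt.fit_brt(obs, shrinkage=1.0, max_trees=20, split_seed=0)
        assert pt.brt_rmse(fit, "train") == pytest.approx(0.0, abs=1e-9)
        assert pt.brt_rmse(fit, "test") == pytest.approx(0.0, abs=1e-9)

    def test_subset_validation(self, brt_fit_planted):
        with pytest.raises(ValidationError):
            pt.brt_rmse(brt_fit_planted, "validation")


def test_sklearn_crosscheck(design):
    """An independently implemented gradient booster reaches a similar fit."""
    sklearn = pytest.importorskip("sklearn.ensemble")
    params = pt.example_params(2)
    obs = pt.simulate_dataset(design, params, seed=13)
    fit = pt.fit_brt(obs, shrinkage=0.05, max_trees=1000, tree_depth=3, split_seed=13)
    X, y = brt.encode(obs)
    Xoh = np.column_stack(
        [(X[:, j] == lv).astype(float) for j, k in enumerate((5, 2, 5)) for lv in range(k)]
    )
    gbr = sklearn.GradientBoostingRegressor(
        learning_rate=0.05, n_estimators=fit.n_trees or 100, max_depth=3, random_state=0
    )
    tr, te = fit.train_indices, fit.test_indices
    gbr.fit(Xoh[tr], y[tr])
    sk_rmse = float(np.sqrt(np.mean((y[te] - gbr.predict(Xoh[te])) ** 2)))
    ours = pt.brt_rmse(fit, "test")
    assert ours == pytest.approx(sk_rmse, rel=0.35)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_importance_normalization_property(seed):
    """Any fit with at least one split has importances summing to 100."""
    design = pt.make_design(2, 100)
    rng = np.random.default_rng(seed)
    obs = obs_from_fn(design, lambda a, g, p: 0.0, rng=rng, noise=1.0)
    fit = pt.fit_brt(obs, shrinkage=0.2, max_trees=30, split_seed=seed, patience=5)
    if fit.n_trees == 0:
        return
    imp = pt.relative_importance(fit)
    assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)
    assert all(v >= 0 for v in pt.interaction_table(fit).values())
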