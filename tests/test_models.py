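"""Hierarchical model definitions, log joint, Gibbs sampler and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

import pooltrend as pt
from pooltrend.models import PosteriorDraws, _PRIOR_VAR
from pooltrend.synthetic import PERIODS, PooledObservation, ValidationError


def _single_cell_obs(values, age="5-15", gender="male", period="2002/03"):
    return [
        PooledObservation.from_log("HCB", age, gender, period, float(v), 100) for v in values
    ]


class TestCatalogue:
    def test_parameter_counts(self):
        assert len(pt.build_model(1).param_names) == 5 + 25 + 2  # beta0, beta, sigma, omega
        assert len(pt.build_model(2).param_names) == 10 + 5 + 2  # alpha, delta_a, sigma, phi
        assert len(pt.build_model(3).param_names) == 5 + 25 + 10 + 2 + 3

    def test_spec3_extends_spec1_with_gender_block(self):
        s1 = set(pt.build_model(1).param_names)
        s3 = set(pt.build_model(3).param_names)
        assert s1 <= s3
        extra = s3 - s1
        assert all(n.startswith(("alpha[", "delta_g[", "phi")) for n in extra)

    def test_gender_offset_flag(self):
        m = pt.build_model(1, include_gender_offset=True)
        assert "alpha_g[male]" in m.param_names and "alpha_g[female]" in m.param_names
        with pytest.raises(ValidationError):
            pt.build_model(2, include_gender_offset=True)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            pt.build_model(0)


class TestLogJoint:
    def _packed(self, model, **over):
        vals = {}
        for n in model.param_names:
            if n in ("sigma", "omega", "phi"):
                vals[n] = 1.0
            else:
                vals[n] = 0.0
        vals.update(over)
        return np.array([vals[n] for n in model.param_names])

    def test_matches_independent_closed_form(self):
        # tiny model 2 (one age, one gender): every term computed by hand
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        y = 0.7
        alpha, delta, sigma, phi = 0.7, 0.2, 1.0, 2.0
        vec = np.array([alpha, delta, sigma, phi])
        obs = _single_cell_obs([y])
        got = pt.log_joint(m, vec, obs)
        expect = (
            stats.norm.logpdf(y, alpha, sigma)
            + stats.norm.logpdf(alpha, delta, phi)
            + stats.norm.logpdf(delta, 0, math.sqrt(_PRIOR_VAR))
            - 2 * math.log(100.0)  # flat priors on sigma and phi
        )
        assert got == pytest.approx(expect, abs=1e-10)
        # the likelihood term at y == mean is -0.5*log(2*pi)
        assert stats.norm.logpdf(0.0, 0.0, 1.0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_sigma_zero_with_residual_is_minus_inf(self):
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        vec = np.array([0.5, 0.0, 0.0, 1.0])  # sigma = 0, residual != 0
        assert pt.log_joint(m, vec, _single_cell_obs([0.7])) == -np.inf

    def test_scale_outside_support_is_minus_inf(self):
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        vec = np.array([0.5, 0.0, 101.0, 1.0])
        assert pt.log_joint(m, vec, _single_cell_obs([0.7])) == -np.inf

    def test_translation_shifts_only_priors(self):
        # shifting data and location parameters together leaves the
        # likelihood unchanged; only the top-level prior terms move
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        c = 3.0
        base = np.array([0.5, 0.2, 1.0, 2.0])
        shifted = base + np.array([c, c, 0.0, 0.0])
        lj0 = pt.log_joint(m, base, _single_cell_obs([0.7]))
        lj1 = pt.log_joint(m, shifted, _single_cell_obs([0.7 + c]))
        prior_delta = stats.norm.logpdf(0.2 + c, 0, math.sqrt(_PRIOR_VAR)) - stats.norm.logpdf(
            0.2, 0, math.sqrt(_PRIOR_VAR)
        )
        assert lj1 - lj0 == pytest.approx(prior_delta, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        m = pt.build_model(2)
        with pytest.raises(ValidationError):
            pt.log_joint(m, np.zeros(3), _single_cell_obs([0.7]))


class TestSampler:
    def test_same_seed_identical_draws(self, study_data):
        m = pt.build_model(2)
        a = pt.sample_posterior(m, study_data, n_iter=200, n_burnin=100, seed=5)
        b = pt.sample_posterior(m, study_data, n_iter=200, n_burnin=100, seed=5)
        assert np.array_equal(a.draws, b.draws)

    def test_conjugate_posterior_mean(self):
        # one age, one gender, scales fixed: alpha's marginal posterior is a
        # known normal; the Gibbs mean must agree within Monte-Carlo error
        arviz = pytest.importorskip("arviz")
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        rng = np.random.default_rng(0)
        sigma, phi = 1.0, 2.0
        y = rng.normal(1.5, sigma, size=30)
        obs = _single_cell_obs(y)
        draws = pt.sample_posterior(
            m, obs, n_iter=4000, n_burnin=1000, seed=3, fixed_scales={"sigma": sigma, "phi": phi}
        )
        a = draws.get("alpha[5-15,male]")
        prior_var = phi**2 + _PRIOR_VAR
        post_prec = len(y) / sigma**2 + 1 / prior_var
        post_mean = (y.sum() / sigma**2) / post_prec
        ess = float(arviz.ess(arviz.convert_to_dataset(a[:, :, None])).x.values.squeeze())
        mcse = a.std() / math.sqrt(max(ess, 1.0))
        assert abs(a.mean() - post_mean) < 3 * mcse
        assert a.var() == pytest.approx(1 / post_prec, rel=0.2)

    def test_one_observation_known_sigma(self):
        # reduces to a single normal mean with an effectively N(0, 10000) prior
        m = pt.build_model(2, age_groups=["5-15"], genders=["male"])
        obs = _single_cell_obs([2.0])
        draws = pt.sample_posterior(
            m, obs, n_iter=6000, n_burnin=1000, seed=8, fixed_scales={"sigma": 1.0, "phi": 100.0}
        )
        a = draws.get("alpha[5-15,male]").ravel()
        prior_var = 100.0**2 + _PRIOR_VAR
        post_prec = 1.0 + 1 / prior_var
        post_mean = 2.0 / post_prec
        se = a.std() / math.sqrt(len(a) / 20)  # conservative autocorrelation allowance
        assert abs(a.mean() - post_mean) < 3 * se

    def test_scales_within_support_and_finite(self, draws3):
        assert np.all(np.isfinite(draws3.draws))
        for name in ("sigma", "omega", "phi"):
            s = draws3.get(name)
            assert np.all(s > 0) and np.all(s <= 100)

    def test_gender_label_swap_leaves_spec1_posterior_unchanged(self, study_data):
        m = pt.build_model(1)
        swapped = [
            PooledObservation.from_log(
                o.ocp,
                o.age_group,
                {"male": "female", "female": "male"}[o.gender],
                o.period,
                o.log_concentration,
                o.pool_size,
            )
            for o in study_data
        ]
        a = pt.sample_posterior(m, study_data, n_iter=300, n_burnin=100, seed=4)
        b = pt.sample_posterior(m, swapped, n_iter=300, n_burnin=100, seed=4)
        assert np.array_equal(a.draws, b.draws)

    def test_invalid_settings_rejected(self, study_data):
        m = pt.build_model(1)
        with pytest.raises(ValidationError):
            pt.sample_posterior(m, [], n_iter=10, seed=0)
        with pytest.raises(ValidationError):
            pt.sample_posterior(m, study_data, n_iter=0, seed=0)
        with pytest.raises(ValidationError):
            pt.sample_posterior(m, study_data, n_iter=10, seed=0, fixed_scales={"sigma": 200.0})


class TestGelmanRubin:
    def _iid_draws(self, n=10_000, offset=0.0):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, n, 1))
        arr[1] += offset
        return PosteriorDraws(arr, ("x",), n_burnin=0, seed=0)

    def test_null_distribution_near_one(self):
        gr = pt.gelman_rubin(self._iid_draws())
        assert 0.99 <= gr.loc["x", "psrf"] <= 1.01
        assert gr.loc["x", "upper"] >= gr.loc["x", "psrf"]

    def test_offset_chains_flagged(self):
        gr = pt.gelman_rubin(self._iid_draws(offset=10.0))
        assert gr.loc["x", "psrf"] > 1.1

    def test_lower_bound_invariant(self, draws3):
        gr = pt.gelman_rubin(draws3)
        n = draws3.n_iter
        assert np.all(gr["psrf"] >= math.sqrt((n - 1) / n) - 1e-12)

    def test_converged_fit_passes_threshold(self, draws3):
        assert pt.gelman_rubin(draws3)["psrf"].max() < 1.1

    def test_single_chain_rejected(self):
        arr = np.random.default_rng(0).standard_normal((1, 100, 1))
        with pytest.raises(ValidationError):
            pt.gelman_rubin(PosteriorDraws(arr, ("x",), 0, 0))

    def test_agrees_with_arviz(self, draws3):
        arviz = pytest.importorskip("arviz")
        gr = pt.gelman_rubin(draws3)
        j = draws3.param_names.index("sigma")
        ref = float(arviz.rhat(arviz.convert_to_dataset(draws3.draws[:, :, j : j + 1])).x.values.squeeze())
        assert gr.loc["sigma", "psrf"] == pytest.approx(ref, abs=0.05)
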