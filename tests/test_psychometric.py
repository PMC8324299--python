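import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurochoice import generator as G
from neurochoice.psychometric import (
    PsychSessionParams,
    SamplerConfig,
    choice_probabilities,
    decision_variables,
    fit_hierarchical,
    posterior_predict,
    session_log_likelihood,
)

from conftest import make_session


class TestDecisionVariables:
    @pytest.mark.parametrize(
        "params, cL, expected_ZL",
        [
            (dict(bL=0, sL=1, n=1.0), 0.5, 0.5),
            (dict(bL=1, sL=2, n=0.5), 0.25, 2.0),  # 1 + 2*sqrt(0.25)
            (dict(bL=0.7, sL=3, n=0.4), 0.0, 0.7),  # zero contrast -> bias only
        ],
    )
    def test_formula(self, params, cL, expected_ZL):
        p = PsychSessionParams(**params)
        ZL, ZR = decision_variables(p, cL, 0.0)
        assert ZL == pytest.approx(expected_ZL)
        assert ZR == pytest.approx(p.bR)

    def test_exponent_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="n"):
            PsychSessionParams(n=1.5)
        with pytest.raises(ValueError, match="n"):
            PsychSessionParams(n=0.0)

    def test_contrast_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            decision_variables(PsychSessionParams(), 1.5, 0.0)


class TestChoiceProbabilities:
    def test_symmetric_zero_gives_thirds(self):
        assert choice_probabilities(0.0, 0.0) == pytest.approx((1 / 3,) * 3)

    def test_log2_case(self):
        pL, pR, p0 = choice_probabilities(math.log(2), 0.0)
        assert (pL, pR, p0) == pytest.approx((0.5, 0.25, 0.25))

    def test_strongly_negative_saturates_to_nogo(self):
        _, _, p0 = choice_probabilities(-50.0, -50.0)
        assert p0 > 0.999

    def test_stable_at_extreme_magnitudes(self):
        pL, pR, p0 = choice_probabilities(700.0, -700.0)
        assert pL == pytest.approx(1.0)
        assert np.isfinite([pL, pR, p0]).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(np.inf, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(-700, 700, allow_nan=False),
        st.floats(-700, 700, allow_nan=False),
    )
    def test_normalisation_property(self, zl, zr):
        pL, pR, p0 = choice_probabilities(zl, zr)
        assert abs(pL + pR + p0 - 1.0) < 1e-12
        assert min(pL, pR, p0) >= 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-2, 2), st.floats(-2, 2), st.floats(0.1, 8), st.floats(0.1, 8),
        st.floats(0.05, 1.0),
    )
    def test_monotone_in_contrast_and_left_right_symmetry(self, bL, bR, sL, sR, n):
        p = PsychSessionParams(bL, bR, sL, sR, n)
        grid = np.linspace(0, 1, 9)
        pL, _, _ = choice_probabilities(*decision_variables(p, grid, 0.3))
        assert np.all(np.diff(pL) >= -1e-12)
        # swapping sides and parameters swaps pLeft/pRight exactly
        swapped = PsychSessionParams(bR, bL, sR, sL, n)
        pL1, pR1, p01 = choice_probabilities(*decision_variables(p, 0.4, 0.7))
        pL2, pR2, p02 = choice_probabilities(*decision_variables(swapped, 0.7, 0.4))
        assert pL1 == pytest.approx(pR2)
        assert pR1 == pytest.approx(pL2)
        assert p01 == pytest.approx(p02)


class TestSessionLogLikelihood:
    def test_uniform_params_give_n_log_third(self):
        sess = make_session([(0.0, 0.0, c) for c in ["Left", "Right", "NoGo"] * 3])
        ll = session_log_likelihood(sess, PsychSessionParams())
        assert ll == pytest.approx(9 * math.log(1 / 3), rel=1e-12)

    def test_saturated_params_give_zero(self):
        sess = make_session([(0.0, 0.0, "Left")] * 4)
        ll = session_log_likelihood(sess, PsychSessionParams(bL=700.0))
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_four_trial_arithmetic_oracle(self):
        # ZL = ln 2, ZR = 0 for every trial -> p = (0.5, 0.25, 0.25)
        params = PsychSessionParams(bL=math.log(2))
        sess = make_session(
            [(0.0, 0.0, "Left"), (0.0, 0.0, "Right"), (0.0, 0.0, "NoGo"), (0.0, 0.0, "Left")]
        )
        expected = math.log(0.5) + math.log(0.25) + math.log(0.25) + math.log(0.5)
        assert session_log_likelihood(sess, params) == pytest.approx(expected, rel=1e-12)

    def test_impossible_choice_returns_minus_inf_with_warning(self):
        sess = make_session([(0.0, 0.0, "NoGo")])
        with pytest.warns(UserWarning, match="probability 0"):
            ll = session_log_likelihood(sess, PsychSessionParams(bL=800.0))
        assert ll == -math.inf

    def test_laser_trials_excluded_by_default(self):
        sess = make_session(
            [
                (0.0, 0.0, "NoGo"),
                (0.0, 0.0, "NoGo", dict(laser_on=True, laser_region="MOs_L")),
            ]
        )
        ll = session_log_likelihood(sess, PsychSessionParams())
        assert ll == pytest.approx(math.log(1 / 3))


class TestLikelihoodGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        from neurochoice.psychometric import _PsychModel, _session_arrays

        cfg = G.GeneratorConfig(n_trials=200)
        trials = G.simulate_choices(
            G.sample_trials(cfg, seed=1), PsychSessionParams(-0.3, 0.2, 4, 4, 0.6),
            seed=2, config=cfg,
        )
        from neurochoice.session_data import Session

        arr = _session_arrays(Session("s0", "m0", trials), False, set())
        model = _PsychModel()
        theta = np.array([-0.2, 0.3, 3.5, 4.2, 0.55])
        _, g = model.loglik_grad(theta, arr)
        h = 1e-6
        for k in range(5):
            e = np.zeros(5)
            e[k] = h
            num = (
                model.loglik_grad(theta + e, arr)[0] - model.loglik_grad(theta - e, arr)[0]
            ) / (2 * h)
            assert g[k] == pytest.approx(num, rel=1e-5, abs=1e-5)


class TestHierarchicalFit:
    def test_empty_session_list_rejected(self):
        with pytest.raises(ValueError, match="at least one session"):
            fit_hierarchical([])

    def test_map_recovers_null_sensitivity(self):
        """Data generated with sL = sR = 0: the 95% intervals for both
        sensitivities contain 0."""
        grand = PsychSessionParams(bL=0.2, bR=-0.1, sL=0.0, sR=0.0, n=0.5)
        cfg = G.GeneratorConfig(n_trials=400, n_sessions=2, n_subjects=3)
        sessions = G.generate_psych_dataset(
            grand, cfg, seed=31, subject_sd=(0.1, 0.1, 0.0, 0.0, 0.02),
            session_sd=(0.1, 0.1, 0.0, 0.0, 0.02),
        )
        draws = fit_hierarchical(sessions, seed=3, method="map", n_draws=400)
        summary = draws.grand_summary()
        for name in ("sL", "sR"):
            mean, sd, lo, hi = summary[name]
            assert lo <= 0.0 <= hi

    def test_posterior_draws_respect_exponent_domain(self):
        grand = PsychSessionParams(-0.3, 0.2, 4, 4, 0.6)
        cfg = G.GeneratorConfig(n_trials=300, n_sessions=2, n_subjects=2)
        sessions = G.generate_psych_dataset(grand, cfg, seed=32)
        draws = fit_hierarchical(sessions, seed=4, method="map", n_draws=300)
        for arr in (draws.grand, draws.subject.reshape(-1, 5), draws.session.reshape(-1, 5)):
            assert np.all(arr[:, 4] > 0.0) and np.all(arr[:, 4] <= 1.0)
            assert np.all(np.isfinite(arr))

    def test_mcmc_path_runs_and_reports_diagnostics(self):
        grand = PsychSessionParams(-0.3, 0.2, 4, 4, 0.6)
        cfg = G.GeneratorConfig(n_trials=150, n_sessions=2, n_subjects=1)
        sessions = G.generate_psych_dataset(grand, cfg, seed=33)
        draws = fit_hierarchical(
            sessions, seed=5, method="mcmc",
            sampler=SamplerConfig(chains=2, warmup=60, samples=60),
        )
        assert draws.method == "mcmc"
        assert np.all(np.isfinite(draws.grand))
        assert np.all(draws.grand[:, 4] > 0) and np.all(draws.grand[:, 4] <= 1)
        assert "max_split_rhat" in draws.diagnostics
        assert "mean_acceptance_fraction" in draws.diagnostics


class TestPosteriorPredict:
    def _draws_from(self, rows):
        from neurochoice._hier import PosteriorDraws

        rows = np.asarray(rows, dtype=float)
        n = rows.shape[0]
        return PosteriorDraws(
            ("bL", "bR", "sL", "sR", "n"),
            rows,
            rows[:, None, :],
            rows[:, None, :],
            ("m0",),
            ("s0",),
            np.array([0]),
        )

    def test_single_draw_degenerate_interval(self):
        draws = self._draws_from([[0.0, 0.0, 1.0, 1.0, 1.0]])
        out = posterior_predict(draws, [0.5], [0.0])
        assert np.allclose(out["lo"], out["hi"])
        assert np.allclose(out["mean"], out["lo"])

    def test_identical_draws_degenerate_interval(self):
        draws = self._draws_from([[0.1, -0.2, 2.0, 2.0, 0.5]] * 7)
        out = posterior_predict(draws, [0.25, 1.0], [0.0, 0.0])
        assert np.allclose(out["lo"], out["hi"])

    def test_two_draw_quantile_arithmetic(self):
        rows = [[0.0, 0.0, 1.0, 1.0, 1.0], [1.0, 0.0, 1.0, 1.0, 1.0]]
        draws = self._draws_from(rows)
        out = posterior_predict(draws, [0.0], [0.0])
        from neurochoice.psychometric import PsychSessionParams as PP

        preds = []
        for r in rows:
            pL, pR, p0 = choice_probabilities(
                *decision_variables(PP.from_array(r), np.array([0.0]), np.array([0.0]))
            )
            preds.append([pL[0], pR[0], p0[0]])
        preds = np.array(preds)
        assert out["mean"][0] == pytest.approx(preds.mean(axis=0))
        # central 95% interval on two points: numpy linear interpolation
        expected_lo = np.percentile(preds, 2.5, axis=0)
        expected_hi = np.percentile(preds, 97.5, axis=0)
        assert out["lo"][0] == pytest.approx(expected_lo)
        assert out["hi"][0] == pytest.approx(expected_hi)

    def test_unknown_level_rejected(self):
        draws = self._draws_from([[0.0, 0.0, 1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="level"):
            posterior_predict(draws, [0.0], [0.0], level="population")
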