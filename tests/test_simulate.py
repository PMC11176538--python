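"""Integration, outcome classification, and basin-boundary bisection."""

import dataclasses

import numpy as np
import pytest

from mmcsim import (
    ModelParameters,
    ScenarioConfig,
    classify_outcome,
    find_initial_size_threshold,
    integrate,
)
from mmcsim.simulate import CURE, PERSISTENCE, drug_closed_form

from conftest import random_admissible_params, random_admissible_state

# long enough to resolve the basin boundary at 1% bracket width: near the
# saddle the unstable eigenvalue is only ~1e-2/day
THRESHOLD_HORIZON = 3000.0


class TestIntegrate:
    def test_constant_at_tumor_free_equilibrium(self, params):
        sc = ScenarioConfig(
            T0=0.0, M0=params.m / params.mu1, E0=params.d0 / params.mu2, horizon=100.0
        )
        traj = integrate(params, sc)
        np.testing.assert_allclose(traj.M, sc.M0, rtol=1e-6)
        np.testing.assert_allclose(traj.T, 0.0, atol=1e-6)
        np.testing.assert_allclose(traj.E, sc.E0, rtol=1e-6)

    def test_first_state_equals_initial_condition(self, params):
        sc = ScenarioConfig(T0=1e6, M0=2.0, E0=5e3)
        traj = integrate(params, sc)
        np.testing.assert_allclose(
            [traj.M[0], traj.T[0], traj.E[0]], [2.0, 1e6, 5e3], rtol=1e-12
        )

    def test_drug_reaches_reported_residual_level(self, params):
        # m = 6.561, mu1 = 21.05: the residual drug level is ~0.311 uM
        traj = integrate(params, ScenarioConfig(T0=1e6, M0=0.0, horizon=10.0))
        assert traj.M[-1] == pytest.approx(0.311, abs=1e-3)

    @pytest.mark.parametrize("method", ["LSODA", "RK45"])
    def test_drug_matches_closed_form(self, params, method):
        sc = ScenarioConfig(T0=1e7, M0=5.0, horizon=400.0)
        traj = integrate(params, sc, method=method)
        ref = drug_closed_form(traj.t, sc.M0, params)
        assert np.max(np.abs(traj.M - ref)) / np.max(ref) <= 1e-6

    def test_untreated_scenario_switches_drug_source_off(self, params):
        sc = ScenarioConfig(T0=1e6, M0=1.0, treated=False, horizon=5.0)
        traj = integrate(params, sc, rtol=1e-10, atol=1e-10)
        assert traj.params.m == 0.0
        np.testing.assert_allclose(
            traj.M, drug_closed_form(traj.t, 1.0, params.untreated()), atol=1e-8
        )

    def test_positivity_invariance_random_runs(self):
        """Solutions started in the positive orthant stay there (200 draws)."""
        rng = np.random.default_rng(7)
        atol = 1e-6
        worst = 0.0
        for _ in range(200):
            p = random_admissible_params(rng)
            M0, T0, E0 = random_admissible_state(rng, p)
            sc = ScenarioConfig(T0=T0, M0=M0, E0=E0, horizon=100.0)
            traj = integrate(p, sc, atol=atol)
            worst = min(worst, traj.M.min(), traj.T.min(), traj.E.min())
        assert worst >= -10 * atol


class TestClassifyOutcome:
    def _traj(self, params, T0, horizon=1500.0, treated=True):
        return integrate(params, ScenarioConfig(T0=T0, treated=treated, horizon=horizon))

    def test_small_tumor_cured_large_persists(self, params):
        assert classify_outcome(self._traj(params, 1e5)) == CURE
        assert classify_outcome(self._traj(params, 1e8)) == PERSISTENCE

    def test_tie_goes_to_persistence(self, params):
        traj = self._traj(params, 1e5)
        assert classify_outcome(traj, cure_threshold=traj.final_T) == PERSISTENCE
        assert classify_outcome(traj, cure_threshold=np.nextafter(traj.final_T, np.inf)) == CURE

    def test_incomplete_trajectory_rejected(self, params):
        traj = self._traj(params, 1e5, horizon=100.0)
        clipped = dataclasses.replace(
            traj, t=traj.t[:-10], M=traj.M[:-10], T=traj.T[:-10], E=traj.E[:-10]
        )
        with pytest.raises(ValueError, match="incomplete"):
            classify_outcome(clipped)


class TestInitialSizeThreshold:
    def test_threshold_lies_inside_bracket_and_orders_regimes(self, params):
        sc = ScenarioConfig(T0=1e6, horizon=THRESHOLD_HORIZON)
        treated = find_initial_size_threshold(params, sc, (1e6, 1e8))
        untreated = find_initial_size_threshold(
            params, dataclasses.replace(sc, treated=False), (1e6, 1e8)
        )
        assert 1e6 < untreated < treated < 1e8
        # drug adds kill capacity: larger tumors remain curable under treatment

    def test_outcome_switches_exactly_once_across_the_bracket(self, params):
        sc = ScenarioConfig(T0=1e6, horizon=THRESHOLD_HORIZON)
        outcomes = [
            classify_outcome(integrate(params, dataclasses.replace(sc, T0=T0), n_points=2))
            for T0 in np.logspace(6, 8, 15)
        ]
        flips = sum(a != b for a, b in zip(outcomes, outcomes[1:]))
        assert outcomes[0] == CURE and outcomes[-1] == PERSISTENCE
        assert flips == 1

    def test_same_outcome_at_both_ends_is_an_error(self, params):
        sc = ScenarioConfig(T0=1e6, horizon=THRESHOLD_HORIZON)
        with pytest.raises(ValueError, match="no threshold"):
            find_initial_size_threshold(params, sc, (1e2, 1e3))

    def test_final_tumor_burden_non_increasing_in_dose(self, params):
        sc = ScenarioConfig(T0=2e7, horizon=400.0)
        finals = [
            integrate(params.replace(m=m), sc, n_points=2).final_T
            for m in (0.0, 2.0, 6.561, 15.0, 40.0)
        ]
        for lo_dose, hi_dose in zip(finals, finals[1:]):
            assert hi_dose <= lo_dose * (1 + 1e-6) + 1e-6


class TestEffectorDynamics:
    """Qualitative immune-compartment behavior on the three reference scenarios."""

    def test_effectors_grow_when_cure_is_achieved(self, params):
        for T0, treated in ((5.3e6, True), (5.3e6, False), (1e7, True)):
            sc = ScenarioConfig(T0=T0, treated=treated, horizon=400.0)
            traj = integrate(params, sc)
            day1 = np.interp(1.0, traj.t, traj.E)
            assert traj.E[-1] > day1

    def test_treatment_raises_effectors_under_persistence(self, params):
        t_eval = np.linspace(1.0, 400.0, 200)
        sc = ScenarioConfig(T0=6.62e7, horizon=400.0)
        treated = integrate(params, sc, t_eval=t_eval)
        untreated = integrate(params, dataclasses.replace(sc, treated=False), t_eval=t_eval)
        assert np.all(treated.E > untreated.E)


class TestTrajectoryExport:
    def test_csv_roundtrip_has_documented_header(self, params, tmp_path):
        import pandas as pd

        traj = integrate(params, ScenarioConfig(T0=1e6, horizon=10.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["t", "M", "T", "E"]
        np.testing.assert_allclose(frame["T"].to_numpy(), traj.T)
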