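"""State machine of the dual-transporter regulon: three programs,
bistability, commitment/hysteresis, and perfect adaptation."""

import numpy as np
import pytest

from phostat.homeostasis import DemandQuery, solve_internal
from phostat.regulon import (
    CellTrajectory,
    NotConvergedError,
    StateLabel,
    classify_state,
    pho4_nuclear,
    population_sweep,
    quasi_steady_internal,
    simulate,
    sweep,
    bistable_window,
)
from phostat.transport import TransporterParams


class TestPho4Transfer:
    def test_three_levels(self, params):
        assert pho4_nuclear(0.0, params) == 1.0
        assert pho4_nuclear(10 * params.phi_plateau, params) < 0.01
        mid = np.sqrt(params.phi_full * params.phi_plateau)
        assert pho4_nuclear(mid, params) == pytest.approx(params.n_mid, abs=0.02)

    def test_monotone_decreasing_and_bounded(self, params):
        grid = np.geomspace(1e-4, 1e3, 200)
        n = pho4_nuclear(grid, params)
        assert np.all(np.diff(n) <= 1e-15)
        assert np.all((n >= 0) & (n <= 1))

    def test_rejects_negative_input(self, params):
        with pytest.raises(ValueError):
            pho4_nuclear(-0.1, params)


class TestQuasiSteadyInternal:
    def test_reduces_to_low_affinity_homeostasis(self, params):
        d = DemandQuery(params.j_demand, "carrier", params.params_L)
        for s_out in (50.0, 400.0, 2000.0):
            expected = solve_internal(d, s_out)
            target = 0.0 if expected.starved else expected.s_in
            assert quasi_steady_internal(0.0, 1.0, s_out, params) == pytest.approx(
                target, abs=1e-6
            )

    def test_reduces_to_high_affinity_homeostasis(self, params):
        e_max = params.alpha_H / params.delta
        pH = params.params_H
        d = DemandQuery(
            params.j_demand,
            "carrier",
            TransporterParams(pH.k2, pH.k4, pH.Kd, e_max * pH.et),
        )
        s_out = 1e4 * pH.Kd
        assert quasi_steady_internal(e_max, 0.0, s_out, params) == pytest.approx(
            solve_internal(d, s_out).s_in, rel=1e-6
        )

    def test_no_transport_means_starvation(self, params):
        assert quasi_steady_internal(0.0, 0.0, 1000.0, params) == 0.0


class TestSimulate:
    def test_rich_medium_stays_off(self, params):
        traj = simulate(params, [(12.0, 4000.0)])
        assert classify_state(traj, 1.0) is StateLabel.OFF
        assert traj.n[-1] < 0.01
        basal = params.basal_reporter
        assert traj.p_plateau[-1] < 2 * basal and traj.p_decoupled[-1] < 2 * basal

    def test_starvation_turns_fully_on(self, params):
        traj = simulate(params, [(12.0, 1.0)])
        assert classify_state(traj, 1.0) is StateLabel.ON
        assert traj.n[-1] == pytest.approx(1.0, abs=1e-6)
        assert traj.p_plateau[-1] > 10 * params.basal_reporter
        assert traj.p_decoupled[-1] > 10 * params.basal_reporter

    def test_commitment_after_return_to_rich(self, params):
        # rich -> intermediate -> rich: the plateau state persists because
        # Spl2 keeps the low-affinity carriers off and the high-affinity
        # system pins s_in at its own set point
        traj = simulate(params, [(6.0, 4000.0), (12.0, 100.0), (12.0, 4000.0)])
        assert classify_state(traj, 1.0) is StateLabel.PLATEAU
        assert traj.a_L[-1] < 0.1

    def test_trajectories_nonnegative_and_bounded(self, params):
        traj = simulate(params, [(4.0, 2000.0), (6.0, 50.0), (4.0, 0.5)])
        for name in ("s_in", "e_H", "spl2", "a_L", "n", "p_plateau", "p_decoupled"):
            assert np.all(getattr(traj, name) >= 0), name
        eps = 1e-9
        assert traj.e_H.max() <= params.alpha_H / params.delta + eps
        assert traj.spl2.max() <= params.alpha_S / params.delta + eps
        cap = (params.alpha_P + params.beta_P) / params.delta + eps
        assert max(traj.p_plateau.max(), traj.p_decoupled.max()) <= cap
        assert np.all(np.diff(traj.time) > 0)
        assert np.all((traj.a_L >= 0) & (traj.a_L <= 1))
        assert np.all(traj.n <= 1)

    def test_rejects_coarse_step(self, params):
        with pytest.raises(ValueError):
            simulate(params, [(1.0, 10.0)], dt=0.2 / params.delta)


def _constant_trajectory(params, n, pp, pd, points=200):
    t = np.linspace(0.0, 2.0, points)
    ones = np.ones(points)
    return CellTrajectory(
        time=t,
        s_in=0.3 * ones,
        e_H=ones,
        spl2=ones,
        a_L=0.5 * ones,
        n=n * ones,
        p_plateau=pp * ones,
        p_decoupled=pd * ones,
        params=params,
    )


class TestClassifyState:
    def test_definitions(self, params):
        basal = params.basal_reporter
        assert classify_state(_constant_trajectory(params, 0.0, basal, basal), 1.0) is StateLabel.OFF
        assert classify_state(_constant_trajectory(params, 1.0, 101.0, 92.0), 1.0) is StateLabel.ON
        assert (
            classify_state(_constant_trajectory(params, params.n_mid, 101.0, basal), 1.0)
            is StateLabel.PLATEAU
        )

    def test_ambiguous_levels_refused(self, params):
        traj = _constant_trajectory(params, 0.5 * params.n_mid, 101.0, 1.0)
        with pytest.raises(NotConvergedError):
            classify_state(traj, 1.0)

    def test_drifting_tail_refused(self, params):
        traj = _constant_trajectory(params, params.n_mid, 101.0, 1.0)
        traj.p_plateau = np.linspace(50.0, 150.0, traj.time.size)
        with pytest.raises(NotConvergedError):
            classify_state(traj, 1.0)

    def test_window_validation(self, params):
        traj = _constant_trajectory(params, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            classify_state(traj, 10.0)


class TestSweeps:
    def test_three_contiguous_programs_downward(self, default_sweeps):
        labels = list(default_sweeps["down"]["label"])
        # descending s_out: OFF block, then PLATEAU block, then ON block
        assert labels == sorted(labels, key=["OFF", "PLATEAU", "ON"].index)
        assert set(labels) == {"OFF", "PLATEAU", "ON"}

    def test_exactly_three_labels_across_directions(self, default_sweeps):
        seen = set(default_sweeps["down"]["label"]) | set(default_sweeps["up"]["label"])
        assert seen == {"OFF", "PLATEAU", "ON"}

    def test_hysteresis_between_directions(self, default_sweeps):
        down = default_sweeps["down"].set_index("s_out")["label"]
        up = default_sweeps["up"].set_index("s_out")["label"]
        disagree = {s for s in down.index if down[s] != up[s]}
        assert disagree, "up and down sweeps must disagree somewhere"
        assert all(up[s] == "PLATEAU" and down[s] == "OFF" for s in disagree)

    def test_no_spl2_erases_hysteresis(self, no_spl2_sweeps):
        down = no_spl2_sweeps["down"].set_index("s_out")["label"]
        up = no_spl2_sweeps["up"].set_index("s_out")["label"]
        assert all(down[s] == up[s] for s in down.index)

    def test_plateau_perfect_adaptation(self, default_sweeps):
        both = [default_sweeps["down"], default_sweeps["up"]]
        s_in = np.concatenate(
            [df.loc[df["label"] == "PLATEAU", "s_in"].to_numpy() for df in both]
        )
        pp = np.concatenate(
            [df.loc[df["label"] == "PLATEAU", "p_plateau"].to_numpy() for df in both]
        )
        assert s_in.max() / s_in.min() < 1.5
        assert pp.max() / pp.min() < 1.5

    def test_plateau_decoupled_reporter_stays_basal(self, default_sweeps, params):
        for df in default_sweeps.values():
            plateau = df[df["label"] == "PLATEAU"]
            on = df[df["label"] == "ON"]
            assert (plateau["p_decoupled"] < 2 * params.basal_reporter).all()
            assert (on["p_decoupled"] > 10 * params.basal_reporter).all()

    def test_plateau_pins_internal_level_at_high_affinity_set_point(self, params):
        traj = simulate(params, [(12.0, 100.0)])
        assert classify_state(traj, 1.0) is StateLabel.PLATEAU
        assert traj.a_L[-1] < 0.1
        pH = params.params_H
        d = DemandQuery(
            params.j_demand,
            "carrier",
            TransporterParams(pH.k2, pH.k4, pH.Kd, params.alpha_H / params.delta * pH.et),
        )
        set_point = solve_internal(d, 100.0).s_in
        assert abs(traj.s_in[-1] - set_point) / set_point < 0.05

    def test_fully_starved_grid_is_all_on(self, params):
        for direction in ("down_from_rich", "up_from_starved"):
            table = sweep(params, [0.5, 2.0], direction)
            assert set(table["label"]) == {"ON"}


class TestBistability:
    def test_window_exists_above_low_affinity_threshold(self, default_bistable, params):
        assert default_bistable is not None
        lo, hi = default_bistable
        d = DemandQuery(params.j_demand, "carrier", params.params_L)
        from phostat.homeostasis import critical_external

        assert lo > critical_external(d)
        assert hi >= lo

    def test_no_spl2_empties_window(self, no_spl2_bistable):
        assert no_spl2_bistable is None

    def test_starved_grid_has_single_attractor(self, params):
        assert bistable_window(params, [0.5, 2.0]) is None


class TestPopulation:
    def test_deterministic_population_steps_once(self, params):
        table = population_sweep(params, [2.0, 100.0, 600.0], cv_etL=0.0,
                                 n_cells=2, seed=0)
        fractions = table["fraction_activated"].to_numpy()
        assert set(fractions) <= {0.0, 1.0}
        assert np.all(np.diff(fractions) <= 0)
        assert fractions[0] == 1.0

    def test_variability_creates_mixed_region(self, params):
        table = population_sweep(params, cv_etL=0.3, n_cells=200, seed=1)
        fractions = table["fraction_activated"].to_numpy()
        assert fractions[0] == 1.0
        assert np.all(np.diff(fractions) <= 1e-12)
        assert np.any((fractions > 0.05) & (fractions < 0.95)), (
            "expected a mixed (bimodal) region at some s_out"
        )

    def test_validation(self, params):
        with pytest.raises(ValueError):
            population_sweep(params, cv_etL=-0.1, n_cells=10)
        with pytest.raises(ValueError):
            population_sweep(params, n_cells=0)
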