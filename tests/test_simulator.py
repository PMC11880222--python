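import math

import numpy as np
import pytest

from pbpkt.errors import DomainError
from pbpkt.exposure import BolusEvent, ExposureSchedule, make_scenario
from pbpkt.fixtures import dcm_config
from pbpkt.population import default_population_spec, sample_population
from pbpkt.simulator import SolverSettings, run_batch, simulate
from pbpkt.template_engine import build_engine


@pytest.fixture()
def engine(chem_dcm, phys):
    return build_engine(dcm_config(), chem_dcm, phys)


class TestSimulate:
    def test_zero_dose_all_states_zero(self, engine):
        res = simulate(engine, make_scenario(1, 0.0), n_points=25)
        assert np.all(res.states == 0.0)
        assert np.all(np.isfinite(res.outputs.drop(columns="time").to_numpy()))

    @pytest.mark.parametrize("n_points", [50, 100, 500])
    def test_requested_grid_lengths(self, engine, n_points):
        res = simulate(engine, make_scenario(1, 0.1), n_points=n_points)
        assert len(res.times) == n_points
        assert res.times[0] == 0.0 and res.times[-1] == 336.0
        assert np.allclose(np.diff(res.times), res.times[1] - res.times[0])

    def test_single_bolus_jumps_cumulative_input(self, engine):
        m = 12.5
        sched = ExposureSchedule(
            route="oral",
            duration=336.0,
            events=(BolusEvent(100.0, "a_stomach_lumen", m),),
        )
        res = simulate(engine, sched, n_points=337)  # grid lands on t=100
        i = list(res.times).index(100.0)
        oral = res.state("e_oral_dose")
        assert oral[i - 1] == 0.0
        assert oral[i] == m  # post-event value at the event time
        assert res.state("e_total_intake")[-1] == m

    def test_event_mass_accounting_exact(self, engine):
        sched = make_scenario(4, 20.0)
        res = simulate(engine, sched, n_points=50)
        assert res.state("e_oral_dose")[-1] == sched.total_bolus_mass()

    def test_min_points_enforced(self, engine):
        with pytest.raises(DomainError):
            simulate(engine, make_scenario(1, 0.1), n_points=1)

    def test_mass_balance_on_periodic_inhalation(self, engine):
        res = simulate(engine, make_scenario(3, 0.35), n_points=60)
        assert res.diagnostics["mass_balance_max_rel"] <= 1e-8

    def test_solver_convergence_under_tolerance_halving(self, engine):
        sched = make_scenario(1, 0.35)
        a = simulate(engine, sched, 50, SolverSettings(rtol=1e-6, atol=1e-6))
        b = simulate(engine, sched, 50, SolverSettings(rtol=1e-8, atol=1e-8))
        ca = a.outputs["c_venous"].iloc[-1]
        cb = b.outputs["c_venous"].iloc[-1]
        assert abs(ca - cb) / cb < 1e-4

    def test_result_csv(self, engine, tmp_path):
        res = simulate(engine, make_scenario(1, 0.1), n_points=10)
        path = tmp_path / "run.csv"
        res.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == 10
        assert "c_venous" in df.columns and "a_venous" in df.columns


class TestRunBatch:
    def test_single_subject(self, engine, phys):
        batch = run_batch(engine, [phys], make_scenario(1, 0.1), n_points=20)
        assert len(batch.results) == 1
        assert batch.cpu_solve >= 0.0

    def test_identical_subjects_identical_results(self, engine, phys):
        batch = run_batch(engine, [phys, phys], make_scenario(1, 0.1), n_points=20)
        a, b = batch.results
        assert np.array_equal(a.states, b.states)

    def test_small_population_sweep_mass_balance(self, engine, phys):
        pop = sample_population(default_population_spec(phys, n=5, seed=2))
        batch = run_batch(engine, pop, make_scenario(1, 0.35), n_points=30)
        assert len(batch.results) == 5
        for res in batch.results:
            assert res.diagnostics["mass_balance_max_rel"] <= 1e-8

    def test_order_preserving(self, engine, phys):
        pop = sample_population(default_population_spec(phys, n=3, seed=5))
        batch = run_batch(engine, pop, make_scenario(1, 0.35), n_points=15)
        # re-running any single subject reproduces its slot
        solo = run_batch(engine, [pop[1]], make_scenario(1, 0.35), n_points=15)
        assert np.array_equal(batch.results[1].states, solo.results[0].states)

    def test_empty_population(self, engine):
        batch = run_batch(engine, [], make_scenario(1, 0.1))
        assert batch.results == []
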