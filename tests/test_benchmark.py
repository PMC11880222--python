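import numpy as np
import pytest

from pbpkt.benchmark import (
    EXPERIMENTS,
    TimingRecord,
    _variants,
    compare_timings,
    run_experiment,
    time_batch,
)
from pbpkt.errors import ComparisonError, ConfigurationError
from pbpkt.exposure import make_scenario
from pbpkt.simulator import run_batch


def _record(times, **kw):
    base = dict(
        experiment_id=1,
        variant="x",
        n_reps=len(times),
        batch_cpu=tuple(times),
        solve_cpu=tuple(t / 2 for t in times),
        batch_size=10,
        scenario=1,
        chemical="dcm",
    )
    base.update(kw)
    return TimingRecord(**base)


class TestTimeBatch:
    def test_records_requested_repetitions(self, chem_dcm, phys):
        from pbpkt.fixtures import dcm_config
        from pbpkt.template_engine import build_engine

        eng = build_engine(dcm_config(), chem_dcm, phys)
        sched = make_scenario(1, 0.1)
        rec = time_batch(
            lambda: run_batch(eng, [phys], sched, n_points=10),
            n_reps=10,
            experiment_id=1,
            variant="t",
            batch_size=1,
            scenario=1,
            chemical="dcm",
        )
        assert rec.n_reps == 10
        assert len(rec.batch_cpu) == 10
        # containment: solve-only span within the batch-total span
        assert all(s <= b for s, b in zip(rec.solve_cpu, rec.batch_cpu))

    def test_empty_batch_still_valid(self, chem_dcm, phys):
        from pbpkt.fixtures import dcm_config
        from pbpkt.template_engine import build_engine

        eng = build_engine(dcm_config(), chem_dcm, phys)
        rec = time_batch(
            lambda: run_batch(eng, [], make_scenario(1, 0.1)),
            n_reps=2,
        )
        assert all(t > 0 for t in rec.batch_cpu)

    def test_too_few_reps(self):
        with pytest.raises(ComparisonError):
            time_batch(lambda: None, n_reps=1)


class TestCompareTimings:
    def test_self_comparison_not_significant(self):
        a = _record([1.0, 1.1, 0.9, 1.05, 0.95])
        c = compare_timings(a, a)
        assert c.p_value == pytest.approx(1.0)
        assert not c.significant

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        a = _record(list(1.0 + 1e-6 * rng.standard_normal(10)))
        b = _record(list(2.0 + 1e-6 * rng.standard_normal(10)), variant="y")
        c = compare_timings(a, b)
        assert c.significant
        assert c.mean_difference == pytest.approx(-1.0, abs=1e-3)

    def test_mismatched_conditions_rejected(self):
        a = _record([1.0, 1.0, 1.0])
        b = _record([1.0, 1.0, 1.0], scenario=2)
        with pytest.raises(ComparisonError):
            compare_timings(a, b)

    def test_null_false_positive_rate_near_5_percent(self):
        # Monte-Carlo calibration: both records drawn from one distribution
        rng = np.random.default_rng(1234)
        hits = 0
        n_trials = 1000
        for _ in range(n_trials):
            a = _record(list(np.abs(1.0 + 0.1 * rng.standard_normal(10))))
            b = _record(list(np.abs(1.0 + 0.1 * rng.standard_normal(10))), variant="y")
            hits += compare_timings(a, b).significant
        rate = hits / n_trials
        assert 0.02 <= rate <= 0.09  # ~3 sigma band around 0.05


class TestExperiments:
    def test_registry_has_eight(self):
        assert sorted(EXPERIMENTS) == list(range(1, 9))

    def test_unknown_experiment(self):
        with pytest.raises(ConfigurationError):
            run_experiment(9)

    def test_exp6_variant_rosters_53_and_34(self):
        variants = _variants(6, "dcm")
        sizes = {label: model.n_states for label, model, _ in variants}
        assert sizes == {"full_roster": 53, "pruned_roster": 34}

    def test_exp1_variant_pair(self):
        variants = _variants(1, "cf")
        assert [label for label, _, _ in variants] == ["template", "standalone"]
        assert variants[1][1].n_states == 19

    def test_exp5_three_variants(self):
        labels = [label for label, _, _ in _variants(5, "dcm")]
        assert labels == ["bw_input_table", "bw_fixed_dynamic", "bw_fixed_init"]

    def test_exp8_lung_triple(self):
        variants = _variants(8, "dcm")
        assert [label for label, _, _ in variants] == [
            "no_lung_ge_ss",
            "lung_ge_ss",
            "lung_ge_state",
        ]
        # the no-lung variant drops the lung states from the live roster
        from pbpkt.template_engine import prune_states

        live = prune_states(variants[0][1].config)
        assert "a_lung" not in live.names

    def test_exp3_points_variants(self):
        assert [pts for _, _, pts in _variants(3, "dcm")] == [50, 100, 500]

    def test_run_experiment_table_schema(self):
        table, records, comparisons = run_experiment(
            4, chemicals=("dcm",), scenarios=(1,), batch_size=2, n_reps=2, n_points=20
        )
        assert list(table.columns) == [
            "experiment",
            "chemical",
            "scenario",
            "variant",
            "mean_s",
            "sd_s",
            "n",
        ]
        assert len(table) == 2
        assert len(comparisons) == 1
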