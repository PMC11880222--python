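"""CPU-time benchmarking of model-implementation choices.

Eight registered experiments each define a set of implementation variants
of the same chemical-specific model; the harness times repeated batches of
simulations (CPU/process time, never wall clock), excludes one-time setup
from the timed span, and compares variants with an unequal-variance
(Welch) location test at the 0.05 level.

The per-repetition protocol generalises a "five runs on two days" design:
``n_reps`` repetitions, each tagged with a block label.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, ConfigurationError
from .exposure import make_scenario
from .fixtures import (
    DEFAULT_DOSE,
    chemical_config,
    chemical_without_lung,
    config_with_lung,
    config_without_lung,
    fixture_chemical,
    fixture_physiology,
)
from .population import default_population_spec, sample_population, subset
from .simulator import SolverSettings, run_batch
from .standalone_models import build_standalone
from .template_engine import (
    BRANCH,
    FIXED_DYNAMIC,
    FIXED_INIT,
    INPUT_TABLE,
    SS_APPROX,
    SWITCH,
    build_engine,
)

#: Experiment registry: id -> short description.
EXPERIMENTS: dict[int, str] = {
    1: "template vs stand-alone implementation",
    2: "ternary conditional operator vs multiplicative switches",
    3: "number of requested output time points (50/100/500)",
    4: "number of output variables (105 vs 76)",
    5: "body-weight handling (input table / fixed dynamic / fixed init)",
    6: "full vs reduced (pruned) state roster",
    7: "blood compartments: steady-state approximation vs state variables",
    8: "lung and gas-exchange representation options",
}


@dataclass(frozen=True)
class TimingRecord:
    """Per-batch CPU-time measurements for one variant."""

    experiment_id: int
    variant: str
    n_reps: int
    batch_cpu: tuple[float, ...]  # seconds per repetition, whole batch span
    solve_cpu: tuple[float, ...]  # seconds per repetition, solve-only span
    batch_size: int
    scenario: int
    chemical: str
    block: str = "block-0"

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ComparisonError("n_reps must be >= 2")
        if len(self.batch_cpu) != self.n_reps or len(self.solve_cpu) != self.n_reps:
            raise ComparisonError("repetition count mismatch")
        if any(t <= 0 for t in self.batch_cpu):
            raise ComparisonError("all times must be > 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.batch_cpu))

    @property
    def sd(self) -> float:
        return float(np.std(self.batch_cpu, ddof=1))


@dataclass(frozen=True)
class Comparison:
    """Welch-test comparison of two timing records."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    mean_difference: float
    p_value: float
    significant: bool


def time_batch(run, n_reps: int = 10, **meta) -> TimingRecord:
    """Time ``run()`` (a zero-argument batch closure) ``n_reps`` times.

    ``run`` must return a :class:`~pbpkt.simulator.BatchResult` so the
    solve-only sub-span can be recorded alongside the batch total.  CPU
    (process) time is used throughout.
    """
    if n_reps < 2:
        raise ComparisonError("n_reps must be >= 2")
    res = time.get_clock_info("process_time").resolution
    if res > 1e-3:
        warnings.warn(f"process-time resolution is coarse ({res} s)", stacklevel=2)
    floor = max(res, 1e-9)
    batch_cpu, solve_cpu = [], []
    for _ in range(n_reps):
        tic = time.process_time()
        batch = run()
        elapsed = time.process_time() - tic
        batch_cpu.append(max(elapsed, floor))
        solve_cpu.append(max(min(batch.cpu_solve, elapsed), 0.0))
    return TimingRecord(
        experiment_id=meta.get("experiment_id", 0),
        variant=meta.get("variant", ""),
        n_reps=n_reps,
        batch_cpu=tuple(batch_cpu),
        solve_cpu=tuple(solve_cpu),
        batch_size=meta.get("batch_size", 0),
        scenario=meta.get("scenario", 0),
        chemical=meta.get("chemical", ""),
        block=meta.get("block", "block-0"),
    )


def compare_timings(a: TimingRecord, b: TimingRecord) -> Comparison:
    """Two-sample unequal-variance location test on per-rep CPU times."""
    if (a.experiment_id, a.batch_size, a.scenario) != (
        b.experiment_id,
        b.batch_size,
        b.scenario,
    ):
        raise ComparisonError("records come from different experimental conditions")
    xa = np.asarray(a.batch_cpu)
    xb = np.asarray(b.batch_cpu)
    if np.var(xa) == 0.0 and np.var(xb) == 0.0:
        p = 1.0 if np.mean(xa) == np.mean(xb) else 0.0
    else:
        p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return Comparison(
        label_a=a.variant,
        label_b=b.variant,
        mean_a=a.mean,
        mean_b=b.mean,
        mean_difference=a.mean - b.mean,
        p_value=p,
        significant=p < 0.05,
    )


# ---------------------------------------------------------------------------
# Experiment variant construction
# ---------------------------------------------------------------------------


def _variants(experiment_id: int, chemical: str):
    """Return [(label, model, n_points_override)] for one experiment."""
    phys = fixture_physiology()
    chem = fixture_chemical(chemical)
    cfg = chemical_config(chemical)
    if experiment_id == 1:
        return [
            ("template", build_engine(cfg, chem, phys), None),
            ("standalone", build_standalone(chemical, chem, phys), None),
        ]
    if experiment_id == 2:
        return [
            ("ternary", build_engine(replace(cfg, conditional_mode=BRANCH), chem, phys), None),
            ("switches", build_engine(replace(cfg, conditional_mode=SWITCH), chem, phys), None),
        ]
    if experiment_id == 3:
        eng = build_engine(cfg, chem, phys)
        return [(f"points_{n}", eng, n) for n in (50, 100, 500)]
    if experiment_id == 4:
        return [
            ("outputs_105", build_engine(cfg, chem, phys), None),
            ("outputs_76", build_engine(replace(cfg, reduced_outputs=True), chem, phys), None),
        ]
    if experiment_id == 5:
        return [
            ("bw_input_table", build_engine(replace(cfg, bw_mode=INPUT_TABLE), chem, phys), None),
            ("bw_fixed_dynamic", build_engine(replace(cfg, bw_mode=FIXED_DYNAMIC), chem, phys), None),
            ("bw_fixed_init", build_engine(replace(cfg, bw_mode=FIXED_INIT), chem, phys), None),
        ]
    if experiment_id == 6:
        return [
            ("full_roster", build_engine(cfg, chem, phys), None),
            ("pruned_roster", build_engine(replace(cfg, prune=True), chem, phys), None),
        ]
    if experiment_id == 7:
        return [
            ("blood_ss", build_engine(replace(cfg, blood_mode=SS_APPROX), chem, phys), None),
            ("blood_state_vars", build_engine(cfg, chem, phys), None),
        ]
    if experiment_id == 8:
        nolung_cfg = config_without_lung(cfg)
        nolung_chem = chemical_without_lung(chem)
        lung_ss = config_with_lung(cfg, ge_state=False)
        lung_state = config_with_lung(cfg, ge_state=True)
        return [
            ("no_lung_ge_ss", build_engine(nolung_cfg, nolung_chem, phys), None),
            ("lung_ge_ss", build_engine(lung_ss, chem, phys), None),
            ("lung_ge_state", build_engine(lung_state, chem, phys), None),
        ]
    raise ConfigurationError(f"unknown experiment id: {experiment_id}")


def run_experiment(
    experiment_id: int,
    chemicals=("dcm", "cf"),
    scenarios=(1,),
    batch_size: int = 100,
    n_reps: int = 10,
    seed: int = 0,
    n_points: int = 100,
    settings: SolverSettings | None = None,
    full_scale: bool = False,
):
    """Run one of the eight timing experiments.

    Returns ``(table, records, comparisons)`` where ``table`` is a tidy
    DataFrame with columns (experiment, chemical, scenario, variant,
    mean_s, sd_s, n).  With ``full_scale`` the batch sizes follow the
    10k/1k protocol (10 000 subjects for continuous scenarios, 1 000 for
    periodic ones) instead of ``batch_size``.
    """
    if experiment_id not in EXPERIMENTS:
        raise ConfigurationError(f"unknown experiment id: {experiment_id}")
    phys = fixture_physiology()
    rows = []
    records: list[TimingRecord] = []
    comparisons: list[Comparison] = []
    for chemical in chemicals:
        variants = _variants(experiment_id, chemical)
        for scenario in scenarios:
            size = batch_size
            if full_scale:
                size = 10_000 if scenario in (1, 2) else 1_000
            spec = default_population_spec(phys, n=size, seed=seed)
            pop = subset(sample_population(spec), size)
            schedule = make_scenario(scenario, DEFAULT_DOSE[scenario])
            scen_records = []
            for label, model, pts in variants:
                rec = time_batch(
                    lambda m=model, p=pts: run_batch(
                        m, pop, schedule, n_points=(p or n_points), settings=settings
                    ),
                    n_reps=n_reps,
                    experiment_id=experiment_id,
                    variant=label,
                    batch_size=size,
                    scenario=scenario,
                    chemical=chemical,
                )
                scen_records.append(rec)
                records.append(rec)
                rows.append(
                    dict(
                        experiment=experiment_id,
                        chemical=chemical,
                        scenario=scenario,
                        variant=label,
                        mean_s=rec.mean,
                        sd_s=rec.sd,
                        n=rec.n_reps,
                    )
                )
            base = scen_records[0]
            for other in scen_records[1:]:
                comparisons.append(compare_timings(base, other))
    return pd.DataFrame(rows), records, comparisons


def plot_experiment(table: pd.DataFrame, path) -> None:
    """Optional grouped bar chart of mean CPU times (means +/- SD)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    groups = table.groupby(["chemical", "scenario"])
    width = 0.8 / max(table["variant"].nunique(), 1)
    variants = list(dict.fromkeys(table["variant"]))
    xs = np.arange(len(groups))
    for j, variant in enumerate(variants):
        means, sds = [], []
        for _, g in groups:
            sel = g[g["variant"] == variant]
            means.append(sel["mean_s"].iloc[0] if len(sel) else np.nan)
            sds.append(sel["sd_s"].iloc[0] if len(sel) else np.nan)
        ax.bar(xs + j * width, means, width, yerr=sds, capsize=3, label=variant)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels([f"{c}/s{s}" for (c, s), _ in groups])
    ax.set_ylabel("CPU time per batch (s)")
    ax.set_title(f"Experiment {table['experiment'].iloc[0]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
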