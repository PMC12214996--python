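"""Desk-scale benchmark experiments on fully synthetic diploid cells.

Each experiment generates a cohort with spiked CNAs under the default
PTA-like stated world (30x-equivalent depth, 100 kb bins, 150 Mb
chromosome), runs the full calling pipeline, and scores the calls against
the ground truth with 50% reciprocal-overlap matching.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluate import MatchResult, match_calls
from .pipeline import PipelineParams, analyze_cohort
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


def _run(config: SimConfig, plans: dict, params: PipelineParams | None = None) -> dict:
    bundle = simulate_cohort(config, plans)
    result = analyze_cohort(bundle, params or PipelineParams(seed=config.seed))
    return {"bundle": bundle, "result": result}


def _score(run: dict, cna_type: str) -> MatchResult:
    truth = run["bundle"]["truth"]
    calls = run["result"]["calls"]
    truth_t = truth[truth["cna_type"] == cna_type]
    calls_t = calls[calls["cna_type"] == cna_type]
    return match_calls(calls_t, truth_t)


def loss_sensitivity_benchmark(
    seed: int,
    n_cells: int = 20,
    sizes: tuple[int, ...] = (1_000_000, 2_500_000, 5_000_000),
) -> dict:
    """Single-copy losses of 1-5 Mb: one event per size in each cell."""
    config = SimConfig(seed=seed)
    plans = {
        f"cell{j:02d}": [("loss_1_0", s) for s in sizes] for j in range(n_cells)
    }
    run = _run(config, plans)
    m = _score(run, "loss_1_0")
    return {"match": m, "sensitivity": m.sensitivity, "n_truth": m.tp + m.fn}


def gain_sensitivity_benchmark(
    seed: int,
    n_cells: int = 40,
    size: int = 500_000,
    events_per_cell: int = 2,
) -> dict:
    """500 kb single-copy gains."""
    config = SimConfig(seed=seed)
    plans = {
        f"cell{j:02d}": [("gain_2_1", size)] * events_per_cell for j in range(n_cells)
    }
    run = _run(config, plans)
    m = _score(run, "gain_2_1")
    return {"match": m, "sensitivity": m.sensitivity, "n_truth": m.tp + m.fn}


def cnloh_benchmark(
    seed: int,
    n_cells: int = 20,
    sizes: tuple[int, ...] = (2_500_000, 5_000_000),
) -> dict:
    """Copy-neutral LOH above 2 Mb: precision and sensitivity."""
    config = SimConfig(seed=seed)
    plans = {
        f"cell{j:02d}": [("cnloh_2_0", s) for s in sizes] for j in range(n_cells)
    }
    run = _run(config, plans)
    m = _score(run, "cnloh_2_0")
    return {
        "match": m,
        "sensitivity": m.sensitivity,
        "precision": m.precision,
        "n_truth": m.tp + m.fn,
    }


def phase_flip_fraction(seed: int, n_sites: int = 100_000) -> dict:
    """Empirical phase-switch fraction over ``n_sites`` simulated gHETs."""
    from .simulate import simulate_cell

    sites_per_bp = 5 / 10_000
    genome_length = int(n_sites / sites_per_bp)
    config = SimConfig(seed=seed, genome_length=genome_length)
    cell = simulate_cell(config, [], seed=seed, cell_id="flip")
    snps = cell["snps"]
    frac = float(snps["phase_flipped"].mean())
    return {"fraction": frac, "n_sites": int(len(snps))}


def ado_cutoff_fraction(seed: int, n_events: int = 10_000) -> dict:
    """Fraction of synthetic dropout lengths exceeding the selected cutoff.

    Lengths are drawn from the simulator's dropout length distribution; the
    raw 95th-percentile cutoff (before ladder rounding) should leave exactly
    5% of the sample above it.
    """
    from .ado import empirical_p95

    config = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    lengths = rng.lognormal(config.ado_log_mean, config.ado_log_sigma, n_events)
    cutoff = empirical_p95(lengths)
    frac = float((lengths > cutoff).mean())
    return {"cutoff": cutoff, "fraction_exceeding": frac, "n": n_events}
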