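"""Synthetic-diploid single-cell data generator.

Emulates, at binned-depth and per-SNP resolution, the construction of a
diploid chromosome from two independently amplified haploid sources: each
haplotype gets its own amplification noise field and allelic-dropout (ADO)
intervals, germline heterozygous SNPs are planted at a realistic density
(5 per 10 kb) with Poisson-sampled allele depths and binomial(0.01)
phase-switch flips, and copy-number events of the four canonical types
(1|0 loss, 2|1 gain, 3|1 gain, 2|0 copy-neutral LOH) are spiked onto
haplotype B:

* loss 1|0     - haplotype-B depth removed inside the interval;
* gain 2|1     - one independently amplified replicate of B added;
* gain 3|1     - two independent replicates added;
* cnLOH 2|0    - total depth untouched; B-allele reads re-labelled as A at
  gHET sites (both copies sample the A haplotype).

Amplification noise is a correlated multiplicative Gamma field with a
locus-shared component (GC-independent waviness affecting both alleles,
the dominant mode in PTA data) and a smaller allele-specific component.
GC bias enters as a deterministic quadratic factor on total depth and is
what the normalization stage must remove.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import make_fixed_bins, write_bed

logger = logging.getLogger(__name__)

CNA_TYPES = ("loss_1_0", "gain_2_1", "gain_3_1", "cnloh_2_0")

#: (cn_a, cn_b) state implied by each CNA type (haplotype B is mutated).
CNA_STATES = {
    "loss_1_0": (1, 0),
    "gain_2_1": (2, 1),
    "gain_3_1": (3, 1),
    "cnloh_2_0": (2, 0),
}


@dataclass
class SimConfig:
    """Stated world of the synthetic diploid experiment.

    Defaults describe a PTA-like cell sequenced to ~30x total
    (15x per haplotype) on a single 150 Mb chromosome with 100 kb bins.
    """

    chrom: str = "chrS"
    genome_length: int = 150_000_000
    bin_size: int = 100_000
    haploid_coverage: float = 15.0
    read_length: int = 100
    # amplification noise: shared locus field + allele-specific field
    amp_cv_shared: float = 0.14
    amp_cv_allelic: float = 0.04
    amp_corr_length: int = 300_000
    # GC model: smooth composition track plus quadratic depth bias
    gc_bias_amplitude: float = 0.2
    # allelic dropout: PTA-like, kilobase-scale events
    ado_rate_per_mb: float = 20.0
    ado_log_mean: float = math.log(2000.0)
    ado_log_sigma: float = 0.6
    # gHET layer
    ghet_per_10kb: int = 5
    phase_switch_prob: float = 0.01
    poisson_noise: bool = True
    # CNA placement stays clear of the chromosome ends (pseudoautosomal-like
    # exclusion) and of previously placed events
    exclusion_margin: int = 3_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.haploid_coverage <= 0 or self.bin_size <= 0:
            raise ValueError("coverage and bin size must be positive")
        if not 0 <= self.phase_switch_prob <= 1:
            raise ValueError("phase-switch probability must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return self.genome_length // self.bin_size

    @property
    def reads_per_bin_haploid(self) -> float:
        return self.haploid_coverage * self.bin_size / self.read_length


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth spiked CNA interval (0-based half-open)."""

    cna_type: str
    chrom: str
    start: int
    end: int
    haplotype: str = "B"

    def __post_init__(self) -> None:
        if self.cna_type not in CNA_TYPES:
            raise ValueError(f"unknown CNA type {self.cna_type}")
        if not self.start < self.end:
            raise ValueError("empty truth interval")


def make_size_grid(min_size: int = 200_000, max_size: int = 5_000_000, n: int = 13) -> np.ndarray:
    """Geometric ladder of CNA sizes (first = min, last = max)."""
    if not (min_size < max_size and n >= 2):
        raise ValueError("need min < max and n >= 2")
    return np.geomspace(min_size, max_size, n)


def _correlated_gamma_field(n: int, cv: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean Gamma field with AR(1) autocorrelation rho between bins."""
    if cv <= 0:
        return np.ones(n)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * math.sqrt(1 - rho**2) if n > 1 else None
    for i in range(1, n):
        z[i] = rho * z[i - 1] + eps[i - 1]
    u = stats.norm.cdf(z)
    shape = 1.0 / cv**2
    return stats.gamma.ppf(np.clip(u, 1e-12, 1 - 1e-12), a=shape, scale=1.0 / shape)


def make_gc_track(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth GC-fraction track in ~[0.30, 0.60] (AR(1) in logit space)."""
    n = config.n_bins
    rho = math.exp(-config.bin_size / (5 * config.amp_corr_length))
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for i in range(1, n):
        z[i] = rho * z[i - 1] + math.sqrt(1 - rho**2) * rng.standard_normal()
    return np.clip(0.45 + 0.05 * z, 0.30, 0.60)


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Quadratic depth bias peaking at GC 0.45."""
    return np.clip(1.0 - amplitude * ((np.asarray(gc) - 0.45) / 0.15) ** 2, 0.3, None)


def _draw_ado_intervals(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """ADO intervals for one haplotype as an (n_events, 2) array of bp."""
    L_mb = config.genome_length / 1e6
    n_events = rng.poisson(config.ado_rate_per_mb * L_mb)
    if n_events == 0:
        return np.empty((0, 2), dtype=np.int64)
    lengths = rng.lognormal(config.ado_log_mean, config.ado_log_sigma, n_events)
    starts = rng.uniform(0, config.genome_length - lengths)
    iv = np.stack([starts, starts + lengths], axis=1).astype(np.int64)
    return iv[np.argsort(iv[:, 0])]


def _interval_bin_fractions(iv: np.ndarray, n_bins: int, bin_size: int) -> np.ndarray:
    """Fraction of each bin covered by the union-ish sum of intervals."""
    frac = np.zeros(n_bins)
    for s, e in iv:
        b0, b1 = int(s // bin_size), int(min(e - 1, n_bins * bin_size - 1) // bin_size)
        if b0 >= n_bins:
            continue
        for b in range(b0, min(b1, n_bins - 1) + 1):
            lo = max(s, b * bin_size)
            hi = min(e, (b + 1) * bin_size)
            frac[b] += max(hi - lo, 0) / bin_size
    return np.clip(frac, 0.0, 1.0)


def _in_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean mask of positions inside any [start, end) interval."""
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
    idx_c = np.clip(idx, 0, len(iv) - 1)
    return (idx >= 0) & (pos < iv[idx_c, 1])


@dataclass
class HaplotypeTrack:
    """Per-bin expected read rate of one haplotype plus its ADO intervals."""

    rate: np.ndarray           # expected reads per bin, ADO not yet applied
    ado_intervals: np.ndarray  # (n, 2) bp coordinates
    ado_bin_fraction: np.ndarray

    @property
    def rate_after_ado(self) -> np.ndarray:
        return self.rate * (1.0 - self.ado_bin_fraction)


def simulate_haplotype_depth(
    config: SimConfig,
    haplotype_id: str,
    seed: int,
    gc: np.ndarray | None = None,
    shared_field: np.ndarray | None = None,
) -> HaplotypeTrack:
    """Expected per-bin read rate for one haplotype of one cell.

    rate = reads_per_bin * gc_factor * shared_amp_field * allelic_amp_field,
    with ADO intervals drawn from the configured log-normal length
    distribution at the configured rate.  With noise off and no ADO the
    track is exactly flat.
    """
    rng = np.random.default_rng(seed)
    n = config.n_bins
    rho = math.exp(-config.bin_size / config.amp_corr_length)
    if shared_field is None:
        shared_field = np.ones(n)
    allelic = (
        _correlated_gamma_field(n, config.amp_cv_allelic, rho, rng)
        if config.poisson_noise
        else np.ones(n)
    )
    gc_factor = gc_bias_factor(gc, config.gc_bias_amplitude) if gc is not None else np.ones(n)
    rate = config.reads_per_bin_haploid * gc_factor * shared_field * allelic
    ado = (
        _draw_ado_intervals(config, rng)
        if config.ado_rate_per_mb > 0
        else np.empty((0, 2), dtype=np.int64)
    )
    return HaplotypeTrack(rate, ado, _interval_bin_fractions(ado, n, config.bin_size))


def place_truth_intervals(
    config: SimConfig,
    plan: list[tuple[str, int]],
    rng: np.random.Generator,
    min_gap: int = 1_000_000,
) -> list[SimTruth]:
    """Draw non-overlapping truth intervals, avoiding the exclusion margins."""
    placed: list[SimTruth] = []
    for cna_type, size in plan:
        size = int(size)
        lo = config.exclusion_margin
        hi = config.genome_length - config.exclusion_margin - size
        if hi <= lo:
            raise ValueError(f"CNA of size {size} does not fit in the genome")
        for _ in range(1000):
            start = int(rng.integers(lo, hi))
            end = start + size
            if all(end + min_gap <= t.start or start >= t.end + min_gap for t in placed):
                placed.append(SimTruth(cna_type, config.chrom, start, end))
                break
        else:
            raise RuntimeError("could not place a non-overlapping CNA interval")
    return sorted(placed, key=lambda t: t.start)


def spike_cna(
    track_a: HaplotypeTrack,
    track_b: HaplotypeTrack,
    truths: list[SimTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Apply depth effects of the truth intervals to haplotype B.

    Returns the modified per-bin B rate (after ADO) and, for gain events,
    the fresh replicate rate fields (keyed by truth index) needed to keep
    gHET depths consistent with bin depths.  cnLOH leaves depth untouched.
    """
    n = config.n_bins
    rho = math.exp(-config.bin_size / config.amp_corr_length)
    rate_b = track_b.rate_after_ado.copy()
    replicates: dict[int, np.ndarray] = {}
    for i, t in enumerate(truths):
        frac = _interval_bin_fractions(np.array([[t.start, t.end]]), n, config.bin_size)
        if t.cna_type == "loss_1_0":
            rate_b *= 1.0 - frac
        elif t.cna_type in ("gain_2_1", "gain_3_1"):
            n_rep = 1 if t.cna_type == "gain_2_1" else 2
            rep = np.zeros(n)
            for _ in range(n_rep):
                fresh = (
                    _correlated_gamma_field(n, config.amp_cv_allelic, rho, rng)
                    if config.poisson_noise
                    else np.ones(n)
                )
                rep += track_b.rate * fresh
            replicates[i] = rep
            rate_b += frac * rep
        # cnloh_2_0: no depth change
    return rate_b, replicates


def place_ghets(
    config: SimConfig,
    track_a: HaplotypeTrack,
    track_b: HaplotypeTrack,
    truths: list[SimTruth],
    replicates: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulated gHET table with allele-specific depths.

    Five uniform positions per 10 kb window; allele depths are Poisson draws
    from the local haplotype coverage (zero inside ADO intervals); CNA
    intervals modify the B-haplotype coverage consistently with the binned
    depth; a binomial(phase_switch_prob) indicator swaps depth_a/depth_b.
    """
    win = 10_000
    k = config.ghet_per_10kb
    n_win = config.genome_length // win
    offsets = rng.integers(0, win, size=(n_win, k))
    pos0 = np.sort((np.arange(n_win)[:, None] * win + offsets).ravel())
    bin_idx = np.clip(pos0 // config.bin_size, 0, config.n_bins - 1)

    per_site = config.read_length / config.bin_size  # bin rate -> site coverage
    cov_a = track_a.rate[bin_idx] * per_site
    cov_b = track_b.rate[bin_idx] * per_site
    cov_a[_in_intervals(pos0, track_a.ado_intervals)] = 0.0
    cov_b[_in_intervals(pos0, track_b.ado_intervals)] = 0.0

    loh_mask = np.zeros(len(pos0), dtype=bool)
    for i, t in enumerate(truths):
        inside = (pos0 >= t.start) & (pos0 < t.end)
        if t.cna_type == "loss_1_0":
            cov_b[inside] = 0.0
        elif t.cna_type in ("gain_2_1", "gain_3_1"):
            cov_b[inside] += replicates[i][bin_idx[inside]] * per_site
        elif t.cna_type == "cnloh_2_0":
            loh_mask |= inside

    if config.poisson_noise:
        depth_a = rng.poisson(cov_a)
        depth_b = rng.poisson(cov_b)
    else:
        depth_a = np.round(cov_a).astype(np.int64)
        depth_b = np.round(cov_b).astype(np.int64)
    # cnLOH: the second copy is haplotype A, so B-haplotype reads carry the
    # A allele; total depth is preserved
    depth_a = np.where(loh_mask, depth_a + depth_b, depth_a)
    depth_b = np.where(loh_mask, 0, depth_b)

    flipped = rng.random(len(pos0)) < config.phase_switch_prob
    da = np.where(flipped, depth_b, depth_a)
    db = np.where(flipped, depth_a, depth_b)

    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos0 + 1,  # 1-based
            "ref": "A",
            "alt": "G",
            "gt": "0|1",
            "depth_a": da.astype(np.int64),
            "depth_b": db.astype(np.int64),
            "bulk_vaf": 0.5,
            "phase_flipped": flipped,
        }
    )


def simulate_cell(
    config: SimConfig,
    plan: list[tuple[str, int]],
    seed: int,
    cell_id: str = "cell",
    gc: np.ndarray | None = None,
) -> dict:
    """One synthetic diploid cell with the given CNA plan.

    Returns a dict with keys bins, observed, snps, truth (DataFrame of
    spiked intervals) and the underlying haplotype tracks.
    """
    ss = np.random.SeedSequence(seed)
    s_cell, s_a, s_b, s_rest = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    rng = np.random.default_rng(s_rest)
    n = config.n_bins
    if gc is None:
        gc = make_gc_track(config, np.random.default_rng(s_cell))
    rho = math.exp(-config.bin_size / config.amp_corr_length)
    shared = (
        _correlated_gamma_field(n, config.amp_cv_shared, rho, np.random.default_rng(s_cell))
        if config.poisson_noise
        else np.ones(n)
    )
    track_a = simulate_haplotype_depth(config, "A", s_a, gc=gc, shared_field=shared)
    track_b = simulate_haplotype_depth(config, "B", s_b, gc=gc, shared_field=shared)

    truths = place_truth_intervals(config, plan, rng) if plan else []
    rate_b_mod, replicates = spike_cna(track_a, track_b, truths, config, rng)
    total_rate = track_a.rate_after_ado + rate_b_mod
    observed = (
        rng.poisson(total_rate) if config.poisson_noise else np.round(total_rate).astype(np.int64)
    )

    snps = place_ghets(config, track_a, track_b, truths, replicates, rng)
    bins = make_fixed_bins(config.chrom, config.genome_length, config.bin_size, gc=gc)
    truth_df = pd.DataFrame(
        [
            {"chrom": t.chrom, "start": t.start, "end": t.end,
             "cna_type": t.cna_type, "cell_id": cell_id, "haplotype": t.haplotype}
            for t in truths
        ],
        columns=["chrom", "start", "end", "cna_type", "cell_id", "haplotype"],
    )
    return {
        "cell_id": cell_id,
        "bins": bins,
        "observed": observed,
        "snps": snps,
        "truth": truth_df,
        "tracks": (track_a, track_b),
    }


def simulate_cohort(
    config: SimConfig,
    plans: dict[str, list[tuple[str, int]]],
    include_control: bool = True,
) -> dict:
    """Simulate a set of cells on a shared bin grid / GC track.

    ``plans`` maps cell_id -> CNA plan; a plan may be empty.  A control cell
    with no events is appended when ``include_control``.
    """
    items = list(plans.items())
    if include_control and "control" not in plans:
        items.append(("control", []))
    master = np.random.SeedSequence(config.seed)
    gc_seed, *cell_seeds = master.spawn(len(items) + 1)
    gc = make_gc_track(config, np.random.default_rng(gc_seed.generate_state(1)[0] % 2**31))
    cells = {}
    truths = []
    for (cell_id, plan), ss in zip(items, cell_seeds):
        seed = int(ss.generate_state(1)[0] % 2**31)
        cell = simulate_cell(config, plan, seed, cell_id=cell_id, gc=gc)
        cells[cell_id] = cell
        if not cell["truth"].empty:
            truths.append(cell["truth"])
    truth_df = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["chrom", "start", "end", "cna_type", "cell_id", "haplotype"])
    )
    bins = next(iter(cells.values()))["bins"]
    return {"config": config, "bins": bins, "cells": cells, "truth": truth_df}


def run_sdx_experiment(
    config: SimConfig,
    conditions: list[tuple[str, int]] | None = None,
    out_dir: str | Path | None = None,
    cells_per_condition: int = 100,
    write_cell_tables: bool = True,
) -> dict:
    """Experiment driver: one mutated cell per start site, per condition.

    For each (cna_type, size) condition, ``cells_per_condition`` mutated
    cells (one event each, random start sites) plus one unmutated control
    are generated.  When ``out_dir`` is given, bin/SNP tables (optional),
    the truth BED and a manifest JSON are written.
    """
    if conditions is None:
        sizes = make_size_grid()
        conditions = [("loss_1_0", int(round(sizes[0])))]
    bundles = {}
    all_truth = []
    for ci, (cna_type, size) in enumerate(conditions):
        cond = f"{cna_type}_{int(size)}"
        sub = SimConfig(**{**asdict(config), "seed": config.seed + 7919 * ci})
        plans = {
            f"{cond}_cell{j:03d}": [(cna_type, int(size))]
            for j in range(cells_per_condition)
        }
        bundle = simulate_cohort(sub, plans)
        bundles[cond] = bundle
        all_truth.append(bundle["truth"])
    truth = pd.concat(all_truth, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed(truth, out / "truth.bed", extra=["cna_type", "cell_id", "haplotype"])
        manifest = {
            "config": {k: v for k, v in asdict(config).items()},
            "conditions": [[t, int(s)] for t, s in conditions],
            "cells_per_condition": cells_per_condition,
            "n_truth_intervals": int(len(truth)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if write_cell_tables:
            for cond, bundle in bundles.items():
                bundle["bins"].to_csv(out / f"{cond}.bins.tsv", sep="\t", index=False)
                counts = pd.DataFrame(
                    {cid: c["observed"] for cid, c in bundle["cells"].items()}
                )
                counts.to_csv(out / f"{cond}.counts.tsv", sep="\t", index=False)
                for cid, c in bundle["cells"].items():
                    c["snps"].to_csv(out / f"{cond}.{cid}.snps.tsv", sep="\t", index=False)
    return {"bundles": bundles, "truth": truth, "conditions": conditions}
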