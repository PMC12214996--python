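"""End-to-end orchestration: normalize -> segment -> BAF -> call.

The in-memory entry point is :func:`analyze_cohort`, which takes a cohort
bundle (shared bin grid, per-cell binned counts and gHET tables — the
structure produced by :mod:`cnascanner.simulate`, or assembled from files)
and returns allelic copy-number calls per cell.  :func:`run_pipeline` wraps
it with file input/output, a run manifest (versions, seeds, parameters,
output checksums) and stage caching.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import aggregate_bin_counts, write_calls, write_bed, CALL_COLUMNS
from .rdr import fit_gc_model, compute_rdr
from .segment import SegmentationConfig, joint_segment, auto_lambda
from .baf import detect_loh, call_baf_peaks, refine_segments_allelic
from .ploidy import (
    find_balanced_bins,
    largest_balanced_cluster,
    candidate_gammas,
    infer_cell_cn,
    estimate_rdr_sigma,
    estimate_rdr_autocorr,
    smooth_states,
    DEFAULT_MAX_TOTAL,
    DEFAULT_MAX_WGD,
)
from .ado import binarize_baf, fit_ado_hmm, decode_ado_events, select_bin_size
from .evaluate import call_type

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "ado", "normalize", "segment", "baf", "call")


@dataclass
class PipelineParams:
    """Tunable parameters of the calling pipeline."""

    lam: float | str = "auto"        # joint-segmentation tuning parameter
    allelic_lam: float | str = "auto"
    alpha: float = 0.05              # LOH test significance level
    edge_band: float = 0.1           # dropout-peak exclusion band on folded BAF
    max_wgd: int = DEFAULT_MAX_WGD   # t: size of the candidate-ploidy grid
    max_total: int = DEFAULT_MAX_TOTAL
    allelic_refinement: bool = True
    min_call_bins: int = 2           # drop boundary-fragment calls below this
    force_theta: int | None = None   # condition on a known WGD status
    seed: int = 0


def _cell_profile(bins: pd.DataFrame, observed: np.ndarray, snps: pd.DataFrame) -> pd.DataFrame:
    profile = bins.copy()
    profile["observed"] = np.asarray(observed)
    counts = aggregate_bin_counts(snps, bins)
    for col in ("count_a", "count_b", "pbaf"):
        profile[col] = counts[col].to_numpy()
    return profile


def analyze_cohort(bundle: dict, params: PipelineParams | None = None) -> dict:
    """Run normalization, joint segmentation, BAF refinement and CN calling.

    Parameters
    ----------
    bundle
        Dict with keys ``bins`` (shared bin table) and ``cells``
        (cell_id -> dict with ``observed`` counts and ``snps`` table).
    params
        Pipeline options.

    Returns
    -------
    dict with ``calls`` (CNA call DataFrame, baseline states dropped),
    ``segments`` (all per-cell segment states), and ``cells``
    (per-cell gamma/theta/ploidy info).
    """
    params = params or PipelineParams()
    bins = bundle["bins"]
    cell_ids = sorted(bundle["cells"])

    # --- normalize: per-cell GC model and RDR -------------------------------
    profiles: dict[str, pd.DataFrame] = {}
    for cid in cell_ids:
        cell = bundle["cells"][cid]
        prof = _cell_profile(bins, cell["observed"], cell["snps"])
        model = fit_gc_model(prof["observed"].to_numpy(), prof["gc"].to_numpy())
        profiles[cid] = compute_rdr(prof, model)

    valid = np.ones(len(bins), dtype=bool)
    for prof in profiles.values():
        valid &= ~prof["rdr"].isna().to_numpy()
    vbins = bins.loc[valid].reset_index(drop=True)
    A = np.stack([profiles[c]["observed"].to_numpy()[valid] for c in cell_ids])
    B = np.stack([profiles[c]["expected"].to_numpy()[valid] for c in cell_ids])

    # --- joint segmentation on read depth -----------------------------------
    chrom_ids = vbins["chrom"].to_numpy()
    boundaries = joint_segment(A, B, SegmentationConfig(lam=params.lam), chrom_ids=chrom_ids)
    logger.info("joint segmentation: %d bins -> %d segments", valid.sum(), len(boundaries))

    # --- per-cell BAF refinement and copy-number calling --------------------
    calls_rows = []
    seg_rows = []
    cell_info = {}
    for gi, cid in enumerate(cell_ids):
        prof = profiles[cid].loc[valid].reset_index(drop=True)
        ca = prof["count_a"].to_numpy(dtype=float)
        cb = prof["count_b"].to_numpy(dtype=float)
        pbaf = prof["pbaf"].to_numpy(dtype=float)
        gc = prof["gc"].to_numpy(dtype=float)
        rdr = prof["rdr"].to_numpy(dtype=float)
        obs = A[gi]
        exp = B[gi]

        cell_bounds = (
            refine_segments_allelic(boundaries, ca, cb, lam=params.allelic_lam)
            if params.allelic_refinement
            else list(boundaries)
        )

        # per-bin pBAF noise scale of this cell, from balanced regions
        folded_all = np.minimum(pbaf, 1 - pbaf)
        bal_folded = folded_all[(pbaf > 0.4) & (pbaf < 0.6)]
        pbaf_sd = 0.05
        if len(bal_folded) >= 30:
            mad = np.median(np.abs(bal_folded - np.median(bal_folded)))
            pbaf_sd = max(float(1.4826 * mad), 0.02)

        segs = []
        for sid, (s, e) in enumerate(cell_bounds):
            sl = slice(s, e + 1)
            loh, ks_stat, ks_p, lowconf = detect_loh(pbaf[sl], gc[sl], alpha=params.alpha)
            baf_res = call_baf_peaks(
                pbaf[sl], loh, edge_band=params.edge_band,
                segment_id=sid, ks_stat=ks_stat, ks_p=ks_p, low_confidence=lowconf,
            )
            seg_rdr = float(obs[sl].sum() / exp[sl].sum())
            segs.append(
                {
                    "segment_id": sid,
                    "chrom": vbins["chrom"].iloc[s],
                    "start": int(vbins["start"].iloc[s]),
                    "end": int(vbins["end"].iloc[e]),
                    "start_bin": s,
                    "end_bin": e,
                    "n_bins": e - s + 1,
                    "rdr": seg_rdr,
                    "baf": baf_res.baf,
                    "loh": baf_res.loh,
                    "ks_stat": baf_res.ks_stat,
                    "ks_p": baf_res.ks_p,
                    "baf_sigma": max(pbaf_sd / np.sqrt(e - s + 1), 0.02),
                }
            )
        seg_df = pd.DataFrame(segs)

        # ploidy: balanced bins -> dominant RDR cluster -> candidate gammas
        bal = find_balanced_bins(pbaf)
        bal_rdr = rdr[bal]
        bal_rdr = bal_rdr[~np.isnan(bal_rdr)]
        try:
            cluster = largest_balanced_cluster(bal_rdr, t=params.max_wgd, seed=params.seed)
            cluster_rdr = bal_rdr[cluster]
        except ValueError:
            cluster_rdr = bal_rdr
        gammas = candidate_gammas(cluster_rdr, theta_grid=range(1, params.max_wgd + 1))
        sigma_bin = estimate_rdr_sigma(cluster_rdr)
        rho = estimate_rdr_autocorr(rdr, bal)

        theta, gamma, cn_calls = infer_cell_cn(
            seg_df, gammas, max_total=params.max_total, rdr_sigma_bin=sigma_bin,
            rho=rho, min_bins_for_selection=5, theta=params.force_theta,
        )
        state = {c.segment_id: (c.cn_a, c.cn_b) for c in cn_calls}
        seg_df["cn_a"] = seg_df["segment_id"].map(lambda i: state[i][0])
        seg_df["cn_b"] = seg_df["segment_id"].map(lambda i: state[i][1])
        seg_df = smooth_states(seg_df, gamma, rdr_sigma_bin=sigma_bin, rho=rho)
        seg_df["cell_id"] = cid
        seg_rows.append(seg_df)

        genome = float(seg_df["n_bins"].sum())
        ploidy = float((seg_df["cn_a"] + seg_df["cn_b"]).mul(seg_df["n_bins"]).sum() / genome)
        cell_info[cid] = {"gamma": gamma, "theta": theta, "ploidy": ploidy}

        cell_calls = _merge_calls(seg_df, baseline=(theta, theta), cell_id=cid)
        if not cell_calls.empty:
            n_call_bins = cell_calls["end_bin"] - cell_calls["start_bin"] + 1
            cell_calls = cell_calls[n_call_bins >= params.min_call_bins]
        calls_rows.append(cell_calls)

    calls_rows = [c for c in calls_rows if not c.empty]
    calls = (
        pd.concat(calls_rows, ignore_index=True)
        if calls_rows
        else pd.DataFrame(columns=CALL_COLUMNS + ["start_bin", "end_bin", "cna_type"])
    )
    calls = calls.sort_values(["cell_id", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    segments = pd.concat(seg_rows, ignore_index=True)
    return {"calls": calls, "segments": segments, "cells": cell_info}


def _merge_calls(seg_df: pd.DataFrame, baseline: tuple[int, int], cell_id: str) -> pd.DataFrame:
    """Merge adjacent same-state segments; keep non-baseline states as calls."""
    rows = []
    current = None
    for r in seg_df.sort_values("start_bin").itertuples():
        state = (r.cn_a, r.cn_b)
        if (
            current is not None
            and state == current["state"]
            and r.chrom == current["chrom"]
            and r.start_bin == current["end_bin"] + 1
        ):
            current["end"] = r.end
            current["end_bin"] = r.end_bin
            current["n_bins"] += r.n_bins
            current["rdr_sum"] += r.rdr * r.n_bins
            current["baf_sum"] += r.baf * r.n_bins
            current["loh"] = current["loh"] or r.loh
        else:
            if current is not None:
                rows.append(current)
            current = {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "start_bin": r.start_bin, "end_bin": r.end_bin,
                "n_bins": r.n_bins, "state": state,
                "rdr_sum": r.rdr * r.n_bins, "baf_sum": r.baf * r.n_bins,
                "loh": bool(r.loh),
            }
    if current is not None:
        rows.append(current)
    out = []
    for c in rows:
        if c["state"] == baseline:
            continue
        cn_a, cn_b = c["state"]
        out.append(
            {
                "chrom": c["chrom"], "start": c["start"], "end": c["end"],
                "cell_id": cell_id, "cn_a": cn_a, "cn_b": cn_b,
                "total_cn": cn_a + cn_b,
                "rdr": c["rdr_sum"] / c["n_bins"],
                "baf": c["baf_sum"] / c["n_bins"],
                "loh_flag": c["loh"],
                "start_bin": c["start_bin"], "end_bin": c["end_bin"],
                "cna_type": call_type(cn_a, cn_b),
            }
        )
    return pd.DataFrame(
        out,
        columns=CALL_COLUMNS + ["start_bin", "end_bin", "cna_type"],
    )


def ado_bin_size(
    bundle: dict,
    train_cells: list[str],
    seed: int = 0,
    ladder=(50_000, 100_000, 500_000),
) -> dict:
    """Fit the ADO HMM on training cells' site-level BAF and pick a bin size."""
    events = []
    params = None
    for cid in train_cells:
        snps = bundle["cells"][cid]["snps"]
        total = snps["depth_a"] + snps["depth_b"]
        keep = total > 0
        baf = (snps["depth_b"][keep] / total[keep]).to_numpy()
        pos = snps["pos"][keep].to_numpy()
        binary = binarize_baf(baf)
        params = fit_ado_hmm(binary, seed=seed)
        events.extend(decode_ado_events(params, pos, binary))
    lengths = [e.length for e in events]
    chosen = select_bin_size(lengths, ladder=ladder)
    return {
        "n_events": len(events),
        "p95": float(np.percentile(lengths, 95)) if lengths else None,
        "chosen_bin_size": chosen,
        "hmm": params,
        "events": events,
    }


# ---------------------------------------------------------------------------
# file-based runner with manifest + caching


@dataclass
class PipelineConfig:
    """File-level configuration of one pipeline invocation (one individual)."""

    out_dir: str
    params: PipelineParams = field(default_factory=PipelineParams)
    include_sex_chromosomes: bool = False
    sim: dict | None = None          # simulator settings, when input is simulated
    sim_plans: dict | None = None    # cell_id -> [(cna_type, size), ...]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_schema_hash() -> str:
    fields = sorted(PipelineParams.__dataclass_fields__) + sorted(
        PipelineConfig.__dataclass_fields__
    )
    return hashlib.sha256(",".join(fields).encode()).hexdigest()[:12]


def version_report() -> str:
    return f"cnascanner {__version__} (config schema {config_schema_hash()})"


def run_pipeline(config: PipelineConfig, bundle: dict | None = None) -> dict:
    """Execute the staged workflow, writing outputs and a run manifest.

    When rerun with unchanged inputs the cached call table is reused after a
    checksum verification; a corrupted intermediate raises with the file
    name.  Two runs with identical config and seeds produce byte-identical
    call BEDs.
    """
    from .simulate import SimConfig, simulate_cohort  # local: optional stage

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    calls_path = out / "calls.bed"
    segments_path = out / "segments.bed"

    if bundle is None:
        if config.sim is None:
            raise ValueError("run_pipeline needs either a bundle or simulator settings")
        sim_cfg = SimConfig(**config.sim)
        plans = {
            cid: [(t, int(s)) for t, s in plan] for cid, plan in (config.sim_plans or {}).items()
        }
        bundle = simulate_cohort(sim_cfg, plans)

    fingerprint = hashlib.sha256(
        json.dumps(
            {
                "params": asdict(config.params),
                "sim": config.sim,
                "plans": config.sim_plans,
                "cells": sorted(bundle["cells"]),
                "version": __version__,
            },
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()

    if manifest_path.exists() and calls_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("fingerprint") == fingerprint:
            actual = _sha256(calls_path)
            if actual != old["checksums"]["calls.bed"]:
                raise RuntimeError(f"checksum mismatch for cached output {calls_path}")
            logger.info("inputs unchanged; reusing cached calls")
            return {"calls_path": calls_path, "manifest": old, "cached": True}

    t0 = time.time()
    result = analyze_cohort(bundle, config.params)
    calls = result["calls"]
    write_calls(calls[CALL_COLUMNS], calls_path)
    write_bed(
        result["segments"],
        segments_path,
        extra=["cell_id", "cn_a", "cn_b", "rdr", "baf", "loh", "ks_stat", "ks_p"],
    )
    (out / "cells.json").write_text(json.dumps(result["cells"], indent=2))

    manifest = {
        "tool": version_report(),
        "fingerprint": fingerprint,
        "stages": list(STAGES),
        "params": asdict(config.params),
        "seed": config.params.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": {
            "calls.bed": _sha256(calls_path),
            "segments.bed": _sha256(segments_path),
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "calls_path": calls_path,
        "calls": calls,
        "segments": result["segments"],
        "cells": result["cells"],
        "manifest": manifest,
        "cached": False,
    }
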