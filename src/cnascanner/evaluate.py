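"""Scoring of CNA call sets against ground truth.

Matching is per cell and per event type with a reciprocal-overlap criterion
(default 50%): a truth interval is a true positive when some same-type call
in the same cell overlaps it by at least the threshold in both directions;
unmatched calls are false positives and unmatched truths false negatives.
Precision with zero calls is defined as 1 (no false positives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CNA_STATES

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5


@dataclass
class MatchResult:
    """Precision/sensitivity summary of a call set against truth."""

    tp: int
    fp: int
    fn: int
    precision_ci: tuple[float, float] | None = None
    sensitivity_ci: tuple[float, float] | None = None

    @property
    def precision(self) -> float:
        return 1.0 if (self.tp + self.fp) == 0 else self.tp / (self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return float("nan") if (self.tp + self.fn) == 0 else self.tp / (self.tp + self.fn)


def call_type(cn_a: int, cn_b: int) -> str | None:
    """Map an allelic state to a canonical CNA type label (None for others)."""
    for name, state in CNA_STATES.items():
        if (cn_a, cn_b) == state:
            return name
    return None


def _reciprocal_overlap(s1, e1, s2, e2) -> float:
    inter = min(e1, e2) - max(s1, s2)
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1), inter / (e2 - s2))


def match_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    bootstrap: int = 0,
    seed: int = 0,
) -> MatchResult:
    """Match calls to truth per cell and type; optionally bootstrap CIs.

    ``calls`` needs columns chrom, start, end, cell_id, cna_type;
    ``truth`` the same.  Matching is greedy one-to-one by decreasing
    reciprocal overlap.  When ``bootstrap`` > 0, 95% CIs over cells are
    attached.
    """
    def _match(calls_df: pd.DataFrame, truth_df: pd.DataFrame) -> tuple[int, int, int]:
        tp = 0
        n_calls = len(calls_df)
        n_truth = len(truth_df)
        for (cell, chrom, ctype), tsub in truth_df.groupby(["cell_id", "chrom", "cna_type"]):
            csub = calls_df[
                (calls_df["cell_id"] == cell)
                & (calls_df["chrom"] == chrom)
                & (calls_df["cna_type"] == ctype)
            ]
            if csub.empty:
                continue
            pairs = []
            for ti, trow in enumerate(tsub.itertuples()):
                for ci, crow in enumerate(csub.itertuples()):
                    ov = _reciprocal_overlap(trow.start, trow.end, crow.start, crow.end)
                    if ov >= min_reciprocal_overlap:
                        pairs.append((ov, ti, ci))
            used_t, used_c = set(), set()
            for ov, ti, ci in sorted(pairs, reverse=True):
                if ti not in used_t and ci not in used_c:
                    used_t.add(ti)
                    used_c.add(ci)
                    tp += 1
        return tp, n_calls - tp, n_truth - tp

    tp, fp, fn = _match(calls, truth)
    result = MatchResult(tp, fp, fn)

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        cells = sorted(set(truth["cell_id"]) | set(calls["cell_id"]))
        precs, senss = [], []
        for _ in range(bootstrap):
            resample = rng.choice(cells, size=len(cells), replace=True)
            c_parts, t_parts = [], []
            for i, cell in enumerate(resample):
                c = calls[calls["cell_id"] == cell].copy()
                t = truth[truth["cell_id"] == cell].copy()
                c["cell_id"] = t_id = f"bs{i}"
                t["cell_id"] = t_id
                c_parts.append(c)
                t_parts.append(t)
            r = MatchResult(*_match(pd.concat(c_parts), pd.concat(t_parts)))
            precs.append(r.precision)
            senss.append(r.sensitivity)
        result.precision_ci = tuple(np.nanpercentile(precs, [2.5, 97.5]))
        result.sensitivity_ci = tuple(np.nanpercentile(senss, [2.5, 97.5]))
    return result


def estimate_fdr(calls: pd.DataFrame, fdr_table: pd.DataFrame) -> float:
    """Mean size-matched FDR over a call set.

    Each call maps to its type's table row with the largest size strictly
    smaller than the call's length; calls smaller than every tabulated size
    take the smallest row (conservative, since FDR grows as size shrinks).
    ``fdr_table`` has columns cna_type, size, fdr.
    """
    if calls.empty:
        logger.warning("FDR of an empty call set is undefined; reporting missing")
        return float("nan")
    values = []
    for row in calls.itertuples():
        sub = fdr_table[fdr_table["cna_type"] == row.cna_type].sort_values("size")
        if sub.empty:
            raise ValueError(f"FDR table has no rows for type {row.cna_type}")
        length = row.end - row.start
        smaller = sub[sub["size"] < length]
        chosen = smaller.iloc[-1] if not smaller.empty else sub.iloc[0]
        values.append(float(chosen["fdr"]))
    return float(np.mean(values))


def classify_clonality(calls: pd.DataFrame) -> pd.DataFrame:
    """Label calls clonal/private by exact bin-coordinate identity.

    A call is clonal when >= 2 cells carry a call with identical
    (chrom, start_bin, end_bin, cna_type); identical calls share a
    ``clone_group`` id.  Requires columns start_bin, end_bin on a shared
    bin grid.
    """
    for col in ("start_bin", "end_bin"):
        if col not in calls.columns:
            raise ValueError("calls must carry bin coordinates on a shared grid")
    out = calls.copy()
    key = ["chrom", "start_bin", "end_bin", "cna_type"]
    grp = out.groupby(key, sort=False)
    out["clone_group"] = grp.ngroup()
    n_cells = grp["cell_id"].transform("nunique")
    out["clonal"] = n_cells >= 2
    out.loc[~out["clonal"], "clone_group"] = -1
    return out
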