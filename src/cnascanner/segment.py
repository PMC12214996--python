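"""Joint multi-cell segmentation of binned read counts by greedy BIC merging.

The model treats the split of reads between a genomic segment and the rest
of the genome as multinomial: a segment with observed reads ``a`` and
expected reads ``b`` contributes ``a log(a/(a+b)) + b log(b/(a+b))`` to the
log-likelihood.  For one cell the simplified Bayesian information criterion
of a partition with ``m`` breakpoints is

    BIC(lambda) = -2 * sum_j [ a_j log(a_j/(a_j+b_j)) + b_j log(b_j/(a_j+b_j)) ]
                  + (m+1) * lambda * log(N),        N = sum_j a_j

and the multi-cell form sums the likelihood over cells ``k`` with a shared
breakpoint set and penalty ``(m+1) * G * lambda * log(sum_k N_k)``.

Segmentation is agglomerative: starting from singleton bins, the adjacent
pair whose merge lowers the BIC the most is merged until no merge lowers
it.  Only read-depth-derived counts enter the criterion; allelic (BAF)
information never does.

Single-cell sequencing counts are overdispersed relative to the multinomial
model, so the effective penalty must scale with the overdispersion;
:func:`auto_lambda` estimates it from adjacent-bin fluctuations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Median of the chi-square(1) distribution, for robust overdispersion scaling.
_CHI2_1_MEDIAN = 0.45493642311957283


@dataclass
class SegmentationConfig:
    """Tuning knobs for the greedy joint segmentation."""

    lam: float | str = "auto"   # tuning parameter lambda > 0, or "auto"
    max_iterations: int = 10**9
    bin_size: int = 100_000

    def __post_init__(self) -> None:
        if isinstance(self.lam, (int, float)) and self.lam <= 0:
            raise ValueError("lambda must be positive")


def _seg_loglik(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a log(a/(a+b)) + b log(b/(a+b)) elementwise, with 0 log 0 = 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    tot = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(a > 0, a * (np.log(a) - np.log(np.where(tot > 0, tot, 1.0))), 0.0)
        tb = np.where(b > 0, b * (np.log(b) - np.log(np.where(tot > 0, tot, 1.0))), 0.0)
    return ta + tb


def bic_single(seg_a, seg_b, lam: float, N: float | None = None) -> float:
    """Simplified BIC of one cell's partition given per-segment count sums."""
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if np.any(a < 0) or np.any(b <= 0):
        raise ValueError("need a_j >= 0 and b_j > 0")
    if N is None:
        N = float(a.sum())
    if N <= 0:
        raise ValueError("total read count N must be positive")
    m = len(a) - 1  # number of breakpoints
    return float(-2.0 * _seg_loglik(a, b).sum() + (m + 1) * lam * math.log(N))


def bic_joint(seg_a, seg_b, lam: float) -> float:
    """Multi-cell simplified BIC; rows are cells, columns shared segments."""
    A = np.atleast_2d(np.asarray(seg_a, dtype=float))
    B = np.atleast_2d(np.asarray(seg_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("cells have mismatched segment grids")
    totals = A.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every cell needs a positive total read count")
    G, n_seg = A.shape
    m = n_seg - 1
    loglik = _seg_loglik(A, B).sum()
    return float(-2.0 * loglik + (m + 1) * G * lam * math.log(totals.sum()))


def estimate_overdispersion(A: np.ndarray, B: np.ndarray) -> float:
    """Overdispersion factor phi of counts relative to the multinomial model.

    For each adjacent bin pair the Pearson statistic of the observed split
    ``a_j : a_{j+1}`` against the expected split ``b_j : b_{j+1}`` is ~
    phi * chi2(1) under the no-changepoint null; the median over pairs
    (robust to true changepoints), scaled by the chi2(1) median and averaged
    over cells, estimates phi.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    phis = []
    for a, b in zip(A, B):
        n = a[:-1] + a[1:]
        p = b[:-1] / (b[:-1] + b[1:])
        ok = (n > 0) & (p > 0) & (p < 1)
        if ok.sum() < 3:
            continue
        x2 = (a[:-1][ok] - n[ok] * p[ok]) ** 2 / (n[ok] * p[ok] * (1 - p[ok]))
        phis.append(np.median(x2) / _CHI2_1_MEDIAN)
    if not phis:
        return 1.0
    return max(1.0, float(np.mean(phis)))


def auto_lambda(A: np.ndarray, B: np.ndarray) -> float:
    """Overdispersion-calibrated lambda for the greedy merge.

    Under the null the deviance of a spurious breakpoint is ~ phi * chi2(G)
    summed over G cells; the per-breakpoint penalty ``G * lambda * log(sum N)``
    is set near the upper tail of that distribution (mean + 4 sd of chi2(G),
    scaled by phi) so noise breakpoints are rejected while shared or strong
    private signal survives.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    G = A.shape[0]
    phi = estimate_overdispersion(A, B)
    log_total = max(math.log(max(float(A.sum()), 2.0)), 1.0)
    lam = phi * (G + 4.0 * math.sqrt(2.0 * G)) / (G * log_total)
    logger.info("auto lambda: phi=%.2f G=%d -> lambda=%.2f", phi, G, lam)
    return max(1.0, lam)


def joint_segment(
    A,
    B,
    config: SegmentationConfig | None = None,
    chrom_ids=None,
) -> list[tuple[int, int]]:
    """Greedy agglomerative joint segmentation.

    Parameters
    ----------
    A, B
        Observed / expected counts, shape (G cells, n bins), on a shared
        bin grid.  Masked bins should be removed before calling.
    config
        Segmentation options; ``lam="auto"`` calibrates the penalty to the
        data's overdispersion.
    chrom_ids
        Optional per-bin chromosome labels; merges never cross a boundary.

    Returns
    -------
    list of (start_bin, end_bin) inclusive index ranges partitioning the
    bin sequence.  Ties in the merge objective break to the leftmost pair,
    making the output deterministic and invariant to cell order.
    """
    config = config or SegmentationConfig()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0:
        raise ValueError("empty profile")
    if A.shape != B.shape:
        raise ValueError("cells have mismatched bin grids")
    G, n = A.shape
    lam = auto_lambda(A, B) if config.lam == "auto" else float(config.lam)
    log_total = max(math.log(max(float(A.sum()), 2.0)), 1.0)
    penalty_drop = G * lam * log_total  # BIC decrease from removing one breakpoint

    # per-segment sufficient statistics (cells x segments)
    SA = A.copy()
    SB = B.copy()
    starts = np.arange(n)
    ends = np.arange(n)
    if chrom_ids is None:
        chrom_arr = np.zeros(n)
    else:
        _, chrom_arr = np.unique(np.asarray(chrom_ids), return_inverse=True)

    lik = _seg_loglik(SA, SB).sum(axis=0)  # per segment, summed over cells
    seg_chrom = chrom_arr.copy()

    for _ in range(config.max_iterations):
        if SA.shape[1] < 2:
            break
        merged_lik = _seg_loglik(SA[:, :-1] + SA[:, 1:], SB[:, :-1] + SB[:, 1:]).sum(axis=0)
        # Delta BIC of merging pair (i, i+1): -2*(lik gain) - penalty_drop
        delta = -2.0 * (merged_lik - lik[:-1] - lik[1:]) - penalty_drop
        delta = np.where(seg_chrom[:-1] == seg_chrom[1:], delta, np.inf)
        i = int(np.argmin(delta))
        if not delta[i] < 0:
            break
        SA[:, i] += SA[:, i + 1]
        SB[:, i] += SB[:, i + 1]
        ends[i] = ends[i + 1]
        lik[i] = merged_lik[i]
        keep = np.ones(SA.shape[1], dtype=bool)
        keep[i + 1] = False
        SA = SA[:, keep]
        SB = SB[:, keep]
        starts = starts[keep]
        ends = ends[keep]
        lik = lik[keep]
        seg_chrom = seg_chrom[keep]

    return list(zip(starts.tolist(), ends.tolist()))


def segment_table(
    boundaries: list[tuple[int, int]],
    bins: pd.DataFrame,
    A: np.ndarray,
    B: np.ndarray,
) -> pd.DataFrame:
    """Summarize a partition: genomic coordinates plus per-cell RDR sums."""
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    rows = []
    for seg_id, (s, e) in enumerate(boundaries):
        rows.append(
            {
                "segment_id": seg_id,
                "chrom": bins["chrom"].iloc[s],
                "start": int(bins["start"].iloc[s]),
                "end": int(bins["end"].iloc[e]),
                "start_bin": s,
                "end_bin": e,
                "n_bins": e - s + 1,
            }
        )
    return pd.DataFrame(rows)
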