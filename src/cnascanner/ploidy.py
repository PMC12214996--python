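"""Cell ploidy (scale factor) and allele-specific copy-number inference.

The scale factor ``gamma`` maps read-depth ratio to total copy number
(``total = gamma * rdr``).  Candidate values come from allelically balanced
bins: bins with pBAF strictly between 0.45 and 0.55 are collected, a
Gaussian mixture over their RDR values isolates the dominant ("largest")
cluster, and for each hypothesised number of whole-genome duplications
``theta`` in {1, ..., t}

    gamma(theta) = 2 * theta / mean(RDR over balanced bins)

since a balanced bin has total copy number 2 theta.  For each candidate
gamma every segment is scored against all states (a, b), a >= b >= 0,
a + b <= max_total under Gaussian models of RDR (mean total/gamma) and
minor-allele BAF (mean b/total); LOH segments are restricted to b = 0.
The gamma minimizing the overall BIC (one effective parameter per
hypothesised duplication, ties to smaller theta) is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

BALANCED_BAND = (0.45, 0.55)
FALLBACK_BAND = (0.4, 0.6)
MIN_BALANCED_BINS = 30
DEFAULT_MAX_TOTAL = 8
DEFAULT_MAX_WGD = 2

#: Floors for the per-state Gaussian scales.
RDR_SIGMA_FLOOR = 0.02
BAF_SIGMA_FLOOR = 0.03


@dataclass
class PloidyModel:
    """Balanced-bin summary and the candidate scale factors."""

    balanced_idx: np.ndarray
    cluster_idx: np.ndarray
    theta_grid: tuple[int, ...]
    gammas: dict[int, float]          # theta -> gamma
    chosen_theta: int | None = None

    @property
    def chosen_gamma(self) -> float:
        if self.chosen_theta is None:
            raise ValueError("gamma not selected yet")
        return self.gammas[self.chosen_theta]


@dataclass
class AllelicCNCall:
    """Integer allele-specific copy-number call for one segment."""

    segment_id: int
    cn_a: int
    cn_b: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if not (self.cn_a >= self.cn_b >= 0):
            raise ValueError("states use the convention cn_a >= cn_b >= 0")

    @property
    def total(self) -> int:
        return self.cn_a + self.cn_b


def expected_baf(cn_a: int, cn_b: int) -> float:
    """Minor-allele BAF of a state: min(a,b)/(a+b); NaN for total 0."""
    total = cn_a + cn_b
    if total == 0:
        return float("nan")
    return min(cn_a, cn_b) / total


def find_balanced_bins(
    pbaf,
    band: tuple[float, float] = BALANCED_BAND,
    min_bins: int = MIN_BALANCED_BINS,
) -> np.ndarray:
    """Indices of bins with pBAF strictly inside the balanced band.

    Fewer than ``min_bins`` hits triggers a warning and a widened band.
    """
    pbaf = np.asarray(pbaf, dtype=float)
    lo, hi = band
    idx = np.flatnonzero((pbaf > lo) & (pbaf < hi))
    if len(idx) < min_bins:
        logger.warning(
            "only %d balanced bins in (%.2f, %.2f); widening to (%.2f, %.2f)",
            len(idx), lo, hi, *FALLBACK_BAND,
        )
        lo, hi = FALLBACK_BAND
        idx = np.flatnonzero((pbaf > lo) & (pbaf < hi))
    return idx


def largest_balanced_cluster(
    rdr_values,
    t: int = DEFAULT_MAX_WGD,
    seed: int = 0,
) -> np.ndarray:
    """Members of the most-populated RDR cluster among balanced bins.

    Gaussian mixtures with 1..t components are fitted; the best model by BIC
    wins and the indices of its largest component are returned.
    """
    x = np.asarray(rdr_values, dtype=float).reshape(-1, 1)
    if len(x) < MIN_BALANCED_BINS:
        raise ValueError("need at least 30 balanced bins")
    best_bic, best_model = np.inf, None
    for k in range(1, t + 1):
        gmm = GaussianMixture(
            n_components=k, random_state=seed, reg_covar=1e-6, n_init=2
        ).fit(x)
        bic = gmm.bic(x)
        if bic < best_bic:
            best_bic, best_model = bic, gmm
    # ploidy-driven RDR clusters differ by integer copy ratios (>= 1.5x);
    # closer modes are amplification waviness, not distinct copy states
    means = np.sort(best_model.means_.ravel())
    if len(means) > 1 and np.all(means[1:] / np.maximum(means[:-1], 1e-9) < 1.4):
        return np.arange(len(x))
    labels = best_model.predict(x)
    counts = np.bincount(labels, minlength=best_model.n_components)
    return np.flatnonzero(labels == int(np.argmax(counts)))


def candidate_gammas(balanced_rdr, theta_grid=(1, 2)) -> dict[int, float]:
    """gamma(theta) = 2 theta / mean balanced RDR for each theta."""
    x = np.asarray(balanced_rdr, dtype=float)
    if len(x) == 0:
        raise ValueError("no balanced bins")
    mean_rdr = float(np.mean(x))
    if mean_rdr <= 0:
        raise ValueError("mean balanced RDR must be positive")
    return {int(t): 2.0 * t / mean_rdr for t in theta_grid}


def _state_grid(max_total: int) -> list[tuple[int, int]]:
    return [
        (a, b)
        for a in range(max_total + 1)
        for b in range(a + 1)
        if 0 < a + b <= max_total
    ]


def _score_segments(
    segs: pd.DataFrame,
    gamma: float,
    max_total: int,
    rdr_sigma_bin: float,
    baf_sigma: float,
    rho: float = 0.0,
) -> tuple[float, list[AllelicCNCall]]:
    """Best state per segment under one gamma; returns (total loglik, calls).

    ``rho`` is the lag-1 autocorrelation of per-bin RDR noise; amplification
    waviness is correlated across bins, so the standard error of a segment
    mean shrinks like sqrt(((1+rho)/(1-rho))/n) rather than sqrt(1/n).
    """
    calls: list[AllelicCNCall] = []
    total_ll = 0.0
    states = _state_grid(max_total)
    rho = min(max(rho, 0.0), 0.95)
    n_eff_factor = (1.0 + rho) / (1.0 - rho)
    for row in segs.itertuples():
        sigma_r = max(
            rdr_sigma_bin * np.sqrt(n_eff_factor / max(row.n_bins, 1)), RDR_SIGMA_FLOOR
        )
        sigma_b = max(getattr(row, "baf_sigma", baf_sigma), BAF_SIGMA_FLOOR)
        best_ll, best_state = -np.inf, (1, 1)
        for a, b in states:
            if row.loh and b != 0:
                continue
            mu_r = (a + b) / gamma
            ll = -0.5 * ((row.rdr - mu_r) / sigma_r) ** 2 - np.log(sigma_r)
            if not np.isnan(row.baf):
                mu_b = expected_baf(a, b)
                ll += -0.5 * ((row.baf - mu_b) / sigma_b) ** 2 - np.log(sigma_b)
            if ll > best_ll:
                best_ll, best_state = ll, (a, b)
        total_ll += best_ll
        calls.append(AllelicCNCall(int(row.segment_id), *best_state, float(best_ll)))
    return total_ll, calls


def infer_cell_cn(
    segments: pd.DataFrame,
    gammas: dict[int, float],
    max_total: int = DEFAULT_MAX_TOTAL,
    rdr_sigma_bin: float = 0.15,
    baf_sigma: float = BAF_SIGMA_FLOOR,
    rho: float = 0.0,
    theta: int | None = None,
    min_bins_for_selection: int = 1,
) -> tuple[int, float, list[AllelicCNCall]]:
    """Maximum-likelihood allelic copy numbers and scale factor for one cell.

    Parameters
    ----------
    segments
        DataFrame with columns segment_id, rdr, baf (minor-allele), loh,
        n_bins.
    gammas
        Candidate scale factors keyed by theta (from
        :func:`candidate_gammas`).
    theta
        When given, skip model selection and call states under this
        hypothesis (used e.g. to condition on a known WGD status).

    Returns ``(theta, gamma, calls)`` where theta minimizes the BIC
    ``-2 loglik + theta * log(n_segments)`` (ties to smaller theta).
    """
    if segments.empty:
        raise ValueError("no segments to call")
    if theta is not None:
        _, calls = _score_segments(
            segments, gammas[theta], max_total, rdr_sigma_bin, baf_sigma, rho
        )
        return theta, gammas[theta], calls

    n = len(segments)
    # boundary-overhang fragments (partial event overlap) carry genuinely
    # fractional states and must not drive the ploidy choice
    reliable = segments["n_bins"].to_numpy() >= min_bins_for_selection
    best = None
    for th in sorted(gammas):
        _, calls = _score_segments(
            segments, gammas[th], max_total, rdr_sigma_bin, baf_sigma, rho
        )
        ll = float(sum(c.log_likelihood for c, ok in zip(calls, reliable) if ok))
        # each hypothesised duplication doubles the candidate state grid of
        # every segment; charging one unit per segment per duplication keeps
        # accumulated noise quantization gains from tipping the choice, while
        # genuine WGD evidence (tens of units per discordant segment) dominates
        bic = -2.0 * ll + th * max(int(reliable.sum()), 1)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, th, calls)
    if best is None or not np.isfinite(best[0]):
        raise ValueError("cell is uncallable: degenerate likelihood for every gamma")
    _, th, calls = best
    return th, gammas[th], calls


def smooth_states(
    seg_df: pd.DataFrame,
    gamma: float,
    rdr_sigma_bin: float,
    rho: float = 0.0,
    max_bins: int = 10,
    threshold: float = 6.0,
) -> pd.DataFrame:
    """Absorb short, weakly supported state islands into matching flanks.

    A segment of at most ``max_bins`` bins whose two bin-adjacent neighbours
    share the same state adopts that state unless its own assignment is
    decisively better (drop in -2 log likelihood above ``threshold``,
    roughly a chi-square(1) tail bound).  This is a minimum-description-
    length guard against amplification excursions fragmenting one event
    into differently labelled pieces; genuine short CNAs are protected by
    their BAF term, which makes the likelihood drop large.
    """
    df = seg_df.sort_values("start_bin").reset_index(drop=True)
    rho = min(max(rho, 0.0), 0.95)
    n_eff_factor = (1.0 + rho) / (1.0 - rho)

    def _ll(row, a: int, b: int) -> float:
        sigma_r = max(
            rdr_sigma_bin * np.sqrt(n_eff_factor / max(row.n_bins, 1)), RDR_SIGMA_FLOOR
        )
        sigma_b = max(getattr(row, "baf_sigma", BAF_SIGMA_FLOOR), BAF_SIGMA_FLOOR)
        mu_r = (a + b) / gamma
        ll = -0.5 * ((row.rdr - mu_r) / sigma_r) ** 2
        if not np.isnan(row.baf) and (a + b) > 0:
            ll += -0.5 * ((row.baf - expected_baf(a, b)) / sigma_b) ** 2
        return ll

    def _runs(frame: pd.DataFrame) -> list[dict]:
        runs: list[dict] = []
        for i, row in enumerate(frame.itertuples()):
            state = (row.cn_a, row.cn_b)
            if (
                runs
                and runs[-1]["state"] == state
                and runs[-1]["end_bin"] + 1 == row.start_bin
            ):
                runs[-1]["end_bin"] = row.end_bin
                runs[-1]["n_bins"] += row.n_bins
                runs[-1]["rows"].append(i)
            else:
                runs.append(
                    {"state": state, "end_bin": row.end_bin, "start_bin": row.start_bin,
                     "n_bins": row.n_bins, "rows": [i]}
                )
        return runs

    changed = True
    while changed:
        changed = False
        runs = _runs(df)
        for k in range(len(runs) - 2):
            flank = runs[k]["state"]
            # island = consecutive runs strictly between two same-state,
            # bin-contiguous flanking runs
            island: list[dict] = []
            for j in range(k + 1, len(runs)):
                if runs[j - 1]["end_bin"] + 1 != runs[j]["start_bin"]:
                    island = []
                    break
                if runs[j]["state"] == flank:
                    break
                island.append(runs[j])
            else:
                island = []
            if not island or sum(r["n_bins"] for r in island) > max_bins:
                continue
            rows = [i for r in island for i in r["rows"]]
            drop = 2.0 * sum(
                _ll(df.iloc[i], df.iloc[i].cn_a, df.iloc[i].cn_b)
                - _ll(df.iloc[i], *flank)
                for i in rows
            )
            if drop <= threshold:
                df.loc[df.index[rows], ["cn_a", "cn_b"]] = flank
                changed = True
                break  # runs are stale; re-derive and rescan
    return df


def estimate_rdr_autocorr(rdr: np.ndarray, balanced_idx: np.ndarray) -> float:
    """Lag-1 autocorrelation of per-bin RDR noise over balanced bins.

    Only genomically adjacent pairs with both members in the balanced set
    are used, so copy-number-altered regions do not inflate the estimate.
    """
    balanced = np.zeros(len(rdr), dtype=bool)
    balanced[balanced_idx] = True
    ok = balanced[:-1] & balanced[1:] & ~np.isnan(rdr[:-1]) & ~np.isnan(rdr[1:])
    if ok.sum() < 30:
        return 0.0
    x, y = rdr[:-1][ok], rdr[1:][ok]
    r = float(np.corrcoef(x, y)[0, 1])
    return min(max(r, 0.0), 0.95)


def estimate_rdr_sigma(rdr_values) -> float:
    """Robust per-bin RDR scale from balanced bins (MAD-based)."""
    x = np.asarray(rdr_values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return 0.15
    mad = np.median(np.abs(x - np.median(x)))
    return max(float(1.4826 * mad), RDR_SIGMA_FLOOR)
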