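"""Per-segment B-allele frequency refinement and LOH detection.

Per-bin phased BAF (pBAF) is noisy: allelic dropout piles mass near 0/1 and
phase-switch errors blur the haplotype assignment.  Per segment this module

1. applies a haplotype-specific *shift* (label swap on high-GC bins) and a
   two-sample Kolmogorov-Smirnov comparison of the allelic-imbalance
   distributions before/after the shift, combined with a homozygosity
   condition, to flag loss of heterozygosity (LOH);
2. calls peaks in the kernel density of pBAF folded to the minor-allele
   scale [0, 0.5], strips dropout peaks near the edge, and reports the
   dominant remaining peak as the segment BAF (0 for LOH segments).

Note on the shift test: allelic imbalance |pBAF - 0.5| is invariant under
the label swap b -> 1 - b, so the folded KS comparison cannot by itself
separate the two distributions; the discriminative power of the LOH call
rests on the homozygosity condition (median |pBAF - 0.5| > 0.4), with the
KS statistic retained as a reported diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import argrelmax

from .segment import SegmentationConfig, joint_segment

logger = logging.getLogger(__name__)

#: Minimum informative bins for the LOH test.
MIN_BINS = 10
#: Median allelic imbalance above which a segment looks homozygous.
HOMOZYGOSITY_THRESHOLD = 0.4
#: Folded-BAF peaks below this location are treated as dropout artifacts.
DEFAULT_EDGE_BAND = 0.1
DEFAULT_ALPHA = 0.05


@dataclass
class SegmentBafResult:
    """Refined BAF call for one segment (minor-allele convention)."""

    segment_id: int
    loh: bool
    ks_stat: float
    ks_p: float
    peaks: list[tuple[float, float]]  # (location, density weight)
    baf: float
    low_confidence: bool = False


def shift_baf(pbaf, gc) -> np.ndarray:
    """Haplotype-specific shift: swap allele labels (b -> 1-b) on bins whose
    GC content is above the segment median."""
    pbaf = np.asarray(pbaf, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if pbaf.shape != gc.shape:
        raise ValueError("pbaf and gc must align")
    high_gc = gc > np.median(gc)
    out = pbaf.copy()
    out[high_gc] = 1.0 - out[high_gc]
    return out


def detect_loh(
    pbaf,
    gc,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[bool, float, float, bool]:
    """LOH test for one segment.

    Returns ``(loh, ks_stat, ks_p, low_confidence)``.  LOH is called when
    the allelic-imbalance distributions before and after the shift are
    indistinguishable (KS p >= alpha) *and* the segment looks homozygous
    (median |pBAF - 0.5| > 0.4).  Segments with fewer than 10 informative
    bins are marked low-confidence and assumed non-LOH.
    """
    pbaf = np.asarray(pbaf, dtype=float)
    gc = np.asarray(gc, dtype=float)
    keep = ~np.isnan(pbaf)
    pbaf, gc = pbaf[keep], gc[keep]
    if len(pbaf) < MIN_BINS:
        return False, float("nan"), float("nan"), True
    shifted = shift_baf(pbaf, gc)
    dev = np.abs(pbaf - 0.5)
    dev_shift = np.abs(shifted - 0.5)
    ks_stat, ks_p = stats.ks_2samp(dev, dev_shift, method="asymp")
    homozygous = float(np.median(dev)) > HOMOZYGOSITY_THRESHOLD
    loh = bool(ks_p >= alpha and homozygous)
    return loh, float(ks_stat), float(ks_p), False


def fold_minor(pbaf: np.ndarray) -> np.ndarray:
    """Fold pBAF to the minor-allele scale min(b, 1-b) in [0, 0.5]."""
    pbaf = np.asarray(pbaf, dtype=float)
    return np.minimum(pbaf, 1.0 - pbaf)


def _kde_peaks(folded: np.ndarray) -> list[tuple[float, float]]:
    """Gaussian-KDE local maxima on [0, 0.5] with boundary reflection."""
    if np.ptp(folded) < 1e-9:
        return [(float(folded[0]), 1.0)]
    # Silverman bandwidth from the data itself ...
    base = stats.gaussian_kde(folded, bw_method="silverman")
    h = max(base.factor * float(np.std(folded, ddof=1)), 0.01)
    # ... then reflect about both edges so boundary modes are not flattened
    augmented = np.concatenate([folded, -folded, 1.0 - folded])
    kde = stats.gaussian_kde(augmented, bw_method=h / float(np.std(augmented, ddof=1)))
    grid = np.linspace(0.0, 0.5, 256)
    dens = kde(grid)
    idx = list(argrelmax(dens)[0])
    # interior grid maxima plus the two endpoints when they dominate
    if dens[0] > dens[1]:
        idx.insert(0, 0)
    if dens[-1] > dens[-2]:
        idx.append(len(grid) - 1)
    return [(float(grid[i]), float(dens[i])) for i in idx]


def call_baf_peaks(
    pbaf,
    loh: bool,
    edge_band: float = DEFAULT_EDGE_BAND,
    segment_id: int = 0,
    ks_stat: float = float("nan"),
    ks_p: float = float("nan"),
    low_confidence: bool = False,
) -> SegmentBafResult:
    """Final segment BAF from the folded per-bin pBAF density.

    LOH segments get BAF 0.  Otherwise peaks with location < ``edge_band``
    are removed as dropout artifacts and the highest-density remaining peak
    is the segment BAF; if none survives, the median folded pBAF is used.
    """
    pbaf = np.asarray(pbaf, dtype=float)
    pbaf = pbaf[~np.isnan(pbaf)]
    if len(pbaf) == 0:
        raise ValueError("empty segment")
    if loh:
        return SegmentBafResult(segment_id, True, ks_stat, ks_p, [], 0.0, low_confidence)
    folded = fold_minor(pbaf)
    peaks = _kde_peaks(folded)
    retained = [(loc, w) for loc, w in peaks if loc >= edge_band]
    if retained:
        baf = max(retained, key=lambda p: p[1])[0]
    else:
        baf = float(np.median(folded))
    # a non-LOH segment never reports exactly 0 (baf == 0 <=> LOH)
    baf = max(baf, 0.01)
    return SegmentBafResult(segment_id, False, ks_stat, ks_p, peaks, float(baf), low_confidence)


def refine_segments_allelic(
    boundaries: list[tuple[int, int]],
    count_a: np.ndarray,
    count_b: np.ndarray,
    lam: float | str = "auto",
) -> list[tuple[int, int]]:
    """Split read-depth segments at allelic-imbalance changepoints.

    The joint read-depth segmentation is blind to copy-neutral LOH, whose
    boundaries leave total depth unchanged.  Within each depth segment this
    pass re-runs the same greedy BIC merge on the per-bin haplotype counts
    (observed = count_b, expected = count_a), placing breakpoints where the
    haplotype fraction changes.  Segments whose bins carry no allelic
    information are left intact.
    """
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    refined: list[tuple[int, int]] = []
    for s, e in boundaries:
        a = cb[s : e + 1]
        b = ca[s : e + 1]
        ok = (a + b) > 0
        if ok.sum() < 2:
            refined.append((s, e))
            continue
        idx = np.flatnonzero(ok)
        # half-count pseudocounts keep the criterion finite when one
        # haplotype drops out entirely (the LOH case of interest)
        sub = joint_segment(
            (a[idx] + 0.5)[None, :], (b[idx] + 0.5)[None, :], SegmentationConfig(lam=lam)
        )
        if len(sub) == 1:
            refined.append((s, e))
            continue
        # map informative-bin ranges back onto the full bin range
        cut_starts = [s] + [int(idx[ss]) + s for ss, _ in sub[1:]]
        for i, cs in enumerate(cut_starts):
            ce = cut_starts[i + 1] - 1 if i + 1 < len(cut_starts) else e
            refined.append((cs, ce))
    return refined
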