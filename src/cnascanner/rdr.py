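"""GC-bias correction of binned read counts into read-depth ratios (RDR).

A semi-parametric (lowess) regression of per-bin count on GC fraction gives
the expected relative depth at each bin; RDR = observed / expected.  The fit
is rescaled so its mean over training bins is exactly one, making the
genome-wide mean RDR of an unaltered diploid cell ~1 by construction.

This is a bin-level stand-in for nucleotide-resolution normalization; an
externally produced expected-count track can be substituted via the
``expected`` override of :func:`compute_rdr`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: Bins with fewer mappable bases than this fraction of the bin size are masked.
MIN_MAPPABLE_FRACTION = 0.5


@dataclass
class GcModel:
    """Smooth mapping from GC fraction to expected *relative* depth.

    ``gc_grid``/``rel_depth`` tabulate the lowess fit (linearly interpolated,
    clamped at the ends); the fit is normalized so the mean of fitted values
    over training bins equals one.  ``mean_count`` is the training-bin mean
    observed count, so expected counts are ``mean_count * predict(gc)``.
    """

    gc_grid: np.ndarray
    rel_depth: np.ndarray
    mean_count: float
    n_bins: int
    residual_var: float
    degenerate: bool = False

    def predict(self, gc) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        rel = np.interp(gc, self.gc_grid, self.rel_depth)
        return np.maximum(rel, 1e-6)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gc_grid": self.gc_grid.tolist(),
            "rel_depth": self.rel_depth.tolist(),
            "mean_count": self.mean_count,
            "n_bins": self.n_bins,
            "residual_var": self.residual_var,
            "degenerate": self.degenerate,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GcModel":
        d = json.loads(Path(path).read_text())
        return cls(
            gc_grid=np.asarray(d["gc_grid"]),
            rel_depth=np.asarray(d["rel_depth"]),
            mean_count=d["mean_count"],
            n_bins=d["n_bins"],
            residual_var=d["residual_var"],
            degenerate=d["degenerate"],
        )


def fit_gc_model(observed, gc, frac: float = 0.3, robust_iters: int = 3) -> GcModel:
    """Fit the lowess count-vs-GC model on one cell's bins.

    Robust iterations down-weight CNA-affected bins.  Constant GC degenerates
    to the global mean (with a warning).
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(gc, dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 bins to fit the GC model")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    mean_count = float(np.mean(y))
    if mean_count <= 0:
        raise ValueError("mean observed count must be positive")

    if np.ptp(x) < 1e-12:
        logger.warning("constant GC track; GC model degenerates to the global mean")
        grid = np.array([0.0, 1.0])
        rel = np.array([1.0, 1.0])
        resid = y / mean_count - 1.0
        return GcModel(grid, rel, mean_count, len(y), float(np.var(resid)), degenerate=True)

    fitted = lowess(y, x, frac=frac, it=robust_iters, return_sorted=True)
    grid_x, grid_y = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for interpolation
    grid_x, uniq_idx = np.unique(grid_x, return_index=True)
    grid_y = grid_y[uniq_idx]
    rel = grid_y / mean_count
    # rescale so fitted values average exactly 1 over the training bins
    rel_at_bins = np.maximum(np.interp(x, grid_x, rel), 1e-6)
    scale = float(np.mean(rel_at_bins))
    rel = rel / scale
    rel_at_bins = rel_at_bins / scale
    resid = y / (mean_count * rel_at_bins) - 1.0
    return GcModel(grid_x, rel, mean_count, len(y), float(np.var(resid)))


def compute_rdr(
    profile: pd.DataFrame,
    model: GcModel,
    expected: np.ndarray | None = None,
    min_mappable_fraction: float = MIN_MAPPABLE_FRACTION,
) -> pd.DataFrame:
    """Attach expected counts and RDR to a per-cell bin profile.

    ``expected_j = mean_count * model(gc_j)`` unless an external expected
    track is supplied.  Bins with non-positive expected count or with
    mappable_bp below ``min_mappable_fraction`` of the bin span get
    ``rdr = NaN`` (masked).
    """
    out = profile.copy()
    if expected is None:
        expected = model.mean_count * model.predict(out["gc"].to_numpy())
    expected = np.asarray(expected, dtype=float)
    span = (out["end"] - out["start"]).to_numpy()
    mappable = out["mappable_bp"].to_numpy() if "mappable_bp" in out else span
    ok = (expected > 0) & (mappable >= min_mappable_fraction * span)
    with np.errstate(divide="ignore", invalid="ignore"):
        rdr = np.where(ok, out["observed"].to_numpy() / expected, np.nan)
    out["expected"] = expected
    out["rdr"] = rdr
    return out
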