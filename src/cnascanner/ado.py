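"""Allelic-dropout (ADO) size modelling and bin-size selection.

Failed amplification of one allele produces runs of homozygous-looking
B-allele frequencies at germline heterozygous SNPs.  A two-state Gaussian
HMM over binarized BAF separates "ADO" from "non-ADO" stretches; the decoded
event-length distribution then fixes the smallest bin size at which dropout
cannot masquerade as a copy-number loss: the 95th percentile of event
lengths (equivalently, a cutoff at the top 5th percentile).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

logger = logging.getLogger(__name__)

#: |BAF - 0.5| below this marks a site as allelically balanced ("0").
BINARIZE_THRESHOLD = 0.2

#: Variance floor for the Gaussian emissions.  Binary observations make the
#: likelihood unbounded as a state collapses onto 0 or 1; the floor caps the
#: peak Gaussian density near 1 (the probability-mass scale of binary data),
#: without which the fitted "transitions" are just observed switching rates
#: and the hidden chain is not recovered.
MIN_VARIANCE = 0.15

DEFAULT_BIN_SIZE = 100_000


@dataclass
class AdoHmmParams:
    """Fitted two-state HMM; state order is canonical: index 1 = "ADO".

    The ADO state is the one with the higher emission mean (binarized BAF of
    1 marks homozygous-looking sites).
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray       # shape (2,)
    variances: np.ndarray   # shape (2,)
    log_likelihood: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.variances = np.asarray(self.variances, dtype=float).ravel()
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def ado_state(self) -> int:
        return 1


@dataclass(frozen=True)
class ADOEvent:
    """A contiguous run of gHETs decoded in the ADO state."""

    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class _BinaryGaussianHMM(GaussianHMM):
    """Gaussian HMM with emission variance tied to the mean.

    For binary observations the state-conditional variance is the Bernoulli
    variance m(1-m), floored at :data:`MIN_VARIANCE`; re-deriving it in each
    M-step instead of free estimation keeps EM away from the degenerate
    zero-variance solution at the support points.
    """

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        m = self.means_
        self.covars_ = np.maximum(m * (1.0 - m), MIN_VARIANCE)


def binarize_baf(baf_values) -> np.ndarray:
    """Binarize per-site BAF: 0 if |BAF - 0.5| < 0.2, else 1."""
    baf = np.asarray(baf_values, dtype=float)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF values must lie in [0, 1]")
    # tolerance so e.g. |0.7 - 0.5| (0.19999...996 in floats) counts as 0.2
    return (np.abs(baf - 0.5) >= BINARIZE_THRESHOLD - 1e-12).astype(np.int8)


def _canonicalize(model: GaussianHMM) -> AdoHmmParams:
    means = model.means_.ravel()
    order = np.argsort(means)  # low-mean state first => index 1 is ADO
    return AdoHmmParams(
        startprob=model.startprob_[order],
        transmat=model.transmat_[np.ix_(order, order)],
        means=means[order],
        variances=np.maximum(model.covars_.ravel()[order], MIN_VARIANCE),
        converged=bool(model.monitor_.converged),
    )


def fit_ado_hmm(
    binary_seq,
    seed: int,
    n_restarts: int = 10,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> AdoHmmParams:
    """Fit the two-state Gaussian HMM by Baum-Welch with random restarts.

    The best-scoring restart is returned with states relabelled so the
    higher-emission-mean state (homozygous-looking) is "ADO".  If no restart
    converges a warning is emitted and the best parameters so far returned.
    """
    obs = np.asarray(binary_seq, dtype=float).reshape(-1, 1)
    if len(obs) < 100:
        raise ValueError("need at least 100 observations to fit the ADO HMM")
    rng = np.random.default_rng(seed)
    best: tuple[float, GaussianHMM] | None = None
    for _ in range(n_restarts):
        model = _BinaryGaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
            init_params="stmc",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(obs)
                score = model.score(obs)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if best is None or score > best[0]:
            best = (score, model)
    if best is None:
        raise RuntimeError("all HMM restarts failed")
    score, model = best
    params = _canonicalize(model)
    params.log_likelihood = score
    if not params.converged:
        logger.warning("ADO HMM did not converge; returning best-so-far parameters")
    return params


def _to_hmm(params: AdoHmmParams) -> GaussianHMM:
    model = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    model.startprob_ = np.clip(params.startprob, 1e-12, None)
    model.startprob_ /= model.startprob_.sum()
    model.transmat_ = np.clip(params.transmat, 1e-12, None)
    model.transmat_ /= model.transmat_.sum(axis=1, keepdims=True)
    model.means_ = params.means.reshape(-1, 1)
    model.covars_ = params.variances.reshape(-1, 1)
    return model


def decode_ado_events(
    params: AdoHmmParams,
    positions,
    binary_obs,
    chrom: str = "chr1",
) -> list[ADOEvent]:
    """Viterbi-decode the observation sequence and extract ADO runs.

    Each maximal run of most-likely-state "ADO" becomes one event spanning
    the first to last gHET of the run; length = last - first + 1.
    """
    positions = np.asarray(positions)
    obs = np.asarray(binary_obs, dtype=float).reshape(-1, 1)
    if len(obs) == 0:
        return []
    if len(positions) != len(obs):
        raise ValueError("positions and observations must align")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    states = _to_hmm(params).predict(obs)
    events: list[ADOEvent] = []
    in_run = False
    run_start = 0
    for i, s in enumerate(states):
        if s == params.ado_state and not in_run:
            in_run, run_start = True, i
        elif s != params.ado_state and in_run:
            in_run = False
            events.append(ADOEvent(chrom, int(positions[run_start]), int(positions[i - 1]), i - run_start))
    if in_run:
        events.append(
            ADOEvent(chrom, int(positions[run_start]), int(positions[len(states) - 1]), len(states) - run_start)
        )
    return events


def empirical_p95(lengths) -> float:
    """Empirical 95th percentile: value at 1-based index ceil(0.95 n) of the
    sorted sample.  Exactly the top 5% of a tie-free sample exceed it."""
    x = np.sort(np.asarray(lengths, dtype=float))
    if len(x) == 0:
        raise ValueError("no event lengths")
    k = math.ceil(0.95 * len(x))
    return float(x[k - 1])


def select_bin_size(
    event_lengths,
    ladder=(),
    default: int = DEFAULT_BIN_SIZE,
    min_events: int = 20,
) -> int:
    """Minimum permissible bin size from the dropout-length distribution.

    Returns the smallest ladder entry >= the empirical 95th percentile of
    event lengths; with an empty ladder, the raw percentile rounded up to
    1 kb granularity with a 10 kb minimum.  Fewer than ``min_events`` events
    triggers a warning and the configured default.
    """
    lengths = np.asarray(event_lengths, dtype=float)
    if len(lengths) < min_events:
        logger.warning(
            "only %d ADO events (< %d); falling back to default bin size %d",
            len(lengths), min_events, default,
        )
        return default
    p95 = empirical_p95(lengths)
    ladder = sorted(int(x) for x in ladder)
    for size in ladder:
        if size >= p95:
            return size
    if ladder:
        logger.warning("95th percentile %.0f exceeds largest ladder entry; using it", p95)
        return ladder[-1]
    return max(int(math.ceil(p95 / 1_000) * 1_000), 10_000)
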