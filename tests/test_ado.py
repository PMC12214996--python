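import itertools

import numpy as np
import pytest

from cnascanner.ado import (
    AdoHmmParams,
    binarize_baf,
    decode_ado_events,
    empirical_p95,
    fit_ado_hmm,
    select_bin_size,
)


class TestBinarize:
    def test_rule(self):
        assert binarize_baf([0.5, 0.45, 0.9]).tolist() == [0, 0, 1]

    def test_boundary_is_homozygous(self):
        # |0.3 - 0.5| = 0.2 is NOT strictly below the threshold
        assert binarize_baf([0.3]).tolist() == [1]
        assert binarize_baf([0.7]).tolist() == [1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_baf([1.2])


def _sample_chain(rng, n, p_stay=(0.95, 0.9), emit=(0.05, 0.9)):
    states = np.empty(n, dtype=int)
    states[0] = 0
    for i in range(1, n):
        s = states[i - 1]
        states[i] = s if rng.random() < p_stay[s] else 1 - s
    obs = (rng.random(n) < np.asarray(emit)[states]).astype(int)
    return states, obs


class TestFitHmm:
    def test_parameter_recovery(self, rng):
        _, obs = _sample_chain(rng, 10_000)
        params = fit_ado_hmm(obs, seed=0)
        # canonical order: state 0 = non-ADO (low mean), state 1 = ADO
        assert params.transmat[0, 0] == pytest.approx(0.95, abs=0.03)
        assert params.transmat[1, 1] == pytest.approx(0.90, abs=0.03)
        assert params.means[1] > params.means[0]

    def test_determinism(self, rng):
        _, obs = _sample_chain(rng, 2_000)
        a = fit_ado_hmm(obs, seed=7)
        b = fit_ado_hmm(obs, seed=7)
        np.testing.assert_allclose(a.transmat, b.transmat)
        np.testing.assert_allclose(a.means, b.means)

    def test_all_zero_degenerate(self):
        params = fit_ado_hmm(np.zeros(200, dtype=int), seed=0)
        events = decode_ado_events(params, np.arange(200) * 100, np.zeros(200, dtype=int))
        assert events == []

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            fit_ado_hmm(np.zeros(50), seed=0)


def _sticky_params():
    return AdoHmmParams(
        startprob=np.array([0.5, 0.5]),
        transmat=np.array([[0.95, 0.05], [0.10, 0.90]]),
        means=np.array([0.05, 0.9]),
        variances=np.array([0.2, 0.2]),
    )


def _viterbi_brute(params, obs):
    """Exhaustive maximum-probability path over all 2^n state sequences."""
    obs = np.asarray(obs, dtype=float)
    best_lp, best_path = -np.inf, None
    for path in itertools.product([0, 1], repeat=len(obs)):
        lp = np.log(params.startprob[path[0]])
        for t in range(1, len(path)):
            lp += np.log(params.transmat[path[t - 1], path[t]])
        for t, s in enumerate(path):
            lp += -0.5 * (obs[t] - params.means[s]) ** 2 / params.variances[s] - 0.5 * np.log(
                2 * np.pi * params.variances[s]
            )
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


class TestDecode:
    def test_single_run_decoded(self):
        obs = np.array([0] * 50 + [1] * 20 + [0] * 50)
        pos = np.arange(len(obs)) * 1000
        events = decode_ado_events(_sticky_params(), pos, obs)
        assert len(events) == 1
        ev = events[0]
        assert ev.start == 50_000 and ev.end == 69_000
        assert ev.length == 19_001  # last - first + 1
        assert ev.n_snps == 20

    def test_matches_exhaustive_viterbi(self, rng):
        params = _sticky_params()
        obs = (rng.random(14) < 0.4).astype(int)
        pos = np.arange(14) * 500
        expected = _viterbi_brute(params, obs)
        events = decode_ado_events(params, pos, obs)
        decoded = np.zeros(14, dtype=int)
        for ev in events:
            decoded[(pos >= ev.start) & (pos <= ev.end)] = 1
        np.testing.assert_array_equal(decoded, expected)

    def test_isolated_one_not_an_event(self):
        obs = np.array([0] * 30 + [1] + [0] * 30)
        events = decode_ado_events(_sticky_params(), np.arange(61) * 1000, obs)
        assert events == []

    def test_events_sorted_nonoverlapping(self, rng):
        obs = (rng.random(500) < 0.3).astype(int)
        events = decode_ado_events(_sticky_params(), np.arange(500) * 100, obs)
        for a, b in zip(events, events[1:]):
            assert a.end < b.start


class TestSelectBinSize:
    def test_percentile_oracle(self):
        lengths = np.arange(1, 101) * 1000  # 1..100 kb
        assert empirical_p95(lengths) == 95_000
        assert select_bin_size(lengths, ladder=()) == 95_000  # multiple of 10 kb already

    def test_exactly_five_percent_exceed(self, rng):
        lengths = rng.lognormal(8, 1, 10_000)  # continuous => tie-free
        cutoff = empirical_p95(lengths)
        assert (lengths > cutoff).mean() == pytest.approx(0.05, abs=1e-9)

    def test_constant_lengths_round_up(self):
        assert select_bin_size([123_456] * 30, ladder=()) == 124_000

    def test_ladder_rounding(self):
        lengths = np.arange(1, 101) * 1000
        assert select_bin_size(lengths, ladder=(50_000, 100_000, 500_000)) == 100_000

    def test_few_events_fall_back_to_default(self):
        assert select_bin_size([5_000] * 10, ladder=(), default=100_000) == 100_000

    def test_pta_vs_mda_scale_separation(self, rng):
        """Protocols with ~100x different dropout scales get ~100x cutoffs.

        Compared on the raw 95th percentile; the 10 kb rounding of the final
        bin size floors the kilobase-scale protocol and would mask the ratio.
        """
        pta = rng.lognormal(np.log(1e3), 0.3, 500)
        mda = rng.lognormal(np.log(1e5), 0.3, 500)
        assert empirical_p95(mda) >= 50 * empirical_p95(pta)
        assert select_bin_size(mda, ladder=()) > select_bin_size(pta, ladder=())
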