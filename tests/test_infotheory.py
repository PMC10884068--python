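import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscomplexity import (
    Alphabet,
    SymbolicSequence,
    TransitionModel,
    analytic_markov_entropy_rate,
    block_entropy,
    block_entropy_profile,
    entropy_rate_excess,
    pai,
    synthesize_surrogate,
)


def binary_entropy(p: float) -> float:
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


class TestBlockEntropy:
    def test_constant_sequence_zero(self, make_seq):
        seq = make_seq("A" * 50)
        for k in (1, 2, 5):
            assert block_entropy(seq, k) == 0.0

    def test_alternating_one_bit_at_k1_and_k2(self, make_seq):
        # only words AB and BA occur at k=2, equiprobable in a long series
        seq = make_seq("AB" * 101)
        assert block_entropy(seq, 1) == pytest.approx(1.0, abs=1e-3)
        assert block_entropy(seq, 2) == pytest.approx(1.0, abs=1e-3)

    def test_iid_uniform_approaches_log2A(self, make_iid):
        seq = make_iid(100_000, A=4, seed=0)
        assert block_entropy(seq, 1) == pytest.approx(2.0, abs=0.01)

    def test_k_larger_than_length_errors(self, make_seq):
        with pytest.raises(ValueError):
            block_entropy(make_seq("ABAB"), 5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=8, max_size=200))
    def test_entropy_bounds(self, states):
        seq = SymbolicSequence(states, Alphabet.default(4))
        prof = block_entropy_profile(seq, k_max=6)
        assert prof.H[0] <= 2.0 + 1e-12
        assert (prof.H >= -1e-12).all()
        assert (prof.H <= prof.k_values * 2.0 + 1e-12).all()
        assert (prof.H <= np.log2(len(seq) - prof.k_values + 1) + 1e-12).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("kind", ["iid", "markov"])
    def test_monotone_in_k_when_well_sampled(self, make_iid, kind, seed):
        # H(k+1) >= H(k) holds whenever word counts are adequate; in the
        # undersampled regime (n - k + 1 distinct words at every k) the
        # plug-in profile can decrease, which is why entropy_rate_excess
        # warns there instead
        if kind == "iid":
            seq = make_iid(30_000, A=4, seed=seed)
        else:
            model = TransitionModel.from_matrix(
                np.full((4, 4), 0.1) + 0.6 * np.eye(4)
            )
            seq = synthesize_surrogate(model, 30_000, seed=seed)
        prof = block_entropy_profile(seq, k_max=6)
        assert (np.diff(prof.H) >= -1e-12).all()


class TestEntropyRateExcess:
    def test_constant_sequence(self, make_seq):
        with pytest.warns(UserWarning, match="undersampled"):
            est = entropy_rate_excess(make_seq("A" * 100))
        assert est.h_X == 0.0 and est.E == 0.0

    def test_iid_uniform_ceiling(self, make_iid):
        est = entropy_rate_excess(make_iid(100_000, A=4, seed=1))
        assert est.h_X == pytest.approx(2.0, abs=0.05)

    def test_two_state_markov_closed_form(self):
        model = TransitionModel.from_matrix([[0.9, 0.1], [0.1, 0.9]])
        seq = synthesize_surrogate(model, 100_000, seed=5)
        est = entropy_rate_excess(seq)
        assert est.h_X == pytest.approx(binary_entropy(0.1), abs=0.02)

    def test_warns_when_undersampled(self, make_iid):
        with pytest.warns(UserWarning, match="undersampled"):
            entropy_rate_excess(make_iid(500, A=4, seed=2), k_max=6)

    def test_kmax_below_two_errors(self, make_iid):
        with pytest.raises(ValueError):
            entropy_rate_excess(make_iid(100), k_max=1)

    def test_markov_recovery_within_two_hundredths(self):
        # plug-in fit recovers the analytic rate of a known chain, 10 seeds
        model = TransitionModel.from_matrix(
            [[0.8, 0.1, 0.05, 0.05],
             [0.1, 0.7, 0.1, 0.1],
             [0.05, 0.1, 0.8, 0.05],
             [0.1, 0.1, 0.1, 0.7]]
        )
        target = analytic_markov_entropy_rate(model)
        ests = [
            entropy_rate_excess(synthesize_surrogate(model, 100_000, seed=s)).h_X
            for s in range(10)
        ]
        assert abs(np.mean(ests) - target) < 0.02

    def test_iid_excess_entropy_vanishes(self, make_iid):
        Es = [entropy_rate_excess(make_iid(100_000, A=4, seed=s)).E for s in range(10)]
        assert abs(np.mean(Es)) < 0.05


class TestAnalyticMarkovRate:
    def test_identity_chain_zero(self):
        model = TransitionModel.from_matrix(np.eye(3), initial=[1.0, 0.0, 0.0])
        assert analytic_markov_entropy_rate(model) == 0.0

    def test_uniform_chain_log2A(self):
        model = TransitionModel.from_matrix(np.full((4, 4), 0.25))
        assert analytic_markov_entropy_rate(model) == pytest.approx(2.0)

    def test_binary_sticky_chain(self):
        model = TransitionModel.from_matrix([[0.9, 0.1], [0.1, 0.9]])
        assert analytic_markov_entropy_rate(model) == pytest.approx(
            binary_entropy(0.1), abs=1e-12
        )
        assert analytic_markov_entropy_rate(model) == pytest.approx(0.4690, abs=5e-5)

    def test_reducible_chain_errors(self):
        # two closed classes with different conditional entropies: the rate
        # would depend on the starting class, so there is no single answer
        P = [[1.0, 0.0, 0.0, 0.0],
             [0.0, 1.0, 0.0, 0.0],
             [0.0, 0.0, 0.5, 0.5],
             [0.0, 0.0, 0.5, 0.5]]
        model = TransitionModel.from_matrix(P)
        with pytest.raises(ValueError, match="not unique"):
            analytic_markov_entropy_rate(model)


class TestPAI:
    def test_iid_all_lags_vanish(self, make_iid):
        # plug-in conditional MI has a positive bias that grows with the
        # conditioning alphabet, roughly (A-1)^2 A^(k-1) / (2 n ln 2):
        # ~6e-5 bits at lag 1 and ~0.017 bits at lag 5 for A=4, n=1e5
        n = 100_000
        prof = pai(make_iid(n, A=4, seed=3), lag_max=5)
        assert prof.pai[0] == pytest.approx(2.0, abs=0.01)
        bias = 9 * 4.0 ** (prof.lags[1:] - 1) / (2 * n * np.log(2))
        assert (prof.pai[1:] < 2 * bias + 0.002).all()

    def test_period_two_saturates_lag_one(self, make_seq):
        prof = pai(make_seq("AB" * 5000), lag_max=3)
        assert prof.pai[0] == pytest.approx(1.0, abs=1e-3)
        assert prof.pai[1] == pytest.approx(1.0, abs=1e-3)

    def test_lag_zero_is_marginal_entropy(self, make_iid):
        seq = make_iid(10_000, A=4, seed=4)
        assert pai(seq, lag_max=2).pai[0] == block_entropy(seq, 1)

    def test_lag_max_exceeding_length_errors(self, make_seq):
        with pytest.raises(ValueError):
            pai(make_seq("ABAB"), lag_max=4)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=2), min_size=20, max_size=300))
    def test_non_negative_by_construction(self, states):
        seq = SymbolicSequence(states, Alphabet.default(3))
        prof = pai(seq, lag_max=4)
        assert (prof.pai >= 0.0).all()
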