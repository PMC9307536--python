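"""Smoothers, HMM post-processor and window tuning against naive oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfsmooth import (
    ConfigurationError,
    DecodingError,
    EstimationError,
    HmmPostProcessor,
    LabelSequence,
    LabelVocabulary,
    SmootherKind,
    count_changes,
    fit_hmm,
    hmm_decode_online,
    make_pair,
    modal_smooth,
    select_window,
    threshold_smooth,
)

from conftest import seq
from oracles import (
    mode_filter_bruteforce,
    path_log_score,
    threshold_filter_statemachine,
    viterbi_exhaustive,
)


@pytest.mark.parametrize("smoother", [modal_smooth, threshold_smooth])
class TestCommonSmootherContract:
    @pytest.mark.parametrize("n", [1, 5, 60])
    def test_constant_input_is_fixed_point(self, smoother, n, vocab3):
        s = seq(vocab3, [2] * 80)
        assert np.array_equal(smoother(s, n).frames, s.frames)

    @pytest.mark.parametrize("n", [0, 61, -3])
    def test_window_outside_range_rejected(self, smoother, n, vocab2):
        with pytest.raises(ConfigurationError):
            smoother(seq(vocab2, [0, 1, 0]), n)

    def test_short_sequence_passes_through(self, smoother, vocab2):
        s = seq(vocab2, [0, 1, 0])
        assert np.array_equal(smoother(s, 10).frames, s.frames)

    def test_first_n_frames_unchanged(self, smoother, vocab2):
        rng = np.random.default_rng(3)
        s = seq(vocab2, rng.integers(0, 2, size=50))
        out = smoother(s, 7)
        assert np.array_equal(out.frames[:7], s.frames[:7])

    def test_causal_prefix_unaffected_by_suffix_mutation(self, smoother, vocab3):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 3, size=120)
        cut = 60
        base = smoother(seq(vocab3, x), 6).frames[:cut]
        for _ in range(10):
            y = x.copy()
            y[cut:] = rng.integers(0, 3, size=len(x) - cut)
            mutated = smoother(seq(vocab3, y), 6).frames[:cut]
            assert np.array_equal(base, mutated)


class TestModalSmooth:
    def test_tie_breaks_to_most_recent(self, vocab2):
        # window {A,B} at t=1 is tied; the later frame wins
        assert list(modal_smooth(seq(vocab2, [0, 1]), 1).frames) == [0, 1]

    def test_all_length2_binary_sequences_match_oracle(self, vocab2):
        for a, b in itertools.product([0, 1], repeat=2):
            out = modal_smooth(seq(vocab2, [a, b]), 1).frames
            assert np.array_equal(out, mode_filter_bruteforce(np.array([a, b]), 1))

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            K = int(rng.integers(2, 5))
            vocab = LabelVocabulary("t", [f"c{i}" for i in range(K)])
            x = rng.integers(0, K, size=int(rng.integers(1, 201)))
            n = int(rng.integers(1, 21))
            out = modal_smooth(seq(vocab, x), n).frames
            assert np.array_equal(out, mode_filter_bruteforce(x, n))


class TestThresholdSmooth:
    def test_hold_previous_output_until_uniform_window(self, vocab2):
        # worked recurrence: [A,B,A,B,B,B], n=2 -> [A,B,B,B,B,B]
        out = threshold_smooth(seq(vocab2, [0, 1, 0, 1, 1, 1]), 2).frames
        assert list(out) == [0, 1, 1, 1, 1, 1]
        assert np.array_equal(
            out, threshold_filter_statemachine(np.array([0, 1, 0, 1, 1, 1]), 2)
        )

    def test_matches_state_machine_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.integers(0, 3, size=int(rng.integers(1, 201)))
            n = int(rng.integers(1, 21))
            vocab = LabelVocabulary("t", ["a", "b", "c"])
            out = threshold_smooth(seq(vocab, x), n).frames
            assert np.array_equal(out, threshold_filter_statemachine(x, n))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        frames=st.lists(st.integers(0, 2), min_size=1, max_size=150),
        n=st.integers(1, 30),
    )
    def test_never_increases_change_count(self, frames, n):
        vocab = LabelVocabulary("t", ["a", "b", "c"])
        s = seq(vocab, frames)
        assert count_changes(threshold_smooth(s, n)) <= count_changes(s)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        frames=st.lists(st.integers(0, 2), min_size=1, max_size=150),
        n=st.integers(1, 30),
    )
    def test_output_changes_at_least_n_plus_1_apart(self, frames, n):
        vocab = LabelVocabulary("t", ["a", "b", "c"])
        out = threshold_smooth(seq(vocab, frames), n).frames
        change_points = [t for t in range(1, len(out)) if out[t] != out[t - 1]]
        late = [t for t in change_points if t >= n]
        assert all(b - a >= n + 1 for a, b in zip(late, late[1:]))


class TestFitHmm:
    def test_counting_is_forced_in_small_alpha_limit(self, vocab2):
        pair = make_pair(seq(vocab2, [0, 0, 1]), seq(vocab2, [0, 0, 1]))
        model = fit_hmm([pair], alpha=1e-12)
        assert np.allclose(model.pi, [1.0, 0.0])
        assert np.allclose(model.A[0], [0.5, 0.5])
        # state 1 has no outgoing transitions: the pseudocount row is uniform
        assert np.allclose(model.A[1], [0.5, 0.5])
        assert np.allclose(model.B, np.eye(2), atol=1e-9)

    def test_laplace_smoothing_gives_strictly_positive_rows(self, vocab3):
        rng = np.random.default_rng(2)
        pairs = [
            make_pair(
                seq(vocab3, rng.integers(0, 3, size=40)),
                seq(vocab3, rng.integers(0, 3, size=40)),
            )
            for _ in range(3)
        ]
        model = fit_hmm(pairs, alpha=1.0)
        for mat in (model.pi[None, :], model.A, model.B):
            assert np.all(mat > 0)
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_training_set_rejected(self):
        with pytest.raises(EstimationError):
            fit_hmm([])

    def test_json_round_trip(self, vocab3, tmp_path):
        pair = make_pair(seq(vocab3, [0, 1, 2]), seq(vocab3, [0, 1, 1]))
        model = fit_hmm([pair], alpha=0.5, lookahead=7)
        path = tmp_path / "hmm.json"
        model.to_json(path)
        back = HmmPostProcessor.from_json(path)
        assert back.labels == model.labels
        assert back.alpha == model.alpha and back.lookahead == model.lookahead
        for a, b in ((back.pi, model.pi), (back.A, model.A), (back.B, model.B)):
            assert np.allclose(a, b)


def _random_model(rng, K, labels=None):
    labels = labels or tuple(f"c{i}" for i in range(K))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    B = rng.dirichlet(np.ones(K), size=K)
    return HmmPostProcessor(labels=labels, pi=pi, A=A, B=B, alpha=1.0, lookahead=5)


class TestHmmDecodeOnline:
    def test_identity_emissions_reproduce_observations(self, vocab2):
        model = HmmPostProcessor(
            labels=vocab2.labels,
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.7, 0.3], [0.4, 0.6]]),
            B=np.eye(2),
            alpha=1.0,
            lookahead=0,
        )
        s = seq(vocab2, [0, 1, 1, 0, 1])
        assert np.array_equal(hmm_decode_online(model, s).frames, s.frames)

    def test_isolated_flip_absorbed_with_lookahead(self, vocab2):
        model = HmmPostProcessor(
            labels=vocab2.labels,
            pi=np.array([0.5, 0.5]),
            A=np.array([[0.9, 0.1], [0.1, 0.9]]),
            B=np.array([[0.9, 0.1], [0.1, 0.9]]),
            alpha=1.0,
            lookahead=5,
        )
        obs = np.array([0, 0, 0, 1, 0, 0, 0])
        out = hmm_decode_online(model, seq(vocab2, obs)).frames
        assert list(out) == [0] * 7
        # exhaustive enumeration confirms the all-zero path is optimal
        assert np.array_equal(
            viterbi_exhaustive(model.pi, model.A, model.B, obs), np.zeros(7, int)
        )

    def test_full_lookahead_equals_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(1, 9))
            vocab = LabelVocabulary("t", [f"c{i}" for i in range(K)])
            model = _random_model(rng, K, vocab.labels)
            obs = rng.integers(0, K, size=T)
            out = hmm_decode_online(model, seq(vocab, obs), lookahead=T).frames
            best = viterbi_exhaustive(model.pi, model.A, model.B, obs)
            ours = path_log_score(model.pi, model.A, model.B, obs, out)
            theirs = path_log_score(model.pi, model.A, model.B, obs, best)
            # distinct paths can tie exactly (same factor multiset); the
            # contract is that the decoded path attains the maximum score
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_full_lookahead_matches_hmmlearn_viterbi(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(5)
        K = 3
        vocab = LabelVocabulary("t", ["a", "b", "c"])
        model = _random_model(rng, K, vocab.labels)
        obs = rng.integers(0, K, size=400)
        ours = hmm_decode_online(model, seq(vocab, obs), lookahead=400).frames
        ref = hmmlearn.CategoricalHMM(n_components=K)
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.emissionprob_ = model.B
        _, ref_path = ref.decode(obs.reshape(-1, 1), algorithm="viterbi")
        assert np.array_equal(ours, ref_path)

    def test_lookahead_limits_dependence_on_future(self, vocab3):
        rng = np.random.default_rng(6)
        pairs = [
            make_pair(
                seq(vocab3, np.sort(rng.integers(0, 3, size=100))),
                seq(vocab3, rng.integers(0, 3, size=100)),
            )
            for _ in range(3)
        ]
        model = fit_hmm(pairs, lookahead=4)
        x = rng.integers(0, 3, size=100)
        base = hmm_decode_online(model, seq(vocab3, x)).frames
        for _ in range(5):
            y = x.copy()
            cut = 60
            y[cut:] = rng.integers(0, 3, size=40)
            mutated = hmm_decode_online(model, seq(vocab3, y)).frames
            # frames before cut - L may not see the mutated suffix
            assert np.array_equal(base[: cut - 4], mutated[: cut - 4])

    def test_zero_probability_observation_raises(self, vocab2):
        model = HmmPostProcessor(
            labels=vocab2.labels,
            pi=np.array([1.0, 0.0]),
            A=np.array([[1.0, 0.0], [0.0, 1.0]]),
            B=np.array([[1.0, 0.0], [0.0, 1.0]]),
            alpha=1.0,
            lookahead=0,
        )
        with pytest.raises(DecodingError):
            hmm_decode_online(model, seq(vocab2, [0, 1]))


class TestSelectWindow:
    def test_changeless_perfect_predictions_score_one_at_every_window(self, vocab3):
        pairs = [
            make_pair(seq(vocab3, [c] * 50), seq(vocab3, [c] * 50))
            for c in range(3)
        ]
        sel = select_window(pairs, SmootherKind.THRESHOLD, (1, 20))
        assert sel.best_n == 1  # ties resolve to the smallest window
        assert all(s == pytest.approx(1.0) for s in sel.scores.values())

    @pytest.mark.parametrize("kind", [SmootherKind.MODAL, SmootherKind.THRESHOLD])
    def test_perfect_predictions_pick_smallest_window(self, kind, vocab3):
        # smoothing a perfect prediction can only add change-point lag, and
        # the lag grows with n, so the smallest window must win
        rng = np.random.default_rng(7)
        pairs = []
        for _ in range(3):
            x = np.sort(rng.integers(0, 3, size=80))
            pairs.append(make_pair(seq(vocab3, x), seq(vocab3, x)))
        sel = select_window(pairs, kind, (1, 20))
        assert sel.best_n == 1

    def test_degenerate_range_returns_its_endpoint(self, vocab3):
        pair = make_pair(seq(vocab3, [0] * 30 + [1] * 30), seq(vocab3, [0] * 60))
        sel = select_window([pair], "modal", (5, 5))
        assert sel.best_n == 5
        assert set(sel.scores) == {5}

    def test_burst_errors_select_bracketing_window(self, vocab2):
        # error bursts of length exactly 3, correct runs > 10 frames
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(4):
            gt = np.repeat([0, 1, 0, 1], 40)
            pred = gt.copy()
            for start in range(15, len(gt) - 3, 25):
                pred[start : start + 3] = 1 - gt[start : start + 3]
            pairs.append(make_pair(seq(vocab2, gt), seq(vocab2, pred)))
        sel = select_window(pairs, SmootherKind.THRESHOLD, (1, 20))
        assert 3 <= sel.best_n <= 10
        assert sel.scores[sel.best_n] > sel.scores[1]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ConfigurationError):
            select_window([], "modal")
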