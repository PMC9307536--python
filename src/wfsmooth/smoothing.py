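"""Temporal smoothing of frame-wise workflow predictions.

Frame-wise classifiers on endoscopic video produce volatile label tracks:
short bursts of spurious classes whenever the scene is occluded or the
endoscope is withdrawn.  This module implements three causal post-processors
that stabilise such tracks:

``modal_smooth`` (the windowed-mode filter M_n)
    Replaces the prediction at frame ``t`` (for ``t >= n``) by the mode of
    the current and previous ``n`` predictions — a window of ``n + 1``
    frames.  The first ``n`` frames pass through unchanged.  When two
    classes tie for the mode, the *most recent* one wins: among the tied
    classes, the one whose latest occurrence inside the window is closest
    to ``t``.

``threshold_smooth`` (the hysteresis/debounce filter T_n)
    Changes its output to class ``c`` only once the current and previous
    ``n`` predictions are all ``c`` (``n + 1`` consecutive identical
    frames); otherwise the previous *output* is held.  The first ``n``
    frames pass through unchanged.  A change therefore requires a sustained
    run, which caps the output's change rate: consecutive output change
    points are at least ``n + 1`` frames apart once past the passthrough
    region.

``hmm_decode_online`` (discrete HMM with fixed lookahead)
    Treats the true workflow state as a Markov chain and the classifier
    output as a noisy categorical emission.  The label at frame ``t`` is
    read off the Viterbi-optimal state path for the observation prefix
    ``pred[0 .. min(t + L, T-1)]`` — i.e. the decoder may peek ``L`` frames
    ahead (at 1 Hz, ``L`` frames = ``L`` seconds of latency) but is
    otherwise causal.

All three operate on integer class indices; window sizes follow the
convention that ``n`` counts *previous* frames, so the effective window is
``n + 1`` frames wide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score

from .errors import (
    ConfigurationError,
    DecodingError,
    EstimationError,
)
from .sequences import LabelSequence, LabelVocabulary, SequencePair

logger = logging.getLogger(__name__)

#: Inclusive window-size range scanned during tuning.
WINDOW_RANGE: tuple[int, int] = (1, 60)

#: Default decoder lookahead, in frames (= seconds at 1 Hz).
DEFAULT_LOOKAHEAD: int = 5


class SmootherKind(str, Enum):
    MODAL = "modal"
    THRESHOLD = "threshold"


@dataclass(frozen=True)
class SmootherConfig:
    """A smoothing method (modal or threshold) together with its window n."""

    kind: SmootherKind
    n: int

    def __post_init__(self) -> None:
        _check_window(self.n)

    def apply(self, pred: LabelSequence) -> LabelSequence:
        if self.kind is SmootherKind.MODAL:
            return modal_smooth(pred, self.n)
        return threshold_smooth(pred, self.n)


def _check_window(n: int) -> None:
    lo, hi = WINDOW_RANGE
    if not (isinstance(n, (int, np.integer)) and lo <= int(n) <= hi):
        raise ConfigurationError(
            f"window size n must be an integer in [{lo}, {hi}], got {n!r}"
        )


def modal_smooth(pred: LabelSequence, n: int) -> LabelSequence:
    """Windowed-mode filter: output[t] = mode of pred[t-n .. t] for t >= n.

    The first ``n`` frames are passed through unchanged.  Modal ties resolve
    to the tied class occurring most recently within the window.  Runs in
    O(T*K) via cumulative one-hot counts.
    """
    _check_window(n)
    x = pred.frames
    T = x.size
    K = pred.vocabulary.K
    out = x.copy()
    if T <= n:
        return pred.replace_frames(out)

    onehot = np.zeros((T, K), dtype=np.int64)
    onehot[np.arange(T), x] = 1
    csum = np.zeros((T + 1, K), dtype=np.int64)
    np.cumsum(onehot, axis=0, out=csum[1:])
    # counts[j, c] = #occurrences of c in window [t-n .. t], t = n + j
    counts = csum[n + 1 :] - csum[: T - n]

    # last_seen[t, c] = latest index <= t where class c occurs (-1 if never).
    occurrence = np.where(onehot.astype(bool), np.arange(T)[:, None], -1)
    last_seen = np.maximum.accumulate(occurrence, axis=0)

    # Classes with the max count are separated by >= 1 count, so scaling the
    # count by T dominates the recency term; among tied classes (all present
    # in the window) last_seen is distinct and inside the window.
    score = counts * np.int64(T) + last_seen[n:]
    out[n:] = np.argmax(score, axis=1)
    return pred.replace_frames(out)


def threshold_smooth(pred: LabelSequence, n: int) -> LabelSequence:
    """Hysteresis filter: the output changes to c only after n+1 consecutive
    predictions of c; otherwise the previous output is held.

    The first ``n`` frames are passed through unchanged; sequences shorter
    than ``n + 1`` frames are returned as-is.
    """
    _check_window(n)
    x = pred.frames
    T = x.size
    if T <= n:
        return pred.replace_frames(x.copy())

    is_start = np.ones(T, dtype=bool)
    is_start[1:] = x[1:] != x[:-1]
    start_idx = np.maximum.accumulate(np.where(is_start, np.arange(T), 0))
    run_len = np.arange(T) - start_idx + 1

    # A frame "commits" its raw prediction when the trailing window of n+1
    # frames is uniform; held frames inherit the last committed value.
    commit = run_len >= n + 1
    commit[:n] = True
    src = np.maximum.accumulate(np.where(commit, np.arange(T), 0))
    return pred.replace_frames(x[src])


# ---------------------------------------------------------------------------
# Discrete HMM post-processing
# ---------------------------------------------------------------------------


@dataclass
class HmmPostProcessor:
    """A supervised discrete HMM over workflow states with lookahead decoding.

    States are the ground-truth workflow classes; observations are the
    classifier's predicted classes.  ``pi`` is the initial state
    distribution, ``A`` the state-transition matrix, ``B`` the emission
    matrix (state -> predicted label), all estimated by additive-pseudocount
    (Laplace) counting on completed annotated sequences.  ``lookahead`` is
    the number of future observations the online decoder may inspect.
    """

    labels: tuple[str, ...]
    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    alpha: float
    lookahead: int = DEFAULT_LOOKAHEAD

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        K = self.K
        if self.pi.shape != (K,) or self.A.shape != (K, K) or self.B.shape != (K, K):
            raise ConfigurationError("pi, A, B must have shapes (K,), (K,K), (K,K)")
        for name, arr, axis_sum in (
            ("pi", self.pi, self.pi.sum()),
            ("A", self.A, self.A.sum(axis=1)),
            ("B", self.B, self.B.sum(axis=1)),
        ):
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} contains negative entries")
            if not np.allclose(axis_sum, 1.0, atol=1e-9):
                raise ConfigurationError(f"rows of {name} must sum to 1 within 1e-9")
        if self.lookahead < 0:
            raise ConfigurationError("lookahead must be >= 0")
        if not self.alpha > 0:
            raise ConfigurationError("pseudocount alpha must be > 0")

    @property
    def K(self) -> int:
        return len(self.labels)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "alpha": self.alpha,
            "lookahead": self.lookahead,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmPostProcessor":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            labels=tuple(d["labels"]),
            pi=np.asarray(d["pi"]),
            A=np.asarray(d["A"]),
            B=np.asarray(d["B"]),
            alpha=float(d["alpha"]),
            lookahead=int(d["lookahead"]),
        )


def fit_hmm(
    training_pairs: Sequence[SequencePair],
    alpha: float = 1.0,
    lookahead: int = DEFAULT_LOOKAHEAD,
) -> HmmPostProcessor:
    """Supervised estimation of the HMM post-processor by Laplace counting.

    ``pi[s]`` counts sequences starting in ground-truth state ``s``;
    ``A[s, s']`` counts ground-truth transitions ``s -> s'``; ``B[s, o]``
    counts frames whose ground truth is ``s`` and prediction ``o``.  Every
    cell receives the additive pseudocount ``alpha`` before row
    normalisation, so all probabilities are strictly positive.
    """
    if len(training_pairs) == 0:
        raise EstimationError("cannot fit an HMM on an empty training set")
    vocab = training_pairs[0].ground_truth.vocabulary
    for p in training_pairs:
        if p.ground_truth.vocabulary != vocab:
            raise EstimationError("all training pairs must share one vocabulary")
    if not alpha > 0:
        raise ConfigurationError("pseudocount alpha must be > 0")

    K = vocab.K
    pi_c = np.full(K, alpha, dtype=float)
    A_c = np.full((K, K), alpha, dtype=float)
    B_c = np.full((K, K), alpha, dtype=float)
    for pair in training_pairs:
        g = pair.ground_truth.frames
        o = pair.prediction.frames
        pi_c[g[0]] += 1.0
        if g.size > 1:
            np.add.at(A_c, (g[:-1], g[1:]), 1.0)
        np.add.at(B_c, (g, o), 1.0)
    return HmmPostProcessor(
        labels=vocab.labels,
        pi=pi_c / pi_c.sum(),
        A=A_c / A_c.sum(axis=1, keepdims=True),
        B=B_c / B_c.sum(axis=1, keepdims=True),
        alpha=alpha,
        lookahead=lookahead,
    )


def hmm_decode_online(
    model: HmmPostProcessor, pred: LabelSequence, lookahead: int | None = None
) -> LabelSequence:
    """Viterbi decoding with a fixed lookahead of L future frames.

    ``output[t]`` is the state at position ``t`` of the max-probability
    state path for the observation prefix ``pred[0 .. min(t+L, T-1)]``.
    With ``L >= T - 1`` this reduces to full-sequence Viterbi decoding.
    Computation is in log space; argmax ties break toward the lower state
    index for cross-platform determinism.
    """
    L = model.lookahead if lookahead is None else int(lookahead)
    if L < 0:
        raise ConfigurationError("lookahead must be >= 0")
    if model.K != pred.vocabulary.K:
        raise DecodingError(
            f"model has {model.K} states but sequence vocabulary has "
            f"{pred.vocabulary.K} classes"
        )
    obs = pred.frames
    T = obs.size
    K = model.K
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_A = np.log(model.A)
        log_B = np.log(model.B)

    # Forward Viterbi pass: delta[t, s] = best log-score of any path ending
    # in state s at frame t; psi[t, s] = argmax predecessor.
    delta = np.empty((T, K), dtype=float)
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = log_pi + log_B[:, obs[0]]
    if not np.isfinite(delta[0]).any():
        raise DecodingError(
            f"no admissible initial state for observation {int(obs[0])}"
        )
    for t in range(1, T):
        scores = delta[t - 1][:, None] + log_A  # (from, to)
        psi[t] = np.argmax(scores, axis=0)
        delta[t] = scores[psi[t], np.arange(K)] + log_B[:, obs[t]]
        if not np.isfinite(delta[t]).any():
            raise DecodingError(
                f"no admissible state path at frame {t} "
                f"(zero-probability observation {int(obs[t])})"
            )

    out = np.empty(T, dtype=np.int64)
    for t in range(T):
        e = min(t + L, T - 1)
        s = int(np.argmax(delta[e]))
        for u in range(e, t, -1):
            s = int(psi[u, s])
        out[t] = s
    return pred.replace_frames(out)


# ---------------------------------------------------------------------------
# Window-size tuning
# ---------------------------------------------------------------------------


@dataclass
class WindowSelection:
    """Result of scanning window sizes for one smoothing method."""

    kind: SmootherKind
    best_n: int
    scores: dict[int, float] = field(repr=False)

    def __post_init__(self) -> None:
        best = max(self.scores.values())
        argmax = min(n for n, s in self.scores.items() if s == best)
        if self.best_n != argmax:
            raise ConfigurationError(
                "best_n must be the smallest argmax of the score table"
            )


def _pooled_weighted_f1(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    y_true = np.concatenate([g for g, _ in pairs])
    y_pred = np.concatenate([p for _, p in pairs])
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def select_window(
    training_pairs: Sequence[SequencePair],
    kind: SmootherKind | str,
    n_range: tuple[int, int] = WINDOW_RANGE,
    pooling: str = "frames",
) -> WindowSelection:
    """Scan window sizes and pick the one maximising training weighted-F1.

    For every ``n`` in ``n_range`` (inclusive), the smoother is applied to
    each training prediction and the weighted-F1 against ground truth is
    recorded; ties resolve to the smallest ``n``.  ``pooling="frames"``
    (default) concatenates all training frames into one dataset-level score;
    ``pooling="videos"`` averages per-video scores instead.
    """
    if len(training_pairs) == 0:
        raise ConfigurationError("cannot select a window on an empty training set")
    kind = SmootherKind(kind)
    lo, hi = int(n_range[0]), int(n_range[1])
    if not (WINDOW_RANGE[0] <= lo <= hi <= WINDOW_RANGE[1]):
        raise ConfigurationError(
            f"n_range must satisfy {WINDOW_RANGE[0]} <= lo <= hi <= {WINDOW_RANGE[1]}"
        )
    if pooling not in ("frames", "videos"):
        raise ConfigurationError("pooling must be 'frames' or 'videos'")

    smoother = modal_smooth if kind is SmootherKind.MODAL else threshold_smooth
    scores: dict[int, float] = {}
    for n in range(lo, hi + 1):
        smoothed = [
            (p.ground_truth.frames, smoother(p.prediction, n).frames)
            for p in training_pairs
        ]
        if pooling == "frames":
            scores[n] = _pooled_weighted_f1(smoothed)
        else:
            scores[n] = float(
                np.mean([_pooled_weighted_f1([pair]) for pair in smoothed])
            )
    best = max(scores.values())
    best_n = min(n for n, s in scores.items() if s == best)
    logger.info("window tuning (%s): best n = %d (weighted-F1 %.4f)", kind.value, best_n, best)
    return WindowSelection(kind=kind, best_n=best_n, scores=scores)
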