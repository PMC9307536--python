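"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops, recounting,
exhaustive enumeration — and shares no code with the implementations under
test.
"""

from __future__ import annotations

import itertools

import numpy as np


def mode_filter_bruteforce(x: np.ndarray, n: int) -> np.ndarray:
    """Windowed mode with most-recent tie-break, recounted frame by frame."""
    x = np.asarray(x)
    out = x.copy()
    for t in range(n, len(x)):
        window = x[t - n : t + 1]
        counts: dict[int, int] = {}
        for v in window:
            counts[int(v)] = counts.get(int(v), 0) + 1
        best = max(counts.values())
        tied = {c for c, k in counts.items() if k == best}
        # scan the window backwards; the first tied class seen is most recent
        for v in window[::-1]:
            if int(v) in tied:
                out[t] = int(v)
                break
    return out


def threshold_filter_statemachine(x: np.ndarray, n: int) -> np.ndarray:
    """Hysteresis filter as an explicit state machine over the output stream."""
    x = np.asarray(x)
    out = x.copy()
    for t in range(n, len(x)):
        window = x[t - n : t + 1]
        if np.all(window == window[0]):
            out[t] = window[0]
        else:
            out[t] = out[t - 1]
    return out


def count_changes_loop(x: np.ndarray) -> int:
    x = np.asarray(x)
    total = 0
    for t in range(1, len(x)):
        if x[t] != x[t - 1]:
            total += 1
    return total


def path_log_score(
    pi: np.ndarray, A: np.ndarray, B: np.ndarray, obs: np.ndarray, path: np.ndarray
) -> float:
    """Log probability of a state path given the observations."""
    with np.errstate(divide="ignore"):
        lp, lA, lB = np.log(pi), np.log(A), np.log(B)
    score = lp[path[0]] + lB[path[0], obs[0]]
    for t in range(1, len(obs)):
        score += lA[path[t - 1], path[t]] + lB[path[t], obs[t]]
    return float(score)


def viterbi_exhaustive(
    pi: np.ndarray, A: np.ndarray, B: np.ndarray, obs: np.ndarray
) -> np.ndarray:
    """Max-probability state path by enumerating all K^T paths.

    Probabilities are multiplied in log space; among equal-probability paths
    the lexicographically smallest wins, matching a decoder that breaks
    argmax ties toward the lower state index at every step.
    """
    K = len(pi)
    T = len(obs)
    with np.errstate(divide="ignore"):
        lp, lA, lB = np.log(pi), np.log(A), np.log(B)
    best_path = None
    best_score = -np.inf
    for path in itertools.product(range(K), repeat=T):
        score = lp[path[0]] + lB[path[0], obs[0]]
        for t in range(1, T):
            score += lA[path[t - 1], path[t]] + lB[path[t], obs[t]]
        # strict > keeps the first (lexicographically smallest) maximiser
        if score > best_score + 1e-12:
            best_score = score
            best_path = path
    return np.asarray(best_path)
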