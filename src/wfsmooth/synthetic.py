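"""Synthetic workflow sequences and classifier-noise generators.

The simulator emulates the statistical structure of operative workflow
annotations and of the frame-wise predictions a spatial CNN produces on
them, without fitting any real dataset:

* ground truth — classes (phases or steps) are visited in a canonical
  clinical order, with occasional *skips* (a step omitted in a particular
  operation) and *revisits* (a brief return to the previous step); per-visit
  durations are heavy-tailed (log-normal, rounded to whole seconds, >= 1 s);

* frame-wise noise — each frame's predicted class is drawn from a confusion
  row concentrated on the true class and its order-neighbours (adjacent
  steps look alike: shared instruments and anatomy);

* burst noise — contiguous intervals of spurious labels emulating
  uninformative frames from scene occlusion or endoscope withdrawal, during
  which the prediction "could be anything".

Every generator is a pure function of (model parameters, seed): identical
inputs give bit-identical output.

Two deterministic worked-example fixtures are included:
:func:`volatility_worked_example` (3 prediction changes over 2 ground-truth
changes, volatility 3/2 = 1.5) and :func:`flicker_worked_example` (a
two-class track with 7 class changes whose short minority runs a window-5
smoother collapses to a single change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .sequences import LabelSequence, LabelVocabulary, SequencePair, make_pair

logger = logging.getLogger(__name__)

#: Default per-visit duration: log-normal with median exp(mu) ~ 600 s.
DEFAULT_DURATION_LOG_MEAN = float(np.log(600.0))
DEFAULT_DURATION_LOG_SD = 0.5


def sequence_from_runs(
    vocab: LabelVocabulary,
    runs: Sequence[tuple[int, int]],
    video_id: str = "synthetic",
) -> LabelSequence:
    """Build a sequence from run-length encoding [(class_index, length), ...]."""
    parts = [np.full(length, cls, dtype=np.int64) for cls, length in runs]
    return LabelSequence(video_id, vocab, np.concatenate(parts))


@dataclass(frozen=True)
class WorkflowModel:
    """Generative model of a ground-truth workflow sequence.

    ``order`` is the canonical visit order (class indices); each class may be
    skipped with ``skip_prob``; after each later visit the previous class may
    be briefly revisited with ``revisit_prob``.  Visit durations are
    log-normal(``duration_log_mean``, ``duration_log_sd``) seconds, rounded
    and clipped to >= 1 s.
    """

    vocabulary: LabelVocabulary
    order: tuple[int, ...] = ()
    skip_prob: float = 0.05
    revisit_prob: float = 0.05
    duration_log_mean: float = DEFAULT_DURATION_LOG_MEAN
    duration_log_sd: float = DEFAULT_DURATION_LOG_SD

    def __post_init__(self) -> None:
        order = self.order if self.order else tuple(range(self.vocabulary.K))
        object.__setattr__(self, "order", tuple(int(c) for c in order))
        if sorted(self.order) != list(range(self.vocabulary.K)):
            raise ConfigurationError(
                "order must be a permutation of all class indices"
            )
        for name in ("skip_prob", "revisit_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.duration_log_sd < 0:
            raise ConfigurationError("duration_log_sd must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Generative model of classifier noise on top of a ground-truth track.

    ``confusion`` is row-stochastic: row ``s`` is the distribution of the
    emitted prediction given ground truth ``s``.  Independently, occlusion
    bursts start at each frame with probability ``burst_start_prob`` (when no
    burst is active), last uniform(``burst_len_min``, ``burst_len_max``)
    frames and overwrite the prediction with wrong labels — per-frame uniform
    over wrong classes (``burst_label_mode="uniform_wrong"``) or one wrong
    class held for the whole burst (``"fixed_class"``).
    """

    confusion: np.ndarray
    burst_start_prob: float = 0.0
    burst_len_min: int = 1
    burst_len_max: int = 1
    burst_label_mode: str = "uniform_wrong"

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
            raise ConfigurationError("confusion must be a square matrix")
        if np.any(conf < 0) or not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("confusion rows must be >= 0 and sum to 1")
        object.__setattr__(self, "confusion", conf)
        if not 0.0 <= self.burst_start_prob <= 1.0:
            raise ConfigurationError("burst_start_prob must be in [0, 1]")
        if not 1 <= self.burst_len_min <= self.burst_len_max:
            raise ConfigurationError(
                "burst lengths must satisfy 1 <= burst_len_min <= burst_len_max"
            )
        if self.burst_label_mode not in ("uniform_wrong", "fixed_class"):
            raise ConfigurationError(
                "burst_label_mode must be 'uniform_wrong' or 'fixed_class'"
            )

    @property
    def K(self) -> int:
        return int(self.confusion.shape[0])


def neighbor_confusion(
    K: int, diag: float = 0.85, neighbor_mass: float | None = None
) -> np.ndarray:
    """Row-stochastic confusion matrix with mass on order-neighbours.

    Row ``s`` puts ``diag`` on the true class, ``neighbor_mass`` (default:
    all remaining mass) split over the adjacent classes ``s±1`` that exist,
    and whatever is left uniformly over the other wrong classes.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if K == 1:
        return np.ones((1, 1))
    if neighbor_mass is None:
        neighbor_mass = 1.0 - diag
    rest = 1.0 - diag - neighbor_mass
    if diag < 0 or neighbor_mass < 0 or rest < -1e-12:
        raise ConfigurationError("diag + neighbor_mass must not exceed 1")
    rest = max(rest, 0.0)
    conf = np.zeros((K, K))
    for s in range(K):
        neighbors = [c for c in (s - 1, s + 1) if 0 <= c < K]
        others = [c for c in range(K) if c != s and c not in neighbors]
        conf[s, s] = diag
        for c in neighbors:
            conf[s, c] = neighbor_mass / len(neighbors)
        if others:
            for c in others:
                conf[s, c] = rest / len(others)
        else:
            conf[s, neighbors] += rest / len(neighbors)
    return conf / conf.sum(axis=1, keepdims=True)


def simulate_ground_truth(
    model: WorkflowModel, seed: int, video_id: str = "sim"
) -> LabelSequence:
    """Draw one ground-truth workflow sequence.

    Visit order follows ``model.order`` with independent per-class skips;
    after each visit past the first, the previous class may be revisited
    (then the interrupted class resumes).  If every class is skipped, the
    draw is retried with skipping disabled for one uniformly chosen class
    (logged).
    """
    rng = np.random.default_rng(seed)
    keep = rng.random(len(model.order)) >= model.skip_prob
    if not keep.any():
        forced = int(rng.integers(len(model.order)))
        keep[forced] = True
        logger.info(
            "video %s: all classes skipped; forcing class %d to be visited",
            video_id,
            model.order[forced],
        )
    base = [c for c, k in zip(model.order, keep) if k]

    visits: list[int] = [base[0]]
    for prev, cur in zip(base[:-1], base[1:]):
        visits.append(cur)
        if rng.random() < model.revisit_prob:
            visits.extend((prev, cur))

    durations = rng.lognormal(
        model.duration_log_mean, model.duration_log_sd, size=len(visits)
    )
    durations = np.maximum(np.rint(durations).astype(np.int64), 1)
    frames = np.repeat(np.asarray(visits, dtype=np.int64), durations)
    return LabelSequence(video_id, model.vocabulary, frames)


def corrupt_predictions(
    gt: LabelSequence, noise: NoiseModel, seed: int
) -> LabelSequence:
    """Emit a synthetic prediction track for a ground-truth sequence.

    Each frame is drawn from the confusion row of its ground-truth class;
    a burst process then overwrites contiguous intervals with wrong labels.
    """
    if noise.K != gt.vocabulary.K:
        raise ConfigurationError(
            f"noise model has {noise.K} classes, sequence has {gt.vocabulary.K}"
        )
    rng = np.random.default_rng(seed)
    K = gt.vocabulary.K
    T = len(gt)

    # frame-wise channel: inverse-CDF sampling per ground-truth class
    cdf = np.cumsum(noise.confusion, axis=1)
    u = rng.random(T)
    pred = (u[:, None] > cdf[gt.frames]).sum(axis=1).astype(np.int64)
    pred = np.minimum(pred, K - 1)

    if noise.burst_start_prob > 0 and K > 1:
        t = 0
        while t < T:
            if rng.random() < noise.burst_start_prob:
                length = int(
                    rng.integers(noise.burst_len_min, noise.burst_len_max + 1)
                )
                end = min(t + length, T)
                if noise.burst_label_mode == "fixed_class":
                    wrong = [c for c in range(K) if c != gt.frames[t]]
                    label = int(rng.choice(wrong))
                    pred[t:end] = label
                else:
                    for u_t in range(t, end):
                        wrong = [c for c in range(K) if c != gt.frames[u_t]]
                        pred[u_t] = int(rng.choice(wrong))
                t = end
            else:
                t += 1
    return LabelSequence(gt.video_id, gt.vocabulary, pred)


@dataclass(frozen=True)
class SimulationRun:
    """A reproducible batch of simulated ground-truth/prediction pairs."""

    seed: int
    workflow: WorkflowModel
    noise: NoiseModel
    pairs: tuple[SequencePair, ...] = field(repr=False, default=())


def simulate_pairs(
    workflow: WorkflowModel,
    noise: NoiseModel,
    n_videos: int,
    seed: int,
    video_prefix: str = "video",
) -> SimulationRun:
    """Simulate ``n_videos`` independent (ground truth, prediction) pairs.

    Per-video seeds are spawned from a :class:`numpy.random.SeedSequence`
    rooted at ``seed``, so the batch is bit-reproducible and videos are
    statistically independent.
    """
    if n_videos < 1:
        raise ConfigurationError("n_videos must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_videos)
    pairs = []
    for i in range(n_videos):
        vid = f"{video_prefix}{i:03d}"
        gt_seed = children[2 * i].generate_state(1)[0] % (2**31)
        pr_seed = children[2 * i + 1].generate_state(1)[0] % (2**31)
        gt = simulate_ground_truth(workflow, int(gt_seed), video_id=vid)
        pred = corrupt_predictions(gt, noise, int(pr_seed))
        pairs.append(make_pair(gt, pred))
    return SimulationRun(seed=seed, workflow=workflow, noise=noise, pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures
# ---------------------------------------------------------------------------


def volatility_worked_example() -> SequencePair:
    """The canonical volatility example: 3 prediction changes / 2 truth changes.

    Ground truth visits P1, P2, P3 in order (runs of 8 frames); the
    prediction briefly falls back to P1 in the middle of P2, giving 3 class
    changes against the ground truth's 2 and hence volatility 3/2 = 1.5.
    """
    vocab = LabelVocabulary("phases", ["P1", "P2", "P3"])
    gt = sequence_from_runs(vocab, [(0, 8), (1, 8), (2, 8)], "worked-example")
    pred = sequence_from_runs(
        vocab, [(0, 8), (1, 5), (0, 3), (2, 8)], "worked-example"
    )
    return make_pair(gt, pred)


def flicker_worked_example() -> LabelSequence:
    """A two-class prediction track with 7 class changes.

    Run-length encoding: [(1,10),(2,2),(1,8),(2,2),(1,8),(2,2),(1,8),(2,20)]
    — every non-terminal class-2 run is 2 frames (a flicker), every class-1
    run is at least 8 frames, and the terminal class-2 run is long.  Both the
    window-5 modal and threshold smoothers collapse the track to a single
    class change at the terminal transition.
    """
    vocab = LabelVocabulary("classes", ["class1", "class2"])
    runs = [(0, 10), (1, 2), (0, 8), (1, 2), (0, 8), (1, 2), (0, 8), (1, 20)]
    return sequence_from_runs(vocab, runs, "flicker-example")
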