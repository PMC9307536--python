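"""Frame-wise label sequences and their CSV/JSON interchange formats.

A surgical workflow annotation is a label per video frame sampled at 1 Hz:
the coarse task uses 3 phases, the fine task 7 steps.  Ground truth and
classifier predictions share the same representation, so every downstream
operation (smoothing, decoding, evaluation) consumes :class:`LabelSequence`
or :class:`SequencePair` and never sees raw files.

The on-disk format is deliberately minimal and self-describing:

* sequence CSV — header ``frame,label``; ``frame`` is 0-based and contiguous
  (one row per second); ``label`` is the class *name*, not its index.
* vocabulary JSON — a list of class names in index order, e.g.
  ``["P1", "P2", "P3"]``.  Index order matters (it defines class adjacency
  for the neighbour-confusion noise model), so it is supplied explicitly
  rather than inferred from files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError, VocabularyError

_LABEL_RE = re.compile(r"^[A-Za-z0-9_-]+$")


@dataclass(frozen=True)
class LabelVocabulary:
    """An ordered class vocabulary for one labelling task.

    Parameters
    ----------
    task_name:
        Short identifier for the task, e.g. ``"phases"`` or ``"steps"``.
    labels:
        Class names in index order; index ``i`` maps bijectively to
        ``labels[i]``.
    """

    task_name: str
    labels: tuple[str, ...]

    def __init__(self, task_name: str, labels: Sequence[str]):
        object.__setattr__(self, "task_name", str(task_name))
        object.__setattr__(self, "labels", tuple(str(x) for x in labels))
        if len(self.labels) == 0:
            raise VocabularyError("vocabulary must contain at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise VocabularyError("vocabulary labels must be unique")
        for lab in self.labels:
            if not _LABEL_RE.match(lab):
                raise VocabularyError(
                    f"label {lab!r} contains characters outside [A-Za-z0-9_-]"
                )

    @property
    def K(self) -> int:
        """Number of classes."""
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise VocabularyError(
                f"label {label!r} not in vocabulary {list(self.labels)}"
            ) from None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.labels)


@dataclass
class LabelSequence:
    """A per-video, 1 Hz sequence of class indices over a fixed vocabulary."""

    video_id: str
    vocabulary: LabelVocabulary
    frames: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        if frames.ndim != 1 or frames.size < 1:
            raise FormatError("a label sequence must contain at least one frame")
        if frames.min() < 0 or frames.max() >= self.vocabulary.K:
            bad = frames[(frames < 0) | (frames >= self.vocabulary.K)][0]
            raise VocabularyError(
                f"class index {int(bad)} outside [0, {self.vocabulary.K - 1}]"
            )
        self.frames = frames

    def __len__(self) -> int:
        return int(self.frames.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelSequence):
            return NotImplemented
        return (
            self.video_id == other.video_id
            and self.vocabulary == other.vocabulary
            and np.array_equal(self.frames, other.frames)
        )

    def label_names(self) -> list[str]:
        """Frames rendered as class names."""
        labs = self.vocabulary.labels
        return [labs[i] for i in self.frames]

    def replace_frames(self, frames: np.ndarray) -> "LabelSequence":
        """A copy of this sequence carrying new frames (same id/vocabulary)."""
        return LabelSequence(self.video_id, self.vocabulary, np.asarray(frames))


@dataclass(frozen=True)
class SequencePair:
    """A ground-truth sequence paired with a prediction of the same video."""

    ground_truth: LabelSequence
    prediction: LabelSequence


def make_pair(gt: LabelSequence, pred: LabelSequence) -> SequencePair:
    """Pair a ground truth with a prediction, enforcing the pairing invariants.

    Raises
    ------
    PairingError
        If the lengths differ (the message states both lengths), the
        vocabularies differ, or the video ids differ.
    """
    if len(gt) != len(pred):
        raise PairingError(
            f"length mismatch: ground truth has {len(gt)} frames, "
            f"prediction has {len(pred)} frames"
        )
    if gt.vocabulary != pred.vocabulary:
        raise PairingError(
            f"vocabulary mismatch: {list(gt.vocabulary.labels)} vs "
            f"{list(pred.vocabulary.labels)}"
        )
    if gt.video_id != pred.video_id:
        raise PairingError(
            f"video id mismatch: {gt.video_id!r} vs {pred.video_id!r}"
        )
    return SequencePair(ground_truth=gt, prediction=pred)


def read_vocabulary(path: str | Path, task_name: str = "labels") -> LabelVocabulary:
    """Read a vocabulary from a JSON list of class names in index order."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise VocabularyError(f"{path}: vocabulary JSON must be a list of names")
    return LabelVocabulary(task_name, data)


def write_vocabulary(vocab: LabelVocabulary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(list(vocab.labels), fh)
        fh.write("\n")


def read_sequence(
    path: str | Path, vocabulary: LabelVocabulary, video_id: str | None = None
) -> LabelSequence:
    """Read a ``frame,label`` CSV into a :class:`LabelSequence`.

    The ``frame`` column must run 0,1,2,... without gaps or duplicates; every
    ``label`` must belong to *vocabulary*.  The first offending row is named
    in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != ["frame", "label"]:
        raise FormatError(
            f"{path}: expected header 'frame,label', found {list(df.columns)}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: sequence file contains no frames")
    try:
        frame_idx = df["frame"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer frame index ({exc})") from None
    expected = np.arange(len(df))
    if not np.array_equal(frame_idx, expected):
        row = int(np.nonzero(frame_idx != expected)[0][0])
        raise FormatError(
            f"{path}: non-contiguous frame index at row {row} "
            f"(found {frame_idx[row]}, expected {row})"
        )
    lut = {lab: i for i, lab in enumerate(vocabulary.labels)}
    frames = np.empty(len(df), dtype=np.int64)
    for row, lab in enumerate(df["label"].to_numpy()):
        try:
            frames[row] = lut[lab]
        except KeyError:
            raise VocabularyError(
                f"{path}: unknown label {lab!r} at row {row}; vocabulary is "
                f"{list(vocabulary.labels)}"
            ) from None
    vid = video_id if video_id is not None else path.stem
    return LabelSequence(video_id=vid, vocabulary=vocabulary, frames=frames)


def write_sequence(seq: LabelSequence, path: str | Path) -> None:
    """Write a sequence as a ``frame,label`` CSV (labels as names, LF endings)."""
    df = pd.DataFrame(
        {"frame": np.arange(len(seq)), "label": seq.label_names()}
    )
    df.to_csv(path, index=False, lineterminator="\n")
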