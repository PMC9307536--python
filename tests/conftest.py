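import numpy as np
import pytest

from wfsmooth import LabelSequence, LabelVocabulary, make_pair


@pytest.fixture
def vocab2():
    return LabelVocabulary("binary", ["A", "B"])


@pytest.fixture
def vocab3():
    return LabelVocabulary("phases", ["P1", "P2", "P3"])


@pytest.fixture
def vocab7():
    return LabelVocabulary("steps", [f"Step{i}" for i in range(1, 8)])


def seq(vocab, frames, video_id="v"):
    return LabelSequence(video_id, vocab, np.asarray(frames))


def random_sequence(rng, vocab, max_len=200, video_id="v"):
    length = int(rng.integers(1, max_len + 1))
    return seq(vocab, rng.integers(0, vocab.K, size=length), video_id)


def random_pair(rng, vocab, max_len=200):
    length = int(rng.integers(2, max_len + 1))
    gt = seq(vocab, rng.integers(0, vocab.K, size=length))
    pred = seq(vocab, rng.integers(0, vocab.K, size=length))
    return make_pair(gt, pred)
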