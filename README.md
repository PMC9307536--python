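# wfsmooth

Temporal smoothing and stability evaluation for frame-wise surgical
workflow predictions.

## The problem

Automated operative workflow recognition labels every frame of a surgical
video (at 1 Hz) with the current surgical phase or step. In small-working-
space surgery such as endoscopic pituitary surgery, frequent occlusions and
endoscope withdrawals produce short runs of uninformative frames, and
frame-wise classifiers respond with *volatile* predictions — the label
flickers between classes from one second to the next, which erodes clinical
trust even when overall accuracy is good. This package is for researchers
building such recognition pipelines: it provides the post-hoc stabilisation
and evaluation layer that sits downstream of any frame-wise classifier.

## What it implements

Given a prediction track `x_0, x_1, ...` (one class index per second):

- **Prediction volatility** — the stability metric
  `V = (# class changes in the prediction) / (# class changes in the ground truth)`.
  A perfectly stable, correctly timed prediction has `V = 1`; flickery
  output has `V ≫ 1`. Undefined (reported as `null`) when the ground truth
  never changes class.
- **Modal smoothing `M_n`** — output at frame `t ≥ n` is the mode of the
  current and previous `n` predictions (a window of `n+1` frames); the
  first `n` frames pass through; modal ties go to the most recently seen
  class.
- **Threshold smoothing `T_n`** — the output changes to class `c` only
  after `n+1` consecutive predictions of `c`; otherwise the previous output
  is held (hysteresis/debouncing). Consecutive output changes are therefore
  at least `n+1` frames apart.
- **Window tuning** — `n` is scanned over `[1, 60]` and the value
  maximising the training weighted-F1 is frozen, then applied to held-out
  videos.
- **Discrete HMM post-processing** — states are the true workflow classes,
  observations the predicted classes; `π`, the transition matrix `A` and
  the emission matrix `B` are estimated by Laplace counting on annotated
  training videos, and decoding at frame `t` reads the Viterbi-optimal path
  for the observation prefix up to `t + L` (lookahead `L = 5` frames by
  default, i.e. a 5 s online delay).
- **Evaluation** — per-class and support-weighted precision/recall/F1,
  mean-accuracy (macro-averaged per-class recall), a confusion matrix
  normalised over the *predicted* class (diagonal = precision,
  off-diagonals = false discovery rate), and mean ± std aggregation across
  cross-validation folds.
- **A workflow/noise simulator** — ordered multi-step workflows with skips,
  revisits and heavy-tailed (log-normal) step durations; neighbour-biased
  misclassification; and burst noise emulating occlusion. Everything is a
  pure function of (parameters, seed).

## Worked example

```bash
python examples/smooth_noisy_track.py
```

```
raw track:        7 class changes over 60 frames
modal M_5:        1 class change(s)
threshold T_5:    1 class change(s)

raw: 111111111122111111112211111111221111111122222222222222222222
M_5: 111111111111111111111111111111111111111111222222222222222222
T_5: 111111111111111111111111111111111111111111111222222222222222
```

The raw two-class track flickers to class 2 three times (runs of 2 frames)
before a genuine transition; both window-5 smoothers remove the flicker and
keep the real transition, reducing the change count from 7 to 1 — `T_5`
commits 5 frames after `M_5` because it waits for 6 consecutive identical
predictions. Similarly, `python examples/measure_volatility.py` prints
`prediction volatility: 1.5` for a track with 3 changes against a truth
with 2, and `python examples/benchmark_table.py` runs the full
simulate/tune/evaluate comparison:

```
method             weighted_f1   ...      volatility
raw              0.775 ± 0.013   ...  51.240 ± 5.605
modal            0.952 ± 0.009   ...   2.850 ± 0.508
threshold        0.957 ± 0.004   ...   1.542 ± 0.445
hmm              0.963 ± 0.009   ...   3.989 ± 0.952
```

i.e. on simulated noisy tracks, smoothing not only suppresses volatility by
an order of magnitude but also *raises* weighted-F1.

## Command line

```bash
wfsmooth simulate --config sim.yaml --seed 0 --n-videos 5 --out data/
wfsmooth tune     --method threshold --pairs data/ --vocab data/vocab.json --report tuning.json
wfsmooth smooth   --method threshold --window 5 --vocab data/vocab.json \
                  --input pred.csv --output smoothed.csv
wfsmooth fit-hmm  --pairs data/ --vocab data/vocab.json --out hmm.json
wfsmooth evaluate --truth gt.csv --pred smoothed.csv --vocab data/vocab.json --report report.json
wfsmooth benchmark --seed 0 --folds 5 --videos-per-fold 2 --report bench.json
```

Sequences are `frame,label` CSVs (0-based contiguous frame index, class
names); vocabularies are JSON lists of class names in index order. Every
command writes a provenance record (parameters, seed, input digests).

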