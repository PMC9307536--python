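# Methods

## Setting and data model

A workflow annotation is a function from video time (sampled at 1 Hz) to a
finite ordered vocabulary of classes — surgical phases (coarse, e.g. 3) or
steps (fine, e.g. 7). Ground truth and classifier output share this
representation (`LabelSequence`); evaluation always operates on a
`SequencePair` of equal length over one vocabulary. Frames are contiguous:
the package models no gaps, and sequences shorter than a smoothing window
are legal (they pass through unchanged). Class *index order* is meaningful:
adjacent indices are adjacent stages of the operation, which is what the
neighbour-confusion noise model and the "neighbouring class" reading of
confusion matrices rely on.

## Smoothing functions

Both smoothers are causal filters on the raw track `x` with window
parameter `n` counting *previous* frames, so the effective window is
`n + 1` frames; the first `n` frames always pass through unchanged.

**Modal `M_n`.** `y_t = mode(x_{t-n}, ..., x_t)` for `t ≥ n`. Ties are
resolved to the *most recent* tied class: among classes attaining the
maximal count, the one whose latest occurrence in the window is closest to
`t`. This reading is deterministic and makes `M_1` the identity (at a
change point the two-frame window ties and the newer class wins). The
implementation is O(T·K) via cumulative one-hot counts plus a running
last-occurrence index; a frame-by-frame recounting oracle in the test suite
checks it on a thousand random tracks.

**Threshold `T_n`.** `y_t = c` if `x_{t-n} = ... = x_t = c`, else
`y_t = y_{t-1}` — hysteresis on the *smoothed* stream, not the raw one.
Chaining on the previous output is what makes the filter hold a stable
class through arbitrary non-uniform noise; chaining on the raw prediction
would re-introduce flicker. Two consequences are tested as invariants:
the output never has more class changes than the input, and output change
points past the passthrough region are at least `n + 1` frames apart.
`T_n` also has a deterministic cost: after every genuine change point it
lags the truth by exactly `n` frames. Hence even a perfect prediction
scores slightly below F1 = 1 after threshold smoothing whenever the truth
has changes — the tuner then correctly prefers small `n` — and under
burst-only noise (bursts ≤ `n` frames, all events > `n` apart, clean first
`n` frames) `T_n` recovers the ground truth *exactly* outside those lag
windows (tested).

**Window tuning.** `n` is scanned over `[1, 60]` (1–60 s at 1 Hz) and the
value maximising the weighted-F1 on the training videos is selected, ties
to the smallest `n`. The default pools all training frames into a single
dataset-level score; per-video averaging is available
(`pooling="videos"`). Tuning is done per task and per fold.

## HMM post-processor

The true workflow state is modelled as a discrete Markov chain; the
classifier's predicted class is a categorical emission. Because annotated
training videos provide complete state sequences, estimation is supervised
counting with an additive pseudocount `alpha` (default 1.0, Laplace):
initial distribution from sequence starts, transitions from consecutive
ground-truth frames, emissions from (truth, prediction) frame pairs.
`alpha > 0` guarantees strictly positive rows, so decoding can never hit an
inadmissible observation. Rows with no observed events tend to the uniform
row in the small-`alpha` limit — the only defensible choice under additive
smoothing. Unsupervised (Baum–Welch) estimation is deliberately absent:
with labelled training sequences it is neither needed nor better
identified. A Gaussian-emission variant is also deliberately absent — the
observations here are categorical class indices, for which a categorical
emission model is the natural likelihood for both the coarse and the fine
task.

**Online decoding with lookahead.** The deployment setting is
intra-operative: the label at time `t` may use all past observations plus a
small fixed lookahead `L` (default 5 frames = 5 s at 1 Hz, configurable).
`output[t]` is the state at position `t` of the Viterbi-optimal path for
the prefix `x_0..x_{min(t+L, T-1)}`. Implementation: one forward Viterbi
pass over the whole stored sequence (log space; argmax ties toward the
lower state index for cross-platform determinism), then an `O(L)` backtrack
per frame — `O(T·K² + T·L)` total. With `L ≥ T` this is exactly
full-sequence Viterbi; the tests verify that against exhaustive enumeration
of all `K^T` paths (small instances; score equality is asserted, since
distinct paths can tie exactly) and against an independent library decoder
on long sequences. Note that unlike `M_n`/`T_n`, the decoder's output at a
given frame can change as the lookahead window slides; causality up to `L`
is tested by suffix mutation.

## Evaluation protocol

Per-class precision, recall and F1 are computed with support = ground-truth
frame count; weighted metrics are support-weighted means over classes
present in the ground truth (classes predicted but absent from the truth
appear with zero support and are excluded from the weighted means).
Weighted recall is algebraically the overall frame accuracy (asserted
numerically in the tests). *Mean-accuracy* is reported alongside as the
macro-average of per-class recall over classes present in the truth — the
package's reading of a term the literature often leaves undefined; it is
distinct from weighted recall exactly when classes are imbalanced.

The confusion matrix is normalised over the predicted class and expressed
in percentages: cell `[o, s]` is the share of frames predicted `o` whose
truth is `s`, so the diagonal is precision and the off-diagonals the false
discovery rate. Rows for never-predicted classes are all zero rather than
undefined. Serialised reports round to 1 decimal place.

**Volatility** divides prediction change count by ground-truth change
count. A zero denominator (single-class video) yields an undefined marker
(`None`/`null`), never infinity or a silent zero; such videos are logged
and excluded from aggregation. Fold-level volatility is the mean over
videos with defined volatility; cross-fold aggregation reports the
arithmetic mean and *population* standard deviation (ddof = 0; the
convention is trivially switchable and documented here because reported ±
values depend on it).

## Synthetic data

The simulator is structural, not fitted: it reproduces the qualitative
features of operative workflow data — ordered stages with occasional skips
and brief revisits, heavy-tailed stage durations, neighbour-biased
misclassification, and occlusion bursts — without matching any particular
dataset's quantiles.

- **Ground truth.** Classes are visited in canonical order; each is skipped
  independently with `skip_prob` (default 0.05); after each later visit the
  previous class is briefly revisited with `revisit_prob` (default 0.05).
  Per-visit durations are log-normal, default median 600 s
  (`duration_log_mean = ln 600`, `duration_log_sd = 0.5`), rounded to whole
  seconds with a 1 s floor. If every class is skipped, the draw retries
  with one uniformly chosen class forced on (logged). The permitted-
  transition grammar (skip + single-step revisit) is an approximation of
  real sequence variation graphs, which are richer.
- **Frame noise.** Each frame's prediction is drawn from the confusion row
  of its true class. `neighbor_confusion(K, diag, neighbor_mass)` builds
  rows with `diag` on the true class (default 0.85) and the remainder split
  over the adjacent classes — the structure real confusion matrices show
  when adjacent stages share instruments and anatomy.
- **Burst noise.** When no burst is active, one starts per frame with
  probability `burst_start_prob`; lengths are uniform on
  `[burst_len_min, burst_len_max]`; labels are per-frame uniform over wrong
  classes (occluded frames could look like anything) or one fixed wrong
  class per burst.

What passing tests on this generator do *not* show: real classifier errors
are temporally correlated beyond bursts, confusion is not symmetric or
stationary across a procedure, and real step-duration distributions are
heavier-tailed and class-specific. Results on synthetic data demonstrate
the machinery's correctness and the qualitative benefit of smoothing, not
clinical performance.

## Benchmark

`run_benchmark` simulates `folds × videos_per_fold` videos, holds out each
fold in turn, tunes `n` (both smoothers) and fits the HMM on the remaining
videos, and reports mean ± std across folds for raw, modal, threshold and
HMM post-processing. The *standard scenario* defaults are: 7 steps,
confusion diagonal 0.85 with the remaining mass on neighbours, bursts
starting with probability 0.02 and lasting 2–8 frames (≈ 10% of frames in
bursts), skip/revisit probability 0.05. For benchmark runs the step-
duration median is 120 s (vs the generator default of 600 s): tuned
comparisons repeated over many seeds are about workflow *structure*, which
is duration-scale-free for all methods here, so the shorter median is a
problem-size choice that keeps multi-seed suites fast. The acceptance suite
repeats the scenario over 20 seeds (2 folds × 2 videos, median 60 s) and
checks the orderings: mean volatility `threshold ≤ modal < raw`, and mean
weighted-F1 of both smoothers ≥ raw.

## Numerical and design choices

- Viterbi in log space; `log 0 = -inf` is tolerated until an entire frame
  is inadmissible, which raises a decoding error.
- Argmax ties (Viterbi) break to the lower state index; modal ties to the
  most recent class; tuning ties to the smallest window. All outputs are
  deterministic functions of inputs and seeds; batch generation spawns
  per-video child seeds from a `SeedSequence`, so runs are bit-reproducible.
- Degenerate inputs: single-frame sequences are valid everywhere;
  sequences shorter than the window pass through; empty training sets are
  errors, never silent defaults.
- CSV interchange stores class *names* (self-describing files), with the
  index order supplied separately as a JSON vocabulary, because index order
  carries the adjacency structure.

## Known limitations

- The online HMM decoder recomputes an `O(L)` backtrack per frame on stored
  sequences; it honours the causal contract but is not a streaming
  implementation.
- Segment-level metrics (segmental edit distance, F1@k) are out of scope;
  all scores are frame-wise.
- The simulator's skip/revisit grammar and stationary confusion are
  simplifications (see above); no attempt is made to fit real duration or
  confusion statistics.
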