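"""Run the cross-validated smoothing benchmark on simulated data.

Simulates a pool of 7-step videos, and per fold tunes the smoothing windows
and fits the HMM on the training videos before evaluating on the held-out
videos.  Prints the mean +/- std table across folds.
"""

from wfsmooth import BenchmarkConfig, run_benchmark

config = BenchmarkConfig(folds=3, videos_per_fold=2)
report = run_benchmark(config, seed=0)

print(report.to_text())
print()
print(f"tuned windows per fold: {report.best_windows}")
print()
print("Reading the table: both smoothers raise weighted-F1 over the raw")
print("track while cutting volatility by an order of magnitude; the")
print("threshold smoother is the stabler of the two because it only changes")
print("class after n+1 consecutive identical predictions.")
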