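"""Compute prediction volatility and the frame-wise evaluation report.

Uses the canonical worked example: a 3-phase ground truth with 2 class
changes and a prediction that briefly falls back to phase 1, giving 3.
"""

from wfsmooth import count_changes, evaluate, volatility_worked_example

pair = volatility_worked_example()
report = evaluate(pair)

print(f"ground-truth changes: {count_changes(pair.ground_truth)}")
print(f"prediction changes:   {count_changes(pair.prediction)}")
print(f"prediction volatility: {report.volatility}")
print(f"weighted-F1: {report.weighted_f1:.3f}")
print("confusion (% of frames predicted as each class, by true class):")
for label, row in zip(report.labels, report.confusion):
    cells = " ".join(f"{v:5.1f}" for v in row)
    print(f"  pred {label}: {cells}")
print()
print("Volatility 1.5 means the prediction changes class 1.5x as often as")
print("the ground truth; the confusion diagonal is each class's precision.")
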