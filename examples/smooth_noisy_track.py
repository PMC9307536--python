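"""Smooth a flickery prediction track with the modal and threshold filters.

Builds the canonical two-class flicker example (short spurious runs of
class2 inside long class1 runs, then a genuine transition) and applies the
window-5 modal filter M_5 and threshold filter T_5.
"""

from wfsmooth import (
    count_changes,
    flicker_worked_example,
    modal_smooth,
    threshold_smooth,
)

track = flicker_worked_example()
m5 = modal_smooth(track, 5)
t5 = threshold_smooth(track, 5)

print(f"raw track:        {count_changes(track)} class changes over {len(track)} frames")
print(f"modal M_5:        {count_changes(m5)} class change(s)")
print(f"threshold T_5:    {count_changes(t5)} class change(s)")
print()
print("raw:", "".join(str(v + 1) for v in track.frames))
print("M_5:", "".join(str(v + 1) for v in m5.frames))
print("T_5:", "".join(str(v + 1) for v in t5.frames))
print()
print("Both smoothers collapse the 7-change flicker to the single genuine")
print("transition; T_5 commits 5 frames later than M_5 because it waits for")
print("6 consecutive identical predictions.")
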