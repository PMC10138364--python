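"""Detect a slow-down in movement habits from three days of activity.

Active hours are walking + sitting + standing.  Two consecutive
day-over-day drops of at least kth = 12.5% flag "slowed down"; two
consecutive rises of at least kth flag "increased".
"""

from gericare.habits import classify_movement_change, percent_diff

# Daily active hours, most recent day first: 3 h, then 5 h, then 7 h.
acth = (3.0, 5.0, 7.0)
verdict = classify_movement_change(acth, kth=12.5)

print(f"active hours (m-1, m-2, m-3): {acth}")
print(f"day-over-day changes: {verdict.diffs[0]:.1f}% and {verdict.diffs[1]:.1f}%")
print(f"verdict: {verdict.value.value}")
print()
print(f"sanity: percent_diff(3, 5) = {percent_diff(3.0, 5.0):.1f}%")
print("Both drops exceed the 12.5% threshold, so the patient's movement "
      "habit is flagged as slowed down; this value feeds the MoveH field "
      "of the care-plan state.")
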