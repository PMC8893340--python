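"""Circular geometry of a single advice-taking trial.

A participant estimates a target location on the circle, sees the
partner's estimate, and revises.  The revision statistic is the
fraction of the angular gap between the two initial estimates that the
revised estimate closes.
"""

from conformity import arc_distance, move_toward, shift_fraction

self_initial = 350.0  # participant's first estimate (degrees)
partner_initial = 40.0  # partner's first estimate

gap = arc_distance(self_initial, partner_initial)
print(f"initial disagreement: {gap:.1f} degrees (shorter arc, wrap-aware)")

revised = move_toward(self_initial, partner_initial, 0.3)
print(f"revising 30% of the way: {self_initial:.0f} -> {revised:.0f} degrees")

revision = shift_fraction(self_initial, revised, partner_initial)
print(f"recomputed revision statistic: {revision:.2f}")
print("0 = kept own estimate, 1 = fully adopted the partner's estimate;")
print("the same statistic computed for the partner's revision is 'influence'.")
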