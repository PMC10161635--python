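"""The 5x5 dose grid and the SOFA/lactate reward on worked examples.

Prints the dosing level for a few IV/VP rates and the reward earned by
typical clinical transitions: unchanged SOFA costs a small penalty,
rising SOFA and lactate cost more, and survival to discharge adds +15 at
the final transition.
"""

from sepsisrl import action_index, discretize_iv, discretize_vp, reward

print("dose discretization:")
for rate in (0, 25, 100, 600):
    print(f"  IV {rate:>4} ml/h        -> level {discretize_iv(rate)}")
for rate in (0.0, 0.05, 0.30, 0.50):
    print(f"  VP {rate:>5} ug/kg/min  -> level {discretize_vp(rate)}")
print(f"  joint action (iv=2, vp=1) -> index {action_index(2, 1)} of 25")

print("\nreward examples (SOFA prev->next, lactate prev->next):")
cases = [
    ("stable SOFA 5->5, lactate 2->2", dict(prev_sofa=5, prev_lactate=2.0, next_sofa=5, next_lactate=2.0)),
    ("SOFA worsens 5->6            ", dict(prev_sofa=5, prev_lactate=2.0, next_sofa=6, next_lactate=2.0)),
    ("SOFA improves 6->5           ", dict(prev_sofa=6, prev_lactate=2.0, next_sofa=5, next_lactate=2.0)),
    ("lactate spikes 2->6          ", dict(prev_sofa=5, prev_lactate=2.0, next_sofa=5, next_lactate=6.0)),
]
for label, kw in cases:
    print(f"  {label} -> r = {reward(**kw):+.4f}")
print(
    "  terminal, survived           -> r = "
    f"{reward(5, 2.0, 5, 2.0, terminal=True, survived=True):+.4f}"
)
# Negative rewards mark deterioration; the +-15 terminal adjustment
# dominates everything else, which is why replay weights it heavily.
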