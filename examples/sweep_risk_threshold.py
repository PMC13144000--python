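"""Locate the social-efficiency risk threshold by parameter sweep.

Sweeps the lifetime melanoma risk p and finds where B+E crosses C, i.e.
where sunscreen use becomes socially efficient.  The bisection estimate is
compared with the closed form p_social = C / ((1-RR) K).
"""

import numpy as np

from sungame import bundled_scenario_path, load_scenario, risk_thresholds, sweep_parameter

config = load_scenario(bundled_scenario_path())
res = sweep_parameter(config.economic, "p", np.linspace(0.05, 0.35, 31))

closed = risk_thresholds(config.economic)
for b in res.boundaries:
    print(f"{b.comparison} boundary at p = {b.value:.6f}")
print(f"closed form p_social = C/((1-RR)K) = {closed.p_social:.6f}  (rounds to {closed.p_social:.2f})")
print(f"closed form p_private = {closed.p_private:.4f}  reachable: {closed.p_private_reachable}")
print(
    "\nBelow p ~ 0.249 non-adoption is also socially efficient; above it the "
    "free-rider problem appears.  No attainable risk makes adoption privately "
    "rational at theta = 0.2 (p_private > 1)."
)
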