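"""Integrate the replicator dynamics for the Australian average-risk scenario.

Starting from a 50/50 population, the cooperator share decays toward zero
because the private payoff gap B - C is about -10,205 AUD.  The numerical
integrator is cross-checked against the exact logistic solution.
"""

import numpy as np

from sungame import (
    PayoffParameters,
    closed_form_trajectory,
    derive_quantities,
    integrate_replicator,
    bundled_scenario_path,
    load_scenario,
)

config = load_scenario(bundled_scenario_path())
d = derive_quantities(config.economic)
params = PayoffParameters(benefit=d.b_private, cost=d.c_lifetime, externality=d.e_external)
print(f"selection coefficient B - C = {params.selection_coefficient:+.2f} AUD")

times = np.linspace(0.0, 0.002, 9)  # the gap is ~1e4, so decay is fast in model time
num = integrate_replicator(params.payoff_difference(), 0.5, times)
exact = closed_form_trajectory(params, 0.5, times)

for t, xn, xe in zip(times, num.states, exact.states):
    print(f"t = {t:8.5f}   x_numeric = {xn:.6f}   x_exact = {xe:.6f}")
print(f"max |numeric - exact| = {np.max(np.abs(num.states - exact.states)):.2e}")
print("\nThe cooperator share collapses toward 0: free-riding is the stable outcome.")
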