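"""Show the minimum-subsidy threshold flipping the stable equilibrium.

At the Australian average risk the private benefit of sunscreen use (585
AUD) falls far short of its lifetime cost (10,790 AUD), so s* = 10,205 AUD.
A subsidy one dollar above s* turns full adoption into the globally stable
state; exactly at s* the dynamics are neutral.
"""

from sungame import PayoffParameters, apply_subsidy, find_equilibria, min_subsidy

base = PayoffParameters(benefit=585, cost=10790, externality=2339)
s_star = min_subsidy(base.benefit, base.cost)
print(f"minimum subsidy s* = C - B = {s_star:.0f} AUD")

for s in (0, s_star, s_star + 1):
    rep = find_equilibria(apply_subsidy(base, s).payoff_difference())
    labels = ", ".join(f"x*={eq.x:g} ({eq.stability})" for eq in rep.equilibria)
    print(f"s = {s:>6.0f}: regime = {rep.regime:<12} {labels}")

print(
    "\nBelow s* the population settles at zero adoption; strictly above s* "
    "it settles at full adoption — the subsidy must exceed the gap, not just meet it."
)
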