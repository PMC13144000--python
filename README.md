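# sungame

An evolutionary game model of sunscreen adoption under shared healthcare
financing, with an Australian health-economic calibration, policy subsidy
analysis, and an aggregate treatment-burden estimator.

## The problem

Regular sunscreen use roughly halves melanoma risk, yet adoption stays low
even in high-UV countries. When treatment is publicly financed, non-users
shift part of their expected treatment cost onto everyone else — a
free-rider problem. This package models that tension quantitatively: for
whom is sunscreen use privately rational, for whom is it only *socially*
efficient, and how large a subsidy closes the gap?

It is a library for health economists and modellers, importable from Python
(see `examples/`) with a thin `sungame` CLI on top.

## The model

A population splits between cooperators (sunscreen users, share `x`) and
defectors. With private benefit `B`, private cost `C`, per-defector
externality `E` and subsidy `s`, expected payoffs are

```
π_C = B − (C − s) − E(1 − x)        π_D = −E(1 − x)
```

and the replicator equation reduces to the logistic form

```
dx/dt = x(1 − x)(B − C + s)
```

The externality cancels: both strategies bear it equally, so selection is
driven by private incentives alone. `x = 0` and `x = 1` are the only
equilibria, and which is stable depends only on the sign of `B − C + s`.
Hence the sharp divergence between *evolutionary stability* (`B − C`) and
*social optimality* (`B + E − C`), and the minimum effective subsidy
`s* = max(0, C − B)`. Frequency-dependent extensions (social norms, peer
effects) plug in as an arbitrary payoff-difference function `g(x)`, for
which the solver finds interior equilibria and tipping points.

The calibration maps economic inputs to game payoffs:

```
C     = (price / volume) × mL/day × days/year × years      lifetime sunscreen cost
K     = K_med + V × ΔQALY                                  monetized loss per case
B + E = p (1 − RR) K                                       prevention benefit
B     = θ (B + E),   E = (1 − θ)(B + E)                    private / external split
```

## Worked example

```
$ python examples/calibrate_australia.py
     p  total_benefit_aud  private_benefit_aud  external_benefit_aud  lifetime_cost_aud                   regime  min_subsidy_aud
0.0674               2925                  585                  2340              10790   efficient_non_adoption            10205
0.2000               8679                 1736                  6943              10790   efficient_non_adoption             9054
0.2500              10849                 2170                  8679              10790 inefficient_non_adoption             8620
0.3000              13018                 2604                 10415              10790 inefficient_non_adoption             8186
```

Reading the table: at the Australian average lifetime risk (p = 0.0674) the
total prevention benefit (2,925 AUD) is below the lifetime sunscreen cost
(10,790 AUD) — non-adoption is efficient. From p ≈ 0.25 upward `B+E > C`
while `B < C` still holds, so adoption would be socially efficient but the
population nevertheless converges to zero use; restoring adoption takes a
subsidy above the `min_subsidy_aud` column (e.g. 8,620 AUD at p = 0.25).

```
$ python examples/subsidy_flip.py
minimum subsidy s* = C - B = 10205 AUD
s =      0: regime = free_riding  x*=0 (stable), x*=1 (unstable)
s =  10205: regime = neutral      x*=0 (neutral), x*=1 (neutral)
s =  10206: regime = adoption     x*=0 (unstable), x*=1 (stable)
```

The other example scripts cover the replicator dynamics against the exact
logistic solution (`simulate_adoption_dynamics.py`), the risk threshold
where the free-rider problem first appears (`sweep_risk_threshold.py`,
p ≈ 0.2487), and the cohort burden estimate (`burden_estimate.py`, ~16.4
billion AUD ≈ 11.6 billion USD for the high-risk 60+ cohort).

The same analyses run from the shell:

```
sungame report --out out/           # full pipeline on the bundled scenario
sungame calibrate --risks 0.25      # one table row
sungame sweep --parameter p --start 0.05 --stop 0.35
```

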