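"""Two-strategy evolutionary game of preventive-behavior adoption.

The population is split between *cooperators* (regular sunscreen users) and
*defectors* (non-users).  Cooperation carries a private benefit ``B`` (reduced
melanoma risk) and a private cost ``C`` (money and time spent on sunscreen);
every defector imposes an external cost ``E`` on others through publicly
shared treatment financing.  A subsidy ``s`` reduces the cooperator's
effective cost to ``C - s``.

With ``x`` the cooperator share, the expected payoffs are

    pi_C = B - (C - s) - E (1 - x)
    pi_D = -E (1 - x)

and the replicator equation reduces to the logistic form

    dx/dt = x (1 - x) (B - C + s).

The externality ``E`` hits both strategies identically, so it cancels from
the dynamics: selection is driven by private incentives alone.  Extensions
where the payoff difference depends on the population state (social norms,
peer effects) are supported through an arbitrary payoff-difference function
``g(x)``, with dynamics ``dx/dt = x (1 - x) g(x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "PayoffParameters",
    "PairwisePayoffMatrix",
    "ExpectedPayoffs",
    "Trajectory",
    "Equilibrium",
    "EquilibriumReport",
    "PayoffDifferenceFunction",
    "constant_difference",
    "build_payoff_matrix",
    "expected_payoffs",
    "replicator_rate",
    "closed_form_trajectory",
    "integrate_replicator",
    "find_equilibria",
    "phase_portrait",
]

#: A payoff-difference function g(x) = pi_C(x) - pi_D(x) on [0, 1].
PayoffDifferenceFunction = Callable[[float], float]


def _check_share(x: float, name: str = "x") -> float:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return float(x)


@dataclass(frozen=True)
class PayoffParameters:
    """Economic primitives of the game, in currency units (AUD).

    Parameters
    ----------
    benefit :
        Private benefit ``B`` of cooperation (risk reduction, monetized).
    cost :
        Private cost ``C`` of cooperation over the relevant horizon.
    externality :
        External cost ``E`` each defector imposes via shared financing.
    subsidy :
        Subsidy ``s`` reducing the cooperator's effective cost to ``C - s``.
    """

    benefit: float
    cost: float
    externality: float
    subsidy: float = 0.0

    def __post_init__(self) -> None:
        for name in ("benefit", "cost", "externality", "subsidy"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    @property
    def effective_cost(self) -> float:
        """Cooperator cost net of subsidy, ``C - s``."""
        return self.cost - self.subsidy

    @property
    def selection_coefficient(self) -> float:
        """The replicator coefficient ``k = B - C + s``.

        Its sign alone determines which boundary equilibrium is stable.
        Computed as ``B - (C - s)`` so that a subsidy is bit-for-bit
        equivalent to the same reduction in cost.
        """
        return self.benefit - self.effective_cost

    def payoff_difference(self) -> PayoffDifferenceFunction:
        """The baseline (constant) payoff difference ``g(x) = B - C + s``."""
        return constant_difference(self.selection_coefficient)


def constant_difference(k: float) -> PayoffDifferenceFunction:
    """Constant payoff-difference function ``g(x) = k``."""

    def g(x: float) -> float:
        return k

    return g


@dataclass(frozen=True)
class PairwisePayoffMatrix:
    """Pairwise payoffs (row player, column player) for each strategy pair.

    The game is symmetric: ``cd`` is the transpose pair of ``dc``.
    """

    cc: tuple[float, float]
    cd: tuple[float, float]
    dc: tuple[float, float]
    dd: tuple[float, float]


def build_payoff_matrix(params: PayoffParameters) -> PairwisePayoffMatrix:
    """Pairwise payoff matrix with the subsidy folded into the effective cost.

    Mutual cooperation yields ``B - C'`` to each (``C' = C - s``); a lone
    cooperator additionally bears the defector's externality, giving
    ``B - C' - E`` against the defector's 0; mutual defection costs each
    player ``E`` through shared treatment financing.
    """
    b, e = params.benefit, params.externality
    c = params.effective_cost
    return PairwisePayoffMatrix(
        cc=(b - c, b - c),
        cd=(b - c - e, 0.0),
        dc=(0.0, b - c - e),
        dd=(-e, -e),
    )


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Population-level expected payoffs at a given cooperator share."""

    pi_cooperator: float
    pi_defector: float
    pi_average: float


def expected_payoffs(params: PayoffParameters, x: float) -> ExpectedPayoffs:
    """Expected payoffs ``pi_C``, ``pi_D`` and the population average at share ``x``."""
    x = _check_share(x)
    b, e = params.benefit, params.externality
    c = params.effective_cost
    pi_c = b - c - e * (1.0 - x)
    pi_d = -e * (1.0 - x)
    pi_bar = x * pi_c + (1.0 - x) * pi_d
    return ExpectedPayoffs(pi_cooperator=pi_c, pi_defector=pi_d, pi_average=pi_bar)


def replicator_rate(g: PayoffDifferenceFunction, x: float) -> float:
    """Instantaneous growth rate of the cooperator share, ``x (1 - x) g(x)``."""
    x = _check_share(x)
    return x * (1.0 - x) * float(g(x))


@dataclass(frozen=True)
class Trajectory:
    """A cooperator-share path ``x(t)`` on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or x.shape != t.shape:
            raise ValueError("times and states must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("states must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)

    def to_frame(self):
        """Two-column DataFrame (t, x)."""
        import pandas as pd

        return pd.DataFrame({"t": self.times, "x": self.states})


def closed_form_trajectory(
    params: PayoffParameters, x0: float, times: Sequence[float]
) -> Trajectory:
    """Exact logistic solution of the constant-coefficient replicator equation.

    With ``k = B - C + s`` the solution is
    ``x(t) = x0 e^{kt} / (1 - x0 + x0 e^{kt})``, evaluated here as
    ``expit(logit(x0) + k t)`` so that arbitrarily large ``k t`` saturates to
    the correct boundary instead of overflowing.
    """
    x0 = _check_share(x0, "x0")
    t = np.asarray(times, dtype=float)
    if x0 == 0.0 or x0 == 1.0:
        return Trajectory(times=t, states=np.full_like(t, x0))
    k = params.selection_coefficient
    states = expit(logit(x0) + k * t)
    return Trajectory(times=t, states=np.clip(states, 0.0, 1.0))


def integrate_replicator(
    g: PayoffDifferenceFunction,
    x0: float,
    times: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Numerically integrate ``dx/dt = x (1 - x) g(x)`` on the given time grid.

    The integration is carried out in internally rescaled time ``tau = M t``
    with ``M = max |g|`` on a probe grid, so that calibrated payoff gaps of
    order 1e4 currency units integrate as accurately as O(1) ones.  States
    are clipped to [0, 1] to absorb floating-point drift at the absorbing
    boundaries.

    Raises
    ------
    RuntimeError
        If the ODE solver fails to converge.
    """
    x0 = _check_share(x0, "x0")
    t = np.asarray(times, dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if x0 == 0.0 or x0 == 1.0:
        return Trajectory(times=t, states=np.full_like(t, x0))

    probe = np.linspace(0.0, 1.0, 257)
    scale = max(float(np.max(np.abs([g(xi) for xi in probe]))), 0.0)
    if scale == 0.0:
        return Trajectory(times=t, states=np.full_like(t, x0))

    def rhs(tau: float, y: np.ndarray) -> np.ndarray:
        x = min(max(y[0], 0.0), 1.0)
        return np.array([x * (1.0 - x) * g(x) / scale])

    tau = t * scale
    sol = solve_ivp(
        rhs,
        (tau[0], tau[-1]),
        [x0],
        t_eval=tau,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    return Trajectory(times=t, states=np.clip(sol.y[0], 0.0, 1.0))


@dataclass(frozen=True)
class Equilibrium:
    """A rest point of the dynamics with its stability label."""

    x: float
    stability: str  # "stable" | "unstable" | "neutral"


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibria, stability, and the selection regime.

    ``regime`` is one of ``adoption`` (k > 0: full adoption globally stable),
    ``free_riding`` (k < 0: non-adoption globally stable), ``neutral``
    (g vanishes identically; every state is a rest point, ``continuum`` set),
    or ``frequency_dependent`` (interior equilibria exist).
    """

    equilibria: tuple[Equilibrium, ...]
    regime: str
    continuum: bool = False

    def stability_of(self, x: float, tol: float = 1e-6) -> str | None:
        for eq in self.equilibria:
            if abs(eq.x - x) <= tol:
                return eq.stability
        return None


def _stability_label(g: PayoffDifferenceFunction, x: float, eps: float = 1e-6) -> str:
    """Stability from the flow direction on either side of a rest point.

    Interior flow direction is sign(g) since x(1-x) > 0 there.
    """
    gl = g(max(x - eps, eps / 2)) if x > 0 else None
    gr = g(min(x + eps, 1 - eps / 2)) if x < 1 else None
    inflow_left = gl is not None and gl > 0
    inflow_right = gr is not None and gr < 0
    outflow_left = gl is not None and gl < 0
    outflow_right = gr is not None and gr > 0
    if x <= 0.0:
        if gr is None or gr == 0:
            return "neutral"
        return "stable" if gr < 0 else "unstable"
    if x >= 1.0:
        if gl is None or gl == 0:
            return "neutral"
        return "stable" if gl > 0 else "unstable"
    if inflow_left and inflow_right:
        return "stable"
    if outflow_left or outflow_right:
        return "unstable"
    return "neutral"


def find_equilibria(
    g: PayoffDifferenceFunction,
    n_grid: int = 1025,
    root_tol: float = 1e-10,
    zero_tol: float = 1e-12,
) -> EquilibriumReport:
    """Locate all rest points of ``dx/dt = x (1 - x) g(x)`` and label stability.

    The boundaries 0 and 1 are always rest points.  Interior rest points are
    sign-change roots of ``g``, bracketed on a uniform grid and refined by
    bisection.  If ``g`` vanishes (within ``zero_tol``) on the whole grid the
    dynamics are neutral and every state is a rest point.
    """
    xs = np.linspace(0.0, 1.0, n_grid)
    gs = np.array([float(g(xi)) for xi in xs])

    if np.max(np.abs(gs)) <= zero_tol:
        eqs = (Equilibrium(0.0, "neutral"), Equilibrium(1.0, "neutral"))
        return EquilibriumReport(equilibria=eqs, regime="neutral", continuum=True)

    interior: list[float] = []
    for i in range(n_grid - 1):
        a, b = gs[i], gs[i + 1]
        if a == 0.0 and 0.0 < xs[i] < 1.0:
            interior.append(float(xs[i]))
        elif a * b < 0.0:
            root = brentq(g, xs[i], xs[i + 1], xtol=root_tol)
            if 0.0 < root < 1.0:
                interior.append(float(root))
    if gs[-1] == 0.0 and 0.0 < xs[-1] < 1.0:  # pragma: no cover - xs[-1] == 1
        interior.append(float(xs[-1]))

    # Deduplicate roots that collapsed to the same point.
    interior.sort()
    deduped: list[float] = []
    for r in interior:
        if not deduped or r - deduped[-1] > 10 * root_tol:
            deduped.append(r)

    points = [0.0] + deduped + [1.0]
    eqs = tuple(Equilibrium(p, _stability_label(g, p)) for p in points)

    if deduped:
        regime = "frequency_dependent"
    else:
        k = float(g(0.5))
        regime = "adoption" if k > 0 else ("free_riding" if k < 0 else "neutral")
    return EquilibriumReport(equilibria=eqs, regime=regime)


def phase_portrait(g: PayoffDifferenceFunction, n_grid: int = 201) -> np.ndarray:
    """Sampled phase line: array of (x, dx/dt) rows on a uniform grid in [0, 1].

    The endpoints always have zero rate (absorbing boundaries).
    """
    if n_grid < 3:
        raise ValueError("n_grid must be at least 3")
    xs = np.linspace(0.0, 1.0, n_grid)
    rates = np.array([replicator_rate(g, xi) for xi in xs])
    return np.column_stack([xs, rates])
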