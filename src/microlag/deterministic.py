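"""Transfer-free dynamics: ODE integration, phase-plane analysis, scenarios.

The three-compartment system is analysed pairwise, as in the classical
two-species competitive Lotka-Volterra phase plane: the relative position of
the nullcline intercepts (K1 versus r2/c2, K2 versus r1/c1) decides whether
the pair coexists, one species excludes the other, or the outcome is
bistable.  The full 3-D system is only ever integrated, never analytically
classified.

Scenarios describe the competitive standing of the introduced population
before and after microbiome acquisition:

* **A** — invaders coexist with natives pre-transfer (``Kn < ri/alpha_ni``
  and ``Ki < rn/alpha_in``); acquisition makes them superior.
* **B** — invaders decline pre-transfer, either through competition
  (``Kn > ri/alpha_ni`` and ``Ki < rn/alpha_in``) or intrinsically
  (``ri < 0``); acquisition rescues them.
* **C** — invaders exclude natives pre-transfer (``Ki > rn/alpha_in`` and
  ``Kn < ri/alpha_ni``) but at low density; acquisition lets them thrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    InitialCondition,
    IntegrationError,
    PopulationParams,
    extinction_threshold,
    rhs,
)
from .trajectory import Trajectory

__all__ = [
    "integrate",
    "Equilibrium",
    "equilibria",
    "ScenarioClass",
    "classify_scenario",
    "lv_regime",
    "PAIRS",
]

#: Supported two-compartment reductions (third compartment held at zero).
PAIRS = ("N-I0", "N-Im", "I0-Im")

RTOL = 1e-10
ATOL = 1e-12


def integrate(
    pop: PopulationParams,
    init: InitialCondition,
    t_end: float,
    dt_out: float = 0.1,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the transfer-free flow from ``init`` to ``t_end``.

    Uses stiff-capable adaptive integration (LSODA) at tight tolerances:
    trajectories of interest linger exponentially close to saddle points —
    that lingering *is* the invasion lag — and loose tolerances distort it.
    Small negative excursions from numerical error are clamped to zero.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    y0 = [init.N0, init.i0, init.Im0]
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    sol = solve_ivp(
        lambda t, y: rhs(y, pop),
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed at t={sol.t[-1]:g}: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    eps = extinction_threshold(pop)
    extinct = {
        name: bool(y[k, -1] < eps) for k, name in enumerate(("N", "I0", "Im"))
    }
    return Trajectory(times=sol.t, N=y[0], I0=y[1], Im=y[2], extinct=extinct)


# ---------------------------------------------------------------------------
# Two-species reductions


def _reduce(pop: PopulationParams, pair: str):
    """Return ((r1, K1, c1), (r2, K2, c2)) for a pair.

    ``c1`` is the per-capita effect of species 2 on species 1.  ``K`` is
    ``None`` for a compartment with ``ri < 0`` (pure exponential decline, no
    logistic branch).  For the I0-Im pair the shared invader total inside
    both logistic brackets makes the cross-competition coefficients r/K.
    """
    if pair == "N-I0":
        s1 = (pop.rn, pop.Kn, pop.alpha_in)
        s2 = (pop.ri, pop.Ki if pop.ri >= 0 else None, pop.alpha_ni)
    elif pair == "N-Im":
        s1 = (pop.rn, pop.Kn, pop.alpha_mn)
        s2 = (pop.rm, pop.Km, pop.alpha_nm)
    elif pair == "I0-Im":
        if pop.ri >= 0:
            s1 = (pop.ri, pop.Ki, pop.ri / pop.Ki)
        else:
            s1 = (pop.ri, None, 0.0)
        s2 = (pop.rm, pop.Km, pop.rm / pop.Km)
    else:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    return s1, s2


def _growth(r, K, u):
    return r * u * (1.0 - u / K) if K is not None else r * u


def _growth_prime(r, K, u):
    return r * (1.0 - 2.0 * u / K) if K is not None else r


def reduced_rhs(u, v, s1, s2):
    r1, K1, c1 = s1
    r2, K2, c2 = s2
    return (_growth(r1, K1, u) - c1 * u * v, _growth(r2, K2, v) - c2 * u * v)


def _jacobian(u, v, s1, s2):
    r1, K1, c1 = s1
    r2, K2, c2 = s2
    return np.array(
        [
            [_growth_prime(r1, K1, u) - c1 * v, -c1 * u],
            [-c2 * v, _growth_prime(r2, K2, v) - c2 * u],
        ]
    )


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of a two-compartment reduction.

    ``kind`` is one of extinction / native-only / invader-only /
    coexistence; ``stability`` is stable / unstable / saddle from the
    Jacobian eigenvalues.  ``degenerate`` flags a structurally unstable
    case (an eigenvalue's real part within ``tol`` of zero) whose label
    should not be trusted.
    """

    pair: str
    state: tuple[float, float]
    kind: str
    stability: str
    eigenvalues: tuple[complex, complex]
    degenerate: bool
    residual: float

    def to_record(self) -> dict:
        return {
            "pair": self.pair,
            "state": list(self.state),
            "kind": self.kind,
            "stability": self.stability,
            "eigenvalues_re": [float(np.real(e)) for e in self.eigenvalues],
            "eigenvalues_im": [float(np.imag(e)) for e in self.eigenvalues],
            "degenerate": self.degenerate,
            "residual": self.residual,
        }


def _kind(pair: str, u: float, v: float) -> str:
    n1, n2 = pair.split("-")
    if u == 0.0 and v == 0.0:
        return "extinction"
    if v == 0.0:
        return "native-only" if n1 == "N" else "invader-only"
    if u == 0.0:
        return "native-only" if n2 == "N" else "invader-only"
    return "coexistence"


def equilibria(
    pop: PopulationParams, pair: str = "N-I0", tol: float = 1e-8
) -> list[Equilibrium]:
    """All boundary equilibria of a reduction, plus any interior one.

    The interior (coexistence) equilibrium is returned only when it lies in
    the strictly positive quadrant.  Stability is classified linearly via
    the Jacobian; eigenvalues with |Re| < ``tol`` (rescaled by the faster
    growth rate) mark the equilibrium as degenerate rather than silently
    classifying it.
    """
    s1, s2 = _reduce(pop, pair)
    r1, K1, c1 = s1
    r2, K2, c2 = s2
    scale = max(abs(r1), abs(r2), 1e-12)
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    if K1 is not None:
        pts.append((K1, 0.0))
    if K2 is not None:
        pts.append((0.0, K2))
    # interior: per-capita growth balances competition in both species
    a = np.zeros((2, 2))
    b = np.zeros(2)
    a[0] = [r1 / K1 if K1 is not None else 0.0, c1]
    b[0] = r1
    a[1] = [c2, r2 / K2 if K2 is not None else 0.0]
    b[1] = r2
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) > 1e-14 * max(scale, 1.0) ** 2:
        u, v = np.linalg.solve(a, b)
        if u > tol and v > tol:
            pts.append((float(u), float(v)))
    out = []
    for u, v in pts:
        ev = np.linalg.eigvals(_jacobian(u, v, s1, s2))
        re = np.real(ev) / scale
        degenerate = bool(np.any(np.abs(re) < tol))
        if np.all(re < 0):
            stab = "stable"
        elif np.all(re > 0):
            stab = "unstable"
        else:
            stab = "saddle"
        du, dv = reduced_rhs(u, v, s1, s2)
        out.append(
            Equilibrium(
                pair=pair,
                state=(u, v),
                kind=_kind(pair, u, v),
                stability=stab,
                eigenvalues=(complex(ev[0]), complex(ev[1])),
                degenerate=degenerate,
                residual=float(math.hypot(du, dv)),
            )
        )
    return out


def lv_regime(s1, s2) -> str:
    """Competition outcome of a reduced pair from mutual invasibility.

    Species 2 invades species 1's monoculture iff ``r2 - c2*K1 > 0``
    (equivalently ``K1 < r2/c2``) and symmetrically for species 1.  Both
    invasible -> stable coexistence; one-sided -> exclusion; neither ->
    bistable (outcome depends on initial conditions and is never resolved
    to a single winner here).
    """
    r1, K1, c1 = s1
    r2, K2, c2 = s2
    if r2 <= 0:
        return "1-excludes-2"
    if r1 <= 0:
        return "2-excludes-1"
    inv2 = r2 - c2 * (K1 if K1 is not None else 0.0) > 0
    inv1 = r1 - c1 * (K2 if K2 is not None else 0.0) > 0
    if inv1 and inv2:
        return "coexistence"
    if inv1 and not inv2:
        return "1-excludes-2"
    if inv2 and not inv1:
        return "2-excludes-1"
    return "bistable"


_REGIME_NAMES = {
    "coexistence": "coexistence",
    "1-excludes-2": "N-excludes-I",
    "2-excludes-1": "I-excludes-N",
    "bistable": "bistable",
}


@dataclass(frozen=True)
class ScenarioClass:
    """Categorical outcome of the scenario inequalities."""

    label: str  # "A" | "B" | "C" | "other"
    pre_transfer_regime: str
    post_transfer_regime: str


def classify_scenario(
    pop_pre: PopulationParams, pop_post: PopulationParams | None = None
) -> ScenarioClass:
    """Assign a scenario label from the printed phase-plane inequalities.

    ``pop_pre`` supplies the N-vs-I0 (pre-acquisition) interaction and
    ``pop_post`` the N-vs-Im (post-acquisition) one; by default both are
    read from the same parameter object.  ``ri < 0`` is scenario B
    regardless of competition.  "other" covers the pre-transfer bistable
    regime and degenerate equalities, which the scenario taxonomy does not
    cover.
    """
    if pop_post is None:
        pop_post = pop_pre
    pre = _REGIME_NAMES[lv_regime(*_reduce(pop_pre, "N-I0"))]
    post = _REGIME_NAMES[lv_regime(*_reduce(pop_post, "N-Im"))]
    p = pop_pre
    if p.ri < 0:
        label = "B"
    else:
        kn_lt = p.Kn < (p.ri / p.alpha_ni if p.alpha_ni > 0 else math.inf)
        ki_lt = p.Ki < (p.rn / p.alpha_in if p.alpha_in > 0 else math.inf)
        if kn_lt and ki_lt:
            label = "A"
        elif (not kn_lt) and ki_lt:
            label = "B"
        elif (not ki_lt) and kn_lt:
            label = "C"
        else:
            label = "other"
    return ScenarioClass(label=label, pre_transfer_regime=pre, post_transfer_regime=post)
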