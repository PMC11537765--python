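"""Model parameters, state, and the competitive Lotka-Volterra vector field.

The model tracks three host compartments: a native population ``N`` and an
introduced population split into individuals without native microbes (``I0``)
and individuals that have acquired them (``Im``).  Each compartment grows
logistically toward its own carrying capacity and is depressed by
inter-specific competition; the two introduced subpopulations share the
invader total inside both logistic brackets.  Microbiome transfer itself is a
jump process handled by :mod:`microlag.stochastic`; the vector field here is
the transfer-free flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "PopulationParams",
    "TransferParams",
    "InitialCondition",
    "SystemState",
    "TransferEvent",
    "ValidationReport",
    "validate_params",
    "rhs",
    "extinction_threshold",
    "ConfigError",
    "RegimeError",
    "IntegrationError",
    "StabilityError",
]


class ConfigError(ValueError):
    """Invalid configuration: unknown key or malformed value."""


class RegimeError(ValueError):
    """A formula's parameter-regime precondition is violated."""


class IntegrationError(RuntimeError):
    """The ODE integrator could not meet its tolerances."""


class StabilityError(RuntimeError):
    """Explicit time-stepping stability (CFL-type) constraint violated."""


@dataclass(frozen=True)
class PopulationParams:
    """Growth, capacity and competition parameters of the three compartments.

    Rates are per unit time; carrying capacities are in individuals;
    competition coefficients ``alpha_wj`` give the per-capita depression of
    population ``j``'s growth by population ``w`` (per individual per time).
    ``ri`` may be negative: an introduced population intrinsically unable to
    attain positive growth then declines exponentially (its logistic bracket
    is dropped, see :func:`rhs`).
    """

    rn: float = 1.0
    ri: float = 0.5
    rm: float = 1.0
    Kn: float = 100.0
    Ki: float = 30.0
    Km: float = 150.0
    alpha_in: float = 0.01   # effect of I0 on N
    alpha_mn: float = 0.015  # effect of Im on N
    alpha_ni: float = 0.004  # effect of N on I0
    alpha_nm: float = 0.002  # effect of N on Im


@dataclass(frozen=True)
class TransferParams:
    """Density-dependent microbiome transfer rates.

    ``lambda_n`` mediates native -> I0 transfer (event rate lambda_n*N*I0),
    ``lambda_m`` mediates conspecific Im -> I0 transfer (rate
    lambda_m*Im*I0).  Zero disables a channel.
    """

    lambda_n: float = 1e-4
    lambda_m: float = 1e-4


@dataclass(frozen=True)
class InitialCondition:
    """Release configuration: natives at ``N0``, ``i0`` founders all in I0."""

    N0: float = 100.0
    i0: float = 10.0
    Im0: float = 0.0


@dataclass(frozen=True)
class SystemState:
    t: float
    N: float
    I0: float
    Im: float


@dataclass(frozen=True)
class TransferEvent:
    """One jump: ``count`` individuals moved I0 -> Im at time ``t``.

    ``channel`` is ``"native"`` (transfer from N) or ``"conspecific"``
    (transfer from Im).  Transfer conserves the introduced total I0+Im.
    """

    t: float
    channel: str
    count: int


@dataclass
class ValidationReport:
    ok: bool = True
    violations: list[str] = field(default_factory=list)

    def fail(self, name: str, message: str) -> None:
        self.ok = False
        self.violations.append(f"{name}: {message}")

    def __bool__(self) -> bool:
        return self.ok


def validate_params(
    pop: PopulationParams,
    tr: TransferParams | None = None,
    init: InitialCondition | None = None,
) -> ValidationReport:
    """Check parameter invariants; returns a report, never raises.

    Violated invariants are named by field so a caller (or the CLI) can point
    at the offending key.
    """
    rep = ValidationReport()
    for name in ("Kn", "Ki", "Km"):
        if not getattr(pop, name) > 0:
            rep.fail(name, "carrying capacity must be strictly positive")
    for name in ("alpha_in", "alpha_mn", "alpha_ni", "alpha_nm"):
        if getattr(pop, name) < 0:
            rep.fail(name, "competition coefficient must be >= 0")
    for name in ("rn", "rm"):
        if not getattr(pop, name) > 0:
            rep.fail(name, "growth rate must be > 0")
    # ri unrestricted in sign: negative models intrinsic decline.
    for name in ("rn", "ri", "rm", "Kn", "Ki", "Km",
                 "alpha_in", "alpha_mn", "alpha_ni", "alpha_nm"):
        if not math.isfinite(getattr(pop, name)):
            rep.fail(name, "must be finite")
    if tr is not None:
        for name in ("lambda_n", "lambda_m"):
            v = getattr(tr, name)
            if not (math.isfinite(v) and v >= 0):
                rep.fail(name, "transfer rate must be finite and >= 0")
    if init is not None:
        if not (math.isfinite(init.N0) and init.N0 >= 0):
            rep.fail("N0", "initial natives must be >= 0")
        if not (math.isfinite(init.i0) and init.i0 > 0):
            rep.fail("i0", "founder number must be > 0")
        if not (math.isfinite(init.Im0) and init.Im0 >= 0):
            rep.fail("Im0", "initial Im must be >= 0")
    return rep


def rhs(state, pop: PopulationParams):
    """Transfer-free rates of change (dN/dt, dI0/dt, dIm/dt).

    ``state`` is any (N, I0, Im) triple (a :class:`SystemState` or a
    sequence).  The jump terms are excluded; they are applied by the
    stochastic engine.  For ``ri < 0`` the I0 growth term is the pure
    exponential decline ``ri*I0`` (an intrinsically maladapted population
    has no positive logistic branch to saturate).
    """
    if isinstance(state, SystemState):
        N, I0, Im = state.N, state.I0, state.Im
    else:
        N, I0, Im = state
    dN = pop.rn * N * (1.0 - N / pop.Kn) - pop.alpha_in * N * I0 - pop.alpha_mn * N * Im
    if pop.ri >= 0:
        growth_i = pop.ri * I0 * (1.0 - (I0 + Im) / pop.Ki)
    else:
        growth_i = pop.ri * I0
    dI0 = growth_i - pop.alpha_ni * I0 * N
    dIm = pop.rm * Im * (1.0 - (Im + I0) / pop.Km) - pop.alpha_nm * Im * N
    return (dN, dI0, dIm)


def extinction_threshold(pop: PopulationParams, rel: float = 1e-6) -> float:
    """Abundance below which a compartment is flagged extinct.

    The flow never reaches exact zero; the default is ``rel`` times the
    largest carrying capacity.
    """
    return rel * max(pop.Kn, pop.Ki, pop.Km)


# ---------------------------------------------------------------------------
# Flat key-value config round-trip

_POP_KEYS = tuple(f.name for f in fields(PopulationParams))
_TR_KEYS = tuple(f.name for f in fields(TransferParams))
_INIT_KEYS = tuple(f.name for f in fields(InitialCondition))


def params_to_dict(
    pop: PopulationParams,
    tr: TransferParams | None = None,
    init: InitialCondition | None = None,
) -> dict:
    """Flatten parameter objects into a single key-value mapping."""
    out: dict = {k: getattr(pop, k) for k in _POP_KEYS}
    if tr is not None:
        out.update({k: getattr(tr, k) for k in _TR_KEYS})
    if init is not None:
        out.update({k: getattr(init, k) for k in _INIT_KEYS})
    return out


def params_from_dict(
    data: dict, *, allow_extra: tuple[str, ...] = ()
) -> tuple[PopulationParams, TransferParams, InitialCondition]:
    """Rebuild parameter objects from a flat mapping.

    Keys must match field names exactly; unknown keys raise
    :class:`ConfigError` (naming the key) so typos cannot silently fall back
    to defaults.  Keys listed in ``allow_extra`` are ignored (used by the CLI
    for run-configuration keys sharing the same file).
    """
    known = set(_POP_KEYS) | set(_TR_KEYS) | set(_INIT_KEYS) | set(allow_extra)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    for k, v in data.items():
        if k not in allow_extra and not isinstance(v, (int, float)):
            raise ConfigError(f"config key {k!r} must be numeric, got {v!r}")
    pop = PopulationParams(**{k: float(data[k]) for k in _POP_KEYS if k in data})
    tr = TransferParams(**{k: float(data[k]) for k in _TR_KEYS if k in data})
    init = InitialCondition(**{k: float(data[k]) for k in _INIT_KEYS if k in data})
    return pop, tr, init
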