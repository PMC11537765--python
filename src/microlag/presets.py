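"""Scenario presets and randomized fixture generation.

The shipped presets are reconstructions: parameter sets chosen to satisfy the
printed scenario inequalities (see :func:`microlag.deterministic.classify_scenario`)
with native carrying capacities of order 100, invader capacities of tens, and
growth rates of order one per unit time.  Transfer rates are placed near the
analytic minimal-rate thresholds so that simulations sit in the transition
regime where timing matters.  They are not fitted to any published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .deterministic import classify_scenario, equilibria
from .params import (
    ConfigError,
    InitialCondition,
    PopulationParams,
    TransferParams,
)
from .spatial import SpatialParams

__all__ = [
    "ScenarioPreset",
    "get_preset",
    "PRESET_NAMES",
    "FixtureSpec",
    "generate_fixtures",
    "DEFAULT_RANGES",
    "random_lv_draw",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully specified parameter set with its scenario label."""

    name: str
    pop: PopulationParams
    tr: TransferParams
    init: InitialCondition
    spatial: SpatialParams | None = None
    note: str = ""

    @property
    def pop_pre(self) -> PopulationParams:
        """Parameters governing the pre-acquisition (N vs I0) interaction."""
        return self.pop

    @property
    def pop_post(self) -> PopulationParams:
        """Parameters governing the post-acquisition (N vs Im) interaction."""
        return self.pop

    @property
    def label(self) -> str:
        return classify_scenario(self.pop).label


def _coexistence_init(pop: PopulationParams) -> InitialCondition:
    """Initial condition at the pre-transfer N-I0 coexistence equilibrium."""
    for eq in equilibria(pop, "N-I0"):
        if eq.kind == "coexistence":
            return InitialCondition(N0=eq.state[0], i0=eq.state[1], Im0=0.0)
    raise ConfigError("no coexistence equilibrium for this parameter set")


def _build_presets() -> dict[str, ScenarioPreset]:
    # Scenario A: coexistence pre-transfer, invaders few; acquisition makes
    # Im superior (higher Km, stronger effect on N).  System starts at the
    # pre-transfer coexistence equilibrium, as maintained until transfer.
    pop_a = PopulationParams(
        rn=1.0, ri=0.5, rm=1.0,
        Kn=100.0, Ki=30.0, Km=150.0,
        alpha_in=0.01, alpha_mn=0.015, alpha_ni=0.004, alpha_nm=0.002,
    )
    a = ScenarioPreset(
        name="A",
        pop=pop_a,
        tr=TransferParams(lambda_n=1e-4, lambda_m=1e-4),
        init=_coexistence_init(pop_a),
        note="reconstruction satisfying Kn<ri/alpha_ni and Ki<rn/alpha_in; "
        "started at the pre-transfer coexistence equilibrium",
    )
    # Variant with a slow post-acquisition growth rate: conversion of I0 to
    # Im by competition is slow, so conspecific transfer (lambda_m) has the
    # most room to shorten the lag.
    pop_a_slow = replace(pop_a, rm=0.3)
    a_small_rm = ScenarioPreset(
        name="A-small-rm",
        pop=pop_a_slow,
        tr=TransferParams(lambda_n=1e-4, lambda_m=5e-3),
        init=_coexistence_init(pop_a_slow),
        note="scenario A with small rm; used to probe the conspecific channel",
    )
    # Scenario B: invaders competitively inferior (Kn>ri/alpha_ni), decline
    # after release; acquisition (rm, Km, weaker alpha_nm) rescues them into
    # coexistence.  Natives start at carrying capacity, founders all in I0.
    pop_b = PopulationParams(
        rn=1.0, ri=0.3, rm=1.0,
        Kn=100.0, Ki=30.0, Km=80.0,
        alpha_in=0.008, alpha_mn=0.005, alpha_ni=0.005, alpha_nm=0.003,
    )
    b = ScenarioPreset(
        name="B",
        pop=pop_b,
        tr=TransferParams(lambda_n=2e-4, lambda_m=1e-4),
        init=InitialCondition(N0=pop_b.Kn, i0=10.0, Im0=0.0),
        note="reconstruction satisfying Kn>ri/alpha_ni and Ki<rn/alpha_in",
    )
    # Scenario B, intrinsic-decline variant: founders cannot grow at all
    # (ri<0, no competition needed to doom them).
    pop_b2 = replace(pop_b, ri=-0.2, alpha_ni=0.0)
    b_intrinsic = ScenarioPreset(
        name="B-intrinsic",
        pop=pop_b2,
        tr=TransferParams(lambda_n=2e-4, lambda_m=1e-4),
        init=InitialCondition(N0=pop_b2.Kn, i0=10.0, Im0=0.0),
        note="scenario B variant with ri<0 and alpha_ni=0 (intrinsic decline)",
    )
    # Scenario C: invaders superior (Ki>rn/alpha_in, Kn<ri/alpha_ni) but
    # with low capacity pre-acquisition; acquisition raises it (Km>>Ki).
    pop_c = PopulationParams(
        rn=1.0, ri=1.2, rm=1.2,
        Kn=50.0, Ki=100.0, Km=200.0,
        alpha_in=0.012, alpha_mn=0.012, alpha_ni=0.004, alpha_nm=0.004,
    )
    c = ScenarioPreset(
        name="C",
        pop=pop_c,
        tr=TransferParams(lambda_n=5e-6, lambda_m=5e-6),
        init=InitialCondition(N0=pop_c.Kn, i0=5.0, Im0=0.0),
        spatial=SpatialParams(Di=1.0, dx_patch=20.0, n_tilde=25.0, j_tilde=50.0, n_cells=20),
        note="reconstruction satisfying Ki>rn/alpha_in and Kn<ri/alpha_ni; "
        "lambda_n near the analytic spatial threshold",
    )
    return {p.name: p for p in (a, a_small_rm, b, b_intrinsic, c)}


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> ScenarioPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Randomized fixtures

#: Per-scenario sampling ranges guaranteeing a usable acceptance rate under
#: rejection against the scenario inequalities.
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "rn": (0.8, 1.2), "ri": (0.4, 0.8), "rm": (0.8, 1.2),
        "Kn": (80, 120), "Ki": (20, 40), "Km": (120, 180),
        "alpha_in": (0.008, 0.012), "alpha_mn": (0.012, 0.02),
        "alpha_ni": (0.002, 0.004), "alpha_nm": (0.001, 0.003),
        "lambda_n": (5e-5, 5e-4), "lambda_m": (0.0, 2e-4),
        "i0": (5, 15),
    },
    "B": {
        "rn": (0.8, 1.2), "ri": (0.2, 0.4), "rm": (0.8, 1.2),
        "Kn": (80, 120), "Ki": (20, 40), "Km": (60, 100),
        "alpha_in": (0.008, 0.012), "alpha_mn": (0.004, 0.006),
        "alpha_ni": (0.005, 0.01), "alpha_nm": (0.002, 0.004),
        "lambda_n": (5e-5, 5e-4), "lambda_m": (0.0, 2e-4),
        "i0": (5, 15),
    },
    "C": {
        "rn": (0.8, 1.2), "ri": (1.0, 1.4), "rm": (1.0, 1.4),
        "Kn": (40, 60), "Ki": (90, 120), "Km": (150, 250),
        "alpha_in": (0.011, 0.015), "alpha_mn": (0.011, 0.015),
        "alpha_ni": (0.002, 0.004), "alpha_nm": (0.002, 0.004),
        "lambda_n": (5e-6, 5e-5), "lambda_m": (0.0, 2e-5),
        "i0": (3, 8),
    },
}


@dataclass(frozen=True)
class FixtureSpec:
    """Request for randomized parameter sets constrained to one scenario."""

    scenario: str
    n_draws: int
    seed: int
    ranges: dict = field(default_factory=dict)  # overrides of DEFAULT_RANGES


def generate_fixtures(spec: FixtureSpec) -> list[ScenarioPreset]:
    """Rejection-sample parameter sets classified into ``spec.scenario``.

    Draws uniformly in each range, keeps draws whose scenario label matches,
    and aborts with a diagnostic when the acceptance rate falls below 1e-3
    (infeasible ranges).  Reproducible from the seed.
    """
    if spec.scenario not in DEFAULT_RANGES:
        raise ConfigError(f"unknown scenario {spec.scenario!r}; expected A, B or C")
    ranges = dict(DEFAULT_RANGES[spec.scenario])
    ranges.update(spec.ranges)
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ConfigError(f"empty range for {key!r}: min {lo:g} > max {hi:g}")
    rng = np.random.default_rng(spec.seed)
    out: list[ScenarioPreset] = []
    max_trials = max(1000, int(spec.n_draws / 1e-3))
    trials = 0
    while len(out) < spec.n_draws:
        if trials >= max_trials:
            raise ConfigError(
                f"fixture sampling infeasible: {len(out)}/{spec.n_draws} draws "
                f"accepted in {trials} trials (rate < 1e-3) for scenario "
                f"{spec.scenario}"
            )
        trials += 1
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        pop = PopulationParams(
            **{k: draw[k] for k in (
                "rn", "ri", "rm", "Kn", "Ki", "Km",
                "alpha_in", "alpha_mn", "alpha_ni", "alpha_nm",
            )}
        )
        if classify_scenario(pop).label != spec.scenario:
            continue
        tr = TransferParams(lambda_n=draw["lambda_n"], lambda_m=draw["lambda_m"])
        init = InitialCondition(N0=pop.Kn, i0=draw["i0"], Im0=0.0)
        out.append(
            ScenarioPreset(
                name=f"{spec.scenario}-fixture-{len(out)}",
                pop=pop,
                tr=tr,
                init=init,
                note=f"rejection-sampled fixture, seed={spec.seed}",
            )
        )
    return out


def random_lv_draw(rng: np.random.Generator) -> PopulationParams:
    """Broad random draw for the N-I0 pair, spanning all four LV regimes.

    Used by stability-oracle checks; the N-Im parameters are left at their
    defaults (they do not enter the N-I0 reduction).
    """
    return PopulationParams(
        rn=float(rng.uniform(0.5, 1.5)),
        ri=float(rng.uniform(0.3, 1.5)),
        Kn=float(rng.uniform(50, 150)),
        Ki=float(rng.uniform(30, 120)),
        alpha_in=float(rng.uniform(0.0, 0.03)),
        alpha_ni=float(rng.uniform(0.0, 0.03)),
    )
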