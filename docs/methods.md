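# Methods

## Model

`microlag` models a native host population competing with an introduced
population that can adapt to local conditions by acquiring beneficial
microbes from the natives.  The introduced population is split into
individuals without native microbes (`I0`) and individuals carrying them
(`Im`); the microbiome is a binary host attribute, not an explicitly
modelled microbial population.  Between transfer events the state follows
competitive Lotka–Volterra flow:

    dN/dt  = rn·N·(1 − N/Kn) − αin·N·I0 − αmn·N·Im
    dI0/dt = ri·I0·(1 − (I0+Im)/Ki) − αni·I0·N
    dIm/dt = rm·Im·(1 − (Im+I0)/Km) − αnm·Im·N

The two introduced subpopulations share the invader total in both logistic
brackets but keep distinct carrying capacities `Ki`, `Km` — acquisition may
expand the niche, so the capacities are not pooled.  A special case: when
`ri < 0` (an introduced population intrinsically unable to attain positive
growth), the I0 growth term is the pure exponential decline `ri·I0`.  With
the logistic bracket kept, a large `Im` would make the bracket negative and
`ri < 0` would then *raise* dI0/dt — a sign artifact that would resurrect a
doomed subpopulation, so the bracket is dropped in that regime only.

Microbiome transfer is a jump process superimposed on the flow.  In an
interval `(t, t+dt)` the number of I0 individuals acquiring microbes is
Poisson:

* native channel: `Λn ~ Pois(λn·N·I0·dt)`
* conspecific channel: `Λm ~ Pois(λm·Im·I0·dt)`

Each converted individual moves I0 → Im, conserving the introduced total.
`λn`, `λm` are density-dependent transfer rates (per donor–recipient pair
per unit time); zero disables a channel.

## Hybrid simulation scheme

Because the event rates ride on a continuously varying state, the engine
uses fixed-grid tau-leaping rather than exact Gillespie: every `dt_jump`
(default 0.05 time units) Poisson counts are drawn from the rate at the
epoch start and applied at the epoch end.  The leap error is bounded by a
runtime guard `γ·dt_jump ≤ 0.1` (warning above it, hard abort above 10).
Draws are capped at `floor(I0)` — a jump can never convert more individuals
than exist — with the native channel served first.  Abundances are
continuous densities; transfer counts are integers; when `I0 < 1` the rate
still uses the continuous value but the floor cap makes events impossible,
which quietly terminates the jump process near extinction.

Between epochs the flow is integrated with LSODA at `rtol 1e-10`,
`atol 1e-12`, chunking 200 epochs per solver call and restarting at each
applied jump.  The tolerances are deliberately tight: trajectories of
interest linger exponentially close to saddle points (that lingering *is*
the invasion lag), loose tolerances distort lag times, and the tight
setting keeps the chained hybrid integration within 1e-6 of a single ODE
solve in the jump-free limit.  Tiny negative excursions are clamped to
zero; a compartment is flagged extinct below `eps_ext = 1e-6·max(K)`.

An exact next-reaction sampler (`sample_first_transfer_time`) integrates
the total rate along the flow and inverts it against a unit-exponential
deviate; it serves as the leap scheme's calibration oracle in tests (first
-event times at the frozen coexistence equilibrium are exponential with
rate `λn·N*·I0*`).

Ensembles spawn one child generator per replicate from a root
`SeedSequence`, so results are order-independent and bit-reproducible from
the base seed.  Event conservation (`I0+Im` across a jump) is exact up to
one float rounding (~1e-13 relative); tests assert it at 1e-9 absolute.

## Scenario taxonomy

The three-compartment system is analysed pairwise in the classical
two-species phase plane; the full 3-D system is only ever integrated.
Mutual invasibility of the N–I0 pair classifies the pre-transfer regime,
and of the N–Im pair the post-transfer regime:

* **A** – coexistence before transfer: `Kn < ri/αni` and `Ki < rn/αin`.
* **B** – invader declines: `Kn > ri/αni` and `Ki < rn/αin`, or `ri < 0`.
* **C** – invader excludes natives: `Ki > rn/αin` and `Kn < ri/αni`.

Both-sides-uninvasible (bistable) parameter sets are reported as
`other`/`bistable` and never resolved to a single winner — the outcome is
initial-condition dependent.  Equilibria of any reduction come with
Jacobian eigenvalues; an eigenvalue's real part within tolerance of zero
flags the equilibrium as degenerate rather than silently classifying it.

## Derived metrics

**Invasion lag** is the time from introduction to the inflexion point of
the total introduced population `I = I0+Im`.  The estimator resamples the
series to ≥ 2000 uniform points, smooths with a moving average of 1% of
the horizon, differentiates centrally and takes the derivative maximum,
excluding one window length at each end.  A trajectory whose total rise is
below 1% of its maximum (e.g. resting at a pre-transfer equilibrium)
reports no inflexion, as does a monotone-declining or boundary-peaked
curve.  On a pure logistic the estimator recovers the closed-form
inflexion time `ln(K/I0 − 1)/r` within 2% at the default sampling.
Both the per-replicate lags and the lag of the ensemble-mean curve are
exposed; tests use the per-replicate mean.

**Establishment probability** is the fraction of replicates whose
introduced total exceeds a threshold at the horizon.  Default threshold
`0.1·Km`: in the decline scenarios the rescued and doomed branches differ
by orders of magnitude there, so the exact cutoff is uncritical.  The
binomial standard error `sqrt(p(1−p)/n)` is reported.

**Minimal transfer rate (rescue).**  With natives at `Kn`, founders
decline at per-capita rate `αni·Kn − ri` and fall below one individual
after `ln(i0)` e-foldings; requiring one expected transfer event
(`λn·Kn·i0` per unit time, holding `I0 ≈ i0`) within that window gives

    λn_min = (αni·Kn − ri) / (Kn·i0·ln i0),   valid for Kn > ri/αni.

The `αni = 0, ri < 0` (intrinsic decline) variant is the direct
substitution `(−ri)/(Kn·i0·ln i0)`; the derivation retains `Kn` because
the encounter rate is proportional to the native population.  The formula
is an on-average approximation: Monte-Carlo bracketing shows the
probability-of-establishment curve crosses 1/2 within a factor of ~2 of
`λn_min` on the shipped presets (the approximation `I0 ≈ i0` over-counts
encounters, so the true crossing sits somewhat above the formula).

**Minimal transfer rate (spatial).**  For a superior competitor sweeping
a patch (`Kn < ri/αni`),

    λn_min = 2·Di·(ri − αni·Kn) / (Δx·ñ·j̃),

with dispersal coefficient `Di`, patch size `Δx`, and average native and
invader densities `ñ`, `j̃` (user-supplied averages; the package does not
prescribe how to estimate them).

## Patch model

The 1-D lattice realizes scenario C in space: `n_cells` cells of width
`Δx/n_cells`, natives sessile, invader compartments dispersing by explicit
finite-difference diffusion with reflecting boundaries (sum-conserving;
the CFL bound `Di·dt/h² ≤ 0.5` is enforced with the required smaller step
named in the error).  Per step: local reaction (fixed-step RK4), invader
diffusion, then per-cell Poisson transfers with the same capped-draw rule
as the nonspatial engine.  Founders are seeded at one boundary cell so the
invasion progresses as a moving front.  Native extinction is the first
time total native abundance across the lattice falls below `eps_ext`;
`acquired_before_displacement` is exactly `t_first_transfer < t_ext` with
never-occurred coded `+inf`.

A structural property worth knowing: when native losses are dominated by
competition, `dN/dt ≈ −αin·N·I0`, so the patch-total contact integral up
to native extinction, `∫ Σ N·I0 dt ≈ (ΔN_total + regrowth)/αin`, is almost
invariant to how fast the front sweeps.  Faster dispersal shortens the
transfer window but widens the native–invader interface by a compensating
amount.  Consequently the acquisition fraction responds strongly to patch
size and native density (more total native mass to lose) but is nearly
flat in `Di` in this lattice: the two opposing dispersal effects —
more contact situations versus faster displacement — cancel almost
exactly, and the slow-dispersal advantage predicted when displacement
speed dominates is not realized here.  The corresponding dispersal test
documents this as a known limitation of the minimal scheme.

## Presets and synthetic fixtures

The shipped presets are this package's own reconstructions of the three
scenarios, chosen once to satisfy the inequalities with native capacities
~100 individuals, invader capacities of tens, growth rates O(1) per unit
time, and transfer rates placed near the analytic thresholds so the
simulations sit in the transition regime where timing matters:

| preset | role | key values |
|---|---|---|
| `A` | coexistence, lag studies | `ri=0.5, Ki=30, Km=150, λn=1e-4`; starts at the N–I0 coexistence equilibrium (N*≈92.1, I0*≈7.9) |
| `A-small-rm` | conspecific-channel probe | `rm=0.3, λn=1e-4, λm=5e-3` |
| `B` | competition-driven decline | `ri=0.3, αni=0.005, i0=10, λn=2e-4` |
| `B-intrinsic` | intrinsic decline | `ri=−0.2, αni=0` |
| `C` | superior invader, patch studies | `Kn=50, Ki=100, Km=200, λn=5e-6`; `Di=1, Δx=20, 20 cells` |

`generate_fixtures` rejection-samples randomized parameter sets against
the scenario inequalities (aborting if the acceptance rate falls below
1e-3), reproducibly from a seed.

What the synthetic runs do and do not show: the generator realizes exactly
the model's assumptions (deterministic demography, a single binary
microbiome trait, transfer as the only stochastic ingredient, well-mixed
or 1-D nearest-neighbour space).  Passing tests demonstrate internal
consistency and the direction and rough magnitude of the predicted
effects; they say nothing about demographic noise, multi-strain dynamics,
or real dispersal kernels, none of which are modelled.

## Problem sizes and numerical defaults

Test ensembles use 100–300 replicates (the figures-of-merit stabilize well
below that; binomial/lag standard errors are carried explicitly), horizons
of 50–600 time units chosen to cover the slowest preset dynamics, `dt_jump
= 0.05` nonspatial and `0.1` on the lattice, and 500 randomized draws for
the stability oracle with a 0.03 eigenvalue margin (slower modes cannot be
resolved by finite-horizon integration and are excluded as degenerate, as
is proper for a structurally unstable classification).

## Known limitations

* Tau-leaping on a fixed grid slightly misplaces event times within an
  epoch (bounded by the `γ·dt ≤ 0.1` guard); the exact sampler exists for
  calibration but not for production ensembles.
* The cap-at-floor rule for fractional `I0` is a modelling choice near
  extinction; sensitivity to it is untested below one individual.
* The lattice dispersal scheme cannot reproduce a slow-dispersal advantage
  in microbiome acquisition (see above); a continuum front treatment would
  be needed to probe that regime.
* `ñ` and `j̃` in the spatial threshold are treated as user-supplied
  averages, not estimated from simulations.
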