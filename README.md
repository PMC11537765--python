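# microlag

Hybrid deterministic–stochastic modelling of microbiome transfer from a
native host population to an introduced one, and of the invasion dynamics
that follow.

## The problem

Introduced species sometimes linger at low abundance for years before
suddenly becoming invasive.  One candidate mechanism for such *invasion
lags* is non-genetic adaptation: invaders pick up beneficial microbes from
the microbiomes of ecologically similar native species, and the acquired
microbiome — not a genetic change — supplies the fitness needed to expand.
`microlag` is a small toolkit for ecologists and modellers who want to
explore that hypothesis quantitatively: when does delayed microbiome
acquisition produce a lag, when does it rescue a doomed introduction, and
when does spatial structure decide whether acquisition happens at all.

## The model

A native population N competes with an introduced population split into
individuals without (I0) and with (Im) native microbes, under competitive
Lotka–Volterra dynamics:

    dN/dt  = rn N (1 − N/Kn) − αin N I0 − αmn N Im
    dI0/dt = ri I0 (1 − (I0+Im)/Ki) − αni I0 N − Λn − Λm
    dIm/dt = rm Im (1 − (Im+I0)/Km) − αnm Im N + Λn + Λm

Microbiome acquisition is a jump process: in each interval dt the number
of converted individuals is Poisson, `Λn ~ Pois(λn N I0 dt)` via contact
with natives and `Λm ~ Pois(λm Im I0 dt)` via contact with already-adapted
conspecifics.  Acquisition shifts an individual from the maladapted
parameter set (ri, Ki, αni, αin) to the adapted one (rm, Km, αnm, αmn).

Three scenario presets cover the pre-acquisition competitive standing of
the invader — coexisting (**A**), declining (**B**, by competition or by
`ri < 0`), or excluding the natives but capped at low density (**C**) —
each defined by printed inequalities among the K's, r's and α's.  Derived
quantities include the invasion lag (time to the inflexion of I0+Im), the
Monte-Carlo establishment probability, and analytic minimal-transfer-rate
thresholds, e.g. rescue of a declining introduction requires roughly

    λn > (αni Kn − ri) / (Kn i0 ln i0).

A minimal 1-D patch model (sessile natives, diffusing invaders, local
transfers) probes whether invaders acquire microbes before displacing the
natives.  See `docs/methods.md` for assumptions, estimators and numerics.

## Worked example

```python
import microlag as ml

p = ml.get_preset("A")          # coexistence scenario, starts at equilibrium
cfg = ml.StochasticRunConfig(dt_jump=0.05, t_end=400.0, seed=None)
summ = ml.run_ensemble(p.pop, p.tr, p.init, cfg, n_reps=100, base_seed=1)
lags = summ.metrics["lag_time"].dropna()
print(f"mean invasion lag: {lags.mean():.1f} time units over {len(lags)} replicates")
print(f"first transfer at t={summ.trajectories[0].events[0].t:.2f}, "
      f"final invader total {summ.trajectories[0].I_total[-1]:.1f}")

thr = ml.lambda_min_establishment(ml.get_preset("B").pop, ml.get_preset("B").init)
print(f"scenario B rescue threshold: lambda_n_min = {thr.lambda_n_min:.3g}")
```

prints

```
mean invasion lag: 19.7 time units over 100 replicates
first transfer at t=1.95, final invader total 150.0
scenario B rescue threshold: lambda_n_min = 8.69e-05
```

Read: starting from stable coexistence (≈7.9 invaders against ≈92 natives),
the first microbiome transfer arrives after an exponential waiting time
(mean ≈ 13.7; the first replicate happened to draw t = 1.95) and the
introduced total then grows to the adapted capacity Km = 150; the inflexion
of that growth sits on average ≈ 20 time units after introduction — the
invasion lag.  In scenario B, transfer
rates above ≈ 8.7e-5 per pair per time are needed, on average, for ten
founders to be rescued before dying out.

The same operations are available from a shell:

```sh
microlag simulate --preset A --seed 1 --out runs/a1      # trajectory + events CSV
microlag sweep --preset A --lambda-n 1e-5:1e-3:5 --reps 100 --out runs/sweep
microlag thresholds --preset B --i0 10 --out runs/thr
microlag patch --preset C --reps 200 --seed 2 --out runs/patch
microlag fixtures --scenario B --n 50 --seed 3 --out runs/fx
```

Every run writes a provenance JSON (full parameters, seeds, version);
identical inputs and seed reproduce byte-identical artifacts.

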