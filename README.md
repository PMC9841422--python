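# smolkin

Automated analysis of high-throughput single-molecule TIRF assays for
enzymes that interconvert double-stranded and single-stranded DNA —
exonuclease digestion, strand-displacement synthesis, helicase unwinding
and displacement of protein blocks from DNA ends.

The experimental readout is simple: surface-tethered linear DNA templates
(2620 bp) are stained with an intercalating dye whose integrated
per-molecule fluorescence tracks the amount of dsDNA, optionally alongside
a labelled ssDNA-binding protein (RPA) channel that tracks exposed ssDNA.
A movie of a single field of view therefore records the full reaction
kinetics of hundreds of molecules in parallel. `smolkin` turns such movies
(or simulated stand-ins with known ground truth) into per-molecule rates,
post-reaction-synchronised ensemble kinetics and first-passage-time step
counts.

## The models

**Per-molecule piecewise-linear fit.** Every intensity trajectory is
fitted with the continuous three-segment function

    f(x) = m·a + t   (x < a)
           m·x + t   (a ≤ x ≤ b)
           m·b + t   (x > b)

where `a` and `b` bracket the enzymatic activity and `m` is the processive
slope. The plateaus define a per-molecule calibration

    I_cal = (I − (m·b + t)) / ((m·a + t) − (m·b + t))

mapping the pre-reaction plateau to 1 (full template) and the
post-reaction plateau to 0, so that |m| on the calibrated scale times the
template length (2620 nt) is the enzymatic rate in nt/s. Incomplete
reactions (negative `a` or `b`, or change points beyond the movie) and
poor fits (R² ≤ 0.7) are discarded with machine-readable reasons.

**Post-reaction synchronisation.** Trajectories are shifted so a
well-defined end-of-reaction event (fitted `b`, or the single-frame
dissociation drop found by a depth-1 regression tree) sits at time zero,
then averaged. This preserves kinetic shape that plain ensemble averaging
destroys when molecules react asynchronously.

**Ensemble kinetics.** The synchronised RPA signal is fitted with
`exp(k(x − x₀))` (synthesis), rates across substrate concentrations with
the Michaelis–Menten equation `v = v_max[S]/(K_M + [S])`, and the
saturation of RPA binding with the first-order model
`[ssDNA_RPA](x) = 2620 − [ssDNA_free]₀·e^(−k(x−x₀))`.

**First-passage-time step counting.** For single-frame disappearance
events (tether rupture), the waiting-time distribution is fitted by
maximum likelihood with a shifted gamma density
`k^n (x−x₀)^(n−1) e^(−k(x−x₀)) / Γ(n)` with x₀ fixed (20 s for reagent
arrival); the shape `n` estimates the number of rate-limiting reaction
intermediates (n = 1 ⇒ a single exponential step).

A full forward simulator (`smolkin.simulate`) generates trajectories,
first-passage-time sets and two-channel TIFF movies — diffraction-limited
Gaussian spots, beam-profile inhomogeneity, stage drift, Poisson shot
noise and Gaussian read noise — with JSON ground-truth sidecars, so every
stage of the pipeline is testable without experimental data.

## Worked example

Simulate a digestion movie and analyse it end to end:

```sh
smolkin simulate --out movie/ --n-molecules 36 --rate-mean 40 --rate-std 5 --seed 4
smolkin run --mode exo --movie movie/dna.tif --out results/
```

Or from Python:

```python
import numpy as np
from smolkin import simulate, trajfit

prog = simulate.KineticProgram(kind="digestion", rate=26.2, start_time=10.0)
traj, truth = simulate.simulate_trajectory(prog, noise_sigma=0.05, seed=1)
fit = trajfit.fit_piecewise_linear(traj.times, traj.primary)
cal = trajfit.calibrate(traj.times, traj.primary, fit)
refit = trajfit.fit_piecewise_linear(cal.times, cal.i_cal)
print(f"a = {refit.a:.1f} s, b = {refit.b:.1f} s, "
      f"rate = {abs(refit.m) * 2620:.1f} nt/s, r2 = {refit.r2:.3f}")
```

which prints

```
a = 9.5 s, b = 111.4 s, rate = 25.7 nt/s, r2 = 0.982
```

the recovered activity window (true 10–110 s) and digestion rate
(true 26.2 nt/s) of that molecule.

The pipeline writes a result bundle per run: `molecules.csv` (one row per
molecule: m, t, a, b, r², rate, kept/discard reason), `ensemble.csv`
(synchronised mean ± SEM), `rates.json`, `survival.csv` and
`kinetics.json` in displacement mode, and a `manifest.json` recording the
full configuration, seed and per-reason discard counts. Reruns with the
same configuration are byte-identical.

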