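# circuitnoise

Stochastic simulation and single-cell quantification of low-noise
gene-expression circuits.

## The problem

Most inducible expression systems in bacteria — a gene of interest
repressed by a constitutively expressed transcriptional repressor — show
high cell-to-cell variability (noise) and a nearly all-or-none response to
inducer.  Negative autoregulation linearizes the dose-response, and
bicistronic expression of the repressor together with the gene of interest
(both translated from the same transcript) removes the transcriptional
noise between them.  This package implements, as a tested and reusable
pipeline, the computational analysis behind that design argument:

- **Simulation**: exact Gillespie (direct-method) SSA of five regulatory
  circuits — constitutive (i), constitutive repressor (ii), autoregulated
  repressor (iii), bicistronic autoregulation (iv) and a hybrid with an
  extra weak constitutive repressor promoter (v) — with extrinsic noise as
  an exponentiated, mean-scaled Ornstein–Uhlenbeck factor (τ = 200 min,
  c = 2.5×10⁻⁵ s⁻¹) multiplying all translation propensities.
- **Analysis**: expression mean and noise CV² = σ²/μ², inducer
  dose-response and noise-vs-mean sweeps, the intrinsic noise limit
  (1+b)/μ with burst size b = k_TL/deg_M, Hill and exponential-decay fit
  operators.
- **Quantification**: the matching single-cell measurement pipeline —
  flow-cytometry scatter-peak gating, fitting fluorescence as an empirical
  autofluorescence background convolved with a log-normal, bootstrap
  confidence intervals, single-molecule gamma spot calibration and
  size-normalized molecules-per-cell estimates.
- **Synthetic data**: seed-deterministic generators with known ground
  truth for every pipeline stage, so everything is testable without
  instrument data.

It is aimed at people designing or analyzing low-noise expression systems
who want to rerun the circuit comparisons with their own rates, and at
anyone who needs a background-convolved log-normal fitter for
flow-cytometry or microscopy intensity distributions.

## Worked example

```python
import numpy as np
import circuitnoise as cn

# Bicistronic autoregulation at intermediate induction, extrinsic noise on
net = cn.build_network("bicistronic_autoregulation", inducer_count=800)
cfg = cn.SimConfig(duration=21_000, burn_in=1_000, seed=1)
factors = cn.generate_extrinsic(cn.OUParams(seed=2), cfg.n_intervals)
traj = cn.simulate(net, cfg, factors)
s = cn.summarize(traj, "P")
print(f"mean P = {s.mean:,.0f} molecules/cell, noise = {s.noise:.3f}")

# Quantification half: synthetic events -> gate -> deconvolution fit
truth = cn.CytometryGroundTruth(log_mean=6.2, log_sd=0.22, n_events=30_000, seed=3)
events = cn.synth_cytometry(truth)
gated = cn.gate_events(events, cn.GateSpec(*cn.find_scatter_peak(events)))
fit = cn.fit_convolution(gated["FL1A"].to_numpy(), np.full(2_000, 191.0))
print(f"fitted mean = {fit.mean:.0f}, noise = {fit.noise:.3f}")
```

prints

```
mean P = 10,216 molecules/cell, noise = 0.092
fitted mean = 504, noise = 0.049
```

The simulated circuit sits at roughly half its fully induced level
(~2.1×10⁴ molecules/cell) with CV² = 0.092 — below the ~0.1 extrinsic
noise plateau that constitutive expression converges to under the same
extrinsic fluctuations, which is the point of the bicistronic design.  The
second half recovers the generating log-normal (mean 505, CV² 0.050) from
gated synthetic events through the background-convolution fit.

A command-line workflow wraps the same functionality
(`circuitnoise simulate|sweep|quantify|synth --help`), writing CSV/TSV/JSON
outputs plus a manifest with every resolved seed and parameter.

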