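# Methods

## The model

The package simulates plasmid-based inducible gene expression in
*Escherichia coli* as a mass-action chemical network in unit volume, so
molecule numbers and concentrations coincide and every propensity carries
units of s⁻¹.  Species are the free and repressor-bound DNA copies of the
gene of interest (D1, D1:R) and of a separate repressor gene (D2, D2:R),
the two mRNAs (M1, M2), the protein of interest P, the transcriptional
repressor R, the inducer-bound repressor R:I and free inducer I.  Five
circuit wirings are built from one reaction catalogue:

| scheme | wiring |
|---|---|
| i  | constitutive expression of P |
| ii | P repressed by a constitutively expressed repressor (conventional inducible system) |
| iii | as ii, but the repressor also represses its own gene |
| iv | bicistronic autoregulation: P and R translated from the same autoregulated transcript |
| v  | hybrid: scheme iv plus a weak (40%-strength), never-repressed promoter expressing extra R |

Default rate constants: transcription k_TX1 = k_TX2 = 1.7×10⁻³ s⁻¹
(6.7×10⁻⁴ s⁻¹ for the hybrid's weak promoter; 6.5×10⁻⁶ s⁻¹ for the
weak-expression end of the unregulated sweep), translation k_TL,P = 0.67 s⁻¹
and k_TL,R = 0.0333 s⁻¹ per mRNA, repressor–DNA binding 10⁻⁵/10⁻⁴ s⁻¹
(on/off), repressor–inducer binding 10⁻⁵/10⁻⁷ s⁻¹, mRNA degradation
0.0033 s⁻¹ (5-min lifetime) and protein/repressor/R:I degradation
1.6667×10⁻⁴ s⁻¹ (dilution at a ~69-min doubling time).  Repression is
monomeric binding of free DNA with no cooperativity; DNA-bound repressor is
protected from degradation; degradation of R:I liberates its inducer
molecule.  Ten unrepressed DNA copies per gene mimic a mid-copy plasmid.
These rates give the characteristic scales: mean mRNA ⟨M1⟩ = 10·k_TX1/deg_M
≈ 5.15, burst size b = k_TL,P/deg_M ≈ 203, fully induced protein
⟨P⟩ ≈ 2.07×10⁴ and total repressor ⟨R+R:I⟩ ≈ 1.03×10³ per cell.

Two inducer limits are supported.  In the fast limit (default) the free
inducer count is clamped: binding and unbinding never change I, modeling
instant re-equilibration with the environment.  In the slow limit the
inducer is a conserved integer pool (I + R:I constant), consumed by binding
and returned by unbinding and by R:I degradation.

## Stochastic simulation

Trajectories are exact realizations of the chemical master equation,
generated by the direct-method Gillespie SSA with full propensity
recomputation at every event (the networks have at most 15 reactions, so
recomputation is cheaper than dependency bookkeeping).  The inner loop is
compiled with numba; a pure-Python fallback produces identical output.
Internal time is seconds; the public interface is in minutes.

Extrinsic noise is a global translation-capacity factor: a stationary
zero-mean Ornstein–Uhlenbeck process x(t) with relaxation time τ = 200 min
and diffusion parameter c = 2.5×10⁻⁵ s⁻¹, sampled exactly on the recording
grid via x(t+Δ) = x(t)·e^(−Δ/τ) + N(0, (cτ/2)(1−e^(−2Δ/τ))), then
exponentiated and divided by its empirical mean.  The resulting positive,
unit-mean factor multiplies every translation propensity (and nothing else)
and is held piecewise constant over each 1-min recording interval.  This
piecewise-constant coupling is an approximation justified by the scale
separation 1 min ≪ τ; within an interval propensities depend only on the
state, so sampling stays statistically exact, and interval boundaries simply
discard the pending exponential waiting time (valid by memorylessness).
Burn-in is simulated with extrinsic noise active and only excluded from
statistics.

The printed diffusion parameter carries no units; interpreting c in s⁻¹
with τ converted to seconds gives stationary variance cτ/2 = 0.15 and a
protein-level noise plateau near the ~0.1 extrinsic limit reported for
highly expressed genes (the factor CV² of e^0.15 − 1 ≈ 0.16, low-pass
filtered through the 100-min protein lifetime by roughly τ/(τ+100) ≈ 2/3).
The per-minute interpretation would give negligible extrinsic noise
(variance 2.5×10⁻³), inconsistent with a visible plateau, so per-second is
the default and the unit is a configurable parameter.

Default protocol: 101,000 simulated minutes, state recorded every minute,
first 1,000 minutes excluded.  The test suite and acceptance script use
20,000–100,000 sampled minutes with 3 replicate seeds per condition —
sizes chosen so that the standard error of a CV² estimate (whose effective
sample count is limited by the 100-min protein and 200-min extrinsic
correlation times, roughly duration/2τ per run) is a few percent,
comfortably inside each assertion's tolerance.

## Summaries and sweeps

Noise is CV² = σ²/μ² of a species' copy number over post-burn-in samples.
Dose-response sweeps rerun the simulator over a log-spaced grid of 12
integer inducer counts spanning 1–10⁴ (configurable; this range covers the
repression-to-saturation transition of every scheme with the default
rates).  CV² is computed per replicate and then averaged, which avoids the
bias a single slow extrinsic excursion would impose on a pooled sample.
"Intermediate induction" is operationalized as the grid point whose mean is
nearest half of the fully induced mean (measured at a saturating 10⁶
inducer count).  The slow-inducer sweep instead extends to 10⁶ molecules:
the right arm of the U-shaped noise curve (return to the extrinsic plateau)
only appears once the conserved pool so far exceeds the ~10³ repressor pool
that autoregulation is fully defeated.

The unregulated reference without extrinsic noise is the intrinsic limit
CV² ≈ (1+b)/μ.  The exact birth-death value is smaller by the factor
deg_M/(deg_M+deg_P) ≈ 0.95, which is why simulated points sit 4–5% below
the limit; assertions use a 10% band around the (1+b)/μ form.

Hill fits use uniformly weighted least squares of
y = y₀ + (y_max−y₀)·dⁿ/(Kⁿ+dⁿ) on mean responses (scipy `curve_fit`,
multi-start-free with data-derived initial values, n bounded to (10⁻³, 20));
exponential decays fit v(t) = A·2^(−t/t_half) + offset.  Experimental
literature values (Hill coefficients, the 64.1-min repression half-time)
serve only as ground truths for synthetic recovery tests of these
operators, never as simulation targets.  The in-silico washout analog
(schedule step to zero inducer) decays at the dilution half-time
ln2/deg_P ≈ 69.3 min toward the repressed steady state; the fitted value on
mean traces runs a few percent fast because the repressor pool is still at
its induced level right after washout (transient over-repression), so the
recovery test uses a 20% band on a 50–800 min post-wash window.

## Flow-cytometry pipeline

Events are gated to the mode of the (FSCA, SSCH) histogram, located on
64-per-axis log-spaced bins, keeping events with
((FSCA−peak)/peak)² + ((SSCH−peak)/peak)² strictly below the squared-radius
threshold (0.25 or 0.5625 depending on instrument configuration).  The
printed form of this criterion is typographically ambiguous about the
denominators; normalizing by the peak coordinates gives a scale-free
ellipse about the mode and is the adopted (and switchable) convention.

Gated fluorescence is fit as background ⊛ log-normal: an observation is a
draw from the empirical autofluorescence distribution of a non-fluorescent
control (binned, 256 bins) plus a log-normal expression draw.  The
log-likelihood is evaluated on a 1024-bin representation of the signal
(the density is smooth on the instrument scale, so binning loses negligible
information and makes each evaluation a 1024×256 matrix product) and
maximized by Nelder–Mead over (log-mean, log(log-sd)) from a moment-matched
start plus two perturbed restarts, tolerance 10⁻⁸ on the objective.  Each
observation's density is floored at 10⁻¹²: real gates leak a small fraction
of background-only events whose density under the convolution model is
zero, and without the floor a handful of them dominates the likelihood and
inflates the fitted log-sd (the floor acts as a tiny uniform contamination
component).  A degenerate (constant) background reduces exactly to a
shifted log-normal, solved in closed form from the log-moments; this fast
path is also what makes the bootstrap coverage study cheap.  Samples whose
mean is within two standard errors of the background mean are reported as
non-identifiable rather than fitted.  Reported mean and noise are those of
the log-normal component (exp(μ+σ²/2), exp(σ²)−1); bootstrap percentile
intervals come from 100 signal resamples refit with a warm start at the
full-sample solution.  Direct moment estimates are available for samples
far above background.

## Microscopy pipeline

Single-molecule spot intensities are fit by 2-parameter maximum-likelihood
gamma estimation (location fixed at zero; MLE chosen over moments, and the
offset-free form, because nothing in the data motivates a third parameter).
The fitted mean is the counts-per-molecule calibration at the reference
imaging condition and transfers to other conditions multiplicatively
(fluorescence is linear in integration time and laser power).  Per-cell
background-subtracted integrated intensity divided by counts-per-molecule
gives molecules per cell; size normalization divides by cell area and
multiplies by the mean area.  Expression distributions of cell populations
reuse the cytometry convolution fit with the non-fluorescent-strain sample
as background.  Spot detection, segmentation and image flattening are out
of scope: the module consumes intensity lists and per-cell tables.

## Synthetic data

The generators are pure functions of (ground truth, seed).  Cytometry event
tables place cells in a tight 2-D log-normal scatter cloud
rejection-sampled strictly inside the nominal gate and debris (default
fraction 2/3, mirroring gates that keep about one third of events) strictly
outside it; cell fluorescence is background + log-normal, debris carries
background only.  The default background is the constant 191-count
autofluorescence level with an optional Gaussian relative width, since no
real control histogram ships with the package.  Microscopy truth draws
gamma spots, unit-mean log-normal cell areas and molecule counts
proportional to area around a log-normal expression law, plus an optional
zero-mean measurement residual.  Defaults are 30,000 events and 300 cells.

What the generators do not emulate: instrument digitization and saturation,
scatter–fluorescence correlations, doublets, autofluorescence that scales
with cell size, photobleaching, and segmentation errors.  Passing recovery
tests therefore demonstrate estimator correctness under the assumed model,
not robustness to every artifact of real cytometers and microscopes — with
one deliberate exception: mis-gated background-only events are generated
whenever the estimated peak differs from the true one, which is what the
likelihood floor is tested against.

## Numerical and design choices

- Direct-method SSA rather than the next-reaction method: both are exact
  samplers of the same process; statistical equivalence is relied on and
  verified against Poisson/birth-death closed forms and a KS test.
- Recording takes the state at grid times, not event averages.
- One RNG stream per simulation segment, seeded via `SeedSequence` spawning
  so replicate, level and extrinsic streams are independent and every
  result is bit-reproducible from one integer seed.
- The OU series is regenerated per run by default; a saved series can be
  reused across schemes for paired comparisons.
- Scheme-similarity assertions ("constitutive and autoregulated repressor
  circuits behave alike") use a factor-1.5 band on the noise ratio at
  matched means: CV² estimates at these run lengths carry few-percent
  standard errors, so strict equality is not testable, while the
  qualitative claim concerns curves that lie within tens of percent of
  each other on axes spanning two decades.

## Known limitations

- Cell division, binomial partitioning and replication-linked copy-number
  fluctuations are absent; dilution is first-order degradation.
- The hybrid scheme's noise exceeds the extrinsic plateau at deeply
  repressed inducer levels (mean ≲ 10³ proteins), where the intrinsic
  limit itself exceeds 0.1; its advertised low-noise behavior concerns the
  responsive part of the induction range.
- The two-operator structure of the real promoter, repressor dimerization
  and cooperativity are deliberately not modeled.
- FCS binary parsing is out of scope; event tables are CSV.
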