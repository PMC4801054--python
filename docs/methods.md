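# Methods

## The model

Each gene copy is a two-state (telegraph) promoter: OFF→ON at rate `kon`
(min⁻¹), ON→OFF at `koff`, and transcription initiation at `kini` while ON.
A nascent transcript elongates at constant speed and stays at the
transcription site for a deterministic residence time `tres` (elongation +
splicing + release), then becomes a mature mRNA degraded stochastically at
rate `kd`.  The cell cycle enters through three events: at the replication
time `trep` the locus doubles (the new copy inherits the parent copy's
ON/OFF state), and the activation rate of both copies becomes `alpha*kon`
(`alpha ≤ 1` is dosage compensation); at the division time `tdiv` mature
mRNA are partitioned binomially with p = 1/2 and one post-division copy
set is retained with the second state slot reset OFF.  A diploid cell is
two statistically independent loci sharing the same cycle clock, so it
carries 2 transcription sites before `trep` and 4 after.

Under the uniform-probe approximation a transcript elongated a fraction f
of the gene contributes f full-transcript equivalents of signal; averaged
over a uniformly distributed transcript age this gives the signal weight
λ = 1/2 per resident transcript.  An explicit probe-position list can be
supplied instead; λ then follows from the positions.

Default parameters emulate mouse ES cells: `tdiv` = 780 min (13-h doubling
time), phase fractions (G1, S, G2/M) = (43, 29, 28)%, mature half-life on
the 7-h scale, and switching rates of the order 10⁻³–10⁻² min⁻¹ with
initiation of order 1 min⁻¹.  `trep` defaults to the midpoint of S phase;
the model has a single replication instant per locus, not a
replication-timing distribution.

## Synthetic populations

`simulate.sample_population` draws cell ages from the age density of an
exponentially growing population, p(a) = (2 ln2/tdiv)·2^(−a/tdiv), runs an
exact Gillespie simulation of each locus (deterministic maturation delays
handled with an event queue) for 5 burn-in divisions so records are
cyclostationary, and reads counts at the sampled age.  DNA content is the
piecewise-deterministic whole-genome content (μ in G1, linear μ→2μ across
the S window implied by the phase fractions, 2μ in G2/M) with
multiplicative Gaussian noise of coefficient of variation `cv` (default
0.05).  What the generator does *not* emulate: extrinsic cell-to-cell
variation in kinetic parameters, cell-volume effects on transcription,
segmentation/spot-detection errors, partial-probe intensity noise, and
per-locus replication-timing spread.  Tests passing on generator output
therefore validate the estimators under the model's own assumptions, not
under every failure mode of real smFISH data.

## Cell-cycle deconvolution

The DNA-content histogram is fitted with the Fried/Baisch five-Gaussian
mixture: component i has mean α_i·μ, α_i = (i+3)/4, and standard deviation
α_i·σ (equal CVs).  Binning is Freedman–Diaconis; the fit is
Poisson-weighted least squares on bin counts with multi-start (μ at the
histogram mode and at sample percentiles, σ at 0.05 μ).  Phase fractions
are integrated component areas (∝ A_i·α_i); gates are G1: x < μ+σ and
G2/M: x > 2μ.  Ergodic rate analysis converts DNA content to time,
t(x) = tdiv·log2(2/(2−F(x))), with F the analytic mixture CDF clipped to
[0, 1].

The replication time and compensation fold come from a two-level step fit:
nascent totals are smoothed with a 50-nearest-neighbour running mean in
time, then n(t) = 2β (t < trep), 4ηβ (t ≥ trep) is fitted by exhaustive
search of the split over observed times (ties toward the earlier time; the
level parameters are segment means, which solve the least-squares problem
exactly).  The total fold change is 2η, and
α = η·koff/((1−η)·kon + koff) converts the per-copy fold to the
activation-rate fold (inverse: η = α(kon+koff)/(α·kon+koff)).

## FSP solver

The chemical master equation for one locus (joint state: two gene-state
slots × mature count, the second slot frozen OFF before `trep`) is
truncated at `mmax` copies and propagated with the discrete Euler operator
(I + QΔt), Δt = 0.001 min, by default.  Two further propagators are
provided and cross-checked against each other: scipy's matrix-exponential
action (`expm`) and uniformization (`uniform`), which evaluates the same
exponential through a Poisson mixture of powers of the substochastic
matrix I + Q/Λ and is the fastest backend on this problem, besides being
nonnegativity-preserving.  The Euler propagator is first-order: its mass
defect against the exact exponential is < 1e-6 per segment, while its
pointwise L1 deviation is of order 1e-5 at Δt = 0.001; the
matrix-exponential backends agree with each other to < 1e-9.

Replication applies R: (s1, s2) → (s1, s1); division applies the binomial
thinning kernel B(m|k) = C(k,m)2^(−k) and the collapse V: (s1, s2) →
(s1, OFF); B and V commute.  Whole cycles (propagate → R → propagate →
B·V) are iterated until the start-of-cycle vector changes by less than
1e-6 in L1; iterates are renormalised between cycles so that truncation
leakage (reported separately, warned above 1e-6) cannot mask convergence.
The converged solution is recorded at 20 evenly spaced times, taken at
window midpoints (j+½)·tdiv/20 so no record point collides with the
replication or division discontinuities.  The truncation default is
mean + 10·sd + 20 with the telegraph Fano factor supplying the variance,
capped at 1500.

Cell-level (two-locus) mature distributions are one autoconvolution of the
locus solution; nascent distributions are one autoconvolution of the
single-copy distribution before `trep` and two successive autoconvolutions
after.

The nascent distribution itself cannot live inside the CME state (a
deterministic delay is non-Markovian), so it is computed by a seeded
semi-analytic Monte Carlo: the gene state at the start of the trailing
residence window is drawn from the regime's stationary telegraph marginal,
the state path over the window is simulated exactly, initiations are
Poisson within ON intervals, each transcript contributes its elongated
fraction, and the summed signal is rounded to the nearest integer (.5
rounds up).  Using the regime-wise *stationary* marginal (rather than the
time-dependent one) matches the closed-form mean
⟨n⟩ = λ·g·kini·tres·kon′/(kon′+koff) at every time point and mirrors the
steady-nascent argument used to derive the η→α mapping; the transient of
mixed regimes within one residence window of `trep` is ignored (`tres` ≪
`tdiv`).

## Inference

Observed counts are rounded to integers (.5 up) and times to the nearest
of the 20 solver time points (midway times round down).  The
log-likelihood is Σ_i log Pmat(m_i, t_i) + log Pnas(n_i, t_i); zero-model-
probability observations contribute log(1e-12) and are counted in a
warning instead of producing −∞.

The canonical scan is log-spaced, 10⁻³–10² min⁻¹ at 10^0.2 steps, with
1/tres fitted on the same grid in principle; a full 4-D scan at this
resolution (26⁴ libraries, each an FSP solve) is far beyond a desk-scale
budget.  The default therefore (i) centres a window of ±2 coarse steps per
axis on cheap moment estimates — duty cycle from the mean/variance of
pre-replication nascent totals treated as a promoter-gated compound
Poisson, `kini` from the mean, `kon+koff` from the mature Fano factor —
(ii) scans that window at coarse resolution with `tres` on a short
sub-grid, and (iii) refines by coordinate descent at 10^0.025 resolution
over ±10^0.5 (one axis at a time, repeated sweeps configurable).  The
moment centre only positions the window; the likelihood does the fitting,
and a `budget` option thins the grid deterministically.  An optimum on the
window boundary raises a "range exhausted" warning.  Libraries are cached
per parameter set, and the nascent Monte Carlo seed is derived
deterministically from the scan seed and the parameter set.

## Deterministic mean model

dR/dt = g(t)·kini − kd·R with g = 1→2 at `trep` and the cyclostationary
boundary condition R(tdiv) = 2R(0) has a piecewise-exponential closed form
(continuous at `trep`; exponentials are evaluated on shifted arguments so
nascent-scale rates, kd·tdiv ≈ 220, never overflow).  The G2/G1 window
ratio RM uses the analytic integrals over [0, t1) and [t2, tdiv), with t1
and t2 the G1/S and S/G2 boundary ages implied by the phase fractions
under the exponential-growth age density.  RM → 2 as kd·tdiv → ∞ and falls
below 2 when the lifetime is comparable to the cycle — the reason nascent
mRNA doubles between G1 and G2 while mature mRNA does not.  The "7.1-hr
lifetime" of mature mRNA is interpreted as a half-life scale,
kd = ln2/(7.1·60) min⁻¹; both conventions are trivial to switch via `kd`.

## Known limitations and caveats

- **Step-fit fold on compensated genes is upward-biased.**  The η→α
  mapping equates 2η with the ratio of *stationary* duty cycles.  But in
  the cyclostationary model the compensated promoter state persists
  through division (early-G1 cells start at the post-replication duty and
  relax back over 1/(kon+koff), ≈ 35–110 min for the default rate scale)
  and active states are inherited at replication (early-post cells sit
  above the compensated duty).  Both effects raise the measured window
  fold above 2η for slowly switching genes; the effect is absent at
  α = 1 and grows as switching slows.  The package reports the measured
  fold as-is; the phase-gated estimator is less affected because its
  windows exclude the transition region, and the two agree within
  combined uncertainties at moderate switching rates.
- The χ² allele-independence test uses 1 degree of freedom (3 categories,
  1 fitted parameter); configurable.
- Transcription-site counts above the known copy number (unresolved sister
  chromatids) are clipped with a warning, not treated as errors.
- Problem sizes used in the test suite (e.g. 10⁴ oracle lineages per time
  point, 600-cell inference datasets, ±2-step scan windows) are the
  package's default desk-scale choices; all are parameters.
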