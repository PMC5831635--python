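# Methods

## The core-clock model

The core model is a deterministic ODE description of the mammalian circadian
transcription–translation network with two interlocked feedback loops:

1. **PER/CRY loop.** CLOCK/BMAL1 activates transcription of *Per2*, *Cry*,
   *Rev-Erb* and *Ror*.  PER protein is phosphorylated in the cytoplasm,
   binds CRY (both phosphorylated and unphosphorylated complexes form), and
   the complexes shuttle into the nucleus where their total represses
   CLOCK/BMAL1-driven transcription.
2. **REV/ROR loop.** Nuclear REV-ERB represses and nuclear ROR activates
   *Bmal1* transcription; BMAL1 protein shuttles into the nucleus and matures
   into the transcriptionally active CLOCK/BMAL1 species.  Nuclear REV-ERB
   additionally represses *Cry* transcription, which is what couples *Bmal1*
   overdrive back into the PER/CRY oscillator.

There are 19 state variables (5 mRNAs, 14 proteins/complexes; the ordering
is fixed and documented in `per2as.model`) and 71 core rate constants, all
in units of hours and dimensionless concentrations.  Clock-gene
transcription uses the saturating activator/repressor form
`a·Vmax·[(1/a) + act^b] / [1 + act^b(1 + rep^c)]`, whose basal rate at zero
activator is `Vmax` and whose maximum is `a·Vmax`; *Bmal1* uses the
competitive form `a5·V5max·[(1/a5) + act] / [1 + act + rep]` with ROR_n as
activator and REV_n as repressor.  All protein steps are first- or
second-order mass action; there are no Michaelis–Menten saturations in the
protein layer.

Antisense extensions (pre-transcriptional interference, post-transcriptional
duplex formation, and the combined irreversible-duplex model) are written as
composable terms on top of the core *Per2* equation; their forms are given in
the README.  The mutant vocabulary consists of an exogenous *Ror*
transcription rate `y4_0` (a constant source in the *Ror* mRNA equation), a
nuclear REV-ERB clamp `x5_0` (the constant is substituted into every term
referencing REV_n and the REV_n derivative is zeroed, keeping the state
dimension uniform), and per-gene dosage multipliers on the `V*max` scales
(knock-out = 0, over-expression > 1).

## The wild-type parameterization

`data/wt.params` is a **calibrated parameter table, not a transcription of a
published one**.  Three constants are fixed a priori to their conventional
wild-type values — fold activation `a = 12`, *Per2* dosage `V1max = 1`,
*Per2* mRNA decay `d_y1 = 0.3 /h` — together with the antisense defaults
`mu = 1`, `lam = 1` and duplex constants `k_assn = k_diss = d_dup = 0.1`.
The remaining rate constants were calibrated (stochastic search over
log-parameter space, performed once, before the test suite was frozen)
against the wild-type phenotypes the model family is known for:

- sustained limit cycle of the pre-transcriptional model at `mu = lam = 1`
  with period ≈ 23.5 h and *Per2* amplitude above the 0.5 classification
  floor;
- *Per2AS* peaking at ≈ 5% of the *Per2* peak, ≈ 12 h out of phase;
- a slow (~50 h) rhythm carried by the autonomous REV/ROR loop when *Per2*
  transcription is strongly reduced (small `mu`), with an amplitude collapse
  of *Per2* near `mu ≈ 0.12`;
- loss of rhythmicity when exogenous *Ror* transcription `y4_0` exceeds ≈ 8,
  mediated by REV-ERB repression of *Cry* starving the PER/CRY loop;
- a stable steady state when nuclear REV-ERB is clamped at `x5_0 = 2.4`.

What the calibrated table reproduces, it reproduces as *structure of this
parameterization*; quantities that depend on fine details of any other
parameterization of the same network (exact Hopf-point abscissae, behaviour
of the emergent rhythms at strong *Ror* + antisense overexpression, the
position of iso-period loci in the combined model) will differ and are
treated as qualitative rather than printed-value checks in the test suite —
the acceptance tests announce this downgrade with a warning at run time.
Known quantitative properties of this table, computed by
`scripts/acceptance.py`: phase offset 11.1 h (just inside the 11–13 h
antiphasic band); circadian-branch amplitude maximal near `mu ≈ 1.65`; three
Hopf points on the μ-scan over [0, 3] (the slow branch reaches `mu = 0`
because the REV/ROR loop is autonomously oscillatory); rhythm loss at
`y4_0 ≈ 8.1`; the combined model's 23.5 h locus crossing `mu = 1` at
`lam1 ≈ 5.5`.

## Rhythm metrics

Simulations use LSODA (stiff-capable) with `rtol 1e-8`, `atol 1e-10`, a
documented default initial state, a discarded transient (default 500 h;
analysis-grade runs in the tests use 1000–2300 h because the wild-type
cycle's amplitude relaxes slowly) and a uniform output grid (default
0.1 h).  Hill-term inputs are clipped at zero because adaptive solvers may
probe marginally negative states.

- **Period**: mean peak-to-peak interval after quadratic interpolation of
  local maxima.  A species is *non-oscillatory* when its relative envelope
  `(max − min)/mean` is below `1e-3` or its peak intervals vary by more than
  5% — both constants are explicit in `per2as.rhythms` since "oscillatory"
  has no canonical definition.  An independent autocorrelation estimator is
  provided as a cross-check (agreement within 1% on clean cycles).
- **Amplitude**: per-species max and min over a whole number of cycles.
- **Phase**: peak time relative to a reference species (*Per2AS* by
  convention, phase ≡ 0), modulo the period, averaged circularly across
  cycles.  Phase differences are reported as circular distances in hours.
- **Classification**: a rhythm is *circadian-antiphasic* when
  `23 h < T < 25 h`, *Per2* amplitude `> 0.5` (model concentration units)
  and `11 h < |φ_Per2 − φ_Per2AS| < 13 h`; a tighter `23.2–23.7 h` period
  band is provided for two-parameter classification maps.  All bounds live
  in a criteria object, not in code.

## Bifurcation analysis

Pseudo-arclength continuation is deliberately replaced by **grid scanning
with solution reuse plus bisection refinement**: steady states are tracked
across a parameter grid by damped Newton iteration (residual tolerance
`1e-9·(1+‖x‖)`, at most 200 iterations, restart from a long integration on
failure) with central finite-difference Jacobians (relative step `1e-6`),
eigenvalues from the dense Jacobian, and every sign change of the leading
real part refined by bisection to `|Re λ| < 1e-6`.  The crossing frequency
is the imaginary part of the complex pair with the largest real part among
eigenvalues with `|Im| > 1e-4 rad/h`.  Oscillation envelopes and periods
along a branch come from simulation, not Floquet continuation.  Iso-period
loci bisect the simulated period to 0.02 h in the second parameter, with
multiple roots per slice all reported.  This is adequate for the scans and
loci this package produces and is a declared limitation for strongly folded
branches; the circadian onset of this parameterization is weakly
subcritical (a small-amplitude cycle coexists with the stable steady state
over ≈ 0.3 in `mu` below the crossing), so Hopf positions and simulated
onset agree only up to that band.

## Ensemble fitting

`fit_cost` is a weighted sum of (i) peak-normalized mean squared error
between model output and data at the sample times, aligned by the best
circular time shift (grid of 64 shifts, parabolic refinement) — rhythmic
expression data carry neither absolute units nor absolute phase; (ii)
quadratic penalties for the period and the *Per2*/*Per2AS* phase difference
leaving their target windows; (iii) penalties for violated qualitative
mutant behaviours.  Failed simulations return a large finite sentinel cost
so samplers survive pathological proposals.  `ensemble_fit` is a Metropolis
random walk in log-parameter space (rate constants span decades) with hard
reflection at the bounds and a step size adapted every 50 proposals toward
a 20–40% acceptance rate; *all* visited parameter sets below a cost
threshold are retained, yielding an ensemble rather than a point estimate.
Runs are deterministic given the seed.

Identifiability note: peak normalization removes each species' scale, so
the antisense synthesis rate and its interference threshold enter the
normalized observables only through ratios (`lam/K_AS`; and `K_S` nearly
cancels when it is far below typical *Per2* levels).  Under these observables the
interference strength `mu` is point-identified (it shapes the *Per2*
waveform and period), while the antisense decay rate `d_AS` is identified
only from below: once the filter is fast relative to the cycle
(`d_AS >> 2*pi/T`), further increases barely change the normalized
*Per2AS* signal.  The recovery checks therefore assert a point estimate
for `mu` and an ensemble lower bound for `d_AS` — a concrete illustration
of why ensembles, not point fits, are the right output here.

## Synthetic data

`generate_waveform_dataset` emulates liver time-course measurements as
raised cosines: unit-peak *Per2*, *Per2AS* scaled to a configurable peak
ratio (default 0.05) and shifted by a configurable offset (default 12 h),
sampled every 2 h over 2 days by default, with multiplicative log-normal
noise (expression data are positive and heteroscedastic; additive Gaussian
noise is available).  `generate_model_dataset` samples the model's own
attractor, peak-normalized, with the same noise models.  Datasets carry
metadata sufficient for bit-identical regeneration.  What the generator does
*not* emulate: replicate structure, count noise of sequencing data, dampened
population-level rhythms, or inter-animal variability — so passing fits on
synthetic data demonstrate correctness of the machinery, not performance on
real measurements.  Period estimation on coarsely sampled datasets uses an
autocorrelation seed refined by a least-squares harmonic fit and refuses to
report a period with fewer than ~4 samples per cycle (aliasing guard).

## Known limitations

- The wild-type table is a calibration: network topology and the anchored
  constants are faithful, everything else is this package's own fit to the
  stated phenotypes.  Quantities downstream of the unavailable original
  parameterization deviate (documented above) and are checked structurally.
- The antiphase of the calibrated cycle (11.0–11.4 h depending on variant
  and window) sits just inside the 11–13 h classification band; analyses
  sensitive to that margin should widen the band via the criteria object.
- No Floquet analysis, period-doubling or torus detection; fold-over of
  strongly subcritical branches is only visible through simulation.
- Stability analysis of the REV-ERB clamp replaces the frozen direction by
  an algebraic constraint, contributing an artificial (harmless) eigenvalue
  of −1.
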