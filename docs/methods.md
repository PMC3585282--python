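# Methods

## The cell-covered electrode model

`ecisfit` analyses ECIS frequency scans with the model of Lo, Ferrier and
Giaever.  A confluent monolayer on a small gold electrode is treated as
disc-shaped cells of radius r_c hovering a distance h above the surface.
Current leaving the electrode under a cell either flows radially through
the thin cell-substrate channel and out through the intercellular
junctions (paracellular path) or crosses the two cell membranes in series
(transcellular path).  Solving the radial cable equation yields the
specific impedance of the cell-covered electrode in terms of the
*measured* cell-free impedance Z_n(f) and three constants:

    1/Z_c = (1/Z_n)·[ Z_n/(Z_n+Z_m) + (Z_m/(Z_n+Z_m)) /
                      ( (γ/2)·I₀(γ)/I₁(γ) + R_b·(1/Z_n + 1/Z_m) ) ],
    γ = α·√(1/Z_n + 1/Z_m),      Z_m = 1/(jπf·C_m).

Assumptions inherited from the model: an intact, confluent monolayer
(R_b ≈ 0 with α preserved marks the edge of validity, as in cadherin
depletion); cells electrically equivalent and disc-like; the reference
electrode carries all electrode-interface physics, which the model passes
through rather than explains.

Conventions (recorded in `ecisfit.model.CONVENTIONS` and in every output's
metadata):

* time dependence e^{+jωt}: capacitive impedances have Im(Z) < 0;
* C_m is the capacitance of ONE membrane; two identical membranes in
  series give Z_m = 1/(jπf·C_m).  The alternative convention (C_m already
  the series value) rescales fitted C_m by 2 — comparisons across software
  must check this;
* γ uses the principal square root; Re(1/Z_n + 1/Z_m) > 0 in all physical
  cases, keeping Re(γ) > 0;
* α = 0 is evaluated through the analytic small-argument limit
  (γ/2)·I₀/I₁ → 1, so the no-cell reduction Z_c = Z_n is exact;
* specific impedance = measured Ω × electrode area.  The default
  geometry is an 8W10E-style array, 10 circular 250 µm electrodes,
  4.91×10⁻³ cm² total; the area is configurable because array vendors do
  not publish it, and whether multi-electrode wells should use total or
  per-electrode area is left to the user (total is the default).

I₀(γ)/I₁(γ) is evaluated with exponentially scaled modified Bessel
functions (`scipy.special.ive`); the scaling cancels in the ratio, which
is stable from |γ| ~ 1e−12 (where the ratio ~ 2/γ) to arbitrarily large
arguments (ratio → 1).  Tests verify it against a 250-term power-series
oracle summed in 80-digit decimal arithmetic — float64 summation is
meaningless at large |γ| with arg(γ) near ±π/2, where series terms cancel
by tens of orders of magnitude.

## Spectrum fitting

`fit_monolayer` estimates (α, R_b, C_m) from one cell-covered scan fitted
*in relation to* a cell-free reference scan:

* **Window 62.5–16000 Hz** (inclusive).  Above ~16 kHz real measurements
  carry a strong inductive lead component the model cannot represent;
  below 62.5 Hz the scan contributes little and acquisition is slow.
* **Reference handling.**  The reference scan is used as measured —
  aligned onto the cell scan's windowed grid by interpolation, linear in
  log-frequency, real and imaginary parts independently; it is not itself
  modelled.
* **Objective.**  Sum over windowed frequencies of |Z_model − Z_meas|²
  normalised per frequency.  Relative weighting divides by the *model*
  magnitude, recomputed every iteration: dividing by the measured
  magnitude correlates the weights with the noise and biases all
  parameters low (a standard pitfall of proportionally weighted complex
  nonlinear least squares).  Absolute weighting is available via
  `FitOptions.weighting`.
* **Optimisation.**  Parameters in log-space under bounds
  (default upper [1e3, 1e4, 1e2], lower clamped to a tiny positive
  floor so R_b → 0 is representable), trust-region reflective least
  squares, one physically motivated start (R_b from the low-frequency
  real-part excess, α from the mid-frequency magnitude ratio,
  C_m = 2 µF/cm²) plus 8 log-uniform random starts drawn deterministically
  from `FitOptions.seed`.  Ties are broken by lowest rms, then lowest R_b.
  Identical inputs and seed give bit-identical results.
* **Diagnostics.**  rms relative residual (against |Z_meas|),
  per-frequency residuals, convergence flag, and a curvature-based
  (Gauss–Newton) confidence interval for C_m.  QC flags: `LOW_BARRIER`
  (R_b < 0.2 Ω·cm² — the intact-monolayer requirement is at its edge),
  `POOR_FIT` (rms > 0.05), `UNSTABLE_CM` (the 95% CI for C_m spans more
  than a decade, as happens when a collapsed barrier shorts the membrane
  path and leaves C_m unidentified).  Pre- and post-stimulation scans are
  always fitted independently.

## Timecourse and statistics

Single-frequency traces (default 4000 Hz) support the absolute-value
plot, the legacy series-RC interpretation (r = Re Z,
c = −1/(2πf·Im Z), undefined for non-capacitive points), and pre/post
summaries: mean |Z| over the 30 samples before the stimulus and over
everything from 10 simulated minutes after it (responses need settling
time before a plateau mean is meaningful); both windows overridable.

The experimental unit is the independent experiment: electrode values are
averaged within an experiment (typically N = 4), and statistics run on
the per-experiment means.  One-way fixed-effects ANOVA is rendered
`A(F;P)`; two-condition contrasts use Student's t-test — paired across
experiments for impedance and colocalization readouts, unpaired for qPCR.
"Student's" is taken literally: the unpaired default pools variances;
Welch is an option.  The statistics are computed from their closed forms
with scipy distributions supplying P-values, and the test suite checks
them against `scipy.stats` as an independent reference.  Degenerate
inputs (all-identical groups → F = 0, P = 1; zero within-variance with
unequal means → F = ∞ with a below-machine P marker; zero-variance
differences → an explicitly flagged degenerate t result) never raise from
valid data.  qPCR uses ΔCt against a reference gene (default HPRT) and
ΔΔCt against a common reference sample; per-sample loading offsets cancel
exactly in ΔCt.  **No multiple-testing correction is applied** — this
matches common practice for this assay and is a documented limitation,
not an endorsement.

## Colocalization

Junctional actin is quantified from paired junction-marker/F-actin
images: each channel is segmented by threshold (Otsu by default; fixed
thresholds available) and the correlation coefficient of the two binary
masks over all pixels is reported (0 = random, 1 = perfect correlation).
Mask correlation equals the phi coefficient of the 2×2 pixel contingency
table and is invariant to channel rescaling.  Whether the historical
ImageJ plugin correlated masks or masked intensities is not recoverable;
both are implemented (`method="mask"` is the default,
`method="intensity"` restricts Pearson to the union mask) and worth
reporting together when they disagree by more than ~0.1.  Images of one
experiment are averaged (typically 5) and feed the same per-experiment
statistics as the impedance readouts.  Edge pixels are included; no
background subtraction is applied.

## Synthetic data

No public raw impedance data accompany this experimental design, so the
generator produces every input with the statistical structure the
analysis assumes; ground truth always accompanies generated data, and all
generators are deterministic under their seed.

* **Reference electrode:** constant-phase element plus solution
  resistance, Z_int = R_sol + 1/(Q·(j2πf)^β), defaults
  Q = 30 µS·s^β/cm², β = 0.95, R_sol = 2 Ω·cm² — typical of gold
  microelectrodes.  The measured spectrum adds a series lead artifact
  Z_art = j2πf·L/(1 − (f/f_res)²) (L = 2×10⁻⁷ H·cm², f_res = 70 kHz): a
  lead inductance resonating with its stray capacitance, inductive and
  steeply growing below resonance.  The default reference's imaginary
  part changes sign near 55 kHz — inside the acquisition range, above the
  analysis window.  A pure jωL artifact common to both wells would
  largely cancel through the model (Z_c → Z_n + Z_m at high frequency);
  what the fit cannot absorb is the *well-to-well* difference in lead
  artifacts, so the window study contrasts a cell well with 4×10⁻⁷ H·cm²
  leads against the 2×10⁻⁷ reference well.  Measured on the baseline
  parameters: windowed fits shift < 0.4% from truth while full-range fits
  shift ~9% — the quantitative rationale for the 62.5–16000 Hz window.
* **Cell scans** are computed from the noiseless interface model through
  the forward model, the well's own lead artifact is added, and
  multiplicative complex Gaussian noise is applied independently of any
  reference realisation.  Cell wells default to 1% relative noise
  (instrument plus the micromotion of a live monolayer); the cell-free
  reference well is far quieter and gets 0.1% instrument-only noise.
* **Baseline parameters** α = 6 Ω^0.5·cm, R_b = 4 Ω·cm²,
  C_m = 1.8 µF/cm² are plausible values for confluent endothelial
  monolayers, fixed as study conditions; they are configuration, not
  measurements.  α may alternatively be derived from a microscopic triple
  (r_c, ρ, h).
* **Replicate structure:** per-experiment and per-electrode mean-one
  log-normal parameter multipliers (CV 15% and 5%), 4 electrodes per
  experiment, treatment factors applied between the pre and post scan of
  each electrode so the contrast is paired.  Condition presets encode the
  emulated effect directions: `007AM` R_b×1.5 with a small C_m effect
  (n = 8 experiments), `siRap1` ×0.6 (n = 8), `siRap2` ×2 (n = 6),
  `siRap1+siRap2` ×1 (n = 4), and `siCadherin` R_b → 0.05 Ω·cm² with α
  preserved and C_m halved (n = 4) — the collapsed-barrier control in
  which C_m becomes poorly identified.
* **Frequency grids.**  The compact doubling series 31.25 Hz → 64 kHz
  (12 points) is the default for single scans and leaves out-of-window
  points on both sides of the analysis window.  The replicate-experiment
  and recovery studies scan at instrument density (4 points/octave, 45
  points): analysers record considerably denser scans than the doubling
  summary, and the attainable precision of small fitted R_b depends
  directly on that density (the Cramér–Rao σ(R_b) at the
  collapsed-barrier truth is ≈0.10 Ω·cm² on the 9 windowed doubling
  points but ≈0.05 Ω·cm² on the dense grid).
* **Timecourses** evolve the parameters toward the condition's factors
  after the stimulus, either instantly or along 1 − exp(−Δt/τ)
  (τ = 10 min), and evaluate the forward model at 4000 Hz.
* **Images** render a Voronoi cell mosaic: the junction channel is the
  blurred cell-boundary network; the actin channel mixes a fraction w of
  junctional signal with (1 − w) transverse stress-fiber stripes of
  random orientation per cell, plus blur and Gaussian noise.  w = 1 with
  zero noise makes the channels identical (CC = 1); mean CC increases
  monotonically in w.
* **Ct tables:** Ct = baseline − log₂(expression fraction) + noise
  (0.15 cycles per measurement), a global per-sample offset (sd 0.3
  cycles) that must cancel in ΔCt, reference gene HPRT at Ct 20, targets
  at Ct 24, and an untreated reference sample per experiment.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: electrode drift and temperature effects, cell
micromotion spectra (noise is white), mixed or sub-confluent coverage,
well-to-well CPE parameter variation, qPCR efficiency differences between
genes, and optical artifacts (uneven illumination, bleed-through) in the
images.

## Verification problem sizes

The test suite and the acceptance script work at desk scale, chosen to
keep every property measurable with comfortable margins: noiseless
recovery on a 3×3×3 parameter grid (≤0.1% error demanded, machine
precision observed); a 50-draw Monte-Carlo recovery study at 1% noise
(median error ≤5%, per-parameter bias ≤2%); condition presets at their
stated experiment counts; 100 random fixtures for the statistics
cross-check; 256×256 images in triplicate per junctionality level.  The
full acceptance script completes in about half a minute on one CPU.

## Known limitations

* The model treats the monolayer as homogeneous; partial coverage or
  wounded monolayers violate it silently (the QC flags catch only the
  collapsed-barrier case).
* The C_m confidence interval is a local curvature approximation; it
  under-covers when the residual surface is strongly non-quadratic,
  exactly the near-degenerate regime it is meant to flag.
* At 1% noise, α below ~2 Ω^0.5·cm with large R_b is weakly identified on
  windowed scans: the noisy-objective global minimum can sit far from the
  truth (verified by direct cost comparison), so occasional large α
  errors are a property of the problem, not the optimiser.
* The vendor software's exact objective, start heuristics and C_m
  convention are unknown; absolute fitted values may differ between tools
  even on identical data, which is why the conventions travel with every
  output.
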