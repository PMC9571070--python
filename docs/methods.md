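# Methods

This note documents the models behind `trifret`, the defaults and why they
were chosen, what the synthetic data emulate (and do not), and the numerical
choices that affect results.

## Förster theory

Pairwise transfer follows standard Förster kinetics. The overlap integral
J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ is evaluated by trapezoidal quadrature on a common
1 nm working grid (300–800 nm); spectra are linearly interpolated inside
their measured range and zero outside, since physical spectra vanish beyond
it. With f_D a unit-area density (1/nm) and ε_A in M⁻¹cm⁻¹, J carries
M⁻¹cm⁻¹nm⁴ and the Förster radius is

    R0 [nm] = 0.02108 · (κ² · n⁻⁴ · Q_D · J)^(1/6)

(the 0.211 Å-convention constant converted to nm). Defaults κ² = 2/3
(isotropic dynamic averaging) and n = 1.4 (protein-crowded aqueous
environment) are both overridable; no κ² distribution modelling is
attempted. For a donor with N equivalent acceptors the transfer channels add,
E = N(R0/r)⁶ / (1 + N(R0/r)⁶), inverted in closed form by
r = R0 (N(1−E)/E)^(1/6). Internal values keep full precision; reported
distances are conventionally rounded to 0.1 nm.

## Cascade model

The three-fluorophore arrangement is collinear: the intermediate A1 sits at
distance x from the donor on the D–A2 axis of length r. Relative to the
donor's unit decay rate the transfer rates are u₁ = (R0_DA1/x)⁶ and
u₂ = (R0_DA2/r)⁶, so a donor excitation reaches A1 with u₁/(1+u₁+u₂), A2
directly with u₂/(1+u₁+u₂), and otherwise decays on the donor; a quantum on
A1 hops on with v/(1+v), v = (R0_A1A2/(r−x))⁶. Back-transfer and photon
re-absorption are neglected (uphill spectral overlap is negligible for a
blue→yellow→red triple). Energy bookkeeping is exact: retained + transferred
fractions sum to 1 to machine precision.

The effective range at a target efficiency (default 10%, the operational
detection limit) is solved by Brent bracketing on r ∈ [0.5, 50] nm to
1e-4 nm. Random intermediate placement is uniform on the open 1-D segment
between donor and terminal acceptor, 1000 samples by default; the same
uniform fractions are reused at every root-search iterate (common random
numbers), which keeps the Monte-Carlo objective strictly monotone in r and
makes the root unique. A 3-D variant (uniform in the ball having the D–A2
segment as diameter) is available as `placement="random3d"` for sensitivity
analysis; it yields shorter effective ranges because off-axis positions are
farther from both endpoints. A mandatory seed makes all ranges reproducible;
at 1000 samples the seed-to-seed spread of the random-placement range is
below 0.15 nm.

## Spectral forward model

A scene is a set of (fluorophore, abundance) pairs, a pairwise transfer
matrix E_ij (row sums ≤ 1, downhill in energy only), and one excitation
line. Member i absorbs abundance_i·ε_i(λ_ex) quanta — acceptor
cross-excitation falls out automatically — quanta flow along the transfer
matrix in energy order, and each member emits (absorbed − transferred)·Q_i
into its unit-area emission density. Everything is linear in abundances at
fixed transfer; intensities are arbitrary units with one global gain
(absolute radiometry is out of scope). Cross-excited intermediate quanta do
relay onward to the terminal acceptor by default; the
`relay_cross_excitation` flag disables that pathway for sensitivity checks.

λ-stacks integrate the piecewise-linear spectrum over [start, start+Δ) bins
(exact for the interpolant, hence partition-additive); the default detector
dialect is 460–625 nm at Δ7.5 nm (22 bins) with sequential channels
458/514/561 nm → 465–505/525–565/605–650 nm. Channel intensities re-simulate
the scene at each channel's line, so bleed-through is included.

### Bundled stand-in spectra

The packaged mTRQ2/mVEN/mRFP records are synthetic Gaussians (emission peaks
474/528/607 nm), not digitized spectra: real spectra are asymmetric with
vibronic structure, so overlap integrals computed from the stand-ins land
near but not on the published Förster radii (5.4 vs 5.7 nm for the
donor/intermediate pair). The intermediate's absorption Gaussian is
broadened (σ = 26 nm) to mimic the blue vibronic shoulder of yellow
fluorescent proteins; without it the well-documented cross-excitation peak
near 525 nm under 458 nm excitation would be artificially suppressed. All
range calculations therefore take the published radii as inputs rather than
deriving them from the stand-ins, and users can load digitized spectra via
`load_spectrum` when quantitative J/R0 values are needed.

## Unmixing and ratio matching

Unmixing is non-negative least squares against references binned on the same
dialect as the data (never the un-binned continuum, avoiding binning bias),
with an optional flat non-negative background column (default on; turn it
off for offset-free data — the extra degree of freedom otherwise soaks
correlated noise into the proportions). Collinear or rank-deficient
reference sets are rejected by name. Proportions are scale-invariant.

Donor-to-acceptor protein ratios solve `response @ abundances = channels`,
where the response matrix holds each pure member's contribution to each
sequential channel; negative solutions are clamped with a warning and a zero
acceptor yields an `inf` sentinel. Ratio-matched comparison keeps only
samples inside the ratio band common to both groups, widened by a relative
tolerance (default ±25%, which keeps nominal 1:4 and 1:10 populations
apart), requires ≥3 survivors per group, and reports means, difference and
the raw arrays — significance testing is deliberately delegated to standard
statistical routines.

The three-chromophore spectral signature combines a terminal-band
(600–625 nm) excess over the donor-only baseline with an intermediate-band
(515–535 nm) drop against the donor+intermediate reference, on unit-total
normalized stacks. The thresholds (0.003 and 0.005 of total intensity) were
sized by propagating the default 2% spectral noise through 20-ROI condition
means: ≥3σ below the ternary ground-truth signals and ≥3σ above the noise
floor of negative conditions. They are appropriate for condition-averaged
stacks; single noisy ROIs need larger thresholds or averaging first.

## TCSPC model and fitting

Decays live on one repetition period (25 ns at 40 MHz, 1024 bins by
default). The model is the periodic steady state exp(−t/τ)/(1−exp(−T/τ))
circularly convolved with a unit-area Gaussian IRF (default FWHM 0.2 ns,
centred 2 ns into the window) — incomplete decay between pulses appears as a
pre-pulse baseline of the model itself, not a correction. Simulated
histograms are multinomial draws of the photon budget over bins, so totals
are exact and seeds reproduce bit-for-bit.

Fitting minimizes the Poisson deviance (counting-statistics MLE; weighted
least squares misbehaves in low-count bins). With the model total pinned to
the observed total, the problem is multinomial: mono-exponential fits reduce
to a bounded Brent search over log τ (τ ∈ [0.05, 20] ns), biexponential fits
to Nelder-Mead over (log τ₁, log τ₂, log amplitude ratio), seeded by a
log-linear tail regression (which also serves as an independent fast
estimator). An optional IRF timing shift is fitted on request; model order
(mono for donor-only, bi for FRET samples) follows explicit user request
rather than automatic selection, with the reduced deviance reported as an
advisory statistic. The headline statistic is the intensity-weighted average
lifetime τ̄ = Σaᵢτᵢ²/Σaᵢτᵢ, which is stable under overparameterization
(fitting two components to a mono-exponential moves τ̄ by <1%).

### Ternary excess-quenching decision

Donor quenching gives E = 1 − τ_DA/τ_D. The decision rule computes the
binary limit (the smaller of the two binary-condition means) and the excess
Δ = binary_limit − ternary_mean; "supported" requires Δ > 0 with
non-overlapping mean ± SEM bands. SEM (not SD) bands implement the intended
question — is the *mean* lifetime significantly lower — as an approximate
two-sample comparison at the z ≈ 1.4 level; population SDs are still
reported, and the raw lifetime arrays pass through for external tests
(t-test at small n, rank tests otherwise).

## Synthetic scenarios

Presets mirror the study's co-expression conditions: donor alone, donor with
one acceptor, the full cascade, an uncoupled-bystander control and a
non-interacting (FLS2-like) control. Defaults are the study regime:
1:1:1 stoichiometry, the 7 nm equidistant cascade geometry, donor lifetimes
3.99 / 3.54 / 3.40 ns (unquenched / binary / ternary) with 0.05 ns ROI-to-ROI
spread, 2% spectral noise with 8-bit quantization (clean peak mapped to
200 a.u., saturation at 255), and 5×10⁵ photons per decay. Expression levels
get a modest lognormal jitter (σ = 0.1) to mimic transient-transformation
variability.

The preset lifetimes are the measured study values rather than the lifetimes
the 7 nm spectral geometry would imply (which would be shorter): in real
samples incomplete acceptor maturation and unlabeled endogenous protein
dilute the donor-side quenching below the geometric efficiency, and the
presets reproduce that observed regime. Consequently the spectral and FLIM
sides of a bundle are each faithful to the data they emulate but are not
derived from a single microscopic parameter set.

What the generator does **not** emulate: spatial image formation (PSF,
pixel-wise unmixing), detector afterpulsing and dead time, autofluorescence
spectra (background is a flat offset), photobleaching, and day-to-day
instrument drift. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated noise model, not robustness
to every artifact of live-cell acquisition.

## Problem sizes

The test suite and the acceptance script run everything at desk scale on one
CPU: 1000 placement samples per cascade range, 100-seed unmixing
calibrations, 50-seed lifetime recoveries at 5×10⁵ photons, and 50–100
seeded replicates of the 20-ROI-per-condition decision pipelines. These
sizes keep Monte-Carlo standard errors several times smaller than every
asserted tolerance.

## Known limitations

- Scalar κ² only; no orientation-factor distributions or linker dynamics.
- Collinear cascade geometry; the 3-D placement variant is exploratory.
- No absolute concentration or radiometric calibration anywhere.
- The bundled spectra are Gaussian stand-ins (see above).
- Biexponential fits with strongly overlapping lifetimes (τ₁/τ₂ ≲ 1.5) are
  ill-conditioned, as in any reconvolution fitter; τ̄ remains reliable.
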