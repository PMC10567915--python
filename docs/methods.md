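# Methods

This note records the models, parameter choices and numerical decisions
behind `mrsquant`, and what the synthetic-data tests do and do not
establish about real data.

## Signal model and fitter

The time-domain model is a sum of exponentially damped complex
sinusoids: each resonance contributes amplitude `A ≥ 0`, chemical shift
(ppm), Lorentzian damping `d > 0` (full width at half maximum in Hz,
decay `e^{−π d t}`) and a zero-order phase.  Multiplets (doublet,
1:2:1 triplet) are part of a resonance: their peaks share all parameters
and sit at offsets ±J/2 or {−J, 0, +J}.  Frequencies follow from
`f = (shift − carrier) · ν₀` with ν₀ = 49.9 MHz (³¹P) or 123.2 MHz (¹H)
at 3 T; the carrier is the PCr position (³¹P) or water at 4.70 ppm (¹H).

Estimation is bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) on the stacked
real/imaginary residual with an analytic Jacobian.  Prior knowledge is
an affine map `full = M · free + c`: fixed parameters and links
(amplitude ratios, shift offsets) are eliminated exactly, so constraint
satisfaction is by construction and covariances propagate linearly.
Starting values: shifts at the priors, dampings at their nominal values
(5 Hz metabolites, 200 Hz macromolecule), phases 0, amplitudes from
magnitude-spectrum peak heights divided by the discrete Lorentzian peak
gain.  Default bounds: shift within ±0.25 ppm of the prior, damping in
[0.05, 1000] Hz, amplitude ≥ 0.  The `t = 0` sample is included; no
first-order phase is fitted (the ³¹P echo time of 2.3 ms is treated as
pure zero-order phase).  Non-convergence within `max_nfev` is flagged on
the result, never raised.

**Error bars.**  The Cramér–Rao lower bound is
`sd = σ · sqrt(diag[(JᵀJ)⁻¹])` on the free parameters at the solution,
pushed through `M`.  The noise σ is the SD of the last 10 % of FID
samples (signal there has decayed by e^{−7} even for 5-Hz lines).
Directions unresolved by the data (singular values below 10⁻¹⁰ of the
largest) are reported as infinite sd rather than silently regularised.

**SNR definition** (declared, since fitting tools differ): the tallest
peak of the magnitude spectrum of the *fitted* model divided by the RMS
of the residual (data − model) spectrum over a designated signal-free
band (by default the positive-frequency band 0.30–0.49 of the
bandwidth, which contains no tissue resonance on either channel).  Using
the residual removes the Lorentzian wings of genuine signal from the
noise estimate; a noiseless input therefore reports infinite SNR, and a
pure-noise input fitted with the standard model stays below the QC
threshold of 3 in ≥ 95 % of runs (measured over 100 seeds).

**Quality control.**  Proton spectra are kept only when SNR > 3 and the
CRLB relative errors of tCr and tCho are below 20 %; phosphorus spectra
are kept when SNR > 3, and individual peaks with relative error above 1
are excluded while the spectrum is retained.

The ¹H channel is fitted with the same engine on a three-singlet model
(tNAA 2.01, tCr 3.03, tCho 3.20 ppm) — a deliberately minimal long-TE
model; basis-set fitting with full spin-system bases is out of scope.

## Standard ³¹P model

Eleven components / fifteen Lorentzian peaks: PE (+6.78 ppm), PC
(+6.24), Pi (+4.77, the position corresponding to pH 6.99), GPE (+3.50),
GPC (+2.96), PCr (0, reference), γ-ATP doublet (−2.5), α-ATP doublet
(−7.5), NAD (−8.3), β-ATP triplet (−16.1), and one very broad
macromolecular component (+2.0 ppm, 200 Hz) carrying the baseline.
ATP J-coupling defaults to 16 Hz with ½/½ and ¼/½/¼ weights.  Shifts are
standard literature positions and are configurable; only shift
*differences* matter for pH and Mg²⁺.  The "standard prior knowledge"
used by the validation studies fixes the zero-order phases and the
macromolecular component's position and width, the usual practice when
the baseline component is part of the prior model; without it the
amplitudes of lines overlapping the broad hump acquire measurable
O(1/SNR²) biases (up to 0.2 CRLB-SD at SNR 10 in our Monte-Carlo runs).

## Quantification

Proton concentrations use the internal-water route

`C = (A_met/R_H,met) / (A_w/R_H,w) · 55 510 · (f_GM·0.78 + f_WM·0.65 + f_CSF·0.97) / (n_met/n_w)`,

with `R_H` the double-spin-echo factor evaluated per metabolite and, for
water, weighted over compartments by volume fraction × water content.
Proton counts (tNAA 3, tCr 3, tCho 9, water 2) normalise signal to
moles; without them the output would not be molar, so the table ships as
explicit configuration.  Phosphorus concentrations use the
phantom-replacement route

`C = C_phantom · (A_met/R_P,met) / (A_phantom/R_phantom) · (U_subject/U_phantom)`,

with `R_P` the steady-state flip-angle/T1 factor, a distinct
configurable T1 (default 5.2 s) for the aqueous KH₂PO₄ resonance, and a
linear coil-loading correction from the transmitter amplitudes `U`
required for a 90° pulse (linear reciprocity; no formula is standard, so
the mechanism is a package choice recorded in the provenance output).
ATP is quantified from the γ-ATP resonance; PME = PE + PC and
PDE = GPE + GPC are summed after per-component relaxation correction.
Both routes end with `C/(1 − f_CSF)`.  Relaxation times are literature
defaults for healthy brain at 3 T, every value overridable in the
configuration; concentration uncertainties propagate the amplitude CRLBs
of metabolite and reference fits in quadrature.

## pH, magnesium, PCr/Cr

The titration constants (6.75, 3.27, 5.63; 4.24, −18.58, −15.74, 0.42,
0.84) live in configuration.  Both maps are strictly monotone on their
open intervals; at or outside the bounds a domain error carrying the
offending shift is raised rather than returning an extrapolated value.
First-order uncertainty propagation from the shift CRLBs agrees with
Monte-Carlo propagation within 10 % for shift SDs up to 0.02 ppm
(tested).  Note on the magnesium inversion: the concentration is the
antilog `[Mg²⁺] = 10^(−pMg)` mol/l (reported in mmol/l); the sometimes
printed form "−log₁₀(pMg)" is dimensionally inconsistent with
physiological values around 0.1 mmol/l and is not implemented.
The PCr/Cr ratio `PCr/(tCr − PCr)` is defined for the volumes where both
channels are acquired (FGM, r_TH, r_TL, r_FWM — the right-hemisphere
list follows from the proton acquisition being right-sided).

## Synthetic cohorts

The generator draws per-subject concentrations log-normally around
group × region × metabolite means (mean-preserving parameterisation),
with published group means as defaults over nine volumes of interest and
groups fN/mN/mC of 21/26/40 subjects.  The inter-subject CV defaults to
15 % — a modelling choice, not a measured value; pH uses 0.5 % since it
varies far less than concentrations.  A subject-level component common
to the left and right voxel of a region (70 % of the log-variance by
default) correlates hemispheres; without it, paired hemispheric tests at
the study's sample sizes could not show the sensitivity that motivates
the paired design.  Voxel contexts draw plausible GM/WM/CSF fractions
per region (normalised to 1) and volumes within 7–18 ml (³¹P) or
8–15 ml (¹H).

**What passing tests show — and don't.**  The generator matches the
fitter's model class exactly (pure Lorentzian lines, white circular
Gaussian noise, no B₀ inhomogeneity, eddy currents, lineshape
distortion, motion, or baseline beyond the single broad component), and
cohorts have log-normal, hemisphere-correlated but otherwise independent
metabolite variation.  Recovery and calibration results therefore
validate the estimator and the statistics under their stated
assumptions; they do not establish accuracy on scanner data, where
lineshape and baseline model error typically dominate CRLBs.  With
CV 15 % and the published mean differences, simulated cohorts also show
*stronger* group significance than the original measurements, whose
within-group variance includes substantial measurement noise.

## Statistics layer

Wilks Λ = det(E)/det(E+H) is computed from within/between cross-product
matrices with Rao's F approximation (exact for two groups); singular or
near-singular E (smallest eigenvalue of the correlation-scaled matrix
below 10⁻¹⁰ of the largest) raises a rank-deficiency error naming the
collinear dependents.  Scheffé p-values use the pooled within-group MSE
over all groups in the region, `p = P[F_{k−1,N−k} ≥ t²/(k−1)]`, which is
conservative against any contrast.  The repeated-measures hemispheric
test is realised as a one-sample Hotelling T² on right-minus-left
difference vectors — equivalent to a within-subject factor with two
levels — both pooled and per group, with paired t tests per metabolite;
subjects lacking either hemisphere raise a pairing error listing their
ids (listwise deletion happens upstream, per region, mirroring per-voxel
QC exclusion).  NAD is excluded from all multivariate tests but remains
representable in the data model.  Percentages are rounded half away from
zero to integers, matching the reporting style of the tables; fractional
values are kept at full precision internally.  Degenerate inputs
(zero-variance cohorts) yield NaN test statistics with warnings rather
than aborting the report.

## Validation studies and problem sizes

The bundled studies (in `mrsquant.validation`, used by the test suite
and the reproduction script) run at 200 replicates each: fitter
calibration on standard ³¹P spectra with SNR drawn uniformly from
10–30, standardising amplitude errors by the exact CRLB at the truth;
quantification round trips (noiseless: < 2 % required; noisy: 95 %
interval coverage at SNR 15); and null-cohort type-I-error rates for
MANOVA (two groups of 500), Scheffé (three study-sized groups), the
hemispheric paired t (26 pairs), and the Bonferroni-screened nine-region
MANOVA family.  Calibration statements about empirical rates carry
binomial sampling error (SD ≈ 1.5 % at 200 replicates); the family-wise
checks therefore test "not significantly above nominal" rather than a
raw cut that a perfectly calibrated pipeline would fail by chance.  The
fitter-bias check applies to the resonances whose worst-case CRLB
relative error over the SNR band is below 20 % (the quality class that
per-peak QC always retains); Pi's empirical scatter genuinely exceeds
1.3× its CRLB at SNR 10 because of its overlap with the broad baseline
component — a known property of weak lines, reported, not hidden.

## Known limitations

- No basis-set (spin-system) fitting, lineshape convolution, or spline
  baselines; the single broad Lorentzian is the only baseline model.
- No B₁/receive-sensitivity mapping or temperature corrections; the
  coil-load correction is linear in the transmitter amplitudes.
- No k-space/CSI reconstruction: the pipeline starts from per-voxel
  FIDs.
- Titration constants carry no temperature or ionic-strength
  corrections.
- The cohort model has no covariates (age, nicotine exposure) and no
  missing-data machinery beyond listwise deletion.
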