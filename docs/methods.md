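# Methods

This note documents the models, parameter choices and numerical decisions
behind `petdsb`, and what the synthetic-data generator does and does not
emulate.

## Blood kinetics

The aortic [18F]FDG concentration is modelled as a three-exponential
surrogate

    c(t) = (A0 / V_blood) · Σᵢ fᵢ 2^(−t/Tᵢ) · 2^(−t/T_phys)

with fast vascular mixing (T₁ = 2 min), intermediate clearance into tissue
(T₂ = 20 min) and a near-constant residual blood pool (T₃ = 5000 min),
damped by physical decay (T_phys = 109.77 min, configurable). The default
fractions f = (0.73, 0.20, 0.07) were calibrated once so that a default
synthetic cohort reproduces the published blood-dose summary: a median
total dose (60 min in vivo + 60 min in vitro) near the middle of the
published 1.5–3.3 mGy range and an in vitro increment of roughly a quarter
of the in vivo dose. With a larger residual fraction the 60-min residual
concentration — which drives the whole in vitro dose — comes out too high
relative to the concentration-time integral.

Per-volunteer variability enters through median-preserving lognormal
multipliers on f₃ and T₂ (both CV 0.25, renormalising the fractions).
These two parameters control the residual level and the clearance rate,
the main sources of the considerable inter-individual dose spread seen in
FDG blood curves; CV 0.25 yields a within-cohort max/min total-dose ratio
of roughly 1.7.

Blood volume uses Nadler's sex-specific anthropometric formula. Measured
time-activity curves (TACs) are emulated on a 55-frame schedule over
[0, 3600] s (12×5, 6×10, 8×30, 9×60, 20×135 s) with multiplicative
lognormal ROI noise (default CV 0.05) at frame midpoints. TAC integration
is trapezoidal through the midpoint concentrations; on the default
schedule it agrees with the closed-form integral of the exponential model
to better than 2 % (tested).

## Dosimetry

Doses are MIRD-style products of cumulated activity and energy deposited
per decay, with blood treated as water of density 1 g/ml.

*In vivo* (0–60 min p.i.): the β self-dose integrates the TAC with an
absorbed fraction of 1 (positron range ≪ vessel dimensions); the photon
cross-fire term assumes complete whole-body retention of the administered
activity, a uniform source, and a whole-body absorbed fraction
φ_γ = 0.33 for the 2 × 511 keV annihilation quanta, with the volunteer's
body mass as target mass. The full β⁺ spectrum is collapsed to its mean
energy (0.2498 MeV) times the positron yield (0.9686); for absorbed
fractions near 1 the spectral detail is a second-order effect.

*In vitro*: the sample's residual concentration (last TAC frame) decays
physically during incubation; the absorbed dose uses tube-specific
absorbed fractions φ_β(V), φ_γ(V) for blood volumes of 3.0–7.5 ml in an
idealised 15-ml conical centrifuge tube (frustum from 1.5 mm tip radius to
7.5 mm inner radius over 20 mm, cylinder above; water-equivalent walls).
The SAF Monte Carlo uses straight-line electron transport with a fixed
0.6-mm CSDA range (no scattering or straggling — adequate for φ_β ≈ 0.97
in cm-scale volumes) and, for photons, local deposition of the energy
attenuated along the chord to the surface (μ = 0.0096/mm at 511 keV).
At 10⁵ histories the standard error of φ_β is < 5·10⁻⁴, and the estimate
agrees with an independent dense-grid quadrature of the same geometry
within 3 SE (tested). SAFs between the five simulated volumes
{3, 4, 5, 6, 7.5} ml are interpolated linearly in ln V. Both β and photon
in vitro components are computed and summed; the photon share is ~25 % of
the in vitro dose.

Typical magnitudes (77 kg, 331 MBq): in vivo 2.2 mGy (β 1.5, photon 0.7),
in vitro at 60 min 0.6 mGy.

## Foci-response kinetics

DSB induction is proportional to dose rate; foci become visible with rate
constant k_form and resolve with k_loss (two-compartment catenary). The
defaults k_form = 0.10/min and k_loss = 0.006/min place the post-pulse
response maximum at 29.9 min, the 30-min assumption used for illustration
in the source study; reported maxima for external irradiation span 5–90
min, and the constructor rejects parameter pairs whose peak falls outside
that range. Convolution is trapezoidal on a default 0–180 min, 0.25-min
grid and agrees with a direct ODE solution of the equivalent system to
< 0.5 % (tested). The gain κ (foci per cell per mGy) is a free scale: the
module provides relative kinetics, and absolute calibration lives in the
synthetic generator's rate model instead.

The steady-state check compares F(t) against the rate-tracking equilibrium
κ·Ḋ(t)·∫h (tolerance 0.15 of max F). For [18F] decay the check honestly
fails — k_loss is comparable to the decay constant, so strict tracking is
never reached — but the foci level varies by only ~7 % of its maximum over
the second exposure hour, which is the flatness the incubation-time
comparisons rely on.

## Synthetic cohort and foci generator

The cohort reproduces the published three-arm allocation: 10 (5M/5F)
radiotracer, 12 (4M/8F) field-only, 10 (5M/5F) combined. Age, weight and
BMI are truncated normals whose *truncated* means match the published
group means (the latent location is shifted to compensate for truncation);
height follows from weight and BMI; administered activity is 4.3 MBq/kg
with 5 % lognormal jitter.

Per-cell foci counts: with probability r/100 (r = condition damage rate in
%) a cell draws a zero-truncated Poisson(μ) count; independently, with
probability a the count is replaced by a uniform draw on 3..8, emulating
rare detection artifacts and feeding the >5 exclusion filter. The pair
(μ = 0.143963, a = 3.033·10⁻⁴) together with a study-average rate of
1.3901 % is the exact solution matching the published per-cell spectrum
for 0, 1 and 2 foci (98.58 / 1.292 / 0.093 %); this is far from plain
Poisson (P₂/P₁ would predict ~11× more 1-foci cells), which is why the
responsive-subpopulation mixture is required. The published tail
(0.020/0.007/0.004/0.004 % for 3/4/5/>5) is heavier than the zero-truncated
Poisson tail; the artifact component absorbs the total tail mass but not
its exact split across classes 3–5, a knowingly coarse treatment of a
3·10⁻⁴ effect.

Condition rates: each volunteer draws a background rate from a normal with
median 1.04 % and SD 0.35 % (truncated at 0.02 %). Immediate-fixation
samples (SP1/IT0) add a venipuncture excess of median 0.16 % whose SD is
set so the across-volunteer variance ratio versus SP1/IT60 is 7.56.
Post-exposure samples of radiotracer arms add β_D · D_total(IT) with
β_D = 0.095 %/mGy, calibrated once so the pipeline's median *relative*
excess at 60-min incubation is ~28 % at the default cohort's median total
dose (≈2.9 mGy); the implied median absolute excess is ~0.27 points. The
field-only arm and the post-imaging-component samples (SP2/IT60) carry no
excess, encoding the study's null findings. Slides per condition are drawn
with median 9 (range 1–10) and cells per slide lognormal with median 2009,
floored at 1002. Slide counts are sampled as multinomials over the
analytic class probabilities — equivalent in distribution to per-cell
sampling (tested) but O(1) in the cell count.

**What the generator does not emulate:** pan-nuclear staining, scorer
drift between slides, within-volunteer correlation of background rates
across conditions beyond the shared background draw, SMF genotoxicity or
FDG×SMF interaction (null by design), and any nonlinearity of the
dose response. Passing tests therefore demonstrate that the pipeline
recovers the parameters of *this* generative model at the study's sample
sizes — not that the model captures every feature of real microscopy data.

## Statistics

Damage rates pool cells across replicate slides of a condition (per-slide
averaging would weight slides unequally; the pooled estimator is invariant
to how a fixed cell population is partitioned into slides — tested).
Excess rates are within-volunteer post-minus-pre differences; volunteers
missing a benchmark condition are reported as skipped, never silently
dropped. The battery runs paired Wilcoxon (within-arm exposure effect and
incubation effect), Mann-Whitney (arm 1 vs arm 3), Kruskal-Wallis across
arms with Dunn's z post hoc (midranks, tie-corrected, no extra
multiplicity correction beyond the stated procedure), Friedman across
incubation times with a Tukey-type (Nemenyi, studentized-range) post hoc,
and Brown-Forsythe (median-centred Levene) for variance equality; all
two-sided at α = 0.05.

Power: each replicate draws three arms of standard normals, shifts one arm
by 1.5 within-arm SDs (primary reading of "1.5-fold of the
inter-individual variance"; the literal variance reading, a √1.5-SD shift,
is available as an option) and applies Kruskal-Wallis via a vectorised
rank statistic against the χ²₂ cutoff. At n = 10 per arm the simulated
power is ~89 %, above the 80 % design target; under the variance reading
the minimum n rises to ~12. Note that for n = 2 per arm the H statistic
cannot exceed 4.57, so the α = 0.05 test has zero power there regardless
of effect — the minimum-n search contract is "smallest n attaining the
target", not "n = 2 attains the size".

## Problem sizes and reproducibility

Default problem sizes keep every stage at desk scale: 10⁵ Monte Carlo
histories per tube volume, 5000 power replicates, one 32-volunteer study
≈ 4.1 million simulated cells (the source study scanned 4.76 million).
`scripts/acceptance.py` derives all child seeds from `--seed`; the
background-rate and relative-excess medians are reported over the pooled
per-volunteer values of three replicate studies of identical default
design, because a single study-size median still carries generator noise
(SE ≈ 0.08 points on the background median) that is a property of the
small cohort, not of the pipeline under test. Every generator accepts a
`numpy` `Generator` or integer seed, and `generate_study` gives each
volunteer an independent child stream so outputs are reproducible and
insensitive to per-volunteer draw counts.

## Known limitations

- The biokinetic surrogate is a calibrated three-exponential, not a
  physiological compartment model fitted to measured TACs.
- Photon cross-fire uses a uniform whole-body source and a single
  absorbed fraction instead of voxel-phantom SAFs; bremsstrahlung and
  annihilation-in-flight are ignored.
- Electron transport in the tube is straight-line with a fixed range;
  fine wall/material detail is not modelled.
- The exclusion-filter tail calibration is coarse above 2 foci per cell.
- Real-data p-values and per-figure data points of the source study are
  not reproducible from synthetic data; only the qualitative significance
  pattern and calibrated summary statistics are.
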