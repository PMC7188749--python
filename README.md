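# petdsb

Blood dosimetry and γH2AX foci analysis for [18F]FDG PET/MRI volunteer
studies — a reusable, tested reimplementation of the computational chain
behind a three-armed human study of DNA double-strand breaks (DSBs) after
radiotracer and 3-T static-magnetic-field exposure.

## Who this is for

Radiation-protection and biodosimetry researchers who want to model or
re-analyse low-dose γH2AX studies: estimate the absorbed dose a blood
sample accrues in vivo and during in vitro incubation, understand the
kinetics that link a dose-rate history to an observable foci curve, and
exercise the full statistical pipeline — exclusion filter, binary damage
rates, excess rates, nonparametric test battery, design power — on
realistic synthetic data when the original volunteer data are not public.

## The model in brief

**Internal dosimetry (MIRD).** The blood dose over the first 60 min after
injection is `D = Δ_β ∫₀ᵀ c(t) dt + Δ_γ φ_γ Ã_body / M_body`: a positron
self-dose from the measured aortic concentration c(t) (absorbed fraction 1
within blood) plus annihilation-photon cross-fire from whole-body retention.
In vitro, a sample with residual concentration c(60) in a conical tube adds
`D_it = Δ c(60) (1 − e^(−λ·IT))/λ · (Δ_β φ_β(V) + Δ_γ φ_γ(V))`, with
tube-geometry specific absorbed fractions φ(V) from a self-contained Monte
Carlo, interpolated in ln V.

**Foci kinetics.** The γH2AX response is linear and time-invariant:
`F(t) = κ ∫₀ᵗ Ḋ(τ) h(t−τ) dτ` with the two-compartment impulse response
`h(t) = k_f/(k_f−k_l) (e^(−k_l t) − e^(−k_f t))`, peaking at
`ln(k_f/k_l)/(k_f−k_l)` ≈ 30 min for the defaults k_f = 0.10/min,
k_l = 0.006/min.

**Foci counts.** Per cell, a zero-inflated Poisson: with probability equal
to the condition's damage rate a cell carries a zero-truncated
Poisson(μ = 0.144) focus count, plus a rare uniform 3–8 artifact component
that exercises the >5-foci exclusion filter. The binary damage rate responds
linearly to dose (β_D per mGy), with a venipuncture excess and inflated
variance at immediate fixation.

**Statistics.** Wilcoxon, Mann-Whitney, Kruskal-Wallis + Dunn,
Friedman + Tukey-type and Brown-Forsythe tests, two-sided at α = 0.05, plus
a Monte Carlo Kruskal-Wallis power simulation for the 10-per-arm design.

## Worked example

```sh
python examples/01_blood_dose.py
```

prints, for a 77-kg male volunteer given 4.3 MBq/kg:

```
blood volume (Nadler): 5.22 l
concentration at injection: 62.7 kBq/ml
residual at 60 min p.i.:    4.17 kBq/ml

in vivo dose (0-60 min): 2.15 mGy (beta 1.48, photon 0.67)
  incubation  0 min: in vitro 0.00 mGy, total 2.15 mGy
  incubation 15 min: in vitro 0.17 mGy, total 2.33 mGy
  incubation 30 min: in vitro 0.33 mGy, total 2.48 mGy
  incubation 45 min: in vitro 0.47 mGy, total 2.63 mGy
  incubation 60 min: in vitro 0.60 mGy, total 2.76 mGy
```

The in vivo dose is dominated by the positron self-dose; 60 min of
incubation adds ~28 % because only physical decay (T½ = 110 min) removes
activity from the sealed sample, so successive 15-min increments shrink.

`examples/03_synthetic_study.py` simulates the full 32-volunteer study
(~4.1 million cells) and runs the analysis pipeline; with seed 1 it prints
a median background damage rate of 1.10 %, a median excess of 0.28
percentage points (relative excess 26.6 %), and a test battery in which
both radiotracer arms show significant excess damage while the field-only
arm does not. `examples/02_foci_kinetics.py` and `examples/04_power.py`
cover the response kinetics and the design power (89 % at n = 10 per arm
for a 1.5-SD shift).

The same pipeline is scriptable from a shell:

```sh
petdsb simulate --seed 1 --outdir study/
petdsb analyze --indir study/ --outdir study/analysis/
petdsb power --n 10
petdsb fig1 --out curves.csv
```

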