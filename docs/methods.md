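# Methods

## Scope and model overview

`micromash` analyses label-free (DIA/SWATH-style) protein and peptide
quantification from mash time courses: normalization against trypsin
self-digest spike-ins, stage-aligned comparison of two mash scales,
classification of abundance changes as time- and/or temperature-dependent
using stage extensions, and external-calibration quantification of wort
sugars and amino acids from MRM peak areas. Because the raw datasets this
workflow targets live in external repositories, the package ships a forward
simulator that emulates their structure — replicated runs over a multi-rest
mash program, rise-then-fall protein profiles, clipped peptide families,
spike-in references and per-run scale factors — together with exact ground
truth, so every downstream operation is testable against a known answer.

## Soluble-protein kinetics

Each feature (protein or peptide form) is modelled as a grain-bound
reservoir G and a soluble pool S:

    dG/dt = −k_ext(T) · G
    dS/dt =  k_ext(T) · G − k_den(T) · S

with extraction accelerating exponentially in temperature,
k_ext(T) = k_ext_ref · exp(b_ext · (T − T_ref)), and irreversible loss
(denaturation/aggregation/precipitation) switching on sigmoidally around a
melting midpoint, k_den(T) = k_den_max / (1 + exp(−(T − T_m)/s_m)).
This is the simplest mechanistic form that reproduces the characteristic
rise-then-fall soluble-abundance profiles of mashing; it is a modelling
choice of this package, not a mechanistic claim.

Within a stage the temperature is constant, so the system has the closed
form G(t) = G0·e^(−at), S(t) = S0·e^(−dt) + aG0·(e^(−at) − e^(−dt))/(d − a)
with a = k_ext, d = k_den. Two numerical details matter:

* **Degenerate line a = d.** Below a relative separation of 1e-12 the
  analytic limit S = (S0 + aG0·t)·e^(−at) is used, keeping the solution
  continuous in the parameters.
* **Near-degenerate cancellation.** For |(d − a)·t| < 1 the difference of
  exponentials is evaluated via `expm1` (as aG0·e^(−at)·(1 − e^(−(d−a)t))/(d−a)),
  which avoids the catastrophic cancellation that would otherwise inflate
  relative error to ~1e-4 for separations near 1e-9. The direct form is used
  for larger |x| where it is both stable and overflow-safe.

Trajectories chain the per-stage closed form with state continuity at stage
boundaries. Extension points are *counterfactual branches*: the stage
temperature is held for the extension length, but the branch state does not
feed the next stage — mirroring how extension samples come from parallel
mashes run longer, not from the mash that continued the program.

## Default mash program

Rests at 52, 63, 73 and 78 °C followed by a boil at 102 °C, sampled at the
start and end of every stage, after each rest's 20 min extension, and after
30 min of boil. The 63 °C rest lasts 35 min and the boil sample is at
30 min; the other rest durations (30, 20, 15 min) and the 20 min extension
length are package defaults, exposed in the program config — the workflow's
source protocol does not pin them, and nothing downstream depends on their
exact values beyond the sampling grid they induce.

## Synthetic data generator

One MS run is simulated per (sample point, replicate). Observed intensity is

    noiseless_S × run_scale(point, replicate) × lognormal(cv)

with run_scale = exp(N(0, run_scale_sd²)) shared by every feature of the run
(trypsin references included, so spike-in normalization cancels it exactly),
and measurement noise lognormal with log-SD sqrt(log(1 + cv²)) so that `cv`
is the exact coefficient of variation. Trypsin self-digest references are
constant-mean features (summed expectation `trypsin_mean`, default 1000,
split over 3 reference peptides). Defaults follow the emulated study design:
triplicate runs, cv = 0.10 (a typical DIA peptide-level CV), run_scale_sd =
0.2. Zeros are never imputed; an optional dropout rate exists but defaults
to 0.

Peptide families share a generation pool: each form's initial amounts are the
family's scaled by its `generation_fraction` (fractions must sum to 1 —
limited proteolysis during malting/early mash fixes the pool), while each
form keeps its own melting midpoint, since clipping alters thermal stability
site-specifically. The two stock families mimic barley IAAA residues 122–145
(four forms) and NLTP1 residues 99–115 (full-tryptic + one clipped form).

**What the simulator does not emulate:** chromatographic drift, missing
values from detection limits, interference/shared peptides, heteroscedastic
low-intensity noise, and any search-engine/FDR artefacts. Passing tests
therefore demonstrate correctness of the computations and calibration of the
statistics under well-behaved multiplicative noise, not robustness to every
pathology of real acquisitions.

## Ground-truth dependence labels

For every stage with an extension and a successor, the noiseless values at
stage end (E), extension (X) and next-stage end (NE) are recorded on the
analysis scale (soluble abundance for proteins, within-family fraction for
peptide forms). With threshold δ (default 0.05, i.e. a 5% change relative to
E):

* |X − E| > δ·E → **time**;
* |NE − X| > δ·E → **temperature** (both labels if both exceed);
* neither exceeds but |NE − E| > δ·E → **time+temperature** (joint);
* otherwise **none**; E ≤ 0 → none by convention.

Labels are deterministic given δ and recomputable from the closed form.

## Normalization layers

1. **Relative abundance** R = intensity / trypsin intensity of the same run.
   "Trypsin intensity" is the *sum* of the run's trypsin-reference features
   (configurable to mean; the sum is the natural estimator when reference
   peptides vary in response).
2. **Normalized abundance** N: per feature and condition, the per-point
   replicate mean of R divided by the sum of those means over all sampled
   points, so mean profiles sum to 1. Replicate-level N (same denominator)
   is retained for statistics. Division uses replicate means rather than the
   sum of all replicate values; with balanced replication the two differ
   only by the constant n.
3. **Family fractions** f: per run, each form divided by the summed detected
   forms of its family.

All three are invariant to per-run scaling by construction; zero totals are
flagged (feature excluded / fraction NaN) rather than pseudo-counted.

## Statistics

The significance engine is native: equal-variance two-sided Student's t-test
(pooled variance, df = n_a + n_b − 2; the t-distribution CDF comes from
scipy), Bonferroni adjustment p_adj = min(1, m·p), and an OLS two-factor
contrast (log2 intensity ~ feature + group) for multi-peptide proteins,
which reduces exactly to the t-test on log2 values for a single feature.
Sign convention throughout: estimate and t are first group minus second.
Zero pooled variance is degenerate: equal means report p = 1, unequal means
report the 0-limit (t = ±inf, p = 0). No empirical-Bayes moderation and no
FDR procedures are provided — the workflow's convention is Bonferroni only.

The scale-comparison difference map D = mean N(condition 1) − mean
N(condition 2) is computed per (feature, stage, point) on the intersected
feature set and grid (mismatches logged and dropped, never zero-filled), with
the Bonferroni family either the whole map (default) or per feature; the
protein-level threshold defaults to α = 0.05.

## Stage-extension classification

Per feature and per extended stage, three t-tests (E vs X, X vs NE, E vs NE)
feed a fixed decision table: significant E–X adds "time", significant X–NE
adds "temperature"; if neither fires, a significant E–NE yields the joint
"time+temperature"; otherwise "none". All 8 significance combinations are
defined; in particular (sig, sig, ·) yields {time, temperature} — the union
reading — and a non-significant E–NE never vetoes the individual labels,
since E–NE can lose power when the two step changes partially cancel.
Protein-level calls use replicate-level normalized abundance at α = 0.05;
peptide-level calls use family fractions at the stringent α = 1e-5 (raw
p-values thresholded; no multiplicity correction inside the classifier, a
deliberate reading of the peptide-level convention, flagged here). Start-of-
stage samples are plotted in profile exports but do not enter the
classification, which uses E/X/NE only. The test is swappable for the linear
contrast.

The standard recovery benchmark simulates 200 proteins at cv = 0.10, n = 6:
100 time-dependent (T_m far below 63 °C, so the loss rate is saturated and
identical at 63 and 73 °C; with the 20 min extension equal to the 20 min
73 °C rest, X and NE coincide and the truth is pure {time}; ~2.2-fold loss
over the extension) and 100 temperature-dependent (T_m = 68 °C between the
rests, ~0.7% drift during the extension, ~3-fold loss across the 73 °C
rest). Agreement is exact label-set match at the designated 63 °C→73 °C
transition; expected agreement is ~95% (limited by the ~5% false-positive
rate of the one irrelevant test per feature), comfortably above the 90%
acceptance floor.

## Metabolite quantification

Linear external calibration per analyte: OLS fit of area on concentration
(≥ 3 strictly increasing standards; optional 1/x weighting, off by default,
since plain linear curves are the stated convention), R² computed explicitly
(constant areas define R² = 0). Curves with R² ≤ 0.99 refuse quantification
outright. Inverse prediction multiplies by the sample dilution (default
1:1000): conc = dilution · (area − intercept)/slope; negative results are
returned but flagged. The analyte panel is 3 sugars (glucose, maltose,
maltotriose) and 15 free amino acids. Brix readings convert to specific
gravity by the standard sucrose-scale quotient approximation
SG = 1 + Bx/(258.6 − (Bx/258.2)·227.1) — a convention choice, documented
because the source workflow names only the instrument. No numeric
concentration targets exist for the emulated study (its values are
figure-only), so metabolite correctness is established by round-trip and
noise-recovery properties.

## Problem sizes and numerical checks

The verification suite runs at the sizes it states: 1,000 random parameter
draws against a 5,000-step RK4 integrator (max relative deviation observed
~3e-10, bound 1e-6, including 100 draws within 1e-9 of the degenerate line);
1,000 random t-test instances against scipy (agreement ~1e-15, bound 1e-10);
10,000 null features for size calibration (0.049 observed, band 0.05 ±
0.01); 100 seed pairs of identically-simulated 100-protein conditions for
the Bonferroni null map (96–98 of 100 seeds with zero significant cells,
floor 95); the 200-protein recovery benchmark (90–97.5% across seeds, floor
90%). Conservation identities (ΣN = 1, Σf = 1) hold to 1e-12 and run-scale
invariance to machine precision on the full default dataset. These sizes
keep the whole suite around a minute on one CPU while matching the stated
conditions exactly.

## Known limitations

* The kinetic model is linear and two-compartment; real extraction and
  aggregation kinetics are neither, and enzymatic proteolysis during the
  mash (which would couple family forms dynamically) is represented only
  through fixed generation fractions and per-form stabilities.
* The classifier inherits the t-test's behaviour at n = 3: limited power for
  small effects, so "none" labels on real triplicates are often
  power-limited rather than evidence of stability.
* Family fractions are compositional; their t-tests ignore the induced
  negative correlation between forms. The stringent peptide-level α
  mitigates but does not remove this.
* The difference map compares conditions point-by-point; it does not model
  the time course jointly.
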