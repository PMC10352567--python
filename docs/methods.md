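# Methods

## The measurement model

Serum N-glycans released by PNGase F are derivatized so that sialic acid
linkage isomers become mass-distinguishable: alpha2,6-linked sialic acids are
ethyl-esterified (+C2H4, +28.0313 Da) and alpha2,3-linked ones lactonized
(−H2O, −18.0106 Da). Each glycan is therefore identified by a residue
composition over eight symbols (H hexose, N HexNAc, F fucose, E/L derivatized
Neu5Ac, Ge/Gl derivatized Neu5Gc, Ac O-acetyl) and detected by MALDI-TOF in
positive mode as the sodiated cation [M+Na]+.

Quantitation is ratio-based: a pooled glycome reduced with sodium
borodeuteride serves as a per-glycan internal standard. Reduction converts
the reducing-end aldehyde to an alditol gaining one H and one D, a constant
+3.0219 Da (nominally "+3 Da") shift, so every analyte (light) peak has a
heavy twin. The readout for each glycan is the light/heavy intensity ratio,
which cancels per-spot ionization and sample-loading variation. Technical
replicates (three spots per sample) are averaged on the ratio scale.

Masses are computed from atomic monoisotopic masses; the sodium adduct uses
the electron-corrected cation mass (22.98922 Da). The seven calibration
glycans reproduce their reference m/z within 2 ppm; the two lactonized-Neu5Gc
calibrants carry a systematic ≈ +1.9 ppm offset against their reference values
whose origin (transcription vs an alternative assumed lactone chemistry)
cannot be resolved from composition arithmetic alone — the 5 ppm comparison
tolerance (typical external-calibration MALDI accuracy) absorbs it.

## Structural classification and derived traits

Classification is composition-only. With N the HexNAc count: high-mannose
(N = 2, H ≥ 5, no fucose or sialic acid), hybrid (N = 3, H ≥ 5), complex
(N ≥ 4, or N = 3 with H ≤ 4), other (remaining N = 2 species). Antennarity is
N − 2 for hybrid/complex glycans; galactoses are the hexoses beyond the core
(3 for complex, 5 for hybrid), capped by the antenna count. "Branched sialic
acid" marks glycans with more sialic acids than antennae (a disialylated
antenna). Bisecting GlcNAc, antenna isomers and O-acetyl localization are
not recoverable from composition and are out of scope.

Eighteen derived traits summarize the panel. Sum traits add the ratios of
qualifying glycans (e.g. fucosylation = Σ ratios of F ≥ 1 glycans); they are
homogeneous of degree one and obey exact partition identities (fucosylation +
afucosylation = total retained signal; likewise sialylation + asialylation).
Per-antenna traits are abundance-weighted degrees, e.g. galactosylation per
antenna = Σ(gal_i · q_i) / Σ(ant_i · q_i) over glycans with at least one
antenna; these are invariant to globally rescaling the ratios. Weighting by
abundance (rather than averaging per-glycan fractions) is a pinned choice; the
registry is a plain list of predicate/weight definitions so alternative
formulas can be swapped without touching the computation. An extra exported
definition isolates O-acetylated glycans carrying only alpha2,6-linked sialic
acid, the class with a distinct (upward) calorie-restriction response.

## Peak processing

* **S/N**: peaks carry no vendor S/N, so noise is estimated as the median
  intensity of peaks lying > 0.5 Da from every library m/z, within 300 Da
  windows (global fallback when a window is empty). The exclusion tolerance is
  in Da, not ppm, because S/N filtering runs before recalibration and must be
  robust to uncorrected drift. The identification threshold is strict
  (S/N > 3).
* **Recalibration**: the seven calibrants are located within a 0.3 Da search
  window; their mass errors are fit as an affine function of m/z (least
  squares) and subtracted. Two parameters are enough for seven calibrants over
  700–3500 m/z; higher orders would overfit. Fewer than two matches ⇒ identity
  transform with a warning. Recalibration is idempotent to numerical
  precision.
* **Matching**: nearest peak in ppm within a 10 ppm tolerance, separately for
  the light and heavy target. A match is flagged ambiguous — never silently
  resolved — when a competing peak lies within tolerance at within 2× the
  intensity, or when one observed peak is claimed by two library entries.
* **Aggregation**: arithmetic mean of the ratio over ok-status replicates;
  technical CV = sample (n−1) sd / mean.

No isotope-envelope overlap correction is applied: the light A+3
isotopologue overlapping the heavy monoisotopic peak inflates the heavy
channel and biases the measured ratio to r/(1 + b·r) for bleed fraction b.
The simulator can inject a positive bleed to demonstrate this bias, but it
defaults to zero to match the uncorrected measurement model.

## Quality control

A glycan enters quantitation only if its ratio CV over repeated measurements
of a pooled reference sample is strictly below 25%. The pooled reference is
rendered by the generator as six technical-noise-only spots of the baseline
glycome (manifest group `POOL`); the choice of six repeats is an artifact
default. Outliers are masked per glycan within (group × week) strata by
single-pass Tukey fencing: values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with
quartiles by linear interpolation between order statistics (the numpy
default, position (n−1)p + 1 — conventions differ at small n, so this one is
pinned and tested). Strata with fewer than four values pass through
unchanged. Masked cells are excluded from all downstream statistics but kept
in raw storage.

## Group statistics

The headline test is the classical equal-variance unpaired Student's t-test,
two-sided, with the conventional star coding of raw p-values (Welch available
behind a flag). Comparisons are run per time point and pooled over all time
points; pooling treats repeated measures of one mouse as independent, an
acknowledged simplification of the underlying repeated-measures design.
Benjamini–Hochberg adjusted p-values are always emitted as an auxiliary
column (adjustment across units within each stratum) but do not drive the
star coding. Sex-stratified comparisons (female vs male within each diet
group) are provided for the fucosylation traits. Heatmap matrices are log10
ratios with nonpositive/missing cells masked and counted, rows ordered by
(group, sex, week, mouse).

## The synthetic-data generator

The generator defines the study conditions every stochastic test runs under:
2 diet groups × 2 sexes × 7 time points (weeks 15–60), 30 mice per group and
sex by default (scaled down in tests), triplicate spots. Per glycan, the true
ratio is baseline × CR multiplier (CR group) × 1.3 (fucosylated glycans in
females) × exp(slope·Δweek) × unit-mean log-normal biological noise, with 2%
of cells multiplied 5× as outliers. Baselines are log-normal (median 1,
log-sd 0.4); CR multipliers are uniform 0.5–0.9 for most glycans and 1.2–1.6
for O-acetylated, purely alpha2,6-linked glycans — magnitudes are synthetic
choices reproducing only the reported directions, as are the biological (20%)
and technical (10%) CVs, which are not reported for the real cohort.
Rendering places the heavy peak at scale 100 and the light peak at
ratio × heavy, applies per-channel log-normal technical noise (the light-side
factor is what the measured ratio inherits), affine calibration drift, 3 mDa
Gaussian m/z jitter, and 50 exponential-intensity decoy peaks kept > 0.2 Da
from library masses. Rendering refuses drifts exceeding half the minimum
library spacing (1.01 Da for the default panel), which would be unmatchable
by construction.

What the generator does **not** emulate: profile-mode spectra and isotope
envelopes, correlated within-mouse longitudinal structure, batch effects
beyond affine drift, panel glycans absent from the internal standard, and
detector saturation. Passing tests therefore demonstrate correctness of the
computational chain and statistical calibration under a faithful multiplicative
noise model — not robustness to every artifact of real acquisitions.

## Problem sizes and numerical choices

The test suite scales the cohort down (2–10 mice per group and sex, one or
two time points) so the full suite runs in well under a minute per stochastic
check; effect-recovery tests use 20 mice per group over five seeds
(delta-method standard errors on the ratio of group means), and the type-I
error check uses 5000 simulated null units of 20 vs 20. All randomness flows
through `numpy.random.default_rng` seeded from the design, making every
table byte-reproducible; figures are exempt from byte-identity only through
image metadata.

## Known limitations

Composition-level identity means co-eluting isobaric structures are summed.
The panel beyond the thirteen named glycans is a plausible reconstruction,
not the full measured panel. The pooled analysis ignores within-mouse
correlation (a per-mouse-mean sensitivity mode is the escape hatch). The CV
filter inherits whatever the pooled reference covers: glycans missing from
it are dropped, not imputed.
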