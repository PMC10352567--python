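# glycoquant

Quantitation of derivatized serum N-glycomes from MALDI-TOF peak lists,
using a per-glycan stable-isotope internal standard, with quality control,
derived glycosylation traits, and diet-group statistics. Built for
glycomics studies comparing ad libitum (AL) and calorie-restricted (CR)
mouse cohorts, but the machinery — composition grammar, mass library, pair
matching, trait registry — is study-agnostic.

## The method

Released N-glycans are derivatized so sialic acid linkage isomers separate
in mass (alpha2,6 → ethyl ester, +C2H4; alpha2,3 → lactone, −H2O) and
detected as [M+Na]+. Compositions are written `H5N4F1Ge2Ac1`-style: hexose
(H), HexNAc (N), fucose (F), derivatized Neu5Ac (E/L), derivatized Neu5Gc
(Ge/Gl), O-acetyl (Ac). A pooled glycome reduced with NaBD4 provides a
heavy twin for every glycan at a constant +3.0219 Da (nominally +3 Da); the
quantitative readout per glycan is the light/heavy intensity ratio

    q_g = I_light(g) / I_heavy(g),

averaged over triplicate spots. Downstream: S/N > 3 identification, affine
mass recalibration against seven calibrant glycans, 10 ppm pair matching, a
CV < 25% reproducibility filter, Tukey (1.5×IQR) outlier masking per
(group × week) stratum, 18 derived traits (sum traits such as fucosylation
= Σ q over F≥1 glycans; abundance-weighted per-antenna traits such as
galactosylation per antenna = Σ gal·q / Σ ant·q), and unpaired Student's
t-tests per glycan and trait, per week and pooled. A synthetic-data module
simulates the full study design (two diets × two sexes × seven ages,
triplicate spots, noise, drift, decoys, outliers) so every stage is
testable end to end without instrument data.

See `docs/methods.md` for the model, assumptions, and defaults.

## Worked example

```python
from glycoquant import (
    StudyDesign, EffectModel, generate_dataset, run_on_dataset,
    sodiated_mz, internal_standard_mz,
)

print(f"{sodiated_mz('H5N4Ge2'):.5f}")           # 2333.82466
print(f"{internal_standard_mz('H5N4Ge2'):.5f}")  # 2336.84658

design = StudyDesign(mice_per_group_sex=10, weeks=(15,), seed=1)
ds = generate_dataset(design, EffectModel())
bundle = run_on_dataset(ds)
print(bundle["quant"].values.shape)              # (40, 45)
```

The two masses are the theoretical sodiated m/z of the biantennary
disialoglycan H5N4Ge2 and of its deuteride-labeled internal standard (+3.02
Da). The pipeline run simulates 10 mice per group and sex at one time
point, renders and processes 126 spots, and retains all 45 panel glycans
(pooled-reference CVs sit near the 10% technical noise, below the 25%
cut). Pooled trait comparisons from `bundle["trait_stats"]` show the
programmed biology:

```
high_mannose                   AL   3.921  CR   2.722  p=4.03e-09 ****
galactosylation_per_antenna    AL   0.893  CR   0.899  p=9.12e-02 ns
fucosylation                   AL  10.478  CR   8.179  p=3.06e-06 ****
oacetylated_sialylation        AL   4.576  CR   4.987  p=1.85e-01 ns
```

High-mannose (and most other) signal drops under CR; the per-antenna
galactosylation degree barely moves because numerator and denominator
shrink together; the aggregate O-acetylation trait mixes up- and
down-regulated glycans (the purely alpha2,6-linked acetylated glycans rise;
an extra exported trait isolates them).

The same analysis runs from the shell:

```sh
glycoquant simulate --mice 10 --weeks 15 --seed 1 -o dataset/
glycoquant all -i dataset/ -o results/
```

writing the library, calibration report, quant matrix and mask, QC report,
trait table, statistics tables, heatmap and trait figures, a run log and a
JSON summary into `results/`.

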