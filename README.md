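# ligfid

Quantitative analysis of DNA ligase fidelity and somatic CAG repeat
expansion, packaged as a tested, reusable pipeline.

High-fidelity DNA ligation matters for trinucleotide-repeat disease: a
ligase variant that rejects damaged or mismatched nicks (for example an
8-oxoG:A pair arising under oxidative stress) instead of sealing them can
slow the somatic expansion of the HTT CAG repeat that drives Huntington's
disease onset. `ligfid` implements the analyses such a study needs, from
raw gel and fragment-analysis tables to the derived fidelity and
instability statistics, with seeded synthetic-data generators standing in
for every raw input so the whole pipeline is testable offline.

## What it computes

**Ligation kinetics.** Nick sealing is a three-step mechanism — enzyme
adenylylation, adenylyl transfer to the nick 5'-phosphate, and sealing —
with an abortive branch that releases the AMP-DNA intermediate instead of
sealing. `ligfid.mechanism` integrates the mass-action system for this
branched scheme; `ligfid.gel_quant` converts band intensities to species
fractions (band over total lane intensity); `ligfid.kinetics` estimates
initial rates from progress curves (straight-line fit over the fraction
< 0.20 window), fits

    v0 / [E] = k_cat [S] / (K_M + [S])

by nonlinear least squares, and derives the fidelity statistics:

- abortive fraction = v_intermediate / (v_intermediate + v_sealed),
  and the fraction ligated F_lig = 1 − abortive fraction;
- discrimination = (k_cat/K_M)_canonical / (k_cat/K_M)_damaged;
- fold changes and Table-style relative parameters between a reference and
  a variant enzyme;
- active-site titration by segmental linear regression
  (y = a·min(x, x₀); the slope a is the active fraction).

**Repeat instability.** `ligfid.repeat_instability` computes somatic CAG
expansion indices from GeneMapper-style peak tables: peaks below 5% of the
tallest peak are discarded, peaks above the reference (modal) allele are
retained, their heights normalised, and the index is the height-weighted
mean repeat-unit gain. Mouse cohorts are referenced to each animal's liver
modal allele and compared per age × tissue stratum by one-way ANOVA with
Tukey-adjusted contrasts.

**Cell assays.** `ligfid.assay_stats` provides percent-of-untreated
viability normalisation (technical replicates averaged first, summaries
over biological replicates), baseline-relative mutation frequencies,
two-way ANOVA with interaction and Tukey comparisons, and 2^−ΔΔCt
relative expression against the geometric mean of three housekeeping
genes.

**Synthetic data.** `ligfid.synthetic_data` generates every input with
known ground truth: ligation gel lanes from a kinetic scheme with
multiplicative lognormal band noise, titration curves with a known active
fraction, repeat traces with a modal allele, PCR stutter and a
gamma-distributed expansion tail, and viability plates with known effect
tables.

## Worked example

Feeding published steady-state parameters for a wild-type ligase and a
fidelity-enhancing variant (k_cat 0.52 vs 0.20 s⁻¹ on the canonical nick,
a 1.9-fold K_M increase, 25-fold k_cat and 2.3-fold K_M defects on the
8-oxoG:A nick, wild-type discrimination 5.1, abortive fractions 0.51 vs
0.93) through the fidelity report:

```python
from ligfid import MichaelisFit, fidelity_report

km_cg, km_oxo = 100.0, 150.0
eff_wt_oxo = (0.52 / km_cg) / 5.1
fits = {
    ("WT", "C:G"): MichaelisFit(k_cat=0.52, K_M=km_cg),
    ("K845N", "C:G"): MichaelisFit(k_cat=0.20, K_M=1.9 * km_cg),
    ("WT", "8-oxoG:A"): MichaelisFit(k_cat=eff_wt_oxo * km_oxo, K_M=km_oxo),
    ("K845N", "8-oxoG:A"): MichaelisFit(k_cat=eff_wt_oxo * km_oxo / 25,
                                        K_M=2.3 * km_oxo),
}
abortive = {("WT", "8-oxoG:A"): 0.51, ("K845N", "8-oxoG:A"): 0.93}
report = fidelity_report(fits, abortive, reference="WT", variant="K845N",
                         canonical="C:G", damaged="8-oxoG:A")
table = report.table(sig=2)
print("k_cat fold decrease (C:G):      ", table["kcat_fold_decrease"]["C:G"])
print("efficiency defect (C:G):        ", table["efficiency_fold_decrease"]["C:G"])
print("efficiency defect (8-oxoG:A):   ", table["efficiency_fold_decrease"]["8-oxoG:A"])
print("discrimination WT / K845N:      ", table["discrimination"]["WT"], "/",
      round(report.discrimination_by_enzyme["K845N"], 1))
print("fidelity increase:              ", table["fidelity_increase"])
print("F_lig ratio (8-oxoG:A):         ", table["f_lig_ratio"]["8-oxoG:A"])
```

prints

```
k_cat fold decrease (C:G):       2.6
efficiency defect (C:G):         4.9
efficiency defect (8-oxoG:A):    58.0
discrimination WT / K845N:       5.1 / 59.4
fidelity increase:               12.0
F_lig ratio (8-oxoG:A):          7.0
```

The variant loses only 2.6-fold in maximal rate on the undamaged nick but
58-fold in catalytic efficiency on the oxidized mispair, so it
discriminates the damaged nick ~60-fold — a 12-fold fidelity gain over
the wild type — and completes 7-fold less ligation of the damaged nick
(F_lig ratio 7.0).

A command-line interface mirrors the library
(`ligfid simulate|kinetics|instability|assay ...`); for example

```sh
ligfid simulate titration --active-fraction 0.92 --dna-conc 100 \
    --nominal 12.5,40,70,100,130,160,200,300,400 --cv 0 --out titration.tsv
ligfid kinetics titrate --table titration.tsv
```

reports `active fraction: 0.9200 (92%)`.

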