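# Methods

## Scope and model

`brainpk` computes the extent of brain distribution of drugs across mouse
genotypes differing in P-glycoprotein (P-gp) efflux — wild type (FVB,
C57BL/6), Mdr1a/1b double knockout, and MDR1-humanized — together with the
absolute expression of the transporters that explain the phenotypes. Four
computational arms share one pipeline:

1. **Distribution.** Per animal, the brain homogenate concentration is
   converted to per-gram-tissue units (multiplying by the weight/volume
   homogenisation fold stored in the record, default 5 for tissue in 4
   volumes of saline), corrected for residual capillary blood, and divided
   by the plasma concentration to give K_p; K_p,uu follows as
   K_p / (V_u,brain · f_u,p). The residual-blood correction is

       V_eff   = f_u,p·V_water + (1 − f_u,p)·V_protein
       A_brain = (C_brain,h − V_eff·C_plasma) / (1 − V_water)

   The `1 − V_water` denominator treats the numeric ml/g value as a
   fraction, as the correction is conventionally written; we implement it
   as printed. A negative numerator (plasma signal exceeding brain signal,
   possible for strongly effluxed drugs measured near the blank) is clamped
   to zero and flagged rather than propagated: amounts are physically
   nonnegative, and downstream ratios would otherwise change sign silently.
2. **Binding assays.** f_u,p is the mean over dialysis replicates of
   buffer-side over plasma-side concentration; identical matrix-matched
   dilution of both sides cancels in the ratio. Replicates with f_u > 1 are
   flagged but retained — truncation would bias weakly bound drugs — and a
   mean above 1 warns. V_u,brain is the mean over QC-passing slices of
   (slice amount per g − v_film·C_buffer)/C_buffer. Slice viability QC
   fails a slice when end-of-incubation pH < 7.25 or LDH release exceeds a
   threshold; failing slices never enter the mean.
3. **Targeted proteomics.** Stable-isotope-dilution quantification per
   transition; a molecule is *expressed* when ≥3 of its 4 transition sets
   are positive (retention-time match and amount ≥ per-transition LOQ); the
   level is the mean ± SEM over the pooled positive transition × run
   amounts. Proteins failing the rule are censored as U.L.Q. and reported
   with their LOQ; fold changes against censored values become bounds.
4. **Group statistics.** Unpaired two-tailed Student's (pooled-variance)
   t-test at α = 0.05 between genotype groups; Welch's test is available via
   `StatsConfig.equal_var = False` and is the safer default when group
   variances may differ, but the pooled test is the package default to match
   the study design this pipeline serves. Blocker effects are mean-K_p
   ratios with no variance attached (ratios of group means). No
   multiple-testing correction is applied; reports carry the number of
   tests performed so readers can apply their own.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `v_water` | 0.0103 | ml/g | literature apparent vascular plasma-water space; not measured in-study, so mandatory config |
| `v_protein` | 0.0080 | ml/g | literature apparent vascular plasma-protein space |
| homogenate dilution | 5 | fold (w/v) | tissue homogenised in 4 volumes of saline; stored per record, not in code |
| slice dilution | 10 | fold (w/v) | slices homogenised in 9 volumes of buffer |
| `v_film` | 0 | ml/g | adherent surface-fluid correction; the originating slice method uses a nonzero value, so it is exposed in config rather than fixed |
| pH viability cutoff | 7.25 | pH | assay-defined viability criterion |
| LDH threshold | 0.25 | fraction | the criterion is named by the assay but no cutoff is published; configurable |
| LOQ rule | 3 × SD of blank-equivalent amounts, molecule LOQ = min over transitions | fmol/µg | declared rule, fully config-driven so an alternative can be swapped in |
| t-test | Student, α = 0.05 | — | study convention; Welch behind a flag |
| expression significance | p < 0.01 | — | proteomics-table convention |

Positivity aggregation across the three analytical runs is not pinned down
by the upstream conventions: we call a transition set positive when **all**
of its runs are retention-time-matched and its run-mean amount reaches the
per-transition LOQ. The call is monotone in the amounts (raising a signal
can never flip expressed → censored).

## Synthetic data generator

The generator emulates the study design: 4 drugs × 4 genotypes, n = 5
animals/group (3 for the oxycodone-like arm if requested), triplicate
dialysis, 6 slices per drug, and 4 transitions × 3 runs per peptide probe
with species-selective probes (human-specific probes receive no mouse
signal and vice versa; the common probe sums both). Default truths mirror
the reference study's printed constants (partition table K_p / V_u,brain /
f_u; expression levels 22.3 / 2.45 / 0.355 fmol/µg with Mdr1b below LOQ) so
recovery tests double as regression tests; everything is overridable.

All noise is multiplicative lognormal with mean 1 (nonnegative, right-
skewed, CV-parameterised). Default CVs, chosen once as typical assay
precision: 10% for in vivo concentrations (bioanalysis plus biological
scatter), 10% for slice assays, 10% for SRM/MRM areas, and 5% for
equilibrium dialysis — both dialysis aliquots are quantified in the same
analytical run, so shared run-level bias cancels in the ratio and the
independent residual is injection-level precision. Typical plasma levels
(50–500 ng/ml by drug) are plausible round numbers for 1–10 mg/kg dosing;
only ratios, not absolute levels, matter downstream.

A single global seed is expanded into named substreams (one per table kind)
so generating one table never perturbs another; a fixed seed yields
byte-identical CSVs.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: plasma time-course kinetics (one
sampling time is assumed at steady ratio), inter-occasion and inter-site
variability, buffer depletion during slice incubation, matrix effects and
chromatographic interference in SRM/MRM, digestion-efficiency differences
between samples, and correlated assay errors beyond the shared-run
cancellation above.

## Numerical and design choices

* Computation and presentation are strictly separated: all statistics are
  formed from full-precision values; the table convention (3 decimals below
  1, else 3 significant figures; `U.L.Q.(< x)` cells; significance stars)
  is applied only when writing report TSVs.
* K_p,uu in the partition report is formed from the group-mean K_p with the
  assay constants, matching how summary tables are conventionally built;
  per-animal K_p,uu values are retained in `results.json`.
* The dialysis CSV schema carries an optional `genotype` column (empty =
  applies to all strains) because plasma binding can differ slightly
  between strains.
* SEM of expression pools transitions × runs (n ≤ 12) — the capillary
  preparation is a single pooled biological sample, so this is technical,
  not inter-individual, variability, and group comparisons on these pools
  are labelled technical-replicate inference.
* Degenerate inputs: single-value groups report SD 0 with a flag; empty
  groups, all-invalid replicates and all-failing slice sets raise typed
  errors (`InvalidInputError`, `AssayFailureError`, `QCFailureError`)
  rather than returning NaNs.
* Test problem sizes (200 replicate cohorts for recovery medians, 10,000
  draws for round-trip and type-I-error checks) keep the full suite around
  ten seconds while leaving the medians and rates stable to well inside
  the asserted margins.

## Known limitations

* The exact V_u,brain formula of the originating slice method (including
  its surface-film term) is published elsewhere; the implemented formula is
  declared above, not inferred, and `v_film` defaults to 0.
* The LOQ rule stands in for a previously published procedure that is not
  restated here; it is config-driven and not claimed equivalent.
* K_p,uu propagates no uncertainty from V_u,brain or f_u,p; like the
  source tables it treats the assay constants as fixed.
* Chromatogram peak integration is out of scope: inputs are peak-area
  tables, not raw vendor/mzML files.
* No compartmental PK modelling, dose normalisation across routes, ANOVA
  or multiple-testing correction.
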