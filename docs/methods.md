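# Methods

## Copy-number model and calling

Input CN values are tumor-vs-paired-normal ratios in arbitrary units with
the diploid baseline at ≈ 2. Calling applies fixed cutoffs per probe:
homozygous deletion CN < 0.8, loss 0.8 ≤ CN ≤ 1.30, neutral
1.30 < CN < 2.50, gain 2.50 ≤ CN ≤ 5, amplification CN > 5. The boundary
semantics (loss/gain inclusive, amplification/homozygous-deletion
exclusive) follow the inequality directions in which such cutoffs are
conventionally printed; the five intervals partition [0, ∞), which a
property test asserts. Negative CN is rejected.

Segmentation is deliberately simple — a run-length scan over per-probe
states — rather than CBS/HMM: the events of interest here are high-level
amplicons and homozygous deletions, many standard deviations away from the
baseline, so state runs are the direct image of the biology. A centred
running median (default window 3 probes, shrinking at chromosome ends so
coordinates are preserved; window 1 disables it) removes single-probe
outliers before classification. Maximal same-state runs of at least
`min_probes_per_event` probes (default 5; no published minimum exists, and
5 suppresses single-probe noise at 500K-array density) become events whose
boundaries are the first/last probe positions of the run. The reported
`mean_cn` is the mean of the *smoothed* values in the run, so it always
lies inside the state's CN interval and segmentation is idempotent on the
mean-CN reconstruction. Adjacent runs of different non-neutral states are
never merged (a gain shoulder next to an amplicon yields two events).

Coordinates are 1-based inclusive throughout; reported segment length is
`end − start` bp (converted to kb in reports). BED import/export converts
to 0-based half-open at the file boundary only. Two array dialects are
harmonised by intersecting probe maps on probe id, erroring on coordinate
disagreement.

## Recurrence and minimal common regions

A case contributes once to a region's frequency if it has ≥ 1 event of the
queried kind overlapping the region by ≥ 1 bp (partial-overlap handling is
not standardised in the literature; ≥ 1 bp is the least-assumption rule).
Percentages are rounded half away from zero to integers, which reproduces
the conventional printed count/percent pairs (24/46 → 52 %, 3/46 → 7 %).
Cohort size is an explicit parameter: event-free cases must count in
denominators.

MCR delineation builds a per-chromosome coverage pileup after merging each
case's events (so one case covers a base pair at most once). Within every
maximal interval of coverage ≥ `min_cases`, the maximal plateau(s) at the
local coverage maximum are reported, in coordinate order when tied. A
region's `case_ids` are the cases whose merged events contain the whole
plateau, which makes the containment invariant (every MCR lies inside
every contributor's event) structural. The implementation is an O(k log k)
breakpoint sweep; tests compare it against an explicit per-base counting
oracle on small coordinates.

## Dosage screen

Gene-level CN is the mean of probes overlapping the gene ± 10 kb flank
(median available as an option; the flank covers probes just outside short
genes at 100 kb spacing). When no probe overlaps, the nearest probe's
value is used and flagged. The screen correlates gene-level CN with
RMA-scale expression per gene over the shared samples, using Pearson r
and the two-sided p from t = r·√(n−2)/√(1−r²) on n−2 df. Both filter
conditions are strict inequalities (R² > 0.70, p < 5·10⁻⁷), read literally
from the conventional dual-cutoff formulation. At the reference sample
size n = 23 the R² implied by p = 5·10⁻⁷ lies within 0.01 of 0.70, so the
dual condition behaves as a single R² cutoff there; a test certifies this
coincidence by bisection. No multiple-testing correction is applied — the
screen deliberately mirrors a fixed-p design across ~12k genes, and the
report header says so. Genes with zero variance in either vector are
skipped with a log entry; genes lacking expression values are carried in
region reports but excluded from the screen. Spearman rank correlation
(average ranks on ties) is provided for orthogonal-assay validation.

## Survival

Kaplan–Meier estimation and the log-rank statistic are computed with
lifelines; this package owns the conventions. The median is the smallest
event time t with S(t) ≤ 0.5 (an ε = 10⁻¹² guard absorbs float error when
S hits 0.5 exactly, as it does for the 42-case clinical group at 13
months). Deaths are processed before censorings at tied times. Zero-month
survivors are retained as deaths at t = 0 by default; the stratifier's
`drop_zero_times` mode reproduces analyses that exclude them. The packaged
46-case clinical table contains one zero-month death, and the published
survival curves for this cohort plot n = 45: excluding that single
zero-month case is the reading that reconciles the printed log-rank
significance (p ≈ 0.0004 here vs 0.0010 with all 46), so the worked
example computes the log-rank in that mode while medians use the full
4-vs-42 split. Group membership comes from event carriage: a case is
positive if any qualifying event overlaps the query gene/region.

## iFISH classification

Inputs are per-case nuclei fractions (≥ 200 nuclei per slide, flagged
below that; doublet spots assumed collapsed upstream). Cutoffs: gain ≥ 5 %
increased spots, loss ≥ 10 % decreased, amplification > 10 % of nuclei
with locus:centromere ratio > 2 or tight clusters, homozygous deletion
≥ 5 % with centromeric but no locus signal. When several criteria fire the
stronger call wins (amplification > homozygous deletion > gain > loss);
the combination rule is not standardised, so this precedence is the
package's choice. Increased/decreased/no-locus fractions are mutually
exclusive per nucleus and may not sum above 1.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes, not raw
array physics. Defaults: 46 samples; probe grid at 100 kb spacing over
eight chromosomes (1, 4, 7, 9, 10, 11, 12, 17) at hg17-like lengths
(~12k probes — a desk-scale stand-in for a ~480k-probe intersection that
preserves the per-event probe counts that matter to segmentation);
Gaussian baseline N(2.0, 0.15) clipped at 0. Implant prevalences follow
the reported recurrence rates — amplicons on chr7 50 %, chr12 22 %,
chr1 11 %, chr4 9 %, chr11 4 %, chr17 4 %; homozygous deletions at
9p21 52 % and 10q 22 % — with regions at the recurrently involved loci
(7p11.2/EGFR, 12q14/CDK4–MDM2, 1q32.1/MDM4, 4q12/PDGFRA,
9p21.3/CDKN2A–MTAP, 10q23.31/PTEN), each ≥ 1.5 Mb so implants span ≥ 14
probes. Implant levels are uniform draws — amplification U(5.5, 8),
homozygous deletion U(0, 0.4) — placed ≥ 4 σ inside the calling intervals
at default noise so noiseless-recovery checks are structural. Boundary
jitter defaults to 100 kb, reflecting variable per-case extents. One seed
drives everything; equal seeds give bit-identical cohorts.

Expression is linear in CN for a configurable coupled gene subset
(expr = a + b·CN + N(0, σ), b > 0, RMA-like scale, a = 6, b = 1 by
default), independent of CN otherwise; the population R² of a coupled
gene is b²·var(CN)/(b²·var(CN) + σ²), which tests verify by Monte Carlo.
Survival is exponential (analytic medians) with baseline median 13 months
and hazard ratio 6.5 for carriers of the flagged 4q12 amplification, so
the carrier median is 13/6.5 = 2 months; censoring marks a configurable
fraction (default 2 %, mirroring the one surviving patient in a 46-case
cohort) alive at their drawn time. iFISH counts are binomial draws around
state-typical nuclei fractions chosen several binomial SDs away from the
percent cutoffs at 200 nuclei.

What the generator does **not** model: raw probe intensities,
allele-specific CN, tumor purity and subclonality, intratumoral
heterogeneity, chromosome-arm-scale gains/losses, GC/wave artefacts, and
gene-specific expression programs. Passing recovery tests therefore shows
the pipeline is correct under its stated model, not that it is robust to
real-array artefacts a CBS/HMM segmenter would be needed for.

## Packaged fixtures

Two small TSV tables ship with the package: a 46-case clinical cohort
(case id, demographics, survival months, vital status, array platform)
and a 46-gene dosage catalogue (gene, cytoband, R²). Loaders verify a
SHA-256 checksum and record counts. These are reference tables for worked
examples and filter checks, not training data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 46-sample
cohorts on the 8-chromosome/100 kb grid (~0.6 M probe values), 20–30
seeded replicates where a rate is averaged, ≤ 20-interval instances for
brute-force oracle comparisons, and n = 23 for screen-recall Monte Carlo.
Floats are serialised at 6 significant digits; writers use stable
orderings so identical configs give byte-identical outputs. Degenerate
inputs have defined behaviour throughout: empty profiles segment to
nothing, all-censored curves have undefined medians (`None`), zero
variance raises rather than returning NaN, and empty MCR input yields an
empty region list.

## Known limitations

- The run-length segmenter is tuned to high-level events; low-amplitude
  mosaics or noisy real arrays need a dedicated segmentation method.
- The dosage screen pairs one CN summary per gene symbol; probe-set-level
  expression collapsing is out of scope.
- X/Y chromosomes are treated like autosomes.
- Recurrence significance (GISTIC-style q-values) is intentionally absent;
  only raw frequencies are reported.
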