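# gbmcna

Integrative copy-number analysis for glioblastoma (GBM) SNP-array cohorts.

Glioblastoma genomes carry focal high-level **amplicons** and **homozygous
deletions** whose driver genes are best identified by combining three views of
the same tumors: probe-level DNA copy number (CN), mRNA expression, and
clinical follow-up. `gbmcna` implements that analysis as a tested pipeline:

1. **CN calling** — probe-level tumor-vs-normal CN values (arbitrary units,
   diploid ≈ 2) are classified with fixed cutoffs: loss CN ≤ 1.30,
   gain CN ≥ 2.50, amplification CN > 5, homozygous deletion CN < 0.8.
   A running-median smoothing and a run-length scan turn each sample's
   profile into contiguous segments.
2. **Recurrence** — events are aggregated across the cohort: per-region
   recurrence frequencies (a case counts once if any event overlaps the
   region by ≥ 1 bp) and **minimal common regions** (MCRs), the maximal
   sub-intervals at the peak of the per-case coverage pileup, annotated with
   overlapping genes.
3. **Dosage screen** — per gene, Pearson *r* between gene-level CN (mean of
   overlapping probes ± 10 kb) and RMA-scale expression over paired samples,
   with two-sided *p* from *t* = *r*·√(*n*−2)/√(1−*r*²). A gene is dosage
   sensitive when *R*² > 0.70 **and** *p* < 5·10⁻⁷ (at *n* = 23 these two
   strict conditions nearly coincide).
4. **iFISH concordance** — interphase-FISH spot-count summaries are
   classified with percent-of-nuclei cutoffs (gain ≥ 5 %, loss ≥ 10 %,
   amplification > 10 % with locus:centromere ratio > 2, homozygous deletion
   ≥ 5 % without locus signal) and cross-tabulated against array calls.
5. **Survival** — Kaplan–Meier curves, medians (smallest *t* with
   S(*t*) ≤ 0.5) and the log-rank test compare event-positive vs
   event-negative cases.

A synthetic-cohort module generates full inputs with the statistical
structure the analysis assumes (segmental events at configurable
prevalences, CN-coupled expression, exponential survival with an
amplification-dependent hazard, binomial iFISH counts), and the package
ships two small clinical/dosage reference tables as fixtures.

## Worked example

```python
import gbmcna as g

# -- survival: 4q12/PDGFRA-amplified cases vs the rest of the 46-case cohort
table1 = g.load_table1_fixture()
records = g.records_from_clinical(table1)
amp = {"G12", "G73", "G82", "G88"}
pos = [r for r in records if r.case_id in amp]
neg = [r for r in records if r.case_id not in amp]
print(g.km_median(g.km_estimate(pos)), g.km_median(g.km_estimate(neg)))
neg45 = [r for r in neg if r.time > 0]   # the published curves plot n = 45
print(g.logrank_test(pos, neg45))

# -- synthetic cohort end to end
cfg = g.CohortConfig(seed=0, noise_sd=0.1)
probe_map, profiles, truth = g.generate_cohort(cfg)
events = g.segment_cohort(profiles)
chr7 = g.GenomicInterval("chr7", 1, 158_000_000)
print(g.recurrence_frequency(events, chr7, g.AMPLIFICATION, cfg.n_samples))
```

prints

```
amplified group median: 2.0 months (n=4)
non-amplified median:  13.0 months (n=42)
log-rank chi2=12.54, p=0.0004
chr7 amplicon recurrence: 23/46 cases (50%)
```

— the amplified group dies a median 11 months earlier, and the simulated
cohort reproduces the 50 % chromosome-7 amplicon rate it was configured
with. MCR delineation on the same cohort pinpoints the implanted 9p21
deletion and its genes:

```
9p21 MCR: chr9:21100000-22900000 (1800 kb), 19 cases (41%), genes: MTAP,CDKN2A,CDKN2B
```

A command-line interface mirrors the library
(`cna simulate | call | recur | dosage | survival | ifish | run`); e.g.
`cna run --out run1 --seed 0` executes every stage and writes TSV reports
plus a run manifest.

## Layout

- `src/gbmcna/cn_calling.py` — cutoff classification, smoothing, segmentation
- `src/gbmcna/recurrence.py` — frequencies, MCR pileup, gene annotation
- `src/gbmcna/integration.py` — gene-level CN, Pearson/Spearman, dosage filter
- `src/gbmcna/survival.py` — KM, medians, log-rank, stratification
- `src/gbmcna/ifish.py` — spot-count classification, concordance
- `src/gbmcna/synthetic.py` — cohort generator and packaged fixtures
- `src/gbmcna/io.py`, `src/gbmcna/cli.py` — TSV/BED I/O, pipeline, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
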