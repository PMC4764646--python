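# Methods

## The analysis model

`crcburden` implements a gene-level collapsing ("burden") analysis for rare
germline variation in a case–control design. The unit of evidence is the
*qualifying variant*: a call that survives a fixed cascade of read-quality,
population-frequency and predicted-impact gates. The analysis assumes:

* diploid autosomal inheritance; zygosity is inferred from the variant-read
  fraction alone (≥ 95 % ⇒ homozygous), with no genotype-likelihood model
  and no phasing — "compound heterozygous" therefore always means
  *putative* compound heterozygous;
* variants are exchangeable within a gene: the burden statistic ignores
  position, allele identity and per-variant effect size;
* cases and controls are comparable — sequenced, called and filtered
  identically. The burden stage enforces the last part mechanically by
  refusing to compare cohorts whose filter-configuration fingerprints
  (a digest of every threshold) differ;
* relatedness is known at the granularity of a per-sample family
  identifier; recurrence counts distinct families, never individuals.

## Filter thresholds

| parameter | default | meaning |
|---|---|---|
| `min_total_reads` | 10 | read depth at the site |
| `min_variant_reads` | 5 | reads supporting the alternate allele |
| `min_unique_starts` | 5 | distinct read starts; substitutions only, the rule is skipped when the field is absent (indels) |
| `min_variant_fraction` | 0.28 | alternate-allele read fraction |
| `max_panel_maf` | 0.001 | MAF = AC/2N ceiling per enforced reference panel |
| `phylop_min` | 3.0 | conservation floor for missense variants |

All thresholds are inclusive. Truncating consequences (nonsense,
frameshift, canonical ±1/2 splice site) qualify regardless of PhyloP — a
deliberate asymmetry: conservation scores at splice dinucleotides are not
informative about transcript disruption. The in-house-style panel is
handled like any other panel; setting a per-panel ceiling of 0.0
(`panel_max_maf={"inhouse": 0.0}`) reproduces the stricter
"absent from the database" policy, so both published readings of that rule
are one configuration apart.

A missense record with no PhyloP value cannot be classified and is
excluded *with a logged warning* — silence here would look like a
conservation verdict.

## Burden statistics

Per recurrent gene the pooled qualifying-variant count T is split under
the null proportionally to cohort sizes (55 : 164 by default — individuals,
not chromosomes; the ratio is identical). Pearson's goodness-of-fit
statistic with 1 df is used without continuity correction; the exact
Fisher backstop (two-sided, minimum-likelihood convention) is applied at
the replication stage where counts are small and panels are large. The
chi-square burden unit defaults to variant observations ("frequencies of
variants"); carrier counting is available (`unit="carriers"`) and is always
used for the Fisher 2×2 tables, whose margins are individuals.

Benjamini–Hochberg is implemented in-package because the screen corrects
over *m* ≥ the number of supplied p-values (e.g. over every recurrent gene
when only a subset is carried forward); the step-up rule and adjusted
p-values follow the standard definitions and are cross-checked against
statsmodels when m equals the list length. Retention for triage uses raw
p ≤ 0.05 with the FDR flags reported alongside: the screen is a *filter*
whose discoveries are expected to need replication, and an all-null FDR
outcome must not silently empty the candidate list.

### What the screen's "type-I error" means

The screen only tests genes already recurrent in cases. Conditioning on
that selection inflates the per-gene rejection rate far above the nominal
α under a global null — with the default study conditions the conditional
rate is ≈ 0.5 at α = 0.05. This is not a defect of the chi-square
approximation but a property of screen-then-test designs (a published
screen of this shape retained 150 of 196 recurrent genes, a 0.77
conditional rate). The calibration routine therefore *reports* the
conditional rate with its Monte-Carlo standard error and raises a flag
when it exceeds α by more than three standard errors, rather than
asserting calibration that the design cannot deliver. For power
comparisons across relative risks the package reports, in addition to the
conditional rate, the *detection power*: the probability that a truly
enriched gene is both recurrent and rejected. The conditional rate is
nearly flat between relative risks 1 and 3 (selection inflates the null
exactly as enrichment inflates the alternative); detection power is the
quantity that orders cleanly (≈ 0.01 / 0.11 / 0.57 at relative risks
1 / 3 / 10 under the defaults).

## The synthetic-cohort generator

`simulate_cohort` draws, per individual and gene, a Poisson number of
variants with per-individual rate `background_rate / n_case`; spiked genes
multiply the case rate by a relative risk ≥ 1. Every emitted variant draws

* a consequence (truncating 0.15, synonymous 0.08, else missense —
  the truncating fraction matches the ≈ 15 % share of truncating calls
  among qualifying variants in screens of this design);
* PhyloP from a two-component uniform mixture on [0, 3) and [3, 7]
  (missense mass above 3.0: 0.65) so the conservation gate is exercised on
  both sides of its threshold;
* panel allele counts that are rare (0–1 alleles) except for a fraction
  (0.12) pushed just above MAF 0.001 in one panel;
* read-level fields that pass all four quality rules, except for a
  fraction (0.10) placed just below one rule chosen uniformly;
* a homozygous read fraction (≥ 0.97) with probability 0.02.

Ground truth records, per variant, which gates it truly passes and, per
gene, its relative risk; a test asserts that the real filter cascade
agrees with the construction truth on every variant.

Default study conditions are 55 cases vs 164 controls. The gene count
(150) and per-gene cohort rate (0.5) are a deliberately scaled-down exome:
they keep the per-gene regime of a real screen (a handful of recurrent
genes per cohort, small expected counts per gene) while letting a
500-replicate calibration run in seconds. The generator does **not**
simulate linkage or haplotype structure, platform batch effects, coverage
heterogeneity, population stratification, or annotation error — so passing
tests demonstrate the correctness and operating characteristics of the
*analysis*, not robustness to those real-data pathologies.

Determinism: all randomness flows from one integer seed through numpy's
PCG64; replicate seeds derive via `SeedSequence([seed, rep])`, so two
configurations sharing a seed share their replicate seed set
(common-random-number comparisons across relative risks).

## The demonstration bundle

`make_paper_fixture` embeds the eight discovery observations and one
replication observation of a published candidate table — transcript-level
changes, PhyloP scores, predictor labels and panel allele counts verbatim —
inside noise variants constructed to fail exactly one gate each. Genomic
positions are synthetic placeholders (the source table reports
transcript coordinates only; no stage consumes absolute positions). One
embedded variant is known to have failed the original study's quality
settings but is counted in its published table; the bundle gives it
passing read evidence so the pipeline reproduces the published tally.
The control-2 per-gene comparison counts are the per-variant control-panel
allele counts summed per gene. The shipped gene-list packs are editable
starter snapshots with provenance headers, not pinned reproductions of the
original study's lists (whose driver and pathway snapshots came from
external catalogues that have since drifted); the demonstration only
requires that *PTPN12* is a driver-list member and *LRP6* a mouse-screen ∩
KEGG member, which is stable across catalogue versions.

## Numerical choices and edge cases

* MAF is returned to 7 significant digits (the rendering precision of
  published frequency tables); the monotonicity and saturation invariants
  hold after rounding.
* A pooled count of zero makes the burden test undefined and is an error,
  not a p-value of 1 — a gene with no qualifying variants anywhere should
  never reach the test.
* Fisher's odds ratio is reported as infinity when a zero cell unbounds
  it; p-values use scipy's exact implementation, validated against
  exhaustive integer-binomial enumeration.
* Ties: every threshold is inclusive; a PhyloP of exactly 3.0 and a
  variant fraction of exactly 0.28 are retained; BH uses ≤ throughout.
* Gene symbols are upper-cased at ingest; alias resolution is out of
  scope and left to the user's annotation pipeline.
* Report files are written with deterministic ordering (gene symbol, then
  position) so identical inputs produce byte-identical reports.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the calibration at 55 vs 164
individuals over 150 genes with 400–500 null replicates and 150–200
replicates per relative-risk point (8 spiked genes), giving Monte-Carlo
standard errors of ~0.01 on the null conditional rate and ~0.01–0.02 on
detection power. These sizes are the package's chosen reporting
conditions; larger runs only tighten the error bars.

## Known limitations

* No covariate adjustment, kinship inference, or population-stratification
  correction; the design assumes the control panel is ancestry-matched.
* No variance-component (SKAT-style) tests: the burden statistic has no
  power against genes with bidirectional or heterogeneous effects.
* The compound-heterozygote caller cannot verify trans configuration.
* VCF ingestion expects the documented INFO/FORMAT convention
  (GENE/CSQ/PHYLOP/AC_*/N_* and DP/VR/US); arbitrary annotation tools'
  outputs need a thin conversion step.
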