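# Methods

## Study design emulated

Two genotypes — salt-tolerant (E) and salt-sensitive (N) — are sampled at
0, 4 and 24 h of salt treatment, giving six samples (SE0, SE4, SE24, SN0,
SN4, SN24). Each sample has a single mRNA-seq library, a single small-RNA
library and three biological iTRAQ replicates. Treated samples are always
compared against the time-0 control of the same genotype (E4/E0, E24/E0,
N4/N0, N24/N0). All stages start from post-quantification tables; read
alignment, spectral search and database retrieval are out of scope and are
replaced by user-supplied (or simulated) tables.

## Differential expression without replicates

With one library per condition no within-condition dispersion is
identifiable, so the DEG caller uses the conditional exact binomial test:
given the total x + y for a gene across the two libraries, under the null
of equal relative abundance x ~ Binomial(x + y, N₁/(N₁+N₂)). The two-sided
p-value doubles the smaller tail (each tail including the observed count)
and is capped at 1; for equal library sizes this is the classical
single-library count test. Doubling a discrete tail makes the test mildly
conservative, which the null calibration quantifies (observed false-positive
rate ≈ 4.6% at α = 0.05 over 100,000 null genes).

Fold changes are formed on RPKM with a floor of 0.01 before the ratio, so
genes absent from one library get a large but finite log₂ fold change.
Benjamini–Hochberg correction is applied within each comparison (the four
comparisons are reported as separate DEG sets), with genes processed in
identifier order so ties resolve reproducibly. Calls require
|log₂ ratio| ≥ 1 (inclusive) and FDR < 0.001 (exclusive).

The same test drives miRNA differential expression, after the eligibility
filters (RPM ≥ 10 in at least one of the two compared samples — "either" by
default, switchable to "both" since the published wording is ambiguous —
and a six-sample RPM sum strictly greater than 60). miRNA calls use
P < 0.05 with |log₂ fc| strictly greater than 1.

## Protein differential abundance

The "average ratio" of the three replicate iTRAQ ratios is the geometric
mean (arithmetic mean of log ratios), because ratios compose
multiplicatively; an arithmetic-mean toggle is provided since the published
description does not specify the mean. The location test is a two-sided
one-sample t-test of the log₂ replicate ratios against 0. Replicate vectors
with fewer than two present ratios, or with zero variance, yield a missing
p-value and can never be called differentially abundant: a constant
replicate vector carries no information about replicate scatter, and
treating it as infinitely significant would let single-channel artefacts
through. Bounds 1.2 and 0.833 are treated as asymmetric published constants
(0.833 ≈ 1/1.2) and both are exclusive. Proteins must also have at least
one peptide among the three replicates to be quantified at all.

## Concordance categories and correlations

Categories I–VI partition every measured gene–protein pair per comparison
(see README). Pairs quantified at both levels but significant at neither
carry no category yet still enter the all-pairs correlation, which uses the
gene log₂ fold change against log₂ of the protein mean ratio so both axes
share a scale. Genes mapped to several proteins form one pair per protein;
no aggregation is attempted. Subsets with fewer than three pairs report an
undefined r.

## Alternative splicing

Gene-level AS status is binary (≥ 1 event of any type in a sample);
cross-sample quantitation of event counts is deliberately not attempted
because depth normalisation for event detection is not well defined from
event tables alone. "Salt-induced" means events at the treated time point
and none in the genotype's time-0 control; the reverse ("lost") set is
computed but not used for candidates. AS-DEG candidates require the
tolerant-genotype response to exceed the sensitive one in absolute log₂
fold change; a `require_tolerant_as` flag (default on) restricts candidates
to AS observed in the tolerant genotype.

## miRNA target scanning and chains

Target sites are gapless antiparallel duplexes: the reverse complement of
the miRNA slides along each CDS and each offset scores
mismatches + 0.5·wobbles, where a G:U pair (miRNA G opposite transcript U,
or miRNA U opposite transcript G) is a wobble. The 0.5 weight follows the
common plant target-prediction convention and can be set to 1.0 to score
wobbles as full mismatches. Sites with penalty strictly below 3 are
reported; T and U are equivalent on input. Chains require a sequence-level
hit plus anticorrelated differential calls in the same tolerant-genotype
comparison; miRNAs DE only in the sensitive genotype are removed first. A
triple that is anticorrelated at both the gene and the protein level is
reported once, at gene level (transcript degradation takes precedence over
the translational-repression interpretation).

## Screening rules

Rules i–v and the protein-only screen are de-duplicated with precedence
i → v, recording the first matching rule. "Common regulation" (rules i and
iv) requires the same direction in both genotypes. Rule iv's quantitation
comparison is interpreted on the log₂ scale of the mean ratios, consistent
with rule i's log₂ form. Each candidate record stores the effects it was
admitted on, so every rule predicate can be re-checked from the output
table alone.

## Synthetic data generator

The generator is first-class, tested code. Distributional choices (the
source tables never state distributions, only tool outputs):

* **mRNA/miRNA counts** — independent Poisson draws around the expected
  abundance, one library per condition; a `noise="none"` mode replaces
  draws with rounded expectations. Gene baselines are log-normal
  (median 200 expected counts, σ = 1.2 on the log scale, floored at 10)
  at a library depth of 5 × 10⁶; planted effects are uniform on
  log₂ ∈ [2, 4] with random sign.
* **Proteins** — replicate ratios scatter log-normally around the
  category-implied true ratio with σ = `protein_cv` (≈ CV of the ratio,
  default 0.10); peptide tallies come from a small discrete distribution
  that populates all four identification tiers; planted non-null proteins
  are quantified in all three replicates so their status is testable,
  while null proteins draw partial presence patterns. Category V proteins
  are identified but never quantified; category VI proteins map to genes
  absent from the expression matrix.
* **Planted structure** — each screening rule receives a configurable
  number of guaranteed hits with effects placed safely inside its
  predicate; concordance categories are drawn for 10% of the
  protein-mapped genes with probabilities (0.12, 0.08, 0.30, 0.20, 0.15,
  0.15) for I–VI. Genes that respond in both genotypes are planted with
  equal gene effects (so they fail rule i's margin) and, for shared
  category IV proteins, with a strictly stronger sensitive-genotype ratio
  — an exactly equal plant would sit on rule iv's strict inequality and
  make recovery a coin flip under any noise.
* **miRNAs** — 21-nt uniform-random sequences; CDSs are uniform-random DNA
  of 300–1500 nt. Abundances are designed in count space so the per-sample
  column total approximates the 2 × 10⁶ small-RNA depth; a 15% low-abundance
  group sits safely below both RPM filters. Planted targets carry the
  reverse complement of their miRNA with 0–2 injected mismatches at a
  recorded offset; for a random 21-mer against random CDS the chance of a
  spurious penalty < 3 hit is negligible (< 10⁻⁹ per offset).
* **AS events** — per-gene Bernoulli per sample (control 0.05, treated
  tolerant 0.09, treated sensitive 0.03, mirroring the observed direction
  of change), 1 + Poisson(0.7) events per positive gene-sample, type
  probabilities (0.55, 0.20, 0.13, 0.12) for IR/ES/A5SS/A3SS. The drawn
  events are themselves the truth; no separate noise layer exists.
* **PPI** — every true candidate is mapped to an ortholog; two hub nodes
  are wired to disjoint halves of the candidates with scores in (200, 900);
  a 30-node background with scores straddling the 160 cutoff exercises the
  edge filter.
* **Seeding** — one master seed; each generator stage draws from its own
  `SeedSequence`-spawned stream, so identical configurations give
  byte-identical output files.

**The noise-free limit.** "Zero noise" means counts equal their rounded
expectations and the replicate scatter is 10⁻³ rather than exactly 0,
because identical replicates have a missing p-value by design (above) and
could never be called. The noise-free preset also raises the baseline floor
to 100 expected counts so that the weakest planted effect (4-fold) is
decisive at the simulated depth even for down-regulated genes. In this
limit the pipeline recovers planted DEGs, DAPs, categories, candidates,
chains and hubs exactly (sensitivity 1.0, zero false discoveries).

**What the generator does not emulate:** gene-length biases and GC effects,
overdispersion beyond Poisson, correlated replicate structure in iTRAQ
channels, isoform-level AS quantitation, miRNA biogenesis (hairpins) and
degradome evidence, and real PPI topology. Passing recovery tests therefore
demonstrates the correctness of the decision logic and its thresholds, not
robustness to every real-data pathology.

## Numerical conventions

Tables are TSV with empty cells for missing values and six significant
digits for floats; a written table is the canonical form of its data and
round-trips exactly. BH ties and hub-degree ties break by identifier.
Degenerate inputs (empty tables, empty graphs, subsets below size 3)
return empty or undefined results rather than errors; genuinely invalid
inputs (unknown AS types, non-nucleotide characters, malformed scores,
inconsistent configurations) raise errors naming the offending field, row
or position.

## Problem sizes

Defaults are a desk-scale version of the study (2000 genes, a 400-protein
mapped subset, 60 miRNAs versus 42k genes / 4004 proteins / thousands of
miRNAs in the original design). Null calibration uses 5000 genes over 20
simulations; noisy recovery uses 10 simulations. These sizes give stable
estimates (binomial standard error < 0.1 percentage points on the null
false-positive rate) while keeping a full validation run under a minute.
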