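# Methods

## Scope and model

`famexome` implements family-based triage of exome variant calls for a fully
penetrant (modulo age) autosomal dominant disorder, plus a per-base audit of
how much of each candidate gene was actually screenable. It consumes called,
annotated variants; alignment, variant calling and functional annotation are
upstream and out of scope. Variant identity is allele-level
(chrom, pos, ref, alt), chromosome names normalized by stripping a leading
`chr`. Multi-allelic records are split per alternate allele before any
filtering, so frequency joins and control exclusion are well-defined per
allele; indels are kept as given in the input (no left-align
re-normalization — a documented limitation). Annotation terms are taken
verbatim from the input, lower-cased; no re-annotation is attempted.

## The cascade

Stages and their exact predicates are in the README. Choices worth noting:

- **"Found in controls"** means any non-missing, non-hom-ref control genotype
  at the same allele-level key. The intent of the stage is removal of shared
  sequencing/processing artifacts, so presence of the allele in any control
  suffices; zygosity is irrelevant.
- **"Shared in all cases"** requires a non-missing carrier genotype in every
  case. A missing genotype fails sharing: this is deliberate and mirrors the
  operational reality that loss of coverage in one case hides a shared
  variant — the coverage audit exists precisely to quantify that risk.
- **Frequency removal** uses `freq >= cutoff` in *any* panel (inclusive
  boundary at the default 1%); a variant absent from every panel is retained.
  Treating missing as common would discard exactly the novel alleles a
  rare-disease design is looking for.
- **"Coding indel"** is operationalized as: indel allele lengths differ and
  at least one coding-class annotation term is present. The qualifying
  coding-term set is configurable because annotation vocabularies differ
  between annotators.
- **No depth/quality gating.** The cascade never looks at DP/AD/QUAL. For a
  dominant disorder with candidate genes, filtering on read support risks
  discarding the true mutation at an under-covered site; review plus
  orthogonal confirmation is the intended error control.
- Stage (ii) applies control exclusion and sex-chromosome exclusion in one
  reported stage; the two removals commute (both are per-variant predicates),
  which the suite asserts as a property rather than fixing an order.
- SNV and indel counts are tracked separately at every stage and summed into
  per-stage totals.

## The coverage audit

CCDS+splice intervals are built per gene by expanding each exon by
`flank` (default 10) bases on both sides and merging overlapping or adjacent
expansions; coordinates are 1-based inclusive internally and converted from
0-based half-open on BED input. Withdrawn exon records (a `status` column in
the gene-model TSV) are dropped before building.

A base fails for a sample iff `depth < depth_min` (default 10) **or**
`site_qual < qual_min` (default 50); a base with no record in the track is
failed, because the upstream caller emits records only for confident sites.
Percentages are computed by exact decimal division and rounded **half-up**
to 2 decimals (1 decimal for the gene-set-wide fraction); IEEE-754 nearest-
even rounding produces a different answer on boundary cells (e.g. a
672-of-2227 cell rounds to 30.18 only under half-up), and the package ships
the published 24-gene benchmark table
(`famexome/data/muscle_gene_coverage_benchmark.tsv`) against which this
arithmetic is verified: every printed all-cases percentage is recomputed
from its printed counts, 24 genes meet the 30% threshold in at least one of
the five benchmark exomes, and 8 meet it in all of them.

Threshold summaries come in two scopes: `any-sample` (max per-sample failed
percentage) answers "was this gene adequately screened in everyone?", and
`all-samples` (failed-in-every-sample percentage) answers "is this gene
systematically un-capturable?".

## Segregation

Violations under the dominant model: an affected hom-ref individual, and an
unaffected carrier aged (at last exam) at or above the family's **maximum
onset age among affecteds**. Younger unaffected carriers are excused and
reported, since the disease may not yet have manifested; this formalizes the
age-allowance reasoning used in late-onset myopathy pedigrees. Married-in
status does not exempt a carrier from the age rule (married-ins function as
within-family controls); it is echoed in the violation reason only.
Unknown-affection carriers are recorded but never constrain the verdict;
missing genotypes constrain nothing. An unaffected carrier with no recorded
exam age is a violation — the allowance cannot be applied blind — and an
unaffected carrier with *no* onset ages on record at all is an error, since
the allowance is undefined. Concordance against orthogonal genotypes marks
untestable assays (e.g. homopolymer context) as excluded from the
denominator; the false-positive signature is "every testable exome-carrier
confirmed hom-ref".

## The synthetic generator

The generator emulates the data of a two-to-three-generation dominant family
with exome-sequenced cases and controls. Defaults are the study conditions:
3 cases, 3 controls (one a married-in spouse), 102 candidate muscle-disease
genes with CCDS totals spread over ~300–16,000 bases, 2,004 candidate-gene
SNVs + 410 indels found in at least one case, two frequency panels, a causal
variant emulating a non-canonical splice mutation (intronic term,
distance-to-splice 3, shared het in all cases, absent from panels and
controls) and one planted false-positive missense shared by all cases whose
confirmation genotypes are hom-ref. The exome-wide remainder is emulated
scaled-down (2,000 background SNVs + 400 indels across 150 background genes,
some on X/Y) to keep generation fast; the candidate-gene stratum, where all
quantitative claims live, is at study scale.

Stratum fractions (85% common, 61.1% of rare calls present in a control,
16.3% likely-functional, 3% of rare variants shared by all cases) were
derived once from the funnel shape of the motivating design
(2414 → 419 → 141 → 23 → 2) and fixed. Common variants draw a panel
frequency uniform on [0.01, 0.5] and sample every individual's genotype from
Hardy–Weinberg proportions at that frequency (conditioned on at least one
case carrier), so panels and family genotypes are mutually consistent; rare
variants realize explicit sharing/artifact flags. With the default seed the
replayed funnel lands at 2414 → 650 → 133 → 26 → 3 — the stage-(ii) removal
is somewhat weaker than the template because control carriage here arises
only from Hardy–Weinberg sampling and planted artifacts, not from the
additional caller-artifact correlation real control exomes exhibit. The
funnel is logged, not asserted.

Coverage gaps are planted as contiguous run-length blocks (capture dropouts
are contiguous, not i.i.d. bases): per gene a shared block failed in every
sample (fraction uniform on [0, 0.13], mean 6.5%) plus a private block per
sample (uniform on [0, 0.10]). Failed bases fail by low depth (~60%) or low
quality (~40%); the exact planted per-gene counts go into the manifest.

Every variant's intended cascade fate is computed at construction time by an
inline re-derivation of the five predicates from raw attributes —
independent of the cascade implementation — and recorded in the bundle
manifest together with per-file MD5 checksums, the causal variant's
genotypes across the full pedigree, and the confirmation genotypes of the
planted artifact. Identical configs (including seed) produce byte-identical
bundles.

**What passing tests do and do not show.** The generator has no read-level
error model, no linkage disequilibrium, no relatedness structure in
background genotypes, no annotation noise and no multi-allelic sites beyond
what the loaders are unit-tested on. Green tests therefore demonstrate that
the *logic* of filtering, auditing and segregation is correct against
independent oracles — not that the thresholds are optimal for any particular
real capture kit or caller.

## Numerical and degenerate-input choices

- Percentage rounding: decimal half-up (see above); never float `round`.
- Empty candidate gene set: rejected at construction, not silently permissive.
- Zero input variants: a valid run with all stage counts 0.
- A gene with no exons: zero-length interval set, total 0 bases; the gene-set
  fraction errors only when the whole set has 0 bases.
- Duplicate frequency-panel keys: last wins, with one logged warning.
- Conflicting non-missing genotypes for one sample when merging per-case
  tables: an error (silent overwrite would fabricate data).

## Problem sizes used by the test suite and acceptance script

The suite replays 1,000 seeded families at a reduced per-family scale
(100 candidate SNVs + 15 indels + 30 background variants over 20 candidate
genes) for the truth-tracking property, and 1,000 random small gene models
(≤5 exons, ≤500 bases) for brute-force audit equivalence; the acceptance
script uses 200 replicates at the same reduced scale plus one full
study-scale bundle end-to-end. These sizes are the package's own choice of
desk-scale verification; all structural fractions are the defaults above.

## Known limitations

- No recessive or compound-heterozygous models; the ≥1% frequency removal is
  explicitly unsafe for recessive alleles carried by healthy individuals.
- No indel normalization/liftover; inputs must share one genome build and
  one left-alignment convention.
- The site-quality score is treated as site-level, shared across samples at
  a site (one QUAL per VCF record); callers that emit per-genotype qualities
  are reduced to their site value.
- No literature/pathogenicity lookup: stage-(iv) survivors not shared by all
  cases still warrant manual review, since a single missing genotype removes
  a true variant at stage (v).
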