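# famexome

Family-based exome variant triage for autosomal dominant Mendelian disease,
with a per-base coverage audit of candidate disease genes and a synthetic
family-exome generator that makes the whole pipeline verifiable without any
sequencing data.

## The problem

Molecular diagnosis of genetically heterogeneous disorders — the motivating
case is limb-girdle muscular dystrophy, with more than 100 known skeletal-
and cardiac-muscle disease genes — faces two coupled obstacles when exome
sequencing is used on a family:

1. **Too many variants.** A multi-sample exome call set for a few affected
   relatives contains tens of thousands of variants; the causal mutation must
   be isolated by filtering, not by inspection.
2. **Too little coverage where it matters.** Capture and alignment leave
   per-individual gaps inside known disease genes. For a *dominant* disorder a
   heterozygous call needs adequate high-quality read depth, so a gap can
   silently hide the answer — and the gaps differ between individuals.

`famexome` implements both halves of that workflow as a tested library plus a
CLI.

## The filtering cascade

For cases $C$, control exomes $K$, frequency panels $P$ and candidate gene
set $G$, a variant $v$ (identified allele-wise as chrom:pos:ref:alt) survives:

- **(i)** $v$ is called non-reference in at least one case (and $\mathrm{gene}(v)\in G$
  in candidate-genes mode);
- **(ii)** no control in $K$ carries $v$, and $v$ is autosomal;
- **(iii)** $\max_{p \in P} f_p(v) < 0.01$ (a variant absent from a panel is
  treated as rare, never as common);
- **(iv)** $v$ is *likely functional*: an annotation term in
  {nonsense, stop-gain, stop-lost, frameshift, missense}, **or** within 10
  bases of a splice junction (deliberately admitting synonymous and intronic
  variants — this is how non-canonical splice mutations are recovered),
  **or** a coding indel;
- **(v)** every case carries $v$ (a missing genotype fails sharing).

No read-depth or quality threshold is applied at any stage: a true mutation
supported by 5 reads in one case survives as long as it was genotyped. The
frequency filter at (iii) is only appropriate for dominant disease.

## The coverage audit

Each gene's CCDS+splice region is the union of its coding exons expanded by
10 bases on both sides (overlaps merged so no base is double-counted). A base
is **failed** for a sample iff

```
depth < 10  or  site_qual < 50        (absent record => failed)
```

Per gene the audit reports failed bases per sample, bases failed in *every*
sample, and percentages rounded half-up to two decimals, plus threshold
summaries (which genes failed ≥30% of their bases in at least one / in every
individual) and the overall failed fraction of the gene set.

## Segregation with an age allowance

A candidate is tested under a dominant model: any affected homozygous-
reference individual is a violation, and so is any unaffected carrier whose
age at last exam is at or above the family's oldest onset age. An unaffected
carrier *younger* than that oldest onset is excused (they may simply not have
manifested yet). Exome and orthogonal-confirmation genotypes can be compared
per sample; a variant called heterozygous in every case but homozygous
reference on confirmation carries the false-positive signature.

## Worked example

```bash
famexome simulate --seed 1 --out bundle/
famexome run-all --bundle bundle/ --out report/
```

prints the candidate-gene filtering funnel and the segregation verdicts for
the stage-(v) survivors:

```
(i) 2414 variants (2004 SNVs, 410 indels)
(ii) 650 variants (537 SNVs, 113 indels)
(iii) 133 variants (114 SNVs, 19 indels)
(iv) 26 variants (23 SNVs, 3 indels)
(v) 3 variants (3 SNVs, 0 indels)
1:1117024:A:G: segregates=True excused=0
2:1009691:A:G: segregates=True excused=1
6:1061340:G:T: segregates=True excused=0
```

2,414 raw calls inside the 102 candidate muscle-disease genes shrink to 3
shared, rare, likely-functional candidates. `2:1009691:A:G` is the planted
causal variant (an intronic substitution 3 bases from a splice junction in
*DES*, recorded in `bundle/manifest.json`); it segregates with one excused
carrier — an unaffected 27-year-old, below the family's oldest onset age.
`6:1061340:G:T` is the planted false-positive artifact, which
`famexome.segregation.genotype_concordance` flags because its confirmation
genotypes are homozygous reference in every case. `report/coverage_table.tsv`
lists the genes whose CCDS+splice bases failed ≥30% in at least one exome,
with per-sample percentages.

Variant tables may be VCF 4.x (annotations in INFO keys `GENE`, `FUNC`,
`DTS`; per-sample `GT:AD:DP`) or an equivalent flat TSV with columns
`chrom, pos, ref, alt, gene, annotation, distance_to_splice, qual` followed
by `<sample>.GT`, `<sample>.AD`, `<sample>.DP` per sample. Frequency panels
are 5-column TSVs (`chrom, pos, ref, alt, freq`); gene sets are
one-symbol-per-line text; gene models are 4-column exon TSVs or BED;
coverage tracks are per-sample TSVs (`chrom, pos, depth, qual`).

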