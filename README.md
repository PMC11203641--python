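# bulkseg

Bulked-segregant analysis (BSA) for monogenic mutants, built around the
workflow that maps an induced recessive mutation from just two pooled
sequencing libraries: a bulk of mutant-phenotype plants and a bulk of
wild-type siblings from the same segregating family.

## Who this is for, and what it does

A mutagenised selfed line segregating 3:1 for a recessive phenotype carries
one causal lesion hidden among hundreds of induced background variants.
`bulkseg` re-implements the candidate-identification logic as a tested,
reusable library plus CLI:

1. **Record filtering** — Picard `FilterVcf`-style hard filters
   (MIN_AB = 0.8 on homozygous calls, MIN_DP = 6, MIN_GQ = 0, MIN_QD = 2).
2. **Effect restriction** — keep variants annotated *missense* or
   *frameshift* (SnpEff `ANN` or a simplified `EFF=class|gene` dialect).
3. **Bulk subtraction** — drop variants called in both bulks, keyed by
   (chrom, pos, ref, alt).
4. **Consistency scoring** — for each mutant-bulk-specific variant, two
   exact two-sided binomial tests of the observed allele depths against the
   frequencies the cross predicts. For a recessive locus the mutant bulk is
   fixed for the mutant allele (SNP index 1), while wild-type segregants are
   1/3 hom-ref : 2/3 het, so a wild-type bulk carries the mutant allele in
   1/3 of its reads (e.g. ~9 of 27 reads). The score of a candidate with
   `a` alt reads of `n` in the mutant bulk and `a'` of `n'` in the WT bulk is

   `score = P_minlike(a | n, 1·(1−e)+e·0) × P_minlike(a' | n', 1/3·(1−e)+2/3·e)`

   where `P_minlike` is the minimum-likelihood exact binomial p-value and
   `e` the per-read error rate. The causal variant is the one that is
   *unsurprising* in both bulks.
5. **IGV batch script** — emits `new/genome/load/goto/snapshot` commands so
   every top candidate can be confirmed on read alignments by eye.

Around this core the package implements the supporting genetics of such a
study: chi-square goodness of fit for 3:1 segregation, marker–phenotype
cosegregation checks, cultivar-panel haplotype classification (haplotypes
carried by ≥2 accessions, tabulated by origin or maturity group and tested
for independence), coding-sequence deletion effects (frameshift vs
in-frame, translation, protein diff), spectrophotometric pigment
quantification (chl a = 9.784·OD663 − 0.990·OD645, etc.), and −ΔΔCt
relative expression. A forward simulator generates every input the
pipeline consumes — families, bulk read depths, VCFs, panels, OD readings —
so the whole analysis is testable without external data.

## Worked example

Simulate two bulks (12 mutant / 28 wild-type plants, mean depth 30×, 500
background variants, 0.001 per-read error) and rank candidates:

```bash
$ bulkseg simulate bulks --n-mutant 12 --n-wt 28 --depth 30 \
    --background 500 --error 0.001 --seed 1 --out-dir sim
wrote sim/mutant.vcf, sim/wt.vcf, sim/truth.tsv

$ bulkseg compare --mutant sim/mutant.vcf --wt sim/wt.vcf \
    --out candidates.tsv --igv-script batch.txt --flank 500
wrote 55 candidates to candidates.tsv
wrote IGV batch script to batch.txt

$ head -2 candidates.tsv
chrom   pos       ref          alt  gene         mut_index  wt_index  p_mut  p_wt     score    rank  wt_testable
Chr02   47983484  CTTGGATACCA  C    gene_causal  1.0        0.4857    1.0    0.07166  0.07166  1     1
```

The planted causal 10 bp deletion ranks 1: its SNP index is 1.0 in the
mutant bulk (every read carries the deletion) and ~0.49 in the wild-type
bulk — within binomial scatter of the expected 1/3 — so both consistency
p-values are large. Background variants fail one test or the other and
score orders of magnitude lower. The IGV script frames the deletion with a
500 bp flank:

```
$ head -6 batch.txt
new
genome genome
load sim/mutant.vcf
load sim/wt.vcf
snapshotDirectory snapshots
goto Chr02:47982985-47983994
```

Segregation tests on phenotype counts from an M4 family and an F2 cross:

```bash
$ bulkseg segtest --counts 111,361 --ratio 1,3
chi2=0.5537	df=1	p=0.4568
$ bulkseg segtest --counts 206,675 --ratio 1,3
chi2=1.2293	df=1	p=0.2675
```

Neither rejects the 3:1 single-recessive-gene expectation. The library API
mirrors the CLI (`bulkseg.run_pipeline`, `bulkseg.chi2_gof`,
`bulkseg.classify_haplotypes`, `bulkseg.quantify_reading`, ...); see the
module docstrings and `docs/methods.md`.

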