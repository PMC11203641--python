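# Methods

## The inheritance model

Everything rests on a single-locus Mendelian model (`CrossDesign`). A
selfed line or F2 family descending from a heterozygous parent has genotype
prior 1/4 hom-ref : 1/2 het : 1/4 hom-alt at the causal locus; phenotype is
a deterministic function of genotype (recessive: mutant iff hom-alt).
Conditioning the prior on phenotype gives the expected mutant-allele
frequency of a phenotype-selected bulk as the dosage-weighted mean:

* mutant-selected bulk (recessive): 1.0 — every plant is hom-alt;
* wild-type-selected bulk: plants are 1/3 hom-ref : 2/3 het, so the
  frequency is (2/3)·(1/2) = **1/3**.

Note the het fraction among wild-type segregants is 2/3, not 1/2; informal
descriptions of such screens sometimes say "half the WT plants are
heterozygous", but 1/3 is the Mendelian bulk-frequency expectation and is
what the scoring uses.

## Consistency scoring

For allele depths `a` of `n` reads and hypothesised frequency `p0`, the
package computes the exact two-sided binomial p-value by the
minimum-likelihood rule: the sum of pmf(k) over all outcomes k with
pmf(k) ≤ pmf(a). Ties are recognised to a relative tolerance of 1e-7
(`_TIE_RTOL`): a float such as `1/3` only approximates the intended
rational frequency, which perturbs exactly tied outcome probabilities by
~1 part in 1e16, and the tolerance keeps intended ties tied. This matches
the convention of standard exact-test implementations, and the test suite
cross-checks every value on a full grid (n ≤ 30) against
`scipy.stats.binomtest` and an independent enumeration.

Candidate score = p_mutant × p_wt. The product (rather than, say, Fisher
combination) was chosen because it is monotone in each test and directly
interpretable with only two components. Expected frequencies are folded
with the per-read error rate e (default 0.001, the generator's default):
p0' = p0(1−e) + (1−p0)e. Without this, the mutant-bulk expectation is
exactly 1 and a *single* miscalled read at the causal site (probability
≈ 3% at 30× and e = 0.001) forces p_mutant to 0 and destroys the ranking;
with it, such a site keeps a small but dominant score. Setting
`error_rate=0` recovers the unadjusted expectations.

Sites with zero wild-type depth cannot be tested on the wild-type side;
they receive p_wt = 1 but are flagged `wt_testable=False` rather than
rewarded. Ties in score are broken by |Δ(SNP index) − 2/3| (the expected
index difference under the recessive design), then by (chrom, pos), making
the ranking a deterministic total order.

## Call sets and bulk subtraction

`subtract_common` is a pure key-level set difference on
(chrom, pos, ref, alt), as in a spreadsheet subtraction of two variant
lists. What makes it informative is how each bulk's *call set* is defined
(`BulkVariantSet.from_records`): a record belongs to a bulk's variations
when its genotype call is non-reference, and — by default — heterozygous
**indel** calls are not emitted. This models the behaviour of conservative
pooled-sample indel calling: an indel fixed in one bulk is called cleanly,
while the same indel segregating at intermediate frequency in the other
bulk is characteristically missed, leaving it bulk-specific after
subtraction even though its reads are visibly heterozygous in the opposite
bulk's alignments. That caller asymmetry is precisely what lets a
subtraction-based screen retain a causal indel; an idealised caller is
available with `call_het_indels=True` (under which a causal indel called
het in both bulks would be subtracted, and the screen would have to rely
on SNV candidates). The wild-type depths used for scoring come from the
full record set (a depth lookup at every site), not from the call set, so
an uncalled site still contributes its read evidence.

Record-level filters reproduce a Picard `FilterVcf`-style hard filter with
inclusive thresholds: total depth ≥ 6, genotype quality ≥ 0, quality-by-
depth ≥ 2 (INFO QD, else QUAL/depth), and an allele-balance floor of 0.8
applied to **homozygous calls only**. A heterozygous call legitimately has
~50% support per allele — and a pooled bulk even less — so an AB floor on
het calls would discard exactly the segregating sites the analysis needs;
restricting it to homozygous calls is the only reading under which a
candidate het-pattern site (9 of 27 reads) survives filtering. Records
missing a field fail the corresponding test conservatively and are dropped
with a logged count; multi-allelic sites are split into bi-allelic records
first, pooling depths of the untested alleles into the reference depth.

## The forward simulator

The generator's defaults are the study conditions the analysis assumes:

* **Family**: genotypes i.i.d. from the 1/4:1/2:1/4 prior; phenotypes
  deterministic. Pipeline experiments simulate a 120-plant line so that
  both bulks (12 mutant, 28 wild-type plants — the empirical bulk sizes of
  such screens) can essentially always be drawn; the read-ratio experiment
  uses 60 plants, enough for the 28-plant wild-type bulk.
* **Bulk composition**: plants are drawn *without replacement* from the
  phenotype class, so the finite-sample het fraction of a 28-plant bulk
  varies between replicates exactly as in the field.
* **Depth**: Poisson(mean 30) per site with a floor of 1 read — the
  standard shotgun assumption; sub-Poisson depth structure (GC bias,
  mappability) is not modelled.
* **Sequencing error**: symmetric per-read allele flip, default 0.001.
* **Background load**: 500 variants per run. Effect classes uniform over
  {missense, frameshift, synonymous, intron, intergenic} (only the first
  two survive the effect filter); 40% are shared between bulks at a common
  segregating frequency (these exercise the subtraction), the rest are
  private to one bulk at Uniform(0.15, 1) frequency, reflecting sub-line
  private mutations and caller dropout; 10% are short indels. These knobs
  (`shared_fraction`, `indel_fraction`) set a realistic order of magnitude
  for a mutagenised line (bulk-specific counts in the hundreds to low
  thousands); the true background density of any particular library is a
  free parameter.
* **Variants are unlinked**: no linkage block around the causal locus is
  simulated, so the simulator cannot produce the cluster of linked
  candidates a real screen shows near the causal region. Passing tests
  therefore demonstrate statistical correctness of the scoring under the
  inheritance model, not robustness to linkage disequilibrium, alignment
  artefacts or annotation errors in real data.

Synthetic VCFs carry GT/AD/GQ and a simplified `EFF=class|gene` INFO key;
genotypes are called from the bulk alt-read fraction at 20%/80% thresholds.
Writing then re-reading reproduces the depth maps exactly, which the test
suite asserts.

## Haplotype classification

Cultivars are grouped by exact allele-tuple identity over the retained
loci after excluding loci inside an overlapping gene's region. Missing
calls become the distinct symbol `.` — a cultivar with missing data forms
or joins its own tuple; nothing is imputed. Haplotypes carried by fewer
than two accessions are dropped (the panel convention), labels `Hap_1…`
descend by carrier count with lexicographic tie-break, and group
association uses Pearson's chi-square of independence without continuity
correction. Panels are treated as effectively homozygous inbred lines;
heterozygous panel calls, if present, are just another allele symbol.

## Coding-sequence effects

Frameshift classification is purely length mod 3. Protein diffs trim the
longest common prefix then suffix and report net residue loss plus aligned
substitutions in the remaining cores — exact for a single indel with local
flank changes, and much cheaper and more deterministic than global
alignment (which backs it as a test oracle). Internal stop codons yield a
truncated product with a flag, not an error, since frameshifts routinely
create them. Genome-coordinate-to-CDS projection across exon structures is
out of scope: deletions are specified in CDS coordinates.

## Quantification

Pigment equations (80% acetone extract):
chl a = 9.784·OD663 − 0.990·OD645; chl b = 21.426·OD645 − 4.650·OD663;
carotenoid = 4.695·OD440 − 0.268·(chl a + chl b), all mg/L, converted to
mg/g fresh weight by ×volume/mass. The extract volume is a required input
— no default is assumed. Negative concentrations (possible with noisy
near-zero ODs) are returned with a warning, never clamped, so simulation
round trips stay exact. Totals are reported at two decimals in summaries.
The two-group comparison is Student's pooled-variance t-test by default
(Welch behind a flag); zero-variance degenerate inputs return t = 0, p = 1
for equal means and p = 0 with a warning otherwise. −ΔΔCt fold change is
2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control.

## Problem sizes used in the test suite

The simulation-backed tests use: 10,000 replicates for the wild-type-bulk
read-ratio mean and for each type-I-error calibration; 200 seeded runs of
the full pipeline (12/28 plants, 30× depth, 500 background variants,
e = 0.001) for the rank-1 recovery rate; 400-seed and 100-seed batches for
the segregation-ratio calibrations. These sizes put Monte-Carlo standard
errors well inside the asserted tolerances (e.g. ±0.2 reads on a mean
whose standard error is ≈0.03).

## Known limitations

* The screen's genome-scale variant counts from any real library depend on
  the mutagen dose, reference genome and caller; the simulator reproduces
  the *structure* of those call sets, not their absolute sizes.
* A real 10 bp first-exon deletion naively frameshifts the entire
  downstream protein; annotation-specific transcript models can reduce the
  reported protein change (e.g. to a dozen residues). The package reports
  the naive classification and leaves such transcript-specific
  reconciliation to the annotation.
* No sliding-window SNP-index plotting, BAM pileup access, or genome
  browser rendering; the IGV batch script delegates visual confirmation to
  IGV itself.
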