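"""The bulk-comparison core: effect restriction, subtraction, ranking, IGV.

The mapping logic of a two-bulk screen for a monogenic mutant: restrict
called variants to protein-changing effect classes, subtract the variants
common to both phenotype-selected bulks, score each bulk-specific variant
for consistency of its read support with the allele frequencies the
inheritance model predicts (fixed in the mutant bulk, one third in a
wild-type bulk for a recessive locus), rank candidates, and emit an IGV
batch script so a human can confirm the top hits on read alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genetics import CrossDesign, binom_consistency, expected_bulk_af
from .variants import VariantRecord, filter_records

__all__ = [
    "DEFAULT_EFFECT_CLASSES",
    "BulkVariantSet",
    "Candidate",
    "select_effect_classes",
    "subtract_common",
    "snp_index",
    "rank_candidates",
    "summarize_loci_genes",
    "variant_interval",
    "igv_batch_script",
    "depth_map",
    "run_pipeline",
]

#: Effect classes kept in the first round of candidate screening.
DEFAULT_EFFECT_CLASSES = frozenset({"missense", "frameshift"})

Key = tuple[str, int, str, str]


def select_effect_classes(
    records: Iterable[VariantRecord],
    classes: frozenset[str] | set[str] = DEFAULT_EFFECT_CLASSES,
) -> list[VariantRecord]:
    """Keep records carrying at least one annotation in ``classes``."""
    wanted = frozenset(classes)
    return [
        rec
        for rec in records
        if any(a.effect_class in wanted for a in rec.annotations)
    ]


@dataclass
class BulkVariantSet:
    """The variants *called* in one bulk, keyed by (chrom, pos, ref, alt)."""

    bulk_label: str
    records: dict[Key, VariantRecord] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantRecord],
        bulk_label: str,
        sample: str | None = None,
        call_het_indels: bool = False,
    ) -> "BulkVariantSet":
        """Build the call set of a bulk from its (filtered) VCF records.

        A record counts as a called variation when the bulk's genotype is
        non-reference.  Heterozygous *indel* calls are excluded by default:
        pooled-sample indel discovery is conservative, and an indel
        segregating at intermediate frequency in a bulk is characteristically
        missed by the caller while the same site fixed in the other bulk is
        called cleanly — the very asymmetry that lets bulk subtraction
        retain a causal indel whose reads are visibly heterozygous in the
        opposite bulk.  Set ``call_het_indels=True`` for an idealised caller.
        """
        out: dict[Key, VariantRecord] = {}
        for rec in records:
            call = rec.sample(sample)
            if call.genotype not in ("het", "hom_alt"):
                continue
            if (
                rec.is_indel
                and call.genotype == "het"
                and not call_het_indels
            ):
                continue
            if rec.key in out:
                raise ValueError(f"duplicate variant key {rec.key}")
            out[rec.key] = rec
        return cls(bulk_label=bulk_label, records=out)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: Key) -> bool:
        return key in self.records


def subtract_common(
    mutant_set: BulkVariantSet, wt_set: BulkVariantSet
) -> tuple[BulkVariantSet, BulkVariantSet]:
    """Remove the variants common to both bulks (key-level set difference).

    Returns ``(mutant_specific, wt_specific)``; their key sets are disjoint
    and jointly form the symmetric difference of the inputs.
    """
    common = mutant_set.records.keys() & wt_set.records.keys()
    mutant_specific = BulkVariantSet(
        bulk_label=mutant_set.bulk_label,
        records={k: r for k, r in mutant_set.records.items() if k not in common},
    )
    wt_specific = BulkVariantSet(
        bulk_label=wt_set.bulk_label,
        records={k: r for k, r in wt_set.records.items() if k not in common},
    )
    return mutant_specific, wt_specific


def snp_index(record: VariantRecord, sample: str | None = None) -> float:
    """Fraction of reads supporting the alternative allele in one bulk.

    Undefined at zero total depth; that condition raises rather than
    returning 0, since "no reads" and "no alternative reads" mean very
    different things downstream.
    """
    call = record.sample(sample)
    total = call.total_depth
    if not total:
        raise ValueError(f"SNP index undefined at zero depth for {record.key}")
    return call.alt_depth / total


@dataclass
class Candidate:
    """A scored, ranked bulk-specific variant."""

    key: Key
    gene_id: str
    mutant_index: float
    wt_index: float | None
    p_mutant: float
    p_wt: float
    score: float
    rank: int = 0
    wt_testable: bool = True

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def pos(self) -> int:
        return self.key[1]


def _fold_error(p0: float, error_rate: float) -> float:
    # A read drawn from an allele at frequency p0 is observed as the
    # alternative with probability p0(1-e) + (1-p0)e.
    return p0 * (1.0 - error_rate) + (1.0 - p0) * error_rate


def rank_candidates(
    mutant_specific: BulkVariantSet | Sequence[VariantRecord],
    wt_depths: Mapping[Key, tuple[int, int]],
    design: CrossDesign,
    error_rate: float = 0.001,
    mutant_sample: str | None = None,
) -> list[Candidate]:
    """Score and rank mutant-bulk-specific variants against the cross model.

    Each candidate gets two exact binomial consistency p-values: the mutant
    bulk's allele depths against the expected mutant-bulk frequency (1 for
    a recessive mutant bulk) and the wild-type bulk's depths against the
    wild-type-bulk expectation (1/3).  Expectations are adjusted for the
    per-read ``error_rate``, so a single miscalled read at a fixed site is
    not fatal.  The score is the product ``p_mutant * p_wt`` — the causal
    variant is the one whose reads are *unsurprising* in both bulks.

    Sites with no wild-type reads are untestable on that side: ``p_wt`` is
    1 and the candidate is flagged (``wt_testable=False``) rather than
    rewarded.  Ties are broken by closeness of the observed SNP-index
    difference to its expectation (2/3 for recessive), then by (chrom, pos);
    ranks are assigned 1..n.
    """
    records = (
        list(mutant_specific.records.values())
        if isinstance(mutant_specific, BulkVariantSet)
        else list(mutant_specific)
    )
    exp_mut = expected_bulk_af(design, "mutant")
    exp_wt = expected_bulk_af(design, "wild_type")
    expected_delta = exp_mut - exp_wt
    p0_mut = _fold_error(exp_mut, error_rate)
    p0_wt = _fold_error(exp_wt, error_rate)
    candidates: list[Candidate] = []
    for rec in records:
        call = rec.sample(mutant_sample)
        n_mut = call.total_depth
        if not n_mut:
            raise ValueError(f"candidate {rec.key} has no mutant-bulk reads")
        mut_index = call.alt_depth / n_mut
        p_mutant = binom_consistency(call.alt_depth, n_mut, p0_mut)
        wt = wt_depths.get(rec.key)
        if wt is None or sum(wt) == 0:
            wt_index, p_wt, testable = None, 1.0, False
        else:
            wt_index = wt[1] / sum(wt)
            p_wt = binom_consistency(wt[1], sum(wt), p0_wt)
            testable = True
        gene = next((a.gene_id for a in rec.annotations if a.gene_id), "")
        candidates.append(
            Candidate(
                key=rec.key,
                gene_id=gene,
                mutant_index=mut_index,
                wt_index=wt_index,
                p_mutant=p_mutant,
                p_wt=p_wt,
                score=p_mutant * p_wt,
                wt_testable=testable,
            )
        )
    candidates.sort(
        key=lambda c: (
            -c.score,
            abs((c.mutant_index - (c.wt_index or 0.0)) - expected_delta),
            c.chrom,
            c.pos,
        )
    )
    for i, c in enumerate(candidates, start=1):
        c.rank = i
    return candidates


def summarize_loci_genes(
    records: Iterable[VariantRecord],
    classes: frozenset[str] | set[str] | None = None,
) -> tuple[int, int]:
    """Count distinct loci and distinct annotated genes.

    A locus annotating two genes contributes to both gene counts.  When
    ``classes`` is given, only annotations of those effect classes
    contribute genes.
    """
    keys: set[Key] = set()
    genes: set[str] = set()
    for rec in records:
        keys.add(rec.key)
        for a in rec.annotations:
            if classes is not None and a.effect_class not in classes:
                continue
            if a.gene_id:
                genes.add(a.gene_id)
    return len(keys), len(genes)


def variant_interval(key: Key) -> tuple[int, int]:
    """1-based inclusive interval of the bases a variant affects.

    SNVs affect the single position; VCF-style deletions carry an anchor
    base, so the affected run is pos+1 .. pos+len(ref)-1; insertions affect
    the two flanking bases.
    """
    _, pos, ref, alt = key
    if len(ref) > 1:  # deletion (anchor base + deleted run)
        return pos + 1, pos + len(ref) - 1
    if len(alt) > 1:  # insertion between pos and pos+1
        return pos, pos + 1
    return pos, pos


def igv_batch_script(
    candidates: Sequence[Candidate],
    flank: int = 500,
    genome_id: str = "genome",
    track_paths: Sequence[str] = (),
    snapshot_dir: str = "snapshots",
) -> str:
    """Build an IGV batch script that snapshots every candidate region.

    The script opens a fresh session, loads the genome and alignment
    tracks, sets the snapshot directory, then for each candidate issues a
    ``goto`` spanning the affected bases plus ``flank`` bp on each side
    (clamped at position 1) and a ``snapshot`` named
    ``<gene>_<chrom>_<pos>.png``.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    lines = ["new", f"genome {genome_id}"]
    lines.extend(f"load {path}" for path in track_paths)
    lines.append(f"snapshotDirectory {snapshot_dir}")
    for c in candidates:
        start, end = variant_interval(c.key)
        lines.append(f"goto {c.chrom}:{max(1, start - flank)}-{end + flank}")
        gene = c.gene_id or "novel"
        lines.append(f"snapshot {gene}_{c.chrom}_{c.pos}.png")
    return "\n".join(lines) + "\n"


def depth_map(
    records: Iterable[VariantRecord], sample: str | None = None
) -> dict[Key, tuple[int, int]]:
    """(ref_depth, alt_depth) per variant key, for use as a depth source."""
    out: dict[Key, tuple[int, int]] = {}
    for rec in records:
        call = rec.sample(sample)
        if call.ref_depth is not None and call.alt_depth is not None:
            out[rec.key] = (call.ref_depth, call.alt_depth)
    return out


def run_pipeline(
    mutant_records: Sequence[VariantRecord],
    wt_records: Sequence[VariantRecord],
    design: CrossDesign | None = None,
    classes: frozenset[str] | set[str] = DEFAULT_EFFECT_CLASSES,
    error_rate: float = 0.001,
    apply_filters: bool = True,
    **filter_kwargs,
) -> list[Candidate]:
    """Run the full comparison on two bulks' records and rank candidates.

    Steps: hard quality filters per bulk, effect-class restriction, call-set
    construction, key-level subtraction of common variants, then consistency
    scoring of the mutant-bulk-specific variants using the wild-type bulk's
    read depths at those sites.
    """
    design = design or CrossDesign()
    if apply_filters:
        mutant_records = filter_records(mutant_records, **filter_kwargs)
        wt_records = filter_records(wt_records, **filter_kwargs)
    wt_all_depths = depth_map(wt_records)
    mutant_kept = select_effect_classes(mutant_records, classes)
    wt_kept = select_effect_classes(wt_records, classes)
    mutant_set = BulkVariantSet.from_records(mutant_kept, "mutant")
    wt_set = BulkVariantSet.from_records(wt_kept, "wild_type")
    mutant_specific, _ = subtract_common(mutant_set, wt_set)
    return rank_candidates(
        mutant_specific, wt_all_depths, design, error_rate=error_rate
    )
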