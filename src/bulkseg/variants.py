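"""VCF reading, writing and record-level filtering.

Records are held as light dataclasses carrying exactly the fields the bulk
analysis consumes: coordinates, alleles, per-sample genotype calls with
allele depths and genotype quality, and functional effect annotations.
Multi-allelic sites are split into bi-allelic records on input, with depths
of the untested alternative alleles pooled into the reference depth.

File access goes through :mod:`pysam`; two annotation dialects are read
from INFO — the SnpEff ``ANN`` field (only allele, effect term and gene id
are consumed) and a simplified ``EFF=class|gene`` key used by the synthetic
bulk writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "EffectAnnotation",
    "SampleCall",
    "VariantRecord",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "filter_records",
    "parse_effect_annotations",
]

#: Canonical effect classes; unknown annotation terms map to "other".
EFFECT_CLASSES = (
    "missense",
    "frameshift",
    "synonymous",
    "stop_gained",
    "utr5",
    "utr3",
    "intron",
    "intergenic",
    "other",
)

# Synonyms across SnpEff versions and free-text dialects.
_EFFECT_SYNONYMS = {
    "missense": "missense",
    "missense_variant": "missense",
    "missense variation": "missense",
    "nonsynonymous_coding": "missense",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "frameshift variation": "frameshift",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "synonymous_coding": "synonymous",
    "stop_gained": "stop_gained",
    "nonsense": "stop_gained",
    "utr5": "utr5",
    "5_prime_utr_variant": "utr5",
    "utr3": "utr3",
    "3_prime_utr_variant": "utr3",
    "intron": "intron",
    "intron_variant": "intron",
    "intergenic": "intergenic",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
}

GENOTYPE_CALLS = ("hom_ref", "het", "hom_alt", "missing")


class VcfParseError(ValueError):
    """Raised when a VCF file cannot be parsed, naming the offending record."""


@dataclass(frozen=True)
class EffectAnnotation:
    """One functional annotation of a variant: effect class plus gene id."""

    effect_class: str
    gene_id: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class: {self.effect_class!r}")


@dataclass
class SampleCall:
    """Genotype call for one sample: call class, allele depths, quality."""

    genotype: str = "missing"
    ref_depth: int | None = None
    alt_depth: int | None = None
    gq: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_CALLS:
            raise ValueError(f"unknown genotype call: {self.genotype!r}")
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValueError("allele depths must be nonnegative")

    @property
    def total_depth(self) -> int | None:
        if self.ref_depth is None or self.alt_depth is None:
            return None
        return self.ref_depth + self.alt_depth


@dataclass
class VariantRecord:
    """One bi-allelic VCF row with per-sample depths and effect annotations."""

    chrom: str
    pos: int  # 1-based, VCF convention; indels carry the anchor base in ref
    ref: str
    alt: str
    qual: float | None = None
    samples: dict[str, SampleCall] = field(default_factory=dict)
    annotations: list[EffectAnnotation] = field(default_factory=list)
    qd: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF is 1-based)")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def sample(self, name: str | None = None) -> SampleCall:
        """The named sample's call, or the only/first sample if unnamed."""
        if not self.samples:
            raise KeyError("record carries no sample calls")
        if name is None:
            return next(iter(self.samples.values()))
        return self.samples[name]


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


def _classify_term(term: str) -> str:
    # SnpEff joins co-occurring terms with '&'; the first recognised wins.
    for sub in term.split("&"):
        mapped = _EFFECT_SYNONYMS.get(sub.strip().lower())
        if mapped is not None:
            return mapped
    return "other"


def parse_effect_annotations(ann_string: str) -> list[EffectAnnotation]:
    """Parse a comma-separated annotation string into effect annotations.

    Two dialects are understood per entry: the SnpEff ``ANN`` layout
    (``Allele|effect|impact|gene|...``, effect in field 2, gene in field 4)
    and the simplified ``class|gene`` pair emitted by the synthetic bulk
    writer.  Unparseable entries map to effect class ``other`` with the raw
    text preserved.
    """
    if not ann_string:
        return []
    out: list[EffectAnnotation] = []
    for entry in ann_string.split(","):
        entry = entry.strip()
        if not entry:
            continue
        parts = entry.split("|")
        if len(parts) >= 4:  # SnpEff ANN dialect
            effect = _classify_term(parts[1])
            gene = parts[3] or (parts[4] if len(parts) > 4 else "")
        elif len(parts) >= 2:  # simplified class|gene dialect
            effect = _classify_term(parts[0])
            gene = parts[1]
        else:
            effect = _classify_term(parts[0])
            gene = ""
        out.append(EffectAnnotation(effect_class=effect, gene_id=gene, raw=entry))
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _call_from_gt(gt: tuple[int | None, ...] | None, allele_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return "missing"
    hits = sum(1 for a in gt if a == allele_index)
    if hits == len(gt):
        return "hom_alt"
    if hits > 0:
        return "het"
    return "hom_ref"


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF file into a list of bi-allelic :class:`VariantRecord`.

    Multi-allelic sites produce one record per alternative allele sharing
    chrom/pos/ref; AD depths for the other alternative alleles are pooled
    into the reference depth.  Records without an AD field carry ``None``
    depths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: not a parseable VCF header ({exc})") from exc
    records: list[VariantRecord] = []
    with vf:
        for i, rec in enumerate(vf, start=1):
            try:
                records.extend(_convert_record(rec))
            except (ValueError, KeyError, TypeError) as exc:
                raise VcfParseError(f"{path}: record {i}: {exc}") from exc
    return records


def _convert_record(rec: pysam.VariantRecord) -> list[VariantRecord]:
    alts = rec.alts or ()
    ann_string = _info_annotation_string(rec)
    # .get on a key absent from the header raises in pysam, so test first.
    qd = rec.info.get("QD") if "QD" in rec.info else None
    if isinstance(qd, tuple):
        qd = qd[0]
    out: list[VariantRecord] = []
    for alt_index, alt in enumerate(alts, start=1):
        samples: dict[str, SampleCall] = {}
        for name, s in rec.samples.items():
            ad = s.get("AD")
            if ad is None or all(a is None for a in ad):
                ref_depth = alt_depth = None
            else:
                ad = [a or 0 for a in ad]
                alt_depth = ad[alt_index] if alt_index < len(ad) else 0
                ref_depth = sum(ad) - alt_depth  # pool untested alts into ref
            gq = s.get("GQ")
            samples[name] = SampleCall(
                genotype=_call_from_gt(s.get("GT"), alt_index),
                ref_depth=ref_depth,
                alt_depth=alt_depth,
                gq=float(gq) if gq is not None else None,
            )
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                qual=rec.qual,
                samples=samples,
                annotations=parse_effect_annotations(ann_string),
                qd=float(qd) if qd is not None else None,
            )
        )
    return out


def _info_annotation_string(rec: pysam.VariantRecord) -> str:
    for key in ("ANN", "EFF"):
        if key in rec.info:
            value = rec.info[key]
            if isinstance(value, tuple):
                return ",".join(str(v) for v in value)
            return str(value)
    return ""


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_GT_TUPLES = {
    "hom_ref": (0, 0),
    "het": (0, 1),
    "hom_alt": (1, 1),
    "missing": (None, None),
}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    ann_key: str = "ANN",
) -> None:
    """Write records to an uncompressed VCF 4.x file.

    The output round-trips through :func:`read_vcf` with identical
    coordinates, alleles, depths and annotations.  ``ann_key`` selects the
    INFO key used for annotations (``ANN`` by default; the synthetic bulk
    writer uses the simplified ``EFF`` dialect).
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_meta("source", "bulkseg")
    for contig in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(contig, length=2**29)
    header.info.add(ann_key, ".", "String", "Functional annotations: effect|gene")
    header.info.add("QD", "1", "Float", "Quality by depth")
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.formats.add("GQ", "1", "Integer", "Genotype quality")
    sample_names = list(dict.fromkeys(n for r in records for n in r.samples))
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            row = vf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            row.qual = rec.qual
            if rec.annotations:
                row.info[ann_key] = ",".join(
                    a.raw or f"{a.effect_class}|{a.gene_id}" for a in rec.annotations
                )
            if rec.qd is not None:
                row.info["QD"] = rec.qd
            for name in sample_names:
                call = rec.samples.get(name)
                if call is None:
                    continue
                row.samples[name]["GT"] = _GT_TUPLES[call.genotype]
                if call.ref_depth is not None and call.alt_depth is not None:
                    row.samples[name]["AD"] = (call.ref_depth, call.alt_depth)
                if call.gq is not None:
                    row.samples[name]["GQ"] = int(round(call.gq))
            vf.write(row)


# ---------------------------------------------------------------------------
# Record filtering
# ---------------------------------------------------------------------------


def filter_records(
    records: Iterable[VariantRecord],
    min_ab: float = 0.8,
    min_dp: int = 6,
    min_gq: float = 0.0,
    min_qd: float = 2.0,
    sample: str | None = None,
) -> list[VariantRecord]:
    """Apply hard record-level quality filters.

    A record is retained iff, for the tested sample:

    * total allele depth >= ``min_dp``;
    * genotype quality >= ``min_gq``;
    * quality-by-depth >= ``min_qd`` (the INFO QD value when present,
      otherwise QUAL divided by total depth);
    * for *homozygous* calls only, the fraction of reads supporting the
      called allele >= ``min_ab``.  Heterozygous calls are exempt from the
      allele-balance floor — a het site legitimately carries ~50% support
      per allele, and a bulk of segregants even less.

    All thresholds are inclusive.  Records lacking a required field
    (missing genotype, missing depths, no usable quality) fail that test
    conservatively and are dropped; the number dropped per reason is
    logged.  The defaults reproduce a Picard ``FilterVcf``-style hard
    filter (MIN_AB 0.8, MIN_DP 6, MIN_GQ 0, MIN_QD 2).
    """
    if min(min_ab, min_dp, min_gq, min_qd) < 0:
        raise ValueError("filter thresholds must be nonnegative")
    retained: list[VariantRecord] = []
    dropped: dict[str, int] = {}

    def fail(reason: str) -> None:
        dropped[reason] = dropped.get(reason, 0) + 1

    for rec in records:
        try:
            call = rec.sample(sample)
        except KeyError:
            fail("no_sample")
            continue
        if call.genotype == "missing":
            fail("missing_genotype")
            continue
        dp = call.total_depth
        if dp is None or dp < min_dp:
            fail("depth")
            continue
        if min_gq > 0 and (call.gq is None or call.gq < min_gq):
            fail("gq")
            continue
        if min_qd > 0:
            qd = rec.qd
            if qd is None:
                qd = rec.qual / dp if rec.qual is not None and dp > 0 else None
            if qd is None or qd < min_qd:
                fail("qd")
                continue
        if min_ab > 0 and call.genotype in ("hom_ref", "hom_alt"):
            supporting = call.alt_depth if call.genotype == "hom_alt" else call.ref_depth
            if dp == 0 or supporting / dp < min_ab:
                fail("allele_balance")
                continue
        retained.append(rec)
    if dropped:
        logger.info(
            "filter_records dropped %d record(s): %s", sum(dropped.values()), dropped
        )
    return retained
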