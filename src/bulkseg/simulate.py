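"""Forward simulation of the study design behind a two-bulk mapping screen.

Everything downstream of raw sequencing is exercisable on data produced
here: a selfed family segregating for a single recessive locus, two
phenotype-selected bulks sequenced to finite depth with sequencing error,
a background of induced variants with per-bulk allele frequencies, VCFs in
the annotation dialect the pipeline consumes, spectrophotometer readings
consistent with the pigment equations, and cultivar-panel genotype
matrices with planted haplotype structure.

All simulators are pure functions of their explicit seed: a single RNG
stream per operation and no global state, so identical calls give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import DOSAGE, GENOTYPES, CrossDesign
from .haplotypes import GenotypeMatrix
from .quantify import PIGMENT_COEFFS
from .variants import EffectAnnotation, SampleCall, VariantRecord, write_vcf

__all__ = [
    "Individual",
    "SimulatedFamily",
    "BulkSpec",
    "SyntheticVariant",
    "TruthTable",
    "PlantedHaplotype",
    "simulate_family",
    "sample_bulk_genotypes",
    "simulate_bulk_depths",
    "simulate_truth_table",
    "bulk_records_from_depths",
    "write_synthetic_bulk_vcfs",
    "simulate_pigment_readings",
    "simulate_haplotype_matrix",
]

BULK_LABELS = ("mutant", "wild_type")

#: Effect classes assigned to background variants; only the first two
#: survive the downstream effect-class restriction, by construction.
BACKGROUND_EFFECT_CLASSES = (
    "missense",
    "frameshift",
    "synonymous",
    "intron",
    "intergenic",
)


@dataclass(frozen=True)
class Individual:
    id: str
    genotype: str  # causal-locus genotype
    phenotype: str


@dataclass(frozen=True)
class SimulatedFamily:
    """A simulated segregating family with deterministic phenotypes."""

    individuals: tuple[Individual, ...]
    design: CrossDesign
    seed: int

    def members(self, phenotype: str) -> tuple[Individual, ...]:
        return tuple(i for i in self.individuals if i.phenotype == phenotype)

    def __len__(self) -> int:
        return len(self.individuals)


def simulate_family(design: CrossDesign, n: int, seed: int) -> SimulatedFamily:
    """Draw ``n`` progeny i.i.d. from the design's genotype prior.

    Phenotypes follow deterministically from genotypes under the design's
    inheritance model (recessive: mutant iff hom_alt).
    """
    if n < 0:
        raise ValueError("family size must be nonnegative")
    rng = np.random.default_rng(seed)
    codes = rng.choice(3, size=n, p=np.asarray(design.genotype_prior, dtype=float))
    individuals = tuple(
        Individual(
            id=f"ind{i + 1:05d}",
            genotype=GENOTYPES[c],
            phenotype=design.phenotype_of(GENOTYPES[c]),
        )
        for i, c in enumerate(codes)
    )
    return SimulatedFamily(individuals=individuals, design=design, seed=seed)


@dataclass(frozen=True)
class BulkSpec:
    """Specification of one phenotype-selected sequencing bulk."""

    selected_phenotype: str
    n_plants: int
    mean_depth: float
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selected_phenotype not in BULK_LABELS:
            raise ValueError(f"unknown phenotype: {self.selected_phenotype!r}")
        if self.n_plants < 1:
            raise ValueError("a bulk needs at least one plant")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class SyntheticVariant:
    """One planted variant with its true per-bulk allele frequencies.

    For the causal variant the frequencies are derived from the sampled
    plants' genotypes at simulation time and the stored values are ignored.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: str = "missense"
    freq_mutant: float = 0.0
    freq_wt: float = 0.0
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def freq(self, bulk: str) -> float:
        return self.freq_mutant if bulk == "mutant" else self.freq_wt


@dataclass(frozen=True)
class TruthTable:
    """The causal variant plus the background of induced variants."""

    causal: SyntheticVariant
    background: tuple[SyntheticVariant, ...] = ()

    def __post_init__(self) -> None:
        seen = {(self.causal.chrom, self.causal.pos)}
        for v in self.background:
            if (v.chrom, v.pos) in seen:
                raise ValueError(f"duplicate variant position {(v.chrom, v.pos)}")
            seen.add((v.chrom, v.pos))

    @property
    def variants(self) -> tuple[SyntheticVariant, ...]:
        ordered = sorted(
            (self.causal, *self.background), key=lambda v: (v.chrom, v.pos)
        )
        return tuple(ordered)

    def is_causal(self, key: tuple[str, int, str, str]) -> bool:
        return key == self.causal.key


_BASES = np.array(list("ACGT"))

#: Default causal lesion: a 10 bp deletion (VCF-style, anchor base in ref).
DEFAULT_CAUSAL = SyntheticVariant(
    chrom="Chr02",
    pos=47_983_484,
    ref="CTTGGATACCA",
    alt="C",
    effect_class="frameshift",
    freq_mutant=1.0,
    freq_wt=1.0 / 3.0,
    gene_id="gene_causal",
)


def simulate_truth_table(
    n_background: int = 500,
    seed: int = 0,
    causal: SyntheticVariant = DEFAULT_CAUSAL,
    shared_fraction: float = 0.4,
    indel_fraction: float = 0.1,
    n_chroms: int = 20,
) -> TruthTable:
    """Plant a causal variant among ``n_background`` induced variants.

    Background variants model the mutation load of a mutagenised line as it
    appears in per-bulk variant calls: a ``shared_fraction`` of them
    segregate in the whole family and show up in both bulks at the same
    frequency (these are removed by bulk subtraction), while the rest are
    private to one bulk — late-arising or sub-line mutations plus caller
    dropout make a large one-bulk-only fraction the empirically observed
    situation.  Private frequencies are uniform on [0.15, 1]; effect
    classes are uniform over missense/frameshift/synonymous/intron/
    intergenic; a small fraction are short indels, the rest SNVs.
    """
    if n_background < 0:
        raise ValueError("n_background must be nonnegative")
    rng = np.random.default_rng(seed)
    taken = {(causal.chrom, causal.pos)}
    background: list[SyntheticVariant] = []
    while len(background) < n_background:
        chrom = f"Chr{rng.integers(1, n_chroms + 1):02d}"
        pos = int(rng.integers(1, 50_000_000))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        ref_base, alt_base = rng.choice(_BASES, size=2, replace=False)
        if rng.random() < indel_fraction:
            del_len = int(rng.integers(1, 11))
            ref = ref_base + "".join(rng.choice(_BASES, size=del_len))
            alt = ref_base
        else:
            ref, alt = ref_base, alt_base
        if rng.random() < shared_fraction:
            f = float(rng.uniform(0.25, 1.0))
            freq_mutant = freq_wt = f
        elif rng.random() < 0.5:
            freq_mutant, freq_wt = float(rng.uniform(0.15, 1.0)), 0.0
        else:
            freq_mutant, freq_wt = 0.0, float(rng.uniform(0.15, 1.0))
        background.append(
            SyntheticVariant(
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                effect_class=str(rng.choice(BACKGROUND_EFFECT_CLASSES)),
                freq_mutant=freq_mutant,
                freq_wt=freq_wt,
                gene_id=f"gene_{chrom}_{pos}",
            )
        )
    return TruthTable(causal=causal, background=tuple(background))


def sample_bulk_genotypes(
    family: SimulatedFamily,
    selected_phenotype: str,
    n_plants: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Causal-locus dosages of ``n_plants`` drawn without replacement.

    Plants are drawn from the family's selected-phenotype class, so the
    finite-sample bulk composition (e.g. the het fraction of a wild-type
    bulk) varies between replicates exactly as it would in the field.
    """
    pool = family.members(selected_phenotype)
    if len(pool) < n_plants:
        raise ValueError(
            f"family has only {len(pool)} {selected_phenotype} plants; "
            f"{n_plants} requested"
        )
    chosen = rng.choice(len(pool), size=n_plants, replace=False)
    return np.array([DOSAGE[pool[i].genotype] for i in chosen])


def simulate_bulk_depths(
    family: SimulatedFamily,
    spec: BulkSpec,
    truth: TruthTable,
) -> dict[tuple[str, int, str, str], tuple[int, int]]:
    """Per-variant (ref_depth, alt_depth) for one phenotype-selected bulk.

    The causal-locus bulk allele frequency is the mean dosage of the
    sampled plants; background variants use their true per-bulk frequency
    from the truth table.  Site depth is Poisson(``mean_depth``) with a
    floor of 1 read; alternative reads are binomial at the frequency mixed
    with the symmetric per-read error rate.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    dosages = sample_bulk_genotypes(
        family, spec.selected_phenotype, spec.n_plants, rng
    )
    causal_freq = float(dosages.mean())
    variants = truth.variants
    freqs = np.array(
        [
            causal_freq if truth.is_causal(v.key) else v.freq(spec.selected_phenotype)
            for v in variants
        ]
    )
    e = spec.error_rate
    read_freqs = freqs * (1.0 - e) + (1.0 - freqs) * e
    depths = np.maximum(rng.poisson(spec.mean_depth, size=len(variants)), 1)
    alts = rng.binomial(depths, read_freqs)
    return {
        v.key: (int(d - a), int(a)) for v, d, a in zip(variants, depths, alts)
    }


# ---------------------------------------------------------------------------
# Synthetic VCF writing
# ---------------------------------------------------------------------------


def _genotype_from_fraction(alt_fraction: float) -> str:
    # Diploid-style call on the pooled sample: thresholds at 20% / 80%.
    if alt_fraction >= 0.8:
        return "hom_alt"
    if alt_fraction <= 0.2:
        return "hom_ref"
    return "het"


def bulk_records_from_depths(
    depths: Mapping[tuple[str, int, str, str], tuple[int, int]],
    truth: TruthTable,
    sample: str,
) -> list[VariantRecord]:
    """Variant records for one bulk, as its VCF would represent them.

    Genotypes are called from the bulk alternative-read fraction with
    20%/80% thresholds; each record carries a simplified ``class|gene``
    annotation and a quality consistent with a clean call (QD 30, GQ 99).
    """
    records: list[VariantRecord] = []
    for v in truth.variants:
        ref_d, alt_d = depths[v.key]
        total = ref_d + alt_d
        gene = v.gene_id or f"gene_{v.chrom}_{v.pos}"
        records.append(
            VariantRecord(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                qual=30.0 * max(total, 1),
                samples={
                    sample: SampleCall(
                        genotype=_genotype_from_fraction(
                            alt_d / total if total else 0.0
                        ),
                        ref_depth=ref_d,
                        alt_depth=alt_d,
                        gq=99.0,
                    )
                },
                annotations=[
                    EffectAnnotation(
                        effect_class=v.effect_class,
                        gene_id=gene,
                        raw=f"{v.effect_class}|{gene}",
                    )
                ],
            )
        )
    return records


def write_synthetic_bulk_vcfs(
    depths_mutant: Mapping[tuple[str, int, str, str], tuple[int, int]],
    depths_wt: Mapping[tuple[str, int, str, str], tuple[int, int]],
    truth: TruthTable,
    mutant_path: str | Path,
    wt_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write one single-sample VCF per bulk plus an optional truth TSV.

    Both VCFs carry every simulated site (they double as a depth source for
    sites not *called* in a bulk); genotypes are assigned from the bulk
    alternative-read fraction with 20%/80% thresholds, and each record
    carries a simplified ``EFF=class|gene`` annotation.  Re-reading the
    files reproduces the depth maps exactly.
    """
    if set(depths_mutant) != set(depths_wt):
        raise ValueError("mutant and wild-type depth maps cover different variants")
    for path, depths, sample in (
        (mutant_path, depths_mutant, "mutant"),
        (wt_path, depths_wt, "wt"),
    ):
        write_vcf(bulk_records_from_depths(depths, truth, sample), path, ann_key="EFF")
    if truth_path is not None:
        frame = pd.DataFrame(
            [
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "is_causal": int(truth.is_causal(v.key)),
                    "effect_class": v.effect_class,
                }
                for v in truth.variants
            ]
        )
        frame.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pigment readings
# ---------------------------------------------------------------------------


def simulate_pigment_readings(
    true_chl_a: float,
    true_chl_b: float,
    true_carotenoid: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Absorbances (OD663, OD645, OD440) that encode the given mg/L contents.

    Inverts the linear pigment equations exactly, then adds independent
    Gaussian absorbance noise with standard deviation ``noise_sd`` (noisy
    absorbances are floored at 0, since a spectrophotometer reports
    nonnegative optical densities).  With ``noise_sd=0`` the forward
    equations recover the true contents to machine precision.
    """
    if min(true_chl_a, true_chl_b, true_carotenoid) < 0:
        raise ValueError("true pigment contents must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    chl_matrix = np.array([PIGMENT_COEFFS["chl_a"], PIGMENT_COEFFS["chl_b"]])
    od663, od645 = np.linalg.solve(chl_matrix, [true_chl_a, true_chl_b])
    od440 = (
        true_carotenoid - PIGMENT_COEFFS["car_chl"] * (true_chl_a + true_chl_b)
    ) / PIGMENT_COEFFS["car_od440"]
    ods = np.array([od663, od645, od440])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ods = np.maximum(ods + rng.normal(0.0, noise_sd, size=3), 0.0)
    return float(ods[0]), float(ods[1]), float(ods[2])


# ---------------------------------------------------------------------------
# Haplotype panels
# ---------------------------------------------------------------------------

DEFAULT_ORIGINS = ("Asia", "America", "Europe", "Africa", "Australia")


@dataclass(frozen=True)
class PlantedHaplotype:
    """One haplotype to plant in a synthetic panel."""

    alleles: tuple[str, ...]
    n_carriers: int
    origin_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_carriers < 1:
            raise ValueError("n_carriers must be >= 1")
        if self.origin_counts is not None:
            if sum(self.origin_counts.values()) != self.n_carriers:
                raise ValueError("origin counts must sum to n_carriers")


def simulate_haplotype_matrix(
    n_cultivars: int,
    n_loci: int,
    planted_haplotypes: Sequence[PlantedHaplotype],
    n_singletons: int = 0,
    seed: int = 0,
    origins: Sequence[str] = DEFAULT_ORIGINS,
    chrom: str = "Chr02",
    region_start: int = 47_976_140,
) -> GenotypeMatrix:
    """Build a cultivar x locus genotype matrix with known haplotype structure.

    Each planted haplotype contributes ``n_carriers`` cultivars with its
    exact allele tuple; ``n_singletons`` additional cultivars receive
    allele tuples unique in the panel, so classification with a
    two-carrier minimum recovers exactly the planted haplotypes.  Origins
    come from each haplotype's ``origin_counts`` when given (otherwise
    drawn from ``origins``); maturity groups are drawn independently of
    haplotype, encoding the no-association null.
    """
    for hap in planted_haplotypes:
        if len(hap.alleles) != n_loci:
            raise ValueError("planted allele tuples must have length n_loci")
    total_planted = sum(h.n_carriers for h in planted_haplotypes)
    if total_planted + n_singletons != n_cultivars:
        raise ValueError(
            f"carriers ({total_planted}) + singletons ({n_singletons}) "
            f"must equal n_cultivars ({n_cultivars})"
        )
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    positions = {
        locus: (chrom, region_start + 50 * (i + 1)) for i, locus in enumerate(loci)
    }
    rows: list[tuple[str, ...]] = []
    meta_rows: list[dict[str, str]] = []
    used = {tuple(h.alleles) for h in planted_haplotypes}
    for h_index, hap in enumerate(planted_haplotypes):
        carrier_origins: list[str] = []
        if hap.origin_counts is not None:
            for origin, count in hap.origin_counts.items():
                carrier_origins.extend([origin] * count)
        else:
            carrier_origins = list(rng.choice(origins, size=hap.n_carriers))
        for origin in carrier_origins:
            rows.append(tuple(hap.alleles))
            meta_rows.append(
                {"origin": str(origin), "maturity_group": f"MG{rng.integers(0, 8)}"}
            )
    for _ in range(n_singletons):
        for _attempt in range(10_000):
            tup = tuple(rng.choice(_BASES, size=n_loci))
            if tup not in used:
                used.add(tup)
                break
        else:
            raise ValueError(
                "could not draw a unique singleton tuple; too few loci for the panel"
            )
        rows.append(tup)
        meta_rows.append(
            {
                "origin": str(rng.choice(origins)),
                "maturity_group": f"MG{rng.integers(0, 8)}",
            }
        )
    ids = [f"cv{i + 1:05d}" for i in range(n_cultivars)]
    calls = pd.DataFrame(rows, index=ids, columns=loci)
    metadata = pd.DataFrame(meta_rows, index=ids)
    return GenotypeMatrix(calls=calls, positions=positions, metadata=metadata)
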