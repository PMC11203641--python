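"""Haplotype classification of a cultivar panel over a gene region.

A :class:`GenotypeMatrix` holds per-cultivar allele calls at the SNP loci of
a gene region together with cultivar metadata (geographic origin, maturity
group).  Loci falling inside an overlapping gene can be excluded, cultivars
are grouped into haplotypes by exact allele-tuple identity, haplotypes
carried by fewer than a minimum number of cultivars (default two) are
dropped, and the retained haplotypes are tabulated against metadata groups
and tested for independence with a Pearson chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING_CALL",
    "GenotypeMatrix",
    "Haplotype",
    "ContingencyTable",
    "exclude_region_loci",
    "classify_haplotypes",
    "tabulate_by_group",
    "haplotype_group_association",
]

#: Symbol substituted for missing allele calls; it is a distinct allele, so a
#: cultivar with missing data forms (or joins) its own tuple rather than
#: being imputed.
MISSING_CALL = "."


@dataclass
class GenotypeMatrix:
    """Cultivar x locus allele calls plus locus positions and metadata.

    ``calls`` is a DataFrame indexed by cultivar id with one column per
    locus id; ``positions`` maps locus id -> (chrom, pos); ``metadata`` is
    indexed by cultivar id with at least ``origin`` and ``maturity_group``
    columns (either may be missing for individual cultivars).
    """

    calls: pd.DataFrame
    positions: dict[str, tuple[str, int]]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = set(self.calls.columns) - set(self.positions)
        if missing:
            raise ValueError(f"loci without positions: {sorted(missing)[:5]}")
        seen: set[tuple[str, int]] = set()
        for locus in self.calls.columns:
            where = self.positions[locus]
            if where in seen:
                raise ValueError(f"duplicate locus position {where}")
            seen.add(where)

    @property
    def cultivars(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class Haplotype:
    """A distinct allele tuple shared by ``n_carriers`` cultivars."""

    label: str
    alleles: tuple[str, ...]
    carrier_ids: tuple[str, ...]

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)


def exclude_region_loci(
    matrix: GenotypeMatrix, region: tuple[str, int, int]
) -> GenotypeMatrix:
    """Drop loci positioned inside ``(chrom, start, end)``, inclusive.

    Used to remove the SNPs that belong to a gene overlapping the region of
    interest (e.g. a gene nested on the opposite strand of an intron)
    before haplotype classification.  Allele calls at retained loci are
    untouched.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("region start must not exceed end")
    keep = [
        locus
        for locus in matrix.calls.columns
        if not (
            matrix.positions[locus][0] == chrom
            and start <= matrix.positions[locus][1] <= end
        )
    ]
    return GenotypeMatrix(
        calls=matrix.calls[keep].copy(),
        positions={locus: matrix.positions[locus] for locus in keep},
        metadata=matrix.metadata,
    )


def classify_haplotypes(
    matrix: GenotypeMatrix, min_carriers: int = 2
) -> list[Haplotype]:
    """Group cultivars into haplotypes by exact allele-tuple identity.

    Missing calls are kept as the distinct symbol :data:`MISSING_CALL`.
    Haplotypes carried by fewer than ``min_carriers`` cultivars are
    dropped (the panel-analysis convention of retaining only haplotypes
    possessed by two or more accessions).  Labels ``Hap_1``, ``Hap_2``, ...
    are assigned by descending carrier count, ties broken by lexicographic
    allele tuple, so labelling is deterministic and invariant to row order.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    calls = matrix.calls.astype("string").fillna(MISSING_CALL).replace("", MISSING_CALL)
    groups: dict[tuple[str, ...], list[str]] = {}
    for cultivar, row in zip(calls.index, calls.to_numpy()):
        groups.setdefault(tuple(row), []).append(str(cultivar))
    kept = [
        (alleles, carriers)
        for alleles, carriers in groups.items()
        if len(carriers) >= min_carriers
    ]
    kept.sort(key=lambda item: (-len(item[1]), item[0]))
    return [
        Haplotype(
            label=f"Hap_{i}",
            alleles=alleles,
            carrier_ids=tuple(sorted(carriers)),
        )
        for i, (alleles, carriers) in enumerate(kept, start=1)
    ]


class ContingencyTable(NamedTuple):
    counts: pd.DataFrame
    row_margins: pd.Series
    col_margins: pd.Series


def tabulate_by_group(
    haplotypes: Sequence[Haplotype],
    metadata: pd.DataFrame,
    group_field: str = "origin",
) -> ContingencyTable:
    """Count haplotype carriers per metadata group (origin or maturity group).

    Carriers absent from the metadata, or with a null group value, are
    counted in an ``"unknown"`` column and logged.  Row margins are carrier
    counts per haplotype; column margins are carriers per group.
    """
    if group_field not in metadata.columns:
        raise ValueError(f"metadata lacks a {group_field!r} column")
    rows = []
    n_unknown = 0
    for hap in haplotypes:
        for cid in hap.carrier_ids:
            if cid in metadata.index and pd.notna(metadata.loc[cid, group_field]):
                group = str(metadata.loc[cid, group_field])
            else:
                group = "unknown"
                n_unknown += 1
            rows.append((hap.label, group))
    if n_unknown:
        logger.info("%d carrier(s) with missing %s metadata", n_unknown, group_field)
    frame = pd.DataFrame(rows, columns=["haplotype", group_field])
    counts = pd.crosstab(frame["haplotype"], frame[group_field])
    counts = counts.reindex([h.label for h in haplotypes], fill_value=0)
    return ContingencyTable(
        counts=counts,
        row_margins=counts.sum(axis=1),
        col_margins=counts.sum(axis=0),
    )


def haplotype_group_association(
    table: ContingencyTable | pd.DataFrame | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square test of haplotype-by-group independence.

    Returns ``(chi2, df, p)`` with df = (rows - 1)(cols - 1) and no
    continuity correction.  The table must have at least two rows and two
    columns with positive margins.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else table
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(arr.sum(axis=0) <= 0) or np.any(arr.sum(axis=1) <= 0):
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
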