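"""Single-locus cross genetics and the statistics built on it.

This module holds the inheritance model used throughout the package — a
single Mendelian locus segregating in a selfed or F2 family — together with
the statistics the bulk analysis needs: the expected mutant-allele frequency
in a phenotype-selected bulk, an exact two-sided binomial consistency test
for observed allele depths, a chi-square goodness-of-fit test for
segregation ratios, and a marker–phenotype cosegregation check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GENOTYPES",
    "CrossDesign",
    "BulkExpectation",
    "SegregationCounts",
    "CosegregationResult",
    "expected_bulk_af",
    "binom_consistency",
    "chi2_gof",
    "cosegregation_check",
]

#: Genotype symbols at the causal locus, in dosage order (0, 1, 2 mutant alleles).
GENOTYPES = ("hom_ref", "het", "hom_alt")

#: Mutant-allele dosage (as a fraction of the diploid genome) per genotype.
DOSAGE = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0}

PHENOTYPES = ("mutant", "wild_type")


@dataclass(frozen=True)
class CrossDesign:
    """Inheritance model for a single segregating locus.

    Parameters
    ----------
    inheritance
        ``"recessive_mutant"`` (mutant phenotype requires two mutant alleles,
        the usual case for an induced loss-of-function allele) or
        ``"dominant_mutant"``.
    generation_label
        Free-text description of the generation, e.g. ``"M3 selfed line"``
        or ``"F2"``.
    genotype_prior
        Probabilities of (hom_ref, het, hom_alt) for an unselected progeny.
        The default 1/4 : 1/2 : 1/4 is the selfing/F2 expectation from a
        heterozygous parent.
    """

    inheritance: str = "recessive_mutant"
    generation_label: str = "F2"
    genotype_prior: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.inheritance not in ("recessive_mutant", "dominant_mutant"):
            raise ValueError(f"unknown inheritance model: {self.inheritance!r}")
        p = self.genotype_prior
        if len(p) != 3 or any(not (0.0 <= x <= 1.0) for x in p):
            raise ValueError("genotype_prior must be three probabilities in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-12:
            raise ValueError("genotype_prior must sum to 1 within 1e-12")

    def phenotype_of(self, genotype: str) -> str:
        """Deterministic phenotype implied by a causal-locus genotype."""
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype: {genotype!r}")
        if self.inheritance == "recessive_mutant":
            return "mutant" if genotype == "hom_alt" else "wild_type"
        return "mutant" if genotype in ("het", "hom_alt") else "wild_type"

    def conditional_genotype_probs(self, phenotype: str) -> dict[str, float]:
        """Genotype distribution conditioned on the observed phenotype."""
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype: {phenotype!r}")
        mass = {
            g: p
            for g, p in zip(GENOTYPES, self.genotype_prior)
            if self.phenotype_of(g) == phenotype
        }
        total = sum(mass.values())
        if total <= 0.0:
            raise ValueError(
                f"phenotype {phenotype!r} has zero prior mass under this design"
            )
        return {g: p / total for g, p in mass.items()}

    def expected_phenotype_fraction(self, phenotype: str) -> float:
        """Prior probability of a phenotype, e.g. 1/4 mutant for recessive."""
        return sum(
            p
            for g, p in zip(GENOTYPES, self.genotype_prior)
            if self.phenotype_of(g) == phenotype
        )


@dataclass(frozen=True)
class BulkExpectation:
    """Expected mutant-allele frequency in a phenotype-selected bulk."""

    selected_phenotype: str
    expected_alt_freq: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.expected_alt_freq <= 1.0):
            raise ValueError("expected_alt_freq must lie in [0, 1]")


def expected_bulk_af(design: CrossDesign, selected_phenotype: str) -> float:
    """Expected mutant-allele frequency in a bulk of phenotype-selected plants.

    The bulk frequency is the dosage-weighted mean over the genotype prior
    conditioned on the selected phenotype.  Under the recessive 1:2:1 design
    a mutant-selected bulk is fixed for the mutant allele (frequency 1.0),
    while wild-type-selected plants are 1/3 hom_ref : 2/3 het, giving an
    expected frequency of 1/3.
    """
    probs = design.conditional_genotype_probs(selected_phenotype)
    return sum(p * DOSAGE[g] for g, p in probs.items())


# ---------------------------------------------------------------------------
# Exact binomial consistency test
# ---------------------------------------------------------------------------


#: Relative tolerance for pmf ties in the minimum-likelihood rule.  A float
#: p0 such as 1/3 only approximates the intended rational frequency, which
#: perturbs exactly-tied outcome probabilities (e.g. pmf(1) = pmf(2) for
#: n = 5 at exactly 1/3) by one part in ~1e16; the tolerance keeps such
#: ties tied, matching the convention of standard exact-test implementations.
_TIE_RTOL = 1e-7


@lru_cache(maxsize=1024)
def _binom_pmf(n: int, p0: float) -> tuple[float, ...]:
    return tuple(
        math.comb(n, k) * p0**k * (1.0 - p0) ** (n - k) for k in range(n + 1)
    )


def binom_consistency(alt: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value for allele-depth consistency.

    Tests whether observing ``alt`` mutant-allele reads out of ``n`` total
    reads is consistent with a hypothesised bulk allele frequency ``p0``.
    Two-sidedness follows the minimum-likelihood rule: the p-value is the
    sum of binomial pmf(k) over every outcome k whose pmf does not exceed
    pmf(alt), with pmf ties recognised to a small relative tolerance (see
    :data:`_TIE_RTOL`).

    A p-value of 1 means the observation sits at the distribution's mode
    region; small values flag allele depths that the hypothesised frequency
    cannot plausibly produce.  The degenerate frequencies ``p0 = 0`` and
    ``p0 = 1`` are handled by the same rule and return 1.0 for the certain
    outcome and 0.0 otherwise.
    """
    if n <= 0:
        raise ValueError("binom_consistency is undefined for zero total depth")
    if not 0 <= alt <= n:
        raise ValueError(f"alt must lie in [0, n]; got alt={alt}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must lie in [0, 1]; got {p0}")
    pmf = _binom_pmf(int(n), float(p0))
    threshold = pmf[alt] * (1.0 + _TIE_RTOL)
    return min(1.0, math.fsum(f for f in pmf if f <= threshold))


# ---------------------------------------------------------------------------
# Chi-square goodness of fit for segregation ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegregationCounts:
    """Observed phenotype-class counts and the Mendelian ratio to test."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...] = (1.0, 3.0)
    class_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.expected_ratio):
            raise ValueError("observed and expected_ratio must have equal length")
        if any(c < 0 for c in self.observed):
            raise ValueError("counts must be nonnegative")
        if any(w <= 0 for w in self.expected_ratio):
            raise ValueError("ratio weights must be positive")
        if sum(self.observed) <= 0:
            raise ValueError("total count must be positive")


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chi2_gof(
    counts: SegregationCounts | Sequence[int],
    expected_ratio: Sequence[float] | None = None,
    yates: bool = False,
) -> Chi2Result:
    """Pearson chi-square goodness of fit against a segregation ratio.

    ``chi2_gof(SegregationCounts((111, 361)))`` tests the classic 3:1
    single-recessive-gene expectation.  The statistic is
    sum((O - E)^2 / E) with E = total * normalised ratio and
    df = classes - 1.  No continuity correction is applied by default;
    pass ``yates=True`` for the Yates-corrected statistic (only meaningful
    for two classes).
    """
    if isinstance(counts, SegregationCounts):
        obs = np.asarray(counts.observed, dtype=float)
        ratio = np.asarray(counts.expected_ratio, dtype=float)
    else:
        obs = np.asarray(counts, dtype=float)
        ratio = np.asarray(
            expected_ratio if expected_ratio is not None else [1.0] * len(obs),
            dtype=float,
        )
    if np.any(ratio <= 0):
        raise ValueError("every expected class weight must be positive")
    expected = obs.sum() * ratio / ratio.sum()
    if yates:
        stat = float(np.sum((np.abs(obs - expected) - 0.5) ** 2 / expected))
    else:
        stat = float(stats.chisquare(obs, f_exp=expected).statistic)
    df = len(obs) - 1
    return Chi2Result(stat, df, float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Marker–phenotype cosegregation
# ---------------------------------------------------------------------------


@dataclass
class CosegregationResult:
    consistent: bool
    mutant_count: int
    wt_class_counts: dict[str, int]
    discordant_ids: list[str] = field(default_factory=list)


def cosegregation_check(
    genotypes: Mapping[str, str],
    phenotypes: Mapping[str, str],
    inheritance: str = "recessive_mutant",
) -> CosegregationResult:
    """Check that a candidate marker cosegregates with the phenotype.

    For a recessive mutant, every mutant-phenotype individual must carry the
    marker homozygously (hom_alt) and no wild-type individual may be
    hom_alt; wild-type individuals may be hom_ref or het in any mix (their
    counts are tabulated and returned).  For a dominant mutant the rule is
    reversed: mutants must carry at least one marker allele and wild types
    must be hom_ref.

    Both tables are keyed by individual id and must cover the same ids.
    """
    design = CrossDesign(inheritance=inheritance)
    g_ids, p_ids = set(genotypes), set(phenotypes)
    if g_ids != p_ids:
        missing = sorted(g_ids.symmetric_difference(p_ids))[:5]
        raise ValueError(
            f"genotype and phenotype tables cover different ids (e.g. {missing})"
        )
    discordant: list[str] = []
    wt_counts = {"hom_ref": 0, "het": 0, "hom_alt": 0}
    mutant_count = 0
    for ind in sorted(genotypes):
        g, ph = genotypes[ind], phenotypes[ind]
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r} for individual {ind!r}")
        if ph not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {ph!r} for individual {ind!r}")
        if ph == "mutant":
            mutant_count += 1
        else:
            wt_counts[g] += 1
        if design.phenotype_of(g) != ph:
            discordant.append(ind)
    return CosegregationResult(
        consistent=not discordant,
        mutant_count=mutant_count,
        wt_class_counts={k: v for k, v in wt_counts.items() if k != "hom_alt"},
        discordant_ids=discordant,
    )
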