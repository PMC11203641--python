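"""Photosynthetic pigment quantification, qPCR fold change, group comparison.

Pigment contents are computed from spectrophotometer absorbances of an
80% acetone leaf extract with the classic three-wavelength equations

    chlorophyll a (mg/L) = 9.784 OD663 - 0.990 OD645
    chlorophyll b (mg/L) = 21.426 OD645 - 4.650 OD663
    carotenoid    (mg/L) = 4.695 OD440 - 0.268 (chl a + chl b)

and converted to mg per gram of fresh tissue with the extract volume and
fresh mass.  Relative transcript abundance uses the -ddCt method, and
two-group comparisons use Student's pooled-variance t-test (Welch's
unpooled variant behind a flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PIGMENT_COEFFS",
    "PigmentReading",
    "PigmentResult",
    "QpcrQuad",
    "pigment_concentrations",
    "per_gram",
    "total_pigments",
    "quantify_reading",
    "ddct_fold_change",
    "two_sample_t",
    "percent",
]

#: Linear map (OD663, OD645) -> (chl a, chl b) in mg/L, plus the carotenoid
#: coefficients (on OD440 and on total chlorophyll).
PIGMENT_COEFFS = {
    "chl_a": (9.784, -0.990),
    "chl_b": (-4.650, 21.426),
    "car_od440": 4.695,
    "car_chl": -0.268,
}


class PigmentConcentrations(NamedTuple):
    chl_a: float
    chl_b: float
    carotenoid: float


@dataclass(frozen=True)
class PigmentReading:
    """One spectrophotometer reading of an acetone leaf extract."""

    od663: float
    od645: float
    od440: float
    extract_volume_l: float
    fresh_mass_g: float
    replicate: str = ""

    def __post_init__(self) -> None:
        if min(self.od663, self.od645, self.od440) < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.extract_volume_l <= 0:
            raise ValueError("extract volume must be positive")
        if self.fresh_mass_g <= 0:
            raise ValueError("fresh mass must be positive")


@dataclass(frozen=True)
class PigmentResult:
    """Pigment contents in mg per g fresh weight."""

    chl_a: float
    chl_b: float
    total_chl: float
    carotenoid: float

    def __post_init__(self) -> None:
        if abs(self.total_chl - (self.chl_a + self.chl_b)) > 1e-9:
            raise ValueError("total_chl must equal chl_a + chl_b")


def pigment_concentrations(
    od663: float, od645: float, od440: float
) -> PigmentConcentrations:
    """Pigment concentrations in mg/L from the three absorbances.

    Negative results (possible with noisy readings near zero) are returned
    unclamped with a warning, so that simulation/quantification round trips
    remain exact.
    """
    if min(od663, od645, od440) < 0:
        raise ValueError("absorbances must be nonnegative")
    a663, a645 = PIGMENT_COEFFS["chl_a"]
    b663, b645 = PIGMENT_COEFFS["chl_b"]
    chl_a = a663 * od663 + a645 * od645
    chl_b = b663 * od663 + b645 * od645
    car = PIGMENT_COEFFS["car_od440"] * od440 + PIGMENT_COEFFS["car_chl"] * (
        chl_a + chl_b
    )
    if min(chl_a, chl_b, car) < 0:
        warnings.warn(
            "negative pigment concentration computed from the given absorbances",
            stacklevel=2,
        )
    return PigmentConcentrations(chl_a, chl_b, car)


def per_gram(conc_mg_per_l: float, extract_volume_l: float, fresh_mass_g: float) -> float:
    """Convert a mg/L extract concentration to mg per g fresh weight."""
    if extract_volume_l <= 0:
        raise ValueError("extract volume must be positive")
    if fresh_mass_g <= 0:
        raise ValueError("fresh mass must be positive")
    return conc_mg_per_l * extract_volume_l / fresh_mass_g


def total_pigments(chl_a: float, chl_b: float, ndigits: int | None = None) -> float:
    """Total chlorophyll (a + b); summaries report it rounded to 2 decimals."""
    total = chl_a + chl_b
    return round(total, ndigits) if ndigits is not None else total


def quantify_reading(reading: PigmentReading) -> PigmentResult:
    """Full per-sample quantification: ODs -> mg/g fresh weight."""
    conc = pigment_concentrations(reading.od663, reading.od645, reading.od440)
    chl_a = per_gram(conc.chl_a, reading.extract_volume_l, reading.fresh_mass_g)
    chl_b = per_gram(conc.chl_b, reading.extract_volume_l, reading.fresh_mass_g)
    car = per_gram(conc.carotenoid, reading.extract_volume_l, reading.fresh_mass_g)
    return PigmentResult(chl_a=chl_a, chl_b=chl_b, total_chl=chl_a + chl_b, carotenoid=car)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrQuad:
    """The four Ct values of one -ddCt comparison."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_control,
            self.ct_reference_control,
        ):
            if not math.isfinite(v):
                raise ValueError("all Ct values must be finite")


def ddct_fold_change(q: QpcrQuad) -> float:
    """Relative expression 2**(-ddCt).

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the control; one cycle of advantage doubles the estimate.
    """
    ddct = (q.ct_target_sample - q.ct_reference_sample) - (
        q.ct_target_control - q.ct_reference_control
    )
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# Two-group comparison
# ---------------------------------------------------------------------------


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test; Student's pooled-variance by default.

    Degenerate inputs with zero variance in both groups return t = 0,
    p = 1 when the means agree and p = 0 (with a warning) when they do not.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    df = (
        a.size + b.size - 2
        if not welch
        else _welch_df(a, b)
    )
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(df), 1.0)
        warnings.warn(
            "zero within-group variance with unequal means: p-value degenerates to 0",
            stacklevel=2,
        )
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), float(df), 0.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0.0:
        return float(a.size + b.size - 2)
    return (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))


def percent(part: float, whole: float, ndigits: int = 0) -> float:
    """Percentage of ``whole`` represented by ``part``, rounded for reporting."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, ndigits)
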