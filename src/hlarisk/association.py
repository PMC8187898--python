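"""Carrier-rate association testing on 2x2 tables.

For each allele the carrier rate in cases is compared with tolerant controls
by a chi-square test on the 2x2 table — Pearson's statistic when all expected
cell counts are at least 5, Yates' continuity-corrected statistic otherwise
(Fisher's exact test is available as a diagnostic alternative for sparse
tables). Effect size is the cross-product odds ratio with a Woolf (log-scale
normal) 95% confidence interval; tables containing a zero cell get the
Haldane–Anscombe 0.5 correction, flagged in the result. Per-locus multiple
testing is handled by Bonferroni correction with the number of distinct
alleles observed at the locus in the cohort.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alleles import HlaAllele
from .cohort import (
    CarrierTable,
    Cohort,
    CohortError,
    Locus,
    build_carrier_table,
    enumerate_alleles,
)

#: z-quantile for 95% Woolf intervals (Phi^{-1}(0.975)).
Z_95 = float(stats.norm.ppf(0.975))


class TestKind(enum.Enum):
    PEARSON = "pearson"
    YATES = "yates"
    FISHER = "fisher"


def _check_margins(table: CarrierTable) -> np.ndarray:
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise CohortError(f"degenerate margin in table {table}")
    return arr


def expected_counts(table: CarrierTable) -> np.ndarray:
    """Expected cell counts under independence, from the margins."""
    arr = _check_margins(table)
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def pearson_chi2(table: CarrierTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; 1 df, two-sided."""
    arr = _check_margins(table)
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def yates_chi2(table: CarrierTable) -> tuple[float, float]:
    """Continuity-corrected chi-square (|O-E| shrunk by 0.5, floored at 0)."""
    arr = _check_margins(table)
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(chi2), float(p)


def fisher_exact(table: CarrierTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= obs)."""
    arr = _check_margins(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def select_test(table: CarrierTable) -> TestKind:
    """Continuity correction iff any expected cell count is below 5."""
    return (
        TestKind.YATES if expected_counts(table).min() < 5 else TestKind.PEARSON
    )


def carrier_test(table: CarrierTable) -> tuple[TestKind, float, float]:
    """Run the selected chi-square variant; returns (test, statistic, p)."""
    kind = select_test(table)
    stat, p = (
        yates_chi2(table) if kind is TestKind.YATES else pearson_chi2(table)
    )
    return kind, stat, p


def odds_ratio_woolf(
    table: CarrierTable, z: float = Z_95
) -> tuple[float, float, float, bool]:
    """Odds ratio with Woolf confidence interval.

    OR = ad/bc; CI = exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)). If any
    cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) for both
    the point estimate and the interval; the returned flag marks the
    correction. An allele carried by nobody in either arm (a = c = 0) has no
    defined OR and raises instead of being corrected.
    """
    a, b, c, d = table.cells
    if a == 0 and c == 0:
        raise CohortError("odds ratio undefined: allele absent from both arms")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        or_point,
        or_point * math.exp(-z * se),
        or_point * math.exp(z * se),
        corrected,
    )


def bonferroni(p_raw: float, multiplicity: int) -> float:
    """Bonferroni-corrected p: min(1, multiplicity * p_raw)."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return min(1.0, multiplicity * p_raw)


@dataclass(frozen=True)
class AssociationResult:
    """Association of one allele with case status in one drug cohort."""

    allele: HlaAllele
    table: CarrierTable
    or_point: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_corrected: float
    test_used: TestKind
    multiplicity: int
    zero_cell_corrected: bool = False

    def as_dict(self) -> dict:
        return {
            "allele": self.allele.short_name,
            "a": self.table.a,
            "case_total": self.table.case_total,
            "c": self.table.c,
            "control_total": self.table.control_total,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_raw,
            "p_corrected": self.p_corrected,
            "test": self.test_used.value,
            "multiplicity": self.multiplicity,
            "zero_cell_corrected": self.zero_cell_corrected,
        }


def associate(
    table: CarrierTable, allele: HlaAllele, multiplicity: int = 1
) -> AssociationResult:
    """Full association result for one carrier table."""
    kind, _, p = carrier_test(table)
    or_point, lo, hi, corrected = odds_ratio_woolf(table)
    return AssociationResult(
        allele=allele,
        table=table,
        or_point=or_point,
        ci_low=lo,
        ci_high=hi,
        p_raw=p,
        p_corrected=bonferroni(p, multiplicity),
        test_used=kind,
        multiplicity=multiplicity,
        zero_cell_corrected=corrected,
    )


def scan_locus(
    cohort: Cohort, locus: Locus, min_carriers: int = 3
) -> list[AssociationResult]:
    """Test every allele observed at a locus against case status.

    Alleles with fewer than ``min_carriers`` pooled carriers are skipped as
    noise, but the Bonferroni multiplicity is always the full number of
    distinct alleles enumerated at the locus — matching how per-locus
    correction denominators are reported. Protective alleles (OR < 1) are
    retained. Results are sorted by raw p-value.
    """
    enumerated = enumerate_alleles(cohort, locus)
    multiplicity = max(1, len(enumerated))
    results = []
    for allele, n_carriers in enumerated:
        if n_carriers < min_carriers:
            continue
        table = build_carrier_table(cohort, allele)
        if table.a + table.c in (0, table.case_total + table.control_total):
            # carried by nobody or by everyone: no contrast to test
            continue
        results.append(associate(table, allele, multiplicity))
    results.sort(key=lambda r: r.p_raw)
    return results
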