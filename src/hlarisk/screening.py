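"""Screening performance of HLA risk markers under an external prevalence.

In-sample carrier tables give sensitivity and specificity directly; PPV, NPV
and the number needed to test (NNT) additionally require the population
incidence of the drug reaction, which in a case-control design must come
from external reports — the defaults below are the reported incidences of
antiepileptic-drug-induced maculopapular exanthema: 3.7% on carbamazepine,
4.8% on lamotrigine, 9% on oxcarbazepine and 2.8% for aromatic AEDs overall.

NNT = 1 / (prevalence x sensitivity) is the expected number of prospective
patients screened per reaction prevented (assuming carriers avoid the drug);
it is reported as the ceiling of that expectation, with the raw value kept
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alleles import HlaAllele
from .cohort import (
    CarrierStatus,
    CarrierTable,
    Cohort,
    CohortError,
    Group,
    is_carrier,
)

#: External prevalence of drug-induced maculopapular exanthema, by drug.
DEFAULT_PREVALENCE = {
    "CBZ": 0.037,
    "LTG": 0.048,
    "OXC": 0.09,
    "POOLED": 0.028,
}


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningResult:
    """Screening metrics for a marker at a stated external prevalence."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    nnt: int
    nnt_raw: float


def sensitivity_specificity(table: CarrierTable) -> tuple[float, float]:
    """Sensitivity a/case_total and specificity 1 - c/control_total."""
    return table.a / table.case_total, 1.0 - table.c / table.control_total


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV by Bayes' rule at the stated prevalence.

    ppv = sens*prev / (sens*prev + (1-spec)(1-prev));
    npv = spec(1-prev) / (spec(1-prev) + (1-sens)*prev).
    """
    if not 0 < prevalence < 1:
        raise ScreeningError("prevalence must lie in (0, 1)")
    pos = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    neg = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if pos == 0 or neg == 0:
        raise ScreeningError(
            "marker is never positive or never negative; predictive value "
            "undefined"
        )
    return sensitivity * prevalence / pos, specificity * (1 - prevalence) / neg


def number_needed_to_test(
    sensitivity: float, prevalence: float
) -> tuple[int, float]:
    """(ceil, raw) of 1/(prevalence x sensitivity)."""
    if sensitivity <= 0 or prevalence <= 0:
        raise ScreeningError(
            "NNT undefined at zero sensitivity or zero prevalence"
        )
    raw = 1.0 / (prevalence * sensitivity)
    return math.ceil(raw), raw


def screen(table: CarrierTable, prevalence: float) -> ScreeningResult:
    """All screening metrics for one carrier table at one prevalence."""
    sens, spec = sensitivity_specificity(table)
    ppv, npv = predictive_values(sens, spec, prevalence)
    nnt, nnt_raw = number_needed_to_test(sens, prevalence)
    return ScreeningResult(
        sensitivity=sens,
        specificity=spec,
        prevalence=prevalence,
        ppv=ppv,
        npv=npv,
        nnt=nnt,
        nnt_raw=nnt_raw,
    )


def combined_screen(
    cohort: Cohort, alleles: set[HlaAllele] | frozenset[HlaAllele]
) -> CarrierTable:
    """Carrier table for the union marker "carries ANY allele in the set".

    An individual untyped at every locus the set touches is excluded from
    the denominators; one typed at some loci counts as a carrier as soon as
    a known locus shows carriage, and as a non-carrier only when all
    relevant loci are typed and negative.
    """
    if not alleles:
        raise ScreeningError("combined screen requires at least one allele")
    counts = {Group.CASE: [0, 0], Group.CONTROL: [0, 0]}
    for rec in cohort.records:
        statuses = [is_carrier(rec, al) for al in alleles]
        if any(s is CarrierStatus.CARRIER for s in statuses):
            counts[rec.group][0] += 1
            counts[rec.group][1] += 1
        elif all(s is CarrierStatus.NON_CARRIER for s in statuses):
            counts[rec.group][1] += 1
        # else: carrier status undecidable -> excluded
    (a, n1), (c, n2) = counts[Group.CASE], counts[Group.CONTROL]
    if n1 == 0 or n2 == 0:
        raise CohortError("no usable individuals in one arm for combined screen")
    return CarrierTable(a=a, case_total=n1, c=c, control_total=n2)
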