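"""Genotype cohorts: data model, I/O, carrier tables and baseline comparisons.

A cohort couples drug-exposed cases (patients who developed maculopapular
exanthema, MPE, on an aromatic antiepileptic drug) with drug-tolerant
controls, each typed at up to four HLA loci. Carriage — at least one copy of
an allele — is the unit of analysis throughout; homozygotes count once.
Genotyping may be missing per locus (both calls absent), so carrier-table
denominators shrink per locus rather than dropping whole records.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alleles import HlaAllele, Locus, parse_allele

logger = logging.getLogger(__name__)

LOCI: tuple[Locus, ...] = (Locus.A, Locus.B, Locus.C, Locus.DRB1)

GENOTYPE_COLUMNS = [
    "sample_id", "group", "drug",
    "A_1", "A_2", "B_1", "B_2", "C_1", "C_2", "DRB1_1", "DRB1_2",
]


class Group(enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Drug(enum.Enum):
    """Aromatic antiepileptic drugs covered by the analysis."""

    CBZ = "CBZ"   # carbamazepine
    LTG = "LTG"   # lamotrigine
    OXC = "OXC"   # oxcarbazepine
    POOLED = "POOLED"


class CarrierStatus(enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non-carrier"
    UNKNOWN = "unknown"


class CohortError(ValueError):
    """Malformed or unusable cohort data."""


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual: id, case/control status, drug, and per-locus calls.

    ``calls`` maps each locus to a pair of alleles or to ``None`` when the
    locus was not genotyped. A locus with exactly one call present is
    invalid — typing yields both chromosomes or neither.
    """

    sample_id: str
    group: Group
    drug: Drug
    calls: dict[Locus, tuple[HlaAllele, HlaAllele] | None] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for locus, pair in self.calls.items():
            if pair is None:
                continue
            a1, a2 = pair
            if a1.locus is not locus or a2.locus is not locus:
                raise CohortError(
                    f"sample {self.sample_id}: call at locus {locus} "
                    f"names a different locus"
                )


@dataclass
class Cohort:
    """A drug-exposure cohort of cases and tolerant controls."""

    drug: Drug
    records: list[GenotypeRecord]

    def __post_init__(self) -> None:
        ids = Counter(r.sample_id for r in self.records)
        dups = sorted(i for i, k in ids.items() if k > 1)
        if dups:
            raise CohortError(f"duplicate sample_id(s): {', '.join(dups)}")

    @property
    def cases(self) -> list[GenotypeRecord]:
        return [r for r in self.records if r.group is Group.CASE]

    @property
    def controls(self) -> list[GenotypeRecord]:
        return [r for r in self.records if r.group is Group.CONTROL]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier/non-carrier by case/control counts for one allele.

    ``a`` case carriers of ``case_total`` cases with known status at the
    locus; ``c`` control carriers of ``control_total``. Non-carrier counts
    are ``b = case_total - a`` and ``d = control_total - c``.
    """

    a: int
    case_total: int
    c: int
    control_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.case_total) or not (
            0 <= self.c <= self.control_total
        ):
            raise CohortError(f"inconsistent carrier counts: {self}")
        if self.case_total <= 0 or self.control_total <= 0:
            raise CohortError("carrier table requires positive group totals")

    @property
    def b(self) -> int:
        return self.case_total - self.a

    @property
    def d(self) -> int:
        return self.control_total - self.c

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def is_carrier(record: GenotypeRecord, allele: HlaAllele) -> CarrierStatus:
    """Carrier status of one individual for one allele (tri-state).

    Carrier iff at least one of the two calls at the allele's locus equals
    the allele; homozygotes count once. Unknown iff the locus is untyped.
    """
    pair = record.calls.get(allele.locus)
    if pair is None:
        return CarrierStatus.UNKNOWN
    return (
        CarrierStatus.CARRIER
        if allele in pair
        else CarrierStatus.NON_CARRIER
    )


def build_carrier_table(cohort: Cohort, allele: HlaAllele) -> CarrierTable:
    """Cross-tabulate carriage of ``allele`` against case/control status.

    Denominators count only individuals typed at the allele's locus, so they
    may differ between alleles at different loci within one cohort.
    """
    counts = {Group.CASE: [0, 0], Group.CONTROL: [0, 0]}  # [carriers, total]
    for rec in cohort.records:
        status = is_carrier(rec, allele)
        if status is CarrierStatus.UNKNOWN:
            continue
        counts[rec.group][1] += 1
        if status is CarrierStatus.CARRIER:
            counts[rec.group][0] += 1
    (a, n1), (c, n2) = counts[Group.CASE], counts[Group.CONTROL]
    if n1 == 0 or n2 == 0:
        raise CohortError(
            f"no usable individuals in one arm at locus {allele.locus} "
            f"for {allele.name}"
        )
    return CarrierTable(a=a, case_total=n1, c=c, control_total=n2)


def enumerate_alleles(cohort: Cohort, locus: Locus) -> list[tuple[HlaAllele, int]]:
    """Distinct alleles observed at ``locus`` with pooled carrier counts.

    Sorted by descending carrier count (cases + controls together), ties by
    canonical name. The length of the returned list is the multiplicity used
    for Bonferroni correction at this locus.
    """
    carriers: Counter[HlaAllele] = Counter()
    for rec in cohort.records:
        pair = rec.calls.get(locus)
        if pair is None:
            continue
        for allele in set(pair):  # homozygote counted once
            carriers[allele] += 1
    return sorted(carriers.items(), key=lambda kv: (-kv[1], kv[0].name))


def pool_cohorts(cohorts: Sequence[Cohort]) -> Cohort:
    """Union of cohorts with each individual counted once by sample id.

    Individuals tolerant to several drugs appear in several control arms;
    pooling keeps one record per id. An individual who is a case in one
    cohort and a control in another is kept as a case (the conflict is
    logged). The same id with differing genotype calls is an error.
    """
    merged: dict[str, GenotypeRecord] = {}
    for cohort in cohorts:
        for rec in cohort.records:
            prev = merged.get(rec.sample_id)
            if prev is None:
                merged[rec.sample_id] = rec
                continue
            if prev.calls != rec.calls:
                raise CohortError(
                    f"sample {rec.sample_id} has conflicting genotypes "
                    f"across cohorts"
                )
            if prev.group is not rec.group:
                logger.warning(
                    "sample %s is case for one drug and control for "
                    "another; kept as case", rec.sample_id,
                )
                if rec.group is Group.CASE:
                    merged[rec.sample_id] = rec
    return Cohort(drug=Drug.POOLED, records=list(merged.values()))


@dataclass(frozen=True)
class GroupComparison:
    """Two-arm baseline comparison: per-arm estimate, difference, p-value."""

    kind: str                 # "numeric" (Welch t) or "binary" (chi-square)
    estimate_cases: float
    estimate_controls: float
    difference: float
    p_value: float
    flagged: bool = False     # p undefined (e.g. zero variance in both arms)


def compare_numeric(
    cases: Iterable[float], controls: Iterable[float]
) -> GroupComparison:
    """Welch (unequal-variance) t-test between two numeric samples."""
    x = np.asarray(list(cases), dtype=float)
    y = np.asarray(list(controls), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise CohortError("numeric comparison requires >=2 values per arm")
    if np.var(x) == 0 and np.var(y) == 0:
        diff = float(np.mean(x) - np.mean(y))
        return GroupComparison(
            "numeric", float(np.mean(x)), float(np.mean(y)), diff,
            p_value=1.0 if diff == 0 else float("nan"), flagged=diff != 0,
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(
        "numeric", float(np.mean(x)), float(np.mean(y)),
        float(np.mean(x) - np.mean(y)), float(res.pvalue),
    )


def compare_numeric_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> GroupComparison:
    """Welch t-test from published summary statistics (mean, SD, n)."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return GroupComparison(
        "numeric", mean1, mean2, mean1 - mean2, float(res.pvalue)
    )


def compare_binary(
    cases: Iterable[int], controls: Iterable[int]
) -> GroupComparison:
    """Pearson chi-square on a binary trait's 2x2 table."""
    x = np.asarray(list(cases), dtype=int)
    y = np.asarray(list(controls), dtype=int)
    table = np.array(
        [[x.sum(), len(x) - x.sum()], [y.sum(), len(y) - y.sum()]]
    )
    p1, p2 = x.mean(), y.mean()
    if (table[:, 0].sum() == 0) or (table[:, 1].sum() == 0):
        # trait constant in both arms: no test possible
        return GroupComparison(
            "binary", float(p1), float(p2), float(p1 - p2),
            p_value=1.0 if p1 == p2 else float("nan"), flagged=True,
        )
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(
        "binary", float(p1), float(p2), float(p1 - p2), float(p)
    )


def cohort_characteristics(
    cases: Sequence[float], controls: Sequence[float], kind: str = "numeric"
) -> GroupComparison:
    """Baseline comparison of one variable between cases and controls.

    ``kind="numeric"`` uses a Welch t-test; ``kind="binary"`` a Pearson
    chi-square on the implied 2x2 table.
    """
    if kind == "numeric":
        return compare_numeric(cases, controls)
    if kind == "binary":
        return compare_binary([int(v) for v in cases], [int(v) for v in controls])
    raise ValueError(f"unknown comparison kind {kind!r}")


# ---------------------------------------------------------------------------
# File I/O — UTF-8 CSV/TSV with header
# sample_id,group,drug,A_1,A_2,B_1,B_2,C_1,C_2,DRB1_1,DRB1_2
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cohort(path: str | Path, drug: Drug | None = None) -> Cohort:
    """Read a genotype cohort from a delimited text file.

    Empty strings are missing calls; a locus must have both calls present or
    both absent. Duplicate sample ids and unknown group labels are errors
    naming the offending row.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise CohortError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        reader = csv.DictReader([first] + fh.readlines(), delimiter=delim)
        missing_cols = set(GENOTYPE_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise CohortError(
                f"{path}: missing column(s) {', '.join(sorted(missing_cols))}"
            )
        records = []
        for row_no, row in enumerate(reader, start=2):
            try:
                group = Group(row["group"].strip().lower())
            except ValueError:
                raise CohortError(
                    f"{path} row {row_no}: group must be case/control, "
                    f"got {row['group']!r}"
                ) from None
            row_drug = Drug(row["drug"].strip().upper())
            calls: dict[Locus, tuple[HlaAllele, HlaAllele] | None] = {}
            for locus in LOCI:
                raw1 = row[f"{locus.value}_1"].strip()
                raw2 = row[f"{locus.value}_2"].strip()
                if bool(raw1) != bool(raw2):
                    raise CohortError(
                        f"{path} row {row_no}: locus {locus.value} has one "
                        f"call present and one missing"
                    )
                if not raw1:
                    calls[locus] = None
                else:
                    calls[locus] = (
                        parse_allele(raw1, locus=locus),
                        parse_allele(raw2, locus=locus),
                    )
            records.append(
                GenotypeRecord(
                    sample_id=row["sample_id"].strip(),
                    group=group,
                    drug=row_drug,
                    calls=calls,
                )
            )
    return Cohort(drug=drug if drug is not None else _infer_drug(records),
                  records=records)


def _infer_drug(records: list[GenotypeRecord]) -> Drug:
    drugs = {r.drug for r in records}
    return drugs.pop() if len(drugs) == 1 else Drug.POOLED


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the genotype CSV format read by :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENOTYPE_COLUMNS)
        for rec in cohort.records:
            row = [rec.sample_id, rec.group.value, rec.drug.value]
            for locus in LOCI:
                pair = rec.calls.get(locus)
                if pair is None:
                    row += ["", ""]
                else:
                    row += [pair[0].short_name, pair[1].short_name]
            writer.writerow(row)
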