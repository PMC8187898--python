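"""Published carrier counts from the southern Han Chinese AED-MPE study.

The original multicenter case-control study of antiepileptic-drug-induced
maculopapular exanthema released its results as per-allele carrier counts
(carriers/typed, by drug cohort), a two-locus joint-carriage table, and the
per-locus allele-diversity counts used as Bonferroni denominators — not as
individual-level genotypes. Those printed counts are the inputs this module
provides, so every downstream statistic can be recomputed from them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alleles import parse_allele
from .cohort import CarrierTable, Locus
from .interaction import JointCarrierTable

#: Reported incidence of MPE by drug, used as external screening prevalence.
PREVALENCE = {"CBZ": 0.037, "LTG": 0.048, "OXC": 0.09, "POOLED": 0.028}

#: Distinct alleles observed per locus per drug cohort (cases + controls):
#: the Bonferroni multiplicities.
MULTIPLICITY = {
    "CBZ": {Locus.A: 24, Locus.B: 51, Locus.C: 25, Locus.DRB1: 26},
    "LTG": {Locus.A: 19, Locus.B: 46, Locus.C: 23, Locus.DRB1: 26},
    "OXC": {Locus.A: 16, Locus.B: 37, Locus.C: 18, Locus.DRB1: 19},
    "POOLED": {Locus.A: 24, Locus.B: 51, Locus.C: 27, Locus.DRB1: 26},
}


@dataclass(frozen=True)
class ReportedRow:
    """One published risk-allele row: cohort, allele and carrier counts."""

    cohort: str                  # CBZ / OXC / POOLED
    allele: str                  # short allele name, or a combined marker id
    table: CarrierTable

    @property
    def prevalence(self) -> float:
        return PREVALENCE[self.cohort]

    @property
    def multiplicity(self) -> int:
        locus = parse_allele(self.allele.split("|")[0]).locus
        return MULTIPLICITY[self.cohort][locus]


#: Single-allele risk rows (carriers/typed in cases vs tolerant controls).
RISK_ALLELE_ROWS = [
    ReportedRow("CBZ", "B*38:02", CarrierTable(18, 145, 10, 179)),
    ReportedRow("OXC", "DRB1*04:06", CarrierTable(8, 51, 1, 94)),
    ReportedRow("POOLED", "A*24:02", CarrierTable(56, 253, 48, 308)),
    ReportedRow("POOLED", "A*30:01", CarrierTable(14, 253, 7, 308)),
    ReportedRow("POOLED", "B*35:01", CarrierTable(11, 261, 4, 344)),
    ReportedRow("POOLED", "B*38:02", CarrierTable(28, 261, 20, 344)),
    ReportedRow("POOLED", "DRB1*04:06", CarrierTable(17, 259, 9, 343)),
]

#: Union marker "carries A*24:02 and/or B*38:02" in the CBZ cohort.
COMBINED_ROW = ReportedRow(
    "CBZ", "A*24:02|B*38:02", CarrierTable(44, 140, 37, 177)
)

#: Joint carriage of A*24:02 x B*38:02 in the CBZ cohort, stratum order
#: (both, A only, B only, neither).
JOINT_TABLE_CBZ = JointCarrierTable(
    allele_a=parse_allele("HLA-A*24:02"),
    allele_b=parse_allele("HLA-B*38:02"),
    cases=(5, 26, 13, 96),
    controls=(1, 27, 9, 140),
)

#: Published daily-dosage summaries (mean, SD, n) for cases vs controls.
DOSAGE_SUMMARIES = {
    "CBZ": ((347.86, 174.13, 70), (540.17, 289.41, 175)),
    "LTG": ((60.39, 62.43, 43), (131.66, 99.99, 101)),
    "OXC": ((481.71, 223.59, 38), (501.90, 263.72, 79)),
}


def reported_row(cohort: str, allele: str) -> ReportedRow:
    """Look up a published row by cohort and short allele name."""
    for row in RISK_ALLELE_ROWS + [COMBINED_ROW]:
        if row.cohort == cohort and row.allele == allele:
            return row
    raise KeyError(f"no reported row for {allele} in {cohort}")
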