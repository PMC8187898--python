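"""Shared fixtures: small synthetic cohorts built to exact carrier counts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from hlarisk import (
    Cohort,
    Drug,
    GenotypeRecord,
    Group,
    HlaAllele,
    Locus,
    parse_allele,
)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# fillers guaranteed distinct from any allele under test
FILLER = {
    Locus.A: parse_allele("HLA-A*99:99"),
    Locus.B: parse_allele("HLA-B*99:99"),
    Locus.C: parse_allele("HLA-C*99:99"),
    Locus.DRB1: parse_allele("HLA-DRB1*99:99"),
}


def record(
    sample_id: str,
    group: Group,
    carried: set[HlaAllele] = frozenset(),
    drug: Drug = Drug.OXC,
    typed_loci: tuple[Locus, ...] = tuple(Locus),
) -> GenotypeRecord:
    """One individual carrying exactly the given alleles (filler otherwise)."""
    calls = {}
    for locus in typed_loci:
        here = [a for a in carried if a.locus is locus]
        if len(here) > 2:
            raise ValueError("at most two alleles per locus")
        pair = (here + [FILLER[locus], FILLER[locus]])[:2]
        calls[locus] = (pair[0], pair[1])
    return GenotypeRecord(
        sample_id=sample_id, group=group, drug=drug, calls=calls
    )


def cohort_from_counts(
    allele: HlaAllele,
    a: int,
    case_total: int,
    c: int,
    control_total: int,
    drug: Drug = Drug.OXC,
) -> Cohort:
    """Cohort whose carrier table for ``allele`` is exactly (a, N1, c, N2)."""
    records = []
    for i in range(case_total):
        records.append(
            record(f"case{i}", Group.CASE, {allele} if i < a else set(), drug)
        )
    for i in range(control_total):
        records.append(
            record(
                f"ctrl{i}", Group.CONTROL, {allele} if i < c else set(), drug
            )
        )
    return Cohort(drug=drug, records=records)


def cohort_from_joint_counts(
    allele_a: HlaAllele,
    allele_b: HlaAllele,
    cases: tuple[int, int, int, int],
    controls: tuple[int, int, int, int],
    drug: Drug = Drug.CBZ,
) -> Cohort:
    """Cohort with exact (both, A only, B only, neither) stratum counts."""
    carried = [
        {allele_a, allele_b},
        {allele_a},
        {allele_b},
        set(),
    ]
    records = []
    i = 0
    for group, strata in ((Group.CASE, cases), (Group.CONTROL, controls)):
        for stratum, count in enumerate(strata):
            for _ in range(count):
                records.append(
                    record(f"J{i}", group, carried[stratum], drug)
                )
                i += 1
    return Cohort(drug=drug, records=records)


@pytest.fixture
def oxc_like_cohort() -> Cohort:
    """Cohort reproducing the published OXC DRB1*04:06 counts (8/51 vs 1/94)."""
    return cohort_from_counts(parse_allele("HLA-DRB1*04:06"), 8, 51, 1, 94)


@pytest.fixture
def toy_genotype_csv(tmp_path):
    """Five-individual genotype file: 3 cases, 2 controls, one missing locus."""
    lines = [
        "sample_id,group,drug,A_1,A_2,B_1,B_2,C_1,C_2,DRB1_1,DRB1_2",
        "S1,case,OXC,A*24:02,A*11:01,B*38:02,B*40:01,C*07:02,C*01:02,"
        "DRB1*04:06,DRB1*09:01",
        "S2,case,OXC,A*11:01,A*11:01,B*40:01,B*46:01,C*01:02,C*03:04,"
        "DRB1*04:06,DRB1*04:06",
        "S3,case,OXC,A*02:01,A*33:03,B*58:01,B*15:02,,,DRB1*12:02,DRB1*15:01",
        "S4,control,OXC,A*24:02,A*02:07,B*46:01,B*58:01,C*07:02,C*12:03,"
        "DRB1*09:01,DRB1*12:02",
        "S5,control,OXC,A*11:01,A*30:01,B*35:01,B*38:02,C*03:04,C*01:02,"
        "DRB1*15:01,DRB1*09:01",
    ]
    path = tmp_path / "toy.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
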