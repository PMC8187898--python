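import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hlarisk import TestKind as ChiKind
from hlarisk import (
    CarrierTable,
    Cohort,
    CohortError,
    Drug,
    Group,
    Locus,
    associate,
    bonferroni,
    expected_counts,
    fisher_exact,
    odds_ratio_woolf,
    parse_allele,
    pearson_chi2,
    scan_locus,
    select_test,
    yates_chi2,
)

from conftest import cohort_from_counts, record

# strategy: non-degenerate 2x2 carrier tables
tables = st.tuples(
    st.integers(0, 30), st.integers(1, 40), st.integers(0, 30), st.integers(1, 40)
).filter(
    lambda t: t[0] <= t[1] and t[2] <= t[3] and 0 < t[0] + t[2]
    and t[0] + t[2] < t[1] + t[3]
).map(lambda t: CarrierTable(a=t[0], case_total=t[1], c=t[2], control_total=t[3]))


class TestChiSquare:
    @pytest.mark.parametrize(
        "cells, expected_p",
        [
            ((56, 253, 48, 308), 0.047),
            ((14, 253, 7, 308), 0.043),
        ],
    )
    def test_pearson_reproduces_reported_p(self, cells, expected_p):
        _, p = pearson_chi2(CarrierTable(*cells))
        assert p == pytest.approx(expected_p, abs=5e-4)

    def test_yates_reproduces_sparse_reported_p(self):
        _, p = yates_chi2(CarrierTable(8, 51, 1, 94))
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_equal_proportions_give_p_one(self):
        stat, p = pearson_chi2(CarrierTable(10, 100, 10, 100))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        stat_y, p_y = yates_chi2(CarrierTable(10, 100, 10, 100))
        assert stat_y == pytest.approx(0.0, abs=1e-12)
        assert p_y == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(CohortError):
            pearson_chi2(CarrierTable(0, 10, 0, 10))
        with pytest.raises(CohortError):
            pearson_chi2(CarrierTable(10, 10, 10, 10))

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_yates_never_exceeds_pearson(self, table):
        """The continuity correction can only shrink the statistic."""
        sp, _ = pearson_chi2(table)
        sy, _ = yates_chi2(table)
        assert sy <= sp + 1e-12

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_pearson_is_squared_two_proportion_z(self, table):
        stat, _ = pearson_chi2(table)
        p1, p2 = table.a / table.case_total, table.c / table.control_total
        pooled = (table.a + table.c) / (table.case_total + table.control_total)
        z = (p1 - p2) / math.sqrt(
            pooled * (1 - pooled)
            * (1 / table.case_total + 1 / table.control_total)
        )
        assert stat == pytest.approx(z * z, rel=1e-9)


def fisher_enumeration_oracle(table: CarrierTable) -> float:
    """Brute-force two-sided Fisher p: sum hypergeometric pmfs <= observed."""
    a, b, c, d = table.cells
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return float(min(1.0, total))


class TestFisher:
    def test_symmetry(self):
        assert fisher_exact(CarrierTable(0, 10, 10, 10)) == pytest.approx(
            fisher_exact(CarrierTable(10, 10, 0, 10))
        )

    def test_balanced_minimal_table(self):
        assert fisher_exact(CarrierTable(1, 2, 1, 2)) == pytest.approx(1.0)

    def test_sparse_reported_table_matches_enumeration(self):
        table = CarrierTable(8, 51, 1, 94)
        assert fisher_exact(table) == pytest.approx(
            fisher_enumeration_oracle(table), rel=1e-9
        )

    @given(tables.filter(lambda t: t.case_total + t.control_total <= 40))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_for_small_tables(self, table):
        assert fisher_exact(table) == pytest.approx(
            fisher_enumeration_oracle(table), rel=1e-9, abs=1e-12
        )


class TestSelectTest:
    @pytest.mark.parametrize(
        "cells, kind, min_expected",
        [
            ((8, 51, 1, 94), ChiKind.YATES, 3.17),
            ((18, 145, 10, 179), ChiKind.PEARSON, 12.5),
            ((11, 261, 4, 344), ChiKind.PEARSON, 6.5),
        ],
    )
    def test_expected_count_rule(self, cells, kind, min_expected):
        table = CarrierTable(*cells)
        assert expected_counts(table).min() == pytest.approx(
            min_expected, abs=0.05
        )
        assert select_test(table) is kind

    def test_type_one_error_within_nominal(self):
        """Selected test under an equal-proportion null rejects at <= ~5%."""
        rng = np.random.default_rng(1234)
        reps, n, p_carrier = 2000, 150, 0.12
        rejections = 0
        for _ in range(reps):
            a = rng.binomial(n, p_carrier)
            c = rng.binomial(n, p_carrier)
            if a + c == 0 or a + c == 2 * n:
                continue
            table = CarrierTable(int(a), n, int(c), n)
            _, p = (
                yates_chi2(table)
                if select_test(table) is ChiKind.YATES
                else pearson_chi2(table)
            )
            rejections += p < 0.05
        rate = rejections / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se


class TestWoolfOddsRatio:
    @pytest.mark.parametrize(
        "cells, or_exp, lo_exp, hi_exp",
        [
            ((18, 145, 10, 179), 2.40, 1.07, 5.37),
            ((8, 51, 1, 94), 17.30, 2.10, 142.72),
            ((56, 253, 48, 308), 1.54, 1.00, 2.36),
            ((14, 253, 7, 308), 2.52, 1.00, 6.34),
            ((11, 261, 4, 344), 3.74, 1.18, 11.88),
            ((17, 259, 9, 343), 2.61, 1.14, 5.95),
            ((44, 140, 37, 177), 1.73, 1.04, 2.88),
        ],
    )
    def test_reproduces_reported_or_and_ci(self, cells, or_exp, lo_exp, hi_exp):
        orp, lo, hi, corrected = odds_ratio_woolf(CarrierTable(*cells))
        assert not corrected
        assert round(orp, 2) == or_exp
        assert round(lo, 2) == lo_exp
        assert round(hi, 2) == hi_exp

    def test_equal_odds_ci_straddles_one(self):
        orp, lo, hi, _ = odds_ratio_woolf(CarrierTable(5, 15, 5, 15))
        assert orp == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_haldane_corrected(self):
        orp, lo, hi, corrected = odds_ratio_woolf(CarrierTable(0, 10, 5, 15))
        assert corrected
        assert 0 < lo < orp < hi < math.inf

    def test_absent_allele_undefined(self):
        with pytest.raises(CohortError):
            odds_ratio_woolf(CarrierTable(0, 10, 0, 15))

    @given(tables.filter(lambda t: 0 < t.a < t.case_total and 0 < t.c < t.control_total))
    @settings(max_examples=200, deadline=None)
    def test_row_exchange_inverts_or(self, table):
        orp, lo, hi, _ = odds_ratio_woolf(table)
        swapped = CarrierTable(
            a=table.c, case_total=table.control_total,
            c=table.a, control_total=table.case_total,
        )
        orp2, lo2, hi2, _ = odds_ratio_woolf(swapped)
        assert orp2 == pytest.approx(1 / orp, rel=1e-9)
        assert lo2 == pytest.approx(1 / hi, rel=1e-9)
        assert hi2 == pytest.approx(1 / lo, rel=1e-9)


class TestBonferroni:
    def test_reported_correction(self):
        assert bonferroni(0.002, 19) == pytest.approx(0.038)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_identity_at_multiplicity_one(self):
        assert bonferroni(0.0123, 1) == 0.0123

    def test_invalid_multiplicity(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)


class TestScanLocus:
    def test_planted_effect_ranks_first(self):
        from hlarisk import RiskModel, SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_cases=150, n_controls=250,
            risk_model=RiskModel(
                intercept=-2.5,
                main_effects={"HLA-DRB1*04:06": math.log(5.0)},
            ),
            seed=42,
        )
        cohort = simulate_cohort(cfg)
        results = scan_locus(cohort, Locus.DRB1)
        assert results[0].allele.short_name == "DRB1*04:06"
        assert results[0].or_point > 1

    def test_multiplicity_one_is_identity(self):
        res = associate(
            CarrierTable(8, 51, 1, 94), parse_allele("HLA-DRB1*04:06"),
            multiplicity=1,
        )
        assert res.p_corrected == res.p_raw

    def test_universal_allele_untestable(self):
        """A single allele carried by every typed individual yields no test."""
        allele = parse_allele("HLA-DRB1*04:06")
        records = [
            record_with_only(allele, f"c{i}", Group.CASE) for i in range(5)
        ] + [
            record_with_only(allele, f"t{i}", Group.CONTROL) for i in range(5)
        ]
        cohort = Cohort(Drug.OXC, records)
        assert scan_locus(cohort, Locus.DRB1) == []

    def test_multiplicity_uses_unfiltered_allele_count(self, toy_genotype_csv):
        from hlarisk import enumerate_alleles, read_cohort

        cohort = read_cohort(toy_genotype_csv)
        results = scan_locus(cohort, Locus.B, min_carriers=2)
        enumerated = enumerate_alleles(cohort, Locus.B)
        for res in results:
            assert res.multiplicity == len(enumerated)
        assert len(results) < len(enumerated)

    def test_protective_alleles_retained(self):
        cohort = cohort_from_counts(
            parse_allele("HLA-B*40:01"), 5, 100, 40, 100, drug=Drug.CBZ
        )
        results = scan_locus(cohort, Locus.B)
        by_name = {r.allele.short_name: r for r in results}
        assert by_name["B*40:01"].or_point < 1

    def test_null_scan_family_error_conservative(self):
        """Minimum Bonferroni-corrected p under the null exceeds alpha ~95%."""
        rng = np.random.default_rng(77)
        from hlarisk import (
            DEFAULT_PROFILE,
            RiskModel,
            simulate_genotypes,
            simulate_phenotypes,
        )
        from hlarisk.cohort import Cohort as C, Group as G

        reps, hits = 120, 0
        for i in range(reps):
            recs = simulate_genotypes(
                DEFAULT_PROFILE, 200, rng, loci=(Locus.DRB1,)
            )
            y = simulate_phenotypes(recs, RiskModel(intercept=-1.0), rng)
            recs = [
                r.__class__(
                    sample_id=r.sample_id,
                    group=G.CASE if y[j] else G.CONTROL,
                    drug=r.drug, calls=r.calls,
                )
                for j, r in enumerate(recs)
            ]
            cohort = C(Drug.OXC, recs)
            if not cohort.cases or not cohort.controls:
                continue
            results = scan_locus(cohort, Locus.DRB1)
            if results and min(r.p_corrected for r in results) < 0.05:
                hits += 1
        rate = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se


def record_with_only(allele, sample_id, group):
    from hlarisk import GenotypeRecord

    return GenotypeRecord(
        sample_id=sample_id, group=group, drug=Drug.OXC,
        calls={allele.locus: (allele, allele)},
    )


def test_associate_bundles_everything():
    table = CarrierTable(8, 51, 1, 94)
    res = associate(table, parse_allele("HLA-DRB1*04:06"), multiplicity=19)
    assert res.test_used is ChiKind.YATES
    assert round(res.or_point, 2) == 17.30
    assert res.p_corrected == pytest.approx(19 * res.p_raw)
    assert res.ci_low <= res.or_point <= res.ci_high
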