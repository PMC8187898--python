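"""Two-locus joint-carrier analysis and interaction decomposition.

Individuals are cross-classified by carriage of two risk alleles at
different loci into four strata (both, first only, second only, neither).
Each stratum's odds ratio is taken against the double-negative reference.
The joint effect is then compared with two no-interaction benchmarks:

* multiplicative: expected joint OR = OR_A x OR_B; the interaction ratio
  OR_joint / (OR_A x OR_B) exceeds 1 when the combined risk is
  super-multiplicative;
* additive (on the OR scale): expected joint OR = OR_A + OR_B - 1; the
  excess risk OR_joint - (OR_A + OR_B - 1) exceeds 0 when combined risk is
  super-additive.

A logistic model with indicator main effects and a product term, fitted to
the grouped stratum counts, gives the same decomposition on the log-odds
scale (the four-parameter model is saturated on four strata, so its fitted
odds ratios equal the empirical cross-product ratios).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .alleles import HlaAllele
from .cohort import CarrierStatus, Cohort, CohortError, Group, is_carrier

#: stratum order: (A+B+, A+B-, A-B+, A-B-)
STRATA = ("both", "a_only", "b_only", "neither")


@dataclass(frozen=True)
class JointCarrierTable:
    """Counts of cases and controls in the four joint-carriage strata.

    Only individuals with known carrier status at both loci are included.
    """

    allele_a: HlaAllele
    allele_b: HlaAllele
    cases: tuple[int, int, int, int]
    controls: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cases + self.controls):
            raise CohortError("negative stratum count")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    def swapped(self) -> "JointCarrierTable":
        """The same table with the roles of the two alleles exchanged."""
        reorder = (0, 2, 1, 3)
        return JointCarrierTable(
            allele_a=self.allele_b,
            allele_b=self.allele_a,
            cases=tuple(self.cases[i] for i in reorder),
            controls=tuple(self.controls[i] for i in reorder),
        )


def build_joint_table(
    cohort: Cohort, allele_a: HlaAllele, allele_b: HlaAllele
) -> JointCarrierTable:
    """Cross-classify a cohort by carriage of two alleles at distinct loci."""
    if allele_a.locus is allele_b.locus:
        raise CohortError(
            "joint analysis requires alleles at different loci; carriage of "
            "two alleles at one locus is mutually constrained"
        )
    cases = [0, 0, 0, 0]
    controls = [0, 0, 0, 0]
    for rec in cohort.records:
        sa = is_carrier(rec, allele_a)
        sb = is_carrier(rec, allele_b)
        if CarrierStatus.UNKNOWN in (sa, sb):
            continue
        ca = sa is CarrierStatus.CARRIER
        cb = sb is CarrierStatus.CARRIER
        idx = 0 if (ca and cb) else 1 if ca else 2 if cb else 3
        (cases if rec.group is Group.CASE else controls)[idx] += 1
    return JointCarrierTable(
        allele_a=allele_a,
        allele_b=allele_b,
        cases=tuple(cases),
        controls=tuple(controls),
    )


def stratum_odds_ratios(
    table: JointCarrierTable,
) -> tuple[float, float, float, bool]:
    """Odds ratios of the three exposed strata against the A-B- reference.

    Returns (or_joint, or_a_only, or_b_only, zero_cell_corrected). Strata
    containing a zero cell get the Haldane 0.5 correction together with the
    reference; an empty reference stratum in either group is an error.
    """
    ref_case, ref_ctrl = table.cases[3], table.controls[3]
    if ref_case == 0 or ref_ctrl == 0:
        raise CohortError("empty double-negative reference stratum")
    ors = []
    corrected = False
    for idx in range(3):
        a, c = table.cases[idx], table.controls[idx]
        rc, rd = ref_case, ref_ctrl
        if a == 0 or c == 0:
            a, c, rc, rd = a + 0.5, c + 0.5, rc + 0.5, rd + 0.5
            corrected = True
        ors.append((a * rd) / (rc * c))
    return ors[0], ors[1], ors[2], corrected


@dataclass(frozen=True)
class InteractionDecomposition:
    """Joint effect versus multiplicative and additive expectations."""

    or_joint: float
    or_a_only: float
    or_b_only: float
    expected_multiplicative: float
    interaction_ratio: float
    expected_additive: float
    excess_risk: float
    rounding: int | None = None


def decompose_interaction(
    or_joint: float,
    or_a_only: float,
    or_b_only: float,
    rounding: int | None = None,
) -> InteractionDecomposition:
    """Decompose a joint odds ratio against no-interaction expectations.

    With ``rounding`` set, the three component ORs are rounded to that many
    decimals before being combined — reproducing arithmetic done on ORs as
    printed in reports; leave ``None`` for full-precision analysis.
    """
    if min(or_joint, or_a_only, or_b_only) <= 0:
        raise ValueError("odds ratios must be positive")
    oj, oa, ob = or_joint, or_a_only, or_b_only
    if rounding is not None:
        oj, oa, ob = (round(v, rounding) for v in (oj, oa, ob))
    expected_mult = oa * ob
    expected_add = oa + ob - 1.0
    return InteractionDecomposition(
        or_joint=oj,
        or_a_only=oa,
        or_b_only=ob,
        expected_multiplicative=expected_mult,
        interaction_ratio=oj / expected_mult,
        expected_additive=expected_add,
        excess_risk=oj - expected_add,
        rounding=rounding,
    )


@dataclass(frozen=True)
class LogisticFit:
    """Grouped-binomial logistic fit with indicator mains and product term.

    Coefficients are on the log-odds scale in the order (intercept, carrier
    of A, carrier of B, product). ``converged`` is False under separation
    (some stratum with only cases or only controls), where the MLE drifts to
    infinity.
    """

    coef: tuple[float, float, float, float]
    se: tuple[float, float, float, float]
    z: tuple[float, float, float, float]
    p: tuple[float, float, float, float]
    converged: bool
    iterations: int

    @property
    def odds_ratios(self) -> tuple[float, float, float]:
        """Fitted ORs (joint, A only, B only) vs the double-negative stratum."""
        b0, ba, bb, bab = self.coef
        return math.exp(ba + bb + bab), math.exp(ba), math.exp(bb)


def fit_logistic_interaction(table: JointCarrierTable) -> LogisticFit:
    """Maximum-likelihood logistic fit to the grouped 2x4 stratum counts.

    Design: intercept, indicator for carrying allele A, indicator for B and
    their product; binomial likelihood per stratum (identical MLE to the
    per-individual fit). Newton/IRLS with score tolerance 1e-10, at most 100
    iterations. Perfect separation — a stratum with cases but no controls or
    vice versa — is reported as a non-converged fit rather than an estimate.
    """
    # rows: A+B+, A+B-, A-B+, A-B-
    design = np.array(
        [[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 0]], dtype=float
    )
    endog = np.column_stack([table.cases, table.controls]).astype(float)
    # saturated on 4 strata: the MLE is finite iff every stratum has both
    # outcomes represented
    separated = any(
        c == 0 or k == 0 for c, k in zip(table.cases, table.controls)
    )
    model = sm.GLM(endog, design, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # boundary iterates trip statsmodels' separation heuristic even
            # when the MLE is finite; separation is decided from the counts
            warnings.simplefilter("ignore")
            res = model.fit(tol=1e-10, maxiter=100)
    except Exception:
        nan4 = (float("nan"),) * 4
        return LogisticFit(nan4, nan4, nan4, nan4, False, 0)
    score_norm = float(np.linalg.norm(model.score(res.params)))
    converged = score_norm < 1e-6 and not separated
    return LogisticFit(
        coef=tuple(float(v) for v in res.params),
        se=tuple(float(v) for v in res.bse),
        z=tuple(float(v) for v in res.tvalues),
        p=tuple(float(v) for v in res.pvalues),
        converged=converged,
        iterations=int(res.fit_history.get("iteration", 0) or 0),
    )
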