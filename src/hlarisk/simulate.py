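"""Synthetic genotype cohorts and multi-study tables.

The generator reproduces the statistical structure the analysis assumes:

* genotypes — two independent allele draws per locus per individual
  (Hardy–Weinberg equilibrium) from a per-locus allele-frequency profile,
  with the unlisted remainder lumped into per-locus "other" alleles;
* phenotypes — Bernoulli case status from a logistic risk model over
  carrier indicators, with optional two-allele product (interaction) terms;
* ascertainment — a large source population is simulated and exactly
  ``n_cases`` cases and ``n_controls`` tolerant controls are sampled from
  it, mimicking retrospective case-control recruitment (the odds ratio is
  invariant under this outcome-dependent sampling, which is what makes the
  case-control design estimate it);
* missingness — whole-locus genotype dropout at a configurable per-locus
  rate, as happens when DNA is insufficient for some assays;
* meta-analysis inputs — per-study true log-ORs drawn Normal(mu, tau^2)
  (between-study heterogeneity) with binomial carrier counts per arm.

All draws descend deterministically from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .alleles import HlaAllele, Locus, parse_allele
from .cohort import Cohort, Drug, GenotypeRecord, Group, LOCI, CarrierStatus, is_carrier
from .meta import StudyRecord
from .cohort import CarrierTable


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleFrequencyProfile:
    """Per-locus allele frequencies; the remainder is a catch-all pool.

    Frequencies at each locus must be non-negative and sum to at most 1;
    the residual mass is spread over synthetic filler alleles (``*90:01``
    upward) so draws stay proper HWE draws over a closed allele universe.
    """

    frequencies: Mapping[Locus, Mapping[str, float]]

    def __post_init__(self) -> None:
        for locus, freqs in self.frequencies.items():
            if any(f < 0 for f in freqs.values()):
                raise SimulationError(f"negative frequency at {locus}")
            if sum(freqs.values()) > 1 + 1e-12:
                raise SimulationError(
                    f"frequencies at {locus} sum above 1"
                )

    def universe(self, locus: Locus, n_filler: int = 8) -> tuple[list[HlaAllele], np.ndarray]:
        """Alleles and probabilities at a locus, filler pool included."""
        freqs = self.frequencies.get(locus)
        if not freqs:
            raise SimulationError(f"no allele frequencies for locus {locus}")
        alleles = [parse_allele(name, locus=locus) for name in freqs]
        probs = np.array([freqs[name] for name in freqs], dtype=float)
        rest = 1.0 - probs.sum()
        if rest > 1e-12:
            filler = [
                HlaAllele(locus, str(90 + i // 100).zfill(2), str(i % 100 + 1).zfill(2))
                for i in range(n_filler)
            ]
            alleles += filler
            probs = np.concatenate([probs, np.full(n_filler, rest / n_filler)])
        return alleles, probs / probs.sum()


#: Frequencies loosely shaped like southern Han Chinese class I/II profiles,
#: including the risk alleles analysed downstream.
DEFAULT_PROFILE = AlleleFrequencyProfile({
    Locus.A: {
        "HLA-A*11:01": 0.20, "HLA-A*24:02": 0.16, "HLA-A*02:01": 0.12,
        "HLA-A*33:03": 0.09, "HLA-A*30:01": 0.04, "HLA-A*02:07": 0.06,
    },
    Locus.B: {
        "HLA-B*40:01": 0.14, "HLA-B*46:01": 0.10, "HLA-B*58:01": 0.08,
        "HLA-B*38:02": 0.04, "HLA-B*15:02": 0.05, "HLA-B*35:01": 0.02,
    },
    Locus.C: {
        "HLA-C*07:02": 0.17, "HLA-C*01:02": 0.15, "HLA-C*03:04": 0.12,
        "HLA-C*12:03": 0.03,
    },
    Locus.DRB1: {
        "HLA-DRB1*09:01": 0.15, "HLA-DRB1*12:02": 0.10,
        "HLA-DRB1*15:01": 0.09, "HLA-DRB1*04:06": 0.021,
    },
})


@dataclass(frozen=True)
class RiskModel:
    """Logistic disease model over carrier indicators.

    ``intercept`` is the baseline log-odds of the drug reaction in
    non-carriers; ``main_effects`` maps allele names to log-odds ratios;
    ``interaction`` optionally adds a product term for one allele pair.
    """

    intercept: float
    main_effects: Mapping[str, float] = dc_field(default_factory=dict)
    interaction: tuple[str, str, float] | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort."""

    n_cases: int
    n_controls: int
    drug: Drug = Drug.OXC
    profile: AlleleFrequencyProfile = DEFAULT_PROFILE
    risk_model: RiskModel = RiskModel(intercept=-2.4)
    missingness: Mapping[Locus, float] = dc_field(default_factory=dict)
    seed: int = 0
    pool_factor: int = 40   # source population = pool_factor * (cases+controls)

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise SimulationError("n_cases and n_controls must be positive")
        for locus, rate in self.missingness.items():
            if not 0 <= rate < 1:
                raise SimulationError(f"missingness at {locus} outside [0,1)")


def simulate_genotypes(
    profile: AlleleFrequencyProfile,
    n: int,
    seed: int | np.random.Generator,
    drug: Drug = Drug.OXC,
    loci: Sequence[Locus] = LOCI,
) -> list[GenotypeRecord]:
    """Draw ``n`` individuals' genotypes under HWE at the given loci."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    per_locus: dict[Locus, tuple[list[HlaAllele], np.ndarray]] = {
        locus: profile.universe(locus) for locus in loci
    }
    draws = {
        locus: rng.choice(len(alleles), size=(n, 2), p=probs)
        for locus, (alleles, probs) in per_locus.items()
    }
    records = []
    for i in range(n):
        calls = {
            locus: (
                per_locus[locus][0][draws[locus][i, 0]],
                per_locus[locus][0][draws[locus][i, 1]],
            )
            for locus in loci
        }
        records.append(
            GenotypeRecord(
                sample_id=f"S{i:06d}", group=Group.CONTROL, drug=drug,
                calls=calls,
            )
        )
    return records


def _carrier_indicator(records: Sequence[GenotypeRecord], allele: HlaAllele) -> np.ndarray:
    return np.array(
        [is_carrier(r, allele) is CarrierStatus.CARRIER for r in records],
        dtype=float,
    )


def simulate_phenotypes(
    records: Sequence[GenotypeRecord],
    risk_model: RiskModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Bernoulli case indicator per individual from the logistic model."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    logit = np.full(len(records), risk_model.intercept, dtype=float)
    for name, log_or in risk_model.main_effects.items():
        logit += log_or * _carrier_indicator(records, parse_allele(name))
    if risk_model.interaction is not None:
        name_a, name_b, log_or = risk_model.interaction
        xa = _carrier_indicator(records, parse_allele(name_a))
        xb = _carrier_indicator(records, parse_allele(name_b))
        logit += log_or * xa * xb
    prob = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random(len(records)) < prob).astype(bool)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a case-control cohort by retrospective ascertainment.

    A source population of ``pool_factor x (n_cases + n_controls)``
    individuals is genotyped and assigned outcomes; exactly ``n_cases``
    cases and ``n_controls`` controls are then sampled without replacement.
    Per-locus missingness is applied afterwards (missingness independent of
    genotype and outcome).
    """
    rng = np.random.default_rng(config.seed)
    n_pool = config.pool_factor * (config.n_cases + config.n_controls)
    population = simulate_genotypes(
        config.profile, n_pool, rng, drug=config.drug
    )
    is_case = simulate_phenotypes(population, config.risk_model, rng)
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise SimulationError(
            f"source population yielded {len(case_idx)} cases / "
            f"{len(ctrl_idx)} controls; increase pool_factor"
        )
    chosen_cases = rng.choice(case_idx, size=config.n_cases, replace=False)
    chosen_ctrls = rng.choice(ctrl_idx, size=config.n_controls, replace=False)
    records = []
    for rank, idx in enumerate(np.concatenate([chosen_cases, chosen_ctrls])):
        src = population[idx]
        group = Group.CASE if rank < config.n_cases else Group.CONTROL
        calls = dict(src.calls)
        for locus in list(calls):
            rate = config.missingness.get(locus, 0.0)
            if rate and rng.random() < rate:
                calls[locus] = None
        records.append(
            GenotypeRecord(
                sample_id=f"P{rank:06d}", group=group, drug=config.drug,
                calls=calls,
            )
        )
    return Cohort(drug=config.drug, records=records)


@dataclass(frozen=True)
class MetaSimulationConfig:
    """Between-study model for synthetic meta-analysis inputs."""

    k: int                       # number of studies
    mu: float                    # mean true log-OR
    tau: float                   # between-study SD of the true log-OR
    control_carrier_freq: float = 0.15
    n_cases_per_study: int = 50
    n_controls_per_study: int = 130
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SimulationError("k must be >= 1")
        if not 0 < self.control_carrier_freq < 1:
            raise SimulationError("control carrier frequency must be in (0,1)")


def simulate_meta_studies(config: MetaSimulationConfig) -> list[StudyRecord]:
    """Simulate per-study 2x2 carrier tables with Normal(mu, tau^2) effects.

    Control-arm carriage is binomial at ``control_carrier_freq``; case-arm
    carriage at the odds implied by the study's true log-OR.
    """
    rng = np.random.default_rng(config.seed)
    studies = []
    p0 = config.control_carrier_freq
    for i in range(config.k):
        theta = rng.normal(config.mu, config.tau)
        odds1 = (p0 / (1 - p0)) * np.exp(theta)
        p1 = odds1 / (1 + odds1)
        a = int(rng.binomial(config.n_cases_per_study, p1))
        c = int(rng.binomial(config.n_controls_per_study, p0))
        studies.append(
            StudyRecord(
                study_id=f"study{i + 1:02d}",
                population=f"population{i + 1}",
                drug="mixed",
                allele="simulated",
                table=CarrierTable(
                    a=a,
                    case_total=config.n_cases_per_study,
                    c=c,
                    control_total=config.n_controls_per_study,
                ),
            )
        )
    return studies
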