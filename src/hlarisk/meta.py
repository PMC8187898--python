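"""Contingency-table meta-analysis across case-control studies.

Pools per-study 2x2 carrier tables for one allele across populations.
Two pooled estimators are provided, mirroring standard systematic-review
practice:

* fixed effect — Mantel–Haenszel pooled odds ratio with the
  Robins–Breslow–Greenland variance for its log;
* random effects — DerSimonian–Laird: inverse-variance pooling of Woolf
  log-odds-ratios with the moment estimator tau^2 of between-study variance.

Heterogeneity is quantified by Cochran's Q on the study log-ORs and
I^2 = max(0, (Q - df)/Q) x 100. The model-selection convention is the usual
screening rule: random effects iff Q's p-value < 0.1 AND I^2 > 50%, fixed
otherwise; both sub-conditions are reported so the rule can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z_95
from .cohort import CarrierTable, CohortError

STUDY_COLUMNS = [
    "study_id", "population", "drug", "allele",
    "case_carriers", "case_total", "control_carriers", "control_total",
]


@dataclass(frozen=True)
class StudyRecord:
    """One study's 2x2 carrier table for one allele."""

    study_id: str
    population: str
    drug: str
    table: CarrierTable
    allele: str = ""


@dataclass(frozen=True)
class PooledEffect:
    or_point: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass(frozen=True)
class MetaResult:
    """Fixed and random pooled ORs with heterogeneity diagnostics."""

    k: int
    log_or: tuple[float, ...]
    variance: tuple[float, ...]
    fixed: PooledEffect
    random: PooledEffect
    q: float
    q_p: float
    i2: float
    tau2: float
    model_selected: str                 # "fixed" | "random"
    het_p_flag: bool = False            # q_p < 0.1
    het_i2_flag: bool = False           # i2 > 50
    methods: dict = field(default_factory=lambda: {
        "fixed": "mantel-haenszel", "random": "dersimonian-laird"
    })

    @property
    def selected(self) -> PooledEffect:
        return self.random if self.model_selected == "random" else self.fixed


def study_effects(study: StudyRecord) -> tuple[float, float]:
    """Woolf log-OR and variance 1/a + 1/b + 1/c + 1/d for one study.

    All four cells get +0.5 when any cell is zero. A study whose case or
    control arm is empty carries no information and is rejected.
    """
    a, b, c, d = study.table.cells
    if (a + b) == 0 or (c + d) == 0:  # pragma: no cover - CarrierTable forbids
        raise CohortError(f"study {study.study_id}: empty arm")
    if a == 0 and c == 0:
        raise CohortError(
            f"study {study.study_id}: allele absent from both arms"
        )
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a * d / (b * c)), 1 / a + 1 / b + 1 / c + 1 / d


def _wald(log_pooled: float, var_pooled: float) -> PooledEffect:
    se = math.sqrt(var_pooled)
    z = log_pooled / se if se > 0 else math.inf
    p = 2 * stats.norm.sf(abs(z))
    return PooledEffect(
        or_point=math.exp(log_pooled),
        ci_low=math.exp(log_pooled - Z_95 * se),
        ci_high=math.exp(log_pooled + Z_95 * se),
        z=z,
        p=float(p),
    )


def pool_fixed_mh(studies: Sequence[StudyRecord]) -> PooledEffect:
    """Mantel–Haenszel fixed-effect pooled OR with RBG variance.

    Pooled OR = sum(a_i d_i / n_i) / sum(b_i c_i / n_i), computed on the
    uncorrected counts (the MH estimator tolerates sparse cells without
    continuity correction).
    """
    if not studies:
        raise ValueError("no studies to pool")
    R = S = 0.0
    # Robins-Breslow-Greenland variance components
    sum_PR = sum_PSQR = sum_QS = 0.0
    for st in studies:
        a, b, c, d = (float(v) for v in st.table.cells)
        n = a + b + c + d
        Ri, Si = a * d / n, b * c / n
        P, Q = (a + d) / n, (b + c) / n
        R += Ri
        S += Si
        sum_PR += P * Ri
        sum_PSQR += P * Si + Q * Ri
        sum_QS += Q * Si
    if S == 0:
        raise CohortError("Mantel-Haenszel pooled OR undefined: no discordance")
    log_or = math.log(R / S)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    return _wald(log_or, var)


def heterogeneity(
    studies: Sequence[StudyRecord],
) -> tuple[float, float, float, float]:
    """Cochran's Q, its p-value, I^2 (percent) and DerSimonian–Laird tau^2."""
    effects = [study_effects(s) for s in studies]
    y = np.array([e[0] for e in effects])
    w = 1.0 / np.array([e[1] for e in effects])
    k = len(y)
    if k == 1:
        return 0.0, 1.0, 0.0, 0.0
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, q_p, i2, tau2


def pool_random_dl(
    studies: Sequence[StudyRecord], tau2: float | None = None
) -> PooledEffect:
    """DerSimonian–Laird random-effects pooled OR.

    Inverse-variance weights 1/(v_i + tau^2) on study log-ORs; when tau^2 is
    zero this reduces to the inverse-variance fixed-effect estimate.
    """
    if not studies:
        raise ValueError("no studies to pool")
    if tau2 is None:
        _, _, _, tau2 = heterogeneity(studies)
    effects = [study_effects(s) for s in studies]
    y = np.array([e[0] for e in effects])
    w = 1.0 / (np.array([e[1] for e in effects]) + tau2)
    log_pooled = float(np.sum(w * y) / np.sum(w))
    return _wald(log_pooled, 1.0 / float(np.sum(w)))


def select_model(q_p: float, i2: float) -> str:
    """Random effects iff q_p < 0.1 AND I^2 > 50%; fixed otherwise."""
    return "random" if (q_p < 0.1 and i2 > 50.0) else "fixed"


def meta_analyse(studies: Sequence[StudyRecord]) -> MetaResult:
    """Full meta-analysis of one allele's per-study carrier tables."""
    if not studies:
        raise ValueError("no studies to pool")
    effects = [study_effects(s) for s in studies]
    q, q_p, i2, tau2 = heterogeneity(studies)
    return MetaResult(
        k=len(studies),
        log_or=tuple(e[0] for e in effects),
        variance=tuple(e[1] for e in effects),
        fixed=pool_fixed_mh(studies),
        random=pool_random_dl(studies, tau2=tau2),
        q=q,
        q_p=q_p,
        i2=i2,
        tau2=tau2,
        model_selected=select_model(q_p, i2),
        het_p_flag=q_p < 0.1,
        het_i2_flag=i2 > 50.0,
    )


def forest_data(
    studies: Sequence[StudyRecord], meta: MetaResult
) -> pd.DataFrame:
    """Per-study rows plus pooled diamond, with percent weights.

    Weights are those of the selected model (MH weights b*c/n for fixed,
    1/(v + tau^2) for random), normalised to sum to 100.
    """
    rows = []
    if meta.model_selected == "random":
        weights = np.array(
            [1.0 / (v + meta.tau2) for v in meta.variance]
        )
    else:
        weights = np.array(
            [st.table.b * st.table.c / sum(st.table.cells) for st in studies],
            dtype=float,
        )
    weights = 100.0 * weights / weights.sum()
    for st, lo_or, var, wt in zip(studies, meta.log_or, meta.variance, weights):
        se = math.sqrt(var)
        rows.append({
            "study_id": st.study_id,
            "population": st.population,
            "or": math.exp(lo_or),
            "ci_low": math.exp(lo_or - Z_95 * se),
            "ci_high": math.exp(lo_or + Z_95 * se),
            "weight_pct": wt,
            "row": "study",
        })
    pooled = meta.selected
    rows.append({
        "study_id": f"pooled ({meta.model_selected})",
        "population": "",
        "or": pooled.or_point,
        "ci_low": pooled.ci_low,
        "ci_high": pooled.ci_high,
        "weight_pct": 100.0,
        "row": "pooled",
    })
    return pd.DataFrame(rows)


def read_studies(path) -> list[StudyRecord]:
    """Read a per-study carrier-count CSV (one row per study x allele)."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(
            f"{path}: missing column(s) {', '.join(sorted(missing))}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                population=str(row["population"]),
                drug=str(row["drug"]),
                allele=str(row["allele"]),
                table=CarrierTable(
                    a=int(row["case_carriers"]),
                    case_total=int(row["case_total"]),
                    c=int(row["control_carriers"]),
                    control_total=int(row["control_total"]),
                ),
            )
        )
    return records


def write_studies(studies: Sequence[StudyRecord], path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "population": s.population,
            "drug": s.drug,
            "allele": s.allele,
            "case_carriers": s.table.a,
            "case_total": s.table.case_total,
            "control_carriers": s.table.c,
            "control_total": s.table.control_total,
        }
        for s in studies
    ]
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)
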