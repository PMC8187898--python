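#!/usr/bin/env python
"""Meta-analysis machinery on simulated multi-population study tables.

The original per-study carrier counts behind the published forest plots are
not available as text, so this driver demonstrates the estimators on
simulated study sets shaped like them (10 studies, about 488 cases and 1277
controls in total) and reports calibration: pooled-OR recovery under a
common effect, Q/I2 behaviour with and without between-study variance, and
the heterogeneity-driven model choice. Writes results/meta_simulation.json
and a forest table for one simulated set.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np

from hlarisk import (
    MetaSimulationConfig,
    forest_data,
    heterogeneity,
    meta_analyse,
    pool_fixed_mh,
    simulate_meta_studies,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=300)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    # recovery of a common OR 1.54 across 10 studies
    pooled = []
    for _ in range(args.reps):
        studies = simulate_meta_studies(
            MetaSimulationConfig(
                k=10, mu=math.log(1.54), tau=0.0, control_carrier_freq=0.25,
                n_cases_per_study=49, n_controls_per_study=128,
                seed=int(rng.integers(2**31)),
            )
        )
        pooled.append(math.log(pool_fixed_mh(studies).or_point))
    recovered = math.exp(float(np.mean(pooled)))

    # Q calibration under homogeneity and sensitivity under tau = 1
    null_rej = het_flagged = 0
    for _ in range(args.reps):
        null = simulate_meta_studies(
            MetaSimulationConfig(
                k=8, mu=math.log(1.5), tau=0.0, control_carrier_freq=0.25,
                n_cases_per_study=150, n_controls_per_study=150,
                seed=int(rng.integers(2**31)),
            )
        )
        null_rej += heterogeneity(null)[1] < 0.1
        hetero = simulate_meta_studies(
            MetaSimulationConfig(
                k=8, mu=math.log(1.5), tau=1.0, control_carrier_freq=0.25,
                n_cases_per_study=150, n_controls_per_study=150,
                seed=int(rng.integers(2**31)),
            )
        )
        result = meta_analyse(hetero)
        het_flagged += result.model_selected == "random"

    # one fully worked simulated set with its forest table
    studies = simulate_meta_studies(
        MetaSimulationConfig(
            k=10, mu=math.log(1.54), tau=0.3, control_carrier_freq=0.25,
            n_cases_per_study=49, n_controls_per_study=128,
            seed=int(rng.integers(2**31)),
        )
    )
    example = meta_analyse(studies)
    forest_data(studies, example).to_csv(
        RESULTS / "forest_simulated.tsv", sep="\t", index=False
    )

    payload = {
        "seed": args.seed,
        "reps": args.reps,
        "common_or_recovery": {"planted": 1.54, "recovered": recovered},
        "q_null_rejection_rate_at_0.1": null_rej / args.reps,
        "random_model_selected_under_tau1": het_flagged / args.reps,
        "example_set": {
            "k": example.k,
            "fixed_or": example.fixed.or_point,
            "random_or": example.random.or_point,
            "q": example.q, "q_p": example.q_p,
            "i2": example.i2, "tau2": example.tau2,
            "model_selected": example.model_selected,
        },
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "meta_simulation.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print(
        f"common OR 1.54 recovered as {recovered:.3f} over {args.reps} "
        f"replicates\nQ false-positive rate at the 0.1 screening level: "
        f"{null_rej / args.reps:.3f}\nrandom model selected under strong "
        f"heterogeneity (tau=1): {het_flagged / args.reps:.2f} of runs\n"
        f"example set: I2 = {example.i2:.1f}%, model = "
        f"{example.model_selected}"
    )


if __name__ == "__main__":
    main()
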