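#!/usr/bin/env python
"""Parameter-recovery study for the segmentation generating model.

Simulates the forced-choice experiment at the default (published)
coefficients with 48 participants x 72 trials, refits the
random-intercept logit model, and records per-coefficient estimates and
95% CI coverage over replicates.  Writes the per-replicate estimates and
a coverage summary to results/recovery/.

Usage: python analysis/04_parameter_recovery.py [n_replicates]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from speakvar import (
    ModelSpec,
    SegmentationSimParams,
    assign_speakers,
    center_predictors,
    fit_mixed_model,
    simulate_segmentation_experiment,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"
SEED_BASE = 50_000

TRUTH = {
    "intercept": 0.343,
    "condition_code": 0.097,
    "novel_speaker": -0.439,
    "familiar_second": -0.258,
    "condition_code:novel_speaker": -0.093,
}
SPEC = ModelSpec(
    response="correct",
    family="binomial-logit",
    fixed_effects=(
        "condition_code",
        "novel_speaker",
        "familiar_second",
        "condition_code:novel_speaker",
    ),
)


def one_replicate(rep: int) -> list[dict]:
    rng = np.random.default_rng(SEED_BASE + rep)
    design = pd.concat(
        [
            assign_speakers("exp1", "single", rng=rng, n_participants=24),
            assign_speakers(
                "exp1", "multiple", rng=rng, n_participants=24, participant_offset=24
            ),
        ],
        ignore_index=True,
    )
    trials = simulate_segmentation_experiment(design, SegmentationSimParams(), rng)
    fit = fit_mixed_model(center_predictors(trials, SPEC.fixed_effects), SPEC)
    rows = []
    for term, truth in TRUTH.items():
        lo, hi = fit.ci95(term)
        rows.append(
            {
                "replicate": rep,
                "term": term,
                "true_beta": truth,
                "estimate": fit.beta(term),
                "se": fit.se(term),
                "covered": int(lo <= truth <= hi),
            }
        )
    return rows


def main() -> None:
    n_reps = int(sys.argv[1]) if len(sys.argv) > 1 else 100
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in range(n_reps):
        rows.extend(one_replicate(rep))
    estimates = pd.DataFrame(rows)
    estimates.to_csv(OUT / "estimates.csv", index=False)

    summary = (
        estimates.groupby("term")
        .agg(
            true_beta=("true_beta", "first"),
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            coverage=("covered", "mean"),
        )
        .reset_index()
    )
    summary.to_csv(OUT / "coverage.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
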