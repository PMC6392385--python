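#!/usr/bin/env python
"""Full ABC inference on the synthetic mtCOI dataset.

Simulates a reference table across the nine demographic scenarios, rejects
to the closest 1%, chooses the scenario by weighted polychotomous logistic
regression, estimates the winning scenario's parameters by local-linear
adjustment, converts the split times to years at 8 and 16 generations/year
and runs the posterior-predictive model check.  Table sizes here are
desk-scale (2,000 simulations per scenario, ~1 minute); the acceptance
script runs the larger calibration experiments.

Outputs under results/: scenario_posterior.tsv, parameters_scenario<k>.tsv,
divergence_years.tsv, model_check.tsv, run_log.txt.
"""

from pathlib import Path

from miteabc.cli_io import RunConfig, run_full_pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(
        fasta=str(BASE / "synthetic" / "sequences.fasta"),
        labels=str(BASE / "synthetic" / "labels.tsv"),
        output_dir=str(BASE),
        n_per_scenario=2000,
        tolerance=0.01,
        n_check_sims=300,
        seed=2019,
    )
    result = run_full_pipeline(cfg)

    print("scenario posterior probabilities (95% CI):")
    print(result.model_choice.table.round(4).to_string())
    best = result.model_choice.best_scenario
    print(f"\nbest scenario: {best} "
          f"(truth for this synthetic dataset: 2)")
    print(f"\nparameter posteriors for scenario {best}:")
    print(result.posterior.table.to_string(float_format=lambda v: f"{v:.4g}"))
    print("\nsplit times in years:")
    print(result.years.to_string(index=False))
    flagged = result.check.flagged
    print(f"\nmodel check: {len(flagged)}/33 statistics flagged at 0.05 "
          f"({', '.join(flagged) if flagged else 'none'}); "
          f"observed depth in PC cloud: {result.check.observed_depth:.2f}")


if __name__ == "__main__":
    main()
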