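#!/usr/bin/env python
"""Calibration experiments behind the headline claims, at reduced size.

1. Neutral single-deme check: mean pairwise differences against 2*N*mu*L
   and mean Tajima's D against 0.
2. Scenario recovery: how often pseudo-observed data simulated under
   scenario 2 at the posterior-median preset is assigned back to scenario 2
   (reduced: 2,000 simulations/scenario, 10 replicates; the acceptance
   script runs 10^4 x 20).
3. Morph-label recovery across 25 generator seeds.

Writes results/calibration.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from miteabc import abc as A
from miteabc import sumstats
from miteabc.abc import SampleConfig
from miteabc.coalsim import MutationModel, evolve_matrix, simulate_genealogy
from miteabc.morphotype import cluster_forms, population_scores
from miteabc.scenarios import PriorSet, ScenarioSpec
from miteabc.synthetic_data import MorphShape, StudyShape, make_morph_dataset, make_sequence_dataset

BASE = Path(__file__).resolve().parent.parent / "results"


def neutral_check(rows: list, rng) -> None:
    n_hap, mu, L, reps = 20_000.0, 2.5e-8, 618, 300
    spec = ScenarioSpec(9, (), {"ML": n_hap})
    model = MutationModel(mu=mu, kappa=2.0, length=L)
    pis, ds = [], []
    for _ in range(reps):
        tree = simulate_genealogy(spec, {"ML": 10}, rng)
        m = evolve_matrix(tree, model, rng)
        pis.append(sumstats.pairwise_diff_moments(m)[0])
        ds.append(sumstats.tajimas_d(m))
    rows.append(("neutral_pi_over_2NmuL", np.mean(pis) / (2 * n_hap * mu * L), reps))
    rows.append(("neutral_tajimas_d_mean", np.mean(ds), reps))
    print(f"neutral calibration: pi/(2NmuL) = {rows[-2][1]:.3f}, "
          f"mean D = {rows[-1][1]:+.3f} over {reps} replicates")


def recovery_check(rows: list) -> None:
    table = A.build_reference_table(range(1, 10), PriorSet(), 2000, SampleConfig(), seed=7)
    wins, p2 = 0, []
    reps = 10
    for rep in range(reps):
        aln, _ = make_sequence_dataset(StudyShape(seed=500 + rep))
        obs = sumstats.summarize(aln).to_numpy()
        choice = A.choose_model(A.reject(table, obs, 0.01))
        wins += choice.best_scenario == 2
        p2.append(float(choice.table.loc[2, "prob"]))
    rows.append(("scenario2_recovery_fraction", wins / reps, reps))
    rows.append(("scenario2_posterior_mean", np.mean(p2), reps))
    print(f"scenario recovery (reduced): {wins}/{reps} wins, "
          f"mean p(scenario 2) = {np.mean(p2):.3f}")


def morph_check(rows: list) -> None:
    rates = []
    for seed in range(25):
        table, truth = make_morph_dataset(MorphShape(seed=seed))
        fa = cluster_forms(population_scores(table))
        rates.append((fa.assignments["form"] == truth.reindex(fa.assignments.index)).mean())
    rows.append(("morph_recovery_mean", float(np.mean(rates)), 25))
    print(f"morph label recovery: {np.mean(rates):.1%} mean over 25 seeds")


def main() -> None:
    rng = np.random.default_rng(11)
    rows: list = []
    neutral_check(rows, rng)
    recovery_check(rows)
    morph_check(rows)
    BASE.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value", "n"]).to_csv(
        BASE / "calibration.tsv", sep="\t", index=False
    )
    print(f"wrote {BASE / 'calibration.tsv'}")


if __name__ == "__main__":
    main()
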