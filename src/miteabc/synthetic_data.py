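"""Study-shaped synthetic datasets for every stage of the pipeline.

Two generators, each with a recorded "truth" so recovery experiments can be
replayed bit-for-bit:

* :func:`make_sequence_dataset` -- one coalescent + HKY simulation shaped
  like the mtCOI data (41 haploid 618-bp sequences split 10 LW / 13 ML /
  18 HG), by default under the hierarchical-split scenario 2 at the
  posterior-median parameter preset inferred for this system (clearly a
  posterior anchor, not ground truth);
* :func:`make_morph_dataset` -- a male leg-measurement table whose
  log leg-I/leg-III ratios form three overlapping unimodal distributions,
  one per form, resembling the observed weapon-morph histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abc import SampleConfig
from .coalsim import LabeledAlignment, MutationModel, evolve_matrix, simulate_genealogy
from .morphotype import LEG1_COLUMNS, LEG3_COLUMNS
from .scenarios import PARAM_NAMES, ParameterDraw, build_scenario

#: posterior-median parameter preset for scenario 2 (haploid N in
#: individuals, times in generations, mu per site per generation)
PAPER_LIKE_PARAMS = {
    "N_LW": 97_500.0,
    "N_ML": 419_000.0,
    "N_HG": 180_000.0,
    "t1": 87_900.0,
    "t2": 320_000.0,
    "r": 0.5,
    "mu": 8.70e-8,
    "kappa": 1.67,
}


@dataclass
class StudyShape:
    """Shape and truth of a synthetic sequence dataset."""

    n_lw: int = 10
    n_ml: int = 13
    n_hg: int = 18
    length: int = 618
    scenario_id: int = 2
    params: dict = field(default_factory=lambda: dict(PAPER_LIKE_PARAMS))
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lw, self.n_ml, self.n_hg) < 1 or self.length < 1:
            raise ValueError("sample counts and length must be positive")

    @property
    def sample_sizes(self) -> dict[str, int]:
        return {"LW": self.n_lw, "ML": self.n_ml, "HG": self.n_hg}

    def sample_config(self) -> SampleConfig:
        return SampleConfig(sample_sizes=self.sample_sizes, length=self.length,
                            freqs=self.freqs)


def make_sequence_dataset(shape: StudyShape | None = None) -> tuple[LabeledAlignment, dict]:
    """Simulate one study-shaped alignment; returns it with a truth record
    (scenario, parameters, seed) sufficient to regenerate it."""
    shape = shape or StudyShape()
    rng = np.random.default_rng(shape.seed)
    draw = ParameterDraw(shape.scenario_id, {p: float(shape.params[p]) for p in PARAM_NAMES})
    spec = build_scenario(shape.scenario_id, draw)
    tree = simulate_genealogy(spec, shape.sample_sizes, rng)
    model = MutationModel(mu=draw.mu, kappa=draw.kappa, freqs=shape.freqs,
                          length=shape.length)
    matrix = evolve_matrix(tree, model, rng)
    forms = [f for f, n in shape.sample_sizes.items() for _ in range(n)]
    counters: dict[str, int] = {}
    ids = []
    for f in forms:
        counters[f] = counters.get(f, 0) + 1
        ids.append(f"{f}{counters[f]:02d}")
    aln = LabeledAlignment.from_matrix(matrix, ids, forms)
    truth = {
        "scenario_id": shape.scenario_id,
        "params": {p: float(shape.params[p]) for p in PARAM_NAMES},
        "sample_sizes": shape.sample_sizes,
        "length": shape.length,
        "freqs": list(shape.freqs),
        "seed": shape.seed,
    }
    return aln, truth


def write_sequence_dataset(aln: LabeledAlignment, truth: dict, outdir) -> dict[str, Path]:
    """Write FASTA (+ population|form headers), label map and truth file."""
    from . import cli_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.yaml",
    }
    cli_io.write_fasta(aln, paths["fasta"])
    cli_io.write_label_map(aln, paths["labels"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths


@dataclass
class MorphShape:
    """Shape and truth of a synthetic male leg-measurement table.

    Log leg-ratio means/SDs per form emulate the observed histogram: form
    means roughly 0.205 (LW), 0.245 (ML) and 0.300 (HG) on the natural-log
    scale with overlap between neighbouring forms at the individual level.
    """

    n_pops: dict = field(default_factory=lambda: {"LW": 11, "ML": 13, "HG": 18})
    form_means: dict = field(default_factory=lambda: {"LW": 0.205, "ML": 0.245, "HG": 0.300})
    between_sd: float = 0.008  # among population means, within a form
    within_sd: float = 0.020  # among individuals, within a population
    individuals: tuple = (8, 22)  # observed per-population range
    leg3_baseline: tuple = (55.0, 35.0, 30.0, 75.0)  # tibia/tarsus/genu/femur, um
    size_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be nonnegative")


def make_morph_dataset(shape: MorphShape | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a per-individual leg-measurement table plus the true form
    of each population.

    Leg III segments are drawn around a baseline with an individual body
    size factor; leg I segments are scaled so that each individual's log
    leg ratio is normal with its population's mean and the within-population
    SD, with segment-level jitter that preserves the leg totals.
    """
    shape = shape or MorphShape()
    rng = np.random.default_rng(shape.seed)
    lo, hi = shape.individuals
    rows = []
    truth = {}
    for form, n_pops in shape.n_pops.items():
        for p in range(1, n_pops + 1):
            pop = f"{form}{p:02d}"
            truth[pop] = form
            pop_mean = rng.normal(shape.form_means[form], shape.between_sd)
            n_ind = int(rng.integers(lo, hi + 1))
            for _ in range(n_ind):
                size = max(rng.normal(1.0, shape.size_cv), 0.5)
                leg3 = np.array(shape.leg3_baseline) * size
                jitter = rng.normal(1.0, 0.03, size=4)
                leg3 = leg3 * jitter * leg3.sum() / (leg3 * jitter).sum()
                log_ratio = rng.normal(pop_mean, shape.within_sd)
                target1 = leg3.sum() * np.exp(log_ratio)
                share = np.array(shape.leg3_baseline) * rng.normal(1.0, 0.03, size=4)
                leg1 = share / share.sum() * target1
                rows.append(
                    {"population": pop, "region": form,
                     **dict(zip(LEG1_COLUMNS, leg1)),
                     **dict(zip(LEG3_COLUMNS, leg3))}
                )
    table = pd.DataFrame(rows)
    return table, pd.Series(truth, name="form")


def write_morph_dataset(table: pd.DataFrame, truth: pd.Series, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"morph": outdir / "morph.tsv", "truth": outdir / "morph_truth.yaml"}
    table.to_csv(paths["morph"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)
    return paths
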