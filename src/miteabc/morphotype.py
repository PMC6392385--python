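"""Male weapon-morph ratios and classification into the three forms.

Males fight with their enlarged first pair of legs, so the ratio of leg I to
leg III length (each the sum of tibia + tarsus + genu + femur) is a proxy
for male-male aggressiveness.  Per-individual ratios are log-transformed and
averaged per population; populations are then grouped by hierarchical
clustering (Euclidean distance, Ward linkage) cut at three clusters, which
are labelled HG (largest mean score), LW (smallest) and ML (intermediate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

SEGMENTS = ("tibia", "tarsus", "genu", "femur")
LEG1_COLUMNS = tuple(f"leg1_{s}" for s in SEGMENTS)
LEG3_COLUMNS = tuple(f"leg3_{s}" for s in SEGMENTS)
MORPH_COLUMNS = ("population",) + LEG1_COLUMNS + LEG3_COLUMNS


def leg_ratio(record) -> float:
    """Leg I / leg III ratio of one individual from its 8 segment lengths."""
    leg1 = sum(float(record[c]) for c in LEG1_COLUMNS)
    leg3 = sum(float(record[c]) for c in LEG3_COLUMNS)
    for c in LEG1_COLUMNS + LEG3_COLUMNS:
        if float(record[c]) <= 0:
            raise ValueError(f"nonpositive segment length in {c}")
    return leg1 / leg3


def population_score(records: pd.DataFrame) -> float:
    """Population mean of the natural-log leg ratio over its individuals."""
    if len(records) == 0:
        raise ValueError("population has no individuals")
    return float(np.mean([math.log(leg_ratio(row)) for _, row in records.iterrows()]))


def population_scores(table: pd.DataFrame) -> pd.Series:
    """Per-population scores from a one-row-per-individual morph table."""
    return table.groupby("population", sort=False).apply(
        population_score, include_groups=False
    )


@dataclass
class FormAssignment:
    """Population -> cluster -> form mapping with the merge history."""

    assignments: pd.DataFrame  # index population; cluster, form, margin
    linkage_matrix: np.ndarray
    populations: list[str]

    def form_of(self, population: str) -> str:
        return str(self.assignments.loc[population, "form"])

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as depths."""
        Z = self.linkage_matrix
        n = len(self.populations)
        height = {i: 0.0 for i in range(n)}

        def build(node: int) -> str:
            if node < n:
                return self.populations[node]
            a, b, h, _ = Z[node - n]
            parts = []
            for child in (int(a), int(b)):
                child_h = 0.0 if child < n else Z[child - n][2]
                parts.append(f"{build(child)}:{h - child_h:.6g}")
            return "(" + ",".join(parts) + ")"

        return build(2 * n - 2) + ";"


def cluster_forms(
    scores: pd.Series,
    variant: str = "D2",
    overrides: dict[str, str] | None = None,
) -> FormAssignment:
    """Ward clustering of scalar population scores into the three forms.

    ``variant`` selects the Ward criterion: "D2" (squared-Euclidean
    increase in within-cluster variance; the default) or "D" (the classical
    update applied to squared distances).  On scalar scores cut at three
    clusters the two almost always agree.  ``overrides`` maps population ids
    to forced form labels (e.g. a borderline population reassigned on
    phylogenetic evidence); overrides are applied after clustering and
    recorded in the output.
    """
    if len(scores) < 3:
        raise ValueError("need at least three populations to identify three forms")
    pops = list(scores.index)
    x = scores.to_numpy(dtype=float)[:, None]
    if variant == "D2":
        Z = linkage(x, method="ward")
    elif variant == "D":
        Z = linkage(pdist(x) ** 2, method="ward")
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    clusters = fcluster(Z, t=3, criterion="maxclust")

    means = {c: x[clusters == c, 0].mean() for c in np.unique(clusters)}
    order = sorted(means, key=means.get)
    label_of = dict(zip(order, ["LW", "ML", "HG"][: len(order)]))
    forms = [label_of[c] for c in clusters]

    # borderline diagnostic: distance margin to the nearest other cluster
    centroid = {c: means[c] for c in means}
    margin = []
    for xi, ci in zip(x[:, 0], clusters):
        own = abs(xi - centroid[ci])
        other = min(abs(xi - centroid[c]) for c in centroid if c != ci)
        margin.append(other - own)

    df = pd.DataFrame(
        {"score": x[:, 0], "cluster": clusters, "form": forms, "margin": margin},
        index=pd.Index(pops, name="population"),
    )
    df["overridden"] = False
    if overrides:
        for pop, form in overrides.items():
            df.loc[pop, ["form", "overridden"]] = [form, True]
    return FormAssignment(df, Z, pops)
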