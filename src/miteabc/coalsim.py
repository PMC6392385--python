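"""Structured-coalescent genealogies and HKY sequence evolution.

The generative engine behind the ABC reference table: a continuous-time
(Kingman) structured coalescent over the three form demes driven by a
:class:`~miteabc.scenarios.ScenarioSpec`, followed by simulation of haploid
mtCOI-like sequences down the genealogy under the Hasegawa-Kishino-Yano
substitution model.

Within a deme of haploid size N, k lineages coalesce at rate k(k-1)/(2N) per
generation.  Split events move every lineage of the source deme into the
target; admixture events reassign each lineage independently.  Sites evolve
independently using the exact HKY transition-probability matrix for each
branch (obtained by spectral decomposition of the rate matrix), which is
distributionally identical to event-by-event simulation but much faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .scenarios import Admixture, ScenarioSpec, Split

BASES = "ACGT"
#: base -> integer code used in alignment matrices; anything else is -1
BASE_CODES = {b: i for i, b in enumerate(BASES)}

_TRANSITION_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


class CoalescenceError(RuntimeError):
    """The event list ended with lineages stranded in more than one deme."""


@dataclass
class Genealogy:
    """A rooted binary coalescent tree over haploid samples.

    Nodes ``0..n_tips-1`` are tips at time 0; internal nodes are appended in
    coalescence order, so node times are nondecreasing with index and the
    last node is the root.  Branch lengths are in generations.
    """

    parent: np.ndarray  # int64, parent index per node; -1 at the root
    time: np.ndarray  # float64, node time in generations (tips at 0)
    tip_deme: list[str]  # deme of origin per tip

    @property
    def n_tips(self) -> int:
        return len(self.tip_deme)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @cached_property
    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                kids[par].append(node)
        return kids

    def total_branch_length(self) -> float:
        internal = self.parent >= 0
        return float(np.sum(self.time[self.parent[internal]] - self.time[internal]))

    def newick(self, labels: list[str] | None = None) -> str:
        """Newick string with branch lengths in generations."""
        if labels is None:
            labels = [f"{d}_{i}" for i, d in enumerate(self.tip_deme)]

        def fmt(node: int) -> str:
            if node < self.n_tips:
                body = labels[node]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            par = self.parent[node]
            if par < 0:
                return body
            return f"{body}:{self.time[par] - self.time[node]:.6g}"

        return fmt(self.root) + ";"


def simulate_genealogy(
    spec: ScenarioSpec,
    sample_sizes: dict[str, int],
    rng: np.random.Generator,
    return_history: bool = False,
) -> Genealogy | tuple[Genealogy, list[tuple[float, dict[str, int]]]]:
    """Simulate one genealogy for the given scenario.

    Parameters
    ----------
    spec
        Demographic model (event list plus deme sizes).
    sample_sizes
        Number of haploid samples per deme; demes absent from the mapping are
        unsampled.  Tip order is deme-blocked, following the mapping order.
    rng
        numpy Generator.
    return_history
        Also return the per-deme lineage counts recorded immediately after
        each demographic event (diagnostic; used to verify event semantics).
    """
    for deme, n in sample_sizes.items():
        if n < 1:
            raise ValueError(f"sample size for {deme} must be positive, got {n}")
        if deme not in spec.deme_sizes:
            raise ValueError(f"sampled deme {deme!r} unknown to the scenario")

    tip_deme = [d for d, n in sample_sizes.items() for _ in range(n)]
    n_tips = len(tip_deme)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    next_node = n_tips

    # active lineages per deme (python lists; n is small)
    active: dict[str, list[int]] = {d: [] for d in spec.deme_sizes}
    tip = 0
    for d, n in sample_sizes.items():
        for _ in range(n):
            active[d].append(tip)
            tip += 1

    history: list[tuple[float, dict[str, int]]] = []
    t = 0.0
    uniform = rng.random
    exponential = rng.exponential

    def coalesce_until(t_stop: float) -> None:
        nonlocal t, next_node
        while True:
            demes = [d for d, lin in active.items() if len(lin) >= 2]
            if not demes:
                t = t_stop if t_stop != np.inf else t
                return
            rates = [
                len(active[d]) * (len(active[d]) - 1) / (2.0 * spec.deme_sizes[d])
                for d in demes
            ]
            total = sum(rates)
            dt = exponential(1.0 / total)
            if t + dt >= t_stop:
                t = t_stop
                return
            t += dt
            if len(demes) == 1:
                d = demes[0]
            else:
                x = uniform() * total
                for d, r in zip(demes, rates):
                    x -= r
                    if x <= 0:
                        break
            lin = active[d]
            i = int(uniform() * len(lin))
            a = lin.pop(i)
            j = int(uniform() * len(lin))
            b = lin.pop(j)
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            lin.append(next_node)
            next_node += 1

    for ev in spec.events:
        coalesce_until(ev.time)
        if isinstance(ev, Split):
            active[ev.dest].extend(active[ev.source])
            active[ev.source] = []
        elif isinstance(ev, Admixture):
            movers = active[ev.source]
            active[ev.source] = []
            for node in movers:
                if uniform() < ev.prob:
                    active[ev.dest].append(node)
                else:
                    active[ev.alt].append(node)
        if return_history:
            history.append((ev.time, {d: len(l) for d, l in active.items()}))

    occupied = [d for d, lin in active.items() if lin]
    if len(occupied) > 1:
        raise CoalescenceError(
            f"lineages stranded in demes {occupied} with no further events"
        )
    coalesce_until(np.inf)

    tree = Genealogy(parent=parent, time=node_time, tip_deme=tip_deme)
    return (tree, history) if return_history else tree


@dataclass(frozen=True)
class MutationModel:
    """HKY substitution model scaled to ``mu`` substitutions/site/generation.

    ``kappa`` is the transition/transversion coefficient (the C/T vs other
    exchange coefficient of the HKY parameterisation); ``freqs`` are the
    stationary base frequencies in A, C, G, T order.
    """

    mu: float
    kappa: float
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length: int = 618

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must be 4 nonnegative values summing to 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")

    def rate_matrix(self) -> np.ndarray:
        """HKY rate matrix normalised to one expected substitution per unit
        of ``mu * t``."""
        pi = np.asarray(self.freqs)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = pi[j] * (self.kappa if _TRANSITION_PARTNER[i] == j else 1.0)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -np.dot(pi, np.diag(q))
        if mean_rate > 0:
            q /= mean_rate
        return q

    @cached_property
    def _spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible Q: symmetrise with diag(sqrt(pi)) and eigendecompose
        pi = np.asarray(self.freqs)
        pos = pi > 0
        sqrt_pi = np.sqrt(np.where(pos, pi, 1.0))
        q = self.rate_matrix()
        sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u.T * sqrt_pi[None, :]
        right = u / sqrt_pi[:, None]
        return lam, right, left

    def transition_matrix(self, t_generations: float) -> np.ndarray:
        """Exact P(t) = exp(Q * mu * t); rows index the parent base."""
        lam, right, left = self._spectral
        p = (right * np.exp(lam * self.mu * t_generations)) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@dataclass
class LabeledAlignment:
    """Aligned haploid sequences with population ids and form labels.

    ``sequences`` are uppercase strings of equal length; ``forms`` gives the
    aggression-form group (LW/ML/HG) per row.  ``matrix`` is the integer
    encoding (A,C,G,T -> 0..3; gaps and IUPAC ambiguity -> -1) used by the
    summary statistics.
    """

    ids: list[str]
    forms: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.forms) == len(self.sequences)):
            raise ValueError("ids, forms and sequences must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @cached_property
    def matrix(self) -> np.ndarray:
        out = np.full((self.n_rows, self.n_sites), -1, dtype=np.int8)
        table = np.full(256, -1, dtype=np.int8)
        for b, code in BASE_CODES.items():
            table[ord(b)] = code
        for i, s in enumerate(self.sequences):
            out[i] = table[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        return out

    def form_indices(self, form: str) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.forms) if f == form], dtype=np.intp)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, ids: list[str], forms: list[str]
    ) -> "LabeledAlignment":
        lookup = np.array(list(BASES + "N"))
        seqs = ["".join(lookup[np.where(row >= 0, row, 4)]) for row in matrix]
        aln = cls(ids=list(ids), forms=list(forms), sequences=seqs)
        aln.__dict__["matrix"] = np.asarray(matrix, dtype=np.int8)
        return aln

    def empirical_freqs(self) -> np.ndarray:
        """Base frequencies over unambiguous sites (A, C, G, T order)."""
        m = self.matrix
        counts = np.array([(m == b).sum() for b in range(4)], dtype=float)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total


def evolve_matrix(
    tree: Genealogy, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Simulate sequences down the tree; returns the tip matrix (int8 codes).

    Sites are iid, so each branch is simulated exactly by (1) drawing the
    number of sites that change state with the branch's per-parent-base
    change probability, (2) placing those changes uniformly among the
    eligible sites and (3) drawing new states from the conditional HKY
    transition row.  Equivalent to per-site sampling from P(t) but much
    faster when substitutions are sparse.
    """
    n_nodes = tree.n_nodes
    L = model.length
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    root = tree.root
    seqs[root] = rng.choice(4, size=L, p=np.asarray(model.freqs))
    if model.mu == 0.0:
        for node in range(n_nodes - 2, -1, -1):
            seqs[node] = seqs[tree.parent[node]]
        return seqs[: tree.n_tips].copy()
    # all branch transition matrices in one spectral evaluation
    lam, right, left = model._spectral
    nodes = np.arange(n_nodes - 1)
    blen = tree.time[tree.parent[nodes]] - tree.time[nodes]
    expterm = np.exp(np.outer(blen, lam) * model.mu)  # (B, 4)
    pmats = np.einsum("ij,bj,jk->bik", right, expterm, left)
    np.clip(pmats, 0.0, None, out=pmats)
    pmats /= pmats.sum(axis=2, keepdims=True)
    diag = np.diagonal(pmats, axis1=1, axis2=2)  # (B, 4) stay-probabilities
    p_change = np.clip(1.0 - diag, 0.0, 1.0)
    cond = pmats.copy()
    for s in range(4):
        cond[:, s, s] = 0.0
    denom = cond.sum(axis=2, keepdims=True)
    cond /= np.where(denom > 0, denom, 1.0)
    cumcond = np.cumsum(cond, axis=2)

    random = rng.random
    # internal nodes are numbered in coalescence (time) order, so descending
    # index visits every parent before its children
    for node in range(n_nodes - 2, -1, -1):
        parent_seq = seqs[tree.parent[node]]
        seqs[node] = parent_seq
        u = random(L)
        changed = np.flatnonzero(u < p_change[node][parent_seq])
        if changed.size:
            ps = parent_seq[changed]
            u2 = random(changed.size)
            seqs[node, changed] = (u2[:, None] > cumcond[node][ps]).sum(axis=1)
    return seqs[: tree.n_tips].copy()


def evolve_sequences(
    tree: Genealogy,
    model: MutationModel,
    rng: np.random.Generator,
    ids: list[str] | None = None,
) -> LabeledAlignment:
    """Simulate an alignment down ``tree`` under the HKY model."""
    tips = evolve_matrix(tree, model, rng)
    if ids is None:
        counters: dict[str, int] = {}
        ids = []
        for d in tree.tip_deme:
            counters[d] = counters.get(d, 0) + 1
            ids.append(f"{d}{counters[d]:02d}")
    return LabeledAlignment.from_matrix(tips, ids, list(tree.tip_deme))
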