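"""Population-genetic summary statistics for labeled alignments.

The DIYABC-style battery used by the ABC engine: per form group (LW, ML, HG)
the number of haplotypes, number of segregating sites, mean and variance of
pairwise differences, Tajima's D, number of private segregating sites and
mean count of the rarest nucleotide at segregating sites; per form-group
pair the same first three statistics on the pooled rows plus the
Hudson-Slatkin-Maddison F_ST.  33 statistics in a fixed canonical order.

Missing data policy (real sequences only; simulated data are complete):
pairwise differences are counted over sites where both rows carry an
unambiguous base, and a site's segregation/informativeness is judged on
unambiguous states only.  Degenerate cases (no segregating sites, zero
between-group diversity) return 0 rather than NaN so reference-table rows
are always complete.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd

from .coalsim import LabeledAlignment

FORM_ORDER = ("LW", "ML", "HG")
FORM_PAIRS = tuple(itertools.combinations(FORM_ORDER, 2))

_ONE_SAMPLE = ("nhap", "nseg", "pi_mean", "pi_var", "tajimas_d", "private_seg", "rarest_mean")
_TWO_SAMPLE = ("nhap", "nseg", "pi_mean", "fst")

#: canonical names of the 33 summary statistics, in output order
STAT_NAMES = tuple(
    [f"{f}_{s}" for f in FORM_ORDER for s in _ONE_SAMPLE]
    + [f"{a}_{b}_{s}" for a, b in FORM_PAIRS for s in _TWO_SAMPLE]
)


def _as_matrix(subset) -> np.ndarray:
    m = np.asarray(subset, dtype=np.int8)
    if m.ndim != 2:
        raise ValueError("expected a 2-D alignment matrix")
    return m


def _base_counts(m: np.ndarray) -> np.ndarray:
    """(4, L) counts of unambiguous bases per column."""
    return np.stack([(m == b).sum(axis=0) for b in range(4)])


def n_haplotypes(subset) -> int:
    """Number of distinct row strings."""
    m = _as_matrix(subset)
    if m.shape[0] < 1:
        raise ValueError("n_haplotypes requires at least one row")
    return len({row.tobytes() for row in m})


def segregating_sites(subset) -> int:
    """Number of columns with >= 2 distinct unambiguous states."""
    m = _as_matrix(subset)
    if m.shape[0] < 2:
        raise ValueError("segregating_sites requires at least two rows")
    return int(((_base_counts(m) > 0).sum(axis=0) >= 2).sum())


def pairwise_diff_matrix(m: np.ndarray) -> np.ndarray:
    """(n, n) matrix of per-pair difference counts over mutually valid sites.

    Computed as (both-valid sites) - (matching sites), each via one-hot
    matrix products, which is exact and fast for alignment-sized inputs.
    """
    valid = (m >= 0).astype(np.float32)
    match = np.zeros((m.shape[0], m.shape[0]), dtype=np.float32)
    for b in range(4):
        onehot = (m == b).astype(np.float32)
        match += onehot @ onehot.T
    d = valid @ valid.T - match
    np.fill_diagonal(d, 0.0)
    return np.rint(d).astype(np.int64)


def _pair_moments(d: np.ndarray) -> tuple[float, float]:
    """Mean and population variance over the n(n-1)/2 unordered pairs of a
    symmetric zero-diagonal difference-count matrix."""
    n = d.shape[0]
    if n < 2:
        return 0.0, 0.0
    npairs2 = n * (n - 1)  # ordered pairs = 2 * unordered
    df = d.astype(float)
    mean = float(df.sum() / npairs2)
    var = float((df * df).sum() / npairs2 - mean * mean)
    return mean, max(var, 0.0)


def pairwise_diff_moments(subset) -> tuple[float, float]:
    """Mean and population variance of pairwise difference counts."""
    m = _as_matrix(subset)
    if m.shape[0] < 2:
        raise ValueError("pairwise_diff_moments requires at least two rows")
    return _pair_moments(pairwise_diff_matrix(m))


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(subset) -> float:
    """Tajima's D; 0 by convention when there are no segregating sites."""
    m = _as_matrix(subset)
    n = m.shape[0]
    if n < 2:
        raise ValueError("tajimas_d requires at least two rows")
    s = segregating_sites(m)
    if s == 0:
        return 0.0
    pi = pairwise_diff_moments(m)[0]
    a1 = np.sum(1.0 / np.arange(1, n))
    e1, e2 = _tajima_constants(n)
    denom = e1 * s + e2 * s * (s - 1)
    if denom <= 0:  # n=2: numerator and variance both vanish
        return 0.0
    return float((pi - s / a1) / np.sqrt(denom))


def private_segregating_sites(focal, others) -> int:
    """Sites segregating within the focal group and monomorphic in the
    union of all other groups."""
    mf = _as_matrix(focal)
    mo = _as_matrix(others)
    if mf.shape[1] != mo.shape[1]:
        raise ValueError("focal and other groups must share the alignment columns")
    seg_focal = (_base_counts(mf) > 0).sum(axis=0) >= 2
    mono_other = (_base_counts(mo) > 0).sum(axis=0) <= 1
    return int((seg_focal & mono_other).sum())


def mean_rarest_nucleotide_count(subset) -> float:
    """Mean count of the least-frequent observed base over segregating
    sites; 0 when no site segregates."""
    m = _as_matrix(subset)
    counts = _base_counts(m)
    seg = (counts > 0).sum(axis=0) >= 2
    if not seg.any():
        return 0.0
    c = counts[:, seg].astype(float)
    c[c == 0] = np.inf
    return float(c.min(axis=0).mean())


def fst_hsm(group_a, group_b) -> float:
    """Hudson-Slatkin-Maddison F_ST = 1 - Hw/Hb.

    Hw averages the two within-group mean pairwise differences; Hb is the
    mean pairwise difference between groups.  Returns 0 when Hb = 0;
    negative values are retained.
    """
    ma, mb = _as_matrix(group_a), _as_matrix(group_b)
    if ma.shape[0] < 2 or mb.shape[0] < 2:
        raise ValueError("fst_hsm requires at least two rows per group")
    hw = (_pair_moments(pairwise_diff_matrix(ma))[0] + _pair_moments(pairwise_diff_matrix(mb))[0]) / 2.0
    both = pairwise_diff_matrix(np.vstack([ma, mb]))
    hb = float(both[: len(ma), len(ma):].mean())
    if hb == 0.0:
        return 0.0
    return float(1.0 - hw / hb)


def pooled_pair_stats(group_a, group_b) -> tuple[int, int, float]:
    """(haplotypes, segregating sites, mean pairwise differences) on the
    union of the two groups' rows."""
    ma, mb = _as_matrix(group_a), _as_matrix(group_b)
    union = np.vstack([ma, mb])
    return (
        n_haplotypes(union),
        segregating_sites(union),
        pairwise_diff_moments(union)[0],
    )


def parsimony_informative_sites(alignment) -> int:
    """Columns with >= 2 unambiguous states each carried by >= 2 rows."""
    m = alignment.matrix if isinstance(alignment, LabeledAlignment) else _as_matrix(alignment)
    if m.shape[0] < 4:
        raise ValueError("parsimony informativeness needs at least four rows")
    return int(((_base_counts(m) >= 2).sum(axis=0) >= 2).sum())


def summarize_matrix(m: np.ndarray, groups: dict[str, np.ndarray]) -> np.ndarray:
    """Fast path: the 33-statistic vector from an int8 matrix and per-form
    row-index arrays.  Order follows :data:`STAT_NAMES`."""
    d_all = pairwise_diff_matrix(m)
    counts = {f: _base_counts(m[idx]) for f, idx in groups.items()}
    hapsets = {f: {row.tobytes() for row in m[idx]} for f, idx in groups.items()}
    out: list[float] = []
    for f in FORM_ORDER:
        idx = groups[f]
        sub = m[idx]
        n = len(idx)
        c = counts[f]
        seg_mask = (c > 0).sum(axis=0) >= 2
        s = int(seg_mask.sum())
        block = d_all[np.ix_(idx, idx)]
        if n >= 2:
            pi_mean, pi_var = _pair_moments(block)
        else:
            pi_mean = pi_var = 0.0
        if s == 0 or n < 2:
            d_taj = 0.0
        else:
            a1 = np.sum(1.0 / np.arange(1, n))
            e1, e2 = _tajima_constants(n)
            denom = e1 * s + e2 * s * (s - 1)
            d_taj = 0.0 if denom <= 0 else float((pi_mean - s / a1) / np.sqrt(denom))
        others = sum(counts[g] for g in FORM_ORDER if g != f)
        mono_other = (others > 0).sum(axis=0) <= 1
        private = int((seg_mask & mono_other).sum())
        if s == 0:
            rarest = 0.0
        else:
            cc = c[:, seg_mask].astype(float)
            cc[cc == 0] = np.inf
            rarest = float(cc.min(axis=0).mean())
        out += [len(hapsets[f]), s, pi_mean, pi_var, d_taj, private, rarest]
    for a, b in FORM_PAIRS:
        ia, ib = groups[a], groups[b]
        pooled_counts = counts[a] + counts[b]
        s = int(((pooled_counts > 0).sum(axis=0) >= 2).sum())
        nhap = len({m[i].tobytes() for i in np.concatenate([ia, ib])})
        both = np.concatenate([ia, ib])
        pi_mean = _pair_moments(d_all[np.ix_(both, both)])[0]
        hw = (
            _pair_moments(d_all[np.ix_(ia, ia)])[0] + _pair_moments(d_all[np.ix_(ib, ib)])[0]
        ) / 2.0
        hb = float(d_all[np.ix_(ia, ib)].mean())
        fst = 0.0 if hb == 0.0 else float(1.0 - hw / hb)
        out += [nhap, s, pi_mean, fst]
    return np.array(out)


def summarize(aln: LabeledAlignment) -> pd.Series:
    """The canonical 33-statistic vector of a labeled alignment."""
    groups = {f: aln.form_indices(f) for f in FORM_ORDER}
    for f, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"form group {f} is empty")
    return pd.Series(summarize_matrix(aln.matrix, groups), index=list(STAT_NAMES))
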