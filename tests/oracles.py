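"""Independent brute-force implementations of the summary statistics.

Deliberately naive (per-column and per-pair python loops) so they share no
code with the package; used as oracles on random alignments.  Matrices are
int8 with codes 0..3 for A,C,G,T and -1 for gap/ambiguous.
"""

import itertools
import math

import numpy as np


def bf_n_haplotypes(m):
    seen = []
    for row in m:
        key = tuple(row)
        if key not in seen:
            seen.append(key)
    return len(seen)


def bf_segregating_sites(m):
    count = 0
    for col in np.asarray(m).T:
        states = {int(x) for x in col if x >= 0}
        if len(states) >= 2:
            count += 1
    return count


def bf_pair_diff(a, b):
    return sum(1 for x, y in zip(a, b) if x >= 0 and y >= 0 and x != y)


def bf_pairwise_moments(m):
    diffs = [bf_pair_diff(m[i], m[j]) for i, j in itertools.combinations(range(len(m)), 2)]
    mean = sum(diffs) / len(diffs)
    var = sum((d - mean) ** 2 for d in diffs) / len(diffs)
    return mean, var


def bf_tajimas_d(m):
    n = len(m)
    s = bf_segregating_sites(m)
    if s == 0:
        return 0.0
    pi = bf_pairwise_moments(m)[0]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def bf_private_segregating(focal, others):
    count = 0
    for j in range(focal.shape[1]):
        fstates = {int(x) for x in focal[:, j] if x >= 0}
        ostates = {int(x) for x in others[:, j] if x >= 0}
        if len(fstates) >= 2 and len(ostates) <= 1:
            count += 1
    return count


def bf_mean_rarest(m):
    vals = []
    for j in range(m.shape[1]):
        col = [int(x) for x in m[:, j] if x >= 0]
        counts = {s: col.count(s) for s in set(col)}
        if len(counts) >= 2:
            vals.append(min(counts.values()))
    return sum(vals) / len(vals) if vals else 0.0


def bf_fst(a, b):
    hw = (bf_pairwise_moments(a)[0] + bf_pairwise_moments(b)[0]) / 2.0
    cross = [bf_pair_diff(x, y) for x in a for y in b]
    hb = sum(cross) / len(cross)
    if hb == 0:
        return 0.0
    return 1.0 - hw / hb


def bf_parsimony_informative(m):
    count = 0
    for j in range(m.shape[1]):
        col = [int(x) for x in m[:, j] if x >= 0]
        counts = {s: col.count(s) for s in set(col)}
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            count += 1
    return count
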