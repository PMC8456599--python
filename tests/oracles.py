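"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive and shares no code path with the
package: per-branch tree traversals, direct group-sum variance formulas,
exhaustive permutation enumeration, and a literal step-up procedure.
"""

from itertools import permutations

import numpy as np


# ---------------------------------------------------------------------------
# UniFrac by explicit per-branch accumulation


def _branches(tree):
    """(branch length, descendant leaf-name set) for every non-root node."""
    out = []
    for node in tree.traverse(include_self=False):
        leaves = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((float(node.length), leaves))
    return out


def unweighted_unifrac_bf(a, b, taxa, tree):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    set_a = {t for t, v in zip(taxa, a) if v > 0}
    set_b = {t for t, v in zip(taxa, b) if v > 0}
    unique = shared_total = 0.0
    for length, leaves in _branches(tree):
        in_a = bool(leaves & set_a)
        in_b = bool(leaves & set_b)
        if in_a or in_b:
            shared_total += length
            if in_a != in_b:
                unique += length
    return unique / shared_total if shared_total > 0 else 0.0


def weighted_unifrac_bf(a, b, taxa, tree, normalized=True):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pa = a / a.sum()
    pb = b / b.sum()
    frac = dict(zip(taxa, range(len(taxa))))
    num = den = 0.0
    for length, leaves in _branches(tree):
        A = sum(pa[frac[t]] for t in leaves if t in frac)
        B = sum(pb[frac[t]] for t in leaves if t in frac)
        num += length * abs(A - B)
        den += length * (A + B)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# one-factor PERMANOVA by direct group-sum arithmetic + exhaustive p


def permanova_oneway_bf(D, groups):
    """R^2 and pseudo-F from the classic within-group pair-sum formula."""
    D = np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    n = len(groups)
    ss_total = (D[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    levels = sorted(set(groups))
    for g in levels:
        idx = np.flatnonzero(groups == g)
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = len(levels) - 1
    df_w = n - len(levels)
    F = (ss_between / df_b) / (ss_within / df_w)
    return ss_between / ss_total, F


def permanova_exhaustive_p(D, groups):
    """Exact p: fraction of all n! label permutations with F >= observed."""
    groups = list(groups)
    _, F_obs = permanova_oneway_bf(D, groups)
    count = hits = 0
    for perm in permutations(range(len(groups))):
        g = [groups[i] for i in perm]
        _, F = permanova_oneway_bf(D, g)
        if F >= F_obs - 1e-12:
            hits += 1
        count += 1
    return hits / count


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by literal step-up


def bh_stepup_bf(pvals):
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


# ---------------------------------------------------------------------------
# misc

def gower_diag_bf(D):
    """LCBD numerators: diagonal of the double-centred -D^2/2 by loops."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = -0.5 * D ** 2
    G = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = A[i, j] - A[i].mean() - A[:, j].mean() + A.mean()
    return np.diag(G)


def welch_t_bf(x, y):
    """Textbook Welch t statistic and Welch-Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    return t, df
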