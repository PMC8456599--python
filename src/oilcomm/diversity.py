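"""Alpha diversity, beta-diversity distances, PCoA, PERMANOVA, and LCBD.

Bray-Curtis comes from scipy; UniFrac is a vectorized per-branch
accumulation over the phylogeny (presence sets for the unweighted form,
branch-length-scaled descending abundance for the weighted form).  The
variance-partitioning statistics built on these distances —
sequential-SS two-factor PERMANOVA in the adonis style, local
contributions to beta diversity (LCBD) with taxon-permutation inference,
and principal-coordinate analysis with an explicit negative-eigenvalue
convention — are implemented here.

All permutation p-values are reported as (b + 1) / (m + 1) where b counts
null statistics at least as extreme as the observed one and m is the
number of permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps


from .core_io import (
    AbundanceTable,
    DistanceMatrix,
    SampleMetadata,
    ValidationError,
    to_relative_abundance,
)

__all__ = [
    "richness",
    "shannon",
    "alpha_diversity_table",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "permanova",
    "lcbd",
    "gower_center",
    "OrdinationResult",
    "PermanovaResult",
    "LCBDResult",
    "pairwise_alpha_tests",
]


# ---------------------------------------------------------------------------
# alpha diversity


def richness(sample: np.ndarray) -> int:
    """Number of taxa with abundance > 0."""
    return int(np.count_nonzero(np.asarray(sample, dtype=float) > 0))


def shannon(sample: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p in nats over nonzero proportions."""
    x = np.asarray(sample, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index."""
    rows = {
        s: {"richness": richness(table.data[s].to_numpy()),
            "shannon": shannon(table.data[s].to_numpy())}
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_alpha_tests(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Welch t-tests between group levels, BH-adjusted.

    Post-hoc comparison for per-sample alpha-diversity (or NRI/NTI/LCBD)
    values between treatments.
    """
    from statsmodels.stats.multitest import multipletests

    levels = sorted(set(groups))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            xa = values[groups == a].to_numpy(dtype=float)
            xb = values[groups == b].to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group_a": a, "group_b": b,
                         "mean_a": xa.mean(), "mean_b": xb.mean(),
                         "t": t, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (proportions mode)."""
    if table.mode != "proportions":
        raise ValidationError(
            "bray_curtis requires proportions mode; "
            "convert with to_relative_abundance() first"
        )
    X = table.values.T  # samples x taxa
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(D, ids=table.sample_ids)


def _check_leaves(table: AbundanceTable, tree) -> None:
    leaves = {t.name for t in tree.tips()}
    present = {
        t for t, row in zip(table.taxa_ids, table.values) if row.any()
    }
    missing = sorted(present - leaves)
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")


def _branch_membership(tree, taxa_ids: list[str]):
    """(branch lengths, branch x taxon descendant-indicator matrix)."""
    col = {t: i for i, t in enumerate(taxa_ids)}
    lengths = []
    rows = []
    for node in tree.traverse(include_self=False):
        lengths.append(float(node.length))
        row = np.zeros(len(taxa_ids))
        for tip in ([node] if node.is_tip() else node.tips()):
            if tip.name in col:
                row[col[tip.name]] = 1.0
        rows.append(row)
    return np.asarray(lengths), np.asarray(rows)


def unweighted_unifrac(table: AbundanceTable, tree) -> DistanceMatrix:
    """Fraction of tree branch length unique to either sample's leaf set.

    For each pair: (branch length leading to leaves of exactly one
    sample) / (branch length leading to leaves of either sample).
    """
    _check_leaves(table, tree)
    lengths, M = _branch_membership(tree, table.taxa_ids)
    present = (M @ (table.values > 0)) > 0  # branches x samples
    n = table.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = present[:, i] | present[:, j]
            differ = present[:, i] ^ present[:, j]
            total = lengths[either].sum()
            D[i, j] = D[j, i] = (
                lengths[differ].sum() / total if total > 0 else 0.0
            )
    return DistanceMatrix(D, ids=table.sample_ids)


def weighted_unifrac(table: AbundanceTable, tree,
                     normalized: bool = True) -> DistanceMatrix:
    """Abundance-weighted UniFrac; normalized variant is the default.

    sum_b l_b |A_b - B_b| where A_b is the fraction of a sample's
    abundance descending from branch b; divided by sum_b l_b (A_b + B_b)
    when normalized, which bounds the distance to [0, 1].
    """
    _check_leaves(table, tree)
    if table.mode != "proportions":
        raise ValidationError(
            "weighted_unifrac requires proportions mode; "
            "convert with to_relative_abundance() first"
        )
    lengths, M = _branch_membership(tree, table.taxa_ids)
    W = M @ table.values  # branch x samples descending-abundance fractions
    scaled = (W * lengths[:, None]).T  # samples x branches
    num = squareform(pdist(scaled, metric="cityblock"))
    if not normalized:
        return DistanceMatrix(num, ids=table.sample_ids)
    s = scaled.sum(axis=1)
    den = s[:, None] + s[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # per returned axis
    negative_eigenvalue_note: str


def gower_center(D: DistanceMatrix) -> np.ndarray:
    """Gower-centred matrix G of -D^2/2: G = (I - 11'/n) A (I - 11'/n)."""
    A = -0.5 * np.asarray(D.data, dtype=float) ** 2
    n = A.shape[0]
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def pcoa(D: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean distances) are reported in the note and
    excluded from the proportion-explained denominator.
    """
    G = gower_center(D)
    evals, evecs = scipy.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(evals[0]), 1.0))
    n_pos = int((evals > tol).sum())
    n_neg = int((evals < -tol).sum())
    if k > n_pos:
        note = (
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            "axes truncated"
        )
        k = n_pos
    else:
        note = ""
    if n_neg:
        neg_mag = float(-evals[evals < -tol].sum())
        note = (note + "; " if note else "") + (
            f"{n_neg} negative eigenvalues (total magnitude {neg_mag:.6g}) "
            "excluded from the proportion-explained denominator"
        )
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    denom = evals[evals > tol].sum()
    prop = (evals[:k] / denom) if denom > 0 else np.zeros(k)
    cols = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(D.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=np.asarray(prop),
        negative_eigenvalue_note=note or "no negative eigenvalues",
    )


# ---------------------------------------------------------------------------
# PERMANOVA (sequential / Type-I SS, adonis style)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index: terms + Residual + Total
    n_permutations: int
    seed: int

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"].dropna()


def _design_columns(md: SampleMetadata, term: str, sample_ids) -> np.ndarray:
    """Full-rank dummy encoding (drop first level) for a factor term."""
    vals = md.factor(term, sample_ids)
    levels = sorted({str(v) for v in vals})
    if len(levels) < 2:
        raise ValidationError(f"term {term!r} has a single level")
    cols = [
        (np.array([str(v) for v in vals]) == lv).astype(float)
        for lv in levels[1:]
    ]
    return np.column_stack(cols)


def _hat(X: np.ndarray) -> np.ndarray:
    # pseudo-inverse based projection tolerates aliased columns
    return X @ np.linalg.pinv(X)


def _pseudo_f(ss_t: float, df_t: int, ss_res: float, df_res: int) -> float:
    # residual SS can be exactly zero under perfect separation; the
    # resulting infinite F compares correctly against permuted values
    with np.errstate(divide="ignore"):
        return float(np.float64(ss_t / df_t) / np.float64(ss_res / df_res))


def _sequential_ss(G: np.ndarray, designs: list[np.ndarray]):
    """Sequential (Type-I) sums of squares of each term on the centred G."""
    n = G.shape[0]
    ones = np.ones((n, 1))
    ss_total = float(np.trace(G))
    ss_terms = []
    prev_H = _hat(ones)
    X = ones
    for Xt in designs:
        X = np.hstack([X, Xt])
        H = _hat(X)
        ss_terms.append(float(np.trace(H @ G)) - float(np.trace(prev_H @ G)))
        prev_H = H
    ss_res = ss_total - sum(ss_terms)
    return ss_terms, ss_res, ss_total, prev_H


def permanova(
    D: DistanceMatrix,
    metadata: SampleMetadata,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Two-factor (or one-factor) PERMANOVA with sequential SS.

    SS_total = sum_{i<j} d_ij^2 / n is partitioned through the
    Gower-centred matrix; per-term pseudo-F uses the residual mean square;
    p-values come from free permutation of sample labels (rows/columns of
    the distance matrix permuted jointly).
    """
    ids = list(D.ids)
    n = len(ids)
    if n < 3:
        raise ValidationError("PERMANOVA needs at least 3 samples")
    exhaustive = n_perm == "exhaustive"
    if exhaustive:
        if n > 8:
            raise ValidationError("exhaustive permutations limited to n <= 8")
    elif n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    designs = [_design_columns(metadata, t, ids) for t in terms]
    dfs = [X.shape[1] for X in designs]
    G = gower_center(D)
    ss_terms, ss_res, ss_total, H_full = _sequential_ss(G, designs)
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")
    F_obs = [
        _pseudo_f(ss_t, df_t, ss_res, df_res)
        for ss_t, df_t in zip(ss_terms, dfs)
    ]

    exceed = np.zeros(len(terms))
    if exhaustive:
        from itertools import permutations as _perms

        count = 0
        for perm in _perms(range(n)):
            Gp = G[np.ix_(perm, perm)]
            ss_t_p, ss_res_p, _, _ = _sequential_ss(Gp, designs)
            for i, df_t in enumerate(dfs):
                Fp = _pseudo_f(ss_t_p[i], df_t, ss_res_p, df_res)
                if Fp >= F_obs[i] - 1e-12:
                    exceed[i] += 1
            count += 1
        pvals = exceed / count  # identity permutation included in count
        n_perm_out = count
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            ss_t_p, ss_res_p, _, _ = _sequential_ss(Gp, designs)
            for i, df_t in enumerate(dfs):
                Fp = _pseudo_f(ss_t_p[i], df_t, ss_res_p, df_res)
                if Fp >= F_obs[i] - 1e-12:
                    exceed[i] += 1
        pvals = (exceed + 1.0) / (n_perm + 1.0)
        n_perm_out = n_perm

    rows = []
    for t, df_t, ss_t, F, p in zip(terms, dfs, ss_terms, F_obs, pvals):
        rows.append({"term": t, "df": df_t, "SS": ss_t,
                     "R2": ss_t / ss_total, "F": F, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "R2": 1.0, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm_out, seed=seed)


# ---------------------------------------------------------------------------
# LCBD


@dataclass
class LCBDResult:
    values: pd.Series  # per-sample LCBD, sums to 1
    ss_total: float
    p: pd.Series | None
    n_permutations: int
    seed: int


def _lcbd_values(D: DistanceMatrix) -> tuple[np.ndarray, float]:
    G = gower_center(D)
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValidationError("SS_total is zero: all samples identical")
    return np.diag(G) / ss_total, ss_total


def lcbd(
    D: DistanceMatrix,
    n_perm: int = 0,
    seed: int = 0,
    table_for_null: AbundanceTable | None = None,
    metric=bray_curtis,
) -> LCBDResult:
    """Local contribution to beta diversity: LCBD_i = G_ii / SS_total.

    When an abundance table is supplied, per-sample p-values are obtained
    by permuting each taxon's abundances independently across samples and
    recomputing the distance matrix with ``metric``.
    """
    vals, ss_total = _lcbd_values(D)
    pser = None
    if table_for_null is not None and n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(vals))
        X = table_for_null.values
        for _ in range(n_perm):
            Xp = np.empty_like(X)
            for i in range(X.shape[0]):
                Xp[i] = X[i, rng.permutation(X.shape[1])]
            perm_table = AbundanceTable(
                pd.DataFrame(Xp, index=table_for_null.taxa_ids,
                             columns=table_for_null.sample_ids),
                mode="counts",
            )
            perm_table = to_relative_abundance(perm_table)
            null_vals, _ = _lcbd_values(metric(perm_table))
            exceed += null_vals >= vals - 1e-12
        pser = pd.Series((exceed + 1.0) / (n_perm + 1.0), index=list(D.ids))
    return LCBDResult(
        values=pd.Series(vals, index=list(D.ids)),
        ss_total=ss_total,
        p=pser,
        n_permutations=n_perm,
        seed=seed,
    )
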