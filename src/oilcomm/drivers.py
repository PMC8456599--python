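"""Drivers of community change: best-subset regression of scalar
community properties on the design factors, minimal ASV-subset search
conserving beta diversity, and rank-based differential abundance.

The subset search renders the idea of "a minimal set of taxa whose
Bray-Curtis structure matches the full table" as greedy forward selection
on the Pearson correlation between the lower triangles of the subset and
full-table distance matrices, with randomized tie-broken restarts; an
exhaustive mode validates the greedy search on small inputs.  Exhaustive
enumeration over thousands of ASVs is combinatorially impossible, so the
greedy interpretation is this package's operational definition.

Differential abundance uses the Wilcoxon rank-sum test on per-sample
proportions with Benjamini-Hochberg correction, and reports the log10
ratio of group median proportions (the heat-tree display statistic); no
parametric count model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, SampleMetadata, ValidationError
from .diversity import permanova, bray_curtis

__all__ = [
    "best_subset_regression",
    "minimal_driver_subset",
    "differential_abundance",
    "SubsetRegressionResult",
    "DriverSubsetResult",
    "DifferentialAbundanceResult",
]


# ---------------------------------------------------------------------------
# best-subset regression


@dataclass
class SubsetRegressionResult:
    response: str
    selected: pd.DataFrame  # index: predictor; columns: coef, p
    criterion: str
    criterion_value: float
    r_squared: float
    all_subsets: pd.DataFrame  # enumerated candidate subsets with criterion
    selected_blocks: tuple[str, ...]


def _indicators(md: SampleMetadata, sample_ids) -> dict[str, pd.DataFrame]:
    """Factor blocks of indicator columns (all levels, named per level)."""
    blocks: dict[str, pd.DataFrame] = {}
    treat = md.factor("treatment", sample_ids)
    tlev = sorted(set(treat))
    blocks["treatment"] = pd.DataFrame(
        {f"treatment={lv}": (treat == lv).astype(float) for lv in tlev},
        index=list(sample_ids),
    )
    days = md.data.loc[list(sample_ids), "day"]
    dlev = sorted({int(d) for d in days.dropna()})
    blocks["day"] = pd.DataFrame(
        {f"day={lv}": (days == lv).astype(float).to_numpy() for lv in dlev},
        index=list(sample_ids),
    )
    return blocks


def _ols_bic(y: np.ndarray, X: np.ndarray, criterion: str) -> tuple[float, float]:
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    rank = np.linalg.matrix_rank(A)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ beta) ** 2).sum())
    # exact fits leave numerically tiny residuals whose log-ratio is pure
    # float noise; clamp relative to the response scale so exact-fit
    # models of different sizes tie and the smaller one wins
    rss = max(rss, 1e-12 * float((y ** 2).sum()) + 1e-300)
    k = rank + 1  # + sigma^2
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    if criterion == "AIC":
        return 2 * k - 2 * ll, rss
    return k * np.log(n) - 2 * ll, rss


def best_subset_regression(
    y: pd.Series,
    metadata: SampleMetadata,
    criterion: str = "BIC",
    max_terms: int = 5,
) -> SubsetRegressionResult:
    """Hierarchical best-subset OLS of a per-sample scalar on the design.

    Stage 1 enumerates subsets of the factor *blocks* (treatment, day) and
    keeps the criterion-minimal one, which controls spurious selection of
    individual indicator levels under noise.  Stage 2 exhaustively
    enumerates subsets (up to ``max_terms``) of the individual indicator
    columns within the selected blocks and returns the criterion-minimal
    model with signed coefficients and p-values.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValidationError("criterion must be AIC or BIC")
    y = y.dropna()
    if len(y) < 10:
        raise ValidationError("need >= 10 finite response values")
    ids = list(y.index)
    yv = y.to_numpy(dtype=float)
    blocks = _indicators(metadata, ids)

    records = []
    # stage 1: factor blocks
    best_crit, best_blocks = _ols_bic(yv, np.empty((len(yv), 0)), criterion)[0], ()
    records.append({"subset": "(intercept)", "k": 0, "criterion": best_crit})
    block_names = [b for b in blocks if blocks[b].shape[1] >= 2]
    for r in range(1, len(block_names) + 1):
        for combo in combinations(block_names, r):
            X = pd.concat([blocks[b] for b in combo], axis=1)
            # drop one reference level per block to avoid aliasing
            keep = []
            for b in combo:
                cols = list(blocks[b].columns)
                keep.extend(cols[1:])
            crit, _ = _ols_bic(yv, X[keep].to_numpy(), criterion)
            records.append({"subset": "+".join(combo), "k": len(keep),
                            "criterion": crit})
            if crit < best_crit - 1e-9:
                best_crit, best_blocks = crit, combo

    # stage 2: prune individual indicators within the selected blocks
    cand_cols: list[str] = []
    for b in best_blocks:
        cand_cols.extend(list(blocks[b].columns))
    Xall = pd.concat(blocks.values(), axis=1)
    best_sub: tuple[str, ...] = ()
    best_sub_crit = _ols_bic(yv, np.empty((len(yv), 0)), criterion)[0]
    limit = min(max_terms, len(cand_cols))
    for r in range(1, limit + 1):
        for combo in combinations(cand_cols, r):
            crit, _ = _ols_bic(yv, Xall[list(combo)].to_numpy(), criterion)
            records.append({"subset": "+".join(combo), "k": r,
                            "criterion": crit})
            if crit < best_sub_crit - 1e-9:
                best_sub_crit, best_sub = crit, combo

    if best_sub:
        X = sm.add_constant(Xall[list(best_sub)].to_numpy())
        fit = sm.OLS(yv, X).fit()
        sel = pd.DataFrame(
            {"coef": fit.params[1:], "p": fit.pvalues[1:]},
            index=list(best_sub),
        )
        r2 = float(fit.rsquared)
        crit_val = best_sub_crit
    else:
        sel = pd.DataFrame(columns=["coef", "p"])
        r2 = 0.0
        crit_val = records[0]["criterion"]
    return SubsetRegressionResult(
        response=str(y.name or "response"),
        selected=sel,
        criterion=criterion,
        criterion_value=float(crit_val),
        r_squared=r2,
        all_subsets=pd.DataFrame(records),
        selected_blocks=tuple(best_blocks),
    )


# ---------------------------------------------------------------------------
# minimal driver-subset search


@dataclass
class DriverSubsetResult:
    subsets: list[dict] = field(default_factory=list)  # ranked by r desc
    target_r: float = 0.95
    reached: bool = False
    search_trace: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def best(self) -> dict:
        return self.subsets[0]


def _pair_vectors(X: np.ndarray):
    """Per-taxon lower-triangle |a-b| and (a+b) pair matrices.

    X is taxa x samples; returns (absdiff, sums) of shape taxa x n_pairs
    so that Bray-Curtis of any taxon subset S (on full-table proportions,
    no renormalization) is absdiff[S].sum(0) / sums[S].sum(0).
    """
    n = X.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    A = X[:, iu]
    B = X[:, ju]
    return np.abs(A - B), A + B


def _corr_with(full: np.ndarray, num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Pearson r between `full` and each row of num/den (candidate BCs)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cand = np.where(den > 0, num / den, 0.0)
    cand_c = cand - cand.mean(axis=1, keepdims=True)
    full_c = full - full.mean()
    denom = np.sqrt((cand_c ** 2).sum(axis=1) * (full_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cand_c @ full_c) / denom
    return np.where(np.isfinite(r), r, -np.inf)


def minimal_driver_subset(
    table: AbundanceTable,
    metadata: SampleMetadata | None = None,
    target_r: float = 0.95,
    restarts: int = 10,
    max_size: int | None = None,
    seed: int = 0,
    top_k: int = 3,
    exhaustive: bool = False,
    permanova_term: str = "day",
    n_perm: int = 999,
) -> DriverSubsetResult:
    """Search for a minimal taxon subset whose Bray-Curtis structure
    correlates with the full table's at >= ``target_r``.

    Greedy forward selection on the Mantel-type Pearson correlation r
    between lower triangles, with randomized tie-broken restarts; each
    accepted taxon must strictly increase r.  ``exhaustive=True``
    enumerates all subsets (small inputs only).  Distinct solutions are
    ranked by r; when metadata is given each is also scored by PERMANOVA
    (``permanova_term``) on its subset distance matrix.
    """
    if table.mode != "proportions":
        raise ValidationError("minimal_driver_subset requires proportions mode")
    if table.n_samples < 4:
        raise ValidationError("need >= 4 samples")
    X = table.values
    n_taxa = X.shape[0]
    if max_size is None:
        max_size = n_taxa
    absd, sums = _pair_vectors(X)
    full_num = absd.sum(axis=0)
    full_den = sums.sum(axis=0)
    full_bc = np.where(full_den > 0, full_num / full_den, 0.0)
    if n_taxa == 1:
        # the only subset is the full table itself
        return DriverSubsetResult(
            subsets=[{"taxa": list(table.taxa_ids), "r": 1.0, "size": 1,
                      "reached": True}],
            target_r=target_r, reached=True, search_trace=[], seed=seed,
        )
    if np.allclose(full_bc, full_bc[0]):
        raise ValidationError("full-table distances are constant; r undefined")

    rng = np.random.default_rng(seed)
    trace: list[dict] = []

    def greedy(first: int | None = None) -> tuple[tuple[int, ...], float]:
        chosen: list[int] = []
        num = np.zeros_like(full_num)
        den = np.zeros_like(full_den)
        best_r = -np.inf
        if first is not None:
            chosen.append(first)
            num = num + absd[first]
            den = den + sums[first]
            best_r = float(
                _corr_with(full_bc, num[None, :], den[None, :])[0]
            )
            trace.append({"subset_size": 1, "added": first, "r": best_r})
        while len(chosen) < max_size and best_r < target_r:
            cand_num = num + absd
            cand_den = den + sums
            r = _corr_with(full_bc, cand_num, cand_den)
            r[chosen] = -np.inf
            j = int(np.argmax(r))
            if r[j] <= best_r + 1e-12:
                break
            chosen.append(j)
            num = num + absd[j]
            den = den + sums[j]
            best_r = float(r[j])
            trace.append({"subset_size": len(chosen), "added": j, "r": best_r})
        return tuple(sorted(chosen)), best_r

    solutions: dict[tuple[int, ...], float] = {}
    if exhaustive:
        if n_taxa > 16:
            raise ValidationError("exhaustive mode limited to <= 16 taxa")
        for r_size in range(1, min(max_size, n_taxa) + 1):
            for combo in combinations(range(n_taxa), r_size):
                idx = list(combo)
                num = absd[idx].sum(axis=0)
                den = sums[idx].sum(axis=0)
                rv = float(_corr_with(full_bc, num[None, :], den[None, :])[0])
                solutions[tuple(combo)] = rv
            if max(solutions.values()) >= target_r:
                break
    else:
        # restart 0: pure greedy; later restarts seed the search from a
        # random strong first taxon so ties and near-ties get explored
        r1 = _corr_with(full_bc, absd, sums)
        top = np.argsort(r1)[::-1][: min(5, n_taxa)]
        sub, rv = greedy(None)
        if sub:
            solutions[sub] = rv
        for _ in range(max(0, restarts - 1)):
            first = int(rng.choice(top))
            sub, rv = greedy(first)
            if sub:
                solutions[sub] = rv

    if not solutions:
        raise ValidationError("no subset found")

    # minimal cardinality at the floor first, then highest r
    def sort_key(item):
        sub, rv = item
        hit = rv >= target_r
        return (not hit, len(sub) if hit else 0, -rv)

    ranked = sorted(solutions.items(), key=sort_key)[:top_k]
    out = []
    for sub, rv in ranked:
        entry = {
            "taxa": [table.taxa_ids[i] for i in sub],
            "r": rv,
            "size": len(sub),
            "reached": rv >= target_r,
        }
        if metadata is not None:
            sub_table = AbundanceTable(
                table.data.iloc[list(sub)] /
                np.maximum(table.data.iloc[list(sub)].sum(axis=0), 1e-300),
                mode="proportions",
            )
            D = bray_curtis(sub_table)
            res = permanova(D, metadata, [permanova_term],
                            n_perm=n_perm, seed=seed)
            entry["permanova_r2"] = float(res.table.loc[permanova_term, "R2"])
            entry["permanova_p"] = float(res.table.loc[permanova_term, "p"])
        out.append(entry)
    return DriverSubsetResult(
        subsets=out,
        target_r=target_r,
        reached=out[0]["reached"],
        search_trace=trace,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# differential abundance


@dataclass
class DifferentialAbundanceResult:
    table: pd.DataFrame  # per taxon: log10_ratio, p, q, significant
    group_a: str
    group_b: str
    pseudo: float


def differential_abundance(
    table: AbundanceTable,
    metadata: SampleMetadata,
    group_a: str,
    group_b: str,
    pseudo: float | None = None,
    alpha: float = 0.05,
) -> DifferentialAbundanceResult:
    """Rank-based two-group differential abundance.

    Per taxon: log10 ratio of group median proportions (a floor ``pseudo``
    replaces a zero median before the ratio), a two-sided Wilcoxon
    rank-sum test on per-sample proportions, and Benjamini-Hochberg
    adjustment across taxa.  Default floor: 1 / (2 * max library size)
    when the table came from counts, else 1e-6.
    """
    if table.mode != "proportions":
        from .core_io import to_relative_abundance

        if pseudo is None:
            pseudo = 1.0 / (2.0 * float(table.values.sum(axis=0).max()))
        table = to_relative_abundance(table)
    elif pseudo is None:
        pseudo = 1e-6
    treat = metadata.factor("treatment", table.sample_ids)
    ia = np.flatnonzero(treat == group_a)
    ib = np.flatnonzero(treat == group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError(f"group absent: {group_a if not len(ia) else group_b}")
    if len(ia) < 3 or len(ib) < 3:
        raise ValidationError("need >= 3 samples per group")
    X = table.values
    A, B = X[:, ia], X[:, ib]
    med_a = np.median(A, axis=1)
    med_b = np.median(B, axis=1)
    ra = np.where(med_a == 0, pseudo, med_a)
    rb = np.where(med_b == 0, pseudo, med_b)
    log10_ratio = np.log10(ra / rb)
    stat, p = sps.mannwhitneyu(A, B, axis=1, alternative="two-sided")
    # identical groups give p = 1 (all ties)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "log10_ratio": log10_ratio,
            "p": p,
            "q": q,
            "significant": q < alpha,
        },
        index=table.taxa_ids,
    )
    return DifferentialAbundanceResult(
        table=df, group_a=group_a, group_b=group_b, pseudo=float(pseudo)
    )
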