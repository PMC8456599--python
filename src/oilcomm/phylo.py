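"""Phylogenetic community structure: MPD/MNTD and NRI/NTI null models.

NRI and NTI are sign-flipped standardized effect sizes of the mean
pairwise distance (MPD) and mean nearest-taxon distance (MNTD) among
co-occurring taxa, against a taxa-label randomization null: positive
values indicate phylogenetic clustering (environmental filtering),
negative values overdispersion.  The null shuffles taxon labels across
the cophenetic distance matrix restricted to the sampling pool — the set
of taxa observed anywhere in the dataset — which matches a closed
microcosm community pool.

Abundance-weighted MPD/MNTD are the defaults: pairs are weighted by
p_i * p_j for MPD and each taxon's nearest-neighbour distance by p_i for
MNTD, with proportions renormalized over present taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import AbundanceTable, ValidationError

__all__ = [
    "cophenetic_matrix",
    "mpd",
    "mntd",
    "nri_nti",
    "PhyloStructureResult",
    "nti_exceeds_threshold",
]


def cophenetic_matrix(tree, taxa_ids: list[str]) -> np.ndarray:
    """Pairwise patristic (cophenetic) leaf distances, ordered by taxa_ids."""
    dm = tree.tip_tip_distances()
    idx = [list(dm.ids).index(t) for t in taxa_ids]
    return np.asarray(dm.data)[np.ix_(idx, idx)]


def mpd(sample: np.ndarray, cophenetic: np.ndarray,
        weighted: bool = True) -> float:
    """Mean pairwise cophenetic distance among present taxa.

    Weighted variant weighs pair (i, j) by p_i * p_j.  Returns NaN when
    fewer than two (effective) taxa are present.
    """
    p = np.asarray(sample, dtype=float)
    mask = p > 0
    if mask.sum() < 2:
        return float("nan")
    D = cophenetic[np.ix_(mask, mask)]
    if weighted:
        w = p[mask]
        num = w @ D @ w
        den = w.sum() ** 2 - (w ** 2).sum()
        if den <= 0:
            return float("nan")
        return float(num / den)
    m = mask.sum()
    return float(D.sum() / (m * (m - 1)))


def mntd(sample: np.ndarray, cophenetic: np.ndarray,
         weighted: bool = True) -> float:
    """Mean distance from each present taxon to its nearest present
    neighbour; weighted variant weighs taxon i's term by p_i."""
    p = np.asarray(sample, dtype=float)
    mask = p > 0
    if mask.sum() < 2:
        return float("nan")
    D = cophenetic[np.ix_(mask, mask)].copy()
    np.fill_diagonal(D, np.inf)
    nearest = D.min(axis=1)
    if weighted:
        w = p[mask]
        return float((w * nearest).sum() / w.sum())
    return float(nearest.mean())


@dataclass
class PhyloStructureResult:
    """Per-sample observed MPD/MNTD, null moments, NRI/NTI, and p-values."""

    table: pd.DataFrame
    n_null: int
    seed: int
    null_model: str = "taxa_labels"
    weighted: bool = True


def _two_sided_p(null: np.ndarray, obs: float) -> float:
    m = len(null)
    lo = (np.sum(null <= obs + 1e-12) + 1) / (m + 1)
    hi = (np.sum(null >= obs - 1e-12) + 1) / (m + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def nri_nti(
    table: AbundanceTable,
    tree,
    null_model: str = "taxa_labels",
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> PhyloStructureResult:
    """NRI/NTI for every sample with a taxa-label shuffle null.

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null) and analogously NTI
    from MNTD, so positive values mean clustering.  Samples where the null
    has zero spread (e.g. a sample containing the whole pool on a label-
    shuffle-invariant metric) are flagged undefined.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    if null_model != "taxa_labels":
        raise ValidationError(f"unknown null model {null_model!r}")
    rng = np.random.default_rng(seed)

    X = table.values  # taxa x samples
    pool = np.flatnonzero(X.sum(axis=1) > 0)
    if len(pool) < 2:
        raise ValidationError("fewer than 2 taxa observed in the dataset")
    pool_taxa = [table.taxa_ids[i] for i in pool]
    D = cophenetic_matrix(tree, pool_taxa)
    P = X[pool]  # pool x samples
    n_samples = P.shape[1]

    obs_mpd = np.array([mpd(P[:, j], D, weighted) for j in range(n_samples)])
    obs_mntd = np.array([mntd(P[:, j], D, weighted) for j in range(n_samples)])

    null_mpd = np.empty((n_null, n_samples))
    null_mntd = np.empty((n_null, n_samples))
    for b in range(n_null):
        perm = rng.permutation(len(pool))
        # shuffling taxon labels on D == relabelling the abundance vector
        Pp = P[perm]
        for j in range(n_samples):
            null_mpd[b, j] = mpd(Pp[:, j], D, weighted)
            null_mntd[b, j] = mntd(Pp[:, j], D, weighted)

    rows = []
    for j, sid in enumerate(table.sample_ids):
        row = {"sample_id": sid}
        for name, obs, null in (
            ("mpd", obs_mpd[j], null_mpd[:, j]),
            ("mntd", obs_mntd[j], null_mntd[:, j]),
        ):
            ses_name = "nri" if name == "mpd" else "nti"
            mean_b = float(np.nanmean(null))
            sd_b = float(np.nanstd(null, ddof=1))
            row[f"{name}_obs"] = obs
            row[f"{name}_null_mean"] = mean_b
            row[f"{name}_null_sd"] = sd_b
            if not np.isfinite(obs):
                row[ses_name] = np.nan
                row[f"p_{ses_name}"] = np.nan
                row[f"{ses_name}_note"] = "undefined: <2 effective taxa"
            elif sd_b <= 1e-12:
                row[ses_name] = np.nan
                row[f"p_{ses_name}"] = np.nan
                row[f"{ses_name}_note"] = (
                    "undefined: null sd is zero (label-shuffle invariant)"
                )
            else:
                row[ses_name] = -(obs - mean_b) / sd_b
                row[f"p_{ses_name}"] = _two_sided_p(null, obs)
                row[f"{ses_name}_note"] = ""
        ses = row.get("nti")
        if ses is None or not np.isfinite(ses):
            row["assembly"] = "undefined"
        elif ses > 2:
            row["assembly"] = "clustered"
        elif ses < -2:
            row["assembly"] = "overdispersed"
        else:
            row["assembly"] = "stochastic"
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return PhyloStructureResult(
        table=df, n_null=n_null, seed=seed,
        null_model=null_model, weighted=weighted,
    )


def nti_exceeds_threshold(nti_values, threshold: float = 2.0):
    """One-sided one-sample t-test of replicate NTI values against the
    clustering threshold (+2 by convention).  Returns (t, p, mean)."""
    x = np.asarray(list(nti_values), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan"), float("nan"), float(np.mean(x)) if len(x) else float("nan")
    t, p = sps.ttest_1samp(x, threshold, alternative="greater")
    return float(t), float(p), float(x.mean())
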