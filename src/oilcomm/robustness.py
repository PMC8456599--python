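"""Taxa-function robustness as attenuation of perturbation-response curves.

A community's functional profile is the abundance-weighted gene content
F(c) = normalize(c' G).  Robustness asks how strongly random taxonomic
perturbations of the composition c propagate into F: for each
perturbation magnitude m, taxa are removed until the removed relative
abundance reaches m and the freed mass is reassigned uniformly at random
to replacement taxa from the observed pool; the taxonomic shift t and
functional shift f between the original and perturbed community are then
paired into a response curve.  Attenuation is the reciprocal slope of the
least-squares fit of f = s * t through the origin: alpha = 1 / s, so a
fully redundant community (f = 0 regardless of t) has infinite
attenuation (capped and flagged) and a community whose every taxon is
functionally unique has alpha = 1 when t and f share the Bray-Curtis
scale.  Higher attenuation means smaller functional shifts and higher
robustness.

The removal-plus-uniform-replacement scheme and the through-origin slope
are this package's operational rendering of the response-curve method;
both sit behind narrow interfaces (:func:`perturb_community`,
:func:`attenuation`) so alternative schemes can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import (
    AbundanceTable,
    GenomeContentMatrix,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "functional_profile",
    "perturb_community",
    "response_curve",
    "attenuation",
    "treatment_robustness",
    "PerturbationSample",
    "AttenuationResult",
    "ALPHA_MAX",
    "DEFAULT_GRID",
]

ALPHA_MAX = 100.0
#: perturbation magnitudes m = 0.05, 0.10, ..., 0.50
DEFAULT_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
_PATHWAY_EPS = 1e-6


def functional_profile(c: np.ndarray, G: GenomeContentMatrix) -> np.ndarray:
    """Relative function abundance F = normalize(c' G)."""
    c = np.asarray(c, dtype=float)
    if abs(c.sum() - 1.0) > 1e-6:
        raise ValidationError("composition must sum to 1")
    F = c @ G.data.to_numpy()
    total = F.sum()
    if total <= 0:
        raise ValidationError("composition maps to an all-zero profile")
    return F / total


def _bray(a: np.ndarray, b: np.ndarray) -> float:
    s = (a + b).sum()
    return float(np.abs(a - b).sum() / s) if s > 0 else 0.0


def perturb_community(
    c: np.ndarray, m: float, pool: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Remove taxa until the removed share is the smallest achievable >= m
    and reassign the removed mass uniformly at random across as many
    replacement taxa (from ``pool`` minus the removed set) as were removed.

    ``pool`` is a boolean mask over taxa eligible as replacements.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    c = np.asarray(c, dtype=float)
    if not (0.0 <= m <= 1.0):
        raise ValidationError("magnitude m must be in [0, 1]")
    if m == 0.0:
        return c.copy()
    present = np.flatnonzero(c > 0)
    order = rng.permutation(present)
    removed_mass = 0.0
    removed: list[int] = []
    for i in order:
        removed.append(int(i))
        removed_mass += c[i]
        if removed_mass >= m - 1e-12:
            break
    removed_arr = np.array(removed)
    candidates = np.flatnonzero(pool)
    candidates = np.setdiff1d(candidates, removed_arr, assume_unique=False)
    n_new = min(len(removed), len(candidates))
    if n_new == 0:
        raise ValidationError("replacement pool too small")
    new_taxa = rng.choice(candidates, size=n_new, replace=False)
    out = c.copy()
    out[removed_arr] = 0.0
    out[new_taxa] += removed_mass / n_new
    return out / out.sum()


@dataclass
class PerturbationSample:
    magnitude: float
    taxonomic_shift: float
    functional_shift: float
    pathway_shifts: dict[str, float]
    replicate: int


def _pathway_aggregate(F: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    return np.array([F[g].sum() for g in groups])


def response_curve(
    c: np.ndarray,
    G: GenomeContentMatrix,
    grid=DEFAULT_GRID,
    R: int = 50,
    metric: str = "bray_curtis",
    seed: int = 0,
    tree=None,
) -> list[PerturbationSample]:
    """R random perturbations per magnitude; t is the taxonomic shift
    (Bray-Curtis by default, weighted UniFrac optional), f the Bray-Curtis
    shift between functional profiles, plus per-pathway relative shifts
    |F_P' - F_P| / max(F_P, eps)."""
    if R < 1:
        raise ValidationError("R must be >= 1")
    grid = [float(m) for m in grid]
    if any(m <= 0 or m > 1 for m in grid):
        raise ValidationError("grid magnitudes must lie in (0, 1]")
    if metric not in ("bray_curtis", "weighted_unifrac"):
        raise ValidationError(f"unknown metric {metric!r}")
    if metric == "weighted_unifrac" and tree is None:
        raise ValidationError("weighted_unifrac metric needs a tree")
    rng = np.random.default_rng(seed)
    c = np.asarray(c, dtype=float)
    pool = np.ones(len(c), dtype=bool)
    F0 = functional_profile(c, G)
    pw = G.pathways()
    col_index = {f: j for j, f in enumerate(G.function_ids)}
    pw_names = sorted(pw)
    pw_groups = [np.array([col_index[f] for f in pw[name]]) for name in pw_names]
    P0 = _pathway_aggregate(F0, pw_groups)

    if metric == "weighted_unifrac":
        from .core_io import AbundanceTable as _AT
        from .diversity import weighted_unifrac as _wu
        taxa = [t.name for t in tree.tips()]

        def tax_shift(a, b):
            tbl = _AT(
                pd.DataFrame({"a": a, "b": b}, index=taxa), "proportions"
            )
            return float(_wu(tbl, tree, normalized=True)["a", "b"])
    else:
        tax_shift = _bray

    samples: list[PerturbationSample] = []
    for m in grid:
        for rep in range(R):
            cp = perturb_community(c, m, pool, rng)
            t = tax_shift(c, cp)
            Fp = functional_profile(cp, G)
            f = _bray(F0, Fp)
            Pp = _pathway_aggregate(Fp, pw_groups)
            shifts = {
                name: float(abs(Pp[i] - P0[i]) / max(P0[i], _PATHWAY_EPS))
                for i, name in enumerate(pw_names)
            }
            samples.append(PerturbationSample(m, t, f, shifts, rep))
    return samples


@dataclass
class AttenuationResult:
    alpha: float
    slope: float
    fit_r2: float
    n_points: int
    t_max: float
    capped: bool
    pathway_alpha: pd.DataFrame = field(default_factory=pd.DataFrame)
    note: str = ""


def _origin_fit(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Least squares f = s*t through the origin; returns (s, R^2)."""
    tt = float((t * t).sum())
    if tt == 0:
        raise ValidationError("all taxonomic shifts are zero")
    s = float((t * f).sum() / tt)
    resid = f - s * t
    denom = float((f ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / denom if denom > 0 else 1.0
    return s, r2


def _alpha_from_slope(s: float) -> tuple[float, bool]:
    if s < 0.01:
        return ALPHA_MAX, True
    return 1.0 / s, False


def attenuation(samples: list[PerturbationSample],
                t_max: float = 0.5) -> AttenuationResult:
    """Attenuation alpha = 1/slope of the through-origin fit of f on t
    over samples with t <= t_max; capped at ALPHA_MAX when the slope is
    below 0.01 (functional shifts indistinguishable from zero)."""
    use = [s for s in samples if s.taxonomic_shift <= t_max]
    if len(use) < 10:
        raise ValidationError(
            f"need >= 10 samples with t <= {t_max}; got {len(use)}"
        )
    t = np.array([s.taxonomic_shift for s in use])
    f = np.array([s.functional_shift for s in use])
    slope, r2 = _origin_fit(t, f)
    alpha, capped = _alpha_from_slope(slope)

    pw_rows = []
    names = sorted(use[0].pathway_shifts) if use[0].pathway_shifts else []
    for name in names:
        fp = np.array([s.pathway_shifts[name] for s in use])
        sp, rp2 = _origin_fit(t, fp)
        ap, cp = _alpha_from_slope(sp)
        pw_rows.append({"pathway": name, "alpha": ap, "slope": sp,
                        "fit_r2": rp2, "capped": cp})
    pw = pd.DataFrame(pw_rows).set_index("pathway") if pw_rows else pd.DataFrame()
    return AttenuationResult(
        alpha=alpha, slope=slope, fit_r2=r2, n_points=len(use),
        t_max=t_max, capped=capped, pathway_alpha=pw,
        note="slope below cap threshold; alpha capped" if capped else "",
    )


def treatment_robustness(
    table: AbundanceTable,
    metadata: SampleMetadata,
    G: GenomeContentMatrix,
    grid=DEFAULT_GRID,
    R: int = 50,
    seed: int = 0,
    t_max: float = 0.5,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Attenuation per (treatment, day) group.

    The group composition is the mean relative abundance across
    replicates; with ``per_replicate=True`` each replicate community gets
    its own curve and alpha (enabling between-treatment Welch tests via
    :func:`compare_pathway_attenuation`).  Returns a tidy DataFrame and
    attaches the per-group AttenuationResult in the ``result`` column.
    """
    from .core_io import to_relative_abundance

    table = to_relative_abundance(table) if table.mode == "counts" else table
    if list(table.taxa_ids) != list(G.taxa_ids):
        raise ValidationError("table and genome content taxa mismatch")
    meta = metadata.data.loc[table.sample_ids]
    rows = []
    ss = np.random.SeedSequence(seed)
    groups = sorted(
        {(t, d) for t, d in zip(meta["treatment"], meta["day"].fillna(-1))}
    )
    child_seeds = {g: s for g, s in zip(groups, ss.spawn(len(groups)))}
    for (treat, day) in groups:
        sel = (meta["treatment"] == treat) & (meta["day"].fillna(-1) == day)
        sids = list(meta.index[sel])
        if not sids:
            continue
        sub_rng = np.random.default_rng(child_seeds[(treat, day)])
        day_val = None if day == -1 else int(day)
        if per_replicate:
            units = [(f"r{i+1}", [s]) for i, s in enumerate(sids)]
        else:
            units = [("mean", sids)]
        for label, unit_ids in units:
            comp = table.data[unit_ids].to_numpy().mean(axis=1)
            comp = comp / comp.sum()
            sub_seed = int(sub_rng.integers(2 ** 31 - 1))
            samples = response_curve(comp, G, grid=grid, R=R, seed=sub_seed)
            res = attenuation(samples, t_max=t_max)
            rows.append({
                "treatment": treat, "day": day_val, "unit": label,
                "alpha": res.alpha, "slope": res.slope,
                "fit_r2": res.fit_r2, "capped": res.capped,
                "result": res,
            })
    return pd.DataFrame(rows)


def compare_pathway_attenuation(rep_results: pd.DataFrame,
                                treat_a: str, treat_b: str,
                                day=None) -> pd.DataFrame:
    """Welch t-test of per-pathway attenuation between two treatments over
    replicate-level curves, BH-adjusted across pathways."""
    def pick(tr):
        sel = rep_results["treatment"] == tr
        if day is not None:
            sel &= rep_results["day"] == day
        return [r.pathway_alpha for r in rep_results.loc[sel, "result"]]

    pa, pb = pick(treat_a), pick(treat_b)
    if len(pa) < 2 or len(pb) < 2:
        raise ValidationError("need >= 2 replicate curves per treatment")
    rows = []
    for name in pa[0].index:
        xa = np.array([p.loc[name, "alpha"] for p in pa])
        xb = np.array([p.loc[name, "alpha"] for p in pb])
        if xa.std() == 0 and xb.std() == 0:
            t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({"pathway": name, "mean_a": xa.mean(), "mean_b": xb.mean(),
                     "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows).set_index("pathway")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
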