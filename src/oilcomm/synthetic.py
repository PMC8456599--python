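"""Synthetic microcosm community generator with planted ground truth.

Emulates the oil-amendment microcosm design — six bottle treatments (SW,
SWBS, SWD, WAF, BEWAF, CEWAF) sampled at days 0/3/7/14/28 in triplicate
plus one in-situ baseline sample (FSC) — so that every downstream analysis
stage has a known answer to recover:

* a Yule phylogeny rescaled to unit mean root-to-tip depth;
* phylogenetically structured genome content with a tunable core fraction
  (functional redundancy knob rho) and accessory gene families evolving as
  a two-state Markov process along the tree;
* per-treatment environmental filtering through a Brownian trait and a
  Gaussian fitness kernel (strength phi), which produces phylogenetically
  clustered communities that the NRI/NTI stage should detect;
* responder-clade blooms (rise-then-decline or late-bloom trajectories)
  and individually planted driver taxa with configured target shares;
* Dirichlet-multinomial count noise around the expected compositions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (
    AbundanceTable,
    GenomeContentMatrix,
    SampleMetadata,
    ValidationError,
    tree_from_newick,
)

__all__ = [
    "Bloom",
    "TreatmentConfig",
    "DriverSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_tree",
    "simulate_genome_content",
    "simulate_experiment",
    "brownian_trait",
    "default_config",
]


@dataclass
class Bloom:
    """A bloom trajectory: share(d) rises from ``start_day`` at ``rate``
    toward ``carrying_share`` and optionally decays again.

    share(d) = carrying * (1 - exp(-rate*(d-start))) * exp(-decay*(d-start))
    for d >= start, else 0.
    """

    start_day: float = 0.0
    rate: float = 0.5
    carrying_share: float = 0.2
    decay: float = 0.0

    def share(self, day: float) -> float:
        if day < self.start_day:
            return 0.0
        dt = day - self.start_day
        return (
            self.carrying_share
            * (1.0 - math.exp(-self.rate * dt))
            * math.exp(-self.decay * dt)
        )


@dataclass
class TreatmentConfig:
    """Per-treatment filtering strength and responder-clade blooms."""

    phi: float = 0.0
    responders: list[Bloom] = field(default_factory=list)
    #: approximate number of leaves in each responder clade
    responder_clade_size: int = 5


@dataclass
class DriverSpec:
    """A planted driver taxon with treatment-specific trajectory.

    ``treatments=None`` applies the bloom in every treatment.
    """

    bloom: Bloom = field(default_factory=Bloom)
    treatments: tuple[str, ...] | None = None


@dataclass
class SimulationConfig:
    n_taxa: int = 300
    n_functions: int = 500
    redundancy: float = 0.3  # rho: fraction of core functions
    phylo_signal: float = 1.0  # lambda: accessory trait-evolution rate
    treatments: dict[str, TreatmentConfig] = field(default_factory=dict)
    planted_drivers: list[DriverSpec] = field(default_factory=list)
    depth: int = 50_000  # reads per sample
    overdispersion: float = 50.0  # Dirichlet-multinomial theta; inf = multinomial
    replicates: int = 3
    days: tuple[int, ...] = (0, 3, 7, 14, 28)
    include_fsc: bool = True
    baseline_sigma_phylo: float = 1.0  # Brownian sd of baseline log-abundance
    baseline_sigma_iid: float = 0.5  # i.i.d. sd of baseline log-abundance
    trait_sigma: float = 1.0  # Brownian sd of the filtering trait
    trait_dims: int = 5  # independent Brownian trait dimensions
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        if not (0.0 <= self.redundancy <= 1.0):
            raise ValidationError("redundancy must be in [0, 1]")
        if self.phylo_signal < 0:
            raise ValidationError("phylo_signal must be >= 0")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion must be positive")
        for name, tc in self.treatments.items():
            if tc.phi < 0:
                raise ValidationError(f"phi < 0 for treatment {name}")


@dataclass
class TruthRecord:
    """Ground truth planted by :func:`simulate_experiment`."""

    driver_taxa: list[str]
    responder_clades: dict[str, list[list[str]]]
    phi: dict[str, float]
    redundancy: float
    #: expected per-taxon proportions per (treatment, day) group key "T.dD"
    expected: dict[str, np.ndarray]
    taxa_ids: list[str]

    def to_json(self, path) -> None:
        payload = {
            "driver_taxa": self.driver_taxa,
            "responder_clades": self.responder_clades,
            "phi": self.phi,
            "redundancy": self.redundancy,
            "taxa_ids": self.taxa_ids,
            "expected": {k: v.tolist() for k, v in self.expected.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# tree


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) tree on ``n_taxa`` leaves, rescaled so the mean
    root-to-tip distance is exactly 1. Deterministic given ``seed``."""
    if n_taxa < 1:
        raise ValidationError("n_taxa must be >= 1")
    if n_taxa == 1:
        return tree_from_newick("(t0:1.0):0.0;")
    return _yule_explicit(n_taxa, seed)


class _N:
    __slots__ = ("name", "length", "children")

    def __init__(self, name=None):
        self.name = name
        self.length = 0.0
        self.children = []


def _yule_explicit(n_taxa: int, seed: int) -> TreeNode:
    rng = np.random.default_rng(seed)
    root = _N()
    a, b = _N("t0"), _N("t1")
    root.children = [a, b]
    active = [a, b]
    nxt = 2
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for node in active:
            node.length += dt
        j = int(rng.integers(k))
        parent = active[j]
        c1, c2 = _N(f"t{nxt - 1}"), _N(f"t{nxt}")
        # keep the split lineage's label on one child so labels stay unique
        c1.name = parent.name
        parent.name = None
        parent.children = [c1, c2]
        active[j] = c1
        active.append(c2)
        nxt += 1
    dt = rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length += dt
    depth_sum = _sum_depths(root, 0.0)
    scale = depth_sum / n_taxa
    _scale(root, 1.0 / scale)
    return tree_from_newick(_newick(root) + ";")


def _sum_depths(node: _N, acc: float) -> float:
    acc += node.length
    if not node.children:
        return acc
    return sum(_sum_depths(c, acc) for c in node.children)


def _scale(node: _N, f: float) -> None:
    node.length *= f
    for c in node.children:
        _scale(c, f)


def _newick(node: _N) -> str:
    if not node.children:
        return f"{node.name}:{node.length!r}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length!r}"


# ---------------------------------------------------------------------------
# traits and genome content


def _preorder_edges(tree: TreeNode):
    """(parent_index, child_index, branch_length) with root index -1;
    returns (edges, index_of_node dict, leaf names in tip order)."""
    idx = {}
    edges = []
    for i, node in enumerate(tree.traverse(include_self=True)):
        idx[id(node)] = i
    for node in tree.traverse(include_self=True):
        if node.parent is not None:
            edges.append(
                (idx[id(node.parent)], idx[id(node)], float(node.length or 0.0))
            )
    leaves = [(idx[id(t)], t.name) for t in tree.tips()]
    return edges, idx, leaves


def brownian_trait(tree: TreeNode, sigma: float, rng: np.random.Generator,
                   n_traits: int = 1) -> pd.DataFrame:
    """Simulate Brownian traits along the tree; rows = leaves, cols = traits."""
    edges, idx, leaves = _preorder_edges(tree)
    n_nodes = len(idx)
    vals = np.zeros((n_nodes, n_traits))
    for parent, child, bl in edges:
        vals[child] = vals[parent] + rng.standard_normal(n_traits) * (
            sigma * math.sqrt(bl)
        )
    data = {name: vals[i] for i, name in leaves}
    return pd.DataFrame.from_dict(data, orient="index")


def simulate_genome_content(
    tree: TreeNode, n_functions: int, rho: float, lam: float, seed: int
) -> GenomeContentMatrix:
    """Core + accessory gene content on the tree.

    The first ceil(rho * n_functions) functions are core (copy number 1 in
    every taxon).  Accessory functions evolve presence/absence as a
    symmetric two-state Markov process with rate ``lam`` from a root state
    drawn Bernoulli(0.5); the flip probability along a branch of length t
    is (1 - exp(-2*lam*t)) / 2.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValidationError("rho must be in [0, 1]")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    n_core = math.ceil(rho * n_functions)
    n_acc = n_functions - n_core
    leaf_names = [t.name for t in tree.tips()]
    n_taxa = len(leaf_names)

    acc = np.zeros((n_taxa, n_acc), dtype=float)
    if n_acc > 0:
        edges, idx, leaves = _preorder_edges(tree)
        n_nodes = len(idx)
        states = np.zeros((n_nodes, n_acc), dtype=bool)
        root_state = rng.random(n_acc) < 0.5
        # root is index of the tree root
        root_i = idx[id(tree)]
        states[root_i] = root_state
        for parent, child, bl in edges:
            pflip = 0.5 * (1.0 - math.exp(-2.0 * lam * bl))
            flips = rng.random(n_acc) < pflip
            states[child] = states[parent] ^ flips
        for i, name in leaves:
            acc[leaf_names.index(name)] = states[i]

    data = np.hstack([np.ones((n_taxa, n_core)), acc])
    # guarantee the at-least-one-function invariant for tiny accessory sets
    empty = data.sum(axis=1) == 0
    if empty.any() and n_functions > 0:
        data[empty, min(n_core, n_functions - 1)] = 1.0
    cols = [f"K{j:05d}" for j in range(n_functions)]
    df = pd.DataFrame(data, index=leaf_names, columns=cols)
    # simple pathway map: consecutive blocks of 10 KOs per pathway
    pmap = {
        col: frozenset([f"ko{j // 10:05d}"]) for j, col in enumerate(cols)
    }
    return GenomeContentMatrix(df, pmap)


# ---------------------------------------------------------------------------
# experiment


def _pick_clades(tree: TreeNode, size: int, n_clades: int,
                 rng: np.random.Generator) -> list[list[str]]:
    """Pick disjoint clades of roughly ``size`` leaves, rng-tie-broken."""
    candidates = []
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if 2 <= len(tips) <= max(2, 3 * size):
            candidates.append(tips)
    rng.shuffle(candidates)
    candidates.sort(key=lambda tips: abs(len(tips) - size))
    chosen: list[list[str]] = []
    used: set[str] = set()
    for tips in candidates:
        if used.isdisjoint(tips):
            chosen.append(tips)
            used.update(tips)
        if len(chosen) == n_clades:
            break
    if len(chosen) < n_clades:
        raise ValidationError("tree too small for requested responder clades")
    return chosen


def simulate_experiment(
    cfg: SimulationConfig, tree: TreeNode, G: GenomeContentMatrix | None = None
) -> tuple[AbundanceTable, SampleMetadata, TruthRecord]:
    """Simulate the full treatment x day x replicate count table.

    The expected composition of a (treatment, day) group is built as:
    softmax of a latent log-abundance (Brownian-on-tree baseline plus
    i.i.d. noise, minus phi * (trait - optimum)^2 environmental-filtering
    penalty), with responder-clade and planted-driver target shares
    overriding their taxa and the background rescaled to the remaining
    mass.  Replicate counts are Dirichlet-multinomial around that mean.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    r_base, r_trait, r_clade, r_driver, r_counts = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    taxa = [t.name for t in tree.tips()]
    n = len(taxa)
    if n != cfg.n_taxa:
        raise ValidationError(
            f"tree has {n} leaves but config says n_taxa={cfg.n_taxa}"
        )
    if G is not None and list(G.taxa_ids) != taxa:
        raise ValidationError("genome content taxa do not match tree leaves")

    base_phylo = brownian_trait(tree, cfg.baseline_sigma_phylo, r_base).loc[
        taxa, 0
    ].to_numpy() if cfg.baseline_sigma_phylo > 0 else np.zeros(n)
    base = base_phylo + r_base.standard_normal(n) * cfg.baseline_sigma_iid
    # multivariate trait: similarity across several independent Brownian
    # dimensions implies relatedness far more strongly than one dimension
    # (convergence in all dimensions at once is unlikely), so a Gaussian
    # fitness kernel on it produces phylogenetically clustered filtering
    trait = brownian_trait(
        tree, cfg.trait_sigma, r_trait, n_traits=cfg.trait_dims
    ).loc[taxa].to_numpy()

    # responder clades per treatment
    responder_clades: dict[str, list[list[str]]] = {}
    used: set[str] = set()
    for tname, tc in cfg.treatments.items():
        if tc.responders:
            clades = _pick_clades(tree, tc.responder_clade_size,
                                  len(tc.responders), r_clade)
            responder_clades[tname] = clades
            for c in clades:
                used.update(c)
        else:
            responder_clades[tname] = []

    # planted drivers: individual taxa outside responder clades
    free = [t for t in taxa if t not in used]
    r_driver.shuffle(free)
    if len(free) < len(cfg.planted_drivers):
        raise ValidationError("not enough free taxa for planted drivers")
    driver_taxa = free[: len(cfg.planted_drivers)]

    tindex = {t: i for i, t in enumerate(taxa)}
    anchor_taxon = {
        tname: int(r_clade.integers(n)) for tname in list(cfg.treatments) + ["FSC"]
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    expected: dict[str, np.ndarray] = {}

    def draw_counts(pi: np.ndarray) -> np.ndarray:
        if math.isinf(cfg.overdispersion):
            p = pi
        else:
            alpha = np.maximum(cfg.overdispersion * pi, 1e-12)
            p = r_counts.dirichlet(alpha)
        return r_counts.multinomial(cfg.depth, p / p.sum())

    def group_expectation(tname: str, day: float) -> np.ndarray:
        tc = cfg.treatments.get(tname, TreatmentConfig())
        clades = responder_clades.get(tname, [])
        latent = base.copy()
        if tc.phi > 0:
            # treatment optimum: the trait vector of an anchor taxon (the
            # first responder clade's centroid, or a seeded random taxon)
            if clades:
                members = clades[0]
                opt = trait[[tindex[m] for m in members]].mean(axis=0)
            else:
                opt = trait[anchor_taxon[tname]]
            penalty = ((trait - opt) ** 2).mean(axis=1)
            latent = latent - tc.phi * penalty
        pi_bg = np.exp(latent - latent.max())
        shares = np.zeros(n)
        for bloom, clade in zip(tc.responders, clades):
            s = bloom.share(day)
            for m in clade:
                shares[tindex[m]] = s / len(clade)
        for spec, dtax in zip(cfg.planted_drivers, driver_taxa):
            if spec.treatments is None or tname in spec.treatments:
                shares[tindex[dtax]] = spec.bloom.share(day)
        S = shares.sum()
        if S > 1.0 + 1e-9:
            raise ValidationError(
                f"planted shares sum to {S:.3f} > 1 for {tname} day {day}"
            )
        pi = np.where(shares > 0, shares, 0.0)
        bg_mask = shares == 0
        bg = pi_bg * bg_mask
        pi = pi + bg / bg.sum() * (1.0 - S)
        return pi / pi.sum()

    if cfg.include_fsc:
        pi = group_expectation("FSC", 0.0)
        expected["FSC"] = pi
        sid = "FSC.r1"
        columns[sid] = draw_counts(pi)
        meta_rows.append((sid, "FSC", pd.NA, 1))

    for tname in cfg.treatments:
        if tname == "FSC":
            continue
        for day in cfg.days:
            pi = group_expectation(tname, day)
            expected[f"{tname}.d{day}"] = pi
            for rep in range(1, cfg.replicates + 1):
                sid = f"{tname}.d{day}.r{rep}"
                columns[sid] = draw_counts(pi)
                meta_rows.append((sid, tname, day, rep))

    table = AbundanceTable(
        pd.DataFrame(columns, index=taxa, dtype=float), mode="counts"
    )
    meta = SampleMetadata(
        pd.DataFrame(
            meta_rows, columns=["sample_id", "treatment", "day", "replicate"]
        ).set_index("sample_id")
    )
    truth = TruthRecord(
        driver_taxa=driver_taxa,
        responder_clades=responder_clades,
        phi={t: tc.phi for t, tc in cfg.treatments.items()},
        redundancy=cfg.redundancy,
        expected=expected,
        taxa_ids=taxa,
    )
    return table, meta, truth


def simulate_two_group(
    n_taxa: int = 200,
    n_per_group: int = 15,
    depth: int = 50_000,
    theta: float = 50.0,
    fold_changes: dict[int, float] | None = None,
    n_planted: int = 0,
    fold: float = 8.0,
    seed: int = 0,
    group_a: str = "CEWAF",
    group_b: str = "WAF",
) -> tuple[AbundanceTable, SampleMetadata, list[str]]:
    """Two-group comparison with planted per-taxon fold changes.

    Both groups share one baseline composition (log-normal shares); taxa
    listed in ``fold_changes`` (index -> fold) are multiplied by that fold
    in group A before renormalisation.  Alternatively ``n_planted`` taxa
    of median baseline share get the common ``fold`` — the median-rank
    choice keeps the planted mass small so renormalisation barely moves
    the background proportions (a large planted mass would turn every
    background taxon into a genuine compositional change and inflate any
    false-discovery count).  Counts are Dirichlet-multinomial with
    concentration ``theta``.  Returns the table, metadata, and the ids of
    the planted taxa — ground truth for false-discovery calibration of
    the differential-abundance stage.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    base = np.exp(rng.standard_normal(n_taxa))
    pi_b = base / base.sum()
    if fold_changes is None and n_planted > 0:
        order = np.argsort(base)
        lo = (n_taxa - n_planted) // 2
        fold_changes = {int(i): fold for i in order[lo:lo + n_planted]}
    mult = np.ones(n_taxa)
    fold_changes = fold_changes or {}
    for i, f in fold_changes.items():
        mult[i] = f
    pi_a = pi_b * mult
    pi_a = pi_a / pi_a.sum()

    def draw(pi):
        alpha = np.maximum(theta * pi, 1e-12)
        p = rng.dirichlet(alpha)
        return rng.multinomial(depth, p / p.sum())

    cols = {}
    rows = []
    for g, pi, name in ((group_a, pi_a, "a"), (group_b, pi_b, "b")):
        for r in range(1, n_per_group + 1):
            sid = f"{g}.r{r}"
            cols[sid] = draw(pi)
            rows.append((sid, g, 0, r))
    table = AbundanceTable(pd.DataFrame(cols, index=taxa, dtype=float))
    meta = SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "treatment", "day",
                                    "replicate"]).set_index("sample_id")
    )
    planted = [taxa[i] for i in fold_changes]
    return table, meta, planted


def default_config(seed: int = 0, n_taxa: int = 300, n_functions: int = 500,
                   depth: int = 50_000) -> SimulationConfig:
    """The study-design default: 6 treatments x 5 days x 3 replicates + FSC.

    Bloom parameters are qualitative calibrations to the observed
    trajectory shapes: early bloomers that rise fast and decline
    (Colwellia/Oleispira-like), late bloomers appearing after day 7-14
    (Cycloclasticus/Alcanivorax-like), and an opportunist clade sustained
    in the dispersant-amended treatments (Rhodobacteraceae/Vibrio-like).
    Filtering is strongest in the synthetic-dispersant treatments (CEWAF,
    SWD), intermediate in the other amended bottles, absent in situ.
    """
    treatments = {
        "SW": TreatmentConfig(phi=0.5, responders=[
            Bloom(0, 0.4, 0.10, decay=0.05),
        ]),
        "SWBS": TreatmentConfig(phi=1.0, responders=[
            Bloom(0, 0.4, 0.15, decay=0.05),
        ]),
        "SWD": TreatmentConfig(phi=3.0, responders=[
            Bloom(0, 0.8, 0.26, decay=0.10),  # Vibrio-like surge then fade
            Bloom(3, 0.2, 0.25),              # opportunist takeover
        ]),
        "WAF": TreatmentConfig(phi=2.0, responders=[
            Bloom(0, 0.5, 0.25, decay=0.08),  # early obligate degraders
            Bloom(7, 0.15, 0.20),             # late PAH/alkane specialists
        ]),
        "BEWAF": TreatmentConfig(phi=2.0, responders=[
            Bloom(0, 0.5, 0.30, decay=0.08),
            Bloom(14, 0.20, 0.12),
        ]),
        "CEWAF": TreatmentConfig(phi=3.0, responders=[
            Bloom(0, 0.5, 0.35, decay=0.12),
            Bloom(3, 0.20, 0.30),             # generalist dominance
        ]),
    }
    drivers = [
        DriverSpec(Bloom(7, 0.25, 0.10), treatments=("WAF", "BEWAF")),
        DriverSpec(Bloom(3, 0.30, 0.08), treatments=("CEWAF", "SWD")),
        DriverSpec(Bloom(14, 0.30, 0.06), treatments=("BEWAF",)),
    ]
    return SimulationConfig(
        n_taxa=n_taxa,
        n_functions=n_functions,
        treatments=treatments,
        planted_drivers=drivers,
        depth=depth,
        seed=seed,
    )
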