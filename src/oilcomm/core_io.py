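"""Data model, readers/writers, and validation for tabular and tree inputs.

The canonical in-memory containers are thin dataclasses around pandas
DataFrames (taxa as rows, samples as columns for abundance data) plus
scikit-bio's :class:`~skbio.TreeNode` and
:class:`~skbio.stats.distance.DistanceMatrix` for trees and pairwise
dissimilarities.  All on-disk formats are plain text: TSV (UTF-8, header
row) for tables, newick for trees, JSON for run manifests.  Floats are
written with 12 significant digits, which round-trips all quantities the
pipeline produces.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "TREATMENTS",
    "DESIGN_DAYS",
    "AbundanceTable",
    "SampleMetadata",
    "GenomeContentMatrix",
    "DistanceMatrix",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative_abundance",
    "rarefy",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_genome_content",
    "write_genome_content",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_manifest",
]

#: Treatment vocabulary of the microcosm design: in-situ baseline (FSC),
#: seawater-only / +biosurfactant / +dispersant controls, and the three
#: oil-containing water-accommodated fractions.
TREATMENTS = ("FSC", "SW", "SWBS", "SWD", "WAF", "BEWAF", "CEWAF")

#: Sampling days of the incubation design grid.
DESIGN_DAYS = (0, 3, 7, 14, 28)

_FLOAT_FMT = "%.12g"


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix.

    Parameters
    ----------
    data : DataFrame
        Non-negative values, taxa as rows, samples as columns.
    mode : {"counts", "proportions"}
        In proportions mode every sample column sums to 1.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite abundance values")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.mode == "proportions":
            colsums = vals.sum(axis=0)
            bad = np.abs(colsums - 1.0) > 1e-9
            if bad.any():
                raise ValidationError(
                    "proportions columns must sum to 1: "
                    f"{list(self.data.columns[bad])}"
                )

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(sample_ids)], self.mode)

    def select_taxa(self, taxa_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(taxa_ids)], self.mode)


@dataclass
class SampleMetadata:
    """Per-sample design labels: treatment, incubation day, replicate.

    ``day`` uses pandas' nullable Int64 so the in-situ FSC baseline (which
    has no incubation day) can carry a missing value.
    """

    data: pd.DataFrame  # index: sample_id; columns: treatment, day, replicate

    def __post_init__(self) -> None:
        required = {"treatment", "day", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        bad = set(self.data["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment level(s): {sorted(bad)}")
        self.data = self.data.copy()
        self.data["day"] = self.data["day"].astype("Int64")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate_days(self, free_design: bool = False) -> None:
        """Reject days outside the incubation grid unless free_design."""
        if free_design:
            return
        days = self.data["day"].dropna()
        off_grid = set(days) - set(DESIGN_DAYS)
        if off_grid:
            raise ValidationError(
                f"day(s) {sorted(off_grid)} not in design grid {DESIGN_DAYS}"
            )

    def check_covers(self, table: AbundanceTable) -> None:
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)}"
            )

    def factor(self, name: str, sample_ids) -> np.ndarray:
        return self.data.loc[list(sample_ids), name].to_numpy()


@dataclass
class GenomeContentMatrix:
    """Taxa x function (KO) copy-number matrix plus KO -> pathway map."""

    data: pd.DataFrame  # taxa rows, function columns, copy numbers
    pathway_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValidationError("negative copy numbers in genome content")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate taxon ids in genome content")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate function ids in genome content")
        empty = vals.sum(axis=1) == 0
        if empty.any():
            raise ValidationError(
                "taxa with all-zero function content: "
                f"{list(self.data.index[empty])}"
            )

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def function_ids(self) -> list[str]:
        return list(self.data.columns)

    def pathways(self) -> dict[str, list[str]]:
        """Invert the KO->pathway map to pathway -> member KOs present here."""
        out: dict[str, list[str]] = {}
        have = set(self.data.columns)
        for ko, pws in self.pathway_map.items():
            if ko not in have:
                continue
            for pw in pws:
                out.setdefault(pw, []).append(ko)
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValidationError(f"non-numeric value in {path}: {e}") from e
    if df.isna().any().any():
        raise ValidationError(f"ragged or missing values in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_abundance_table(path, orientation: str = "taxa-as-rows") -> AbundanceTable:
    """Read a TSV count table; first column holds row ids.

    orientation="samples-as-rows" transposes on read so the in-memory
    layout is always taxa x samples.
    """
    df = _read_tsv_matrix(path)
    if orientation == "samples-as-rows":
        df = df.T
    elif orientation != "taxa-as-rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return AbundanceTable(df, mode="counts")


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample proportions (no pseudocount)."""
    if table.mode == "proportions":
        return table
    colsums = table.values.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        raise ValidationError(
            f"all-zero sample(s): {list(table.data.columns[np.flatnonzero(zero)])}"
        )
    return AbundanceTable(table.data / colsums, mode="proportions")


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Off by default everywhere in the pipeline; provided for sensitivity
    checks only.  Samples with fewer than ``depth`` reads are dropped.
    """
    if table.mode != "counts":
        raise ValidationError("rarefaction requires counts mode")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in table.sample_ids:
        counts = table.data[s].to_numpy()
        total = int(counts.sum())
        if total < depth:
            continue
        picked = rng.choice(
            np.repeat(np.arange(len(counts)), counts.astype(int)),
            size=depth,
            replace=False,
        )
        cols[s] = np.bincount(picked, minlength=len(counts))
    if not cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return AbundanceTable(pd.DataFrame(cols, index=table.data.index), "counts")


def read_metadata(path, free_design: bool = False) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata TSV requires a sample_id column")
    df = df.set_index("sample_id")
    md = SampleMetadata(df)
    md.validate_days(free_design=free_design)
    return md


def write_metadata(md: SampleMetadata, path) -> None:
    md.data.to_csv(path, sep="\t", index_label="sample_id")


def _check_branch_lengths(tree: TreeNode) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "<internal>"
            raise ValidationError(
                f"node {name!r} has no branch length (no silent default)"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every non-root branch needs a length."""
    tree = TreeNode.read(str(path), format="newick")
    if tree.length is None:
        tree.length = 0.0
    _check_branch_lengths(tree)
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def tree_from_newick(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    if tree.length is None:
        tree.length = 0.0
    _check_branch_lengths(tree)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_genome_content(path, pathway_map_path=None) -> GenomeContentMatrix:
    """Read taxa x KO copy numbers and an optional KO->pathway TSV.

    The pathway map TSV has columns ``function_id`` and ``pathway_id``;
    a KO may map to several pathways (one row each).
    """
    df = _read_tsv_matrix(path)
    pmap: dict[str, frozenset[str]] = {}
    if pathway_map_path is not None:
        pm = pd.read_csv(pathway_map_path, sep="\t", dtype=str)
        if not {"function_id", "pathway_id"} <= set(pm.columns):
            raise ValidationError(
                "pathway map requires function_id and pathway_id columns"
            )
        grouped = pm.groupby("function_id")["pathway_id"].apply(frozenset)
        pmap = grouped.to_dict()
    return GenomeContentMatrix(df, pmap)


def write_genome_content(G: GenomeContentMatrix, path, pathway_map_path=None) -> None:
    G.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    if pathway_map_path is not None:
        rows = [
            {"function_id": ko, "pathway_id": pw}
            for ko, pws in sorted(G.pathway_map.items())
            for pw in sorted(pws)
        ]
        pd.DataFrame(rows, columns=["function_id", "pathway_id"]).to_csv(
            pathway_map_path, sep="\t", index=False
        )


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv_matrix(path)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.data, index=D.ids, columns=D.ids).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (seed, config, package versions)."""
    import oilcomm

    manifest = {"oilcomm_version": oilcomm.__version__}
    manifest.update(entries)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
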