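"""End-to-end orchestration: simulate -> diversity -> phylo -> drivers ->
robustness -> differential abundance -> chemistry, as one reproducible run.

A single master seed spawns one child seed per stage through a counter
scheme (`numpy.random.SeedSequence(master, spawn_key=(stage_index,))`),
so any stage can be re-run in isolation and reproduce its outputs.
Outputs are TSV/JSON files in the run directory plus a JSON manifest
recording the effective configuration and per-stage seeds.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io
from .core_io import ValidationError, to_relative_abundance
from . import diversity as dv
from . import phylo as ph
from . import drivers as dr
from . import robustness as rb
from . import chemistry as ch
from . import synthetic as syn

__all__ = ["RunConfig", "run_all", "STAGES"]

STAGES = ("simulate", "diversity", "phylo", "drivers", "diffabund",
          "robustness", "chemistry")


@dataclass
class RunConfig:
    out_dir: str = "oilcomm_run"
    master_seed: int = 0
    # simulation (used unless explicit input paths are given)
    n_taxa: int = 300
    n_functions: int = 500
    depth: int = 50_000
    # explicit inputs (all four required to skip simulation)
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    content_path: str | None = None
    pathway_map_path: str | None = None
    # stage toggles
    stages: tuple[str, ...] = STAGES
    # per-stage parameters
    n_perm: int = 199
    n_null: int = 199
    permanova_terms: tuple[str, ...] = ("treatment", "day")
    target_r: float = 0.95
    restarts: int = 5
    driver_treatment: str = "CEWAF"
    diffabund_groups: tuple[str, str] = ("CEWAF", "WAF")
    robustness_grid: tuple[float, ...] = tuple(
        np.round(np.arange(0.05, 0.501, 0.05), 2)
    )
    robustness_reps: int = 10
    robustness_day: int = 28

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2 ** 31 - 1))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "permanova_terms", "diffabund_groups",
                    "robustness_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log(msg: str) -> None:
    print(f"[oilcomm] {msg}", file=sys.stderr)


def run_all(cfg: RunConfig) -> dict:
    """Run the enabled stages; returns the manifest dictionary.

    Any stage failure raises after writing the partial manifest with the
    failure point recorded; previously written stage outputs remain.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "stages_run": [],
    }
    t_all = time.perf_counter()
    enabled = set(cfg.stages)

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages_run"].append(name)
        _log(f"stage {name} done in {time.perf_counter() - t0:.1f}s")

    try:
        # ---- inputs -----------------------------------------------------
        t0 = time.perf_counter()
        if cfg.table_path:
            needed = (cfg.metadata_path, cfg.tree_path, cfg.content_path)
            if not all(needed):
                raise ValidationError(
                    "explicit inputs need table, metadata, tree and content paths"
                )
            table = core_io.read_abundance_table(cfg.table_path)
            meta = core_io.read_metadata(cfg.metadata_path)
            tree = core_io.read_tree(cfg.tree_path)
            G = core_io.read_genome_content(cfg.content_path,
                                            cfg.pathway_map_path)
            truth = None
            _log("loaded inputs from disk")
        elif "simulate" in enabled:
            seed = cfg.stage_seed("simulate")
            sim_cfg = syn.default_config(
                seed=seed, n_taxa=cfg.n_taxa,
                n_functions=cfg.n_functions, depth=cfg.depth,
            )
            tree = syn.simulate_tree(cfg.n_taxa, seed)
            G = syn.simulate_genome_content(
                tree, cfg.n_functions, sim_cfg.redundancy,
                sim_cfg.phylo_signal, seed,
            )
            table, meta, truth = syn.simulate_experiment(sim_cfg, tree, G)
            core_io.write_abundance_table(table, out / "abundance.tsv")
            core_io.write_metadata(meta, out / "metadata.tsv")
            core_io.write_tree(tree, out / "tree.nwk")
            core_io.write_genome_content(G, out / "genome_content.tsv",
                                         out / "pathway_map.tsv")
            truth.to_json(out / "truth.json")
            finish_stage("simulate", t0)
        else:
            raise ValidationError(
                "no input paths given and simulate stage toggled off"
            )
        meta.check_covers(table)
        props = to_relative_abundance(table)
        non_fsc = [s for s in table.sample_ids
                   if meta.data.loc[s, "treatment"] != "FSC"]

        summary_lines: list[str] = []

        # ---- diversity --------------------------------------------------
        if "diversity" in enabled:
            t0 = time.perf_counter()
            seed = cfg.stage_seed("diversity")
            alpha = dv.alpha_diversity_table(table)
            alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                         index_label="sample_id")
            D_bc = dv.bray_curtis(props)
            D_uu = dv.unweighted_unifrac(props, tree)
            D_wu = dv.weighted_unifrac(props, tree)
            for name, D in (("bray_curtis", D_bc), ("unweighted_unifrac", D_uu),
                            ("weighted_unifrac", D_wu)):
                core_io.write_distance_matrix(D, out / f"dist_{name}.tsv")
                ord_res = dv.pcoa(D, k=2)
                ord_res.coordinates.to_csv(
                    out / f"pcoa_{name}.tsv", sep="\t",
                    index_label="sample_id",
                )
            # PERMANOVA / LCBD on the bottle samples (FSC has no day factor)
            D_bc_t = dv.bray_curtis(props.select_samples(non_fsc))
            perm = dv.permanova(
                D_bc_t, meta, list(cfg.permanova_terms),
                n_perm=cfg.n_perm, seed=seed,
            )
            perm.table.to_csv(out / "permanova.tsv", sep="\t")
            lc = dv.lcbd(D_bc, n_perm=0, seed=seed)
            lc.values.to_frame("lcbd").to_csv(out / "lcbd.tsv", sep="\t",
                                              index_label="sample_id")
            _log(f"PERMANOVA ({cfg.n_perm} perms)")
            for term in cfg.permanova_terms:
                r2 = perm.table.loc[term, "R2"]
                p = perm.table.loc[term, "p"]
                summary_lines.append(
                    f"PERMANOVA {term}: R2={r2:.3f} p={p:.4g}"
                )
            manifest["permanova"] = json.loads(
                perm.table.to_json(orient="index")
            )
            finish_stage("diversity", t0)

        # ---- phylo ------------------------------------------------------
        if "phylo" in enabled:
            t0 = time.perf_counter()
            seed = cfg.stage_seed("phylo")
            ps = ph.nri_nti(props, tree, n_null=cfg.n_null, seed=seed)
            ps.table.to_csv(out / "phylo_structure.tsv", sep="\t")
            _log(f"NRI/NTI ({cfg.n_null} nulls)")
            by_treat = ps.table.join(meta.data).groupby("treatment")["nti"]
            for treat, vals in by_treat:
                tstat, pval, mean = ph.nti_exceeds_threshold(vals)
                summary_lines.append(
                    f"NTI {treat}: mean={mean:.2f} "
                    f"P(mean>2)={pval:.3g}"
                )
            finish_stage("phylo", t0)

        # ---- drivers ----------------------------------------------------
        if "drivers" in enabled:
            t0 = time.perf_counter()
            seed = cfg.stage_seed("drivers")
            treat_ids = [s for s in non_fsc
                         if meta.data.loc[s, "treatment"] == cfg.driver_treatment]
            sub = to_relative_abundance(
                core_io.AbundanceTable(table.data[treat_ids], "counts")
            )
            res = dr.minimal_driver_subset(
                sub, metadata=meta, target_r=cfg.target_r,
                restarts=cfg.restarts, seed=seed, n_perm=cfg.n_perm,
            )
            with open(out / "driver_subsets.json", "w") as fh:
                json.dump({"treatment": cfg.driver_treatment,
                           "target_r": cfg.target_r,
                           "subsets": res.subsets}, fh, indent=1)
                fh.write("\n")
            best = res.best
            summary_lines.append(
                f"driver subset ({cfg.driver_treatment}): size={best['size']} "
                f"r={best['r']:.3f} "
                f"PERMANOVA(time) R2={best.get('permanova_r2', float('nan')):.3f} "
                f"p={best.get('permanova_p', float('nan')):.4g}"
            )
            # best-subset regressions of scalar community properties
            alpha = dv.alpha_diversity_table(table)
            reg_out = {}
            for resp in ("richness", "shannon"):
                y = alpha.loc[non_fsc, resp]
                reg = dr.best_subset_regression(y, meta)
                reg_out[resp] = {
                    "selected": {k: float(v)
                                 for k, v in reg.selected["coef"].items()},
                    "criterion": reg.criterion,
                    "criterion_value": reg.criterion_value,
                    "r_squared": reg.r_squared,
                }
            with open(out / "subset_regression.json", "w") as fh:
                json.dump(reg_out, fh, indent=1)
                fh.write("\n")
            finish_stage("drivers", t0)

        # ---- differential abundance ------------------------------------
        if "diffabund" in enabled:
            t0 = time.perf_counter()
            ga, gb = cfg.diffabund_groups
            da = dr.differential_abundance(table, meta, ga, gb)
            da.table.to_csv(out / "differential_abundance.tsv", sep="\t",
                            index_label="taxon")
            n_sig = int(da.table["significant"].sum())
            summary_lines.append(
                f"differential abundance {ga} vs {gb}: "
                f"{n_sig} taxa at q<0.05"
            )
            finish_stage("diffabund", t0)

        # ---- robustness -------------------------------------------------
        if "robustness" in enabled:
            t0 = time.perf_counter()
            seed = cfg.stage_seed("robustness")
            rob = rb.treatment_robustness(
                table, meta, G, grid=cfg.robustness_grid,
                R=cfg.robustness_reps, seed=seed,
            )
            tidy = rob.drop(columns=["result"])
            tidy.to_csv(out / "attenuation.tsv", sep="\t", index=False)
            pw_rows = []
            for _, row in rob.iterrows():
                pa = row["result"].pathway_alpha
                for pw_name, prow in pa.iterrows():
                    pw_rows.append({
                        "treatment": row["treatment"], "day": row["day"],
                        "pathway": pw_name, "alpha": prow["alpha"],
                    })
            pd.DataFrame(pw_rows).to_csv(out / "pathway_attenuation.tsv",
                                         sep="\t", index=False)
            end = rob[rob["day"] == cfg.robustness_day]
            for _, row in end.sort_values("alpha").iterrows():
                summary_lines.append(
                    f"attenuation {row['treatment']} day {cfg.robustness_day}: "
                    f"alpha={row['alpha']:.2f}"
                )
            finish_stage("robustness", t0)

        # ---- chemistry --------------------------------------------------
        if "chemistry" in enabled:
            t0 = time.perf_counter()
            seed = cfg.stage_seed("chemistry")
            peaks = ch.simulate_peak_table(seed=seed)
            rt = ch.biomarker_ratios(peaks)
            rt.per_sample.to_csv(out / "biomarker_ratios.tsv", sep="\t",
                                 index_label="sample_id")
            rt.group_stats.to_csv(out / "biomarker_group_stats.tsv",
                                  sep="\t", index=False)
            tests = [
                ch.compare_ratio_over_time(rt, "Pr/nC17", tr, 14, 28)
                for tr in ("WAF", "BEWAF", "CEWAF")
            ]
            with open(out / "chemistry_tests.json", "w") as fh:
                json.dump(tests, fh, indent=1, default=float)
                fh.write("\n")
            for rec in tests:
                summary_lines.append(
                    f"Pr/nC17 {rec['treatment']} d14->d28: "
                    f"diff={rec['difference']:+.3f} p={rec['p']:.3g} "
                    f"({rec['direction']})"
                )
            finish_stage("chemistry", t0)

        # timings go to the stderr log only, keeping the manifest
        # byte-identical across reruns with the same master seed
        manifest["summary"] = summary_lines
        core_io.write_manifest(out / "manifest.json", **manifest)
        with open(out / "summary.txt", "w") as fh:
            fh.write("\n".join(summary_lines) + "\n")
        _log(f"run complete in {time.perf_counter() - t_all:.1f}s")
        return manifest
    except Exception as e:  # noqa: BLE001 - record failure point, re-raise
        manifest["failed_stage"] = (
            manifest["stages_run"][-1] + "+1" if manifest["stages_run"]
            else "inputs"
        )
        manifest["error"] = str(e)
        core_io.write_manifest(out / "manifest.json", **manifest)
        raise
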