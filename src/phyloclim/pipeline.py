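"""End-to-end orchestration: simulate/load -> clean -> climate -> tests.

One global seed fans out deterministically (via ``numpy.random.SeedSequence``)
to every stochastic stage, so a run is a pure function of (inputs,
parameters, seed): re-running with the same config yields a byte-identical
results file.  Results are written as sorted-key JSON plus a plain-text
summary; logs (timestamped) go to a separate file so outputs stay
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import koppen, occurrences as occ, phylo, synthetic, traits as tr
from .grid import read_asc_dir, write_asc_dir
from .trees import as_arrays, read_tree, write_tree

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # paths (None => must simulate)
    tree: str | None = None
    traits: str | None = None
    occurrences: str | None = None
    grid: str | None = None
    outdir: str = "phyloclim_out"
    simulate: bool = False
    # parameters
    min_records: int = 10
    cell_arcmin: float = 2.5
    assign_threshold: float = 0.70
    min_node: int = 25
    map_threshold: float = 1250.0
    alpha: float = 0.05
    n_perm: int = 1000
    n_sim: int = 1000
    seed: int = 0
    # simulation scale
    n_tips: int = 183
    records_per_species: int = 120

    def __post_init__(self) -> None:
        for name in ("min_records", "cell_arcmin", "assign_threshold",
                     "min_node", "map_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in fixed order; returns the results dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    # paths are excluded so the results file depends only on data + params
    results: dict = {
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("tree", "traits", "occurrences", "grid", "outdir")
        }
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8) % (2**31 - 1)

    try:
        stage = "inputs"
        if config.simulate:
            tree = synthetic.simulate_yule_tree(
                config.n_tips, seed=int(seeds[0])
            )
            grid = synthetic.simulate_climate_grid(seed=int(seeds[1]))
            sim_cfg = synthetic.SimConfig(
                n_tips=config.n_tips,
                records_per_species=config.records_per_species,
                seed=int(seeds[2]),
            )
            ta = as_arrays(tree)
            records, trait_table, sim_info = synthetic.simulate_occurrences(
                ta.tip_labels, grid, sim_cfg, seed=int(seeds[2])
            )
            results["simulation"] = {
                "n_base_records": sim_info["n_base_records"],
                "n_duplicates": sim_info["n_duplicates"],
                "n_undersampled_species": len(sim_info["undersampled_species"]),
            }
            write_tree(tree, outdir / "tree.nwk")
            records.to_csv(outdir / "occurrences.csv", index=False)
            trait_table.to_csv(outdir / "traits.csv", index=False)
            write_asc_dir(grid, outdir / "grid")
        else:
            for name in ("tree", "traits", "occurrences", "grid"):
                if getattr(config, name) is None:
                    raise FileNotFoundError(f"missing input path {name!r}")
            tree = read_tree(config.tree)
            trait_table = pd.read_csv(config.traits)
            records = occ.read_occurrences(config.occurrences)
            grid = read_asc_dir(config.grid)
            ta = as_arrays(tree)

        stage = "filter"
        kept, report = occ.filter_occurrences(
            records, min_records=config.min_records, cell_arcmin=config.cell_arcmin
        )
        results["filter"] = {
            "n_input": report.n_input,
            "n_removed_basis": report.n_removed_basis,
            "n_removed_duplicate": report.n_removed_duplicate,
            "n_removed_sparse_species": report.n_removed_sparse_species,
            "n_kept": report.n_kept,
            "n_species_kept": len(report.species_kept),
        }

        stage = "bioclim"
        annotated = occ.extract_bioclim(kept, grid)
        medians = occ.species_climate_medians(annotated)
        results["bioclim"] = {"n_species_with_climate": len(medians)}

        stage = "koppen"
        cats = koppen.classify_grid(grid)
        assign = {}
        for sp, sub in annotated.dropna(subset=["MAT"]).groupby("species"):
            cells = {
                (int(i), int(j)): cats[int(i), int(j)]
                for i, j in zip(sub["cell_i"], sub["cell_j"])
            }
            assign[sp] = koppen.assign_species_climate(
                cells, threshold=config.assign_threshold
            )
        group_counts: dict[str, int] = {}
        n_na = 0
        for cat, grp in assign.values():
            if grp is None:
                n_na += 1
            else:
                group_counts[grp] = group_counts.get(grp, 0) + 1
        results["climate_groups"] = {
            "counts": dict(sorted(group_counts.items())),
            "n_na": n_na,
            "n_assigned": len(assign) - n_na,
        }

        stage = "crosstab"
        trait_table = trait_table.set_index("species", drop=False)
        leaf_bin = tr.collapse_leaf_binary(trait_table["leaf_type"])
        grp_series = pd.Series(
            {sp: g for sp, (c, g) in assign.items() if g is not None}
        )
        common = grp_series.index.intersection(leaf_bin.index)
        if len(common) and grp_series[common].nunique() > 1:
            ct = tr.crosstab(leaf_bin[common], grp_series[common])
            results["crosstab"] = {
                "observed": ct.observed,
                "chi2": ct.chi2,
                "df": ct.df,
                "p": ct.p,
                "posthoc": ct.posthoc,
            }
        else:
            results["crosstab"] = "not available"

        stage = "regression"
        model_species = [
            sp for sp in ta.tip_labels if sp in medians.index and sp in leaf_bin.index
        ]
        if len(model_species) < 3:
            raise ValueError("fewer than 3 species with tree, trait and climate data")
        # phylogenetic stages run on the tree pruned to analysable species
        tree_model = tree.extract_tree_with_taxa_labels(model_species)
        ta_m = as_arrays(tree_model)
        med = medians.loc[model_species]
        y = leaf_bin.loc[model_species].to_numpy()
        Z, transforms = occ.standardize_predictors(med)
        vif = occ.compute_vif(Z)
        results["predictors"] = {
            "transforms": transforms,
            "vif": vif,
            "n_species": len(model_species),
        }
        # response: simple leaves (1 = simple) against climate
        y_simple = 1 - y
        glm_res = tr.glm_logistic(y_simple, Z)
        firth_res = tr.firth_logistic(y_simple, Z)
        results["glm"] = {"coef": glm_res.coef, "p": glm_res.p,
                          "converged": glm_res.converged}
        results["firth"] = {"coef": firth_res.coef, "p": firth_res.p}

        stage = "partition"
        part = tr.cart_partition(y_simple, med[list(occ.BIOCLIM_VARS)],
                                 min_node=config.min_node)
        results["partition"] = {"tree": part.describe(), "n_leaves": len(part.leaves())}
        rf = tr.random_forest_importance(y_simple, Z, seed=int(seeds[3]))
        results["random_forest_importance"] = rf

        stage = "ploidy"
        if "chromosome_2n" in trait_table.columns:
            counts = {"diploid": 0, "tetraploid": 0, "polyploid_other": 0}
            n_counted = 0
            for v in trait_table["chromosome_2n"].dropna():
                try:
                    counts[tr.classify_ploidy(int(v))] += 1
                    n_counted += 1
                except ValueError:
                    pass
            results["ploidy"] = {"counts": counts, "n_with_counts": n_counted}
        else:
            results["ploidy"] = "not available"

        stage = "mk_models"
        leaf_states = trait_table.loc[
            [sp for sp in ta_m.tip_labels if sp in trait_table.index], "leaf_type"
        ].to_dict()
        missing = [sp for sp in ta_m.tip_labels if sp not in leaf_states]
        if missing:
            raise ValueError(f"tree tips without trait data: {missing[:5]}")
        fits = [
            phylo.fit_mk(ta_m, leaf_states, model=m, seed=int(seeds[4]))
            for m in phylo.MODELS
        ]
        best = phylo.select_model_aic(fits)
        results["mk_aic"] = {
            f.model: {"lnL": f.lnl, "AIC": f.aic, "free_rates": f.n_free}
            for f in fits
        }
        results["mk_best_model"] = best.model

        stage = "asr"
        bin_states = {sp: int(leaf_bin[sp]) for sp in ta_m.tip_labels}
        bin_fit = phylo.fit_mk(ta_m, bin_states, model="SYM", seed=int(seeds[4]))
        asr = phylo.marginal_asr(ta_m, bin_fit, tip_states=bin_states)
        trans = phylo.count_transitions(ta_m, asr, tip_states=bin_states)
        results["transitions"] = {f"{a}->{b}": n for (a, b), n in sorted(trans.items())}

        stage = "dstat"
        if 0 < sum(bin_states.values()) < len(bin_states):
            d = phylo.phylo_d(ta_m, bin_states, n_perm=config.n_perm,
                              n_sim=config.n_sim, seed=int(seeds[5]))
            results["phylo_d"] = {
                "D": d.D, "d_obs": d.d_obs,
                "mean_d_random": d.mean_d_random,
                "mean_d_brownian": d.mean_d_brownian,
                "p_random": d.p_random, "p_brownian": d.p_brownian,
            }
        else:
            results["phylo_d"] = "not available"

        stage = "pglmm"
        ymat = np.array([bin_states[sp] for sp in ta_m.tip_labels], dtype=float)
        zmap = Z["MAP"].reindex(ta_m.tip_labels)
        if zmap.notna().all():
            pg = phylo.binary_pglmm(ta_m, ymat, pd.DataFrame({"MAP": zmap}))
            results["pglmm"] = {"coef": pg.coef, "p": pg.p, "s2": pg.s2,
                                "converged": pg.converged}
        else:
            results["pglmm"] = "not available"

        stage = "recoding"
        map_by_sp = med["MAP"].to_dict()
        if all(sp in map_by_sp for sp in ta_m.tip_labels):
            rec = phylo.recoding_experiment(
                ta_m, bin_states, map_by_sp,
                map_threshold=config.map_threshold, alpha=config.alpha,
                seed=int(seeds[6]),
            )
            results["recoding"] = {
                "baseline_transitions": rec.baseline_transitions,
                "baseline_p": rec.baseline_p,
                "achieved": rec.achieved,
                "transitions_needed": rec.transitions_needed,
                "n_recoded": rec.n_recoded,
                "trajectory": rec.trajectory,
            }
        else:
            results["recoding"] = "not available"

        stage = "report"
        write_report(results, outdir)
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        log.removeHandler(fh)
        raise StageError(stage, exc) from exc
    log.removeHandler(fh)
    return results


def write_report(results: dict, outdir) -> None:
    """Write the machine-readable JSON and the plain-text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(results)
    with open(outdir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = ["phyloclim pipeline summary", "=" * 26, ""]

    def section(title, body):
        lines.append(title)
        lines.append("-" * len(title))
        if isinstance(body, str) and body == "not available":
            lines.append("not available")
        else:
            lines.append(json.dumps(_jsonable(body), indent=2, sort_keys=True))
        lines.append("")

    for key in (
        "simulation", "filter", "bioclim", "climate_groups", "crosstab",
        "predictors", "glm", "firth", "partition",
        "random_forest_importance", "ploidy", "mk_aic", "mk_best_model",
        "transitions", "phylo_d", "pglmm", "recoding",
    ):
        if key in results:
            section(key, results[key])
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("\n".join(lines))
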