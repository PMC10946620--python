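"""End-to-end orchestration: synthetic data -> popgen -> demography -> DE ->
parallelism -> cRDA -> FST scan, from a single YAML config.

Every stochastic stage gets a seed derived from the master seed, all
parameters and output checksums are written to a run manifest, and
re-running an unchanged config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import crda as crda_mod
from . import demography, expression, parallelism, popgen
from .simulate import ExpressionScenario, GeneticScenario, gen_expression, gen_genetic, study_model

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "expression": {
        "n_genes": 2000, "reps": 3, "frac_de": 0.05, "frac_shared": 0.02,
        "logfc_mean": 2.0, "logfc_sd": 0.5, "dispersion": 0.1,
    },
    "genetic": {
        "topology": "two_origins", "mode": "SI", "n_loci": 3000,
        "sample_size": 6, "locus_length": 200.0,
    },
    "demography": {
        "enabled": True, "topologies": ["one_origin", "two_origins"],
        "modes": ["SI"], "n_restarts": 1, "n_sims": 1500, "maxiter": 60,
    },
    "de": {"fdr": 0.05},
    "parallelism": {"n_perm": 300},
    "crda": {"n_perm": 199, "thresholds": [2.0, 2.6]},
    "fst": {"alpha": 0.05, "n_perm": 500},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            sub = dict(default)
            extra = set(user.get(key, {})) - set(default)
            if extra:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(extra)}")
            sub.update(user.get(key, {}))
            cfg[key] = sub
        else:
            cfg[key] = user.get(key, default)
    return cfg


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    stage_seed = {name: master + i for i, name in enumerate(
        ["expression", "genetic", "demography", "de", "parallelism", "crda", "fst"]
    )}
    manifest = {"config": cfg, "seeds": stage_seed, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "stages": {}}
    summary: list[str] = ["# Pipeline summary", ""]

    def finish_stage(name: str, files: list[Path]):
        manifest["stages"][name] = {
            "outputs": {f.name: _sha1(f) for f in files},
        }

    # --- synthetic expression data -------------------------------------
    scen = ExpressionScenario(seed=stage_seed["expression"], **cfg["expression"])
    experiment, truth, _ = gen_expression(scen)
    counts_f = out / "counts.tsv"
    samples_f = out / "samples.tsv"
    truth_f = out / "expression_truth.tsv"
    experiment.counts.to_csv(counts_f, sep="\t")
    experiment.samples.to_csv(samples_f, sep="\t")
    truth.to_csv(truth_f, sep="\t", index=False)
    finish_stage("expression_sim", [counts_f, samples_f, truth_f])

    # --- synthetic genetic data ----------------------------------------
    gcfg = cfg["genetic"]
    model = study_model(gcfg["topology"], gcfg["mode"], gcfg["sample_size"])
    gscen = GeneticScenario(model=model, n_loci=gcfg["n_loci"],
                            locus_length=gcfg["locus_length"],
                            seed=stage_seed["genetic"])
    counts_tbl, jsfs, _ = gen_genetic(gscen, out_dir=out / "genetic")
    finish_stage("genetic_sim", sorted((out / "genetic").iterdir()))

    # --- popgen summaries ----------------------------------------------
    pg_rows = []
    for (a, b), spec in jsfs.items():
        pg_rows.append({"pop1": a, "pop2": b,
                        "weighted_fst": popgen.weighted_fst(spec),
                        "polymorphic_sites": spec.n_sites})
    pg = pd.DataFrame(pg_rows)
    pg_f = out / "pairwise_fst.tsv"
    pg.to_csv(pg_f, sep="\t", index=False)
    finish_stage("popgen", [pg_f])
    summary += ["## Pairwise weighted FST", pg.to_string(index=False), ""]

    # --- demographic model selection ------------------------------------
    dcfg = cfg["demography"]
    if dcfg["enabled"]:
        fits = []
        for topo in dcfg["topologies"]:
            for mode in dcfg["modes"]:
                fits.append(demography.fit_model(
                    jsfs, topo, mode,
                    n_restarts=dcfg["n_restarts"], n_sims=dcfg["n_sims"],
                    seed=stage_seed["demography"], maxiter=dcfg["maxiter"],
                ))
        sel = demography.model_select(fits)
        sel_f = out / "model_selection.tsv"
        sel.to_csv(sel_f, sep="\t", index=False)
        finish_stage("demography", [sel_f])
        summary += ["## Demographic model selection (delta AIC)",
                    sel.to_string(index=False), ""]

    # --- differential expression ----------------------------------------
    filtered = expression.filter_cpm(experiment)
    filtered = expression.ExpressionExperiment(
        filtered.counts, filtered.samples, expression.tmm_factors(filtered)
    )
    de_res = expression.fit_test(filtered)
    de_f = out / "de_results.tsv"
    de_res.table.to_csv(de_f, sep="\t", index=False)
    sets = expression.deg_sets(de_res, fdr=cfg["de"]["fdr"])
    sets_f = out / "deg_sets.tsv"
    pd.DataFrame(
        [(nm, g) for nm, s in sets.sets.items() for g in sorted(s)],
        columns=["set_name", "gene_id"],
    ).to_csv(sets_f, sep="\t", index=False)
    finish_stage("de", [de_f, sets_f])
    n_deg = {nm: len(s) for nm, s in sorted(sets.sets.items())}
    summary += ["## DEG counts per pair x direction",
                "\n".join(f"- {k}: {v}" for k, v in n_deg.items()), ""]

    # --- parallelism -----------------------------------------------------
    over = [nm for nm in sets.sets if nm.endswith("over_in_M")]
    under = [nm for nm in sets.sets if nm.endswith("under_in_M")]
    rep = parallelism.overlap_report(sets)
    rep_f = out / "overlap_report.tsv"
    rep.to_csv(rep_f, sep="\t", index=False)
    part_over = parallelism.sharing_partition(sets, over)
    part_under = parallelism.sharing_partition(sets, under)
    glob = {}
    for nm, group in (("over_in_M", over), ("under_in_M", under)):
        try:
            glob[nm] = parallelism.c_hyper_global(
                sets, n_perm=cfg["parallelism"]["n_perm"],
                seed=stage_seed["parallelism"], set_names=group)
        except ValueError as err:
            glob[nm] = {"error": str(err)}
    par_f = out / "parallelism.json"
    par_f.write_text(json.dumps({
        "sharing_over_in_M": {str(k): v for k, v in part_over["exactly"].items()},
        "sharing_under_in_M": {str(k): v for k, v in part_under["exactly"].items()},
        "c_hyper_global": glob,
    }, indent=2, default=float))
    finish_stage("parallelism", [rep_f, par_f])
    summary += ["## Sharing partition (genes in exactly k pairs, overexpressed in M)",
                json.dumps({str(k): v for k, v in part_over["exactly"].items()}), ""]

    # --- cRDA ------------------------------------------------------------
    cpm = filtered.cpm(use_tmm=True)
    res = crda_mod.crda_fit(cpm, filtered.samples["ecotype"], filtered.samples["pair"])
    anova = crda_mod.crda_anova(
        cpm, filtered.samples["ecotype"], filtered.samples["pair"],
        n_perm=cfg["crda"]["n_perm"], seed=stage_seed["crda"],
    )
    outliers = crda_mod.crda_outliers(res, tuple(cfg["crda"]["thresholds"]))
    crda_f = out / "crda.json"
    crda_f.write_text(json.dumps({
        "fraction_conditioned": res.fraction_conditioned,
        "fraction_constrained": res.fraction_constrained,
        "fraction_unconstrained": res.fraction_unconstrained,
        "pseudo_F": res.pseudo_F,
        "anova_p": anova["p_value"],
        "n_outliers": {str(t): len(v) for t, v in outliers.items()},
    }, indent=2))
    scores_f = out / "crda_scores.tsv"
    pd.DataFrame({"score": res.gene_scores, "z": res.gene_z}).to_csv(scores_f, sep="\t")
    finish_stage("crda", [crda_f, scores_f])
    summary += ["## cRDA",
                f"constrained fraction = {res.fraction_constrained:.4f}, "
                f"ANOVA p = {anova['p_value']:.3f}", ""]

    # --- FST scan on the two well-sampled pairs --------------------------
    fcfg = cfg["fst"]
    names = model.deme_names
    scan_pairs = [(names[0], names[1], "pair1"), (names[2], names[3], "pair3")]
    outlier_sets = {}
    fst_tables = {}
    for a, b, label in scan_pairs:
        tbl = popgen.fst_gene(counts_tbl, a, b)
        tbl = popgen.top_fraction_outliers(tbl, alpha=fcfg["alpha"])
        tbl.to_csv(out / f"fst_{label}.tsv", sep="\t")
        fst_tables[label] = tbl
        outlier_sets[label] = set(tbl.index[tbl["outlier"]])
    common_bg = sorted(
        set(fst_tables["pair1"].index[fst_tables["pair1"]["fst"].notna()])
        & set(fst_tables["pair3"].index[fst_tables["pair3"]["fst"].notna()])
    )
    o1 = outlier_sets["pair1"] & set(common_bg)
    o3 = outlier_sets["pair3"] & set(common_bg)
    x = len(o1 & o3)
    fst_stats = {
        "n_outliers_pair1": len(outlier_sets["pair1"]),
        "n_outliers_pair3": len(outlier_sets["pair3"]),
        "shared_outliers_common_background": x,
        "hypergeom_p": parallelism.hypergeom_overlap(
            x, len(o1), len(o3), len(common_bg)) if min(len(o1), len(o3)) else 1.0,
        "jaccard": parallelism.jaccard(o1, o3),
    }
    fst_json = out / "fst_scan.json"
    fst_json.write_text(json.dumps(fst_stats, indent=2))
    finish_stage("fst", [out / "fst_pair1.tsv", out / "fst_pair3.tsv", fst_json])
    summary += ["## FST outlier scan", json.dumps(fst_stats), ""]

    (out / "summary.md").write_text("\n".join(summary))
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
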