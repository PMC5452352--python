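"""Stage orchestration: simulate -> events -> dis -> enrich -> chromatin ->
phenotype -> report, with a run manifest.

Every stage reads and writes plain-text files in the output directory, so a
re-run with an unchanged config and seed reproduces the outputs
byte-identically (the manifest, which carries wall-clock timestamps, is the
one exception).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import as_events, chromatin, expression_enrichment, phenotype, psi_dis
from .io_formats import read_bed, read_gtf, write_bed, write_gtf, write_table
from .synthetic_data import CONDITIONS, SimConfig, generate_all

__all__ = ["PipelineError", "run_pipeline", "load_config", "DEFAULT_ANALYSIS"]

DEFAULT_ANALYSIS = {
    "seed": 1337,
    "bf_threshold": 5.0,   # minimum Bayes factor for significance
    "min_reads": 20,       # isoform-specific reads per qualifying replicate
    "min_reps": 2,         # qualifying replicates per condition
    "n_draws": 100_000,    # posterior draws for the Savage-Dickey density
    "lfc_threshold": 1.0,  # |log2FC| for DEG calling
    "alpha": 0.05,         # BH-adjusted significance level
    "min_term_genes": 5,   # study hits for a reported enrichment term
    "overlap_mode": "containment",
    "distance_overlap_mode": "any",
}

STAGES = ["simulate", "events", "dis", "enrich", "chromatin", "phenotype",
          "report"]


class PipelineError(RuntimeError):
    pass


def load_config(config) -> dict:
    """Accept a dict or a YAML path; validate keys before any stage runs."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - {"sim", "analysis"}
    if unknown:
        raise PipelineError(f"unknown config section(s): {sorted(unknown)}")
    sim = SimConfig.from_dict(config.get("sim", {}))
    analysis = dict(DEFAULT_ANALYSIS)
    bad = set(config.get("analysis", {})) - set(DEFAULT_ANALYSIS)
    if bad:
        raise PipelineError(f"unknown analysis key(s): {sorted(bad)}")
    analysis.update(config.get("analysis", {}))
    return {"sim": sim, "analysis": analysis}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage '{stage}': missing input file {path}")
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg, out: Path, manifest):
    bundle = generate_all(cfg["sim"])
    write_gtf(bundle["genes"], out / "genes.gtf")
    for genotype, df in bundle["event_counts"].items():
        write_table(df, out / f"counts_{genotype}.tsv")
    for cond in CONDITIONS:
        write_bed(bundle["mark_regions"][cond], out / f"marks_{cond}.bed")
        bundle["tracks"][cond].to_bedgraph(out / f"track_{cond}.bedgraph")
    expr = bundle["expression"].rename_axis("gene_id").reset_index()
    write_table(expr, out / "expression.tsv")
    write_table(bundle["phenotype"], out / "phenotype.tsv")
    write_table(bundle["term_map"], out / "term_map.tsv")
    write_table(bundle["truth"].events, out / "truth_events.tsv")
    write_table(bundle["truth"].genes, out / "truth_genes.tsv")
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({"sim": cfg["sim"].to_dict(),
                        "analysis": cfg["analysis"]}, fh, sort_keys=True)
    manifest["row_counts"]["simulate"] = {
        "genes": len(bundle["genes"]),
        "events_truth": len(bundle["truth"].events),
    }


def _stage_events(cfg, out: Path, manifest):
    gtf = _require(out / "genes.gtf", "events")
    genes = read_gtf(gtf)
    events = [ev for g in genes for ev in as_events.enumerate_events(g)]
    write_table(as_events.events_to_frame(events), out / "events.tsv")
    manifest["inputs"]["events"] = {str(gtf): _digest(gtf)}
    manifest["row_counts"]["events"] = len(events)


def _stage_dis(cfg, out: Path, manifest):
    ana = cfg["analysis"]
    genotypes = list(cfg["sim"].genotypes)
    events_path = _require(out / "events.tsv", "dis")
    events = pd.read_csv(events_path, sep="\t")
    known = set(events["event_id"])
    manifest["inputs"]["dis"] = {str(events_path): _digest(events_path)}
    results: dict[str, pd.DataFrame] = {}
    for genotype in genotypes:
        cpath = _require(out / f"counts_{genotype}.tsv", "dis")
        manifest["inputs"]["dis"][str(cpath)] = _digest(cpath)
        counts = pd.read_csv(cpath, sep="\t")
        counts = counts[counts["event_id"].isin(known)]
        results[genotype] = psi_dis.call_dis_table(
            counts, CONDITIONS[0], CONDITIONS[1],
            bf_threshold=ana["bf_threshold"], min_reads=ana["min_reads"],
            min_reps=ana["min_reps"], n_draws=ana["n_draws"],
            seed=ana["seed"], label=genotype)
        write_table(results[genotype], out / f"dis_{genotype}.tsv")
    wt = genotypes[0]
    mutants = genotypes[1:]
    by_id = {g: results[g].set_index("event_id") for g in genotypes}
    dep_rows = []
    for event_id, row in by_id[wt].iterrows():
        sig_wt = bool(row["significant"])
        mut_sigs = [bool(by_id[m].loc[event_id, "significant"])
                    for m in mutants if event_id in by_id[m].index]
        if sig_wt and mut_sigs and not any(mut_sigs):
            call = "dependent"
        elif sig_wt and mut_sigs and all(mut_sigs):
            call = "independent"
        else:
            call = "unclassified"
        dep_rows.append({"event_id": event_id, "wt_significant": sig_wt,
                         "dependence": call})
    write_table(pd.DataFrame(dep_rows), out / "dependence_calls.tsv")
    sig_ids = by_id[wt].index[by_id[wt]["significant"]]
    ks_rows = []
    for m in mutants:
        shared = [e for e in sig_ids if e in by_id[m].index]
        if shared:
            cmp = psi_dis.delta_psi_ecdf_compare(
                by_id[wt].loc[shared, "delta_psi"].abs(),
                by_id[m].loc[shared, "delta_psi"].abs())
            ks_rows.append({"mutant": m, "n_events": len(shared),
                            "ks_statistic": cmp.statistic,
                            "p_value": cmp.p_value})
    write_table(pd.DataFrame(ks_rows,
                             columns=["mutant", "n_events", "ks_statistic",
                                      "p_value"]),
                out / "ks_summary.tsv")
    manifest["row_counts"]["dis"] = {g: len(results[g]) for g in genotypes}


def _stage_enrich(cfg, out: Path, manifest):
    ana = cfg["analysis"]
    expr_path = _require(out / "expression.tsv", "enrich")
    dis_path = _require(out / f"dis_{list(cfg['sim'].genotypes)[0]}.tsv", "enrich")
    events_path = _require(out / "events.tsv", "enrich")
    term_path = _require(out / "term_map.tsv", "enrich")
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    groups = {c: c.split("_")[0] for c in expr.columns}
    deg = expression_enrichment.call_deg(
        expr, groups, CONDITIONS[0], CONDITIONS[1],
        lfc_threshold=ana["lfc_threshold"], alpha=ana["alpha"])
    write_table(deg, out / "deg.tsv")
    events = pd.read_csv(events_path, sep="\t")
    dis = pd.read_csv(dis_path, sep="\t")
    sig_events = set(dis.loc[dis["significant"], "event_id"])
    dis_genes = sorted(set(
        events.loc[events["event_id"].isin(sig_events), "gene_id"]))
    deg_genes = sorted(set(deg.loc[deg["is_deg"], "gene_id"]))
    n_dis, n_deg, n_both = expression_enrichment.overlap_sets(dis_genes, deg_genes)
    with open(out / "overlap.json", "w") as fh:
        json.dump({"dis_only": n_dis, "deg_only": n_deg, "both": n_both}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    term_df = pd.read_csv(term_path, sep="\t")
    term_map = {t: set(g["gene_id"]) for t, g in term_df.groupby("term_id")}
    population = set(expr.index)
    enr = expression_enrichment.hypergeom_enrichment(
        set(dis_genes) & population, population, term_map,
        alpha=ana["alpha"], min_genes=ana["min_term_genes"])
    write_table(pd.DataFrame([e.__dict__ for e in enr]), out / "enrichment.tsv")
    manifest["row_counts"]["enrich"] = {
        "deg": int(deg["is_deg"].sum()), "dis_genes": len(dis_genes),
        "terms_tested": len(enr)}


def _stage_chromatin(cfg, out: Path, manifest):
    ana = cfg["analysis"]
    genes = read_gtf(_require(out / "genes.gtf", "chromatin"))
    regions = {c: read_bed(_require(out / f"marks_{c}.bed", "chromatin"), c)
               for c in CONDITIONS}
    all_regions = regions["16C"] + regions["25C"]
    annotations = chromatin.associate_regions(genes, all_regions,
                                              mode=ana["overlap_mode"])
    ann_by_id = {a.gene_id: a for a in annotations}
    wt = list(cfg["sim"].genotypes)[0]
    dis = pd.read_csv(_require(out / f"dis_{wt}.tsv", "chromatin"), sep="\t")
    events = pd.read_csv(_require(out / "events.tsv", "chromatin"), sep="\t")
    deg = pd.read_csv(_require(out / "deg.tsv", "chromatin"), sep="\t")
    sig_events = set(dis.loc[dis["significant"], "event_id"])
    dis_genes = sorted(set(events.loc[events["event_id"].isin(sig_events),
                                      "gene_id"]))
    deg_genes = sorted(set(deg.loc[deg["is_deg"], "gene_id"]) - set(dis_genes))
    other = sorted(set(g.gene_id for g in genes) - set(dis_genes) - set(deg_genes))
    frac_rows = []
    for label, gene_set in (("DiS", dis_genes), ("DEG", deg_genes),
                            ("other", other)):
        if gene_set:
            frac_rows.append({
                "gene_class": label, "n_genes": len(gene_set),
                "fraction_marked": chromatin.fraction_marked(gene_set,
                                                             annotations)})
    write_table(pd.DataFrame(frac_rows), out / "fractions.tsv")

    classes = {g: "DiS" for g in dis_genes}
    classes.update({g: "DEG" for g in deg_genes})
    classes.update({g: "other" for g in other})
    prof_rows = []
    for cond in CONDITIONS:
        track = chromatin.OccupancyTrack.from_bedgraph(
            _require(out / f"track_{cond}.bedgraph", "chromatin"),
            bin_size=cfg["sim"].track_step)
        for anchor in ("TSS", "TTS"):
            profiles = chromatin.metagene_profile(track, genes, anchor=anchor,
                                                  classes=classes)
            for label, prof in sorted(profiles.items()):
                for off, sig in zip(prof.offsets, prof.mean_signal):
                    prof_rows.append({"condition": cond, "anchor": anchor,
                                      "gene_class": label, "offset": off,
                                      "mean_signal": sig,
                                      "n_genes": prof.n_genes})
    write_table(pd.DataFrame(prof_rows), out / "profiles.tsv")

    dep = pd.read_csv(_require(out / "dependence_calls.tsv", "chromatin"),
                      sep="\t")
    ev_by_id = {}
    for g in genes:
        for ev in as_events.enumerate_events(g):
            ev_by_id[ev.event_id] = ev
    dist_ann = {a.gene_id: a for a in chromatin.associate_regions(
        genes, all_regions, mode=ana["distance_overlap_mode"])}
    dist_rows = []
    for row in dep.itertuples(index=False):
        if row.dependence not in ("dependent", "independent"):
            continue
        ev = ev_by_id.get(row.event_id)
        if ev is None:
            continue
        d = chromatin.event_region_distance(ev, dist_ann[ev.gene_id])
        dist_rows.append({"event_id": row.event_id,
                          "dependence": row.dependence,
                          "distance_bp": d if d is not None else ""})
    dist_df = pd.DataFrame(dist_rows,
                           columns=["event_id", "dependence", "distance_bp"])
    write_table(dist_df, out / "distances.tsv")

    summary = {}
    dep_d = [r["distance_bp"] for r in dist_rows
             if r["dependence"] == "dependent" and r["distance_bp"] != ""]
    ind_d = [r["distance_bp"] for r in dist_rows
             if r["dependence"] == "independent" and r["distance_bp"] != ""]
    if dep_d and ind_d:
        u, p = chromatin.compare_distance_distributions(dep_d, ind_d)
        summary["distance_test"] = {"u_statistic": u, "p_value": p,
                                    "n_dependent": len(dep_d),
                                    "n_independent": len(ind_d)}
    widths = chromatin.compare_region_widths(regions["16C"], regions["25C"])
    summary["region_widths"] = {
        "median_16C": widths.median_a, "median_25C": widths.median_b,
        "ratio": widths.ratio, "p_value": widths.p_value}
    t16 = chromatin.OccupancyTrack.from_bedgraph(out / "track_16C.bedgraph",
                                                 bin_size=cfg["sim"].track_step)
    t25 = chromatin.OccupancyTrack.from_bedgraph(out / "track_25C.bedgraph",
                                                 bin_size=cfg["sim"].track_step)
    summary["track_correlation_1kb"] = chromatin.binned_track_correlation(t16, t25)
    with open(out / "chromatin_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["row_counts"]["chromatin"] = {
        "regions": len(all_regions), "distances": len(dist_rows)}


def _stage_phenotype(cfg, out: Path, manifest):
    pheno = pd.read_csv(_require(out / "phenotype.tsv", "phenotype"), sep="\t")
    genotypes = sorted(pheno["genotype"].unique())
    wt = list(cfg["sim"].genotypes)[0]
    rows = []
    for trait in ("DTB", "RLN"):
        summaries = {g: phenotype.response_ratio(pheno, g, trait)
                     for g in genotypes}
        for g in genotypes:
            s = summaries[g]
            row = {"genotype": g, "trait": trait,
                   "mean_ratio": s.mean_ratio,
                   "per_tray_ratios": ",".join(f"{r:.6f}"
                                               for r in s.per_replicate_ratios)}
            if g != wt and wt in summaries:
                t, p = phenotype.compare_response(summaries[wt], s)
                row["t_vs_wt"], row["p_vs_wt"] = t, p
            else:
                row["t_vs_wt"], row["p_vs_wt"] = "", ""
            rows.append(row)
    write_table(pd.DataFrame(rows), out / "phenotype_summary.tsv")
    manifest["row_counts"]["phenotype"] = len(rows)


def _stage_report(cfg, out: Path, manifest):
    from . import report
    report.build_report(cfg, out)
    manifest["row_counts"]["report"] = "done"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "events": _stage_events,
    "dis": _stage_dis,
    "enrich": _stage_enrich,
    "chromatin": _stage_chromatin,
    "phenotype": _stage_phenotype,
    "report": _stage_report,
}


def run_pipeline(config, out_dir, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in dependency order; returns the output dir."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = STAGES if stages is None else stages
    bad = [s for s in todo if s not in _STAGE_FUNCS]
    if bad:
        raise PipelineError(f"unknown stage(s): {bad}")
    manifest = {
        "tool": "thermosplice",
        "version": __version__,
        "config": {"sim": cfg["sim"].to_dict(), "analysis": cfg["analysis"]},
        "seeds": {"sim": cfg["sim"].seed, "analysis": cfg["analysis"]["seed"]},
        "inputs": {},
        "row_counts": {},
        "stages": list(todo),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage in STAGES:
        if stage not in todo:
            continue
        _STAGE_FUNCS[stage](cfg, out, manifest)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
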