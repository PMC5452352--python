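"""Headless summary plots and tables from a finished pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # never requires a display

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import psi_dis
from .io_formats import write_table
from .synthetic_data import CONDITIONS

__all__ = ["build_report"]


def build_report(cfg, out: Path) -> None:
    """PSI heatmap, metagene profile plot, |dPSI| ecdf plot, ratio table."""
    out = Path(out)
    genotypes = list(cfg["sim"].genotypes)
    wt = genotypes[0]
    dis = {g: pd.read_csv(out / f"dis_{g}.tsv", sep="\t").set_index("event_id")
           for g in genotypes}
    sig_ids = list(dis[wt].index[dis[wt]["significant"]])

    # heatmap matrix: significant events x genotype/condition pooled PSI
    cols = [f"{g}_{c}" for g in genotypes for c in CONDITIONS]
    mat = pd.DataFrame(index=pd.Index(sig_ids, name="event_id"), columns=cols,
                       dtype=float)
    for g in genotypes:
        for cond in CONDITIONS:
            col = f"psi_{cond}"
            mat[f"{g}_{cond}"] = dis[g].reindex(sig_ids)[col]
    write_table(mat.reset_index(), out / "heatmap_psi.tsv")
    summary = {"n_significant_events": len(sig_ids)}
    if sig_ids:
        order = np.argsort(mat[f"{wt}_{CONDITIONS[1]}"].to_numpy()
                           - mat[f"{wt}_{CONDITIONS[0]}"].to_numpy())
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(mat.to_numpy()[order], aspect="auto", cmap="viridis",
                       vmin=0, vmax=1)
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=7)
        ax.set_ylabel("significant events")
        fig.colorbar(im, ax=ax, label="PSI")
        fig.tight_layout()
        fig.savefig(out / "heatmap_psi.png", dpi=100)
        plt.close(fig)
    else:
        summary["note"] = "no significant events"

    # metagene profile (TSS anchor, 16C)
    prof_path = out / "profiles.tsv"
    if prof_path.exists():
        prof = pd.read_csv(prof_path, sep="\t")
        sub = prof[(prof["anchor"] == "TSS") & (prof["condition"] == "16C")]
        fig, ax = plt.subplots(figsize=(6, 4))
        for label, grp in sub.groupby("gene_class"):
            ax.plot(grp["offset"], grp["mean_signal"], label=label)
        ax.set_xlabel("distance from TSS (bp)")
        ax.set_ylabel("mean occupancy")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "metagene_profile.png", dpi=100)
        plt.close(fig)

    # |delta PSI| ecdf of WT-significant events, per genotype, KS-annotated
    fig, ax = plt.subplots(figsize=(6, 4))
    annotations = []
    if sig_ids:
        wt_abs = dis[wt].loc[sig_ids, "delta_psi"].abs().to_numpy()
        for g in genotypes:
            shared = [e for e in sig_ids if e in dis[g].index]
            vals = dis[g].loc[shared, "delta_psi"].abs().to_numpy()
            x = np.sort(vals)
            ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=g)
            if g != wt and len(shared):
                cmp = psi_dis.delta_psi_ecdf_compare(wt_abs, vals)
                annotations.append(f"{g}: D={cmp.statistic:.2f}, "
                                   f"p={cmp.p_value:.2g}")
    ax.set_xlim(0, 1)
    ax.set_xlabel("|delta PSI|")
    ax.set_ylabel("ecdf")
    if annotations:
        ax.text(0.55, 0.15, "\n".join(annotations), transform=ax.transAxes,
                fontsize=8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "ecdf_dpsi.png", dpi=100)
    plt.close(fig)

    # response-ratio bar table
    pheno_path = out / "phenotype_summary.tsv"
    if pheno_path.exists():
        ps = pd.read_csv(pheno_path, sep="\t")
        sub = ps[ps["trait"] == "DTB"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(sub["genotype"], sub["mean_ratio"])
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_ylabel("DTB ratio 16C / 25C")
        fig.tight_layout()
        fig.savefig(out / "response_ratio.png", dpi=100)
        plt.close(fig)

    with open(out / "report_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
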