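"""Seeded generators for every pipeline input, with truth tables.

The generators emulate the structure of a two-temperature (16C vs 25C)
splicing study in a plant transcriptome: multi-isoform genes each carrying
one engineered alternative-splicing event (intron-retention-heavy mix, as in
plants), isoform-specific read counts with condition-dependent PSI shifts
concentrated in a differentially-spliced (DiS) subset, genotype-dependent
attenuation of those shifts for histone-mark-dependent events,
mark regions peaking ~0.5 kb downstream of the TSS with condition-dependent
width plus matching occupancy tracks, negative-binomial expression counts
with a differentially-expressed (DEG) subset, and per-plant flowering
phenotypes on a 2-day screening grid.  Every generator is deterministic
given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import as_events
from .io_formats import GeneModel, MarkRegion, TranscriptModel

__all__ = ["SimConfig", "TruthTable", "gen_gene_models", "gen_event_counts",
           "gen_mark_data", "gen_expression_counts", "gen_phenotype",
           "gen_term_map", "gen_block_reads", "generate_all"]

logger = logging.getLogger(__name__)

CONDITIONS = ("16C", "25C")


@dataclass
class SimConfig:
    """Data-generating parameters; defaults are the study conditions."""

    seed: int = 1337
    n_genes: int = 300
    event_mix: dict = field(default_factory=lambda: {
        "IR": 0.40, "ES": 0.15, "A5": 0.15, "A3": 0.15, "MXE": 0.15})
    dis_fraction: float = 0.5
    dependent_fraction: float = 0.5   # of DiS events, mark-dependent share
    true_delta_psi: float = 0.3
    baseline_psi_range: tuple = (0.2, 0.6)
    depth_per_replicate: float = 100.0
    n_replicates: int = 3
    genotypes: dict = field(default_factory=lambda: {
        "WT": 0.0, "sdg8": 1.0, "sdg26": 1.0})  # name -> attenuation
    marked_fraction_by_class: dict = field(default_factory=lambda: {
        "DiS": 0.96, "DEG": 0.65, "other": 0.60})
    mark_peak_offset: int = 500      # bp downstream of TSS
    mark_width_by_condition: dict = field(default_factory=lambda: {
        "16C": 300, "25C": 450})
    mark_mode: str = "tss"           # tss | event (marks on dependent events)
    track_step: int = 10             # bp per track cell
    deg_fraction: float = 0.1
    true_lfc: float = 2.0
    nb_dispersion: float = 0.1
    phenotype_effects: dict = field(default_factory=lambda: {
        "WT": {"16C": 70.0, "25C": 50.0},
        "sdg8": {"16C": 70.0, "25C": 69.0},
        "sdg26": {"16C": 70.0, "25C": 69.0}})
    plants_per_tray: int = 15
    n_trays: int = 3
    phenotype_sd: float = 3.0
    genes_per_chrom: int = 50
    gene_gap: int = 2000
    chrom_margin: int = 2500
    min_gene_length: int = 1500

    def __post_init__(self) -> None:
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix must sum to 1")
        if not all(0 <= p <= 1 for p in self.event_mix.values()):
            raise ValueError("event_mix proportions must be in [0,1]")
        if self.depth_per_replicate <= 0 and self.depth_per_replicate != 0:
            raise ValueError("depth must be nonnegative")
        if self.mark_mode not in ("tss", "event"):
            raise ValueError("mark_mode must be 'tss' or 'event'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth emitted alongside the data, for recovery tests."""

    events: pd.DataFrame   # per-event true PSI / DiS / dependence labels
    genes: pd.DataFrame    # per-gene class / marked / DEG labels
    config: SimConfig


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng([cfg.seed, stream])


def _build_gene(rng, gene_id, chrom, strand, offset, etype_requested, cfg):
    """Two (occasionally three) exon chains containing exactly one event."""
    exon = lambda: int(rng.integers(100, 301))
    intron = lambda: int(rng.integers(80, 1001))
    ext = lambda: int(rng.integers(30, 121))
    # construct with plus-strand geometry; A5/A3 swap on the minus strand
    etype = etype_requested
    if strand == "-" and etype in ("A5", "A3"):
        etype = {"A5": "A3", "A3": "A5"}[etype]

    if etype == "IR":
        l1, l2, i1 = exon(), exon(), intron()
        end = l1 + i1 + l2
        incl = [(0, end)]
        excl = [(0, l1), (l1 + i1, end)]
        alt, fl, fr = (l1, l1 + i1), (0, l1), (l1 + i1, end)
    elif etype == "ES":
        l1, le, l3, i1, i2 = exon(), exon(), exon(), intron(), intron()
        s2, s3 = l1 + i1, l1 + i1 + le + i2
        end = s3 + l3
        incl = [(0, l1), (s2, s2 + le), (s3, end)]
        excl = [(0, l1), (s3, end)]
        alt, fl, fr = (s2, s2 + le), (0, l1), (s3, end)
    elif etype == "A5":
        l1, ex, i1, l2 = exon(), ext(), intron(), exon()
        s2 = l1 + ex + i1
        end = s2 + l2
        incl = [(0, l1 + ex), (s2, end)]
        excl = [(0, l1), (s2, end)]
        alt, fl, fr = (l1, l1 + ex), (0, l1), (s2, end)
    elif etype == "A3":
        l1, i1, ex, l2 = exon(), intron(), ext(), exon()
        s_lo, s_hi = l1 + i1, l1 + i1 + ex
        end = s_hi + l2
        incl = [(0, l1), (s_lo, end)]
        excl = [(0, l1), (s_hi, end)]
        alt, fl, fr = (s_lo, s_hi), (0, l1), (s_hi, end)
    else:  # MXE
        l1, la, lb, l4 = exon(), exon(), exon(), exon()
        i1, i2, i3 = intron(), intron(), intron()
        sa = l1 + i1
        sb = sa + la + i2
        sd = sb + lb + i3
        end = sd + l4
        incl = [(0, l1), (sa, sa + la), (sd, end)]
        excl = [(0, l1), (sb, sb + lb), (sd, end)]
        alt, fl, fr = (sa, sb + lb), (0, l1), (sd, end)

    # pad the terminal exon so every gene reaches a minimum span (keeps
    # TSS-anchored mark regions inside the gene body)
    pad = max(0, cfg.min_gene_length - end)
    if pad:
        incl = incl[:-1] + [(incl[-1][0], incl[-1][1] + pad)]
        excl = excl[:-1] + [(excl[-1][0], excl[-1][1] + pad)]
        fr = (fr[0], fr[1] + pad)
        end += pad

    shift = lambda iv: (iv[0] + offset, iv[1] + offset)
    t1 = TranscriptModel(f"{gene_id}.1", [shift(e) for e in incl])
    t2 = TranscriptModel(f"{gene_id}.2", [shift(e) for e in excl])
    transcripts = [t1, t2]
    if rng.random() < 0.3:  # redundant isoform; must not add events
        transcripts.append(TranscriptModel(f"{gene_id}.3", list(t1.exons)))
    gene = GeneModel(gene_id, chrom, strand, offset, offset + end, transcripts)
    # the classifier reports the strand-corrected (requested) type
    event_id = as_events.event_id_for_key(
        etype_requested, chrom, strand, shift(alt), shift(fl), shift(fr))
    return gene, event_id, etype_requested, shift(alt)


def gen_gene_models(cfg: SimConfig) -> tuple[list[GeneModel], TruthTable]:
    """Gene models (GTF-ready) plus the per-event / per-gene truth table."""
    rng = _rng(cfg, 1)
    types = list(cfg.event_mix)
    probs = np.array([cfg.event_mix[t] for t in types])
    genes: list[GeneModel] = []
    event_rows, gene_rows = [], []
    cursor = cfg.chrom_margin
    chrom_idx = 1
    for i in range(cfg.n_genes):
        if i and i % cfg.genes_per_chrom == 0:
            chrom_idx += 1
            cursor = cfg.chrom_margin
        chrom = f"chr{chrom_idx}"
        gene_id = f"g{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        etype_req = types[int(rng.choice(len(types), p=probs))]
        gene, event_id, etype, alt = _build_gene(
            rng, gene_id, chrom, strand, cursor, etype_req, cfg)
        cursor = gene.end + cfg.gene_gap
        genes.append(gene)
        is_dis = bool(rng.random() < cfg.dis_fraction)
        psi_a = float(rng.uniform(*cfg.baseline_psi_range))
        if is_dis:
            dependence = ("dependent" if rng.random() < cfg.dependent_fraction
                          else "independent")
            delta = cfg.true_delta_psi
        else:
            dependence, delta = "none", 0.0
        event_rows.append({
            "event_id": event_id, "gene_id": gene_id, "event_type": etype,
            "chrom": chrom, "strand": strand,
            "alt_start": alt[0], "alt_end": alt[1],
            "psi_16C": psi_a, "delta_psi_true": delta,
            "is_dis": is_dis, "dependence": dependence,
        })
        gene_rows.append({
            "gene_id": gene_id, "chrom": chrom, "strand": strand,
            "start": gene.start, "end": gene.end,
            "gene_class": "DiS" if is_dis else "other",
            "is_deg_true": False, "marked": False,
        })
    truth = TruthTable(pd.DataFrame(event_rows), pd.DataFrame(gene_rows), cfg)
    return genes, truth


def true_psi(row, condition: str, genotype: str, cfg: SimConfig) -> float:
    """Ground-truth PSI of an event for a genotype/condition cell."""
    psi = row["psi_16C"]
    if condition != "16C" and row["is_dis"]:
        shift = row["delta_psi_true"]
        if row["dependence"] == "dependent":
            shift *= 1.0 - cfg.genotypes[genotype]
        psi = psi + shift
    if not 0.0 <= psi <= 1.0:
        logger.warning("true PSI %.3f clipped to [0,1]", psi)
        psi = min(1.0, max(0.0, psi))
    return psi


def gen_event_counts(cfg: SimConfig, truth: TruthTable) -> dict[str, pd.DataFrame]:
    """Per-genotype isoform-specific count tables (replicated, both conditions).

    Per replicate the total isoform-specific depth is Poisson(depth) and the
    inclusion count Binomial(total, psi) at the genotype/condition truth PSI.
    """
    out = {}
    for gi, genotype in enumerate(cfg.genotypes):
        rng = _rng(cfg, 100 + gi)
        rows = []
        for _, ev in truth.events.iterrows():
            for condition in CONDITIONS:
                psi = true_psi(ev, condition, genotype, cfg)
                for rep in range(1, cfg.n_replicates + 1):
                    total = int(rng.poisson(cfg.depth_per_replicate))
                    n_incl = int(rng.binomial(total, psi)) if total else 0
                    rows.append({
                        "event_id": ev["event_id"],
                        "sample_id": f"{genotype}_{condition}_rep{rep}",
                        "condition": condition, "replicate": rep,
                        "n_incl": n_incl, "n_excl": total - n_incl,
                    })
        out[genotype] = pd.DataFrame(rows)
    return out


def _clamp_region(start: int, end: int, lo: int, hi: int) -> tuple[int, int]:
    """Shift an interval (width-preserving) to lie within [lo, hi)."""
    if end - start >= hi - lo:
        return lo, hi
    if start < lo:
        end += lo - start
        start = lo
    if end > hi:
        start -= end - hi
        end = hi
    return start, end


def gen_mark_data(cfg: SimConfig, truth: TruthTable, genes: list[GeneModel]
                  ) -> tuple[dict[str, list[MarkRegion]], dict]:
    """Mark regions per condition plus Gaussian-bump occupancy tracks.

    Genes are marked per-class with probability marked_fraction_by_class.
    In mark_mode='tss' regions sit mark_peak_offset bp downstream of the TSS
    (strand-aware); in mark_mode='event', genes with a mark-dependent event
    get a region centered on the event's alternative region while all other
    marked genes are anchored at the TSS.  Widths are per-condition with
    +/-10% jitter; tracks add a low seeded background.  Updates
    truth.genes['marked'] in place.
    """
    from .chromatin import OccupancyTrack

    rng = _rng(cfg, 2)
    gene_cls = truth.genes.set_index("gene_id")["gene_class"]
    ev_by_gene = truth.events.set_index("gene_id")
    chrom_len = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0),
                                 g.end + cfg.chrom_margin)
    step = cfg.track_step
    tracks = {c: {ch: np.zeros(-(-L // step)) for ch, L in chrom_len.items()}
              for c in CONDITIONS}
    regions: dict[str, list[MarkRegion]] = {c: [] for c in CONDITIONS}
    marked_flags = {}
    for g in genes:
        cls = gene_cls[g.gene_id]
        frac = cfg.marked_fraction_by_class.get(cls,
                                                cfg.marked_fraction_by_class["other"])
        marked = bool(rng.random() < frac)
        occupancy = float(rng.lognormal(1.0, 0.3))
        jitter = {c: float(rng.uniform(0.9, 1.1)) for c in CONDITIONS}
        marked_flags[g.gene_id] = marked
        if not marked:
            continue
        ev = ev_by_gene.loc[g.gene_id]
        if cfg.mark_mode == "event" and ev["dependence"] == "dependent":
            center = int((ev["alt_start"] + ev["alt_end"]) // 2)
        elif cfg.mark_mode == "event" and ev["dependence"] == "independent":
            center = g.start if g.strand != "-" else g.end  # at the TSS
        else:
            center = (g.start + cfg.mark_peak_offset if g.strand != "-"
                      else g.end - cfg.mark_peak_offset)
        for condition in CONDITIONS:
            width = int(round(cfg.mark_width_by_condition[condition]
                              * jitter[condition]))
            s, e = _clamp_region(center - width // 2, center - width // 2 + width,
                                 g.start, g.end)
            regions[condition].append(
                MarkRegion(g.chrom, s, e, occupancy, condition,
                           f"{g.gene_id}_{condition}"))
            arr = tracks[condition][g.chrom]
            sigma = max(width / 4.0, 1.0)
            mid = (s + e) / 2.0
            lo = max(0, int((mid - 4 * sigma) // step))
            hi = min(len(arr), int((mid + 4 * sigma) // step) + 1)
            coords = (np.arange(lo, hi) + 0.5) * step
            arr[lo:hi] += occupancy * np.exp(-0.5 * ((coords - mid) / sigma) ** 2)
    for condition in CONDITIONS:
        for ch in tracks[condition]:
            noise = rng.gamma(2.0, 0.01, size=len(tracks[condition][ch]))
            tracks[condition][ch] += noise
    truth.genes["marked"] = truth.genes["gene_id"].map(marked_flags)
    occ_tracks = {c: OccupancyTrack(tracks[c], bin_size=step) for c in CONDITIONS}
    return regions, occ_tracks


def gen_expression_counts(cfg: SimConfig, truth: TruthTable,
                          depth_factors: list[float] | None = None
                          ) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples, two conditions).

    A deg_fraction of genes (drawn from non-DiS genes so the DiS/DEG classes
    stay disjoint) get a |log2 fold change| of true_lfc at 25C, alternating
    sign.  Updates truth.genes['is_deg_true'] and 'gene_class' in place.
    """
    rng = _rng(cfg, 3)
    gene_ids = truth.genes["gene_id"].to_list()
    non_dis = [g for g, c in zip(gene_ids, truth.genes["gene_class"])
               if c != "DiS"]
    n_deg = int(round(cfg.deg_fraction * len(gene_ids)))
    n_deg = min(n_deg, len(non_dis))
    deg_genes = set(rng.choice(non_dis, size=n_deg, replace=False))
    samples = [f"{c}_rep{r}" for c in CONDITIONS
               for r in range(1, cfg.n_replicates + 1)]
    if depth_factors is None:
        depth_factors = [1.0] * len(samples)
    base = rng.lognormal(np.log(100.0), 1.0, size=len(gene_ids))
    signs = {}
    flip = 1.0
    for g in sorted(deg_genes):
        signs[g] = flip
        flip = -flip
    mat = np.zeros((len(gene_ids), len(samples)))
    inv_disp = 1.0 / cfg.nb_dispersion
    for j, (sample, depth) in enumerate(zip(samples, depth_factors)):
        cond = sample.split("_")[0]
        mu = base.copy()
        if cond == "25C":
            fold = np.array([2.0 ** (cfg.true_lfc * signs.get(g, 0.0))
                             for g in gene_ids])
            mu = mu * fold
        mu = mu * depth
        p = inv_disp / (inv_disp + mu)
        mat[:, j] = rng.negative_binomial(inv_disp, p)
    truth.genes["is_deg_true"] = truth.genes["gene_id"].isin(deg_genes)
    truth.genes.loc[truth.genes["is_deg_true"], "gene_class"] = "DEG"
    return pd.DataFrame(mat.astype(int), index=gene_ids, columns=samples)


def gen_phenotype(cfg: SimConfig) -> pd.DataFrame:
    """Per-plant flowering phenotypes on the 2-day screening grid.

    DTB ~ Normal(genotype/condition mean, sd) rounded to even days; RLN is
    correlated with DTB (leaves accumulate until bolting).
    """
    rng = _rng(cfg, 4)
    rows = []
    for genotype, means in cfg.phenotype_effects.items():
        for condition in CONDITIONS:
            for tray in range(1, cfg.n_trays + 1):
                for plant in range(1, cfg.plants_per_tray + 1):
                    dtb = rng.normal(means[condition], cfg.phenotype_sd)
                    dtb = max(2.0, 2.0 * round(dtb / 2.0))
                    rln = max(0.0, round(0.2 * dtb + rng.normal(0.0, 1.0)))
                    rows.append({
                        "genotype": genotype, "condition": condition,
                        "replicate_tray": tray,
                        "plant_id": f"{genotype}_{condition}_t{tray}_p{plant}",
                        "dtb": dtb, "rln": rln,
                    })
    return pd.DataFrame(rows)


def gen_term_map(cfg: SimConfig, truth: TruthTable, n_terms: int = 20,
                 term_size: int = 25) -> pd.DataFrame:
    """Gene-to-term annotation map with one term enriched in DiS genes."""
    rng = _rng(cfg, 5)
    gene_ids = truth.genes["gene_id"].to_list()
    dis_genes = truth.genes.loc[truth.genes["gene_class"] == "DiS",
                                "gene_id"].to_list()
    rows = []
    for t in range(1, n_terms + 1):
        term = f"T{t:03d}"
        if t == 1 and len(dis_genes) >= term_size:
            members = rng.choice(dis_genes, size=term_size, replace=False)
        else:
            members = rng.choice(gene_ids,
                                 size=min(term_size, len(gene_ids)),
                                 replace=False)
        for g in members:
            rows.append({"term_id": term, "gene_id": g,
                         "description": f"synthetic term {term}"})
    return pd.DataFrame(rows)


def gen_block_reads(event, n_reads: int, psi: float,
                    rng: np.random.Generator, read_length: int = 80
                    ) -> list[list[tuple[int, int]]]:
    """Block-interval reads drawn uniformly along an event's two forms.

    Each read picks the inclusion form with probability psi, a start
    uniformly along the form's spliced coordinates, and is mapped back to
    genomic blocks.  Reads landing entirely in shared flank come out
    ambiguous, exactly as in real data.
    """
    reads = []
    for _ in range(n_reads):
        form = event.inclusion_form if rng.random() < psi else event.exclusion_form
        total = sum(e - s for s, e in form)
        rl = min(read_length, total)
        start = int(rng.integers(0, total - rl + 1))
        blocks = []
        remaining, pos = rl, start
        for s, e in form:
            seg = e - s
            if pos >= seg:
                pos -= seg
                continue
            take = min(seg - pos, remaining)
            blocks.append((s + pos, s + pos + take))
            remaining -= take
            pos = 0
            if remaining == 0:
                break
        reads.append(blocks)
    return reads


def generate_all(cfg: SimConfig) -> dict:
    """Run every generator; returns genes, truth, counts, marks, tracks,
    expression, phenotype and the term map in one bundle."""
    genes, truth = gen_gene_models(cfg)
    counts = gen_event_counts(cfg, truth)
    # expression runs before the mark generator: DEG class labels feed the
    # class-specific marked fractions
    expression = gen_expression_counts(cfg, truth)
    regions, tracks = gen_mark_data(cfg, truth, genes)
    phenotypes = gen_phenotype(cfg)
    term_map = gen_term_map(cfg, truth)
    return {
        "genes": genes, "truth": truth, "event_counts": counts,
        "mark_regions": regions, "tracks": tracks,
        "expression": expression, "phenotype": phenotypes,
        "term_map": term_map,
    }
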