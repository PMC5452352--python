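"""Integration of histone-mark intervals and occupancy tracks with genes.

Covers region-to-gene association (containment by default, the literal
"within the start and the end of the gene" rule, with overlap-mode
alternatives), marked-gene fractions, strand-oriented metagene occupancy
profiles around TSS/TTS, event-to-region distances with a rank test between
event classes, region-width comparisons between conditions, and binned
replicate track correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GeneModel, MarkRegion

__all__ = [
    "GeneMarkAnnotation", "OccupancyTrack", "MetageneProfile", "WidthSummary",
    "associate_regions", "fraction_marked", "metagene_profile",
    "event_region_distance", "compare_distance_distributions",
    "compare_region_widths", "binned_track_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneMarkAnnotation:
    gene_id: str
    regions: list[MarkRegion] = field(default_factory=list)

    @property
    def marked(self) -> bool:
        return bool(self.regions)


@dataclass
class OccupancyTrack:
    """Per-chromosome nonnegative signal at a fixed genomic step (bp/cell)."""

    values: dict[str, np.ndarray]
    bin_size: int = 1

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative signal on {chrom}")
            self.values[chrom] = arr

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                v = self.values[chrom]
                for i, x in enumerate(v):
                    if x != 0:
                        fh.write(f"{chrom}\t{i * self.bin_size}\t"
                                 f"{(i + 1) * self.bin_size}\t{x:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path, bin_size: int = 1) -> "OccupancyTrack":
        spans: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")
                spans.setdefault(chrom, []).append((int(s), int(e), float(v)))
        values = {}
        for chrom, rows in spans.items():
            length = max(e for _, e, _ in rows)
            n = -(-length // bin_size)
            arr = np.zeros(n)
            for s, e, v in rows:
                arr[s // bin_size:-(-e // bin_size)] = v
            values[chrom] = arr
        return cls(values, bin_size)


@dataclass
class MetageneProfile:
    anchor: str  # TSS | TTS
    offsets: np.ndarray  # bin centers relative to the anchor, bp
    mean_signal: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.mean_signal):
            raise ValueError("offset and signal grids differ in length")
        if self.n_genes < 1:
            raise ValueError("profile over zero genes")

    @property
    def peak_offset(self) -> float:
        return float(self.offsets[int(np.argmax(self.mean_signal))])


def associate_regions(genes: list[GeneModel], regions: list[MarkRegion],
                      mode: str = "containment") -> list[GeneMarkAnnotation]:
    """Associate mark regions with genes.

    mode='containment' (default): the region lies fully within the gene span;
    'any': any overlap; 'midpoint': the region midpoint falls in the gene.
    """
    if mode not in ("containment", "any", "midpoint"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    out = []
    for gene in genes:
        hits: list[MarkRegion] = []
        tree = trees.get(gene.chrom)
        if tree is not None:
            for iv in sorted(tree.overlap(gene.start, gene.end)):
                r = iv.data
                if mode == "containment":
                    ok = r.start >= gene.start and r.end <= gene.end
                elif mode == "midpoint":
                    ok = gene.start <= (r.start + r.end) // 2 < gene.end
                else:
                    ok = True
                if ok:
                    hits.append(r)
        out.append(GeneMarkAnnotation(gene.gene_id, hits))
    return out


def fraction_marked(gene_set, annotations: list[GeneMarkAnnotation]) -> float:
    """Fraction of the gene set carrying at least one associated region."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    by_id = {a.gene_id: a for a in annotations}
    missing = [g for g in gene_set if g not in by_id]
    if missing:
        raise KeyError(f"genes without annotation records: {missing[:5]}")
    return sum(by_id[g].marked for g in gene_set) / len(gene_set)


def metagene_profile(track: OccupancyTrack, genes: list[GeneModel],
                     anchor: str = "TSS", window: tuple[int, int] = (-2000, 2000),
                     bin_size: int = 50,
                     classes: dict[str, str] | None = None,
                     ) -> dict[str, MetageneProfile]:
    """Mean strand-oriented occupancy around TSS or TTS, per gene class.

    Positive offsets point downstream of transcription (minus-strand genes
    are reversed).  Genes whose window exceeds chromosome bounds are skipped
    with a logged count.  Returns one profile per class label ('all' when no
    classes are given).
    """
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be TSS or TTS")
    w0, w1 = window
    if (w1 - w0) % bin_size:
        raise ValueError("window width must be a multiple of bin_size")
    step = track.bin_size
    if bin_size % step:
        raise ValueError("bin_size must be a multiple of the track resolution")
    n_bins = (w1 - w0) // bin_size
    per_class: dict[str, list[np.ndarray]] = {}
    skipped = 0
    for gene in genes:
        label = classes.get(gene.gene_id, None) if classes is not None else "all"
        if label is None:
            continue
        arr = track.values.get(gene.chrom)
        if arr is None:
            skipped += 1
            continue
        pos = gene.tss if anchor == "TSS" else gene.tts
        if gene.strand != "-":
            lo, hi = pos + w0, pos + w1
        else:
            lo, hi = pos + 1 - w1, pos + 1 - w0
        # snap to the track grid (sub-cell shift, < bin_size/2)
        lo_cell = int(round(lo / step))
        hi_cell = lo_cell + (w1 - w0) // step
        if lo_cell < 0 or hi_cell > len(arr):
            skipped += 1
            continue
        sig = arr[lo_cell:hi_cell]
        if gene.strand == "-":
            sig = sig[::-1]
        binned = sig.reshape(n_bins, bin_size // step).mean(axis=1)
        per_class.setdefault(label, []).append(binned)
    if skipped:
        logger.info("metagene_profile: skipped %d gene(s) outside track bounds",
                    skipped)
    offsets = np.arange(n_bins) * bin_size + w0 + bin_size / 2.0
    return {
        label: MetageneProfile(anchor, offsets,
                               np.mean(np.vstack(rows), axis=0), len(rows))
        for label, rows in per_class.items()
    }


def event_region_distance(event, annotation: GeneMarkAnnotation) -> int | None:
    """Minimum bp gap between an event's alternative region and any mark
    region of its gene (0 if overlapping); None for unmarked genes."""
    if event.gene_id != annotation.gene_id:
        raise ValueError(
            f"event gene {event.gene_id} != annotation gene {annotation.gene_id}"
        )
    if not annotation.marked:
        return None
    s, e = event.alt_region
    return min(max(0, r.start - e, s - r.end) for r in annotation.regions)


def compare_distance_distributions(dep_dists, indep_dists,
                                   method: str = "auto"):
    """One-sided Mann-Whitney U (dependent events closer than independent).

    None values are dropped before testing.  Returns (U, p); the exact null
    distribution is used for small tie-free samples, otherwise the normal
    approximation with continuity correction.
    """
    dep = [d for d in dep_dists if d is not None]
    indep = [d for d in indep_dists if d is not None]
    if not dep or not indep:
        raise ValueError("both distance samples must be nonempty after "
                         "dropping unmarked genes")
    res = stats.mannwhitneyu(dep, indep, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class WidthSummary:
    median_a: float
    median_b: float
    ratio: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_region_widths(regions_a: list[MarkRegion],
                          regions_b: list[MarkRegion]) -> WidthSummary:
    """Median region widths per condition and a two-sided rank test."""
    wa = np.array([r.width for r in regions_a], dtype=float)
    wb = np.array([r.width for r in regions_b], dtype=float)
    if wa.size == 0 or wb.size == 0:
        raise ValueError("both region lists must be nonempty")
    res = stats.mannwhitneyu(wa, wb, alternative="two-sided", method="auto")
    ma, mb = float(np.median(wa)), float(np.median(wb))
    return WidthSummary(ma, mb, mb / ma, float(res.statistic),
                        float(res.pvalue), wa.size, wb.size)


def binned_track_correlation(track1: OccupancyTrack, track2: OccupancyTrack,
                             bin_size: int = 1000,
                             trim_quantile: float = 0.999) -> float:
    """Pearson correlation of per-window signal sums across two tracks.

    The genome is partitioned into fixed windows; windows where either track
    exceeds its own trim quantile are removed (guarding against a few
    extreme-count windows dominating r).
    """
    chroms = sorted(set(track1.values) & set(track2.values))
    if not chroms:
        raise ValueError("tracks share no chromosomes")
    xs, ys = [], []
    for chrom in chroms:
        def window_sums(track):
            v = track.values[chrom]
            cells = bin_size // track.bin_size
            n_win = -(-len(v) // cells)
            padded = np.zeros(n_win * cells)
            padded[:len(v)] = v
            return padded.reshape(n_win, cells).sum(axis=1)

        wx, wy = window_sums(track1), window_sums(track2)
        n_win = max(len(wx), len(wy))
        xs.append(np.pad(wx, (0, n_win - len(wx))))
        ys.append(np.pad(wy, (0, n_win - len(wy))))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    keep = (x <= np.quantile(x, trim_quantile)) & (y <= np.quantile(y, trim_quantile))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 windows remain after trimming")
    r, _ = stats.pearsonr(x[keep], y[keep])
    return float(r)
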