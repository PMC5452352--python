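"""Enumeration of alternative-splicing events from transcript exon chains.

Five event types are detected by pairwise comparison of a gene's full-length
isoforms: intron retention (IR), exon skipping (ES), alternative 5' splice
site (A5), alternative 3' splice site (A3), and mutually exclusive exons
(MXE).  Donor/acceptor sides for A5/A3 are assigned by strand.  Alternative
first/last exons and complex regions are deliberately not events.

Each event carries two "forms": the inclusion form is the one with more
transcribed sequence in the alternative region (retained intron, included
exon, longer splice-site variant; for MXE the form holding the exon that is
upstream in transcript orientation).  PSI downstream is the inclusion
fraction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

from .io_formats import GeneModel, TranscriptModel

__all__ = ["ASEvent", "classify_pair", "enumerate_events", "event_id_for_key",
           "events_to_frame", "EVENT_TYPES"]

EVENT_TYPES = ("IR", "ES", "A5", "A3", "MXE")

Interval = tuple[int, int]
Form = tuple[Interval, ...]


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing event with its two isoform forms."""

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    alt_region: Interval
    flank_left: Interval
    flank_right: Interval
    inclusion_form: Form
    exclusion_form: Form

    def key(self) -> tuple:
        return (
            self.event_type, self.chrom, self.strand,
            self.alt_region, self.flank_left, self.flank_right,
        )

    @staticmethod
    def junctions(form: Form) -> list[Interval]:
        return [(form[i][1], form[i + 1][0]) for i in range(len(form) - 1)]


def event_id_for_key(event_type: str, chrom: str, strand: str,
                     alt_region: Interval, flank_left: Interval,
                     flank_right: Interval) -> str:
    """Stable content-derived id: 12 hex digits of a SHA-1 of the event key."""
    payload = (
        f"{event_type}|{chrom}|{strand}|{alt_region[0]}|{alt_region[1]}|"
        f"{flank_left[0]}|{flank_left[1]}|{flank_right[0]}|{flank_right[1]}"
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _make_event(event_type, gene_id, chrom, strand, alt, fl, fr, incl, excl):
    # degenerate anchors (shared flank overlap < 1 bp) are discarded upstream
    return ASEvent(
        event_id=event_id_for_key(event_type, chrom, strand, alt, fl, fr),
        gene_id=gene_id,
        event_type=event_type,
        chrom=chrom,
        strand=strand,
        alt_region=alt,
        flank_left=fl,
        flank_right=fr,
        inclusion_form=tuple(incl),
        exclusion_form=tuple(excl),
    )


def _ir_events(x: TranscriptModel, y: TranscriptModel, strand, chrom, gene_id):
    """Introns of x lying strictly inside a single exon of y."""
    out = []
    for i, (s, e) in enumerate(x.introns):
        xl, xr = x.exons[i], x.exons[i + 1]
        for c, d in y.exons:
            if c < s and d > e:
                fl = (max(xl[0], c), s)
                fr = (e, min(xr[1], d))
                if fl[1] - fl[0] < 1 or fr[1] - fr[0] < 1:
                    continue
                incl = [(fl[0], fr[1])]
                excl = [fl, fr]
                out.append(_make_event("IR", gene_id, chrom, strand,
                                       (s, e), fl, fr, incl, excl))
    return out


def _es_events(x: TranscriptModel, y: TranscriptModel, strand, chrom, gene_id):
    """Internal exons of x absent from y, with y joining the shared flanks."""
    out = []
    for i in range(1, len(x.exons) - 1):
        exon = x.exons[i]
        if any(ye[0] < exon[1] and ye[1] > exon[0] for ye in y.exons):
            continue
        xl, xr = x.exons[i - 1], x.exons[i + 1]
        for j, (ys, ye) in enumerate(y.introns):
            ya, yb = y.exons[j], y.exons[j + 1]
            if ya[1] == xl[1] and yb[0] == xr[0]:
                fl = (max(xl[0], ya[0]), xl[1])
                fr = (xr[0], min(xr[1], yb[1]))
                if fl[1] - fl[0] < 1 or fr[1] - fr[0] < 1:
                    continue
                incl = [fl, exon, fr]
                excl = [fl, fr]
                out.append(_make_event("ES", gene_id, chrom, strand,
                                       exon, fl, fr, incl, excl))
    return out


def _altss_events(x: TranscriptModel, y: TranscriptModel, strand, chrom, gene_id):
    """Intron pairs sharing exactly one boundary: A5/A3 by strand."""
    out = []
    for i, (xs, xe) in enumerate(x.introns):
        xl, xr = x.exons[i], x.exons[i + 1]
        for j, (ys, ye) in enumerate(y.introns):
            yl, yr = y.exons[j], y.exons[j + 1]
            if xe == ye and xs != ys:
                # left (genomically upstream) intron boundary differs
                lo, hi = min(xs, ys), max(xs, ys)
                fl = (max(xl[0], yl[0]), lo)
                fr = (xe, min(xr[1], yr[1]))
                if fl[1] - fl[0] < 1 or fr[1] - fr[0] < 1:
                    continue
                if strand == ".":
                    raise ValueError(
                        f"gene {gene_id}: strand '.' but alternative splice-"
                        "site candidate requires a strand to assign donor side"
                    )
                etype = "A5" if strand == "+" else "A3"
                incl = [(fl[0], hi), fr]
                excl = [(fl[0], lo), fr]
                out.append(_make_event(etype, gene_id, chrom, strand,
                                       (lo, hi), fl, fr, incl, excl))
            elif xs == ys and xe != ye:
                # right intron boundary differs
                lo, hi = min(xe, ye), max(xe, ye)
                fl = (max(xl[0], yl[0]), xs)
                fr = (hi, min(xr[1], yr[1]))
                if fl[1] - fl[0] < 1 or fr[1] - fr[0] < 1:
                    continue
                if strand == ".":
                    raise ValueError(
                        f"gene {gene_id}: strand '.' but alternative splice-"
                        "site candidate requires a strand to assign donor side"
                    )
                etype = "A3" if strand == "+" else "A5"
                incl = [fl, (lo, fr[1])]
                excl = [fl, (hi, fr[1])]
                out.append(_make_event(etype, gene_id, chrom, strand,
                                       (lo, hi), fl, fr, incl, excl))
    return out


def _mxe_events(x: TranscriptModel, y: TranscriptModel, strand, chrom, gene_id):
    """Non-overlapping internal exons A (x only) and B (y only) sharing flanks."""
    out = []
    for i in range(1, len(x.exons) - 1):
        a = x.exons[i]
        xl, xr = x.exons[i - 1], x.exons[i + 1]
        for j in range(1, len(y.exons) - 1):
            b = y.exons[j]
            if a[1] >= b[0] and b[1] >= a[0]:
                continue  # A and B overlap or touch
            yl, yr = y.exons[j - 1], y.exons[j + 1]
            if xl[1] != yl[1] or xr[0] != yr[0]:
                continue
            bnd_l, bnd_r = xl[1], xr[0]
            if not (bnd_l <= a[0] and a[1] <= bnd_r and
                    bnd_l <= b[0] and b[1] <= bnd_r):
                continue
            if any(ye[0] < a[1] and ye[1] > a[0] for ye in y.exons):
                continue  # y has exonic overlap with A
            if any(xe[0] < b[1] and xe[1] > b[0] for xe in x.exons):
                continue  # x has exonic overlap with B
            fl = (max(xl[0], yl[0]), bnd_l)
            fr = (bnd_r, min(xr[1], yr[1]))
            if fl[1] - fl[0] < 1 or fr[1] - fr[0] < 1:
                continue
            alt = (min(a[0], b[0]), max(a[1], b[1]))
            # inclusion carries the upstream-in-transcript exon
            first, second = (a, b) if a[0] < b[0] else (b, a)
            up_exon = first if strand != "-" else second
            dn_exon = second if strand != "-" else first
            incl = [fl, up_exon, fr]
            excl = [fl, dn_exon, fr]
            out.append(_make_event("MXE", gene_id, chrom, strand,
                                   alt, fl, fr, incl, excl))
    return out


def classify_pair(t1: TranscriptModel, t2: TranscriptModel, strand: str,
                  chrom: str = "", gene_id: str = "",
                  chrom2: str | None = None) -> list[ASEvent]:
    """All five-pattern events distinguishing two isoforms of one gene.

    Symmetric in its arguments up to the inclusion/exclusion labelling rule.
    Raises if the transcripts are declared on different chromosomes.
    """
    if chrom2 is not None and chrom2 != chrom:
        raise ValueError(
            f"transcripts {t1.transcript_id}/{t2.transcript_id} on different "
            f"chromosomes ({chrom} vs {chrom2})"
        )
    events: list[ASEvent] = []
    for x, y in ((t1, t2), (t2, t1)):
        events += _ir_events(x, y, strand, chrom, gene_id)
        events += _es_events(x, y, strand, chrom, gene_id)
        events += _mxe_events(x, y, strand, chrom, gene_id)
    # alt splice-site scan is symmetric in construction: one direction suffices
    events += _altss_events(t1, t2, strand, chrom, gene_id)
    # de-duplicate (the two scan directions can rediscover the same event)
    seen: dict[tuple, ASEvent] = {}
    for ev in events:
        seen.setdefault(ev.key(), ev)
    return sorted(seen.values(), key=lambda e: (e.alt_region, e.event_type))


def enumerate_events(gene: GeneModel) -> list[ASEvent]:
    """Union of :func:`classify_pair` over all unordered isoform pairs.

    De-duplicated by the full event key (type, coordinates, flank anchors);
    deterministic order.  Single-transcript genes yield no events.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id}: no transcripts")
    seen: dict[tuple, ASEvent] = {}
    for t1, t2 in combinations(gene.transcripts, 2):
        for ev in classify_pair(t1, t2, gene.strand, gene.chrom, gene.gene_id):
            seen.setdefault(ev.key(), ev)
    return sorted(seen.values(), key=lambda e: (e.alt_region, e.event_type))


def events_to_frame(events: list[ASEvent]):
    """Event catalog as a DataFrame (one row per event, TSV-ready)."""
    import pandas as pd

    def fmt_form(form: Form) -> str:
        return ",".join(f"{s}-{e}" for s, e in form)

    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "alt_start": ev.alt_region[0],
            "alt_end": ev.alt_region[1],
            "flank_left": f"{ev.flank_left[0]}-{ev.flank_left[1]}",
            "flank_right": f"{ev.flank_right[0]}-{ev.flank_right[1]}",
            "inclusion_form": fmt_form(ev.inclusion_form),
            "exclusion_form": fmt_form(ev.exclusion_form),
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "event_type", "chrom", "strand",
                 "alt_start", "alt_end", "flank_left", "flank_right",
                 "inclusion_form", "exclusion_form"],
    )
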