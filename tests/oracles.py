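"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms from the package: event
detection by elementary-segment label runs instead of exon-chain pattern
matching, the Bayes-factor posterior density at zero by exact Beta-product
integration instead of kernel density on samples, Mann-Whitney p by full
enumeration of the U null distribution, and the KS statistic by a direct
sup over the pooled support.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import integrate, stats


# ---------------------------------------------------------------- AS events

def _labels(boundaries, exons):
    """Label each elementary segment E (exonic) or I (intronic)."""
    labs = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        mid = (s + e) / 2.0
        labs.append("E" if any(a <= mid < b for a, b in exons) else "I")
    return labs


def brute_force_pair_events(exons1, exons2, strand):
    """(type, alt_region) set for a transcript pair by segment-run matching."""
    lo = max(exons1[0][0], exons2[0][0])
    hi = min(exons1[-1][1], exons2[-1][1])
    if lo >= hi:
        return set()
    bounds = sorted({lo, hi} | {
        x for iv in exons1 + exons2 for x in iv if lo <= x <= hi})
    l1 = _labels(bounds, exons1)
    l2 = _labels(bounds, exons2)
    # merge adjacent segments with identical label pairs
    runs = []  # (lab1, lab2, start, end)
    for i, (a, b) in enumerate(zip(l1, l2)):
        seg = (bounds[i], bounds[i + 1])
        if runs and runs[-1][0] == a and runs[-1][1] == b:
            runs[-1] = (a, b, runs[-1][2], seg[1])
        else:
            runs.append((a, b, seg[0], seg[1]))
    anchors = [i for i, r in enumerate(runs) if r[0] == "E" and r[1] == "E"]
    found = set()
    for ai, bi in zip(anchors[:-1], anchors[1:]):
        mid = runs[ai + 1:bi]
        pat = [(r[0], r[1]) for r in mid]
        span = [(r[2], r[3]) for r in mid]
        if len(pat) == 1 and pat[0] in (("I", "E"), ("E", "I")):
            found.add(("IR", span[0]))
        elif pat in ([("I", "I"), ("E", "I"), ("I", "I")],
                     [("I", "I"), ("I", "E"), ("I", "I")]):
            found.add(("ES", span[1]))
        elif pat in ([("E", "I"), ("I", "I")], [("I", "E"), ("I", "I")]):
            etype = "A5" if strand == "+" else "A3"
            found.add((etype, span[0]))
        elif pat in ([("I", "I"), ("E", "I")], [("I", "I"), ("I", "E")]):
            etype = "A3" if strand == "+" else "A5"
            found.add((etype, span[1]))
        elif pat in ([("I", "I"), ("E", "I"), ("I", "I"), ("I", "E"), ("I", "I")],
                     [("I", "I"), ("I", "E"), ("I", "I"), ("E", "I"), ("I", "I")]):
            found.add(("MXE", (span[1][0], span[3][1])))
    return found


def brute_force_gene_events(gene):
    """Union of pairwise brute-force events over a gene's isoforms."""
    out = set()
    for t1, t2 in combinations(gene.transcripts, 2):
        out |= brute_force_pair_events(t1.exons, t2.exons, gene.strand)
    return out


# ------------------------------------------------------------- Bayes factor

def exact_bayes_factor(n_incl_a, n_excl_a, n_incl_b, n_excl_b,
                       prior_a=1.0, prior_b=1.0):
    """Savage-Dickey BF with the posterior density of delta at 0 computed by
    exact numerical integration of the Beta-posterior product."""
    a1, b1 = n_incl_a + prior_a, n_excl_a + prior_b
    a2, b2 = n_incl_b + prior_a, n_excl_b + prior_b

    def integrand(x):
        return stats.beta.pdf(x, a1, b1) * stats.beta.pdf(x, a2, b2)

    dens0, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return 1.0 / max(dens0, 1e-300)


# --------------------------------------------------------------- rank tests

def exact_mannwhitney_less(x, y):
    """One-sided (x stochastically smaller) exact Mann-Whitney p by full
    enumeration of group assignments (tie-safe, tiny n only)."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        return sum((xi < yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    observed = sum((xi < yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    # alternative "less" means few y-values below x, i.e. LARGE observed U
    # of (x below y); p = P(U >= observed) under permutation
    total = 0
    hits = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if u_stat(idx) >= observed:
            hits += 1
    return hits / total


def brute_force_ks(x, y):
    """sup_t |F_x(t) - F_y(t)| over the pooled support."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    support = np.concatenate([x, y])
    d = 0.0
    for t in support:
        d = max(d, abs(np.mean(x <= t) - np.mean(y <= t)))
    return d


# ------------------------------------------------------------- read counting

def brute_force_read_class(blocks, form):
    """Compatibility of one read with one form by per-base membership and
    explicit junction simulation."""
    covered = set()
    for s, e in form:
        covered.update(range(s, e))
    for s, e in blocks:
        if any(p not in covered for p in range(s, e)):
            return False
    # adjacent covered positions inside one block must be contiguous exon
    for s, e in blocks:
        for fs, fe in form:
            if fs <= s < fe and not (fs <= s and e <= fe):
                return False
    junctions = {(form[i][1], form[i + 1][0]) for i in range(len(form) - 1)}
    for (s1, e1), (s2, e2) in zip(blocks[:-1], blocks[1:]):
        if (e1, s2) not in junctions:
            return False
    return True
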