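"""Percent-spliced-in quantification and Bayes-factor differential splicing.

The statistical model is a two-form Beta-Binomial: for an event with
isoform-specific inclusion/exclusion read counts (k, n-k), PSI has a
Beta(k + a, n - k + b) posterior under a Beta(a, b) prior (Uniform(0,1) by
default).  The differential test between two conditions is a Savage-Dickey
Bayes factor on the pooled counts,

    BF10 = p_prior(delta = 0) / p_posterior(delta = 0),  delta = psi_b - psi_a,

where the prior on (psi_a, psi_b) is independent Uniform(0,1) -- so the
prior density of delta at 0 is exactly 1 (triangular on [-1, 1]) -- and the
posterior density at 0 is estimated from paired Beta posterior draws with a
Gaussian kernel (Silverman bandwidth, floored).  Replicates feed two filter
rules: a minimum isoform-specific read support per condition, and the
requirement that within-condition PSI spread stay below the
between-condition difference.  An event is significant when both filters
pass and BF >= the threshold (default 5).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventCounts", "PsiEstimate", "DiSResult", "DependenceCall", "EcdfComparison",
    "count_event_reads", "estimate_psi", "pool_counts", "bayes_factor_delta",
    "support_filter", "consistency_filter", "call_dis", "call_dis_table",
    "classify_dependence", "delta_psi_ecdf_compare", "derive_event_seed",
]

DEFAULT_SEED = 1337


@dataclass
class EventCounts:
    """Isoform-specific read support for one event in one sample."""

    event_id: str
    sample_id: str
    condition: str
    replicate: int | str
    n_incl: int
    n_excl: int

    def __post_init__(self) -> None:
        if self.n_incl < 0 or self.n_excl < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_incl + self.n_excl


@dataclass
class PsiEstimate:
    psi_mean: float
    ci_low: float
    ci_high: float
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.psi_mean <= self.ci_high <= 1):
            raise ValueError("PSI estimate ordering violated")


@dataclass
class DiSResult:
    event_id: str
    psi_a: PsiEstimate
    psi_b: PsiEstimate
    delta_psi: float
    bayes_factor: float
    passed_support: bool
    passed_consistency: bool
    significant: bool
    replicate_psis_a: list[float] = field(default_factory=list)
    replicate_psis_b: list[float] = field(default_factory=list)


@dataclass
class DependenceCall:
    event_id: str
    dependence: str  # dependent | independent | unclassified


def count_event_reads(event, alignments, sample_id: str = "",
                      condition: str = "", replicate: int | str = 0) -> EventCounts:
    """Count reads compatible with exactly one of an event's two forms.

    ``alignments`` is a list of block lists (sorted genomic exonic segments
    per read).  A read is compatible with a form when every block nests in a
    single form exon and every junction it spans is a junction of that form;
    reads compatible with both forms (e.g. entirely in shared flank) or with
    neither are ignored.
    """
    incl = excl = 0
    incl_form, excl_form = event.inclusion_form, event.exclusion_form
    for blocks in alignments:
        a = _compatible(blocks, incl_form)
        b = _compatible(blocks, excl_form)
        if a and not b:
            incl += 1
        elif b and not a:
            excl += 1
    return EventCounts(event.event_id, sample_id, condition, replicate, incl, excl)


def _compatible(blocks, form) -> bool:
    junctions = {(form[i][1], form[i + 1][0]) for i in range(len(form) - 1)}
    for i, (s, e) in enumerate(blocks):
        if s >= e:
            return False
        if not any(fs <= s and e <= fe for fs, fe in form):
            return False
        if i + 1 < len(blocks):
            gap = (e, blocks[i + 1][0])
            if gap not in junctions:
                return False
    return True


def estimate_psi(n_incl: int, n_excl: int, prior_a: float = 1.0,
                 prior_b: float = 1.0, ci: float = 0.95) -> PsiEstimate:
    """Posterior mean and central credible interval of the Beta posterior."""
    if n_incl < 0 or n_excl < 0:
        raise ValueError("counts must be nonnegative")
    a = n_incl + prior_a
    b = n_excl + prior_b
    mean = a / (a + b)
    tail = (1.0 - ci) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], a, b)
    return PsiEstimate(float(mean), float(lo), float(hi), n_incl + n_excl)


def pool_counts(replicates: list[EventCounts]) -> EventCounts:
    """Sum isoform-specific counts across the replicates of one condition."""
    if not replicates:
        raise ValueError("no replicates to pool")
    first = replicates[0]
    for r in replicates[1:]:
        if r.condition != first.condition or r.event_id != first.event_id:
            raise ValueError("cannot pool across conditions or events")
    return EventCounts(
        first.event_id, "pooled", first.condition, "pooled",
        sum(r.n_incl for r in replicates), sum(r.n_excl for r in replicates),
    )


def bayes_factor_delta(pooled_a: EventCounts, pooled_b: EventCounts,
                       n_draws: int = 100_000, seed: int = DEFAULT_SEED,
                       prior_a: float = 1.0, prior_b: float = 1.0,
                       bw_floor: float = 0.01) -> float:
    """Savage-Dickey Bayes factor for delta-PSI != 0 on pooled counts.

    The posterior density of delta at 0 is a Gaussian-kernel estimate from
    ``n_draws`` paired Beta posterior draws (Silverman's rule bandwidth with
    a floor); the prior density at 0 is exactly 1.  Deterministic given the
    seed.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    # one independent stream per condition, assigned canonically by the
    # count pair so that swapping conditions exactly negates the delta draws
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    ka = (pooled_a.n_incl, pooled_a.n_excl)
    kb = (pooled_b.n_incl, pooled_b.n_excl)
    seq_a, seq_b = (s1, s2) if ka <= kb else (s2, s1)
    da = np.random.default_rng(seq_a).beta(
        pooled_a.n_incl + prior_a, pooled_a.n_excl + prior_b, n_draws)
    db = np.random.default_rng(seq_b).beta(
        pooled_b.n_incl + prior_a, pooled_b.n_excl + prior_b, n_draws)
    delta = db - da
    sd = float(np.std(delta, ddof=1))
    q75, q25 = np.percentile(delta, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = max(0.9 * spread * n_draws ** (-0.2), bw_floor)
    dens0 = float(np.mean(np.exp(-0.5 * (delta / bw) ** 2))) / (bw * math.sqrt(2 * math.pi))
    return 1.0 / max(dens0, 1e-300)


def support_filter(replicates_a: list[EventCounts], replicates_b: list[EventCounts],
                   min_reads: int = 20, min_reps: int = 2) -> bool:
    """True iff each condition has >= min_reps replicates with >= min_reads
    isoform-specific reads."""
    for reps in (replicates_a, replicates_b):
        if not reps:
            return False
        qualifying = sum(1 for r in reps if r.total >= min_reads)
        if qualifying < min_reps:
            return False
    return True


def consistency_filter(replicate_psis_a: list[float],
                       replicate_psis_b: list[float]) -> bool:
    """Within-condition PSI spread must stay strictly below the
    between-condition difference.

    Spread is the maximum pairwise |PSI_i - PSI_j| within either condition;
    the between-condition difference is |mean_a - mean_b| of per-replicate
    posterior means.  Ties fail.
    """
    if not replicate_psis_a or not replicate_psis_b:
        raise ValueError("need at least one replicate PSI per condition")

    def max_spread(psis):
        return max(
            (abs(p - q) for i, p in enumerate(psis) for q in psis[i + 1:]),
            default=0.0,
        )

    within = max(max_spread(replicate_psis_a), max_spread(replicate_psis_b))
    between = abs(float(np.mean(replicate_psis_a)) - float(np.mean(replicate_psis_b)))
    return within < between


def call_dis(replicates_a: list[EventCounts], replicates_b: list[EventCounts],
             bf_threshold: float = 5.0, min_reads: int = 20, min_reps: int = 2,
             n_draws: int = 100_000, seed: int = DEFAULT_SEED) -> DiSResult:
    """Full differential-splicing call for one event between two conditions.

    Per-replicate posterior-mean PSIs feed the consistency filter; the
    Bayes factor and pooled PSI estimates are computed on replicate-merged
    counts.  Replicates with zero isoform-specific reads are excluded from
    the consistency computation (they still count against support).
    """
    if not replicates_a or not replicates_b:
        raise ValueError("need replicate counts for both conditions")
    event_id = replicates_a[0].event_id
    pooled_a = pool_counts(replicates_a)
    pooled_b = pool_counts(replicates_b)
    psi_a = estimate_psi(pooled_a.n_incl, pooled_a.n_excl)
    psi_b = estimate_psi(pooled_b.n_incl, pooled_b.n_excl)
    rep_psis_a = [estimate_psi(r.n_incl, r.n_excl).psi_mean
                  for r in replicates_a if r.total > 0]
    rep_psis_b = [estimate_psi(r.n_incl, r.n_excl).psi_mean
                  for r in replicates_b if r.total > 0]
    passed_support = support_filter(replicates_a, replicates_b, min_reads, min_reps)
    if rep_psis_a and rep_psis_b:
        passed_consistency = consistency_filter(rep_psis_a, rep_psis_b)
    else:
        passed_consistency = False
    bf = bayes_factor_delta(pooled_a, pooled_b, n_draws=n_draws, seed=seed)
    return DiSResult(
        event_id=event_id,
        psi_a=psi_a,
        psi_b=psi_b,
        delta_psi=psi_b.psi_mean - psi_a.psi_mean,
        bayes_factor=bf,
        passed_support=passed_support,
        passed_consistency=passed_consistency,
        significant=bool(passed_support and passed_consistency
                         and bf >= bf_threshold),
        replicate_psis_a=rep_psis_a,
        replicate_psis_b=rep_psis_b,
    )


def derive_event_seed(base_seed: int, label: str, event_id: str) -> int:
    """Stable per-event sub-seed (< 2^31) from a base seed and labels."""
    h = hashlib.sha1(f"{base_seed}|{label}|{event_id}".encode()).hexdigest()
    return int(h[:8], 16) % (2 ** 31)


def call_dis_table(counts: pd.DataFrame, cond_a: str = "16C",
                   cond_b: str = "25C", *, bf_threshold: float = 5.0,
                   min_reads: int = 20, min_reps: int = 2,
                   n_draws: int = 100_000, seed: int = DEFAULT_SEED,
                   label: str = "") -> pd.DataFrame:
    """Differential-splicing calls for every event in a counts table.

    ``counts`` needs the columns event_id/sample_id/condition/replicate/
    n_incl/n_excl.  Each event gets a stable sub-seed derived from ``seed``
    and ``label`` (e.g. the genotype), so results are reproducible and
    independent of event order.
    """
    grouped: dict[str, dict[str, list[EventCounts]]] = {}
    order: list[str] = []
    for row in counts.itertuples(index=False):
        if row.event_id not in grouped:
            order.append(row.event_id)
        grouped.setdefault(row.event_id, {}).setdefault(
            row.condition, []).append(
            EventCounts(row.event_id, row.sample_id, row.condition,
                        row.replicate, row.n_incl, row.n_excl))
    rows = []
    for event_id in order:
        conds = grouped[event_id]
        reps_a = conds.get(cond_a, [])
        reps_b = conds.get(cond_b, [])
        if not reps_a or not reps_b:
            continue
        res = call_dis(reps_a, reps_b, bf_threshold=bf_threshold,
                       min_reads=min_reads, min_reps=min_reps,
                       n_draws=n_draws,
                       seed=derive_event_seed(seed, label, event_id))
        rows.append({
            "event_id": event_id,
            f"psi_{cond_a}": res.psi_a.psi_mean,
            f"psi_{cond_b}": res.psi_b.psi_mean,
            f"ci_low_{cond_a}": res.psi_a.ci_low,
            f"ci_high_{cond_a}": res.psi_a.ci_high,
            f"ci_low_{cond_b}": res.psi_b.ci_low,
            f"ci_high_{cond_b}": res.psi_b.ci_high,
            "delta_psi": res.delta_psi,
            "bayes_factor": res.bayes_factor,
            "passed_support": res.passed_support,
            "passed_consistency": res.passed_consistency,
            "significant": res.significant,
            f"replicate_psis_{cond_a}": ",".join(
                f"{p:.6f}" for p in res.replicate_psis_a),
            f"replicate_psis_{cond_b}": ",".join(
                f"{p:.6f}" for p in res.replicate_psis_b),
        })
    return pd.DataFrame(rows)


def classify_dependence(wt: DiSResult, mutants: list[DiSResult]) -> DependenceCall:
    """Histone-mark dependence of a temperature-induced splicing event.

    dependent:   significant in wild type but in no mutant genotype;
    independent: significant in wild type and in every mutant genotype;
    unclassified otherwise.
    """
    if any(m.event_id != wt.event_id for m in mutants):
        raise ValueError("dependence call across mismatched event ids")
    if wt.significant and mutants and not any(m.significant for m in mutants):
        dependence = "dependent"
    elif wt.significant and mutants and all(m.significant for m in mutants):
        dependence = "independent"
    else:
        dependence = "unclassified"
    return DependenceCall(wt.event_id, dependence)


@dataclass
class EcdfComparison:
    statistic: float
    p_value: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]


def _ecdf(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(sample)
    return x, np.arange(1, len(x) + 1) / len(x)


def delta_psi_ecdf_compare(abs_dpsi_a, abs_dpsi_b) -> EcdfComparison:
    """Two-sample Kolmogorov-Smirnov comparison of |delta-PSI| distributions,
    returning the step functions for ecdf plotting."""
    a = np.asarray(abs_dpsi_a, dtype=float)
    b = np.asarray(abs_dpsi_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both |delta PSI| samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return EcdfComparison(float(res.statistic), float(res.pvalue),
                          _ecdf(a), _ecdf(b))
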