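import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_ks, brute_force_read_class, exact_bayes_factor
from thermosplice.as_events import classify_pair
from thermosplice.io_formats import TranscriptModel
from thermosplice.psi_dis import (
    DiSResult,
    EventCounts,
    bayes_factor_delta,
    call_dis,
    classify_dependence,
    consistency_filter,
    count_event_reads,
    delta_psi_ecdf_compare,
    estimate_psi,
    pool_counts,
    support_filter,
)
from thermosplice.synthetic_data import gen_block_reads


def ec(n_incl, n_excl, condition="16C", replicate=1, event_id="ev"):
    return EventCounts(event_id, f"s{replicate}", condition, replicate,
                       n_incl, n_excl)


@pytest.fixture
def ir_event():
    (ev,) = classify_pair(TranscriptModel("t1", [(0, 300)]),
                          TranscriptModel("t2", [(0, 100), (200, 300)]),
                          "+", chrom="chr1", gene_id="g")
    return ev


class TestReadCounting:
    def test_read_crossing_into_retained_intron_is_inclusion(self, ir_event):
        counts = count_event_reads(ir_event, [[(90, 130)]])
        assert (counts.n_incl, counts.n_excl) == (1, 0)

    def test_junction_read_is_exclusion(self, ir_event):
        counts = count_event_reads(ir_event, [[(80, 100), (200, 220)]])
        assert (counts.n_incl, counts.n_excl) == (0, 1)

    def test_flank_only_read_is_ambiguous(self, ir_event):
        counts = count_event_reads(ir_event, [[(50, 90)]])
        assert (counts.n_incl, counts.n_excl) == (0, 0)

    def test_no_reads_gives_zero_counts(self, ir_event):
        counts = count_event_reads(ir_event, [])
        assert (counts.n_incl, counts.n_excl) == (0, 0)

    def test_matches_per_base_oracle_on_generated_reads(self, small_sim):
        from thermosplice.as_events import enumerate_events

        _, genes, _ = small_sim
        rng = np.random.default_rng(5)
        for gene in genes[:20]:
            (event,) = enumerate_events(gene)
            reads = gen_block_reads(event, 40, 0.5, rng, read_length=60)
            counts = count_event_reads(event, reads)
            incl = excl = 0
            for blocks in reads:
                a = brute_force_read_class(blocks, event.inclusion_form)
                b = brute_force_read_class(blocks, event.exclusion_form)
                incl += a and not b
                excl += b and not a
            assert (counts.n_incl, counts.n_excl) == (incl, excl)


class TestPsiEstimate:
    @pytest.mark.parametrize("k, n_excl, expected", [
        (10, 10, 0.5),
        (30, 0, 31 / 32),
        (0, 30, 1 / 32),
    ])
    def test_posterior_mean_closed_form(self, k, n_excl, expected):
        assert estimate_psi(k, n_excl).psi_mean == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_prior_only_case(self):
        est = estimate_psi(0, 0)
        assert est.psi_mean == 0.5
        assert est.ci_low == pytest.approx(0.025, abs=1e-9)
        assert est.ci_high == pytest.approx(0.975, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_psi(-1, 5)

    @given(st.integers(0, 200), st.integers(0, 200))
    def test_interval_ordering_invariant(self, k, m):
        est = estimate_psi(k, m)
        assert 0 <= est.ci_low <= est.psi_mean <= est.ci_high <= 1


class TestPooling:
    def test_additivity(self):
        pooled = pool_counts([ec(12, 8), ec(20, 10)])
        assert (pooled.n_incl, pooled.n_excl) == (32, 18)
        assert pooled.replicate == "pooled"

    def test_single_replicate_identity(self):
        pooled = pool_counts([ec(7, 3)])
        assert (pooled.n_incl, pooled.n_excl) == (7, 3)

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=6), st.randoms(use_true_random=False))
    def test_order_invariance(self, pairs, shuffler):
        reps = [ec(a, b, replicate=i) for i, (a, b) in enumerate(pairs)]
        shuffled = list(reps)
        shuffler.shuffle(shuffled)
        p1, p2 = pool_counts(reps), pool_counts(shuffled)
        assert (p1.n_incl, p1.n_excl) == (p2.n_incl, p2.n_excl)

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValueError):
            pool_counts([ec(1, 1, "16C"), ec(1, 1, "25C")])


class TestBayesFactor:
    def test_identical_data_gives_evidence_for_null(self):
        bf = bayes_factor_delta(ec(50, 50), ec(50, 50, "25C"), seed=1)
        assert bf < 1

    def test_opposite_extremes_strongly_significant(self):
        bf = bayes_factor_delta(ec(90, 10), ec(10, 90, "25C"), seed=1)
        assert bf > 5

    def test_swap_invariance(self):
        a, b = ec(70, 30), ec(40, 60, "25C")
        assert bayes_factor_delta(a, b, seed=2) == \
            bayes_factor_delta(b, a, seed=2)

    @pytest.mark.parametrize("counts", [
        (50, 50, 50, 50), (60, 40, 40, 60), (30, 20, 20, 30), (5, 5, 8, 2),
    ])
    def test_tracks_exact_density_integral(self, counts):
        ia, ea, ib, eb = counts
        bf = bayes_factor_delta(ec(ia, ea), ec(ib, eb, "25C"), seed=4)
        exact = exact_bayes_factor(ia, ea, ib, eb)
        assert bf == pytest.approx(exact, rel=0.25)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_delta(ec(5, 5), ec(5, 5, "25C"), n_draws=10)


class TestFilters:
    def test_support_requires_min_replicates_per_condition(self):
        a = [ec(20, 5), ec(10, 8), ec(25, 5)]   # totals 25, 18, 30
        b = [ec(11, 10, "25C"), ec(12, 10, "25C"), ec(3, 2, "25C")]
        assert support_filter(a, b) is True
        a2 = [ec(20, 5), ec(10, 8), ec(10, 9)]  # totals 25, 18, 19
        b2 = [ec(11, 10, "25C"), ec(12, 10, "25C"), ec(20, 10, "25C")]
        assert support_filter(a2, b2) is False

    def test_zero_threshold_always_passes(self):
        a = [ec(0, 0), ec(0, 0)]
        b = [ec(0, 0, "25C"), ec(0, 0, "25C")]
        assert support_filter(a, b, min_reads=0, min_reps=2) is True

    def test_consistency_spread_below_shift(self):
        assert consistency_filter([0.20, 0.25, 0.22], [0.60, 0.55, 0.65])
        assert not consistency_filter([0.1, 0.6], [0.35, 0.40])

    def test_consistency_single_replicates(self):
        assert consistency_filter([0.2], [0.5]) is True
        assert consistency_filter([0.5], [0.5]) is False  # tie fails


class TestDisCall:
    def test_true_shift_called_significant(self):
        rng = np.random.default_rng(11)
        reps_a = [ec(int(k), 60 - int(k)) for k in rng.binomial(60, 0.2, 3)]
        reps_b = [ec(int(k), 60 - int(k), "25C")
                  for k in rng.binomial(60, 0.7, 3)]
        res = call_dis(reps_a, reps_b, seed=11)
        assert res.significant
        assert res.delta_psi == pytest.approx(0.5, abs=0.15)

    def test_support_failure_gates_significance(self):
        reps_a = [ec(90, 90), ec(2, 1)]          # only 1 qualifying replicate
        reps_b = [ec(10, 170, "25C"), ec(12, 160, "25C")]
        res = call_dis(reps_a, reps_b, seed=3)
        assert res.bayes_factor > 5  # the data alone are extreme
        assert not res.passed_support
        assert not res.significant

    def test_zero_read_replicates_excluded_from_consistency(self):
        reps_a = [ec(30, 30), ec(25, 35), ec(0, 0)]
        reps_b = [ec(55, 5, "25C"), ec(50, 10, "25C"), ec(52, 8, "25C")]
        res = call_dis(reps_a, reps_b, seed=3)
        assert len(res.replicate_psis_a) == 2
        assert res.passed_consistency


class TestDependence:
    def _res(self, significant, event_id="ev"):
        psi = estimate_psi(10, 10)
        return DiSResult(event_id, psi, psi, 0.0, 10.0, True, True,
                         significant)

    def test_wt_only_is_dependent(self):
        call = classify_dependence(self._res(True),
                                   [self._res(False), self._res(False)])
        assert call.dependence == "dependent"

    def test_all_genotypes_is_independent(self):
        call = classify_dependence(self._res(True),
                                   [self._res(True), self._res(True)])
        assert call.dependence == "independent"

    def test_mixed_mutants_unclassified(self):
        call = classify_dependence(self._res(True),
                                   [self._res(True), self._res(False)])
        assert call.dependence == "unclassified"

    def test_nonsignificant_wt_unclassified(self):
        call = classify_dependence(self._res(False),
                                   [self._res(False), self._res(False)])
        assert call.dependence == "unclassified"

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            classify_dependence(self._res(True),
                                [self._res(True, event_id="other")])


class TestEcdfComparison:
    def test_identical_samples(self):
        res = delta_psi_ecdf_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        res = delta_psi_ecdf_compare([0.9] * 50, [0.1] * 50)
        assert res.statistic == 1.0

    def test_matches_bruteforce_sup(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            x = rng.uniform(0, 1, int(rng.integers(3, 30)))
            y = rng.uniform(0, 1, int(rng.integers(3, 30)))
            res = delta_psi_ecdf_compare(x, y)
            assert res.statistic == pytest.approx(brute_force_ks(x, y),
                                                  abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            delta_psi_ecdf_compare([], [0.1])
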