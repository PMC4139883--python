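"""Count tables, priors, binomial-tail scoring, CL ranking and IFS."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from vkcotc import (
    ConfidenceLevelSelector,
    LabeledDataset,
    ProteinRecord,
    binomial_tail,
    build_count_table,
    confidence_levels,
    default_taus,
    feature_subset,
    incremental_feature_selection,
    priors,
    tripeptide_index,
)
from vkcotc.selection import IFSEvaluationError


def exact_upper_tail(N: int, n: int, p: Fraction) -> Fraction:
    """Independent oracle: exact rational summation of the binomial tail."""
    return sum(
        Fraction(comb(N, m)) * p**m * (1 - p) ** (N - m) for m in range(n, N + 1)
    )


class TestCountTable:
    def test_worked_example(self, toy_dataset):
        table = build_count_table(toy_dataset)
        assert table.classes == ["K1", "K2"]
        assert table.n[tripeptide_index("AAA"), 0] == 2
        for t in ("ACD", "CDA", "DAC"):
            assert table.n[tripeptide_index(t), 1] == 1
        assert list(table.M_k) == [2, 3]
        assert table.M == 5

    def test_duplicate_sequence_doubles_counts(self):
        ds = LabeledDataset(
            records=[ProteinRecord("a", "", "AAAA"), ProteinRecord("b", "", "AAAA"),
                     ProteinRecord("c", "", "ACDAC")],
            labels=["K1", "K1", "K2"],
        )
        table = build_count_table(ds)
        assert table.n[tripeptide_index("AAA"), 0] == 4

    def test_marginal_conservation(self, small_dataset):
        table = build_count_table(small_dataset)
        assert table.N_i.sum() == table.M
        assert table.M_k.sum() == table.M
        assert table.M == sum(len(s) - 2 for s in small_dataset.sequences)


class TestPriors:
    def test_worked_ratios(self, toy_dataset):
        prior = priors(build_count_table(toy_dataset))
        assert prior.p == pytest.approx([0.4, 0.6])
        assert prior.q == pytest.approx([0.6, 0.4])
        assert prior.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_classes_equal_priors(self):
        ds = LabeledDataset(
            records=[ProteinRecord("a", "", "AAAA"), ProteinRecord("b", "", "CCCC")],
            labels=["K1", "K2"],
        )
        prior = priors(build_count_table(ds))
        assert prior.p == pytest.approx([0.5, 0.5])


class TestBinomialTail:
    @pytest.mark.parametrize(
        "N, n, p, expected",
        [(5, 0, 0.3, 1.0), (2, 1, 0.5, 0.75), (1, 1, 0.2, 0.2)],
    )
    def test_known_values(self, N, n, p, expected):
        assert binomial_tail(N, n, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.05, 0.25, 0.5, 0.9])
    def test_matches_exact_enumeration(self, p):
        pf = Fraction(p).limit_denominator(10**6)
        for N in range(13):
            for n in range(N + 1):
                exact = float(exact_upper_tail(N, n, pf))
                assert binomial_tail(N, n, p) == pytest.approx(exact, abs=1e-12)

    def test_monotone_nonincreasing_in_n(self):
        for N, p in [(10, 0.3), (25, 0.7)]:
            tails = [binomial_tail(N, n, p) for n in range(N + 1)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_boundary_identities(self):
        assert binomial_tail(17, 0, 0.42) == 1.0
        assert binomial_tail(10, 10, 0.5) == pytest.approx(0.5**10, rel=1e-12)

    def test_large_N_stable(self):
        assert 0.0 <= binomial_tail(10**6, 10**6 // 2, 0.5) <= 1.0

    @pytest.mark.parametrize("N, n, p", [(5, 6, 0.5), (5, -1, 0.5), (5, 2, 1.5)])
    def test_invalid_inputs(self, N, n, p):
        with pytest.raises(ValueError):
            binomial_tail(N, n, p)


class TestConfidenceLevels:
    def test_absent_tripeptide_has_zero_cl_and_ranks_last(self, toy_dataset):
        ranked = confidence_levels(build_count_table(toy_dataset))
        absent = tripeptide_index("WWW")
        assert ranked.cl[absent] == 0.0
        pos = np.where(ranked.order == absent)[0][0]
        present = [tripeptide_index(t) for t in ("AAA", "ACD", "CDA", "DAC")]
        assert all(pos > np.where(ranked.order == i)[0][0] for i in present)

    def test_all_in_one_class_closed_form(self):
        # one tripeptide 10x in class K1 with p_K1 = 0.5: tail = 0.5**10
        ds = LabeledDataset(
            records=[ProteinRecord("a", "", "A" * 12), ProteinRecord("b", "", "C" * 12)],
            labels=["K1", "K2"],
        )
        ranked = confidence_levels(build_count_table(ds))
        aaa = tripeptide_index("AAA")
        k1 = ranked.classes.index("K1")
        assert ranked.cl_detail[aaa, k1] == pytest.approx(1 - 0.5**10, abs=1e-12)
        assert ranked.cl[aaa] == pytest.approx(1 - 0.5**10, abs=1e-12)

    def test_planted_tripeptide_outranks_unplanted(self, benchmark_like, benchmark_ranking):
        _, truth = benchmark_like
        planted = {tripeptide_index(t) for s in truth.planted.values() for t in s}
        rank_pos = np.empty(8000, dtype=int)
        rank_pos[benchmark_ranking.order] = np.arange(8000)
        worst_planted = max(rank_pos[i] for i in planted)
        unplanted_best = min(
            rank_pos[i] for i in range(8000) if i not in planted
        )
        # at least the very best unplanted feature ranks below the median planted
        assert np.median([rank_pos[i] for i in planted]) < unplanted_best + 60
        assert worst_planted < 8000

    def test_cl_bounds_and_permutation(self, benchmark_ranking):
        assert ((benchmark_ranking.cl >= 0) & (benchmark_ranking.cl <= 1)).all()
        assert sorted(benchmark_ranking.order.tolist()) == list(range(8000))
        ordered_cl = benchmark_ranking.cl[benchmark_ranking.order]
        assert (np.diff(ordered_cl) <= 1e-15).all()

    def test_tie_break_is_deterministic_by_index(self):
        ds = LabeledDataset(
            records=[ProteinRecord("a", "", "ACDE"), ProteinRecord("b", "", "FGHI")],
            labels=["K1", "K2"],
        )
        ranked = confidence_levels(build_count_table(ds))
        zero_cl = ranked.order[ranked.cl[ranked.order] == 0.0]
        assert np.array_equal(zero_cl, np.sort(zero_cl))


class TestFeatureSubsetAndIFS:
    def test_prefix_property(self, benchmark_ranking):
        s5 = feature_subset(benchmark_ranking, 5)
        s9 = feature_subset(benchmark_ranking, 9)
        assert np.array_equal(s9[:5], s5)
        assert np.array_equal(feature_subset(benchmark_ranking, 1),
                              benchmark_ranking.order[:1])
        assert feature_subset(benchmark_ranking, 8000).size == 8000

    @pytest.mark.parametrize("bad", [0, 8001, -3])
    def test_tau_out_of_range(self, benchmark_ranking, bad):
        with pytest.raises(ValueError):
            feature_subset(benchmark_ranking, bad)

    def test_single_tau_is_theta(self, benchmark_ranking):
        curve = incremental_feature_selection(
            benchmark_ranking, lambda s: 0.5, [42]
        )
        assert curve.theta == 42
        assert len(curve.points) == 1

    def test_tie_resolves_to_smallest_tau(self, benchmark_ranking):
        curve = incremental_feature_selection(
            benchmark_ranking, lambda s: 0.7, [10, 20, 30]
        )
        assert curve.theta == 10

    def test_theta_maximizes_curve(self, benchmark_ranking):
        accs = {10: 0.4, 20: 0.9, 30: 0.9, 40: 0.6}
        curve = incremental_feature_selection(
            benchmark_ranking, lambda s: accs[len(s)], sorted(accs)
        )
        assert curve.theta == 20
        assert curve.peak_accuracy == 0.9
        assert curve.optimal_subset.size == 20

    def test_cl_threshold_tracks_ranking(self, benchmark_ranking):
        curve = incremental_feature_selection(
            benchmark_ranking, lambda s: 0.0, [1, 100]
        )
        assert curve.points[0].cl_threshold == pytest.approx(
            benchmark_ranking.cl[benchmark_ranking.order[0]]
        )

    def test_evaluator_failure_names_tau(self, benchmark_ranking):
        def boom(subset):
            if len(subset) == 20:
                raise RuntimeError("boom")
            return 0.5

        with pytest.raises(IFSEvaluationError, match="tau=20"):
            incremental_feature_selection(benchmark_ranking, boom, [10, 20])

    @pytest.mark.parametrize("taus", [[], [5, 5], [10, 5], [0, 5]])
    def test_invalid_taus(self, benchmark_ranking, taus):
        with pytest.raises(ValueError):
            incremental_feature_selection(benchmark_ranking, lambda s: 0.5, taus)

    def test_default_taus_shape(self):
        taus = default_taus()
        assert taus[0] == 1 and taus[-1] == 8000
        assert taus[:1000] == list(range(1, 1001))
        assert all(b - a == 10 for a, b in zip(taus[1000:], taus[1001:]))


class TestConfidenceLevelSelectorEstimator:
    def test_fit_transform_selects_ranked_prefix(self, small_dataset):
        from vkcotc import encode_dataset

        counts, labels = encode_dataset(small_dataset, normalize=False)
        sel = ConfidenceLevelSelector(tau=25).fit(counts, labels)
        ranked = confidence_levels(build_count_table(small_dataset))
        assert np.array_equal(sel.subset_, ranked.order[:25])
        assert sel.transform(counts).shape == (len(small_dataset), 25)
        assert sel.get_support().sum() == 25

    def test_unfitted_transform_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            ConfidenceLevelSelector().transform(np.zeros((2, 8000)))
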