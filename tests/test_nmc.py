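"""Order-statistic spacing probabilities and the NMC cluster scan."""

from collections import Counter
from itertools import combinations_with_replacement
from math import factorial

import numpy as np
import pytest

import mutclust as mc
from mutclust.variants import MutationProfile


class TestSpacingPvalue:
    def test_full_support_tail_is_one(self):
        assert mc.spacing_pvalue(1, 2, 1.0) == pytest.approx(1.0)

    def test_beta_2_2_symmetry(self):
        assert mc.spacing_pvalue(2, 3, 0.5) == pytest.approx(0.5)

    def test_adjacent_spacing_closed_form(self):
        # spacing between consecutive order statistics: P = 1 - (1 - s)^m
        assert mc.spacing_pvalue(1, 5, 0.2) == pytest.approx(1 - 0.8**5)
        assert mc.spacing_pvalue(1, 2, 0.01) == pytest.approx(1 - 0.99**2)

    @pytest.mark.parametrize("d,m,span", [(0, 5, 0.1), (5, 5, 0.1), (1, 3, 0.0), (1, 3, 1.5)])
    def test_invalid_arguments_raise(self, d, m, span):
        with pytest.raises(ValueError):
            mc.spacing_pvalue(d, m, span)

    @pytest.mark.parametrize("d,m,span", [(1, 10, 0.05), (3, 10, 0.2), (5, 20, 0.1)])
    def test_monte_carlo_oracle(self, d, m, span):
        """Empirical spacing frequencies over 1e5 uniform samples match the Beta tail."""
        rng = np.random.default_rng(20240601)
        draws = np.sort(rng.random((100_000, m)), axis=1)
        spacings = draws[:, d] - draws[:, 0]  # spacing distribution is index-free
        freq = np.mean(spacings <= span)
        p = mc.spacing_pvalue(d, m, span)
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(freq - p) < 5 * se + 1e-12

    def test_increasing_in_span_decreasing_in_co_location(self):
        spans = np.linspace(0.01, 1.0, 25)
        ps = [mc.spacing_pvalue(3, 12, s) for s in spans]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        # at fixed span and m, more co-located events (larger d) means smaller p
        ps_d = [mc.spacing_pvalue(d, 12, 0.05) for d in range(1, 12)]
        assert all(b < a for a, b in zip(ps_d, ps_d[1:]))

    @pytest.mark.parametrize("m,N,i,j", [(4, 8, 1, 3), (5, 10, 2, 4), (6, 12, 2, 6)])
    def test_beta_tail_brackets_exact_discrete_tail(self, m, N, i, j):
        """Exhaustive enumeration over discrete uniform positions brackets the Beta p."""
        d = j - i
        for observed_gap in (0, 1, 2):
            exact = _discrete_tail(i, j, m, N, observed_gap)
            lo = mc.spacing_pvalue(d, m, observed_gap / N) if observed_gap else 0.0
            hi = mc.spacing_pvalue(d, m, (observed_gap + 1) / N)
            assert lo <= exact <= hi


def _discrete_tail(i, j, m, N, gap):
    """P(X_(j) - X_(i) <= gap) by complete enumeration of position multisets."""
    total = 0
    for multiset in combinations_with_replacement(range(1, N + 1), m):
        if multiset[j - 1] - multiset[i - 1] <= gap:
            w = factorial(m)
            for rep in Counter(multiset).values():
                w //= factorial(rep)
            total += w
    return total / N**m


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert mc.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test_unchanged(self):
        assert mc.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_monotone_in_raw_p_and_capped(self):
        rng = np.random.default_rng(7)
        raw = rng.random(200)
        adj = mc.bh_adjust(raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= raw - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mc.bh_adjust([0.2, 1.2])


class TestScan:
    def test_two_tied_events_match_closed_form(self):
        profile = MutationProfile(gene="X", protein_length=100, events=np.array([7, 7]))
        (result,) = mc.nmc_scan(profile)
        assert result.span == pytest.approx(0.01)
        assert result.raw_p == pytest.approx(1 - 0.99**2)
        assert result.single_residue

    def test_extreme_events_cover_whole_protein(self):
        profile = MutationProfile(gene="X", protein_length=50, events=np.array([1, 50]))
        (result,) = mc.nmc_scan(profile)
        assert result.span == pytest.approx(1.0)
        assert result.raw_p == pytest.approx(1.0)

    def test_fewer_than_two_events_rejected(self):
        profile = MutationProfile(gene="X", protein_length=50, events=np.array([3]))
        with pytest.raises(ValueError, match="at least two"):
            mc.nmc_scan(profile)

    def test_pair_count_and_sample_counts(self):
        events = np.array([10, 10, 10, 40, 90])
        profile = MutationProfile(gene="X", protein_length=100, events=events)
        results = mc.nmc_scan(profile)
        assert len(results) == 10  # C(5,2)
        full = next(r for r in results if r.d == 4)
        assert (full.start_residue, full.end_residue, full.n_samples) == (10, 90, 5)

    def test_statistics_invariant_under_event_permutation(self):
        rng = np.random.default_rng(11)
        events = rng.integers(1, 101, size=12)
        base = mc.nmc_scan(MutationProfile("X", 100, events))
        shuffled = mc.nmc_scan(MutationProfile("X", 100, rng.permutation(events)))
        assert [(r.start_residue, r.end_residue, r.raw_p) for r in base] == [
            (r.start_residue, r.end_residue, r.raw_p) for r in shuffled
        ]

    def test_ck2a_strongest_cluster_is_residue_198(self, ck2a_profile, ck2a_domains):
        rows = mc.single_residue_clusters(
            mc.nmc_scan(ck2a_profile), domains=ck2a_domains
        )
        assert rows[0]["residue"] == 198
        assert rows[0]["n_samples"] == 24
        assert rows[0]["domains"] == "Activation segment; P+1 loop"
        assert rows[0]["adj_p"] < 1e-30

    def test_ck2b_reports_residue_32_with_seven_samples(self, ck2b_profile):
        rows = mc.single_residue_clusters(mc.nmc_scan(ck2b_profile))
        assert rows[0]["residue"] == 32
        assert rows[0]["n_samples"] == 7

    def test_distinct_singleton_events_yield_no_hotspots(self):
        profile = MutationProfile(
            gene="X", protein_length=100, events=np.arange(1, 11)
        )
        assert mc.single_residue_clusters(mc.nmc_scan(profile)) == []

    def test_output_sorted_by_adjusted_p_then_residue(self, ck2a_profile):
        rows = mc.single_residue_clusters(mc.nmc_scan(ck2a_profile))
        keys = [(r["adj_p"], r["residue"]) for r in rows]
        assert keys == sorted(keys)
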