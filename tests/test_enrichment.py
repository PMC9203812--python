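"""Exact test, CMLE odds ratio, matched nulls and window association."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as st
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from chromkit.enrichment import (
    ContingencyTable,
    feature_enrichment,
    fisher_exact,
    matched_random_fragments,
    uniform_overlap_probability,
    window_association,
)
from chromkit.genome_io import GenomeModel, GenomicInterval, IntervalSet

from conftest import random_interval_set


def enumeration_oracle_p(a, b, c, d, tol=Fraction(1, 10**7)):
    """Exact-rational two-sided p by full fixed-margin enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(w.values())
    cutoff = Fraction(w[a]) * (1 + tol)
    return float(Fraction(sum(v for v in w.values() if v <= cutoff), total))


class TestFisherExamples:
    def test_balanced_cross_table(self):
        r = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert r.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_symmetric_table_is_null(self):
        r = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert r.p_value == 1.0
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separation(self):
        r = fisher_exact(ContingencyTable(10, 0, 0, 10))
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-10)
        assert r.odds_ratio == math.inf

    def test_zero_margin_undefined(self):
        r = fisher_exact(ContingencyTable(0, 0, 3, 4))
        assert r.p_value == 1.0
        assert not r.or_defined

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestFisherOracles:
    def test_p_matches_rational_enumeration(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            mine = fisher_exact(ContingencyTable(a, b, c, d)).p_value
            assert mine == pytest.approx(
                enumeration_oracle_p(a, b, c, d), abs=1e-12
            )

    def test_p_matches_scipy(self, rng):
        for _ in range(200):
            t = [int(x) for x in rng.integers(0, 40, 4)]
            mine = fisher_exact(ContingencyTable(*t)).p_value
            sp = st.fisher_exact([[t[0], t[1]], [t[2], t[3]]]).pvalue
            assert mine == pytest.approx(sp, abs=1e-9)

    def test_cmle_matches_scipy_conditional(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, 4))
            mine = fisher_exact(ContingencyTable(a, b, c, d)).odds_ratio
            ref = scipy_odds_ratio([[a, b], [c, d]], kind="conditional").statistic
            assert mine == pytest.approx(ref, rel=1e-6)

    def test_cmle_beats_likelihood_grid(self, rng):
        from scipy.special import gammaln, logsumexp

        def loglik(a, b, c, d, psi):
            r1, r2, c1 = a + b, c + d, a + c
            x = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
            lw = (
                gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                + gammaln(r2 + 1) - gammaln(c1 - x + 1)
                - gammaln(r2 - c1 + x + 1)
            )
            return a * np.log(psi) - logsumexp(lw + x * np.log(psi))

        grid = np.logspace(-4, 4, 4001)
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, 4))
            est = fisher_exact(ContingencyTable(a, b, c, d)).odds_ratio
            best = max(loglik(a, b, c, d, g) for g in grid)
            assert loglik(a, b, c, d, est) >= best - 1e-9

    def test_transpose_invariance_and_reciprocal(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, 4))
            r = fisher_exact(ContingencyTable(a, b, c, d))
            rt = fisher_exact(ContingencyTable(a, c, b, d))
            rs = fisher_exact(ContingencyTable(b, a, d, c))
            assert r.p_value == pytest.approx(rt.p_value, abs=1e-12)
            assert r.odds_ratio == pytest.approx(1 / rs.odds_ratio, rel=1e-8)


class TestMatchedRandomFragments:
    def test_empty_observed(self, tiny_genome):
        out = matched_random_fragments(IntervalSet(), tiny_genome, seed=0)
        assert len(out) == 0

    def test_forced_unique_placement(self):
        gm = GenomeModel(chrom_sizes={"chr1": 100})
        obs = IntervalSet([GenomicInterval("chr1", 0, 100)])
        out = matched_random_fragments(obs, gm, seed=3)
        assert (out[0].start, out[0].end) == (0, 100)

    def test_length_multiset_preserved_and_exclusion_respected(self, tiny_genome, rng):
        obs = random_interval_set(rng, 300, size=6000)
        exclude = random_interval_set(rng, 20, size=6000)
        out = matched_random_fragments(obs, tiny_genome, exclude, seed=9)
        assert sorted(out.lengths()) == sorted(obs.lengths())
        assert exclude.count_overlapping(out) == 0

    def test_deterministic_under_seed(self, tiny_genome, rng):
        obs = random_interval_set(rng, 50, size=6000)
        a = matched_random_fragments(obs, tiny_genome, seed=4)
        b = matched_random_fragments(obs, tiny_genome, seed=4)
        assert [(i.chrom, i.start) for i in a] == [(i.chrom, i.start) for i in b]

    def test_impossible_length_names_it(self):
        gm = GenomeModel(chrom_sizes={"chr1": 50})
        obs = IntervalSet([GenomicInterval("chr1", 0, 40)])
        exclude = IntervalSet([GenomicInterval("chr1", 20, 30)])
        with pytest.raises(ValueError, match="40"):
            matched_random_fragments(obs, gm, exclude, seed=0)

    def test_chromosome_allocation_proportional_to_eligible_space(self):
        gm = GenomeModel(chrom_sizes={"chr1": 30_000, "chr2": 10_000})
        obs = IntervalSet(
            [GenomicInterval("chr1", i * 120, i * 120 + 100) for i in range(200)]
        )
        counts = {"chr1": 0, "chr2": 0}
        n_seeds = 50
        for s in range(n_seeds):
            out = matched_random_fragments(obs, gm, seed=s)
            for iv in out:
                counts[iv.chrom] += 1
        # eligible placements: (size - L + 1) per chromosome
        e1, e2 = 30_000 - 99, 10_000 - 99
        p1 = e1 / (e1 + e2)
        n = 200 * n_seeds
        se = math.sqrt(p1 * (1 - p1) / n)
        assert abs(counts["chr1"] / n - p1) < 3 * se


class TestUniformOverlapProbability:
    def test_exact_on_hand_case(self):
        gm = GenomeModel(chrom_sizes={"c": 100})
        feat = IntervalSet([GenomicInterval("c", 40, 50)])
        # L=10: placements 0..90 (91); overlapping: x in [31, 49] -> 19
        p = uniform_overlap_probability([10], feat, gm)
        assert p == pytest.approx(19 / 91)

    def test_matches_monte_carlo(self, tiny_genome, rng):
        feat = random_interval_set(rng, 10, size=6000)
        obs = random_interval_set(rng, 200, size=6000)
        p = uniform_overlap_probability(obs.lengths(), feat, tiny_genome)
        hits, n = 0, 0
        for s in range(30):
            null = matched_random_fragments(obs, tiny_genome, seed=s)
            hits += int(feat.overlaps_any(null).sum())
            n += len(null)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se


class TestFeatureEnrichment:
    def test_saturated_feature_is_undefined(self, tiny_genome):
        feat = IntervalSet(
            [GenomicInterval(c, 0, s) for c, s in tiny_genome.chrom_sizes.items()]
        )
        obs = IntervalSet([GenomicInterval("chr1", 10, 50)])
        r = feature_enrichment(obs, feat, tiny_genome, seed=0)
        assert r.p_value == 1.0
        assert not r.or_defined

    def test_carries_null_provenance(self, tiny_genome, rng):
        obs = random_interval_set(rng, 40, size=6000)
        feat = random_interval_set(rng, 10, size=6000)
        r = feature_enrichment(obs, feat, tiny_genome, seed=17, n_draws=5)
        assert r.null_description["seed"] == 17
        assert len(r.null_description["null_overlap_counts"]) == 5
        assert r.table.a + r.table.b == len(obs)


class TestWindowAssociation:
    @pytest.fixture
    def toy(self):
        genes = [
            GenomicInterval("c", i * 1000, i * 1000 + 500, "+", f"g{i}")
            for i in range(20)
        ]
        background = IntervalSet(genes)
        degs = IntervalSet(genes[:4])
        # peaks inside g0, g1 (DEGs) and g10, g11 (non-DEGs)
        peaks = IntervalSet(
            [GenomicInterval("c", i * 1000 + 100, i * 1000 + 200) for i in (0, 1, 10, 11)]
        )
        return degs, background, peaks

    def test_toy_counts_and_sample_odds_ratio(self, toy):
        degs, background, peaks = toy
        r = window_association(degs, background, peaks, window=0)
        t = r.table
        assert (t.a, t.b, t.c, t.d) == (2, 2, 2, 14)
        assert r.sample_odds_ratio == pytest.approx(7.0)

    def test_window_zero_is_intragenic(self, toy):
        degs, background, peaks = toy
        # a peak just outside a DEG body is only captured with a window
        extra = IntervalSet(list(peaks) + [GenomicInterval("c", 2600, 2700)])
        r0 = window_association(degs, background, extra, window=0)
        r200 = window_association(degs, background, extra, window=200)
        assert r0.table.a == 2 and r200.table.a == 3

    def test_counts_non_decreasing_in_window(self, toy, rng):
        degs, background, _ = toy
        peaks = random_interval_set(rng, 30, chroms=("c",), size=20_000)
        counts = [
            window_association(degs, background, peaks, w).table.a
            for w in (0, 100, 500, 1000)
        ]
        assert counts == sorted(counts)

    def test_gene_outside_universe_rejected(self, toy):
        degs, background, peaks = toy
        rogue = IntervalSet([GenomicInterval("c", 0, 10, "+", "not_a_gene")])
        with pytest.raises(ValueError, match="not_a_gene"):
            window_association(rogue, background, peaks, 0)
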