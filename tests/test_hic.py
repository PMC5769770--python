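import warnings

import numpy as np
import pytest

from tadbound.alleles import Edit, EditScript, lift_matrix_to_backbone, mask_dropped_bins
from tadbound.hic import (
    ContactMatrix,
    RestrictionMap,
    assign_fragment,
    bin_pairs,
    classify_pair,
    compare_domain_intensity,
    compute_mask,
    dedupe,
    filter_pairs,
    ice_normalize,
    make_pair,
    subtract,
)
from tadbound.intervals import GenomicInterval
from tadbound.stats import rank_sum_test
from tadbound.synth import simulate_hic, two_tad_spec

from conftest import exact_two_sided_ranksum_p, symmetric_matrix


class TestAssignFragment:
    def test_plus_strand_shift_crosses_cut_site(self, toy_rmap):
        assert assign_fragment(998, "+", toy_rmap) == 1

    def test_minus_strand_shift_crosses_back(self, toy_rmap):
        assert assign_fragment(1001, "-", toy_rmap) == 0

    def test_interior_position(self, toy_rmap):
        assert assign_fragment(500, "+", toy_rmap) == 0

    def test_clamped_at_ends(self, toy_rmap):
        assert assign_fragment(1999, "+", toy_rmap) == 1
        assert assign_fragment(1, "-", toy_rmap) == 0

    def test_out_of_range(self, toy_rmap):
        with pytest.raises(ValueError):
            assign_fragment(2000, "+", toy_rmap)


class TestClassifyPair:
    @pytest.fixture
    def rmap(self):
        return RestrictionMap("chr1", list(range(0, 11_000, 1000)))

    def test_same_fragment_inward_is_dangling_end(self, rmap):
        p = make_pair("chr1", 7100, "+", "chr1", 7800, "-")
        assert classify_pair(p, rmap) == "dangling_end"

    def test_same_fragment_outward_is_self_circle(self, rmap):
        p = make_pair("chr1", 7100, "-", "chr1", 7800, "+")
        assert classify_pair(p, rmap) == "self_circle"

    def test_same_fragment_same_strand_is_error(self, rmap):
        p = make_pair("chr1", 7100, "+", "chr1", 7800, "+")
        assert classify_pair(p, rmap) == "error_pair"

    def test_different_fragments_valid(self, rmap):
        p = make_pair("chr1", 3500, "-", "chr1", 9500, "+")
        assert classify_pair(p, rmap) == "valid"

    def test_single_side(self, rmap):
        p = make_pair("chr1", 3500, "+", "chr1", 9500, "+", mapped2=False)
        assert classify_pair(p, rmap) == "single_side"

    def test_partition_property(self, rmap, rng):
        pairs = [
            make_pair(
                "chr1", int(rng.integers(0, 10_000)), "+-"[rng.integers(2)],
                "chr1", int(rng.integers(0, 10_000)), "+-"[rng.integers(2)],
                mapped2=bool(rng.integers(0, 5)),
            )
            for _ in range(500)
        ]
        kept, tally = filter_pairs(pairs, rmap)
        assert sum(tally.values()) == len(pairs)
        assert tally["valid"] == len(kept)


class TestDedupe:
    def test_identical_records_collapse(self):
        p = make_pair("chr1", 10, "+", "chr1", 500, "-")
        assert dedupe([p, p, p]) == [p]

    def test_strand_difference_kept(self):
        a = make_pair("chr1", 10, "+", "chr1", 500, "-")
        b = make_pair("chr1", 10, "-", "chr1", 500, "-")
        assert dedupe([a, b]) == [a, b]

    def test_order_of_first_occurrence(self):
        a = make_pair("chr1", 10, "+", "chr1", 500, "-")
        b = make_pair("chr1", 20, "+", "chr1", 600, "-")
        assert dedupe([b, a, b, a]) == [b, a]

    def test_large_duplicate_fraction_matches_set_oracle(self, rng):
        base = [
            make_pair(
                "chr1", int(rng.integers(0, 100_000)), "+-"[rng.integers(2)],
                "chr1", int(rng.integers(0, 100_000)), "+-"[rng.integers(2)],
            )
            for _ in range(8800)
        ]
        dupes = [base[i] for i in rng.integers(0, len(base), size=1200)]
        pairs = base + dupes
        expected = len(
            {(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2) for p in pairs}
        )
        assert len(dedupe(pairs)) == expected


class TestBinPairs:
    def test_midpoint_bin_assignment(self):
        # fragment [74,399,000, 74,401,000) has midpoint 74,400,000 -> bin 1860
        edges = [0, 74_000_000, 74_399_000, 74_401_000, 74_800_000]
        rmap = RestrictionMap("chr2", edges)
        extent = GenomicInterval("chr2", 74_000_000, 74_800_000)
        p = make_pair("chr2", 74_100_000, "+", "chr2", 74_399_500, "+")
        m = bin_pairs([p], rmap, 40_000, extent)
        offset = 74_000_000 // 40_000
        b1 = 74_199_500 // 40_000 - offset  # midpoint of [74.0M, 74.399M)
        b2 = 1860 - offset
        assert m.counts[b1, b2] == 1 and m.counts[b2, b1] == 1

    def test_midpoint_on_edge_goes_right(self):
        # midpoint exactly at 80,000 must land in bin 2 (floor convention)
        edges = [0, 79_000, 81_000, 120_000]
        rmap = RestrictionMap("chr2", edges)
        extent = GenomicInterval("chr2", 0, 120_000)
        p = make_pair("chr2", 79_100, "+", "chr2", 100, "+")
        m = bin_pairs([p], rmap, 40_000, extent)
        assert m.counts[0, 2] == 1 and m.counts[2, 0] == 1

    def test_count_conservation(self, rng):
        rmap = RestrictionMap.regular("chrS", 400_000, 4_000)
        extent = GenomicInterval("chrS", 0, 400_000)
        pairs = [
            make_pair(
                "chrS", int(rng.integers(10, 399_000)), "+",
                "chrS", int(rng.integers(10, 399_000)), "-",
            )
            for _ in range(1000)
        ]
        m = bin_pairs(pairs, rmap, 40_000, extent)
        assert m.total_pairs() == 1000
        assert m.discarded == 0

    def test_outside_extent_tallied(self):
        rmap = RestrictionMap.regular("chrS", 400_000, 4_000)
        extent = GenomicInterval("chrS", 0, 80_000)
        pairs = [make_pair("chrS", 100, "+", "chrS", 399_000, "-")]
        m = bin_pairs(pairs, rmap, 40_000, extent)
        assert m.discarded == 1
        assert m.total_pairs() == 0


class TestComputeMask:
    def make_matrix(self):
        # 4 bins, 200 pairs total, bin 0 marginal 9 (< 100/10)
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 9
        counts[1, 2] = counts[2, 1] = 80
        counts[2, 3] = counts[3, 2] = 71
        counts[1, 3] = counts[3, 1] = 40
        return ContactMatrix("chrS", 0, 1000, counts)

    def test_marginal_rule(self):
        m = self.make_matrix()
        assert m.total_pairs() == 200
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = compute_mask(m)
        assert mask[0]
        assert not mask[1:].any()

    def test_fragment_rule_strict_boundary(self):
        m = ContactMatrix("chrS", 0, 1200, self.make_matrix().counts)
        rmap = RestrictionMap.regular("chrS", 4800, 200)
        # 6 fragments per bin; bin 1: 3 of 6 covered (not masked),
        # bin 2: 2 of 6 covered (masked)
        reads = np.zeros(rmap.n_fragments)
        for b, n_cov in ((0, 6), (1, 3), (2, 2), (3, 6)):
            frags = [i for i in range(rmap.n_fragments) if rmap.midpoint(i) // 1200 == b]
            assert len(frags) == 6
            for f in frags[:n_cov]:
                reads[f] = 2
        mask = compute_mask(m, fragment_reads=reads, rmap=rmap)
        assert mask[0]  # marginal rule
        assert not mask[1]  # exactly half covered: "less than half" is strict
        assert mask[2]
        assert not mask[3]

    def test_missing_coverage_warns(self):
        m = self.make_matrix()
        with pytest.warns(UserWarning, match="marginal rule only"):
            compute_mask(m)


class TestIceNormalize:
    def test_balanced_matrix_unchanged(self):
        m = ContactMatrix("chrS", 0, 1000, np.array([[0.0, 4.0], [4.0, 0.0]]))
        out = ice_normalize(m)
        np.testing.assert_allclose(out.counts, m.counts)
        np.testing.assert_allclose(out.biases[0], out.biases[1])
        assert out.normalized and out.converged

    def test_all_masked_raises(self):
        m = ContactMatrix(
            "chrS", 0, 1000, np.zeros((3, 3)), mask=np.ones(3, dtype=bool)
        )
        with pytest.raises(ValueError, match="no unmasked bins"):
            ice_normalize(m)

    def test_planted_bias_recovery(self):
        # oracle: independent fixed-point iteration to machine tolerance
        b = np.array([1.0, 2.0, 0.5, 1.0, 1.0])
        base = np.ones((5, 5)) * 3.0
        raw = base * np.outer(b, b)
        m = ContactMatrix("chrS", 0, 1000, raw)
        out = ice_normalize(m, tol=1e-10, max_iter=2000)
        est = np.ones(5)
        W = raw.copy()
        for _ in range(200_000):
            marg = W.sum(axis=1)
            db = marg / marg.mean()
            if np.max(np.abs(db - 1)) < 1e-15:
                break
            W /= np.outer(db, db)
            est *= db
        ratio_oracle = est / np.exp(np.mean(np.log(est)))
        np.testing.assert_allclose(out.biases, ratio_oracle, rtol=1e-6)
        # recovered proportional to planted within 1e-4
        scaled = out.biases / out.biases[0] * b[0]
        np.testing.assert_allclose(scaled, b, rtol=1e-4)

    def test_sum_preserved_and_marginal_cv(self, rng):
        counts = symmetric_matrix(rng, 20, 1, 100)
        m = ContactMatrix("chrS", 0, 1000, counts, mask=np.arange(20) == 3)
        m = m.with_mask(m.mask)
        out = ice_normalize(m, tol=1e-8, max_iter=5000)
        active = ~out.mask
        before = m.counts[np.ix_(active, active)].sum()
        after = out.counts[np.ix_(active, active)].sum()
        assert abs(after - before) / before < 1e-9
        marg = out.counts.sum(axis=1)[active]
        assert marg.std() / marg.mean() < 1e-7
        # biases normalized to unit geometric mean over unmasked bins
        assert abs(np.exp(np.mean(np.log(out.biases[active]))) - 1) < 1e-9
        assert np.isnan(out.biases[3])

    def test_nonconvergence_flagged(self, rng):
        counts = symmetric_matrix(rng, 10, 1, 100)
        m = ContactMatrix("chrS", 0, 1000, counts)
        with pytest.warns(UserWarning, match="did not converge"):
            out = ice_normalize(m, tol=1e-12, max_iter=2)
        assert out.converged is False


class TestSubtract:
    def normed(self, rng, n=8):
        m = ContactMatrix("chrS", 0, 1000, symmetric_matrix(rng, n))
        return ice_normalize(m, tol=1e-8, max_iter=5000)

    def test_self_subtraction_zero(self, rng):
        a = self.normed(rng)
        d = subtract(a, a)
        active = ~d.mask
        assert np.all(d.counts[np.ix_(active, active)] == 0)

    def test_antisymmetry(self, rng):
        a, b = self.normed(rng), self.normed(rng)
        d1, d2 = subtract(a, b), subtract(b, a)
        np.testing.assert_allclose(d1.counts, -d2.counts, equal_nan=True)

    def test_grid_mismatch(self, rng):
        a = self.normed(rng)
        b = ContactMatrix("chrS", 0, 2000, a.counts.copy(), normalized=True)
        with pytest.raises(ValueError, match="grid"):
            subtract(a, b)

    def test_requires_normalized(self, rng):
        a = self.normed(rng)
        raw = ContactMatrix("chrS", 0, 1000, a.counts.copy())
        with pytest.raises(ValueError, match="normalized"):
            subtract(a, raw)

    def test_union_mask_is_nan(self, rng):
        a, b = self.normed(rng), self.normed(rng)
        am = a.with_mask(np.arange(8) == 2)
        d = subtract(am, b)
        assert np.isnan(d.counts[2]).all()

    def test_deletion_difference_concentrates_at_fusion(self):
        """Difference of wt vs fused-allele expected matrices is largest on
        cross-boundary entries (generative-model oracle)."""
        from tadbound.synth import apply_allele, expected_hic_matrix

        spec = two_tad_spec(n_bins=60, bin_size=40_000, rho=0.1, seed=0)
        script = EditScript(
            "chrS", spec.extent.end,
            (Edit("deletion", spec.boundary_region, label="del-full"),),
        )
        mut_spec, _ = apply_allele(spec, script)
        wt_m, _ = simulate_hic(spec, noiseless=True)
        mut_m, _ = simulate_hic(mut_spec, noiseless=True)
        wt_n = ice_normalize(wt_m, tol=1e-9, max_iter=10_000)
        mut_n = ice_normalize(mut_m, tol=1e-9, max_iter=10_000)
        lifted, dropped = lift_matrix_to_backbone(
            mut_n, script.coordinate_map(), wt_extent=spec.extent
        )
        wt_cmp = mask_dropped_bins(wt_n, dropped)
        diff = subtract(lifted, wt_cmp)
        wall_bin = spec.wall // spec.bin_size
        cross = np.zeros_like(diff.counts, dtype=bool)
        cross[:wall_bin, wall_bin:] = True
        cross |= cross.T
        ok = ~np.isnan(diff.counts)
        np.fill_diagonal(ok, False)
        gain_cross = np.nanmean(diff.counts[cross & ok])
        rest = np.nanmean(np.abs(diff.counts[~cross & ok]))
        assert gain_cross > 0
        assert gain_cross > 1.5 * rest


class TestCompareDomainIntensity:
    def build(self, values, n=5, domain_bins=(0, 5)):
        counts = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        counts[iu, ju] = values
        counts[ju, iu] = values
        return ContactMatrix("chrS", 0, 1000, counts, normalized=True)

    def test_identical_matrices_p_near_one(self, rng):
        vals = rng.uniform(1, 10, size=10)
        a = self.build(vals)
        cmp_ = compare_domain_intensity(a, a, GenomicInterval("chrS", 0, 5000))
        assert cmp_.p_value > 0.9
        assert cmp_.n_bins_used == 5

    def test_matches_rank_sum_of_offdiag_values(self, rng):
        va, vb = rng.uniform(1, 10, size=10), rng.uniform(1, 10, size=10)
        a, b = self.build(va), self.build(vb)
        cmp_ = compare_domain_intensity(a, b, GenomicInterval("chrS", 0, 5000))
        stat, p = rank_sum_test(va, vb)
        assert cmp_.p_value == pytest.approx(p)
        assert cmp_.statistic == pytest.approx(stat)

    def test_too_few_bins_raises(self, rng):
        a = self.build(rng.uniform(1, 10, size=10))
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_domain_intensity(a, a, GenomicInterval("chrS", 0, 1000))

    def test_block_factor_detected_across_seeds(self):
        """1.5x contact intensity in one TAD only ("active" vs "inactive"):
        p < 0.05 in nearly all seeds.

        Matrices are depth-normalized (equal totals): iterative correction
        would absorb a spatially uniform block factor into its bias vector,
        so the factor must be compared on visibility-preserving matrices.
        """
        from dataclasses import replace as dc_replace

        from tadbound.synth import TADBlock

        def depth_normalized(m):
            return ContactMatrix(
                m.chrom, m.start, m.bin_size,
                m.counts * (1e6 / m.total_pairs()), normalized=True,
            )

        domain = GenomicInterval("chrS", 0, 840_000)  # 21 bins -> 210 values
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            sa = two_tad_spec(n_bins=50, intra_factor=3.0, coverage=150_000, seed=seed)
            sb = dc_replace(
                two_tad_spec(n_bins=50, intra_factor=3.0, coverage=150_000,
                             seed=seed + 1000),
                tads=(
                    TADBlock(sa.tads[0].interval, 4.5),  # "active" first TAD
                    TADBlock(sa.tads[1].interval, 3.0),
                ),
            )
            ma, _ = simulate_hic(sa)
            mb, _ = simulate_hic(sb)
            na, nb = depth_normalized(ma), depth_normalized(mb)
            if compare_domain_intensity(na, nb, domain).p_value < 0.05:
                hits += 1
        assert hits >= n_seeds - 2


class TestRankSumExactness:
    def test_canonical_three_vs_three(self):
        # {1,2,3} vs {4,5,6}: exhaustive two-sided p over all 20 rank splits
        oracle = exact_two_sided_ranksum_p([1, 2, 3], [4, 5, 6])
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert oracle == pytest.approx(0.1)
        assert p == pytest.approx(oracle)

    def test_random_tie_free_samples(self, rng):
        for _ in range(25):
            vals = rng.choice(1000, size=6, replace=False)
            x, y = vals[:3], vals[3:]
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(exact_two_sided_ranksum_p(x, y))
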