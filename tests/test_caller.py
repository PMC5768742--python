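import numpy as np
import pytest
import scipy.sparse as sp

import tadscape as ts
from tadscape.caller import (
    CallerConfig,
    Domain,
    DomainSet,
    boundary_centers,
    call_domains_consensus,
    call_domains_dp,
    contiguity_fraction,
    domain_quality,
    domain_size_stats,
    nest_domains,
    optimal_segmentation,
    read_domains,
    readdesert_fallback,
    write_domains,
)
from tadscape.matrix import ContactMatrix


def brute_force_best(qt, min_bins):
    """Exhaustive search over all valid segmentations (left-to-right sums)."""

    best = {"obj": 0.0}

    def rec(pos, acc, doms):
        if acc > best["obj"]:
            best["obj"], best["doms"] = acc, list(doms)
        for k in range(pos, qt.n):
            for l in range(k + min_bins - 1, qt.n):
                g = qt.qprime(k, l)
                if g > 0:
                    doms.append((k, l))
                    rec(l + 1, acc + g, doms)
                    doms.pop()

    rec(0, 0.0, [])
    return best["obj"]


def block_matrix(n, blocks, high=10.0, low=0.5):
    a = np.full((n, n), low)
    for s, e in blocks:
        a[s : e + 1, s : e + 1] = high
    np.fill_diagonal(a, 0.0)
    return a


class TestQuality:
    def test_two_bin_interval(self):
        qt = domain_quality(np.array([[0.0, 3.0], [3.0, 0.0]]), gamma=1.0)
        assert qt.q[0, 1] == pytest.approx(3.0)
        assert qt.mu[1] == pytest.approx(3.0)
        assert qt.qprime(0, 1) == pytest.approx(0.0)

    def test_gamma_zero_is_raw_sum(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(5, 5))
        a = a + a.T
        qt = domain_quality(a, gamma=0.0)
        for k in range(5):
            for l in range(k + 1, 5):
                assert qt.q[k, l - k] == pytest.approx(np.triu(a[k : l + 1, k : l + 1]).sum())

    def test_against_quartic_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(8, 8))
        a = a + a.T
        gamma = 0.7
        qt = domain_quality(a, gamma=gamma)
        for k in range(8):
            for l in range(k + 1, 8):
                s = sum(a[i, j] for i in range(k, l + 1) for j in range(i, l + 1))
                assert qt.q[k, l - k] == pytest.approx(s / (l - k) ** gamma)
        for d in range(1, 8):
            mus = [qt.q[k, d] for k in range(8 - d)]
            assert qt.mu[d] == pytest.approx(np.mean(mus))


class TestSegmentationDP:
    def test_matches_exhaustive_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            a = rng.uniform(size=(n, n))
            a = a + a.T
            qt = domain_quality(a, gamma=float(rng.uniform(0.2, 1.5)))
            segs = optimal_segmentation(qt, min_domain_bins=2)
            obj = sum(s for _, _, s in segs)
            assert obj == pytest.approx(brute_force_best(qt, 2), abs=1e-12)

    def test_two_dense_blocks_recovered_exactly(self):
        a = block_matrix(8, [(0, 3), (4, 7)])
        qt = domain_quality(a, gamma=0.5)
        segs = optimal_segmentation(qt, 2)
        assert [(k, l) for k, l, _ in segs] == [(0, 3), (4, 7)]
        obj = sum(s for _, _, s in segs)
        assert obj == pytest.approx(brute_force_best(qt, 2), abs=1e-12)

    def test_all_zero_matrix_no_domains(self):
        qt = domain_quality(np.zeros((6, 6)), gamma=0.9)
        assert optimal_segmentation(qt, 2) == []

    def test_single_dense_block_covers_axis(self):
        # one dense block over (almost) the whole axis -> a single domain; a
        # perfectly uniform full-span matrix has q' identically 0 (mu equals q)
        # and correctly yields nothing, so contrast comes from weak flank bins
        a = block_matrix(8, [(1, 6)], high=5.0, low=0.1)
        qt = domain_quality(a, gamma=0.5)
        segs = optimal_segmentation(qt, 2)
        assert [(k, l) for k, l, _ in segs] == [(1, 6)]

    def test_chromosome_shorter_than_min_bins(self, tiny_fragments):
        counts = sp.csr_matrix((6, 6))
        m = ContactMatrix(tiny_fragments, counts)
        ds = call_domains_dp(m, CallerConfig(min_domain_bins=3))
        assert len([d for d in ds if d.chrom == "chr2"]) == 0  # chr2 has 2 fragments

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = block_matrix(12, [(0, 5), (6, 11)]) + rng.uniform(0, 0.1, size=(12, 12))
        a = np.triu(a) + np.triu(a, 1).T
        np.fill_diagonal(a, 0)
        qt1 = domain_quality(a, gamma=0.9)
        qt2 = domain_quality(2.5 * a, gamma=0.9)
        s1 = [(k, l) for k, l, _ in optimal_segmentation(qt1, 2)]
        s2 = [(k, l) for k, l, _ in optimal_segmentation(qt2, 2)]
        assert s1 == s2


def _matrix_from_dense(fragments, a):
    return ContactMatrix(fragments, sp.csr_matrix(np.triu(a)))


class TestFallback:
    def _design(self, deserts=()):
        return ts.SyntheticDesign(
            genome=ts.GenomeLayout((("chrS", 400_000),)),
            depth=1.1e6,
            seed=11,
            deserts=deserts,
        )

    def test_no_masked_bins_is_noop(self, small_matrix, small_tads):
        out, triggered = readdesert_fallback(small_matrix, small_tads, CallerConfig(max_domain_bins=600))
        assert triggered == []
        assert [(d.start_bin, d.end_bin) for d in out] == [
            (d.start_bin, d.end_bin) for d in small_tads
        ]

    def test_desert_at_boundary_triggers_fallback_gamma(self):
        import tadscape.synthetic as syn

        design = self._design(deserts=(("chrS", 200_000, 202_000),))
        fm = syn.make_fragment_map(design)
        truth = syn.build_ground_truth(design, fm)
        m = ts.ice_normalize(syn.simulate_contact_matrix(design, fm, truth))
        cfg = CallerConfig(max_domain_bins=500)
        tads = call_domains_dp(m, cfg)
        out, triggered = readdesert_fallback(m, tads, cfg)
        assert len(triggered) >= 1
        assert all(d.gamma_used == cfg.gamma_fallback for d in out)

    def test_desert_far_from_boundaries_no_rerun(self, tiny_fragments):
        # one big dense block on chr1; chr2 fully masked but has no domains
        a = np.zeros((6, 6))
        a[:4, :4] = 5.0
        np.fill_diagonal(a, 0)
        m = ts.ice_normalize(_matrix_from_dense(tiny_fragments, a))
        doms = DomainSet("TAD", [Domain("chr1", 0, 3, 0, 1000, 1.0, 0.9)], axis=tiny_fragments)
        cfg = CallerConfig(desert_min=3)
        out, triggered = readdesert_fallback(m, doms, cfg)
        # chr2's 2-bin masked run is below desert_min and has no boundaries
        assert triggered == []
        assert [d.gamma_used for d in out] == [0.9]


class TestBoundaryGeometry:
    def _domains(self, spans, chrom="c"):
        doms = [
            Domain(chrom, 0, 0, s, e, 1.0, 0.9) for s, e in spans
        ]
        return DomainSet("TAD", doms)

    def test_midpoint_center(self):
        ds = self._domains([(0, 5000), (7000, 9000)])
        bs = boundary_centers(ds)
        assert bs.centers == [("c", 6000)]

    def test_zero_gap_center(self):
        ds = self._domains([(0, 5000), (5000, 9000)])
        assert boundary_centers(ds).centers == [("c", 5000)]

    def test_three_domains_two_centers(self):
        ds = self._domains([(0, 100), (200, 300), (400, 500)])
        assert len(boundary_centers(ds)) == 2


class TestContiguity:
    def test_adjacent_fragments_count_as_same(self, tiny_fragments):
        doms = DomainSet(
            "TAD",
            [
                Domain("chr1", 0, 1, 0, 500, 1.0, 0.9),
                Domain("chr1", 2, 3, 500, 1000, 1.0, 0.9),
            ],
            axis=tiny_fragments,
        )
        frac, table = contiguity_fraction(doms, tiny_fragments)
        assert frac == 1.0
        assert table["gap_fragments"].tolist() == [0]

    def test_mixed_junctions(self):
        genome = ts.GenomeLayout((("c", 2000),))
        fm = ts.FragmentMap(
            genome, starts={"c": np.arange(20) * 100}, ends={"c": np.arange(1, 21) * 100}
        )
        doms = DomainSet(
            "TAD",
            [
                Domain("c", 0, 4, 0, 500, 1, 0.9),
                Domain("c", 5, 9, 500, 1000, 1, 0.9),
                Domain("c", 15, 19, 1500, 2000, 1, 0.9),
            ],
            axis=fm,
        )
        frac, table = contiguity_fraction(doms, fm)
        assert frac == 0.5
        assert table["gap_fragments"].tolist() == [0, 5]

    def test_planted_synthetic_contiguity(self, small_truth, small_tads):
        frac, _ = contiguity_fraction(small_tads, small_truth.fragments)
        assert frac >= 0.9


class TestNesting:
    def _super(self):
        return DomainSet("super-TAD", [Domain("c", 0, 0, 0, 10_000, 1, 0.9)],
                         axis=None)

    def test_majority_overlap_assigned(self):
        genome = ts.GenomeLayout((("c", 30_000),))
        tads = DomainSet("TAD", [Domain("c", 0, 0, 8_000, 13_000, 1, 0.9)])
        supers = DomainSet("super-TAD", [Domain("c", 0, 0, 0, 12_000, 1, 0.9)])
        tads.axis = supers.axis = ts.BinnedAxis(genome, 1000)
        res = nest_domains(tads, supers, inclusion=0.75)
        assert res.assignment.loc[0, "region"] == "super-TAD"  # 80% inside

    def test_half_overlap_unassigned_at_75(self):
        genome = ts.GenomeLayout((("c", 30_000),))
        tads = DomainSet("TAD", [Domain("c", 0, 0, 9_500, 14_500, 1, 0.9)])
        supers = DomainSet("super-TAD", [Domain("c", 0, 0, 0, 12_000, 1, 0.9)])
        tads.axis = supers.axis = ts.BinnedAxis(genome, 1000)
        res = nest_domains(tads, supers, inclusion=0.75)
        assert res.assignment.loc[0, "region"] is None

    def test_tad_in_gap_assigned_to_inter(self):
        genome = ts.GenomeLayout((("c", 50_000),))
        tads = DomainSet("TAD", [Domain("c", 0, 0, 15_000, 20_000, 1, 0.9)])
        supers = DomainSet(
            "super-TAD",
            [Domain("c", 0, 0, 0, 12_000, 1, 0.9), Domain("c", 0, 0, 30_000, 50_000, 1, 0.9)],
        )
        tads.axis = supers.axis = ts.BinnedAxis(genome, 1000)
        res = nest_domains(tads, supers, inclusion=0.75)
        assert res.assignment.loc[0, "region"] == "inter-super-TAD"
        assert res.counts_inter.sum() == 1


class TestSizeStats:
    def test_odd_count_median(self):
        doms = DomainSet(
            "TAD",
            [
                Domain("c", 0, 0, 0, 3_000, 1, 0.9),
                Domain("c", 0, 0, 10_000, 23_000, 1, 0.9),
                Domain("c", 0, 0, 100_000, 560_000, 1, 0.9),
            ],
        )
        stats = domain_size_stats(doms, total_bp=1_000_000)
        assert stats["median_bp"] == 13_000

    def test_half_coverage(self):
        doms = DomainSet("TAD", [Domain("c", 0, 0, 0, 500_000, 1, 0.9)])
        assert domain_size_stats(doms, total_bp=1_000_000)["coverage"] == 0.5

    def test_planted_sizes_match_truth(self, small_truth):
        stats = domain_size_stats(small_truth.tads, total_bp=1_000_000)
        assert stats["median_bp"] == pytest.approx(np.median(small_truth.tads.sizes()))


class TestDomainIO:
    def test_bed_round_trip(self, tiny_fragments, tmp_path):
        doms = DomainSet(
            "TAD",
            [
                Domain("chr1", 0, 1, 0, 500, 1.25, 0.9),
                Domain("chr1", 2, 3, 500, 1000, 0.5, 0.6),
            ],
            axis=tiny_fragments,
        )
        path = tmp_path / "doms.bed"
        write_domains(doms, path)
        back = read_domains(path, axis=tiny_fragments)
        assert back.level == "TAD"
        assert [(d.start_bp, d.end_bp, d.start_bin, d.end_bin, d.gamma_used) for d in back] == [
            (0, 500, 0, 1, 0.9),
            (500, 1000, 2, 3, 0.6),
        ]


def test_consensus_keeps_stable_blocks():
    a = block_matrix(12, [(0, 5), (6, 11)])
    genome = ts.GenomeLayout((("c", 1200),))
    fm = ts.FragmentMap(
        genome, starts={"c": np.arange(12) * 100}, ends={"c": np.arange(1, 13) * 100}
    )
    m = ContactMatrix(fm, sp.csr_matrix(np.triu(a)))
    cfg = CallerConfig(gamma_max=1.5, gamma_step=0.25)
    ds = call_domains_consensus(m, cfg)
    assert [(d.start_bin, d.end_bin) for d in ds] == [(0, 5), (6, 11)]


def test_called_domains_never_overlap(small_tads):
    for chrom, ds in small_tads.per_chrom().items():
        for a, b in zip(ds, ds[1:]):
            assert b.start_bin > a.end_bin
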