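import numpy as np
import pytest

from breakscape import hic
from breakscape.model import ContactMatrix, DamageDomain, GenomicInterval, ValidationError


def _random_intra(rng, n, res=100):
    raw = rng.random((n, n)) * 5
    sym = np.triu(raw) + np.triu(raw, 1).T
    return ContactMatrix("chr1", "chr1", res, sym)


def _brute_expected(counts):
    n = len(counts)
    return [
        np.mean([counts[i, i + d] for i in range(n - d)]) for d in range(n)
    ]


class TestExpectedProfile:
    def test_worked_example(self, worked_matrix):
        prof = hic.expected_profile(worked_matrix)
        np.testing.assert_allclose(prof.values, [4.0, 2.0, 1.0])

    def test_constant_matrix(self):
        m = ContactMatrix("chr1", "chr1", 100, np.full((4, 4), 2.0))
        np.testing.assert_allclose(hic.expected_profile(m).values, 2.0)

    def test_single_bin(self):
        m = ContactMatrix("chr1", "chr1", 100, np.array([[3.0]]))
        assert hic.expected_profile(m).values.tolist() == [3.0]

    def test_inter_matrix_rejected(self):
        m = ContactMatrix("chr1", "chr2", 100, np.ones((2, 3)))
        with pytest.raises(ValidationError):
            hic.expected_profile(m)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(20)[:]:
            m = _random_intra(rng, int(rng.integers(2, 30)))
            np.testing.assert_allclose(
                hic.expected_profile(m).values, _brute_expected(m.counts)
            )


class TestOENormalize:
    def test_worked_example(self, worked_matrix):
        oe = hic.oe_normalize(worked_matrix)
        assert oe.counts[0, 1] == pytest.approx(1.5)
        assert oe.counts[1, 2] == pytest.approx(0.5)
        assert oe.counts[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(oe.counts), 1.0)

    def test_distance_only_matrix_gives_all_ones(self):
        # entries depending only on |i-j| must normalize to exactly 1
        n = 12
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = ContactMatrix("chr1", "chr1", 100, 10.0 / (d + 1.0))
        np.testing.assert_allclose(hic.oe_normalize(m).counts, 1.0)

    def test_zero_matrix_fully_masked(self):
        m = ContactMatrix("chr1", "chr1", 100, np.zeros((3, 3)))
        assert np.isnan(hic.oe_normalize(m).counts).all()

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(11)
        oe = hic.oe_normalize(_random_intra(rng, 15)).counts
        np.testing.assert_allclose(oe, oe.T)


class TestDomainScores:
    def test_worked_intra_score(self, worked_matrix):
        oe = hic.oe_normalize(worked_matrix)
        dom = DamageDomain(GenomicInterval("chr1", 0, 300), "TAD", True)
        score = hic.intra_domain_score(oe, dom)
        assert score.score == pytest.approx(1.0)  # (1.5 + 1.0 + 0.5) / 3
        assert score.n_pairs == 3

    def test_all_ones_matrix_scores_one(self):
        m = ContactMatrix("chr1", "chr1", 100, np.ones((5, 5)))
        dom = DamageDomain(GenomicInterval("chr1", 0, 500), "TAD", True)
        assert hic.intra_domain_score(hic.oe_normalize(m), dom).score == 1.0

    def test_single_bin_domain_errors(self, worked_matrix):
        oe = hic.oe_normalize(worked_matrix)
        dom = DamageDomain(GenomicInterval("chr1", 0, 100), "TAD", True)
        with pytest.raises(ValidationError):
            hic.intra_domain_score(oe, dom)

    def test_intra_score_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            oe = hic.oe_normalize(_random_intra(rng, n))
            b0, b1 = sorted(rng.choice(n, size=2, replace=False))
            b1 += 1
            if b1 - b0 < 2:
                continue
            dom = DamageDomain(
                GenomicInterval("chr1", b0 * 100, b1 * 100), "TAD", True
            )
            vals = [
                oe.counts[i, j]
                for i in range(b0, b1)
                for j in range(i + 1, b1)
                if not np.isnan(oe.counts[i, j])
            ]
            assert hic.intra_domain_score(oe, dom).score == pytest.approx(
                np.mean(vals)
            )

    def test_rectangle_score_matches_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(8, 30))
            oe = hic.oe_normalize(_random_intra(rng, n))
            mid = n // 2
            dom_a = DamageDomain(
                GenomicInterval("chr1", 0, (mid - 1) * 100), "TAD", True
            )
            dom_b = DamageDomain(
                GenomicInterval("chr1", mid * 100, n * 100), "TAD", True
            )
            vals = [
                oe.counts[i, j]
                for i in range(0, mid - 1)
                for j in range(mid, n)
                if not np.isnan(oe.counts[i, j])
            ]
            assert hic.inter_domain_score(oe, dom_a, dom_b).score == pytest.approx(
                np.mean(vals)
            )

    def test_overlapping_domains_rejected(self, worked_matrix):
        oe = hic.oe_normalize(worked_matrix)
        a = DamageDomain(GenomicInterval("chr1", 0, 200), "TAD", True)
        b = DamageDomain(GenomicInterval("chr1", 100, 300), "TAD", True)
        with pytest.raises(ValidationError):
            hic.inter_domain_score(oe, a, b)


class TestDomainFC:
    def test_identical_conditions_fc_one(self):
        rng = np.random.default_rng(14)
        m = _random_intra(rng, 20)
        domains = [
            DamageDomain(GenomicInterval("chr1", 0, 1000), "TAD", True),
            DamageDomain(GenomicInterval("chr1", 1000, 2000), "TAD", False),
        ]
        table, _ = hic.intra_domain_fc(m, m, domains)
        np.testing.assert_allclose(table.fc, 1.0)
        pairs = [(domains[0], domains[1])]
        ptable, _ = hic.inter_domain_pair_fc(m, m, pairs)
        np.testing.assert_allclose(ptable.fc, 1.0)

    def test_fc_invariant_under_depth_doubling(self):
        rng = np.random.default_rng(15)
        t, u = _random_intra(rng, 20), _random_intra(rng, 20)
        domains = [DamageDomain(GenomicInterval("chr1", 0, 800), "TAD", True)]
        fc1 = hic.intra_domain_fc(t, u, domains)[0].fc.iloc[0]
        t2 = ContactMatrix("chr1", "chr1", 100, 2 * t.counts)
        u2 = ContactMatrix("chr1", "chr1", 100, 2 * u.counts)
        fc2 = hic.intra_domain_fc(t2, u2, domains)[0].fc.iloc[0]
        assert fc2 == pytest.approx(fc1, rel=1e-12)


class TestViewpoint:
    def test_zero_matrices_give_zero_track(self):
        m = ContactMatrix("chr1", "chr1", 100, np.zeros((30, 30)))
        _, v = hic.viewpoint_track(m, m, 10, half_window=1000)
        np.testing.assert_allclose(v, 0.0)

    def test_simple_ratio(self):
        t = ContactMatrix("chr1", "chr1", 100, np.full((5, 5), 3.0))
        u = ContactMatrix("chr1", "chr1", 100, np.full((5, 5), 1.0))
        _, v = hic.viewpoint_track(t, u, 2, half_window=100)
        np.testing.assert_allclose(v, 1.0)  # log2(4/2)

    def test_window_clipped_at_chromosome_start(self):
        m = ContactMatrix("chr1", "chr1", 100, np.ones((50, 50)))
        bins, v = hic.viewpoint_track(m, m, 0, half_window=1000)
        assert bins[0] == 0 and len(bins) == 1000 // 100 + 1

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(16)
        t, u = _random_intra(rng, 40), _random_intra(rng, 40)
        _, v1 = hic.viewpoint_track(t, u, 20, half_window=1500)
        _, v2 = hic.viewpoint_track(u, t, 20, half_window=1500)
        np.testing.assert_allclose(v1, -v2, atol=1e-12)


class TestTransWindow:
    def _inter(self, counts):
        return ContactMatrix("chr1", "chr2", 250_000, counts)

    def test_uniform_block(self):
        m = self._inter(np.full((20, 20), 2.0))
        assert hic.trans_window_score(m, 10 * 250_000, 10 * 250_000) == 50.0

    def test_zero_matrix(self):
        m = self._inter(np.zeros((10, 10)))
        assert hic.trans_window_score(m, 0, 0) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            na, nb = int(rng.integers(6, 25)), int(rng.integers(6, 25))
            m = self._inter(rng.random((na, nb)))
            ia, ib = int(rng.integers(na)), int(rng.integers(nb))
            brute = sum(
                m.counts[i, j]
                for i in range(max(0, ia - 2), min(na, ia + 3))
                for j in range(max(0, ib - 2), min(nb, ib + 3))
            )
            score = hic.trans_window_score(m, ia * 250_000, ib * 250_000)
            assert score == pytest.approx(brute)

    def test_non_canonical_resolution_warns(self):
        m = ContactMatrix("chr1", "chr2", 100_000, np.ones((5, 5)))
        with pytest.warns(UserWarning):
            hic.trans_window_score(m, 0, 0)

    @pytest.mark.parametrize(
        "sums,expected",
        [((0, 0), 0.0), ((1.9, 0.9), 1.0), ((50, 24.9), 1.0029)],
    )
    def test_log2fc_pseudocount(self, sums, expected):
        assert hic.trans_window_log2fc(*sums) == pytest.approx(expected, abs=1e-3)

    def test_log2fc_rejects_negative(self):
        with pytest.raises(ValidationError):
            hic.trans_window_log2fc(-1, 0)
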