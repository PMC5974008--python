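import itertools
import math

import numpy as np
import pytest

from contourreg.geometry import InputError
from contourreg.matching import (
    AffinityMatrix,
    AffinityParams,
    ContourSet,
    Correspondence,
    CorrespondenceSet,
    build_affinity,
    contour_term,
    descriptor_similarity,
    geodesic_consistency,
    rigidity_kernel,
    spectral_prune,
)


class TestConsistency:
    def test_equal_distances_give_one(self):
        assert geodesic_consistency(10.0, 10.0, eps=1e-8) == pytest.approx(
            1.0, abs=1e-8)

    def test_direct_ratio(self):
        assert geodesic_consistency(10.0, 20.0, eps=1e-8) == pytest.approx(
            0.5, abs=1e-9)

    def test_degenerate_zero_distance(self):
        assert geodesic_consistency(10.0, 0.0) == pytest.approx(0.0, abs=1e-8)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            geodesic_consistency(-1.0, 5.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(1, 100, 2)
            s = rng.uniform(0.1, 10)
            assert abs(geodesic_consistency(a, b)
                       - geodesic_consistency(s * a, s * b)) < 1e-6

    def test_symmetric_in_arguments(self):
        assert geodesic_consistency(3.0, 7.0) == geodesic_consistency(7.0, 3.0)


class TestRigidityKernel:
    @pytest.mark.parametrize("c,expected", [
        (1.0, 1.0),
        (0.7, math.exp(-0.5)),
        (0.4, math.exp(-2.0)),
    ])
    def test_direct_values(self, c, expected):
        assert rigidity_kernel(c, 0.3) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_on_unit_interval(self):
        cs = np.linspace(0, 1, 50)
        gs = rigidity_kernel(cs, 0.3)
        assert (np.diff(gs) > 0).all()

    def test_invalid_sigma(self):
        with pytest.raises(InputError):
            rigidity_kernel(0.5, 0.0)


class TestContourTerm:
    def test_fully_consistent_pairs(self):
        assert contour_term(5.0, 5.0, 9.0, 9.0, 0.3) == pytest.approx(1.0,
                                                                      abs=1e-7)

    def test_half_consistent_average(self):
        # pair i consistent; pair j at c = 0.7 -> (1 + e^-0.5) / 2
        g = contour_term(5.0, 5.0, 7.0, 10.0, 0.3, eps=1e-12)
        assert g == pytest.approx((1 + math.exp(-0.5)) / 2, rel=1e-9)

    def test_symmetric_under_pair_swap(self):
        a = contour_term(5.0, 6.0, 7.0, 10.0, 0.3)
        b = contour_term(7.0, 10.0, 5.0, 6.0, 0.3)
        assert a == b


class TestDescriptorSimilarity:
    def test_zero_distance_full_similarity(self):
        assert descriptor_similarity(0.0, sigma_f=2.0) == 1.0

    def test_at_bandwidth(self):
        assert descriptor_similarity(2.0, sigma_f=2.0) == pytest.approx(
            math.exp(-0.5), rel=1e-12)

    def test_monotone_decreasing(self):
        s = descriptor_similarity(np.array([0.0, 2.0, 4.0]), sigma_f=2.0)
        assert s[0] > s[1] > s[2]

    def test_all_zero_distances_floored(self):
        s = descriptor_similarity(np.zeros(5))
        assert (s == 1.0).all()


def toy_setup(n_m=6, n_t=6, seed=0):
    rng = np.random.default_rng(seed)
    gm = rng.uniform(10, 100, (n_m, n_m))
    gm = 0.5 * (gm + gm.T)
    np.fill_diagonal(gm, 0)
    gt = gm.copy()
    return gm, gt


class TestBuildAffinity:
    def test_direct_mixing_value(self):
        # two candidate pairs engineered so g = 1 and the contour term = 0.5
        gm, gt = np.zeros((2, 2)), np.zeros((2, 2))
        gm[0, 1] = gm[1, 0] = 40.0
        gt[0, 1] = gt[1, 0] = 40.0  # equal geodesics -> g = 1
        # inner contour kernels of 0.5 each: c with exp(-(c-1)^2/2s^2)=0.5
        c_half = 1.0 - 0.3 * math.sqrt(2 * math.log(2))
        cm = ContourSet([0], feature_to_contour=np.array([10.0, 10.0]))
        ct = ContourSet([0], feature_to_contour=np.array([10.0 / c_half,
                                                          10.0 / c_half]))
        C = CorrespondenceSet([Correspondence(0, 0, 1.0),
                               Correspondence(1, 1, 1.0)])
        params = AffinityParams(sigma_d=0.3, sigma_b=0.3, alpha=0.6,
                                eps=1e-12, w_min=0.0)
        W = build_affinity(C, gm, gt, params, cm, ct).W
        assert W[0, 1] == pytest.approx(0.6 * 1.0 + 0.4 * 0.5, abs=1e-6)

    def test_symmetry_and_range(self):
        gm, gt = toy_setup()
        C = CorrespondenceSet([Correspondence(i, j, float(i + j))
                               for i, j in itertools.product(range(3),
                                                             range(3))])
        cm = ContourSet([0], feature_to_contour=np.linspace(5, 30, 6))
        ct = ContourSet([0], feature_to_contour=np.linspace(6, 28, 6))
        W = build_affinity(C, gm, gt, AffinityParams(), cm, ct).W
        assert np.array_equal(W, W.T)
        assert W.min() >= 0 and W.max() <= 1

    def test_alpha_one_is_pure_rigidity(self):
        gm, gt = toy_setup()
        C = CorrespondenceSet([Correspondence(0, 0, 1.0),
                               Correspondence(1, 1, 1.0),
                               Correspondence(2, 2, 1.0)])
        params = AffinityParams(alpha=1.0, w_min=0.0)
        W = build_affinity(C, gm, gt, params).W
        c = gm[0, 1] / gt[0, 1] if gm[0, 1] < gt[0, 1] else gt[0, 1] / gm[0, 1]
        assert W[0, 1] == pytest.approx(rigidity_kernel(
            geodesic_consistency(gm[0, 1], gt[0, 1]), 0.3), rel=1e-9)

    def test_conflicting_pairs_zeroed(self):
        gm, gt = toy_setup()
        C = CorrespondenceSet([Correspondence(0, 0, 1.0),
                               Correspondence(0, 1, 1.0),   # shares m
                               Correspondence(2, 1, 1.0)])  # shares t
        W = build_affinity(C, gm, gt, AffinityParams(alpha=1.0)).W
        assert W[0, 1] == 0.0 and W[1, 2] == 0.0

    def test_contour_required_when_alpha_below_one(self):
        gm, gt = toy_setup()
        C = CorrespondenceSet([Correspondence(0, 0, 1.0)])
        from contourreg.matching import MissingContourError

        with pytest.raises(MissingContourError):
            build_affinity(C, gm, gt, AffinityParams(alpha=0.6))

    def test_infinite_geodesics_give_zero_support(self):
        gm, gt = toy_setup()
        gm[0, 1] = gm[1, 0] = np.inf
        C = CorrespondenceSet([Correspondence(0, 0, 1.0),
                               Correspondence(1, 1, 1.0)])
        W = build_affinity(C, gm, gt, AffinityParams(alpha=1.0)).W
        assert W[0, 1] == 0.0


def brute_force_best_subset(W, C):
    """Maximise x^T W x over one-to-one binary assignments (oracle)."""
    n = len(C)
    best_score, best = -1.0, ()
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            ms = [C.pairs[i].m for i in subset]
            ts = [C.pairs[i].t for i in subset]
            if len(set(ms)) < r or len(set(ts)) < r:
                continue
            x = np.zeros(n)
            x[list(subset)] = 1 / np.sqrt(r)
            score = x @ W @ x
            if score > best_score:
                best_score, best = score, subset
    return set(best)


class TestSpectralPrune:
    def make_planted(self, n_good=8, n_out=8, seed=0):
        rng = np.random.default_rng(seed)
        n = n_good + n_out
        W = np.zeros((n, n))
        W[:n_good, :n_good] = 0.9
        out = rng.uniform(0.0, 0.05, (n, n))
        out = 0.5 * (out + out.T)
        W[n_good:, :] = out[n_good:, :]
        W[:, n_good:] = out[:, n_good:]
        np.fill_diagonal(W, 0.5)
        C = CorrespondenceSet([Correspondence(i, i, 1.0) for i in range(n)])
        return W, C

    def test_recovers_planted_cluster(self):
        W, C = self.make_planted()
        Cp = spectral_prune(AffinityMatrix(W), C)
        assert {p.m for p in Cp.pairs} == set(range(8))

    def test_matches_brute_force_oracle(self):
        # exhaustive x^T W x maximisation on small instances
        for seed in range(5):
            rng = np.random.default_rng(seed)
            W = np.zeros((8, 8))
            W[:4, :4] = rng.uniform(0.7, 1.0)
            noise = rng.uniform(0.0, 0.05, (8, 8))
            W = np.where(W == 0, 0.5 * (noise + noise.T), W)
            np.fill_diagonal(W, rng.uniform(0.3, 0.6, 8))
            W = 0.5 * (W + W.T)
            C = CorrespondenceSet([Correspondence(i, i, 1.0)
                                   for i in range(8)])
            oracle = brute_force_best_subset(W, C)
            got = {p.m for p in spectral_prune(AffinityMatrix(W), C).pairs}
            assert got == oracle

    def test_diagonal_matrix_keeps_largest_unary(self):
        W = np.diag([0.2, 0.9, 0.4])
        C = CorrespondenceSet([Correspondence(i, i, 1.0) for i in range(3)])
        Cp = spectral_prune(AffinityMatrix(W), C)
        assert [p.m for p in Cp.pairs] == [1]

    def test_one_to_one(self):
        rng = np.random.default_rng(2)
        n = 20
        W = rng.uniform(0.3, 1.0, (n, n))
        W = 0.5 * (W + W.T)
        pairs = [Correspondence(int(m), int(t), 1.0)
                 for m, t in zip(rng.integers(0, 6, n),
                                 rng.integers(0, 6, n))]
        seen, uniq = set(), []
        for p in pairs:
            if (p.m, p.t) not in seen:
                seen.add((p.m, p.t))
                uniq.append(p)
        C = CorrespondenceSet(uniq)
        Cp = spectral_prune(AffinityMatrix(W[:len(uniq), :len(uniq)]), C)
        assert len({p.m for p in Cp.pairs}) == len(Cp)
        assert len({p.t for p in Cp.pairs}) == len(Cp)

    def test_zero_matrix_warns_empty(self):
        C = CorrespondenceSet([Correspondence(0, 0, 1.0)])
        with pytest.warns(UserWarning):
            Cp = spectral_prune(AffinityMatrix(np.zeros((1, 1))), C)
        assert len(Cp) == 0

    def test_max_size_cap(self):
        W, C = self.make_planted(n_good=8, n_out=0)
        Cp = spectral_prune(AffinityMatrix(W), C, max_size=4)
        assert len(Cp) == 4
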