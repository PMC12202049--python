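import numpy as np
import pytest

from conftest import random_rotation
from molray.align import AlignmentResult, CEParams, ce_align, kabsch_superpose
from molray.fixtures import make_perturbed_helix


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_exact_recovery(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(20, 3)) * 5
        R_true = random_rotation(seed)
        t_true = rng.normal(size=3) * 10
        Q = P @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(P, Q)
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        np.testing.assert_allclose(t, t_true, atol=1e-8)
        assert rmsd < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_noise_envelope(self):
        # sigma = 0.1 isotropic noise, n = 100: rmsd concentrates near
        # sigma * sqrt(3) ~ 0.17; Monte-Carlo envelope over 100 seeds
        rmsds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            P = rng.normal(size=(100, 3)) * 8
            Q = P + rng.normal(scale=0.1, size=(100, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            rmsds.append(rmsd)
        assert all(0.05 <= r <= 0.25 for r in rmsds)

    def test_reflection_corrected(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(12, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rank_deficient(self):
        P = np.zeros((5, 3))
        P[:, 0] = np.arange(5)
        with pytest.raises(ValueError):
            kabsch_superpose(P, P)


def brute_force_ce(A, B, params=None):
    """Independent path-enumeration oracle mirroring the documented rules
    (no pruning, exhaustive)."""
    p = params or CEParams()
    dA = np.linalg.norm(A[:, None] - A[None, :], axis=2)
    dB = np.linalg.norm(B[:, None] - B[None, :], axis=2)
    m = p.m
    iu = np.triu_indices(m, k=1)
    afps = [
        (i, j)
        for i in range(len(A) - m + 1)
        for j in range(len(B) - m + 1)
        if np.abs(dA[i : i + m, i : i + m] - dB[j : j + m, j : j + m])[iu].mean() <= p.d0
    ]

    def pairs_of(path):
        seen, out = set(), []
        for i, j in path:
            for k in range(m):
                pr = (i + k, j + k)
                if pr not in seen:
                    seen.add(pr)
                    out.append(pr)
        return out

    def cross_ok(path, cand):
        i, j = cand
        ks = np.arange(m)
        ai = np.concatenate([np.arange(pi, pi + m) for pi, _ in path])
        bi = np.concatenate([np.arange(pj, pj + m) for _, pj in path])
        return np.abs(dA[np.ix_(i + ks, ai)] - dB[np.ix_(j + ks, bi)]).mean() <= p.d1

    def rmsd_of(pairs):
        ai = np.array([a for a, _ in pairs])
        bi = np.array([b for _, b in pairs])
        _, _, r = kabsch_superpose(A[ai], B[bi])
        return r

    best = None
    stack = [[start] for start in afps]
    while stack:
        path = stack.pop()
        pairs = pairs_of(path)
        key = (-len(pairs), rmsd_of(pairs), tuple(path))
        if best is None or key < best[0]:
            best = (key, pairs)
        li, lj = path[-1]
        for ci, cj in afps:
            if ci <= li or cj <= lj:
                continue
            overlap = ci < li + m or cj < lj + m
            if overlap and ci - li != cj - lj:
                continue
            if not overlap and (ci - li - m > p.max_gap or cj - lj - m > p.max_gap):
                continue
            if cross_ok(path, (ci, cj)):
                if overlap:
                    new_pairs = pairs_of(path + [(ci, cj)])
                    k2 = (-len(new_pairs), rmsd_of(new_pairs), tuple(path + [(ci, cj)]))
                    if best is None or k2 < best[0]:
                        best = (k2, new_pairs)
                else:
                    stack.append(path + [(ci, cj)])
    return best[1] if best else []


class TestCEAlign:
    def test_self_alignment(self):
        A = make_perturbed_helix(30, sigma=0.5, seed=7).coordinates
        result = ce_align(A, A)
        assert result.aligned_length == 30
        assert result.rmsd < 1e-6
        assert result.pairs == [(k, k) for k in range(30)]

    def test_rigid_copy(self):
        A = make_perturbed_helix(30, sigma=0.5, seed=7).coordinates
        R = random_rotation(3)
        B = A @ R.T + np.array([4.0, -2.0, 9.0])
        result = ce_align(A, B)
        assert result.aligned_length == 30
        assert result.rmsd < 1e-6
        np.testing.assert_allclose(result.rotation, R, atol=1e-6)

    def test_fragment_containment_matches_oracle(self):
        A = make_perturbed_helix(26, sigma=0.5, seed=11).coordinates
        frag = A[6:22]  # 16 residues
        result = ce_align(A, frag)
        oracle_pairs = brute_force_ce(A, frag)
        assert result.aligned_length == len(oracle_pairs) == 16
        assert result.pairs == oracle_pairs
        assert result.pairs[0] == (6, 0)

    def test_small_instance_matches_oracle(self):
        A = make_perturbed_helix(18, sigma=0.6, seed=2).coordinates
        B = make_perturbed_helix(18, sigma=0.6, seed=2).coordinates[::-1].copy()[:14]
        result = ce_align(A, B)
        oracle_pairs = brute_force_ce(A, B)
        assert result.aligned_length == len(oracle_pairs)

    def test_symmetry(self):
        A = make_perturbed_helix(24, sigma=0.5, seed=5).coordinates
        B = A[4:20]
        r_ab = ce_align(A, B)
        r_ba = ce_align(B, A)
        assert r_ab.aligned_length == r_ba.aligned_length
        assert r_ab.rmsd == pytest.approx(r_ba.rmsd, abs=1e-9)

    def test_no_admissible_afp_empty(self):
        A = make_perturbed_helix(12, sigma=0.2, seed=1).coordinates
        B = A * 5.0  # uniformly scaled: no distance matrix agreement
        result = ce_align(A, B)
        assert result.aligned_length == 0
        assert result.pairs == []

    def test_internal_consistency_rmsd(self):
        A = make_perturbed_helix(30, sigma=0.5, seed=9).coordinates
        B = A @ random_rotation(4).T + 2.0
        result = ce_align(A, B)
        ai = np.array([a for a, _ in result.pairs])
        bi = np.array([b for _, b in result.pairs])
        _, _, rmsd = kabsch_superpose(A[ai], B[bi])
        assert rmsd == pytest.approx(result.rmsd, abs=1e-9)

    def test_pairs_strictly_increasing(self):
        A = make_perturbed_helix(30, sigma=0.5, seed=13).coordinates
        result = ce_align(A, A[3:])
        for (a1, b1), (a2, b2) in zip(result.pairs, result.pairs[1:]):
            assert a2 > a1 and b2 > b1

    def test_rotation_proper(self):
        A = make_perturbed_helix(20, sigma=0.4, seed=6).coordinates
        result = ce_align(A, A)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_short_rejected(self):
        A = make_perturbed_helix(5, sigma=0.3, seed=0).coordinates
        with pytest.raises(ValueError):
            ce_align(A, A)

    def test_empty_result_type(self):
        r = AlignmentResult.empty()
        assert r.aligned_length == 0 and r.rmsd == 0.0
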