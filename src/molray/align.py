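"""Rigid superposition (Kabsch) and combinatorial-extension structural
alignment over alpha-carbon traces.

The CE search builds aligned fragment pairs (AFPs) of fixed length ``m``
whose intra-fragment distance matrices agree within ``d0`` on average, then
extends paths of AFPs whose cross-consistency with the existing path stays
within ``d1``; the longest admissible path wins (ties: smaller final RMSD,
then lexicographically first pair list).  The final rotation, translation
and RMSD come from a Kabsch superposition over all aligned residue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["kabsch_superpose", "ce_align", "AlignmentResult", "CEParams"]


def _superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    X = P - cp
    Y = Q - cq
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid**2).sum() / len(P)))
    return R, t, rmsd


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping P onto Q.

    Returns (rotation, translation, rmsd) with det(rotation) = +1
    (reflections corrected).  Requires n >= 3 paired, non-degenerate points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected matching n x 3 coordinate arrays")
    n = len(P)
    if n < 3:
        raise ValueError("kabsch requires at least 3 points")
    H = (P - P.mean(axis=0)).T @ (Q - Q.mean(axis=0))
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate point sets (rank-deficient covariance)")
    return _superpose(P, Q)


@dataclass(frozen=True)
class CEParams:
    m: int = 8  # fragment length
    d0: float = 3.0  # AFP self-consistency threshold (Angstrom)
    d1: float = 4.0  # path cross-consistency threshold (Angstrom)
    max_gap: int = 30  # residue gap cap in either chain
    max_expansions: int = 500_000  # deterministic search budget


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]  # aligned residue indices (A, B), increasing
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    aligned_length: int

    @staticmethod
    def empty() -> "AlignmentResult":
        return AlignmentResult([], np.eye(3), np.zeros(3), 0.0, 0)


def _afp_admissible(dA: np.ndarray, dB: np.ndarray, i: int, j: int, m: int, d0: float) -> bool:
    """Average |dA - dB| over intra-fragment residue pairs (k < l) <= d0."""
    sub = np.abs(dA[i : i + m, i : i + m] - dB[j : j + m, j : j + m])
    iu = np.triu_indices(m, k=1)
    return float(sub[iu].mean()) <= d0


def _admissible_afps(dA: np.ndarray, dB: np.ndarray, p: CEParams) -> list[tuple[int, int]]:
    nA = len(dA)
    nB = len(dB)
    out = []
    for i in range(nA - p.m + 1):
        for j in range(nB - p.m + 1):
            if _afp_admissible(dA, dB, i, j, p.m, p.d0):
                out.append((i, j))
    return out


def _cross_consistency(
    dA: np.ndarray, dB: np.ndarray, path: list[tuple[int, int]], cand: tuple[int, int], m: int
) -> float:
    """Mean |dA(i'+k, a) - dB(j'+k, b)| over path residue pairs (a, b)."""
    i, j = cand
    ks = np.arange(m)
    a_idx = np.concatenate([np.arange(pi, pi + m) for pi, _ in path])
    b_idx = np.concatenate([np.arange(pj, pj + m) for _, pj in path])
    diff = np.abs(dA[np.ix_(i + ks, a_idx)] - dB[np.ix_(j + ks, b_idx)])
    return float(diff.mean())


def ce_align(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params: CEParams | None = None,
) -> AlignmentResult:
    """Combinatorial-extension alignment of two CA coordinate arrays.

    Returns the longest admissible AFP path (ties broken by smaller final
    RMSD, then lexicographically first pair list); an empty alignment when no
    admissible AFP exists.  Symmetric in its inputs for equal-length results.
    """
    p = params or CEParams()
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != 3 or B.shape[1] != 3:
        raise ValueError("expected n x 3 CA coordinate arrays")
    if len(A) < p.m or len(B) < p.m:
        raise ValueError(f"both chains need at least m={p.m} CA atoms")

    dA = np.linalg.norm(A[:, None, :] - A[None, :, :], axis=2)
    dB = np.linalg.norm(B[:, None, :] - B[None, :, :], axis=2)
    afps = _admissible_afps(dA, dB, p)
    if not afps:
        return AlignmentResult.empty()

    def path_pairs(path: list[tuple[int, int]]) -> list[tuple[int, int]]:
        seen: set[tuple[int, int]] = set()
        out: list[tuple[int, int]] = []
        for i, j in path:
            for k in range(p.m):
                pair = (i + k, j + k)
                if pair not in seen:
                    seen.add(pair)
                    out.append(pair)
        return out

    best_path: list[tuple[int, int]] = []
    best_key: tuple | None = None
    expansions = 0

    def path_rmsd(pairs: list[tuple[int, int]]) -> float:
        ai = np.array([a for a, _ in pairs])
        bi = np.array([b for _, b in pairs])
        _, _, r = _superpose(A[ai], B[bi])
        return r

    def consider(path: list[tuple[int, int]]) -> None:
        nonlocal best_path, best_key
        pairs = path_pairs(path)
        key = (-len(pairs), path_rmsd(pairs), tuple(path))
        if best_key is None or key < best_key:
            best_key = key
            best_path = list(path)

    def successors(path: list[tuple[int, int]]):
        """(candidate, is_terminal) extensions of the path.

        Non-overlapping successors obey the gap cap in both chains.  A
        fragment overlapping its predecessor is admitted only on the same
        diagonal (identical residue pairing in the overlap) and terminates
        the path: it exists to cover chain tails shorter than m.
        """
        li, lj = path[-1]
        for cand in afps:
            ci, cj = cand
            if ci <= li or cj <= lj:
                continue
            overlap = ci < li + p.m or cj < lj + p.m
            if overlap:
                if ci - li != cj - lj:
                    continue
            elif ci - li - p.m > p.max_gap or cj - lj - p.m > p.max_gap:
                continue
            if _cross_consistency(dA, dB, path, cand, p.m) <= p.d1:
                yield cand, overlap

    def upper_bound(path: list[tuple[int, int]], n_pairs: int) -> int:
        li, lj = path[-1]
        rem = min(len(A) - li - p.m, len(B) - lj - p.m)
        return n_pairs + max(rem, 0)

    def dfs(path: list[tuple[int, int]]) -> None:
        nonlocal expansions
        if expansions >= p.max_expansions:
            return
        expansions += 1
        consider(path)
        n_pairs = len(path_pairs(path))
        if best_key is not None and upper_bound(path, n_pairs) < -best_key[0]:
            return
        for cand, terminal in successors(path):
            path.append(cand)
            if terminal:
                consider(path)
            else:
                dfs(path)
            path.pop()

    for start in afps:
        dfs([start])

    pairs = path_pairs(best_path)
    ai = np.array([a for a, _ in pairs])
    bi = np.array([b for _, b in pairs])
    R, t, rmsd = _superpose(A[ai], B[bi])
    return AlignmentResult(
        pairs=pairs, rotation=R, translation=t, rmsd=rmsd, aligned_length=len(pairs)
    )
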