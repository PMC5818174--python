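"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (plain
quadratic dynamic programming, direct enumeration, closed-form algebra)
and never calls into the package's own implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def smith_waterman_score(a: str, b: str, gap_open: float = 11.0,
                         gap_extend: float = 1.0) -> float:
    """Brute-force affine-gap local alignment (Gotoh, three matrices)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + blosum62_score(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = 0.267, K: float = 0.041) -> float:
    return K * m * n * math.exp(-lam * score)


def geometric_mean_evalue(evalues: list[float]) -> float:
    logs = [math.log10(max(e, 1e-300)) for e in evalues]
    return 10.0 ** (sum(logs) / len(logs))


def pairwise_identity_fraction(a: str, b: str) -> float:
    """Hamming identity over the shorter sequence (ungapped prefix model).

    Only valid for the generator's indel-free sequences, where homologous
    positions line up without alignment.
    """
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def enumerate_shortest_paths(edges: set[tuple[str, str]], src: str, dst: str):
    """All shortest simple paths by explicit breadth-first enumeration."""
    adjacency: dict[str, set[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    frontier = [(src,)]
    found: list[tuple[str, ...]] = []
    while frontier and not found:
        nxt = []
        for path in frontier:
            for nb in adjacency.get(path[-1], ()):
                if nb in path:
                    continue
                if nb == dst:
                    found.append(path + (nb,))
                else:
                    nxt.append(path + (nb,))
        frontier = nxt
    return found


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx = B.T @ A  # correlation matrix
    K = np.zeros((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam_max = np.linalg.eigvalsh(K).max()
    n = A.shape[0]
    ga = (A ** 2).sum()
    gb = (B ** 2).sum()
    msd = max((ga + gb - 2.0 * lam_max) / n, 0.0)
    return math.sqrt(msd)


def brute_force_crossing_census(records, labels, threshold, align):
    """Count inter-label sequence pairs with E below threshold.

    ``align`` is a callable (a, b) -> E-value supplied by the caller so the
    census logic itself stays a plain double loop.
    """
    ids = sorted(records)
    count = 0
    evalues = []
    for a, b in itertools.combinations(ids, 2):
        la, lb = labels.get(a), labels.get(b)
        if la is None or lb is None or la == lb:
            continue
        e = align(records[a], records[b])
        if e < threshold:
            count += 1
            evalues.append(e)
    return count, evalues
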