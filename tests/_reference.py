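"""Independent naive reference implementations used as test oracles.

These are deliberately simple O(n·m) / exhaustive algorithms, written
without reference to the package's implementations, so agreement is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction

import biotite.sequence.align as balign
import numpy as np

_STD = balign.SubstitutionMatrix.std_protein_matrix()
_ALPH = _STD.get_alphabet1()
_RAW = _STD.score_matrix().copy()
_X = _ALPH.encode("X")
_RAW[_X, :] = 0
_RAW[:, _X] = 0


def blosum62(a: str, b: str) -> int:
    """BLOSUM62 score of one residue pair, with X neutral (0)."""
    return int(_RAW[_ALPH.encode(a), _ALPH.encode(b)])


def sw_score(a: str, b: str, gap_open: int = 11, gap_ext: int = 1) -> int:
    """Naive Gotoh local-alignment score (affine gaps, clamped at 0).

    A gap of length L costs gap_open + (L − 1)·gap_ext.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_ext)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_ext)
            diag = H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def naive_upgma(dist: np.ndarray, labels: list[str]):
    """Straightforward UPGMA: repeatedly merge the closest cluster pair.

    Returns (clades, heights): the leaf-label frozenset and merge height
    of every internal cluster, in merge order.
    """
    clusters = [frozenset([lab]) for lab in labels]
    d = {
        (frozenset([labels[i]]), frozenset([labels[j]])): dist[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }

    def get(u, v):
        return d.get((u, v), d.get((v, u)))

    clades, heights = [], []
    while len(clusters) > 1:
        pairs = [(get(u, v), u, v) for i, u in enumerate(clusters) for v in clusters[i + 1:]]
        val, u, v = min(pairs, key=lambda t: t[0])
        merged = u | v
        for w in clusters:
            if w is u or w is v:
                continue
            d[(merged, w)] = (len(u) * get(u, w) + len(v) * get(v, w)) / (len(u) + len(v))
        clusters = [w for w in clusters if w is not u and w is not v] + [merged]
        clades.append(merged)
        heights.append(val)
    return clades, heights


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X ≥ k) by full enumeration with integer arithmetic."""
    total = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    acc = Fraction(0)
    for j in range(max(k, lo), hi + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return float(acc)
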