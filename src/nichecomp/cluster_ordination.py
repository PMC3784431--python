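"""Bray-Curtis distances, bootstrap-supported UPGMA, and nMDS ordination.

Genome functional profiles are compared with the Bray-Curtis
dissimilarity, clustered by UPGMA (average linkage on the dissimilarity
matrix), and the robustness of each internal bipartition is assessed by
bootstrap-resampling the profile *columns* (categories) with replacement
— the standard convention for profile clustering.  Nonmetric
multidimensional scaling embeds the same dissimilarities in k dimensions
by minimizing Kruskal stress-1, starting from a classical-scaling
configuration plus seeded random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from skbio.tree import TreeNode


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).

    Defined for equal-length non-negative vectors; undefined (error) when
    both are all-zero.  Lies in [0, 1]: 0 iff x == y, 1 for disjoint
    supports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the same category set")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with ordered genome labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between profile rows."""
    values = profiles.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("profiles must be non-negative")
    if (values.sum(axis=1) == 0).any():
        bad = profiles.index[values.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero profile row(s): {bad}")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(labels=list(profiles.index), values=d)


def _clade_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf-label set under each internal merge, in merge order."""
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + i] = s
        out.append(s)
    return out


def _bipartitions(Z: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Canonical non-trivial bipartitions of a dendrogram.

    Each bipartition is represented by the side *not* containing the
    lexicographically smallest label, so representation is rooting- and
    orientation-independent.
    """
    n = len(labels)
    anchor = min(labels)
    out = set()
    for s in _clade_sets(Z, labels):
        if len(s) < 2 or len(s) > n - 2:
            continue
        canon = s if anchor not in s else frozenset(labels) - s
        out.add(canon)
    return out


@dataclass
class TreeResult:
    """UPGMA dendrogram with optional per-bipartition bootstrap support."""

    labels: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float] | None = None

    @property
    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.linkage_matrix, self.labels)

    def support_of(self, side: set[str]) -> float:
        """Support (percent) of the bipartition separating ``side``."""
        if self.supports is None:
            raise ValueError("supports have not been computed")
        anchor = min(self.labels)
        canon = frozenset(side)
        if anchor in canon:
            canon = frozenset(self.labels) - canon
        if canon not in self.supports:
            raise KeyError("bipartition not present in the dendrogram")
        return self.supports[canon]

    def to_newick(self) -> str:
        """Newick string; internal node names carry bootstrap support."""
        tree = TreeNode.from_linkage_matrix(
            self.linkage_matrix, [str(l) for l in self.labels]
        )
        if self.supports is not None:
            anchor = min(self.labels)
            full = frozenset(self.labels)
            for node in tree.non_tips():
                leaves = frozenset(t.name for t in node.tips())
                canon = leaves if anchor not in leaves else full - leaves
                if canon in self.supports:
                    node.name = f"{self.supports[canon]:.0f}"
        return str(tree).strip()


def upgma(dm: DistanceMatrix) -> TreeResult:
    """Average-linkage (UPGMA) agglomeration of a distance matrix."""
    if len(dm.labels) < 2:
        raise ValueError("UPGMA needs at least two genomes")
    Z = linkage(dm.condensed, method="average")
    return TreeResult(labels=list(dm.labels), linkage_matrix=Z)


def bootstrap_support(
    profiles: pd.DataFrame,
    n_reps: int = 1000,
    seed: int | None = None,
    distance=bray_curtis_matrix,
) -> TreeResult:
    """UPGMA tree with column-bootstrap support values.

    Categories (columns) are resampled with replacement ``n_reps`` times;
    the support of each internal bipartition of the original tree is the
    percentage of replicate trees containing it.  A replicate whose
    resampled matrix leaves some genome all-zero is redrawn.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if profiles.shape[0] < 3 or profiles.shape[1] < 2:
        raise ValueError("need at least 3 genomes and 2 categories")
    tree = upgma(distance(profiles))
    target = tree.bipartitions
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = profiles.shape[1]
    done = 0
    attempts = 0
    while done < n_reps:
        attempts += 1
        if attempts > 100 * n_reps:
            raise RuntimeError("too many degenerate bootstrap replicates")
        cols = rng.integers(0, n_cols, size=n_cols)
        boot = profiles.iloc[:, cols]
        try:
            rep = upgma(distance(boot))
        except ValueError:
            continue  # all-zero resampled row; redraw
        rep_bps = rep.bipartitions
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
        done += 1
    tree.supports = {bp: 100.0 * k / n_reps for bp, k in hits.items()}
    return tree


def kruskal_stress(dm: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Disparities are the isotonic (monotone non-decreasing, ties averaged)
    regression of configuration distances on observed dissimilarities;
    stress-1 = sqrt(Σ(d − d̂)² / Σd²).
    """
    obs = dm.condensed
    fit = pdist(coords)
    disp = IsotonicRegression(increasing=True).fit_transform(obs, fit)
    denom = float((fit**2).sum())
    if denom == 0:
        raise ValueError("degenerate configuration (all points coincide)")
    return float(np.sqrt(((fit - disp) ** 2).sum() / denom))


def _classical_scaling(dm: DistanceMatrix, k: int) -> np.ndarray:
    """Torgerson classical scaling, sign-canonicalized per axis."""
    d2 = dm.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    X = vecs[:, order] * np.sqrt(lam)
    # canonical sign: the largest-magnitude coordinate of each axis positive
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            X[:, j] = -col
    return X


@dataclass
class OrdinationResult:
    """nMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    best_start: int
    converged: bool = True


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS by iterative stress majorization.

    Start 0 is the classical-scaling configuration; the remaining
    ``n_starts − 1`` starts are seeded random configurations.  Each start
    is refined by SMACOF with isotonic disparities and the lowest
    stress-1 configuration is returned.  The raw classical-scaling
    configuration itself remains a candidate, so the returned stress
    never exceeds that of the initialization.
    """
    n = len(dm.labels)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for a {k}-D embedding")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    init = _classical_scaling(dm, k)
    candidates: list[tuple[float, np.ndarray, int, bool]] = [
        (kruskal_stress(dm, init), init, 0, True)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for start in range(n_starts):
            start_seed = int(rng.integers(0, 2**31 - 1))
            kw = dict(
                metric=False,
                n_components=k,
                n_init=1,
                max_iter=max_iter,
                eps=1e-7,
                normalized_stress=True,
                return_n_iter=True,
            )
            if start == 0:
                X, _, n_iter = smacof(dm.values, init=init, **kw)
            else:
                X, _, n_iter = smacof(dm.values, random_state=start_seed, **kw)
            candidates.append((kruskal_stress(dm, X), X, start, n_iter < max_iter))
    stress, X, best, conv = min(candidates, key=lambda c: c[0])
    if not conv:
        warnings.warn("nMDS did not converge within max_iter; returning best-so-far")
    coords = pd.DataFrame(
        X, index=dm.labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        best_start=best,
        converged=conv,
    )
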