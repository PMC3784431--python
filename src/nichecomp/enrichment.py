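"""One-tailed Fisher's-exact category enrichment with representation ratios.

For a category with K annotated proteins among N in the reference set and
k among the n proteins of an inspected set, the over-representation
p-value is the hypergeometric upper tail P(X ≥ k), and the
representation ratio is (k/n)/(K/N) — above 1 means the category is
over-represented in the inspected set, below 1 under-represented.  Only
the over-representation tail is tested; under-representation is reported
through the ratio.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def fisher_one_tailed(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    k: category hits in the inspected set; n: inspected-set size;
    K: category hits in the reference; N: reference size.
    Margins must be consistent: 0 ≤ k ≤ n ≤ N, k ≤ K ≤ N, n − k ≤ N − K.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent margins: k={k}, n={n}, K={K}, N={N}")
    if n - k > N - K:
        raise ValueError(
            f"inconsistent margins: {n - k} misses cannot come from {N - K} non-category proteins"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def _as_category_map(annotations) -> dict[str, set[str]]:
    """protein → set of categories, from a mapping or a two-column table."""
    if isinstance(annotations, pd.DataFrame):
        cols = list(annotations.columns[:2])
        out: dict[str, set[str]] = {}
        for pid, cat in annotations[cols].itertuples(index=False):
            out.setdefault(str(pid), set()).add(str(cat))
        return out
    return {str(p): set(c) for p, c in annotations.items()}


def enrich(
    set_annotations,
    reference_annotations,
    alpha: float = 0.05,
    disjoint_universe: bool = False,
) -> pd.DataFrame:
    """Per-category one-tailed Fisher enrichment of a set against a reference.

    Inputs are protein → categories mappings (or two-column DataFrames of
    protein_id, category).  By default the inspected set must be a subset
    of the reference universe; ``disjoint_universe=True`` instead treats
    the two sets as disjoint samples and tests against their union.
    Returns one row per category, sorted by p-value, with the
    representation ratio (inf, flagged, when the category is absent from
    the reference), the raw p-value and its Benjamini-Hochberg
    adjustment; ``significant`` flags p < alpha (unadjusted, the default
    selection rule).
    """
    inspected = _as_category_map(set_annotations)
    reference = _as_category_map(reference_annotations)
    if not inspected:
        raise ValueError("inspected set is empty")
    if not disjoint_universe:
        outside = set(inspected) - set(reference)
        if outside:
            raise ValueError(
                f"inspected proteins missing from the reference universe: {sorted(outside)[:5]} "
                "(use disjoint_universe=True for disjoint sets)"
            )
    n = len(inspected)
    N = len(reference)
    categories = sorted({c for cats in inspected.values() for c in cats} |
                        {c for cats in reference.values() for c in cats})
    rows = []
    for cat in categories:
        k = sum(cat in cats for cats in inspected.values())
        K = sum(cat in cats for cats in reference.values())
        if disjoint_universe:
            p = fisher_one_tailed(k, n, K + k, N + n)
            ratio_ref = K / N if K else 0.0
        else:
            p = fisher_one_tailed(k, n, K, N)
            ratio_ref = K / N if K else 0.0
        ratio = (k / n) / ratio_ref if ratio_ref > 0 else math.inf
        rows.append(
            {
                "category": cat,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "representation_ratio": ratio,
                "ratio_undefined": ratio_ref == 0,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
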