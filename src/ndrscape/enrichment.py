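"""Per-cluster enrichment of downregulated genes.

Genes are called downregulated when their log2 fold change is strictly below
a threshold (default −0.5). For each cluster, a 2×2 table of membership ×
downregulation is formed over the universe of genes present in both the
clustering and the expression table, and tested with a one-sided Fisher exact
test in the enrichment direction: the p-value is the hypergeometric upper
tail P(X >= observed in-cluster downregulated), computed with exact integer
binomial coefficients (the universe here is a few thousand genes at most, so
exact arithmetic is cheap and removes any tail-accuracy concern).
"""

from __future__ import annotations

from functools import lru_cache
from math import comb
from typing import Iterable, Mapping, Set

import pandas as pd

from .errors import NdrscapeError, SchemaError, ValidationError
from .tss_matrix import ClusterAssignment

__all__ = [
    "label_downregulated",
    "hypergeom_tail",
    "fisher_one_sided",
    "cluster_enrichment",
]


def label_downregulated(expr: pd.DataFrame, threshold: float = -0.5) -> set[str]:
    """Genes with log2 fold change strictly below ``threshold``.

    ``expr`` needs columns gene_id and log2fc; gene_ids must be unique.
    """
    missing = {"gene_id", "log2fc"} - set(expr.columns)
    if missing:
        raise SchemaError(f"expression table missing columns {sorted(missing)}")
    if expr["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in expression table")
    if len(expr) == 0:
        return set()
    if not pd.api.types.is_numeric_dtype(expr["log2fc"]) or expr["log2fc"].isna().any():
        raise ValidationError("log2fc must be finite numeric")
    return set(expr.loc[expr["log2fc"] < threshold, "gene_id"])


def hypergeom_tail(a: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=big_n, K=big_k, n draws).

    Exact integer-combinatoric summation, correctly rounded to float.
    """
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise ValidationError("invalid hypergeometric parameters")
    hi = min(n, big_k)
    if a > hi:
        return 0.0
    lo = max(a, max(0, n + big_k - big_n))
    num = sum(comb(big_k, i) * comb(big_n - big_k, n - i) for i in range(lo, hi + 1))
    return num / comb(big_n, n)


def fisher_one_sided(in_down: int, in_not: int, out_down: int, out_not: int) -> float:
    """One-sided Fisher exact p for enrichment of 'down' inside the cluster."""
    if min(in_down, in_not, out_down, out_not) < 0:
        raise ValidationError("counts must be non-negative")
    big_n = in_down + in_not + out_down + out_not
    return hypergeom_tail(in_down, big_n, in_down + out_down, in_down + in_not)


def cluster_enrichment(
    clusters: ClusterAssignment,
    downregulated: Set[str],
    expression_genes: Iterable[str] | None = None,
    alternative: str = "greater",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Test each cluster for enrichment of downregulated genes.

    The universe is the intersection of clustered genes with
    ``expression_genes`` (all genes the expression table covers); genes absent
    from the expression table are excluded, not counted as "not
    downregulated", and their count is reported in the ``n_missing_expression``
    dataframe attribute. ``alternative`` is "greater" (enrichment, default,
    exact hypergeometric tail) or "two-sided" (delegated to scipy). With
    ``bonferroni`` the p-values are additionally multiplied by k (capped at 1)
    in a separate column.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    clustered = set(clusters.labels)
    if expression_genes is None:
        universe = clustered
    else:
        universe = clustered & set(expression_genes)
    n_missing = len(clustered) - len(universe)
    if not universe:
        raise NdrscapeError("empty universe: no clustered gene has expression data")
    down = downregulated & universe
    rows = []
    for label in range(1, clusters.k + 1):
        members = {g for g in universe if clusters.labels[g] == label}
        in_down = len(members & down)
        in_not = len(members) - in_down
        out_down = len(down) - in_down
        out_not = len(universe) - len(members) - out_down
        if alternative == "greater":
            p = fisher_one_sided(in_down, in_not, out_down, out_not)
        else:
            from scipy.stats import fisher_exact

            _, p = fisher_exact(
                [[in_down, in_not], [out_down, out_not]], alternative="two-sided"
            )
        odds = (
            (in_down * out_not) / (in_not * out_down)
            if in_not * out_down > 0
            else float("inf") if in_down * out_not > 0 else float("nan")
        )
        rows.append(
            {
                "cluster": label,
                "n_genes": len(members),
                "n_down": in_down,
                "n_down_outside": out_down,
                "frequency_down": in_down / len(members) if members else 0.0,
                "odds_ratio": odds,
                "pvalue": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if bonferroni:
        df["pvalue_bonferroni"] = (df["pvalue"] * clusters.k).clip(upper=1.0)
    df.attrs["n_missing_expression"] = n_missing
    df.attrs["universe_size"] = len(universe)
    return df
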