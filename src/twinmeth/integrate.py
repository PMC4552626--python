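"""Expression-side computations and methylation-expression integration.

Covers quantile normalization of RPKM matrices, log2 fold changes from
replicate means, the Pearson correlation between promoter methylation
differences and expression changes, and a generic hypergeometric gene-set
enrichment (the same machinery GO or ENCODE term analyses use, with
user-supplied GMT gene sets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .dmr import bh_qvalues


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's sorted values are replaced by the across-column means of
    the order statistics; tied values within a column receive the mean of
    the reference values across their rank range.  Idempotent, and exact
    identity when the columns are already identically distributed.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = table.to_numpy(float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties: average the reference values across the tied rank range
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def log2_group_fold_change(
    table: pd.DataFrame,
    case_cols: list[str],
    control_cols: list[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene log2(mean_case / mean_control) over replicate columns.

    Genes whose control (or case) mean is zero get a NaN fold change and
    ``undefined=True`` rather than +/-inf, unless a pseudocount is supplied.
    """
    if not case_cols or not control_cols:
        raise ValueError("both groups need at least one sample column")
    mean_case = table[case_cols].mean(axis=1) + pseudocount
    mean_control = table[control_cols].mean(axis=1) + pseudocount
    ok = (mean_case > 0) & (mean_control > 0)
    l2fc = pd.Series(np.nan, index=table.index)
    l2fc[ok] = np.log2(mean_case[ok] / mean_control[ok])
    return pd.DataFrame(
        {
            "mean_case": mean_case - pseudocount,
            "mean_control": mean_control - pseudocount,
            "log2fc": l2fc,
            "undefined": ~ok,
        }
    )


def meth_expr_correlation(delta_meth, log2fc) -> tuple[float, int]:
    """Pearson correlation between per-gene methylation differences
    (percentage points, case - control) and expression log2 fold changes.

    Returns (r, n).  Requires >= 3 complete pairs and non-constant vectors.
    """
    d = np.asarray(delta_meth, float)
    f = np.asarray(log2fc, float)
    if d.shape != f.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(d) | np.isnan(f))
    d, f = d[ok], f[ok]
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"only {n} complete gene pairs; need >= 3")
    if np.ptp(d) == 0 or np.ptp(f) == 0:
        raise UndefinedStatisticError("correlation undefined: constant vector")
    r = float(np.corrcoef(d, f)[0, 1])
    return r, n


# ---------------------------------------------------------------------------
# gene-set enrichment


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeom_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against term sets.

    Every term is intersected with the universe; p is the probability of
    drawing at least the observed overlap k when sampling |query| genes
    without replacement from the universe.  BH FDR across terms; sorted by p.
    """
    query = set(query)
    universe = set(universe)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    n, N = len(query), len(universe)
    rows = []
    for term, genes in gene_sets.items():
        term_genes = genes & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_qvalues(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
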