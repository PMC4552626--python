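"""Promoter DMR testing and the multi-comparison filtering cascade.

Each promoter is tested with a pooled two-sided Fisher's exact test on the
2x2 table of (methylated, unmethylated) C read counts, case versus control,
with replicate counts summed within each group before testing.  P-values are
converted to q-values by a sliding-linear-model (SLIM) pi0 estimate times a
Benjamini-Hochberg step-up (plain BH is available as a cross-check).  A
promoter is called a DMR when q <= 0.001 and the absolute methylation
difference is at least 25 percentage points; the sign convention is
case - control, so positive means hypermethylated in the case.

The cascade filters a focal comparison's DMR set against control comparisons
(exclusion) and an unrelated case/control comparison (intersection), keeping
only DMRs plausibly induced by the condition under study.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import FixtureIntegrityError, InsufficientDataError, KeySpaceMismatchError

DEFAULT_Q_THRESHOLD = 1e-3
DEFAULT_DIFF_THRESHOLD = 25.0

#: relative slack when comparing table probabilities for the two-sided sum
_TIE_SLACK = 1e-7

_REGION_KEY = ["chrom", "start", "end", "name"]

_FIXTURE_DIGESTS = {
    "table2": ("table2_dmrs.tsv", "bb68ad88e0efd5327e1d469a80591b193ccc7a2fa920a662a11eb8ef1b306839"),
    "table4": ("table4_meth_expr.tsv", "76a8487c478c34b24fea1e1a6ade3043af9fed77e84c654914a6ec1fce6b54f2"),
    "table6": ("table6_chd_dmrs.tsv", "dab999c87f9aa2c9b02543258187102d0d09cf4bf4a69bd443f9389ca159267a"),
}


# ---------------------------------------------------------------------------
# Fisher's exact test


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of every table with the
    same margins whose probability is at or below the observed table's
    (within 1e-7 relative slack for floating ties).  A zero row or column
    margin makes the table degenerate: only one table is possible, p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate: a zero margin fixes the table
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_binom(r1, support)
        + _log_binom(r2, c1 - support)
        - _log_binom(n, c1)
    )
    p_obs = logp[a - lo]
    total = np.exp(logp[logp <= p_obs + np.log1p(_TIE_SLACK)]).sum()
    if total >= 1.0 - 1e-9:  # whole support included: exactly 1 up to fp error
        return 1.0
    return float(total)


# ---------------------------------------------------------------------------
# multiple-testing correction

SLIM_LAMBDA_GRID = np.concatenate([[0.01], np.arange(0.05, 0.9501, 0.05)])


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a 1-D array of at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def slim_pi0(pvals, lambda_grid=None, window: int = 6) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The empirical CDF of the p-values is evaluated on a lambda grid; on the
    upper part of the grid (lambda >= 0.4, where signal p-values are rare)
    straight lines are fitted to the CDF in sliding windows of ``window``
    grid points.  Under the two-group mixture model the CDF slope there is
    pi0, so the estimate is the median window slope, clipped to [0, 1].
    """
    p = _check_pvals(pvals)
    grid = SLIM_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    cdf = np.array([(p <= lam).mean() for lam in grid])
    slopes = []
    for i in range(len(grid) - window + 1):
        lam = grid[i : i + window]
        if lam[0] < 0.4:
            continue
        y = cdf[i : i + window]
        slope = np.polyfit(lam, y, 1)[0]
        slopes.append(slope)
    if not slopes:  # grid too short for sliding windows: single-line fit
        slopes = [np.polyfit(grid, cdf, 1)[0]]
    return float(np.clip(np.median(slopes), 0.0, 1.0))


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = _check_pvals(pvals)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def slim_qvalues(pvals, lambda_grid=None, return_pi0: bool = False):
    """SLIM q-values: q_i = pi0 * p_(i) * n / rank, monotonized from the
    largest p down.  With pi0 = 1 this reduces to Benjamini-Hochberg."""
    p = _check_pvals(pvals)
    pi0 = slim_pi0(p, lambda_grid=lambda_grid) if p.size >= 20 else 1.0
    q = np.minimum(pi0 * bh_qvalues(p), 1.0)
    if return_pi0:
        return q, pi0
    return q


# ---------------------------------------------------------------------------
# promoter testing


def test_promoters(
    case_table: pd.DataFrame,
    control_table: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    q_method: str = "slim",
) -> pd.DataFrame:
    """Per-promoter differential methylation test on pooled count tables.

    Both inputs are region-methylation tables (chrom, start, end, name,
    meth_c, total_c, percent) with replicate counts already pooled per group.
    Regions present in only one group are skipped, not imputed.  Returns one
    row per shared region with meth_diff (case - control, percentage
    points), Fisher p, q by ``q_method`` ('slim' or 'bh'), and the is_dmr
    call at the given thresholds.
    """
    if q_method not in ("slim", "bh"):
        raise ValueError("q_method must be 'slim' or 'bh'")
    merged = case_table.merge(
        control_table, on=_REGION_KEY, suffixes=("_case", "_control")
    )
    if len(merged) == 0:
        raise InsufficientDataError("case and control tables share no regions")
    mc = merged["meth_c_case"].to_numpy(np.int64)
    tc = merged["total_c_case"].to_numpy(np.int64)
    mk = merged["meth_c_control"].to_numpy(np.int64)
    tk = merged["total_c_control"].to_numpy(np.int64)
    pvals = np.array(
        [
            fisher_exact_2x2(int(a), int(t1 - a), int(c), int(t2 - c))
            for a, t1, c, t2 in zip(mc, tc, mk, tk)
        ]
    )
    q = slim_qvalues(pvals) if q_method == "slim" else bh_qvalues(pvals)
    out = merged[_REGION_KEY].copy()
    out["meth_case"] = 100.0 * mc / tc
    out["meth_control"] = 100.0 * mk / tk
    out["meth_diff"] = out["meth_case"] - out["meth_control"]
    out["p"] = pvals
    out["q"] = q
    out["is_dmr"] = (q <= q_threshold) & (out["meth_diff"].abs() >= diff_threshold)
    return out


# ---------------------------------------------------------------------------
# comparison sets and the filtering cascade


@dataclass
class ComparisonSet:
    """One labelled case/control comparison and its DMR test results."""

    comparison_id: str
    case_ids: list
    control_ids: list
    results: pd.DataFrame  # test_promoters output

    def __post_init__(self):
        case, ctrl = set(self.case_ids), set(self.control_ids)
        if not case or not ctrl:
            raise ValueError(f"{self.comparison_id}: case and control must be non-empty")
        if case & ctrl:
            raise ValueError(f"{self.comparison_id}: case and control overlap")

    def universe(self) -> frozenset:
        return frozenset(map(tuple, self.results[_REGION_KEY].itertuples(index=False)))

    def dmr_keys(self) -> frozenset:
        hits = self.results[self.results["is_dmr"]]
        return frozenset(map(tuple, hits[_REGION_KEY].itertuples(index=False)))


def _tally(df: pd.DataFrame) -> dict:
    return {
        "n": len(df),
        "hyper": int((df["meth_diff"] > 0).sum()),
        "hypo": int((df["meth_diff"] < 0).sum()),
    }


@dataclass
class CascadeResult:
    """Staged DMR sets of the filtering cascade (final within after_exclusion
    within initial), with per-stage counts and hyper/hypo tallies taken from
    the focal comparison's signed differences."""

    initial: pd.DataFrame
    after_exclusion: pd.DataFrame
    final: pd.DataFrame
    counts: dict = field(default_factory=dict)


def run_cascade(
    discordant: ComparisonSet,
    controls: list[ComparisonSet],
    unrelated: ComparisonSet,
) -> CascadeResult:
    """Filter the focal comparison's DMRs through the control comparisons.

    Stage 1: the focal (e.g. twins discordant for the trisomy) DMR set.
    Stage 2: drop any DMR also called in at least one control comparison
    (these are not condition-induced).  Stage 3: keep only DMRs also called
    in the unrelated case/control comparison.  DMR identity is the exact
    promoter key; all comparisons must share one promoter universe.
    """
    uni = discordant.universe()
    for comp in [*controls, unrelated]:
        if comp.universe() != uni:
            raise KeySpaceMismatchError(
                f"comparison {comp.comparison_id!r} does not share the promoter "
                f"key space of {discordant.comparison_id!r}"
            )
    initial = discordant.results[discordant.results["is_dmr"]].copy()
    excluded = frozenset().union(*[c.dmr_keys() for c in controls]) if controls else frozenset()
    keys = pd.Series(map(tuple, initial[_REGION_KEY].itertuples(index=False)), index=initial.index)
    after = initial[~keys.isin(excluded)].copy()
    keys_after = keys[after.index]
    final = after[keys_after.isin(unrelated.dmr_keys())].copy()
    counts = {
        "initial": _tally(initial),
        "after_exclusion": _tally(after),
        "final": _tally(final),
    }
    return CascadeResult(initial=initial, after_exclusion=after, final=final, counts=counts)


# ---------------------------------------------------------------------------
# published-table fixtures


def load_published_dmr_table(which: str) -> pd.DataFrame:
    """Load a packaged fixture transcribing a published DMR table.

    'table2': the 37 gene rows (35 distinct 3-kb promoter intervals) of the
    final trisomy-induced DMR list, with signed methylation differences.
    'table6': the 13 promoters differentially methylated in both sets of
    twins discordant for a congenital heart defect.  'table4': methylation
    differences and expression log2 fold changes for the morphogenesis gene
    set, in fibroblasts and iPS cells.  The file's SHA-256 is verified
    against the digest recorded at packaging time.
    """
    if which not in _FIXTURE_DIGESTS:
        raise KeyError(f"unknown fixture {which!r}; valid: {sorted(_FIXTURE_DIGESTS)}")
    fname, digest = _FIXTURE_DIGESTS[which]
    ref = resources.files("twinmeth.data").joinpath(fname)
    raw = ref.read_bytes()
    got = hashlib.sha256(raw).hexdigest()
    if got != digest:
        raise FixtureIntegrityError(f"{fname}: checksum {got} != expected {digest}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", na_values=["NA"])
    return df


def direction_discordance(table6: pd.DataFrame) -> list[str]:
    """Genes whose methylation differences have opposite signs in the two
    heart-defect twin comparisons, sorted alphabetically."""
    opp = table6["avsd_meth_diff"] * table6["vsd_meth_diff"] < 0
    return sorted(table6.loc[opp, "gene"])


def write_dmr_tables(results: pd.DataFrame, tsv_path=None, bed_path=None) -> None:
    """Write DMR test results as TSV and/or 0-based BED (name=gene, score=q)."""
    if tsv_path is not None:
        results.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        hits = results[results["is_dmr"]]
        bed = hits[["chrom", "start", "end", "name"]].copy()
        bed["score"] = hits["q"]
        bed["strand"] = "."
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
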