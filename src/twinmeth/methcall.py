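"""Per-CpG methylation calling from cytosine count reports.

The unit of input is a Bismark-style cytosine report: one row per cytosine
with strand-aware methylated/unmethylated read counts.  Calling a CpG means
retaining it under a minimum-coverage filter and computing

    percent = 100 * count_m / (count_m + count_u).

Base-quality (Phred >= 20) filtering is assumed to have been applied upstream
by the aligner/extractor that produced the counts; this module records that
assumption rather than re-implementing base-level quality logic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParseError, UndefinedStatisticError

#: column order of the in-memory call table
CALL_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "percent"]

_REPORT_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context"]


@dataclass
class SampleMethylome:
    """Filtered per-CpG methylation calls for one sample.

    ``calls`` holds one row per retained CpG with 1-based positions, sorted by
    (chrom, pos, strand).  ``min_coverage`` records the filter that every call
    passed.
    """

    sample_id: str
    group: str
    calls: pd.DataFrame
    min_coverage: int = 20
    destranded: bool = False
    filters: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"call table lacks columns {missing}")

    @property
    def n_cpgs(self) -> int:
        return len(self.calls)


def _validate_counts(df: pd.DataFrame) -> None:
    if (df["count_m"] < 0).any() or (df["count_u"] < 0).any():
        raise ParseError("negative read counts")
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"duplicate record at {row['chrom']}:{row['pos']}{row['strand']}"
        )


def calls_from_counts(
    counts: pd.DataFrame,
    sample_id: str,
    group: str = "",
    min_coverage: int = 20,
) -> SampleMethylome:
    """Build a :class:`SampleMethylome` from an in-memory count table.

    ``counts`` needs columns chrom, pos (1-based), strand, count_m, count_u
    and optionally context (non-"CpG" rows are dropped).  Rows whose coverage
    is below ``min_coverage`` are filtered out; duplicates are an error, not
    silently summed.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    df = counts.copy()
    if "context" in df.columns:
        df = df[df["context"] == "CpG"]
    _validate_counts(df)
    cov = df["count_m"] + df["count_u"]
    df = df[cov >= min_coverage].copy()
    cov = df["count_m"] + df["count_u"]
    df["percent"] = np.where(cov > 0, 100.0 * df["count_m"] / cov, np.nan)
    df = df[CALL_COLUMNS].sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return SampleMethylome(
        sample_id=sample_id,
        group=group,
        calls=df,
        min_coverage=min_coverage,
        filters={"min_coverage": min_coverage, "phred_filter": "upstream (>=20)"},
    )


def read_report_table(path) -> pd.DataFrame:
    """Parse a Bismark-style cytosine report into a raw count table.

    Expected columns per row (tab-separated, no header): chrom, 1-based
    position, strand (+/-), count_methylated, count_unmethylated, context;
    a 7th column (trinucleotide) is tolerated and ignored.
    """
    rows = []
    opener = open(path) if not isinstance(path, io.TextIOBase) else path
    with opener as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"expected >=6 tab-separated fields, got {len(parts)}", lineno)
            chrom, pos, strand, cm, cu, context = parts[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"bad strand {strand!r}", lineno)
            try:
                pos_i, cm_i, cu_i = int(pos), int(cm), int(cu)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if pos_i < 1:
                raise ParseError("positions are 1-based; got {pos_i}", lineno)
            rows.append((chrom, pos_i, strand, cm_i, cu_i, context))
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def read_bedgraph_counts(path) -> pd.DataFrame:
    """Parse the 6-column bedGraph-with-counts dialect.

    Columns: chrom, 0-based start, end, percent, count_m, count_u.  Returns a
    raw count table in report layout (1-based position, '+' strand, CpG
    context).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "percent", "count_m", "count_u"],
        comment="#",
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int) + 1,
            "strand": "+",
            "count_m": df["count_m"].astype(int),
            "count_u": df["count_u"].astype(int),
            "context": "CpG",
        }
    )
    return out


def read_cytosine_report(
    path,
    min_coverage: int = 20,
    sample_id: str = "",
    group: str = "",
) -> SampleMethylome:
    """Read a cytosine report and call CpG methylation.

    Only CpG-context rows are retained; rows with coverage below
    ``min_coverage`` (default 20X) are dropped.  Returns a valid empty
    methylome when nothing survives the filters.
    """
    raw = read_report_table(path)
    sid = sample_id or str(path)
    return calls_from_counts(raw, sample_id=sid, group=group, min_coverage=min_coverage)


def destrand(methylome: SampleMethylome, enabled: bool = True) -> SampleMethylome:
    """Merge CpG dyads: the - strand record at position p joins the + strand
    record at p-1, summing counts; the dyad is reported at the + position.

    Unpaired - strand records are kept, re-anchored at p-1.  Disabled, this is
    the identity.  Total counts are conserved either way.
    """
    if not enabled:
        return methylome
    df = methylome.calls.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    grouped = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)[["count_m", "count_u"]]
        .sum()
    )
    grouped["strand"] = "+"
    cov = grouped["count_m"] + grouped["count_u"]
    grouped["percent"] = 100.0 * grouped["count_m"] / cov
    grouped = grouped[CALL_COLUMNS].reset_index(drop=True)
    return SampleMethylome(
        sample_id=methylome.sample_id,
        group=methylome.group,
        calls=grouped,
        min_coverage=methylome.min_coverage,
        destranded=True,
        filters=dict(methylome.filters),
    )


def conversion_rate(path_or_table) -> float:
    """Bisulfite conversion rate, in percent, from non-CpG cytosines.

    Non-CpG cytosines (CHH/CHG context) are presumed unmethylated, so reads
    still showing C there reflect incomplete conversion:

        rate = 100 * sum(count_u over non-CpG) / sum(coverage over non-CpG)

    No coverage filter is applied; the estimate pools every non-CpG row.
    """
    if isinstance(path_or_table, pd.DataFrame):
        raw = path_or_table
    else:
        raw = read_report_table(path_or_table)
    non = raw[raw["context"] != "CpG"]
    total = int(non["count_m"].sum() + non["count_u"].sum())
    if len(non) == 0 or total == 0:
        raise UndefinedStatisticError(
            "conversion rate undefined: no covered non-CpG cytosines in report"
        )
    return 100.0 * float(non["count_u"].sum()) / total


def replicate_correlation(a: SampleMethylome, b: SampleMethylome) -> tuple[float, int]:
    """Pearson correlation of percent methylation over shared CpGs.

    Returns ``(r, n_shared)``.  Requires at least 3 shared (chrom, pos,
    strand) calls and non-constant percent vectors on the intersection.
    """
    merged = a.calls.merge(
        b.calls, on=["chrom", "pos", "strand"], suffixes=("_a", "_b")
    )
    n = len(merged)
    if n < 3:
        raise InsufficientDataError(
            f"only {n} shared CpG calls between {a.sample_id} and {b.sample_id}; need >=3"
        )
    x = merged["percent_a"].to_numpy(float)
    y = merged["percent_b"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: constant percent vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n


def pool_reports(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool raw count tables (technical replicates) by summing counts at each
    (chrom, pos, strand, context) site before any coverage filtering."""
    if not tables:
        raise ValueError("no tables to pool")
    cat = pd.concat(tables, ignore_index=True)
    keys = [c for c in ["chrom", "pos", "strand", "context"] if c in cat.columns]
    return (
        cat.groupby(keys, as_index=False, sort=True)[["count_m", "count_u"]]
        .sum()
    )


def write_calls(methylome: SampleMethylome, path) -> None:
    """Write the call table as TSV (1-based positions, header included)."""
    methylome.calls.to_csv(path, sep="\t", index=False)
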