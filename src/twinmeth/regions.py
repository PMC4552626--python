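"""Genomic annotation model and region-level methylation scoring.

Internal coordinates are 0-based half-open; cytosine-report positions are
1-based and converted on the way in.  A region's methylation level is the
count-pooled density — methylated C reads over total C reads across the
region's passing CpGs — not an unweighted mean of per-CpG percents.  Scoring
a region requires at least three CpGs each covered by at least 20 reads;
regions below that return *missing*, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError
from .methcall import SampleMethylome

INTERVAL_COLUMNS = ["chrom", "start", "end", "name"]

#: promoter window around the TSS, in bp (upstream negative)
DEFAULT_PROMOTER_OFFSETS = (-2000, 1000)
#: width of a CpG shore on each side of an island, bp
SHORE_WIDTH = 2000

FEATURE_CLASSES = (
    "promoters",
    "cpg_islands",
    "cpg_shores",
    "exons",
    "introns",
    "lads",
    "ilads",
)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    name: str = ""
    strand: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start >= self.end:
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationModel:
    """Interval sets for every scored feature class, plus the gene table."""

    genes: pd.DataFrame
    promoters: pd.DataFrame
    cpg_islands: pd.DataFrame
    cpg_shores: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    lads: pd.DataFrame
    ilads: pd.DataFrame
    chrom_sizes: dict = field(default_factory=dict)

    def feature(self, class_name: str) -> pd.DataFrame:
        if class_name not in FEATURE_CLASSES:
            raise KeyError(
                f"unknown feature class {class_name!r}; valid: {', '.join(FEATURE_CLASSES)}"
            )
        return getattr(self, class_name)


def _empty_intervals() -> pd.DataFrame:
    return pd.DataFrame(columns=INTERVAL_COLUMNS).astype(
        {"chrom": str, "start": int, "end": int, "name": str}
    )


def _as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = ""
    out = out[[c for c in INTERVAL_COLUMNS if c in out.columns] + [c for c in out.columns if c not in INTERVAL_COLUMNS]]
    bad = out["start"] >= out["end"]
    if bad.any():
        row = out[bad].iloc[0]
        raise ValueError(f"degenerate interval {row['chrom']}:{row['start']}-{row['end']}")
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (merged, sorted)."""
    if len(df) == 0:
        return _empty_intervals()
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, ""))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e, ""))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def subtract_intervals(df: pd.DataFrame, minus: pd.DataFrame) -> pd.DataFrame:
    """Set difference df \\ minus, splitting intervals where needed."""
    if len(df) == 0:
        return _empty_intervals()
    minus = merge_intervals(minus)
    rows = []
    for _, iv in df.iterrows():
        pieces = [(int(iv["start"]), int(iv["end"]))]
        sub = minus[minus["chrom"] == iv["chrom"]]
        for ms, me in zip(sub["start"], sub["end"]):
            nxt = []
            for s, e in pieces:
                if me <= s or ms >= e:
                    nxt.append((s, e))
                    continue
                if s < ms:
                    nxt.append((s, ms))
                if me < e:
                    nxt.append((me, e))
            pieces = nxt
        for s, e in pieces:
            if e > s:
                rows.append((iv["chrom"], s, e, iv.get("name", "")))
    if not rows:
        return _empty_intervals()
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def complement_intervals(df: pd.DataFrame, chrom_sizes: dict) -> pd.DataFrame:
    """Per-chromosome complement within [0, size)."""
    whole = pd.DataFrame(
        [(c, 0, int(n), "") for c, n in sorted(chrom_sizes.items())],
        columns=INTERVAL_COLUMNS,
    )
    return subtract_intervals(whole, df)


def read_bed(path) -> pd.DataFrame:
    """Read BED (>=3 columns; name/score/strand optional), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError("BED needs >=3 columns")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if "name" not in df.columns:
        df["name"] = ""
    return _as_intervals(df[["chrom", "start", "end", "name"] + (["strand"] if "strand" in df.columns else [])])


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Read a refFlat-like gene TSV: symbol, chrom, strand, txStart, txEnd."""
    df = pd.read_csv(path, sep="\t")
    needed = {"symbol", "chrom", "strand", "txStart", "txEnd"}
    if not needed.issubset(df.columns):
        raise ParseError(f"gene table needs columns {sorted(needed)}")
    return df


def promoters_from_genes(
    genes: pd.DataFrame,
    offsets: tuple[int, int] = DEFAULT_PROMOTER_OFFSETS,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS.

    For a + strand gene the TSS is txStart and the window is
    [TSS+offsets[0], TSS+offsets[1]); for a - strand gene the TSS is txEnd
    and the offsets are mirrored, so upstream stays biologically upstream.
    Promoters sharing exact coordinates (divergent gene pairs) are collapsed
    to one interval whose name joins the gene symbols with ';'.
    """
    up, down = offsets
    if up >= down:
        raise ValueError("promoter offsets must satisfy upstream < downstream")
    if len(genes) == 0:
        return _empty_intervals()
    plus = genes["strand"] == "+"
    tss = np.where(plus, genes["txStart"], genes["txEnd"])
    start = np.where(plus, tss + up, tss - down)
    end = np.where(plus, tss + down, tss - up)
    df = pd.DataFrame(
        {"chrom": genes["chrom"], "start": start.astype(int), "end": end.astype(int), "name": genes["symbol"]}
    )
    if chrom_sizes:
        df["start"] = df["start"].clip(lower=0)
        df["end"] = [min(e, chrom_sizes.get(c, e)) for c, e in zip(df["chrom"], df["end"])]
        df = df[df["start"] < df["end"]]
    # collapse coordinate-identical promoters, keeping every gene symbol
    df = (
        df.groupby(["chrom", "start", "end"], as_index=False, sort=True)["name"]
        .agg(lambda s: ";".join(sorted(set(s))))
    )
    return df[INTERVAL_COLUMNS]


def shores_from_islands(
    islands: pd.DataFrame, width: int = SHORE_WIDTH, chrom_sizes: dict | None = None
) -> pd.DataFrame:
    """CpG shores: ``width``-bp flanks on each side of every island, with any
    overlap with islands themselves removed and ends clipped to the genome."""
    rows = []
    for _, iv in islands.iterrows():
        s, e = int(iv["start"]), int(iv["end"])
        rows.append((iv["chrom"], s - width, s, f"{iv['name']}_shore_up"))
        rows.append((iv["chrom"], e, e + width, f"{iv['name']}_shore_down"))
    if not rows:
        return _empty_intervals()
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    df["start"] = df["start"].clip(lower=0)
    if chrom_sizes:
        df["end"] = [min(int(e), int(chrom_sizes.get(c, e))) for c, e in zip(df["chrom"], df["end"])]
    df = df[df["start"] < df["end"]]
    return _as_intervals(subtract_intervals(df, islands))


def build_annotation(
    genes: pd.DataFrame,
    islands: pd.DataFrame | None = None,
    lads: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    introns: pd.DataFrame | None = None,
    promoter_offsets: tuple[int, int] = DEFAULT_PROMOTER_OFFSETS,
    chrom_sizes: dict | None = None,
) -> AnnotationModel:
    """Assemble the full annotation model from its parts.

    Introns default to gene span minus exons.  iLADs are the per-chromosome
    complement of LADs (requires ``chrom_sizes``).  BED chromosomes absent
    from the gene table are a reconciliation error.
    """
    chrom_sizes = dict(chrom_sizes or {})
    known = set(genes["chrom"]) | set(chrom_sizes)
    for label, df in (("islands", islands), ("lads", lads), ("exons", exons)):
        if df is not None:
            extra = sorted(set(df["chrom"]) - known)
            if extra:
                raise ParseError(f"{label} BED has chromosomes absent from gene table: {extra}")
    islands = _as_intervals(islands) if islands is not None else _empty_intervals()
    lads = _as_intervals(lads) if lads is not None else _empty_intervals()
    exons = _as_intervals(exons) if exons is not None else _empty_intervals()
    promoters = promoters_from_genes(genes, promoter_offsets, chrom_sizes)
    shores = shores_from_islands(islands, SHORE_WIDTH, chrom_sizes)
    if introns is None:
        spans = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["txStart"].astype(int),
                "end": genes["txEnd"].astype(int),
                "name": genes["symbol"],
            }
        )
        introns = subtract_intervals(spans, exons) if len(exons) else _empty_intervals()
    if chrom_sizes:
        ilads = complement_intervals(lads, chrom_sizes)
    else:
        ilads = _empty_intervals()
    return AnnotationModel(
        genes=genes.reset_index(drop=True),
        promoters=promoters,
        cpg_islands=islands,
        cpg_shores=shores,
        exons=exons,
        introns=_as_intervals(introns) if len(introns) else _empty_intervals(),
        lads=lads,
        ilads=ilads,
        chrom_sizes=chrom_sizes,
    )


# ---------------------------------------------------------------------------
# region scoring


class _IndexedMethylome:
    """Per-chromosome sorted position arrays with count prefix sums, for
    O(log n) interval aggregation."""

    def __init__(self, methylome: SampleMethylome, min_coverage: int):
        self.by_chrom = {}
        calls = methylome.calls
        cov = calls["count_m"] + calls["count_u"]
        calls = calls[cov >= min_coverage]
        for chrom, grp in calls.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            pos0 = grp["pos"].to_numpy(np.int64) - 1  # 0-based
            cm = np.concatenate([[0], np.cumsum(grp["count_m"].to_numpy(np.int64))])
            cu = np.concatenate([[0], np.cumsum(grp["count_u"].to_numpy(np.int64))])
            self.by_chrom[chrom] = (pos0, cm, cu)

    def aggregate(self, chrom: str, start: int, end: int) -> tuple[int, int, int]:
        """(n_cpgs, meth_c, total_c) over [start, end)."""
        if chrom not in self.by_chrom:
            return 0, 0, 0
        pos0, cm, cu = self.by_chrom[chrom]
        lo = int(np.searchsorted(pos0, start, side="left"))
        hi = int(np.searchsorted(pos0, end, side="left"))
        meth = int(cm[hi] - cm[lo])
        unmeth = int(cu[hi] - cu[lo])
        return hi - lo, meth, meth + unmeth


def score_region(
    methylome: SampleMethylome,
    interval: GenomicInterval,
    min_cpgs: int = 3,
    min_coverage: int = 20,
):
    """Score one region; returns a dict row or None (missing) when fewer than
    ``min_cpgs`` passing CpGs fall inside the half-open interval."""
    idx = _IndexedMethylome(methylome, min_coverage)
    n, meth, total = idx.aggregate(interval.chrom, interval.start, interval.end)
    if n < min_cpgs:
        return None
    return {
        "chrom": interval.chrom,
        "start": interval.start,
        "end": interval.end,
        "name": interval.name,
        "n_cpgs": n,
        "meth_c": meth,
        "total_c": total,
        "percent": 100.0 * meth / total,
    }


def score_intervals(
    methylome: SampleMethylome,
    intervals: pd.DataFrame,
    min_cpgs: int = 3,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Score every interval in a table; regions without enough data are
    excluded and counted in ``result.attrs['n_missing']``."""
    idx = _IndexedMethylome(methylome, min_coverage)
    rows = []
    n_missing = 0
    for chrom, start, end, name in zip(
        intervals["chrom"], intervals["start"], intervals["end"], intervals["name"]
    ):
        n, meth, total = idx.aggregate(chrom, int(start), int(end))
        if n < min_cpgs:
            n_missing += 1
            continue
        rows.append((chrom, int(start), int(end), name, n, meth, total, 100.0 * meth / total))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "n_cpgs", "meth_c", "total_c", "percent"],
    )
    out.attrs["n_missing"] = n_missing
    out.attrs["n_total"] = len(intervals)
    return out


def score_feature_class(
    methylome: SampleMethylome,
    annotation: AnnotationModel,
    class_name: str,
    min_cpgs: int = 3,
    min_coverage: int = 20,
) -> pd.DataFrame:
    """Score every region of one annotation class (promoters, cpg_islands,
    cpg_shores, exons, introns, lads, ilads)."""
    intervals = annotation.feature(class_name)
    return score_intervals(methylome, intervals, min_cpgs=min_cpgs, min_coverage=min_coverage)


def pool_counts(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate region tables by summing counts per region key.

    Only regions scored in every replicate are kept; n_cpgs is taken from the
    first replicate (identical filters imply an identical CpG set).
    """
    if not tables:
        raise ValueError("no tables to pool")
    key = ["chrom", "start", "end", "name"]
    merged = tables[0][key + ["n_cpgs", "meth_c", "total_c"]].copy()
    for i, t in enumerate(tables[1:], start=2):
        merged = merged.merge(
            t[key + ["meth_c", "total_c"]], on=key, suffixes=("", f"_{i}")
        )
        merged["meth_c"] = merged["meth_c"] + merged[f"meth_c_{i}"]
        merged["total_c"] = merged["total_c"] + merged[f"total_c_{i}"]
        merged = merged[key + ["n_cpgs", "meth_c", "total_c"]]
    merged["percent"] = 100.0 * merged["meth_c"] / merged["total_c"]
    return merged
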