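"""Global methylome comparisons and the metagene ("gene model") profile.

Two complementary views of a pair of methylomes:

* per-feature-class comparison — region-level percent methylation of the two
  samples paired on identical region keys, compared with a two-sided
  Mann-Whitney U test, plus histograms of per-CpG differences in both
  orientations (case - control and control - case);

* metagene profile — every gene is mapped onto a common model (upstream
  flank -10 kb..+1 kb of the TSS in fixed 250-bp bins, gene body TSS+1 kb..
  TTS-1 kb in proportionally scaled bins, downstream flank TTS-1 kb..+10 kb,
  plus a pooled intergenic remainder).  Methylation density per bin is the
  percent of methylated C reads over all C reads pooled across genes, and
  the per-bin fold change is density_case / density_control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .methcall import SampleMethylome
from .regions import AnnotationModel, merge_intervals, score_feature_class

FLANK_BP = 10_000
INNER_BP = 1_000
DEFAULT_FLANK_BINS = 44  # 250-bp bins across the 11-kb flank
DEFAULT_BODY_BINS = 60

#: switch from the exact U distribution to the tie-corrected normal
#: approximation above this per-group sample size
EXACT_MAX_N = 50


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null distribution for small untied
    samples, tie-corrected normal approximation otherwise.  Returns (U, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FeatureComparison:
    """Paired region-level comparison of one feature class between samples."""

    feature_class: str
    n: int
    case_percent: np.ndarray
    control_percent: np.ndarray
    u_stat: float
    p: float
    median_case: float
    median_control: float
    diff_bins: np.ndarray = field(default=None)
    hist_case_minus_control: np.ndarray = field(default=None)
    hist_control_minus_case: np.ndarray = field(default=None)


def _hist_right_closed(values, edges):
    """Histogram with (a, b] bins (first bin also takes the left endpoint) —
    the exact mirror of numpy's left-closed convention on negated data."""
    idx = np.clip(np.searchsorted(edges, values, side="left") - 1, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def _percent_difference_histograms(case: SampleMethylome, control: SampleMethylome, n_bins: int):
    shared = case.calls.merge(
        control.calls, on=["chrom", "pos", "strand"], suffixes=("_case", "_control")
    )
    d = (shared["percent_case"] - shared["percent_control"]).to_numpy(float)
    edges = np.linspace(-100.0, 100.0, n_bins + 1)
    h_fwd, _ = np.histogram(d, bins=edges)
    # the reversed orientation uses right-closed bins so that the two
    # histograms are exact mirror images even for edge-valued differences
    h_rev = _hist_right_closed(-d, edges)
    return edges, h_fwd, h_rev


def compare_feature(
    case: SampleMethylome,
    control: SampleMethylome,
    annotation: AnnotationModel,
    class_name: str,
    min_cpgs: int = 3,
    min_coverage: int = 20,
    n_hist_bins: int = 80,
) -> FeatureComparison:
    """Compare region-level methylation of one feature class between two
    methylomes (regions paired on identical keys, scored in both)."""
    t_case = score_feature_class(case, annotation, class_name, min_cpgs, min_coverage)
    t_ctrl = score_feature_class(control, annotation, class_name, min_cpgs, min_coverage)
    merged = t_case.merge(
        t_ctrl, on=["chrom", "start", "end", "name"], suffixes=("_case", "_control")
    )
    if len(merged) < 3:
        raise InsufficientDataError(
            f"{class_name}: only {len(merged)} regions scored in both samples; need >=3"
        )
    x = merged["percent_case"].to_numpy(float)
    y = merged["percent_control"].to_numpy(float)
    u, p = mannwhitney_u(x, y)
    edges, h_fwd, h_rev = _percent_difference_histograms(case, control, n_hist_bins)
    return FeatureComparison(
        feature_class=class_name,
        n=len(merged),
        case_percent=x,
        control_percent=y,
        u_stat=u,
        p=p,
        median_case=float(np.median(x)),
        median_control=float(np.median(y)),
        diff_bins=edges,
        hist_case_minus_control=h_fwd,
        hist_control_minus_case=h_rev,
    )


def feature_comparison_table(comparisons: list[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": c.feature_class,
                "n": c.n,
                "U": c.u_stat,
                "p": c.p,
                "median_case": c.median_case,
                "median_control": c.median_control,
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# metagene profile


@dataclass
class GeneModelProfile:
    """Binned metagene methylation densities and their fold change.

    ``table`` has one row per (segment, bin) with pooled counts and densities
    for both conditions; fold_change is NaN (flagged) where either density's
    denominator is empty or the control density is zero.
    """

    table: pd.DataFrame
    n_genes_used: int
    n_genes_skipped: int
    flank_bins: int
    body_bins: int


class _CpGCounts:
    """Sorted per-chromosome CpG arrays for pooled count lookups."""

    def __init__(self, methylome: SampleMethylome):
        self.by_chrom = {}
        for chrom, grp in methylome.calls.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            self.by_chrom[chrom] = (
                grp["pos"].to_numpy(np.int64) - 1,  # 0-based
                grp["count_m"].to_numpy(np.int64),
                (grp["count_m"] + grp["count_u"]).to_numpy(np.int64),
            )

    def slice(self, chrom, start, end):
        if chrom not in self.by_chrom:
            return (np.empty(0, np.int64),) * 3
        pos, cm, ct = self.by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], cm[lo:hi], ct[lo:hi]


def _gene_segments(tx_start: int, tx_end: int, strand: str):
    """(segment, seg_start, seg_end) triples in genomic coordinates; None if
    the body would be empty (gene shorter than 2 kb)."""
    if tx_end - tx_start <= 2 * INNER_BP:
        return None
    if strand == "+":
        tss, tts = tx_start, tx_end
        return [
            ("upstream", tss - FLANK_BP, tss + INNER_BP),
            ("body", tss + INNER_BP, tts - INNER_BP),
            ("downstream", tts - INNER_BP, tts + FLANK_BP),
        ]
    tss, tts = tx_end, tx_start
    return [
        ("upstream", tss - INNER_BP, tss + FLANK_BP),
        ("body", tts + INNER_BP, tss - INNER_BP),
        ("downstream", tts - FLANK_BP, tts + INNER_BP),
    ]


def _bin_indices(pos, seg_start, seg_end, n_bins, strand):
    """Map 0-based positions within [seg_start, seg_end) to bins 0..n_bins-1,
    mirrored for - strand genes so bin 0 is biologically 5'-most."""
    frac = (pos - seg_start) / (seg_end - seg_start)
    idx = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    if strand == "-":
        idx = n_bins - 1 - idx
    return idx


def gene_model_profile(
    case: SampleMethylome,
    control: SampleMethylome,
    genes: pd.DataFrame,
    flank_bins: int = DEFAULT_FLANK_BINS,
    body_bins: int = DEFAULT_BODY_BINS,
) -> GeneModelProfile:
    """Pool CpG counts of both methylomes onto the common gene model and
    compute per-bin methylation densities and their case/control fold change.

    Genes whose body segment would be empty (span <= 2 kb) are skipped and
    counted.  Every CpG inside a gene's model maps to exactly one bin of that
    gene; the intergenic remainder (per-chromosome complement of all gene
    models) is pooled into a single row.
    """
    counters = {"case": _CpGCounts(case), "control": _CpGCounts(control)}
    seg_bins = {"upstream": flank_bins, "body": body_bins, "downstream": flank_bins}
    acc = {
        (seg, b): {"meth_case": 0, "total_case": 0, "meth_control": 0, "total_control": 0}
        for seg, nb in seg_bins.items()
        for b in range(nb)
    }
    acc[("intergenic", 0)] = {"meth_case": 0, "total_case": 0, "meth_control": 0, "total_control": 0}

    used = skipped = 0
    model_spans = []
    for _, g in genes.iterrows():
        segs = _gene_segments(int(g["txStart"]), int(g["txEnd"]), g["strand"])
        if segs is None:
            skipped += 1
            continue
        used += 1
        for seg, s, e in segs:
            model_spans.append((g["chrom"], max(0, s), e, ""))
            for cond, counter in counters.items():
                pos, cm, ct = counter.slice(g["chrom"], s, e)
                if len(pos) == 0:
                    continue
                idx = _bin_indices(pos, s, e, seg_bins[seg], g["strand"])
                for b in range(seg_bins[seg]):
                    sel = idx == b
                    if sel.any():
                        acc[(seg, b)][f"meth_{cond}"] += int(cm[sel].sum())
                        acc[(seg, b)][f"total_{cond}"] += int(ct[sel].sum())
    if used == 0:
        raise InsufficientDataError("no gene with a non-empty body segment (> 2 kb span)")

    # intergenic remainder: everything outside all gene models
    model = merge_intervals(pd.DataFrame(model_spans, columns=["chrom", "start", "end", "name"]))
    for cond, counter in counters.items():
        for chrom, (pos, cm, ct) in counter.by_chrom.items():
            inside = np.zeros(len(pos), bool)
            sub = model[model["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="left")
                inside[lo:hi] = True
            acc[("intergenic", 0)][f"meth_{cond}"] += int(cm[~inside].sum())
            acc[("intergenic", 0)][f"total_{cond}"] += int(ct[~inside].sum())

    rows = []
    for (seg, b), v in acc.items():
        dc = 100.0 * v["meth_case"] / v["total_case"] if v["total_case"] else np.nan
        dk = 100.0 * v["meth_control"] / v["total_control"] if v["total_control"] else np.nan
        fc = dc / dk if (v["total_case"] and v["total_control"] and dk > 0) else np.nan
        rows.append({"segment": seg, "bin": b, **v, "density_case": dc, "density_control": dk, "fold_change": fc})
    order = {"upstream": 0, "body": 1, "downstream": 2, "intergenic": 3}
    table = (
        pd.DataFrame(rows)
        .sort_values(["segment", "bin"], key=lambda s: s.map(order) if s.name == "segment" else s)
        .reset_index(drop=True)
    )
    return GeneModelProfile(
        table=table,
        n_genes_used=used,
        n_genes_skipped=skipped,
        flank_bins=flank_bins,
        body_bins=body_bins,
    )
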