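"""Synthetic RRBS cohort generator with a ground-truth ledger.

The generator emulates the statistical structure the analysis assumes, not
the sequencing chemistry: CpG sites cluster in promoters (RRBS enriches for
CpG-dense regions), per-CpG coverage is overdispersed (negative binomial),
and per-CpG methylation is beta-binomial — a latent methylation proportion
drawn per CpG from a region-class beta prior (islands/promoters low,
background high, mirroring the bimodality of real methylomes), counts drawn
binomially per sample.

Twin pairs share one latent methylome; the affected twin's promoter CpGs get
a small global hypermethylation shift plus any planted DMR deltas, applied on
the percent scale and clamped to [0.01, 0.99] before sampling.  Technical
replicates re-measure the same individual with independent coverage/count
draws plus per-CpG jitter.  Unrelated individuals draw independent latent
methylomes.  Every sample has its own RNG stream derived from the master
seed, so adding samples never perturbs earlier ones, and an identical seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SizingError
from .methcall import SampleMethylome, calls_from_counts
from .regions import AnnotationModel, build_annotation

CLAMP_LO, CLAMP_HI = 0.01, 0.99

#: margin at each chromosome end so every gene model (10-kb flanks) fits
_CHROM_MARGIN = 12_000
# promoters reach 2 kb beyond a gene end on each side, so neighbouring gene
# models need at least 4 kb of slack to keep promoters disjoint
_GENE_BUFFER = 4_500

# RNG stream roles (spawn keys off the master seed)
_KEY_LAYOUT = 0
_KEY_LATENT = 1
_KEY_SAMPLE = 2
_KEY_EXPR = 3


@dataclass
class SimulationConfig:
    """Study-condition knobs of the synthetic cohort.

    Effects (``global_shift``, planted deltas, replicate jitter) are in
    percentage points; ``background_cpg_density`` and ``noncpg_density`` are
    sites per kb; coverage is negative binomial with the given mean and
    dispersion (variance = mean + dispersion * mean^2, Poisson at 0).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_500_000
    n_promoters: int = 100
    cpgs_per_promoter_range: tuple[int, int] = (15, 25)
    background_cpg_density: float = 1.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.1
    baseline_methylation_beta: dict = field(
        default_factory=lambda: {"promoter": (1.5, 13.5), "background": (8.0, 2.0)}
    )
    global_shift: float = 0.0
    planted_dmrs: list = field(default_factory=list)
    replicate_noise_sd: float = 10.0
    expression_coupling: float = 0.05
    expression_noise_sd: float = 0.3
    n_replicates: int = 2
    gene_length: int = 20_000
    island_length: int = 1_000
    noncpg_density: float = 0.5
    noncpg_methylation_percent: float = 0.2

    def validate(self) -> None:
        lo, hi = self.cpgs_per_promoter_range
        if not (0 < lo <= hi):
            raise ValueError("cpgs_per_promoter_range must satisfy 0 < min <= max")
        if self.n_replicates < 1 or self.n_chromosomes < 1:
            raise ValueError("need >= 1 replicate and >= 1 chromosome")
        g = self._genes_per_chrom()
        usable = self.chromosome_length - 2 * _CHROM_MARGIN - self.gene_length
        if usable < 0 or (max(g) > 1 and usable // (max(g) - 1) < self.gene_length + _GENE_BUFFER):
            raise SizingError(
                f"{self.n_promoters} promoters with {self.gene_length} bp genes do "
                f"not fit on {self.n_chromosomes} x {self.chromosome_length} bp"
            )

    def _genes_per_chrom(self) -> list[int]:
        base = self.n_promoters // self.n_chromosomes
        extra = self.n_promoters % self.n_chromosomes
        return [base + (1 if i < extra else 0) for i in range(self.n_chromosomes)]

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))
        )


@dataclass
class TruthLedger:
    """Ground truth of the planted signal: one entry per promoter with its
    interval and signed planted delta (0 for nulls)."""

    entries: pd.DataFrame  # chrom, start, end, name, region_class, planted_delta_percent, is_null

    def __post_init__(self):
        e = self.entries
        mismatch = (e["planted_delta_percent"] == 0) != e["is_null"]
        if mismatch.any():
            raise ValueError("ledger invariant violated: delta == 0 iff is_null")
        for (chrom, cls), grp in e.groupby(["chrom", "region_class"]):
            grp = grp.sort_values("start")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping truth intervals on {chrom}/{cls}")

    def planted(self) -> pd.DataFrame:
        return self.entries[~self.entries["is_null"]]


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> AnnotationModel:
    """Lay out genes, promoters, CpG islands/shores, exons/introns and
    LADs/iLADs on the synthetic genome.

    Genes are evenly spaced, strands alternate, every promoter is the
    standard (-2000, +1000) TSS window (3000 bp), each with a CpG island
    centred on its TSS; LADs tile alternating 100-kb blocks.  Raises
    :class:`SizingError` when the layout does not fit the chromosome.
    """
    config.validate()
    chrom_sizes = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    rows = []
    gi = 0
    for ci, g in enumerate(config._genes_per_chrom()):
        chrom = f"chr{ci + 1}"
        if g == 0:
            continue
        usable = config.chromosome_length - 2 * _CHROM_MARGIN - config.gene_length
        spacing = usable // max(g - 1, 1) if g > 1 else 0
        for j in range(g):
            tx_start = _CHROM_MARGIN + j * spacing
            tx_end = tx_start + config.gene_length
            strand = "+" if gi % 2 == 0 else "-"
            rows.append((f"G{gi + 1:05d}", chrom, strand, tx_start, tx_end))
            gi += 1
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "txStart", "txEnd"])

    tss = np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"])
    half = config.island_length // 2
    islands = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": tss - half,
            "end": tss + (config.island_length - half),
            "name": genes["symbol"] + "_island",
        }
    )
    exon_len = 200
    exons = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": genes["chrom"],
                    "start": genes["txStart"] + off,
                    "end": genes["txStart"] + off + exon_len,
                    "name": genes["symbol"] + f"_exon{k + 1}",
                }
            )
            for k, off in enumerate(
                [0, config.gene_length // 2, config.gene_length - exon_len]
            )
        ],
        ignore_index=True,
    )
    lad_rows = []
    block = 100_000
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, 2 * block):
            lad_rows.append((chrom, s, min(s + block, size), f"{chrom}_lad_{s}"))
    lads = pd.DataFrame(lad_rows, columns=["chrom", "start", "end", "name"])
    return build_annotation(
        genes, islands=islands, lads=lads, exons=exons, chrom_sizes=chrom_sizes
    )


# ---------------------------------------------------------------------------
# CpG site layout


@dataclass
class SiteLayout:
    """Genomic CpG (and non-CpG cytosine) positions shared by every sample."""

    sites: pd.DataFrame  # chrom, pos0, region_class ('promoter'/'background'), promoter_idx
    noncpg: pd.DataFrame  # chrom, pos0, context


def generate_sites(config: SimulationConfig, annotation: AnnotationModel) -> SiteLayout:
    """Place promoter-clustered and background CpGs plus non-CpG cytosines."""
    rng = config.rng(_KEY_LAYOUT)
    promoters = annotation.promoters.reset_index(drop=True)
    lo, hi = config.cpgs_per_promoter_range
    chroms, positions, pidxs = [], [], []
    for pi, (chrom, start, end) in enumerate(
        zip(promoters["chrom"], promoters["start"], promoters["end"])
    ):
        n = int(rng.integers(lo, hi + 1))
        width = int(end - start)
        offs = np.sort(rng.choice(width, size=min(n, width), replace=False))
        chroms.append(np.full(len(offs), chrom, dtype=object))
        positions.append(start + offs)
        pidxs.append(np.full(len(offs), pi))
    frames = [
        pd.DataFrame(
            {
                "chrom": np.concatenate(chroms),
                "pos0": np.concatenate(positions),
                "region_class": "promoter",
                "promoter_idx": np.concatenate(pidxs),
            }
        )
    ]
    L = config.chromosome_length
    for chrom in sorted({c for c in promoters["chrom"]} | set(annotation.chrom_sizes)):
        n_bg = int(round(config.background_cpg_density * L / 1000))
        if n_bg == 0:
            continue
        pos = np.unique(rng.integers(0, L, size=int(n_bg * 1.05) + 8))[:n_bg]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos0": pos, "region_class": "background", "promoter_idx": -1}
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.drop_duplicates(subset=["chrom", "pos0"], keep="first")
    sites = sites.sort_values(["chrom", "pos0"]).reset_index(drop=True)

    # background CpGs that happen to fall inside a promoter belong to it;
    # promoters are disjoint, so a sorted interval lookup suffices
    for chrom, prom_grp in promoters.groupby("chrom", sort=False):
        prom_grp = prom_grp.sort_values("start")
        starts = prom_grp["start"].to_numpy()
        ends = prom_grp["end"].to_numpy()
        pidx = prom_grp.index.to_numpy()
        sel = sites["chrom"] == chrom
        pos = sites.loc[sel, "pos0"].to_numpy()
        slot = np.searchsorted(starts, pos, side="right") - 1
        ok = (slot >= 0) & (pos < ends[np.clip(slot, 0, len(ends) - 1)])
        rows = sites.index[sel][ok]
        sites.loc[rows, "region_class"] = "promoter"
        sites.loc[rows, "promoter_idx"] = pidx[slot[ok]]

    nc_frames = []
    for chrom in sorted(annotation.chrom_sizes):
        n_nc = int(round(config.noncpg_density * L / 1000))
        if n_nc == 0:
            continue
        pos = np.unique(rng.integers(0, L, size=int(n_nc * 1.05) + 8))[:n_nc]
        nc_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos0": pos,
                    "context": np.where(np.arange(len(pos)) % 2 == 0, "CHH", "CHG"),
                }
            )
        )
    noncpg = (
        pd.concat(nc_frames, ignore_index=True)
        if nc_frames
        else pd.DataFrame(columns=["chrom", "pos0", "context"])
    )
    return SiteLayout(sites=sites, noncpg=noncpg)


# ---------------------------------------------------------------------------
# methylomes


def _draw_latent(
    config: SimulationConfig, sites: pd.DataFrame, rng, mirror: np.ndarray | None = None
) -> np.ndarray:
    """Per-CpG latent methylation proportions from the class beta priors.

    ``mirror`` flags CpGs whose baseline is reflected (p -> 1 - p): promoters
    carrying a planted hypomethylation delta start methylated, since a large
    negative shift from a near-zero baseline would be clamped away.
    """
    p = np.empty(len(sites))
    for cls, (a, b) in config.baseline_methylation_beta.items():
        mask = (sites["region_class"] == cls).to_numpy()
        p[mask] = rng.beta(a, b, size=int(mask.sum()))
    if mirror is not None:
        p[mirror] = 1.0 - p[mirror]
    return p


def _plant_effects(
    config: SimulationConfig,
    annotation: AnnotationModel,
    sites: pd.DataFrame,
) -> tuple[np.ndarray, TruthLedger]:
    """Per-CpG case-group delta (fractions) and the truth ledger.

    The global shift applies to every promoter-class CpG (promoters contain
    the islands here); each planted DMR adds its delta to one distinct
    promoter, chosen from a layout-derived stream so every comparison sees
    the same planted loci.
    """
    promoters = annotation.promoters.reset_index(drop=True)
    delta_by_promoter = np.zeros(len(promoters))
    rng = config.rng(_KEY_LAYOUT, 1)
    n_plant = len(config.planted_dmrs)
    if n_plant > len(promoters):
        raise SizingError(f"cannot plant {n_plant} DMRs into {len(promoters)} promoters")
    chosen = rng.choice(len(promoters), size=n_plant, replace=False) if n_plant else []
    for idx, spec_entry in zip(chosen, config.planted_dmrs):
        if spec_entry.get("region_class", "promoter") != "promoter":
            raise ValueError("only promoter-class DMR planting is supported")
        delta_by_promoter[idx] = float(spec_entry["delta_percent"])

    pidx = sites["promoter_idx"].to_numpy()
    is_prom = pidx >= 0
    delta = np.zeros(len(sites))
    delta[is_prom] = config.global_shift + delta_by_promoter[pidx[is_prom]]

    entries = promoters[["chrom", "start", "end", "name"]].copy()
    entries["region_class"] = "promoter"
    entries["planted_delta_percent"] = delta_by_promoter
    entries["is_null"] = delta_by_promoter == 0
    return delta / 100.0, TruthLedger(entries=entries)


def _draw_counts(
    config: SimulationConfig, sites: pd.DataFrame, p_true: np.ndarray, rng
) -> pd.DataFrame:
    """One sample's raw CpG count table (report layout, 1-based, + strand)."""
    n = len(sites)
    if config.coverage_dispersion <= 1e-12:
        cov = rng.poisson(config.coverage_mean, size=n)
    else:
        shape = 1.0 / config.coverage_dispersion
        prob = shape / (shape + config.coverage_mean)
        cov = rng.negative_binomial(shape, prob, size=n)
    jitter = rng.normal(0.0, config.replicate_noise_sd / 100.0, size=n)
    p = np.clip(p_true + jitter, CLAMP_LO, CLAMP_HI)
    meth = rng.binomial(cov, p)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos0"].to_numpy() + 1,
            "strand": "+",
            "count_m": meth,
            "count_u": cov - meth,
            "context": "CpG",
        }
    )


def _noncpg_counts(config: SimulationConfig, noncpg: pd.DataFrame, rng) -> pd.DataFrame:
    n = len(noncpg)
    if n == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count_m", "count_u", "context"])
    cov = rng.poisson(config.coverage_mean, size=n)
    meth = rng.binomial(cov, config.noncpg_methylation_percent / 100.0)
    return pd.DataFrame(
        {
            "chrom": noncpg["chrom"].to_numpy(),
            "pos": noncpg["pos0"].to_numpy() + 1,
            "strand": "+",
            "count_m": meth,
            "count_u": cov - meth,
            "context": noncpg["context"].to_numpy(),
        }
    )


def simulate_comparison(
    config: SimulationConfig,
    annotation: AnnotationModel,
    layout: SiteLayout,
    comparison_index: int = 0,
    kind: str = "discordant",
    label: str | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthLedger]:
    """Simulate one paired comparison (case vs control, each with replicates).

    kinds: 'discordant' — twins sharing a latent methylome, case gets shift
    and planted deltas; 'null_twins' — twins with no case effect;
    'unrelated' — independent latent methylomes, case gets the effects.
    Returns raw per-sample count tables keyed by sample id.
    """
    if kind not in ("discordant", "null_twins", "unrelated"):
        raise ValueError(f"unknown comparison kind {kind!r}")
    label = label or kind
    delta, truth = _plant_effects(config, annotation, layout.sites)
    mirror = delta < 0
    latent_rng = config.rng(_KEY_LATENT, comparison_index)
    p_control = _draw_latent(config, layout.sites, latent_rng, mirror)
    if kind == "unrelated":
        p_case_base = _draw_latent(config, layout.sites, latent_rng, mirror)
    else:
        p_case_base = p_control.copy()
    if kind == "null_twins":
        p_case = p_case_base
    else:
        p_case = np.clip(p_case_base + delta, CLAMP_LO, CLAMP_HI)
    p_control = np.clip(p_control, CLAMP_LO, CLAMP_HI)

    samples: dict[str, pd.DataFrame] = {}
    for r in range(config.n_replicates):
        for gi, (group, p_true) in enumerate([("Normal", p_control), ("T21", p_case)]):
            sample_no = comparison_index * 1000 + r * 2 + gi
            rng = config.rng(_KEY_SAMPLE, sample_no)
            counts = _draw_counts(config, layout.sites, p_true, rng)
            counts = pd.concat(
                [counts, _noncpg_counts(config, layout.noncpg, rng)], ignore_index=True
            )
            counts = counts.sort_values(["chrom", "pos"]).reset_index(drop=True)
            samples[f"{label}_{group}_rep{r + 1}"] = counts
    return samples, truth


def simulate_methylomes(
    config: SimulationConfig, annotation: AnnotationModel
) -> tuple[dict[str, pd.DataFrame], TruthLedger]:
    """Simulate the focal discordant twin pair (the single-comparison entry
    point): per-sample Bismark-style count tables plus the truth ledger."""
    layout = generate_sites(config, annotation)
    return simulate_comparison(config, annotation, layout, 0, "discordant")


def methylomes_from_counts(
    samples: dict[str, pd.DataFrame], min_coverage: int = 20
) -> dict[str, SampleMethylome]:
    """Run the calling filters over simulated raw count tables."""
    out = {}
    for sid, counts in samples.items():
        group = "T21" if "_T21_" in sid else "Normal"
        out[sid] = calls_from_counts(counts, sample_id=sid, group=group, min_coverage=min_coverage)
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig, truth: TruthLedger
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample RPKM table coupled to the planted methylation deltas.

    True log2 fold change per gene is -coupling * planted_delta plus Gaussian
    noise; four control and three case replicates scatter around the group
    means (mirroring a 4-vs-3 replicate design).  Returns (rpkm, truth_expr)
    where truth_expr records each gene's true log2 fold change.
    """
    rng = config.rng(_KEY_EXPR)
    genes = truth.entries["name"].str.split(";").str[0].to_numpy()
    delta = truth.entries["planted_delta_percent"].to_numpy()
    l2fc = -config.expression_coupling * delta + rng.normal(
        0.0, config.expression_noise_sd, size=len(genes)
    )
    base = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=len(genes))
    rep_sd = 0.1
    cols = {}
    for r in range(4):
        cols[f"Normal_rep{r + 1}"] = base * 2 ** rng.normal(0, rep_sd, len(genes))
    for r in range(3):
        cols[f"T21_rep{r + 1}"] = base * 2 ** (l2fc + rng.normal(0, rep_sd, len(genes)))
    rpkm = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth_expr = pd.DataFrame(
        {"gene": genes, "planted_delta_percent": delta, "true_log2fc": l2fc}
    ).set_index("gene")
    return rpkm, truth_expr


# ---------------------------------------------------------------------------
# cohort-level convenience and writers


def simulate_cohort(config: SimulationConfig):
    """Simulate the four comparison sets of the twin-study design on one
    shared genome: discordant twins (effects planted), two null twin pairs,
    and an unrelated case/control pair (same effects, independent baselines).

    Returns (annotation, layout, comparisons, truth) where comparisons maps
    label -> dict of raw per-sample count tables.
    """
    annotation = generate_annotation(config)
    layout = generate_sites(config, annotation)
    comparisons = {}
    specs = [
        ("discordantT21", "discordant"),
        ("normalTwins", "null_twins"),
        ("concordantT21", "null_twins"),
        ("unrelated", "unrelated"),
    ]
    truth = None
    for idx, (label, kind) in enumerate(specs):
        samples, t = simulate_comparison(config, annotation, layout, idx, kind, label=label)
        comparisons[label] = samples
        truth = truth or t
    return annotation, layout, comparisons, truth


def write_cytosine_report(counts: pd.DataFrame, path) -> None:
    """Write a raw count table as a Bismark-style cytosine report TSV."""
    counts[["chrom", "pos", "strand", "count_m", "count_u", "context"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_annotation(annotation: AnnotationModel, outdir) -> None:
    """Write BED6 per feature class, the gene table, and chromosome sizes."""
    from pathlib import Path

    from .regions import FEATURE_CLASSES, write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls in FEATURE_CLASSES:
        write_bed(annotation.feature(cls), outdir / f"{cls}.bed")
    annotation.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(annotation.chrom_sizes).to_csv(
        outdir / "chrom_sizes.tsv", sep="\t", header=False
    )


def write_truth(truth: TruthLedger, path) -> None:
    truth.entries.to_csv(path, sep="\t", index=False)
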