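"""Synthetic cohort generator: determinism, layout, planted-signal recovery."""

import io

import numpy as np
import pandas as pd
import pytest

from twinmeth import integrate, simulate
from twinmeth.errors import SizingError


class TestAnnotationLayout:
    def test_promoters_are_exactly_3kb(self, small_annotation):
        spans = small_annotation.promoters["end"] - small_annotation.promoters["start"]
        assert (spans == 3_000).all()

    def test_zero_promoters_still_yields_ilads(self):
        cfg = simulate.SimulationConfig(seed=0, n_promoters=0, chromosome_length=300_000,
                                        n_chromosomes=1)
        ann = simulate.generate_annotation(cfg)
        assert len(ann.promoters) == 0
        assert len(ann.ilads) > 0
        # iLADs complement LADs exactly
        covered = (ann.lads["end"] - ann.lads["start"]).sum() + (
            ann.ilads["end"] - ann.ilads["start"]
        ).sum()
        assert covered == cfg.chromosome_length

    def test_infeasible_layout_raises_sizing_error(self):
        cfg = simulate.SimulationConfig(seed=0, n_promoters=500, chromosome_length=300_000)
        with pytest.raises(SizingError):
            simulate.generate_annotation(cfg)

    def test_all_intervals_within_chromosome_bounds(self, small_annotation):
        for cls in ("promoters", "cpg_islands", "cpg_shores", "exons", "introns", "lads", "ilads"):
            df = small_annotation.feature(cls)
            for chrom, size in small_annotation.chrom_sizes.items():
                sub = df[df["chrom"] == chrom]
                assert (sub["start"] >= 0).all() and (sub["end"] <= size).all()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_reports(self, small_config, small_annotation):
        outputs = []
        for _ in range(2):
            samples, _ = simulate.simulate_methylomes(small_config, small_annotation)
            buf = io.StringIO()
            simulate.write_cytosine_report(samples["discordant_Normal_rep1"], buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_adding_samples_does_not_perturb_earlier_ones(self, small_config, small_annotation):
        one = simulate.SimulationConfig(**{**small_config.__dict__, "n_replicates": 1})
        two = simulate.SimulationConfig(**{**small_config.__dict__, "n_replicates": 2})
        s1, _ = simulate.simulate_methylomes(one, small_annotation)
        s2, _ = simulate.simulate_methylomes(two, small_annotation)
        pd.testing.assert_frame_equal(
            s1["discordant_Normal_rep1"], s2["discordant_Normal_rep1"]
        )


class TestTruthLedger:
    def test_null_iff_zero_delta(self, small_cohort):
        _, _, _, truth, _ = small_cohort
        e = truth.entries
        assert ((e["planted_delta_percent"] == 0) == e["is_null"]).all()
        assert len(truth.planted()) == 2

    def test_inconsistent_ledger_rejected(self):
        bad = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [3000],
                "name": ["G"],
                "region_class": ["promoter"],
                "planted_delta_percent": [40.0],
                "is_null": [True],
            }
        )
        with pytest.raises(ValueError):
            simulate.TruthLedger(entries=bad)


class TestMethylomeStatistics:
    def test_null_groups_have_no_mean_difference(self):
        # law of large numbers: with no shift and no planted signal the mean
        # per-CpG percent difference between twins stays within +/-1 point
        cfg = simulate.SimulationConfig(
            seed=21, n_promoters=100, n_chromosomes=2, chromosome_length=3_000_000,
            background_cpg_density=2.0, cpgs_per_promoter_range=(20, 30),
        )
        ann = simulate.generate_annotation(cfg)
        samples, _ = simulate.simulate_methylomes(cfg, ann)
        meths = simulate.methylomes_from_counts(samples)
        a = meths["discordant_T21_rep1"].calls
        b = meths["discordant_Normal_rep1"].calls
        merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
        assert len(merged) >= 10_000
        assert abs((merged["percent_a"] - merged["percent_b"]).mean()) < 1.0

    def test_planted_delta_recovered_within_binomial_sampling_error(self):
        # jitter-free conditions isolate binomial sampling error: the pooled
        # promoter difference must land within +/-5 points of the planted 40
        # at 20 CpGs x 30X
        from twinmeth import regions

        cfg = simulate.SimulationConfig(
            seed=77, n_promoters=40, n_chromosomes=1, chromosome_length=1_200_000,
            cpgs_per_promoter_range=(20, 20), coverage_mean=30.0,
            replicate_noise_sd=0.0,
            planted_dmrs=[{"region_class": "promoter", "delta_percent": 40.0}] * 4
            + [{"region_class": "promoter", "delta_percent": -40.0}] * 2,
        )
        annotation = simulate.generate_annotation(cfg)
        samples, truth = simulate.simulate_methylomes(cfg, annotation)
        methylomes = simulate.methylomes_from_counts(samples)
        case = regions.pool_counts(
            [
                regions.score_feature_class(methylomes[f"discordant_T21_rep{r}"], annotation, "promoters")
                for r in (1, 2)
            ]
        )
        ctrl = regions.pool_counts(
            [
                regions.score_feature_class(methylomes[f"discordant_Normal_rep{r}"], annotation, "promoters")
                for r in (1, 2)
            ]
        )
        merged = case.merge(ctrl, on=["chrom", "start", "end", "name"], suffixes=("_c", "_k"))
        merged = merged.merge(truth.planted(), on=["chrom", "start", "end", "name"])
        observed = merged["percent_c"] - merged["percent_k"]
        assert len(merged) == 6
        assert np.all(np.abs(observed - merged["planted_delta_percent"]) <= 5.0)

    def test_global_shift_raises_promoter_methylation(self):
        cfg = simulate.SimulationConfig(seed=33, n_promoters=60, n_chromosomes=1,
                                        chromosome_length=1_800_000, global_shift=10.0)
        ann = simulate.generate_annotation(cfg)
        samples, _ = simulate.simulate_methylomes(cfg, ann)
        meths = simulate.methylomes_from_counts(samples)
        a = meths["discordant_T21_rep1"].calls
        b = meths["discordant_Normal_rep1"].calls
        merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
        assert (merged["percent_a"] - merged["percent_b"]).mean() > 2.0


class TestExpression:
    def test_zero_coupling_gives_weak_correlation(self):
        cfg = simulate.SimulationConfig(
            seed=9, n_promoters=50, n_chromosomes=1, chromosome_length=1_500_000,
            expression_coupling=0.0,
            planted_dmrs=[{"region_class": "promoter", "delta_percent": 40.0}] * 10,
        )
        ann = simulate.generate_annotation(cfg)
        _, truth = simulate.simulate_methylomes(cfg, ann)
        rpkm, _ = simulate.simulate_expression(cfg, truth)
        fc = integrate.log2_group_fold_change(
            rpkm, [c for c in rpkm if c.startswith("T21")], [c for c in rpkm if c.startswith("Normal")]
        )
        r, _ = integrate.meth_expr_correlation(
            truth.entries["planted_delta_percent"], fc["log2fc"]
        )
        assert abs(r) < 0.3

    def test_strong_coupling_with_vanishing_noise_approaches_minus_one(self):
        cfg = simulate.SimulationConfig(
            seed=9, n_promoters=50, n_chromosomes=1, chromosome_length=1_500_000,
            expression_coupling=0.05, expression_noise_sd=1e-6,
            planted_dmrs=[{"region_class": "promoter", "delta_percent": 40.0}] * 10
            + [{"region_class": "promoter", "delta_percent": -40.0}] * 5,
        )
        ann = simulate.generate_annotation(cfg)
        _, truth = simulate.simulate_methylomes(cfg, ann)
        _, truth_expr = simulate.simulate_expression(cfg, truth)
        r, _ = integrate.meth_expr_correlation(
            truth_expr["planted_delta_percent"], truth_expr["true_log2fc"]
        )
        assert r == pytest.approx(-1.0, abs=1e-3)

    def test_rpkm_strictly_positive(self, small_cohort):
        cfg, _, _, truth, _ = small_cohort
        rpkm, _ = simulate.simulate_expression(cfg, truth)
        assert (rpkm.to_numpy() > 0).all()

    def test_seven_gene_ledger_correlation_matches_direct_formula(self):
        # a hand-sized ledger: brute-force Pearson agrees with the pipeline's
        deltas = np.array([35.2, 62.16, 45.3, 45.3, 31.3, 41.5, 60.58])
        l2fc = np.array([-0.8, -2.84, -0.32, -1.85, -0.3, 0.0, 3.12])
        r, n = integrate.meth_expr_correlation(deltas, l2fc)
        dx = deltas - deltas.mean()
        dy = l2fc - l2fc.mean()
        brute = float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
        assert n == 7
        assert r == pytest.approx(brute, rel=1e-12)


def test_cohort_comparisons_share_annotation_and_sites(small_config):
    ann, layout, comps, truth = simulate.simulate_cohort(
        simulate.SimulationConfig(**{**small_config.__dict__, "n_replicates": 1})
    )
    assert set(comps) == {"discordantT21", "normalTwins", "concordantT21", "unrelated"}
    pos = {
        label: samples[f"{label}_Normal_rep1"][["chrom", "pos"]]
        for label, samples in comps.items()
    }
    base = pos["discordantT21"]
    for label in ("normalTwins", "concordantT21", "unrelated"):
        pd.testing.assert_frame_equal(base, pos[label])
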