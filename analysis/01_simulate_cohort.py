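#!/usr/bin/env python
"""Generate the synthetic twin cohort and write its data products.

Cytosine reports (bulky) go under scratch/cohort/; the per-sample summary
(CpG calls at 20X, bisulfite conversion rate, replicate correlation) goes to
results/01_cohort_summary.tsv.
"""

import pandas as pd

from twinmeth import methcall, simulate

from _cohort import COHORT_CONFIG, RESULTS, SCRATCH, build_cohort


def main():
    annotation, layout, comparisons, truth = build_cohort()
    outdir = SCRATCH / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    simulate.write_annotation(annotation, outdir / "annotation")
    simulate.write_truth(truth, outdir / "truth_ledger.tsv")
    rpkm, truth_expr = simulate.simulate_expression(COHORT_CONFIG, truth)
    rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
    truth_expr.to_csv(outdir / "truth_expression.tsv", sep="\t")

    rows = []
    for label, samples in comparisons.items():
        d = outdir / label
        d.mkdir(exist_ok=True)
        for sid, counts in samples.items():
            simulate.write_cytosine_report(counts, d / f"{sid}.cov.tsv")
            m = methcall.calls_from_counts(counts, sid)
            rows.append(
                {
                    "sample": sid,
                    "comparison": label,
                    "n_cpg_calls_20x": m.n_cpgs,
                    "conversion_rate_percent": round(methcall.conversion_rate(counts), 3),
                }
            )
    summary = pd.DataFrame(rows)

    disc = simulate.methylomes_from_counts(comparisons["discordantT21"])
    r_n, _ = methcall.replicate_correlation(
        disc["discordantT21_Normal_rep1"], disc["discordantT21_Normal_rep2"]
    )
    r_t, _ = methcall.replicate_correlation(
        disc["discordantT21_T21_rep1"], disc["discordantT21_T21_rep2"]
    )

    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)
    print(f"wrote {len(summary)} samples to {outdir}")
    print(f"planted DMRs: {len(truth.planted())} "
          f"({int((truth.planted()['planted_delta_percent'] > 0).sum())} hyper)")
    print(f"technical replicate correlation: normal {r_n:.3f}, trisomic {r_t:.3f}")
    print(f"median conversion rate: {summary['conversion_rate_percent'].median():.2f}%")


if __name__ == "__main__":
    main()
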