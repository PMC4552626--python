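#!/usr/bin/env python
"""Promoter DMR calling and the multi-comparison filtering cascade.

Tests every promoter in all four comparisons (pooled Fisher exact, SLIM
q-values, q <= 0.001 and |delta| >= 25 points), excludes DMRs also called in
control twin pairs, intersects with the unrelated comparison, and confronts
the surviving candidate list with the simulation's truth ledger.  Writes
results/03_dmr_calls.tsv and results/03_cascade_counts.tsv.
"""

import pandas as pd

from twinmeth import dmr, regions, simulate

from _cohort import RESULTS, build_cohort, methylomes_by_group

KEY = ["chrom", "start", "end", "name"]


def main():
    annotation, _, comparisons, truth = build_cohort()

    def comparison(label):
        def pooled(group):
            meths = methylomes_by_group(comparisons[label], group)
            return regions.pool_counts(
                [regions.score_feature_class(m, annotation, "promoters") for m in meths.values()]
            )

        return dmr.ComparisonSet(
            label, [f"{label}_T21"], [f"{label}_Normal"],
            dmr.test_promoters(pooled("T21"), pooled("Normal")),
        )

    sets = {label: comparison(label) for label in comparisons}
    for label, s in sets.items():
        print(f"{label}: {len(s.dmr_keys())} DMRs of {len(s.results)} tested promoters")

    cascade = dmr.run_cascade(
        sets["discordantT21"], [sets["normalTwins"], sets["concordantT21"]], sets["unrelated"]
    )
    counts = pd.DataFrame(cascade.counts).T.rename_axis("stage").reset_index()
    RESULTS.mkdir(exist_ok=True)
    counts.to_csv(RESULTS / "03_cascade_counts.tsv", sep="\t", index=False)
    sets["discordantT21"].results.to_csv(RESULTS / "03_dmr_calls.tsv", sep="\t", index=False)

    merged = sets["discordantT21"].results.merge(truth.entries, on=KEY)
    tp = int((~merged["is_null"] & merged["is_dmr"]).sum())
    fp = int((merged["is_null"] & merged["is_dmr"]).sum())
    n_planted = int((~merged["is_null"]).sum())
    final = set(map(tuple, cascade.final[KEY].itertuples(index=False)))
    planted = set(map(tuple, truth.planted()[KEY].itertuples(index=False)))

    print("\ncascade:")
    print(counts.to_string(index=False))
    print(f"\nsensitivity {tp}/{n_planted}, false positives {fp} "
          f"of {int(merged['is_null'].sum())} null promoters")
    print(f"final candidate list matches the planted trisomy-induced set: {final == planted}")


if __name__ == "__main__":
    main()
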