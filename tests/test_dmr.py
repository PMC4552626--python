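"""Fisher testing, SLIM q-values, DMR calling and the filtering cascade."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from twinmeth import dmr, regions, simulate
from twinmeth.errors import InsufficientDataError, KeySpaceMismatchError


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by enumerating all tables with the
    observed margins (independent of the gammaln-based implementation)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom) for x in range(lo, hi + 1)]
    obs = probs[a - lo]
    return float(sum(p for p in probs if p <= obs))


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert dmr.fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        # 70 tables share the 4+4 margins; enumeration gives 34/70
        assert dmr.fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(0.4857142857, rel=1e-8)

    def test_extreme_table_is_twice_the_point_mass(self):
        p = dmr.fisher_exact_2x2(0, 20, 20, 0)
        assert p < 1e-9
        assert p == pytest.approx(2.0 / math.comb(40, 20), rel=1e-9)

    def test_zero_margin_is_degenerate_p_one(self):
        assert dmr.fisher_exact_2x2(0, 0, 5, 5) == 1.0
        assert dmr.fisher_exact_2x2(0, 5, 0, 5) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dmr.fisher_exact_2x2(-1, 2, 3, 4)

    def test_random_tables_match_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 60, size=4)
            ours = dmr.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_moderate_margins_match_exact_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            r1, r2 = rng.integers(1, 31, size=2)
            a = int(rng.integers(0, r1 + 1))
            c = int(rng.integers(0, r2 + 1))
            assert dmr.fisher_exact_2x2(a, int(r1) - a, c, int(r2) - c) == pytest.approx(
                fisher_oracle(a, int(r1) - a, c, int(r2) - c), rel=1e-9
            )


class TestSlim:
    def test_p_zero_maps_to_q_zero(self):
        p = np.concatenate([[0.0], np.random.default_rng(0).uniform(size=99)])
        assert dmr.slim_qvalues(p)[0] == 0.0

    def test_single_pvalue_bounded_by_itself(self):
        assert dmr.slim_qvalues([0.04])[0] <= 0.04

    def test_uniform_null_pi0_near_one_and_close_to_bh(self):
        rng = np.random.default_rng(123)
        p = rng.uniform(size=1000)
        q, pi0 = dmr.slim_qvalues(p, return_pi0=True)
        assert 0.8 <= pi0 <= 1.0
        qbh = dmr.bh_qvalues(p)
        assert np.all(np.abs(q - qbh) <= 0.25 * qbh)

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        q = dmr.slim_qvalues(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_slim_q_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=200) ** 2
        q = dmr.slim_qvalues(p)
        assert np.all(q <= np.minimum(p * p.size, 1.0) + 1e-12)

    def test_signal_shrinks_pi0(self):
        rng = np.random.default_rng(42)
        p = np.concatenate([rng.beta(0.1, 10, 300), rng.uniform(size=700)])
        _, pi0 = dmr.slim_qvalues(p, return_pi0=True)
        assert pi0 < 0.9

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dmr.slim_qvalues([0.5, 1.5])
        with pytest.raises(ValueError):
            dmr.bh_qvalues([-0.1])


def region_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "meth_c", "total_c"])
    df["n_cpgs"] = 3
    df["percent"] = 100.0 * df["meth_c"] / df["total_c"]
    return df


class TestTestPromoters:
    def test_identical_tables_give_p_one_and_no_dmrs(self):
        t = region_table([("chr1", 0, 3000, "A", 50, 200), ("chr1", 5000, 8000, "B", 150, 200)])
        res = dmr.test_promoters(t, t.copy())
        assert (res["p"] == 1.0).all()
        assert res["is_dmr"].sum() == 0
        assert (res["meth_diff"] == 0).all()

    def test_planted_large_difference_is_called(self):
        case = region_table([("chr1", 0, 3000, "A", 600, 1200), ("chr1", 5000, 8000, "B", 120, 1200)])
        ctrl = region_table([("chr1", 0, 3000, "A", 120, 1200), ("chr1", 5000, 8000, "B", 118, 1200)])
        res = dmr.test_promoters(case, ctrl).set_index("name")
        assert bool(res.loc["A", "is_dmr"])
        assert res.loc["A", "meth_diff"] == pytest.approx(40.0)
        assert not bool(res.loc["B", "is_dmr"])

    def test_sign_convention_case_minus_control(self):
        case = region_table([("chr1", 0, 3000, "A", 100, 1000)])
        ctrl = region_table([("chr1", 0, 3000, "A", 500, 1000)])
        res = dmr.test_promoters(case, ctrl)
        assert res["meth_diff"].iloc[0] == pytest.approx(-40.0)

    def test_no_shared_regions_is_error(self):
        a = region_table([("chr1", 0, 3000, "A", 1, 30)])
        b = region_table([("chr2", 0, 3000, "B", 1, 30)])
        with pytest.raises(InsufficientDataError):
            dmr.test_promoters(a, b)


def results_frame(keys, dmr_flags=None, diffs=None):
    dmr_flags = dmr_flags if dmr_flags is not None else [True] * len(keys)
    diffs = diffs if diffs is not None else [30.0] * len(keys)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * len(keys),
            "start": [i * 10_000 for i, _ in enumerate(keys)],
            "end": [i * 10_000 + 3_000 for i, _ in enumerate(keys)],
            "name": keys,
            "meth_diff": diffs,
            "p": 1e-10,
            "q": 1e-10,
            "is_dmr": dmr_flags,
        }
    )


def comp(label, keys, flags=None, diffs=None):
    return dmr.ComparisonSet(label, ["case"], ["ctrl"], results_frame(keys, flags, diffs))


class TestCascade:
    UNIVERSE = ["A", "B", "C", "D"]

    def test_set_algebra(self):
        disc = comp("disc", self.UNIVERSE, [True, True, True, False])
        ctrl1 = comp("c1", self.UNIVERSE, [False, True, False, False])
        ctrl2 = comp("c2", self.UNIVERSE, [False] * 4)
        unrel = comp("u", self.UNIVERSE, [True, False, True, True])
        res = dmr.run_cascade(disc, [ctrl1, ctrl2], unrel)
        assert sorted(res.final["name"]) == ["A", "C"]
        assert res.counts["initial"]["n"] == 3
        assert res.counts["after_exclusion"]["n"] == 2

    def test_empty_controls_and_matching_unrelated_keep_everything(self):
        disc = comp("disc", self.UNIVERSE, [True, True, True, False])
        unrel = comp("u", self.UNIVERSE, [True, True, True, False])
        res = dmr.run_cascade(disc, [], unrel)
        pd.testing.assert_frame_equal(res.final, res.initial)

    def test_hyper_hypo_tallies_use_discordant_signs(self):
        disc = comp("disc", self.UNIVERSE, [True, True, True, True], [30, -30, 40, -40])
        unrel = comp("u", self.UNIVERSE)
        res = dmr.run_cascade(disc, [], unrel)
        assert res.counts["final"] == {"n": 4, "hyper": 2, "hypo": 2}

    def test_stages_are_nested_for_random_inputs(self):
        rng = np.random.default_rng(17)
        keys = [f"G{i}" for i in range(40)]
        for _ in range(10):
            flags = lambda: list(rng.uniform(size=40) < 0.4)
            res = dmr.run_cascade(
                comp("d", keys, flags()),
                [comp("c1", keys, flags()), comp("c2", keys, flags())],
                comp("u", keys, flags()),
            )
            f = set(res.final["name"])
            a = set(res.after_exclusion["name"])
            i = set(res.initial["name"])
            assert f <= a <= i
            for stage in res.counts.values():
                assert stage["hyper"] + stage["hypo"] == stage["n"]

    def test_key_space_mismatch_names_the_comparison(self):
        disc = comp("disc", self.UNIVERSE)
        other = comp("weird", ["A", "B"])
        with pytest.raises(KeySpaceMismatchError, match="weird"):
            dmr.run_cascade(disc, [other], comp("u", self.UNIVERSE))

    def test_case_control_overlap_rejected(self):
        with pytest.raises(ValueError):
            dmr.ComparisonSet("x", ["s1"], ["s1"], results_frame(["A"]))


class TestDirectionDiscordance:
    def test_all_same_sign_is_empty(self):
        t = pd.DataFrame({"gene": ["X"], "avsd_meth_diff": [30.0], "vsd_meth_diff": [40.0]})
        assert dmr.direction_discordance(t) == []

    def test_single_opposite_pair_found(self):
        t = pd.DataFrame({"gene": ["X"], "avsd_meth_diff": [30.0], "vsd_meth_diff": [-40.0]})
        assert dmr.direction_discordance(t) == ["X"]


def test_fixture_checksum_tampering_detected(monkeypatch):
    from twinmeth.errors import FixtureIntegrityError

    monkeypatch.setitem(dmr._FIXTURE_DIGESTS, "table2", ("table2_dmrs.tsv", "0" * 64))
    with pytest.raises(FixtureIntegrityError):
        dmr.load_published_dmr_table("table2")


def test_unknown_fixture_rejected():
    with pytest.raises(KeyError):
        dmr.load_published_dmr_table("table99")
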