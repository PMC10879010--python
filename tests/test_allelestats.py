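"""Allele-specific statistics tests: exact binomial imbalance testing with
BH control, the mechanism cascade, distance analyses, stability correlation
and fusion-transcript detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromoshard import allelestats as al
from chromoshard import workflows
from chromoshard.assembly import Segment, SegmentMap
from chromoshard.sv import Breakend, SvCall


def _counts(pairs, **extra):
    df = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(len(pairs))],
            "count_hap1": [a for a, _ in pairs],
            "count_hap2": [b for _, b in pairs],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestImbalanceTest:
    def test_vectorised_pvalues_match_scipy_binomtest(self):
        rng = np.random.default_rng(2)
        n = rng.integers(1, 300, size=60)
        k = rng.binomial(n, 0.5)
        for p0 in (0.5, 0.3):
            ours = al.exact_binom_pvalues(k, n, p0)
            ref = np.array(
                [stats.binomtest(int(ki), int(ni), p0).pvalue for ki, ni in zip(k, n)]
            )
            np.testing.assert_allclose(ours, ref, rtol=1e-9)

    def test_balanced_counts_p_one(self):
        out = al.allelic_imbalance_test(_counts([(10, 10)]))
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "differential"]
        assert out.loc[0, "direction"] == "none"

    def test_extreme_counts_hand_computed(self):
        # (0, 20) at p0=0.5: both tails collapse to 2 * 0.5**20
        out = al.allelic_imbalance_test(_counts([(0, 20)]))
        assert out.loc[0, "p_value"] == pytest.approx(2 * 0.5**20, rel=1e-6)
        assert out.loc[0, "differential"]
        assert out.loc[0, "direction"] == "weaker-on-derivative"

    def test_bh_adjustment_matches_hand_step_up(self):
        out = al.allelic_imbalance_test(
            _counts([(0, 15), (2, 20), (30, 42), (55, 45), (100, 102)])
        )
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        adj[order] = p[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p downwards
        for i in range(m - 2, -1, -1):
            adj[order[i]] = min(adj[order[i]], adj[order[i + 1]])
        np.testing.assert_allclose(out["q_value"], np.minimum(adj, 1), rtol=1e-12)

    def test_zero_total_skipped_not_dropped(self):
        out = al.allelic_imbalance_test(_counts([(0, 0), (5, 30)]))
        assert not out.loc[0, "tested"]
        assert np.isnan(out.loc[0, "p_value"])
        assert out.loc[1, "tested"]
        assert len(out) == 2

    def test_cn_adjusted_expected_proportion(self):
        # 2:1 copy number: 66 of 99 derivative reads is the null expectation
        out = al.allelic_imbalance_test(_counts([(66, 33)], expected_p=2 / 3))
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            al.allelic_imbalance_test(_counts([(-1, 5)]))


class TestMechanismCascade:
    features = pd.DataFrame(
        {
            "feature_id": ["dosage_peak", "disrupted_peak", "mystery_peak", "flat"],
            "start": [1_000, 50_000, 90_000, 130_000],
            "end": [2_000, 51_000, 91_000, 131_000],
            "differential": [True, True, True, False],
            "tested": True,
        }
    )
    cn = pd.DataFrame(
        {"start": [0], "end": [10_000], "cn_derivative": [1], "cn_wildtype": [2]}
    )
    svs = [
        SvCall(Breakend("chr1", 50_500, "left"), Breakend("chr1", 400_000, "right"),
               status="validated")
    ]

    def test_cascade_order(self):
        mech = al.classify_mechanism(self.features, self.cn, [], self.svs)
        out = dict(zip(mech["feature_id"], mech["mechanism"]))
        assert out == {
            "dosage_peak": "dosage",
            "disrupted_peak": "direct_disruption",
            "mystery_peak": "unexplained",
        }

    def test_loh_counts_as_dosage(self):
        mech = al.classify_mechanism(
            self.features, pd.DataFrame(columns=["start", "end", "cn_derivative",
                                                 "cn_wildtype"]),
            [(89_000, 92_000)], [],
        )
        out = dict(zip(mech["feature_id"], mech["mechanism"]))
        assert out["mystery_peak"] == "dosage"

    def test_categories_partition_differential_set(self):
        mech = al.classify_mechanism(self.features, self.cn, [], self.svs)
        assert len(mech) == int(self.features["differential"].sum())
        assert set(mech["mechanism"]) <= {"dosage", "direct_disruption", "unexplained"}

    def test_missing_cn_track_warns_and_skips_dosage(self):
        with pytest.warns(UserWarning, match="copy-number"):
            mech = al.classify_mechanism(self.features, None, [], self.svs)
        out = dict(zip(mech["feature_id"], mech["mechanism"]))
        assert out["dosage_peak"] == "unexplained"

    def test_planted_scenario_summary(self):
        sc = workflows.planted_mechanism_scenario(20, 5, 10, 65)
        feats = al.allelic_imbalance_test(sc["features"])
        mech = al.classify_mechanism(
            feats, sc["cn_segments"], sc["loh_tracts"], sc["svs"]
        )
        summ = al.differential_summary(feats, mech)
        assert summ["n_resolved"] == 100
        assert summ["n_differential"] == 35
        assert (summ["n_dosage"], summ["n_direct_disruption"],
                summ["n_unexplained"]) == (20, 5, 10)
        assert summ["pct_differential"] == pytest.approx(35.0)


class TestRankSum:
    def test_hand_enumerated_example(self):
        # {1,2,3} vs {4,5,6}: 1 extreme configuration each tail of C(6,3)=20
        assert al.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_exact_enumeration_small_groups(self):
        # brute force: two-sided p from the permutation distribution of the
        # rank sum over all C(n1+n2, n1) splits
        rng = np.random.default_rng(3)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            x = rng.permutation(100)[: n1 + n2].astype(float)
            a, b = x[:n1], x[n1:]
            obs = sum(stats.rankdata(x)[:n1])
            ranks = stats.rankdata(x)
            splits = list(itertools.combinations(range(n1 + n2), n1))
            sums = np.array([ranks[list(s)].sum() for s in splits])
            mu = sums.mean()
            p_exact = np.mean(np.abs(sums - mu) >= abs(obs - mu) - 1e-9)
            assert al.rank_sum_test(a, b) == pytest.approx(p_exact, abs=1e-12)

    def test_all_equal_gives_p_one(self):
        assert al.rank_sum_test([5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_empty_group_nan(self):
        assert np.isnan(al.rank_sum_test([], [1.0]))


class TestNearestBreakend:
    svs = [
        SvCall(Breakend("chr1", 90, "left"), Breakend("chr1", 150, "right")),
    ]

    def test_interval_arithmetic(self):
        feats = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "start": [95, 100, 140],
                "end": [105, 110, 160],
            }
        )
        d = al.nearest_breakend_distances(feats, self.svs)
        # breakend 90 is 5 bp left of [95,105); 10 bp left of [100,110);
        # breakend 150 falls inside [140,160)
        assert d.tolist() == [5, 10, 0]

    def test_no_svs_raises(self):
        feats = pd.DataFrame({"feature_id": ["a"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            al.nearest_breakend_distances(feats, [])

    def test_planted_enrichment_recovered(self):
        # differential features planted within 5 kb of breakends, the rest
        # uniform: group medians must order differential < non-differential
        rng = np.random.default_rng(8)
        bk_pos = rng.integers(50_000, 950_000, size=30)
        svs = [
            SvCall(Breakend("chr1", int(p), "left"),
                   Breakend("chr1", int(p) + 2_000_000, "right"))
            for p in bk_pos
        ]
        rows = []
        for i in range(60):
            p = int(rng.choice(bk_pos) + rng.integers(-5_000, 5_000))
            rows.append((f"d{i}", max(p, 0), max(p, 0) + 500, "weaker-on-derivative"))
        for i in range(60):
            p = int(rng.integers(0, 1_000_000))
            rows.append((f"n{i}", p, p + 500, "none"))
        feats = pd.DataFrame(rows, columns=["feature_id", "start", "end", "direction"])
        res = al.nearest_breakend_analysis(feats, svs, threshold_bp=10_000)
        g = res["groups"]
        assert g["weaker-on-derivative"]["median"] < g["none"]["median"]
        assert g["weaker-on-derivative"]["frac_within"] > g["none"]["frac_within"]
        assert res["pairwise_p"][("none", "weaker-on-derivative")] < 0.05


class TestSvSummary:
    def test_size_class_fractions(self):
        svs = [
            SvCall(Breakend("chr1", 1_000, "left"), Breakend("chr1", 1_500, "right"),
                   haplotype="hap2"),
            SvCall(Breakend("chr1", 0, "left"), Breakend("chr1", 2_000_000, "right"),
                   haplotype="hap2"),
        ]
        out = al.sv_summary(svs).set_index("haplotype")
        assert out.loc["hap2", "frac_over_1mb"] == 0.5
        assert out.loc["hap2", "frac_under_1kb"] == 0.5

    def test_empty_haplotype_absent(self):
        out = al.sv_summary([])
        assert out.empty

    def test_truth_junction_count_conserved(self, study):
        counts = al.sv_summary(study.truth.breakends).set_index("haplotype")
        assert counts.loc["hap1", "n"] == len(study.truth.breakends)


class TestCorrelation:
    def test_identical_tables_r_one(self):
        t = _counts([(10, 5), (3, 2), (40, 44), (7, 7)])
        res = al.correlate_shared_features(t, t)
        assert res["r"] == pytest.approx(1.0)
        assert res["n_shared"] == 4

    def test_perfect_anti_order_r_minus_one(self):
        # counts 2**k - 1 make log2(count+1) exactly linear in k
        vals = [2**k - 1 for k in range(1, 7)]
        a = pd.DataFrame({"feature_id": list("abcdef"), "count": vals})
        b = pd.DataFrame({"feature_id": list("abcdef"), "count": vals[::-1]})
        res = al.correlate_shared_features(a, b)
        assert res["r"] == pytest.approx(-1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(12)
        hits = 0
        runs = 60
        for _ in range(runs):
            ids = [f"f{i}" for i in range(1_000)]
            a = pd.DataFrame({"feature_id": ids, "count": rng.poisson(50, 1_000)})
            b = pd.DataFrame({"feature_id": ids, "count": rng.poisson(50, 1_000)})
            if abs(al.correlate_shared_features(a, b)["r"]) < 0.1:
                hits += 1
        assert hits / runs >= 0.95

    def test_gained_and_lost_sets(self):
        a = pd.DataFrame({"feature_id": ["x", "y", "z"], "count": [0, 5, 3]})
        b = pd.DataFrame({"feature_id": ["x", "y", "z"], "count": [9, 0, 3]})
        res = al.correlate_shared_features(a, b)
        assert res["gained"] == ["x"] and res["lost"] == ["y"]

    def test_too_few_shared_raises(self):
        a = pd.DataFrame({"feature_id": ["x", "y"], "count": [1, 2]})
        with pytest.raises(ValueError):
            al.correlate_shared_features(a, a)


class TestFusionTranscripts:
    smap = SegmentMap(
        "der", 30_000, "chr1",
        [
            Segment(0, 10_000, "chr1", 100_000, 110_000, "+"),
            Segment(10_000, 20_000, "chr1", 500_000, 510_000, "+"),
            Segment(20_000, 30_000, "chr1", 200_000, 210_000, "-"),
        ],
    )

    def test_colinear_transcript_no_call(self):
        calls, bad = al.detect_fusion_transcripts(
            [("t1", [(1_000, 1_500), (3_000, 3_400), (8_000, 8_300)])],
            self.smap, min_jump=50_000,
        )
        assert calls.empty and bad == []

    def test_distant_junction_called(self):
        calls, _ = al.detect_fusion_transcripts(
            [("t2", [(8_000, 9_000), (11_000, 12_000)])], self.smap,
            min_jump=50_000,
        )
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["jump"] > 300_000 and not row["orientation_change"]

    def test_inversion_junction_flags_orientation(self):
        calls, _ = al.detect_fusion_transcripts(
            [("t3", [(18_000, 19_000), (21_000, 22_000)])], self.smap,
            min_jump=10_000_000,
        )
        assert len(calls) == 1
        assert bool(calls.iloc[0]["orientation_change"])

    def test_exon_in_gap_unresolvable(self):
        gappy = SegmentMap(
            "der", 30_000, "chr1",
            [Segment(0, 10_000, "chr1", 100_000, 110_000, "+")],
        )
        calls, bad = al.detect_fusion_transcripts(
            [("t4", [(1_000, 1_100), (15_000, 15_100)])], gappy,
        )
        assert bad == ["t4"] and calls.empty

    def test_truth_built_junction_from_simulator(self, small_genome):
        from chromoshard import simulate as sim

        der, truth = sim.apply_chromothripsis(
            small_genome, "chr1", "hap1", (10_000, 90_000), 8, 0.0, seed=43
        )
        smap = SegmentMap("der", len(der), "chr1")
        cursor = 0
        for s, e, o in truth.fragments:
            smap.segments.append(Segment(cursor, cursor + e - s, "chr1", s, e, o))
            cursor += e - s
        # exon chain straddling the first real junction
        first_junction = None
        offs = np.cumsum([0] + [e - s for s, e, _ in truth.fragments])
        for i, ((s1, e1, o1), (s2, e2, o2)) in enumerate(
            zip(truth.fragments, truth.fragments[1:])
        ):
            if o1 == o2 == "+" and e1 == s2:
                continue
            first_junction = int(offs[i + 1])
            break
        exons = [(first_junction - 900, first_junction - 200),
                 (first_junction + 200, first_junction + 900)]
        calls, bad = al.detect_fusion_transcripts(
            [("t", exons)], smap, min_jump=5_000
        )
        assert bad == []
        assert len(calls) == 1


class TestGeneToPeakClass:
    peaks = pd.DataFrame(
        {
            "feature_id": ["p_act", "p_inact"],
            "start": [10_000, 500_000],
            "end": [11_000, 501_000],
            "mark": ["H3K27ac", "H3K27me3"],
            "differential": [True, True],
        }
    )

    def test_adjacent_gene_distance_zero(self):
        genes = pd.DataFrame(
            {"feature_id": ["g"], "start": [11_000], "end": [12_000],
             "direction": ["stronger-on-derivative"]}
        )
        res = al.gene_to_peak_class_distance(genes, self.peaks)
        assert res["active"]["medians"]["stronger-on-derivative"] == 0.0

    def test_equidistant_groups_p_one(self):
        genes = pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3", "g4"],
                "start": [20_000] * 4,
                "end": [21_000] * 4,
                "direction": ["stronger-on-derivative"] * 2 + ["none"] * 2,
            }
        )
        res = al.gene_to_peak_class_distance(genes, self.peaks)
        p = res["active"]["pairwise_p"][("none", "stronger-on-derivative")]
        assert p == 1.0

    def test_planted_coupling_recovered(self):
        rng = np.random.default_rng(17)
        peak_pos = rng.integers(0, 1_000_000, size=25)
        peaks = pd.DataFrame(
            {
                "feature_id": [f"p{i}" for i in range(25)],
                "start": peak_pos,
                "end": peak_pos + 800,
                "mark": "H3K27ac",
                "differential": True,
            }
        )
        rows = []
        for i in range(40):  # upregulated genes planted near active peaks
            p = int(rng.choice(peak_pos) + rng.integers(-3_000, 3_000))
            rows.append((f"up{i}", max(p, 0), max(p, 0) + 1_000,
                         "stronger-on-derivative"))
        for i in range(40):
            p = int(rng.integers(0, 1_000_000))
            rows.append((f"bg{i}", p, p + 1_000, "none"))
        genes = pd.DataFrame(rows, columns=["feature_id", "start", "end", "direction"])
        res = al.gene_to_peak_class_distance(genes, peaks)
        med = res["active"]["medians"]
        assert med["stronger-on-derivative"] < med["none"]

    def test_empty_class_skipped(self):
        genes = pd.DataFrame(
            {"feature_id": ["g"], "start": [0], "end": [100], "direction": ["none"]}
        )
        only_active = self.peaks[self.peaks["mark"] == "H3K27ac"]
        res = al.gene_to_peak_class_distance(genes, only_active)
        assert "inactive" not in res
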