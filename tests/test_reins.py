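"""TFR/RRT core: catalog building, overlap counting, ratio algebra,
significance and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtf.formats import GenomicInterval
from methtf.reins import (
    TFBindingCatalog,
    build_tf_catalog,
    compute_rrt,
    compute_tfr,
    merge_intervals,
    multi_signature_tfr,
    overlap_counts,
    rank_tfs,
    tf_significance,
    tfr_report,
)


def _catalog(spec):
    """spec: {tf: [(chrom, start, end), ...]} (merged on construction)."""
    return TFBindingCatalog(
        {tf: merge_intervals([GenomicInterval(c, s, e) for c, s, e in ivs])
         for tf, ivs in spec.items()}
    )


def _random_instance(rng, n_cpgs=200, n_tfs=5, n_intervals=30, span=5000):
    positions = [
        (f"chr{rng.integers(1, 3)}", int(rng.integers(0, span)))
        for _ in range(n_cpgs)
    ]
    spec = {}
    for t in range(n_tfs):
        ivs = []
        for _ in range(int(rng.integers(1, n_intervals + 1))):
            s = int(rng.integers(0, span - 1))
            e = s + int(rng.integers(1, 100))
            ivs.append((f"chr{rng.integers(1, 3)}", s, e))
        spec[f"TF{t}"] = ivs
    return positions, spec


def _brute_force_counts(positions, spec):
    counts = {}
    for tf, ivs in spec.items():
        k = 0
        for chrom, pos in positions:
            if any(c == chrom and s <= pos < e for c, s, e in ivs):
                k += 1
        counts[tf] = k
    return counts


class TestCatalog:
    def test_union_merge_overlapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        cat = build_tf_catalog([("A", "cellX", p)])
        assert [(iv.start, iv.end) for iv in cat.intervals["A"]] == [(10, 30)]

    def test_disjoint_peaks_from_two_cell_types_retained(self, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        p1.write_text("chr1\t10\t20\n")
        p2.write_text("chr1\t100\t200\n")
        cat = build_tf_catalog([("A", "cellX", p1), ("A", "cellY", p2)])
        assert len(cat.intervals["A"]) == 2
        assert set(cat.provenance["A"]) == {(str(p1), "cellX"), (str(p2), "cellY")}

    def test_adjacent_intervals_coalesced(self):
        merged = merge_intervals(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)]
        )
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20)]

    def test_merged_counts_equal_unmerged_with_dedup(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            positions, spec = _random_instance(rng, n_cpgs=80, n_tfs=3)
            cat = _catalog(spec)
            assert overlap_counts(positions, cat) == _brute_force_counts(positions, spec)


class TestOverlapCounts:
    def test_point_inside(self):
        cat = _catalog({"A": [("chr1", 10, 20)]})
        assert overlap_counts([("chr1", 15)], cat) == {"A": 1}

    def test_half_open_end_excluded(self):
        cat = _catalog({"A": [("chr1", 10, 20)]})
        assert overlap_counts([("chr1", 20)], cat) == {"A": 0}

    def test_empty_inputs_give_zero(self):
        cat = _catalog({"A": [("chr1", 10, 20)]})
        assert overlap_counts([], cat) == {"A": 0}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            positions, spec = _random_instance(
                rng,
                n_cpgs=int(rng.integers(1, 500)),
                n_tfs=int(rng.integers(1, 10)),
                n_intervals=int(rng.integers(1, 40)),
            )
            cat = _catalog(spec)
            assert overlap_counts(positions, cat) == _brute_force_counts(positions, spec)


class TestTFRAlgebra:
    @pytest.mark.parametrize(
        "n_overlap,n_total,expected",
        [(2, 4, 50.0), (0, 478, 0.0), (478, 478, 100.0)],
    )
    def test_tfr_direct_formula(self, n_overlap, n_total, expected):
        assert compute_tfr(n_overlap, n_total) == expected

    def test_empty_class_is_hard_error(self):
        with pytest.raises(ValueError, match="empty CpG class"):
            compute_tfr(0, 0)

    def test_rrt_symmetry_point(self):
        rrt, l2, pseudo = compute_rrt(2, 4, 3, 6)  # both TFR = 50
        assert rrt == pytest.approx(1.0) and l2 == pytest.approx(0.0)
        assert not pseudo

    def test_rrt_direct_evaluation(self):
        rrt, l2, pseudo = compute_rrt(2, 4, 1, 5)
        assert rrt == pytest.approx(2.5)
        assert l2 == pytest.approx(np.log2(2.5), rel=1e-12)
        assert not pseudo

    def test_pseudocount_on_zero_overlap(self):
        rrt, l2, pseudo = compute_rrt(0, 10, 5, 10)
        assert pseudo
        assert rrt == pytest.approx((0.5 / 10) / (5.5 / 10))
        assert np.isfinite(l2)

    def test_hyper_biased_tf_has_negative_log2rrt(self):
        # sign contract: a TF whose sites are predominantly hyper-methylated
        # scores below zero
        _, l2, _ = compute_rrt(5, 100, 60, 100)
        assert l2 < 0

    def test_scale_invariance(self):
        r1 = compute_rrt(3, 10, 4, 20)
        r2 = compute_rrt(6, 20, 8, 40)
        assert r1[0] == pytest.approx(r2[0]) and r1[1] == pytest.approx(r2[1])


class TestSignificance:
    def test_fisher_against_exact_enumeration(self):
        res = tf_significance({"A": (3, 4, 1, 4)})
        # table [[3,1],[1,3]]: two-sided p = 34/70
        assert res.at["A", "fisher_p"] == pytest.approx(34 / 70, rel=1e-9)

    def test_identical_rows_give_p_one(self):
        res = tf_significance({"A": (5, 12, 5, 12)})
        assert res.at["A", "fisher_p"] == pytest.approx(1.0)

    def test_bh_dominates_raw(self):
        rng = np.random.default_rng(3)
        counts = {
            f"T{i}": (int(rng.integers(0, 10)), 20, int(rng.integers(0, 10)), 20)
            for i in range(15)
        }
        res = tf_significance(counts)
        assert np.all(res["adj_p"] >= res["fisher_p"] - 1e-12)


class TestRanking:
    def _report(self, rows):
        df = pd.DataFrame(rows).set_index("tf_label")
        return df

    def test_descending_log2rrt(self):
        rep = self._report(
            [{"tf_label": t, "log2_rrt": v, "fisher_p": 0.5}
             for t, v in [("a", 1.0), ("b", 0.0), ("c", -3.0)]]
        )
        ranked = rank_tfs(rep)
        assert list(ranked.index) == ["a", "b", "c"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_tie_break_by_smaller_p(self):
        rep = self._report(
            [{"tf_label": "x", "log2_rrt": 1.0, "fisher_p": 0.2},
             {"tf_label": "y", "log2_rrt": 1.0, "fisher_p": 0.01}]
        )
        assert list(rank_tfs(rep).index) == ["y", "x"]

    def test_swap_antisymmetry_reverses_ranking(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            positions, spec = _random_instance(rng, n_cpgs=300, n_tfs=6)
            hypo, hyper = positions[:150], positions[150:]
            cat = _catalog(spec)
            fwd = tfr_report(hypo, hyper, cat)
            rev = tfr_report(hyper, hypo, cat)
            both = fwd.join(rev, rsuffix="_rev")
            clean = ~(both["pseudocount_used"] | both["pseudocount_used_rev"])
            assert np.allclose(
                both.loc[clean, "log2_rrt"], -both.loc[clean, "log2_rrt_rev"],
                atol=1e-12,
            )
            gaps = np.diff(np.sort(fwd["log2_rrt"]))
            if clean.all() and len(gaps) and gaps.min() > 1e-9:
                assert list(rev.sort_values("rank").index) == list(
                    fwd.sort_values("rank", ascending=False).index
                )


class TestReport:
    def test_report_tfr_matches_brute_force_recomputation(self, tiny_data, tiny_diff, tiny_catalog):
        mf = tiny_data.manifest
        hypo_ids = tiny_diff.index[tiny_diff["class"] == "hypo"]
        hyper_ids = tiny_diff.index[tiny_diff["class"] == "hyper"]
        hypo = mf.positions(hypo_ids)
        hyper = mf.positions(hyper_ids)
        rep = tfr_report(hypo, hyper, tiny_catalog)
        for tf in rep.index:
            ivs = [(iv.chrom, iv.start, iv.end) for iv in tiny_catalog.intervals[tf]]
            bf_hypo = _brute_force_counts(hypo, {tf: ivs})[tf]
            bf_hyper = _brute_force_counts(hyper, {tf: ivs})[tf]
            assert rep.at[tf, "n_hypo_overlap"] == bf_hypo
            assert rep.at[tf, "tfr_hypo"] == pytest.approx(100 * bf_hypo / len(hypo))
            assert rep.at[tf, "tfr_hyper"] == pytest.approx(100 * bf_hyper / len(hyper))

    def test_empty_class_rejected(self, tiny_catalog):
        with pytest.raises(ValueError, match="empty CpG class"):
            tfr_report([], [("chr1", 5)], tiny_catalog)


class TestMultiSignature:
    def test_single_signature_reduces_to_tfr(self):
        cat = _catalog({"A": [("chr1", 0, 100)]})
        hypo = [("chr1", 10), ("chr1", 500)]
        hyper = [("chr1", 20), ("chr1", 30), ("chr1", 600)]
        res = multi_signature_tfr([("sig1", hypo, hyper)], cat, tf="A")
        assert res.loc[("sig1", "A"), "tfr_hypo"] == pytest.approx(50.0)
        assert res.loc[("sig1", "A"), "tfr_hyper"] == pytest.approx(200 / 3)

    def test_shared_cpg_sets_give_identical_rows(self):
        cat = _catalog({"A": [("chr1", 0, 100)]})
        hypo = [("chr1", 10)] * 3
        hyper = [("chr1", 200)] * 3
        res = multi_signature_tfr(
            [("s1", hypo, hyper), ("s2", hypo, hyper)], cat, tf="A"
        )
        assert res.loc[("s1", "A")].equals(res.loc[("s2", "A")])

    def test_empty_class_flagged_na(self):
        cat = _catalog({"A": [("chr1", 0, 100)]})
        res = multi_signature_tfr([("s1", [], [("chr1", 5)])], cat, tf="A")
        assert bool(res.loc[("s1", "A"), "empty_class"])
        assert np.isnan(res.loc[("s1", "A"), "tfr_hypo"])

    def test_planted_signature_specific_enrichment(self):
        rng = np.random.default_rng(31)
        # TF covers the hypo CpGs of signature 1 only
        sig1_hypo = [("chr1", int(p)) for p in rng.integers(0, 1000, 100)]
        tf_ivs = [("chr1", p - 2, p + 3) for _, p in sig1_hypo[:60]]
        far = [("chr2", int(p)) for p in rng.integers(0, 1000, 100)]
        cat = _catalog({"A": tf_ivs})
        res = multi_signature_tfr(
            [("s1", sig1_hypo, far), ("s2", far, far)], cat, tf="A"
        )
        assert res.loc[("s1", "A"), "tfr_hypo"] > res.loc[("s1", "A"), "tfr_hyper"]
        assert res.loc[("s2", "A"), "tfr_hypo"] == pytest.approx(
            res.loc[("s2", "A"), "tfr_hyper"]
        )
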