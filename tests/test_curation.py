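"""Driver nomination, CNA filtering/binarization, aneuploidy and arm calls."""

import numpy as np
import pandas as pd
import pytest

from panhallmark import curation as cur
from panhallmark.io_formats import (ArmCallMatrix, GisticResult, MutationTable,
                                    SegmentTable)
from oracles import driver_oracle, merge_overlaps_oracle


class TestClassifyVariant:
    @pytest.mark.parametrize("term,expected", [
        ("Silent", "synonymous"),
        ("Intron", "synonymous"),
        ("3'UTR", "synonymous"),
        ("Missense_Mutation", "nonsynonymous"),
        ("Nonsense_Mutation", "nonsynonymous"),
        ("Weird_New_Term", "nonsynonymous"),
    ])
    def test_rule(self, term, expected):
        assert cur.classify_variant(term) == expected

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            cur.classify_variant("")


class TestOutlierThreshold:
    def test_interpolated_quantiles(self):
        assert cur.outlier_threshold([1, 2, 3, 4, 100]) == 10.0

    def test_equal_counts_give_the_count(self):
        assert cur.outlier_threshold([7, 7, 7, 7]) == 7.0

    def test_single_count(self):
        assert cur.outlier_threshold([5]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cur.outlier_threshold([])

    def test_q3_term_monotone_under_larger_maximum(self, rng):
        # replacing the maximum by a larger value never lowers Q3
        from panhallmark._stats import quantile
        for _ in range(25):
            a = rng.integers(0, 50, size=rng.integers(3, 20)).astype(float)
            b = a.copy()
            b[np.argmax(b)] = b.max() + rng.integers(1, 10)
            assert quantile(b, 0.75) >= quantile(a, 0.75)


def _random_mutation_rows(rng, n_samples=30, n_genes=8):
    genes = [f"GENE{k}" for k in range(n_genes)]
    classes = ["Missense_Mutation", "Silent", "Nonsense_Mutation", "Intron"]
    rows = []
    for _ in range(rng.integers(20, 120)):
        rows.append(dict(sample=f"S{rng.integers(n_samples)}",
                         gene=genes[rng.integers(n_genes)],
                         variant_classification=classes[rng.integers(4)],
                         is_hotspot=bool(rng.random() < 0.4)))
    groups = {f"S{i}": ("G1" if i < n_samples // 2 else "G2")
              for i in range(n_samples)}
    return rows, groups, genes


class TestDriverSelection:
    def test_minimum_count_rule(self):
        rows = [dict(sample=f"S{i}", gene="TP53",
                     variant_classification="Missense_Mutation",
                     is_hotspot=False) for i in range(2)]
        muts = MutationTable(pd.DataFrame(rows))
        cat = cur.select_tumor_suppressors(
            muts, {f"S{i}": "T1" for i in range(2)}, ["TP53"])
        assert cat.combos.empty
        assert "fewer than 3" in cat.table.iloc[0]["reason"]

    def test_silent_fraction_rule(self):
        rows = ([dict(sample=f"S{i}", gene="X",
                      variant_classification="Missense_Mutation",
                      is_hotspot=False) for i in range(5)]
                + [dict(sample=f"S{i + 5}", gene="X",
                        variant_classification="Silent",
                        is_hotspot=False) for i in range(5)])
        # add a second gene so the outlier threshold can be exceeded
        rows += [dict(sample="S0", gene="Y",
                      variant_classification="Missense_Mutation",
                      is_hotspot=False)]
        muts = MutationTable(pd.DataFrame(rows))
        groups = {f"S{i}": "T1" for i in range(10)}
        cat = cur.select_tumor_suppressors(muts, groups, ["X", "Y"])
        x_row = cat.table[cat.table["gene"] == "X"].iloc[0]
        assert not x_row["passed"]
        assert "silent" in x_row["reason"]

    def test_strictly_above_threshold_boundary(self):
        # hotspot count 3 with group threshold exactly 3 must fail
        rows = [dict(sample=f"S{i}", gene="G0",
                     variant_classification="Missense_Mutation",
                     is_hotspot=True) for i in range(3)]
        rows += [dict(sample=f"S{i}", gene=g,
                      variant_classification="Missense_Mutation",
                      is_hotspot=True)
                 for g in ("G1", "G2", "G3") for i in range(3)]
        muts = MutationTable(pd.DataFrame(rows))
        groups = {f"S{i}": "T1" for i in range(3)}
        cat = cur.select_oncogenes(muts, groups, ["G0", "G1", "G2", "G3"])
        # all four genes have count 3 = threshold (IQR 0) -> none pass
        assert cat.combos.empty

    @pytest.mark.parametrize("selector,silent_rule,hotspot_only", [
        (cur.select_tumor_suppressors, True, False),
        (cur.select_oncogenes, False, True),
    ])
    def test_matches_exhaustive_oracle(self, selector, silent_rule,
                                       hotspot_only):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rows, groups, genes = _random_mutation_rows(rng)
            muts = MutationTable(pd.DataFrame(rows))
            cat = selector(muts, groups, genes)
            got = {(r["gene"], r["group"])
                   for _, r in cat.table.iterrows() if r["passed"]}
            want = driver_oracle(rows, groups, genes, silent_rule,
                                 hotspot_only)
            assert got == want

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        rows, groups, genes = _random_mutation_rows(rng)
        muts1 = MutationTable(pd.DataFrame(rows))
        muts2 = MutationTable(pd.DataFrame(rows[::-1]).reset_index(drop=True))
        c1 = cur.select_tumor_suppressors(muts1, groups, genes)
        c2 = cur.select_tumor_suppressors(muts2, groups, genes)
        pd.testing.assert_frame_equal(c1.combos, c2.combos)

    def test_subtype_and_type_passes_unioned(self):
        # gene passes only at subtype level; combo still reports its tumor type
        rows = [dict(sample=f"S{i}", gene="DRV",
                     variant_classification="Missense_Mutation",
                     is_hotspot=False) for i in range(4)]
        rows += [dict(sample=f"N{i}", gene=f"BG{i}",
                      variant_classification="Missense_Mutation",
                      is_hotspot=False) for i in range(8)]
        types = {**{f"S{i}": "T1" for i in range(4)},
                 **{f"N{i}": "T1" for i in range(8)}}
        subtypes = {**{f"S{i}": "T1_a" for i in range(4)},
                    **{f"N{i}": "T1_b" for i in range(8)}}
        genes = ["DRV"] + [f"BG{i}" for i in range(8)]
        cat = cur.select_tumor_suppressors(MutationTable(pd.DataFrame(rows)),
                                           types, genes, subtypes)
        assert ("DRV", "T1") in set(map(tuple, cat.combos.values))


class TestFocalPeaks:
    def _gistic(self, peaks):
        fp = pd.DataFrame(peaks, columns=["peak_id", "chromosome", "start",
                                          "end", "direction", "q_value"])
        fp["gene"] = np.nan
        return GisticResult(fp, pd.DataFrame(columns=["arm", "direction",
                                                      "q_value"]))

    def test_q_and_width_filters(self):
        g = self._gistic([("p1", "chr1", 0, 300_000, "amp", 0.02),
                          ("p2", "chr1", 0, 300_000, "amp", 0.005),
                          ("p3", "chr1", 0, 100_000, "amp", 0.005)])
        out = cur.filter_focal_peaks(g)
        assert len(out) == 1  # p1 fails q, p3 fails width

    def test_single_base_overlap_merges(self):
        g = self._gistic([("p1", "chr1", 0, 300_000, "del", 1e-3),
                          ("p2", "chr1", 300_000, 600_000, "del", 1e-3)])
        out = cur.filter_focal_peaks(g)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 600_000

    def test_transitive_merge_matches_oracle(self, rng):
        for _ in range(10):
            peaks = []
            for i in range(6):
                s = int(rng.integers(0, 3_000_000))
                peaks.append((f"p{i}", "chr2", s,
                              s + int(rng.integers(250_000, 1_500_000)),
                              "amp", 1e-4))
            out = cur.filter_focal_peaks(self._gistic(peaks))
            got = sorted(zip(out["start"], out["end"]))
            want = merge_overlaps_oracle([(p[2], p[3]) for p in peaks])
            assert got == want

    def test_gene_assignment_nearest(self):
        g = self._gistic([("p1", "chr1", 1000, 300_000, "amp", 1e-4)])
        gm = pd.DataFrame(dict(chromosome=["chr1", "chr1"],
                               start=[400_000, 2_000_000],
                               end=[450_000, 2_100_000],
                               gene=["NEAR", "FAR"]))
        out = cur.filter_focal_peaks(g, gene_map=gm)
        assert out.iloc[0]["alteration"] == "NEAR_Amp"

    def test_unmapped_peak_keeps_interval_id(self):
        g = self._gistic([("p1", "chr9", 0, 300_000, "del", 1e-4)])
        out = cur.filter_focal_peaks(g, gene_map=None)
        assert out.iloc[0]["alteration"].startswith("chr9:")


class TestArmBinarization:
    def _calls(self):
        return ArmCallMatrix(pd.DataFrame(
            [[1, -1, 0], [0, np.nan, 1], [-1, 0, 0]],
            index=["A", "B", "C"], columns=["1p", "1q", "8q"]))

    def test_expansion_rules(self):
        m = cur.binarize_arm_calls(self._calls())
        assert m.values.loc["A", "1p_Amp"] == 1
        assert m.values.loc["A", "1p_Del"] == 0
        assert m.values.loc["A", "1q_Del"] == 1
        assert m.values.loc["A", "8q_Amp"] == 0
        assert np.isnan(m.values.loc["B", "1q_Amp"])
        assert np.isnan(m.values.loc["B", "1q_Del"])

    def test_conservation_of_nonzero_calls(self):
        calls = self._calls()
        m = cur.binarize_arm_calls(calls)
        total_binary = np.nansum(m.values.values)
        nonzero = np.nansum(np.abs(calls.calls.values))
        assert total_binary == nonzero

    def test_aneuploidy_profile_and_wgd(self):
        m = cur.binarize_arm_calls(self._calls())
        profiles = {p.sample: p for p in cur.aneuploidy_profile(
            m, ploidy={"A": 3.0, "B": 2.9, "C": 2.0})}
        assert profiles["A"].score == 2 and not profiles["A"].high
        assert profiles["A"].wgd is True
        assert profiles["B"].wgd is False

    def test_high_aneuploidy_boundary(self):
        cols = {f"{c}q_Amp" if i % 2 else f"{c}p_Amp": [1.0]
                for i, c in enumerate(range(1, 17))}
        # 16 altered arms -> high; build a minimal matrix by hand
        values = pd.DataFrame(cols, index=["S"])
        meta = pd.DataFrame({"alteration_class": "arm", "direction": "amp",
                             "qualifying_types": [("T",)] * len(cols)},
                            index=values.columns)
        m = cur.AlterationMatrix(values, meta)
        (p,) = cur.aneuploidy_profile(m)
        assert p.score == 16 and p.high

    def test_amp_and_del_both_set_rejected(self):
        values = pd.DataFrame({"1p_Amp": [1.0], "1p_Del": [1.0]}, index=["S"])
        meta = pd.DataFrame({"alteration_class": "arm",
                             "direction": ["amp", "del"],
                             "qualifying_types": [("T",), ("T",)]},
                            index=values.columns)
        with pytest.raises(ValueError, match="amplified AND deleted"):
            cur.AlterationMatrix(values, meta)


class TestArmFractionCalls:
    ARMS = {"1p": ("1", 0, 1000), "1q": ("1", 1000, 3000),
            "2p": ("2", 0, 1000)}

    def _segs(self, rows):
        return SegmentTable(pd.DataFrame(rows, columns=["sample",
                                                        "chromosome", "start",
                                                        "end", "log2_ratio"]))

    def test_sixty_percent_amplified(self):
        segs = self._segs([("A", "1", 0, 600, 0.2), ("A", "1", 600, 1000, 0.0)])
        calls = cur.arm_fraction_calls(segs, self.ARMS)
        assert calls.calls.loc["A", "1p"] == 1

    def test_forty_percent_is_neutral(self):
        segs = self._segs([("A", "1", 0, 400, 0.2), ("A", "1", 400, 1000, 0.0)])
        calls = cur.arm_fraction_calls(segs, self.ARMS)
        assert calls.calls.loc["A", "1p"] == 0

    def test_uncovered_arm_missing(self):
        segs = self._segs([("A", "1", 0, 600, 0.2)])
        calls = cur.arm_fraction_calls(segs, self.ARMS)
        assert np.isnan(calls.calls.loc["A", "2p"])

    def test_matches_base_counting_oracle(self, rng):
        for _ in range(10):
            rows = []
            pos = 0
            for _ in range(6):
                w = int(rng.integers(100, 800))
                rows.append(("A", "1", pos, pos + w,
                             float(rng.choice([-0.3, -0.05, 0.0, 0.05, 0.3]))))
                pos += w
            segs = self._segs(rows)
            calls = cur.arm_fraction_calls(segs, self.ARMS)
            for arm, (chrom, a0, a1) in self.ARMS.items():
                amp = dele = 0
                for (_, c, s, e, lr) in rows:
                    if c != chrom:
                        continue
                    ov = max(0, min(e, a1) - max(s, a0))
                    if lr > 0.1:
                        amp += ov
                    elif lr < -0.1:
                        dele += ov
                covered = sum(max(0, min(e, a1) - max(s, a0))
                              for (_, c, s, e, _) in rows if c == chrom)
                got = calls.calls.loc["A", arm]
                if covered == 0:
                    assert np.isnan(got)
                elif amp / (a1 - a0) > 0.5:
                    assert got == 1
                elif dele / (a1 - a0) > 0.5:
                    assert got == -1
                else:
                    assert got == 0


class TestSubtypeCnaAndCooccurrence:
    def _arm_matrix(self, rows, samples):
        values = pd.DataFrame(rows, index=samples,
                              columns=["1p_Amp", "1p_Del"])
        meta = pd.DataFrame({"alteration_class": "arm",
                             "direction": ["amp", "del"],
                             "qualifying_types": [("T",), ("T",)]},
                            index=values.columns)
        return cur.AlterationMatrix(values.astype(float), meta)

    def test_signed_percentage_rules(self):
        m = self._arm_matrix([[0, 1]] * 6 + [[1, 0]] * 1 + [[0, 0]] * 3,
                             [f"s{i}" for i in range(10)])
        labels = {f"s{i}": "sub1" for i in range(10)}
        out = cur.subtype_cna_matrix(m, labels)
        assert out.loc["1p", "sub1"] == -60.0

    def test_tie_resolves_to_amplification(self):
        m = self._arm_matrix([[1, 0]] * 3 + [[0, 1]] * 3 + [[0, 0]] * 4,
                             [f"s{i}" for i in range(10)])
        out = cur.subtype_cna_matrix(m, {f"s{i}": "x" for i in range(10)})
        assert out.loc["1p", "x"] == 30.0

    def test_all_neutral_gives_zero(self):
        m = self._arm_matrix([[0, 0]] * 4, [f"s{i}" for i in range(4)])
        out = cur.subtype_cna_matrix(m, {f"s{i}": "x" for i in range(4)})
        assert out.loc["1p", "x"] == 0.0

    def test_cooccurrence_counting(self):
        samples = [f"s{i}" for i in range(6)]
        focal_vals = pd.DataFrame({"MYC_Amp": [1, 1, 1, 0, 0, 0]},
                                  index=samples, dtype=float)
        fmeta = pd.DataFrame({"alteration_class": "focal", "direction": "amp",
                              "qualifying_types": [("T",)]},
                             index=["MYC_Amp"])
        focal = cur.AlterationMatrix(focal_vals, fmeta)
        arms = self._arm_matrix([[1, 0], [1, 0], [0, 0],
                                 [1, 0], [0, 0], [0, 0]], samples)
        # rename arm col to 8q for realism is unnecessary; map MYC->1p
        out = cur.focal_arm_cooccurrence(focal, arms, {"MYC_Amp": "1p_Amp"},
                                         {s: "T" for s in samples})
        assert out.iloc[0]["pct_cooccur"] == pytest.approx(100 * 2 / 3)

    def test_unmapped_focal_errors(self):
        samples = ["s0"]
        focal_vals = pd.DataFrame({"X_Amp": [1]}, index=samples, dtype=float)
        fmeta = pd.DataFrame({"alteration_class": "focal", "direction": "amp",
                              "qualifying_types": [("T",)]}, index=["X_Amp"])
        focal = cur.AlterationMatrix(focal_vals, fmeta)
        arms = self._arm_matrix([[0, 0]], samples)
        with pytest.raises(ValueError, match="no arm mapping"):
            cur.focal_arm_cooccurrence(focal, arms, {}, {"s0": "T"})
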