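"""V_ST statistic, scans, unique unions, gene overlap, length contrast."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cnvpopgen as c
from cnvpopgen.differentiation import (
    annotate_overlap,
    gene_overlap_contrast,
    manhattan_table,
    read_genes_bed,
    read_genes_gff3,
    unique_differentiated,
    vst,
    vst_scan,
)
from cnvpopgen.errors import InputError
from cnvpopgen.evaluate import truth_region_labels

from conftest import make_region


class TestVst:
    def test_complete_differentiation(self):
        values = np.array([-1.0] * 10 + [0.0] * 10)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        assert vst(values, labels) == pytest.approx(1.0)

    def test_constant_values_degenerate_zero(self):
        values = np.full(8, 0.25)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        assert vst(values, labels) == 0.0

    def test_hand_computed_oracle(self):
        # A = {-1,-1,0,0}, B = {0,0,0,0}: V_T=0.1875, V_S=0.125, V_ST=1/3
        values = np.array([-1.0, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        assert vst(values, labels) == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            vst(np.array([1.0, 2.0]), np.array(["A", "A"]))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-5, 5),
           st.floats(0.1, 10).filter(lambda s: abs(s) > 1e-6))
    def test_bounds_and_affine_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 10, 2)
        values = rng.normal(size=n_a + n_b)
        labels = np.array(["A"] * n_a + ["B"] * n_b)
        v = vst(values, labels)
        assert 0.0 <= v <= 1.0
        v2 = vst(values * scale + shift, labels)
        assert v2 == pytest.approx(v, abs=1e-9)

    def test_unbiased_variant_may_dip_below_zero(self):
        values = np.array([0.0, 1.0, 0.5, 0.5])
        labels = np.array(["A", "A", "B", "B"])
        v = vst(values, labels, unbiased=True)
        assert v <= 1.0  # reported unclamped


class TestVstScan:
    def test_power_on_differentiated_loci(self):
        cfg = dataclasses.replace(
            c.SimConfig(), n_chrom=3, n_cnv_loci=14, n_differentiated_loci=10,
            diff_freq_pair=(0.9, 0.05), noise_sd=0.1)
        lrr, sheet, truth = c.simulate_cohort(cfg)
        m = c.gc_correct(lrr, mode="trimmed")
        segset = c.segment_lrr(m, c.SegConfig(n_perm=200, seed=2))
        regions = c.filter_frequency(c.merge_regions(segset))
        table = vst_scan(regions, sheet, [("G1", "G2"), ("G1", "G3")])
        labels = truth_region_labels(truth, regions)
        flagged = 0
        for rid, j in labels.items():
            if j is not None and j < cfg.n_differentiated_loci:
                if table.loc[table["region_id"] == rid, "V_ST"].max() > 0.4:
                    flagged += 1
        assert flagged >= 9

    def test_specificity_on_undifferentiated_cohort(self):
        cfg = dataclasses.replace(
            c.SimConfig(), n_chrom=3, n_cnv_loci=20, n_differentiated_loci=0,
            divergence_F=(0.02, 0.02))
        lrr, sheet, _ = c.simulate_cohort(cfg)
        m = c.gc_correct(lrr, mode="trimmed")
        segset = c.segment_lrr(m, c.SegConfig(n_perm=200, seed=3))
        regions = c.filter_frequency(c.merge_regions(segset))
        table = vst_scan(regions, sheet, [("G1", "G2"), ("G1", "G3"), ("G2", "G3")])
        assert (table["V_ST"] < 0.4).mean() >= 0.95

    def test_degenerate_region_never_flagged(self):
        r = make_region(0.0, n_samples=8, region_id="CNV1",
                        means=np.zeros(8))
        sheet = pd.DataFrame({"sample": [f"s{i}" for i in range(8)],
                              "breed": ["X"] * 8,
                              "group": ["A"] * 4 + ["B"] * 4})
        table = vst_scan([r], sheet, [("A", "B")])
        assert bool(table.loc[0, "degenerate"])
        assert table.loc[0, "V_ST"] == 0.0
        assert not table.loc[0, "above_0.4"]

    def test_unknown_label_rejected(self):
        r = make_region(0.5, n_samples=4, region_id="CNV1")
        sheet = pd.DataFrame({"sample": list("abcd"), "breed": ["X"] * 4,
                              "group": ["A", "A", "B", "B"]})
        with pytest.raises(InputError):
            vst_scan([r], sheet, [("A", "NOPE")])

    def test_breed_level_comparison_resolves(self):
        r = make_region(0.5, n_samples=4, region_id="CNV1")
        sheet = pd.DataFrame({"sample": list("abcd"),
                              "breed": ["HOL", "HOL", "ANG", "ANG"],
                              "group": ["TAU"] * 4})
        table = vst_scan([r], sheet, [("HOL", "ANG")])
        assert len(table) == 1

    def test_manhattan_slice(self):
        r = make_region(0.5, n_samples=4, region_id="CNV1")
        sheet = pd.DataFrame({"sample": list("abcd"), "breed": ["X"] * 4,
                              "group": ["A", "A", "B", "B"]})
        table = vst_scan([r], sheet, [("A", "B")])
        man = manhattan_table(table, "A_vs_B")
        assert list(man.columns) == ["chrom", "midpoint_bp", "V_ST"]


class TestUniqueDifferentiated:
    def _table(self, ids, vals):
        return pd.DataFrame({"region_id": ids, "V_ST": vals,
                             "degenerate": [False] * len(ids)})

    def test_set_union(self):
        t1 = self._table(list("abc"), [0.5, 0.6, 0.7])
        t2 = self._table(list("bd"), [0.9, 0.5])
        t3 = self._table(list("cde"), [0.41, 0.42, 0.43])
        assert unique_differentiated([t1, t2, t3], 0.4) == set("abcde")

    def test_empty_flags(self):
        t = self._table(list("ab"), [0.1, 0.2])
        assert unique_differentiated([t], 0.4) == set()

    def test_fixture_counts_41_11_48_union_78(self):
        # constructed overlap pattern with per-comparison counts 41, 11, 48
        a = [f"CNV{i}" for i in range(1, 42)]
        b = [f"CNV{i}" for i in range(38, 49)]
        cset = [f"CNV{i}" for i in range(31, 79)]
        tables = [self._table(ids, [0.5] * len(ids)) for ids in (a, b, cset)]
        assert len(a) == 41 and len(b) == 11 and len(cset) == 48
        assert len(unique_differentiated(tables, 0.4)) == 78


class TestAnnotate:
    def region_frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])

    def gene_frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])

    def test_one_bp_overlap_reported(self):
        regions = self.region_frame([("1", 100, 200, "r1")])
        genes = self.gene_frame([("1", 199, 300, "g1")])
        out = annotate_overlap(regions, genes)
        assert len(out) == 1
        assert out.loc[0, "overlap_bp"] == 1

    def test_touching_half_open_intervals_do_not_overlap(self):
        regions = self.region_frame([("1", 100, 200, "r1")])
        genes = self.gene_frame([("1", 200, 300, "g1")])
        assert annotate_overlap(regions, genes).empty

    def test_hand_enumerated_toy(self):
        regions = self.region_frame([
            ("1", 0, 100, "r1"), ("1", 500, 800, "r2"), ("2", 0, 50, "r3")])
        genes = self.gene_frame([
            ("1", 50, 60, "gA"), ("1", 90, 120, "gB"), ("1", 400, 501, "gC"),
            ("2", 25, 30, "gD"), ("3", 0, 1000, "gE")])
        out = annotate_overlap(regions, genes)
        got = set(zip(out["region_id"], out["gene_id"]))
        assert got == {("r1", "gA"), ("r1", "gB"), ("r2", "gC"), ("r3", "gD")}

    def test_overlap_is_symmetric(self):
        regions = self.region_frame([("1", 10, 120, "r1")])
        genes = self.gene_frame([("1", 100, 300, "g1")])
        a = annotate_overlap(regions, genes).loc[0, "overlap_bp"]
        b = annotate_overlap(
            genes.rename(columns={"gene_id": "region_id"}),
            regions.rename(columns={"region_id": "gene_id"})).loc[0, "overlap_bp"]
        assert a == b == 20

    def test_malformed_interval_rejected(self):
        regions = self.region_frame([("1", 200, 100, "r1")])
        genes = self.gene_frame([("1", 0, 10, "g1")])
        with pytest.raises(InputError):
            annotate_overlap(regions, genes)

    def test_gff3_one_based_conversion(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA;Name=A\n"
            "1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1\n"
            "2\tsrc\tgene\t1\t50\t.\t-\t.\tName=geneB\n")
        genes = read_genes_gff3(gff)
        assert len(genes) == 2  # exon rows are skipped
        assert genes.loc[0, "start"] == 100 and genes.loc[0, "end"] == 200
        assert genes.loc[1, "gene_id"] == "geneB"

    def test_bed_reader(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t0\t100\tg1\n1\t500\t900\tg2\n")
        genes = read_genes_bed(bed)
        assert list(genes["gene_id"]) == ["g1", "g2"]


class TestContrast:
    def _regions(self, lengths, freqs, prefix):
        out = []
        for i, (L, f) in enumerate(zip(lengths, freqs)):
            r = make_region(f, n_samples=100, start=1000, end=1000 + L - 1,
                            region_id=f"{prefix}{i}")
            out.append(r)
        return out

    def test_identical_classes_give_null_result(self):
        with_genes = self._regions([100, 200, 300], [0.2, 0.3, 0.4], "a")
        without = self._regions([100, 200, 300], [0.2, 0.3, 0.4], "b")
        overlaps = pd.DataFrame({"region_id": [r.region_id for r in with_genes],
                                 "gene_id": "g", "overlap_bp": 10})
        res = gene_overlap_contrast(with_genes + without, overlaps)
        assert res["length_test"]["t"] == 0.0
        assert res["length_test"]["p"] == 1.0

    def test_welch_hand_oracle(self):
        a = self._regions([10, 20, 30], [0.4, 0.5, 0.6], "a")
        b = self._regions([40, 50, 60], [0.1, 0.2, 0.3], "b")
        overlaps = pd.DataFrame({"region_id": [r.region_id for r in a],
                                 "gene_id": "g", "overlap_bp": 1})
        res = gene_overlap_contrast(a + b, overlaps)
        # direct formula: means 20/50, s^2 = 100 each, se = sqrt(200/3)
        t_expected = (20 - 50) / np.sqrt(200 / 3)
        assert res["length_test"]["t"] == pytest.approx(t_expected)
        assert res["length_test"]["df"] == pytest.approx(4.0)
        assert res["overlapping"].mean_length == pytest.approx(20.0)
        assert res["non_overlapping"].mean_length == pytest.approx(50.0)

    def test_sem_is_sample_sd_over_sqrt_n(self):
        a = self._regions([10, 20, 30], [0.4, 0.5, 0.6], "a")
        b = self._regions([40, 50, 60], [0.1, 0.2, 0.3], "b")
        overlaps = pd.DataFrame({"region_id": [r.region_id for r in a],
                                 "gene_id": "g", "overlap_bp": 1})
        res = gene_overlap_contrast(a + b, overlaps)
        assert res["overlapping"].sem_length == pytest.approx(np.std([10, 20, 30], ddof=1) / np.sqrt(3))

    def test_small_class_skips_test_with_warning(self):
        a = self._regions([10], [0.5], "a")
        b = self._regions([40, 50, 60], [0.1, 0.2, 0.3], "b")
        overlaps = pd.DataFrame({"region_id": [r.region_id for r in a],
                                 "gene_id": "g", "overlap_bp": 1})
        with pytest.warns(UserWarning, match="N < 2"):
            res = gene_overlap_contrast(a + b, overlaps)
        assert "length_test" not in res
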