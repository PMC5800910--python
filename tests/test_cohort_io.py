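"""Cohort file IO: round-trips, detection floor, VCF allele orientation."""

import numpy as np
import pandas as pd
import pytest

import gencorrect as gc
from gencorrect.cohort import DETECTION_FLOOR, PHENOTYPE_COLUMNS


def _write_files(cohort, tmp_path, tag=""):
    ph = tmp_path / f"ph{tag}.tsv"
    gt = tmp_path / f"gt{tag}.tsv"
    gc.write_cohort(cohort, ph, gt)
    return ph, gt


class TestRoundTrip:
    def test_write_read_is_identity(self, tmp_path):
        cohort = gc.simulate_cohort(gc.SimulationConfig(n_subjects=100, seed=3))
        ph, gt = _write_files(cohort, tmp_path)
        back = gc.read_cohort(ph, gt)
        pd.testing.assert_frame_equal(back.phenotypes, cohort.phenotypes)
        pd.testing.assert_frame_equal(back.genotypes, cohort.genotypes)

    def test_round_trip_is_byte_identical(self, tmp_path):
        cohort = gc.simulate_cohort(gc.SimulationConfig(n_subjects=60, seed=4))
        ph1, gt1 = _write_files(cohort, tmp_path, "1")
        back = gc.read_cohort(ph1, gt1)
        ph2, gt2 = _write_files(back, tmp_path, "2")
        assert ph1.read_bytes() == ph2.read_bytes()
        assert gt1.read_bytes() == gt2.read_bytes()

    def test_missing_genotypes_survive_round_trip(self, tmp_path):
        cohort = gc.simulate_cohort(gc.SimulationConfig(n_subjects=30, seed=6))
        cohort.genotypes.iloc[0, 0] = np.nan
        cohort.genotypes.iloc[5, 3] = np.nan
        ph, gt = _write_files(cohort, tmp_path)
        assert "NA" in gt.read_text()
        back = gc.read_cohort(ph, gt)
        assert np.isnan(back.genotypes.iloc[0, 0])
        pd.testing.assert_frame_equal(back.genotypes, cohort.genotypes)

    def test_empty_cohort_round_trips(self, tmp_path):
        cohort = gc.simulate_cohort(gc.SimulationConfig(n_subjects=5, seed=1))
        empty = gc.Cohort(
            phenotypes=cohort.phenotypes.iloc[:0],
            genotypes=cohort.genotypes.iloc[:0],
        )
        ph, gt = _write_files(empty, tmp_path)
        back = gc.read_cohort(ph, gt)
        assert back.n_subjects == 0
        assert list(back.phenotypes.reset_index().columns) == list(PHENOTYPE_COLUMNS)


class TestDetectionFloor:
    def _toy_phenotypes(self, tmp_path, afp="0.003"):
        ph = tmp_path / "ph.tsv"
        gt = tmp_path / "gt.tsv"
        header = "\t".join(PHENOTYPE_COLUMNS)
        rows = [
            f"A\t{afp}\t7.0\t1.5\t60\tmale\t24\tnever\tnever\tyes\tno\t0\t5.0\tnone",
            "B\t2.5\t8.0\t2.0\t65\tfemale\t23\tever\tnever\tyes\tno\t1\t2.5\tliver",
            "C\t3.1\t6.5\t1.8\t62\tmale\t25\tnever\tever\tno\tyes\t0\t5.0\tnone",
        ]
        ph.write_text(header + "\n" + "\n".join(rows) + "\n")
        gt.write_text(
            "rsid\tA\tB\tC\nrs12506899\t0\t1\t2\nrs2251844\t1\tNA\t0\n"
        )
        return ph, gt

    def test_below_threshold_floored(self, tmp_path):
        ph, gt = self._toy_phenotypes(tmp_path, afp="0.003")
        cohort = gc.read_cohort(ph, gt)
        assert cohort.phenotypes.loc["A", "afp"] == DETECTION_FLOOR
        assert cohort.n_subjects == 3
        cohort.validate()

    def test_at_threshold_untouched(self, tmp_path):
        ph, gt = self._toy_phenotypes(tmp_path, afp="0.01")
        cohort = gc.read_cohort(ph, gt)
        assert cohort.phenotypes.loc["A", "afp"] == 0.01

    def test_negative_biomarker_rejected(self, tmp_path):
        ph, gt = self._toy_phenotypes(tmp_path, afp="-1.0")
        with pytest.raises(ValueError, match="negative"):
            gc.read_cohort(ph, gt)

    def test_subject_missing_from_genotypes_warns(self, tmp_path):
        ph, gt = self._toy_phenotypes(tmp_path)
        gt.write_text("rsid\tA\tB\nrs12506899\t0\t1\n")
        with pytest.warns(UserWarning, match="missing from genotypes"):
            cohort = gc.read_cohort(ph, gt)
        assert cohort.genotypes.loc["C"].isna().all()


def _write_vcf(path, samples, records):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, rsid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


class TestVcfGenotypes:
    def test_effect_allele_on_ref_flips_dosage(self, tmp_path, panels):
        # rs12506899 effect allele T; as REF, genotype 0/0 carries 2 copies
        vcf = tmp_path / "g.vcf"
        _write_vcf(
            vcf,
            ["A", "B", "C"],
            [("4", 74538147, "rs12506899", "T", "C", ["0/0", "0/1", "1/1"])],
        )
        ph = tmp_path / "ph.tsv"
        header = "\t".join(PHENOTYPE_COLUMNS)
        rows = [
            "A\t2.0\t7.0\t1.5\t60\tmale\t24\tnever\tnever\tyes\tno\t0\t5.0\tnone",
            "B\t2.5\t8.0\t2.0\t65\tfemale\t23\tever\tnever\tyes\tno\t1\t2.5\tliver",
            "C\t3.1\t6.5\t1.8\t62\tmale\t25\tnever\tever\tno\tyes\t0\t5.0\tnone",
        ]
        ph.write_text(header + "\n" + "\n".join(rows) + "\n")
        cohort = gc.read_cohort(ph, vcf, panels)
        assert list(cohort.genotypes["rs12506899"]) == [2.0, 1.0, 0.0]

    def test_swapped_ref_alt_gives_complementary_counts(self, tmp_path, panels):
        ph = tmp_path / "ph.tsv"
        header = "\t".join(PHENOTYPE_COLUMNS)
        rows = [
            "A\t2.0\t7.0\t1.5\t60\tmale\t24\tnever\tnever\tyes\tno\t0\t5.0\tnone",
            "B\t2.5\t8.0\t2.0\t65\tfemale\t23\tever\tnever\tyes\tno\t1\t2.5\tliver",
        ]
        ph.write_text(header + "\n" + "\n".join(rows) + "\n")
        v1, v2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        # same physical genotypes described from both orientations
        _write_vcf(v1, ["A", "B"], [("4", 74538147, "rs12506899", "T", "C", ["0/1", "1/1"])])
        _write_vcf(v2, ["A", "B"], [("4", 74538147, "rs12506899", "C", "T", ["0/1", "0/0"])])
        c1 = gc.read_cohort(ph, v1, panels)
        c2 = gc.read_cohort(ph, v2, panels)
        pd.testing.assert_frame_equal(
            c1.genotypes[["rs12506899"]], c2.genotypes[["rs12506899"]]
        )
        # and counts from an inverted GT column are complementary (c <-> 2 - c)
        v3 = tmp_path / "c.vcf"
        _write_vcf(v3, ["A", "B"], [("4", 74538147, "rs12506899", "C", "T", ["0/1", "1/1"])])
        c3 = gc.read_cohort(ph, v3, panels)
        assert (c3.genotypes["rs12506899"] == 2 - c1.genotypes["rs12506899"]).all()

    def test_unknown_effect_base_resolved_via_other_allele(self, tmp_path, panels):
        # rs2251844: listed (decreasing) allele T, effect allele stored as "*"
        ph = tmp_path / "ph.tsv"
        header = "\t".join(PHENOTYPE_COLUMNS)
        rows = [
            "A\t2.0\t7.0\t1.5\t60\tmale\t24\tnever\tnever\tyes\tno\t0\t5.0\tnone",
            "B\t2.5\t8.0\t2.0\t65\tfemale\t23\tever\tnever\tyes\tno\t1\t2.5\tliver",
        ]
        ph.write_text(header + "\n" + "\n".join(rows) + "\n")
        vcf = tmp_path / "g.vcf"
        _write_vcf(
            vcf, ["A", "B"], [("15", 41623770, "rs2251844", "T", "C", ["0/0", "0/1"])]
        )
        cohort = gc.read_cohort(ph, vcf, panels)
        # T (= other allele) is REF, so effect-allele count equals ALT dosage
        assert list(cohort.genotypes["rs2251844"]) == [0.0, 1.0]
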