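"""Round trips, subject alignment and format validation for cohort I/O."""

import numpy as np
import pandas as pd
import pytest

from pqtlmeta import io
from pqtlmeta.types import AnalyteMeta, BiomarkerPanel, GenotypeMatrix, VariantInfo


def write_study(bundle, tmp_path, prefix):
    io.write_genotype_table(bundle.genotypes, tmp_path / f"{prefix}.genotypes.tsv")
    io.write_biomarker_table(bundle.biomarkers, tmp_path / f"{prefix}.biomarkers.tsv")
    io.write_lloq_table(bundle.biomarkers.analytes, tmp_path / f"{prefix}.lloq.tsv")
    io.write_covariate_table(bundle.covariates, tmp_path / f"{prefix}.covariates.tsv")
    io.write_phenotype_table(bundle.phenotypes, tmp_path / f"{prefix}.phenotypes.tsv")
    return [
        tmp_path / f"{prefix}.{part}.tsv"
        for part in ("genotypes", "biomarkers", "lloq", "covariates", "phenotypes")
    ]


class TestCohortRoundTrip:
    def test_full_bundle_round_trip(self, small_study, tmp_path):
        b1, _, _ = small_study
        paths = write_study(b1, tmp_path, "c1")
        back = io.read_cohort(*paths, name="c1")
        assert back.subjects == b1.subjects  # generation order is lexicographic
        np.testing.assert_array_equal(back.genotypes.dosage, b1.genotypes.dosage)
        np.testing.assert_allclose(back.biomarkers.raw, b1.biomarkers.raw)
        np.testing.assert_array_equal(back.biomarkers.below_lloq, b1.biomarkers.below_lloq)
        assert back.genotypes.variants == b1.genotypes.variants
        pd.testing.assert_frame_equal(
            back.phenotypes.data, b1.phenotypes.data, check_dtype=False
        )

    def test_missing_covariate_subject_dropped(self, small_study, tmp_path):
        b1, _, _ = small_study
        paths = write_study(b1, tmp_path, "c1")
        cov = pd.read_csv(paths[3], sep="\t")
        cov.loc[2, "bmi"] = np.nan
        cov.to_csv(paths[3], sep="\t", index=False, na_rep="NA")
        back = io.read_cohort(*paths, name="c1")
        dropped = cov.loc[2, "subject_id"]
        assert back.n == b1.n - 1
        assert dropped not in back.subjects

    def test_subject_alignment_after_intersection(self, small_study, tmp_path):
        # shuffle the covariate row order; alignment must be restored by id
        b1, _, _ = small_study
        paths = write_study(b1, tmp_path, "c1")
        cov = pd.read_csv(paths[3], sep="\t").sample(frac=1.0, random_state=1)
        cov.to_csv(paths[3], sep="\t", index=False)
        back = io.read_cohort(*paths, name="c1")
        assert back.covariates.subjects == back.genotypes.subjects
        orig = b1.covariates.data.set_index(pd.Index(b1.subjects))
        got = back.covariates.data.set_index(pd.Index(back.subjects))
        pd.testing.assert_frame_equal(got.loc[b1.subjects], orig, check_dtype=False)

    def test_empty_intersection_is_an_error(self, small_study, tmp_path):
        b1, _, _ = small_study
        paths = write_study(b1, tmp_path, "c1")
        cov = pd.read_csv(paths[3], sep="\t")
        cov["subject_id"] = [f"ZZ{i}" for i in range(len(cov))]
        cov.to_csv(paths[3], sep="\t", index=False)
        with pytest.raises(ValueError, match="intersection"):
            io.read_cohort(*paths, name="c1")


class TestGenotypeFormat:
    def test_bad_dosage_value_names_file_and_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "variant_id\tchromosome\tposition\tallele_ref\tallele_alt\ts1\ts2\n"
            "rs1\t1\t100\tA\tG\t0\t3\n"
        )
        with pytest.raises(io.FormatError, match=r"g\.tsv:2"):
            io.read_genotype_table(path)

    def test_na_dosage_round_trips_as_missing(self, tmp_path):
        g = GenotypeMatrix(
            subjects=["s1", "s2"],
            variants=[VariantInfo("rs1", "1", 100, "A", "G")],
            dosage=np.array([[1.0], [np.nan]]),
        )
        io.write_genotype_table(g, tmp_path / "g.tsv")
        back = io.read_genotype_table(tmp_path / "g.tsv")
        assert back.dosage[0, 0] == 1.0
        assert np.isnan(back.dosage[1, 0])


class TestVcfImport:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
        "1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
        "1\t300\trsC\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
    )

    def test_hand_parsed_fixture(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(self.VCF)
        with pytest.warns(UserWarning, match="multi-allelic"):
            g = io.read_vcf_genotypes(path)
        assert g.subjects == ["S1", "S2", "S3"]
        assert g.variant_ids == ["rsA", "rsB"]  # multi-allelic rsC skipped
        # hand-read dosages: 0/1 -> 1, 1/1 -> 2, 0/0 -> 0, ./. -> missing
        np.testing.assert_array_equal(g.dosage[:, 0], [1.0, 2.0, 0.0])
        assert np.isnan(g.dosage[0, 1])
        np.testing.assert_array_equal(g.dosage[1:, 1], [1.0, 2.0])
        assert g.variants[0].position == 100
        assert g.variants[1].allele_alt == "T"


class TestPlinkImport:
    def test_ped_map_hand_checked(self, tmp_path):
        (tmp_path / "x.map").write_text("1\trs1\t0\t100\n2\trs2\t0\t200\n")
        (tmp_path / "x.ped").write_text(
            "F1 I1 0 0 1 0 A G C C\n"
            "F2 I2 0 0 2 0 G G C T\n"
            "F3 I3 0 0 1 0 A A 0 0\n"
        )
        g = io.read_plink_text(tmp_path / "x.ped", tmp_path / "x.map")
        assert g.subjects == ["I1", "I2", "I3"]
        # rs1: alleles A (x3), G (x3) -> tie, lexicographically greater G counted
        assert g.variants[0].allele_alt == "G"
        np.testing.assert_array_equal(g.dosage[:, 0], [1.0, 2.0, 0.0])
        # rs2: C (x3), T (x1) -> minor T counted; missing pair -> NaN
        assert g.variants[1].allele_alt == "T"
        np.testing.assert_array_equal(g.dosage[:2, 1], [0.0, 1.0])
        assert np.isnan(g.dosage[2, 1])


class TestAssociationTable:
    def test_empty_results_write_header_only(self, tmp_path):
        io.write_association_table([], tmp_path / "a.tsv")
        text = (tmp_path / "a.tsv").read_text().strip().split("\n")
        assert len(text) == 1
        assert text[0].split("\t") == io.ASSOCIATION_COLUMNS

    def test_simulated_records_round_trip_bitwise(self, tmp_path, rng):
        n = 100
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(n)],
                "chr": ["1"] * n,
                "pos": np.arange(1, n + 1),
                "analyte": ["A"] * n,
                "cohort": ["c1"] * n,
                "model": ["ols"] * n,
                "n": np.full(n, 750),
                "beta": rng.normal(size=n),
                "se": np.abs(rng.normal(size=n)) + 0.01,
                "z": rng.normal(size=n),
                "p": rng.uniform(1e-300, 1, size=n),
            }
        )
        io.write_association_table(df, tmp_path / "a.tsv")
        back = io.read_association_table(tmp_path / "a.tsv")
        for col in ("beta", "se", "z", "p"):
            np.testing.assert_array_equal(back[col].to_numpy(), df[col].to_numpy())


def test_analyte_meta_invariants():
    with pytest.raises(ValueError, match="lloq"):
        AnalyteMeta("a", lloq=-1.0)
    with pytest.raises(ValueError, match="gene_start"):
        AnalyteMeta("a", gene_start=10, gene_end=5, lloq=1.0)
    with pytest.raises(ValueError, match="position"):
        VariantInfo("rs1", "1", 0, "A", "G")


def test_below_lloq_mask_matches_definition(rng):
    raw = rng.uniform(0, 10, size=(20, 2))
    raw[0, 0] = np.nan
    mask = BiomarkerPanel.mask_from_lloq(raw, [5.0, 2.0])
    expect = np.zeros_like(mask)
    expect[:, 0] = np.where(np.isfinite(raw[:, 0]), raw[:, 0] < 5.0, False)
    expect[:, 1] = raw[:, 1] < 2.0
    np.testing.assert_array_equal(mask, expect)
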