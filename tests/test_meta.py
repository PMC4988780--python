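"""Signed-Z meta-analysis, replication rules, recursive conditioning,
and local/distant classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from pqtlmeta import meta
from pqtlmeta.meta import (
    CohortScanData,
    call_significant,
    bonferroni_threshold,
    classify_local_distant,
    recursive_conditioning,
    replication_check,
    signed_z,
    stouffer_meta,
)
from pqtlmeta.types import AnalyteMeta, VariantInfo


class TestSignedZ:
    def test_known_quantile(self):
        assert signed_z(0.05, 1.0) == pytest.approx(1.959964, abs=1e-5)
        assert signed_z(0.05, -2.0) == pytest.approx(-1.959964, abs=1e-5)

    def test_p_equal_one_gives_zero(self):
        assert signed_z(1.0, 123.0) == 0.0
        assert signed_z(1.0, -123.0) == 0.0

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            signed_z(0.0, 1.0)
        with pytest.raises(ValueError):
            signed_z(1.5, 1.0)

    def test_extreme_p_stays_finite_and_monotone(self):
        zs = [signed_z(p, 1.0) for p in (1e-100, 1e-300, 1e-320)]
        assert all(np.isfinite(zs))
        assert zs[0] < zs[1] < zs[2]

    def test_log_space_agrees_with_direct_quantile(self):
        # at p = 1e-250 both the direct and the log-space route are exact
        p = 1e-250
        direct = abs(ndtri(p / 2))
        assert signed_z(p, 1.0) == pytest.approx(direct, rel=1e-12)


class TestStoufferMeta:
    def test_identical_studies_reproduce_single_study_p(self):
        for z in (0.5, 1.96, -3.2):
            Z, p = stouffer_meta(z, 400, z, 400)
            assert Z == pytest.approx(z)
            assert p == pytest.approx(2 * ndtr(-abs(z)))

    def test_worked_example_with_study_sizes(self):
        Z, p = stouffer_meta(2.0, 750, 1.0, 590)
        assert Z == pytest.approx((750 * 2.0 + 590 * 1.0) / 1340)
        assert p == pytest.approx(2 * ndtr(-abs(Z)))

    def test_opposite_effects_cancel(self):
        Z, p = stouffer_meta(2.5, 600, -2.5, 600)
        assert Z == 0.0
        assert p == pytest.approx(1.0)

    def test_cohort_swap_symmetry_exact(self):
        for z1, n1, z2, n2 in [(1.7, 750, -0.4, 590), (3.0, 100, 2.0, 900)]:
            a = stouffer_meta(z1, n1, z2, n2)
            b = stouffer_meta(z2, n2, z1, n1)
            assert a[0] == pytest.approx(b[0], abs=0.0)
            assert a[1] == b[1]

    def test_sample_size_weighting_is_conservative_vs_classical(self):
        # for equal z > 0 and unequal n, the arithmetic-mean denominator
        # always yields a smaller |Z| than the classical sqrt-n weights
        for z in (0.5, 1.0, 2.0, 4.0):
            for n1, n2 in [(750, 590), (100, 900), (50, 51)]:
                Zs, _ = stouffer_meta(z, n1, z, n2, method="sample-size")
                Zc, _ = stouffer_meta(z, n1, z, n2, method="classical")
                assert abs(Zs) < abs(Zc)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            stouffer_meta(1.0, 0, 1.0, 100)


class TestSignificance:
    def test_strict_inequality_boundary(self):
        flags = call_significant(np.array([7.9e-10, 8e-10, 8.1e-10]), threshold=8e-10)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_bonferroni_helper(self):
        assert bonferroni_threshold(664_913, 88) == pytest.approx(0.05 / (664_913 * 88))


class TestReplication:
    def _frames(self):
        a = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "analyte": ["A", "A", "A"],
                "beta": [1.0, -1.0, 0.5],
                "p": [1e-12, 1e-12, 0.5],
            }
        )
        b = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "analyte": ["A", "A"],
                "beta": [0.8, 1.0],  # v2 flips direction
                "p": [1e-8, 1e-8],
            }
        )
        return a, b

    def test_direction_and_threshold_rule(self):
        a, b = self._frames()
        table, summary = replication_check(a, b, discovery_threshold=1e-10)
        assert summary["m_discovery"] == 2
        assert summary["per_test_threshold"] == pytest.approx(0.025)
        by_id = table.set_index("variant_id")
        assert bool(by_id.loc["v1", "replicated"])
        assert not bool(by_id.loc["v2", "replicated"])  # direction flip

    def test_missing_association_is_unreplicated(self):
        a, b = self._frames()
        a.loc[2, "p"] = 1e-12  # now v3 is a discovery but absent from B
        table, _ = replication_check(a, b, discovery_threshold=1e-10)
        row = table.set_index("variant_id").loc["v3"]
        assert not bool(row["replicated"]) and bool(row["missing_in_b"])

    def test_per_test_threshold_from_discovery_count(self):
        a = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(182)],
                "analyte": ["A"] * 182,
                "beta": np.ones(182),
                "p": np.full(182, 1e-12),
            }
        )
        _, summary = replication_check(a, a, discovery_threshold=1e-10)
        assert summary["per_test_threshold"] == pytest.approx(0.05 / 182)


class TestRecursiveConditioning:
    def _cohort(self, rng, n, slopes, n_variants=5):
        G = rng.binomial(2, 0.3, size=(n, n_variants)).astype(float)
        y = G @ np.asarray(slopes) + rng.normal(size=n)
        X = np.ones((n, 1))
        return CohortScanData(y=y, X=X, dosages=G, n=n)

    def test_single_candidate_returned_without_conditioning(self, rng):
        c1 = self._cohort(rng, 200, [0.8, 0, 0, 0, 0])
        c2 = self._cohort(rng, 180, [0.8, 0, 0, 0, 0])
        c1.dosages = c1.dosages[:, :1]
        c2.dosages = c2.dosages[:, :1]
        out = recursive_conditioning("A", ["v0"], c1, c2)
        assert out.selected == ["v0"]
        assert out.stop_reason == "single candidate"

    def test_two_independent_signals_both_selected(self, rng):
        slopes = [0.8, 0.0, 0.8, 0.0, 0.0]
        c1 = self._cohort(rng, 500, slopes)
        c2 = self._cohort(rng, 400, slopes)
        out = recursive_conditioning("A", [f"v{i}" for i in range(5)], c1, c2)
        assert sorted(out.selected) == ["v0", "v2"]
        assert len(out.conditional_meta_p) == 2

    def test_never_selects_near_duplicate_dosages(self, rng):
        n = 400
        g = rng.binomial(2, 0.3, n).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.3, n)])
        y = 0.8 * g + rng.normal(size=n)
        c1 = CohortScanData(y=y, X=np.ones((n, 1)), dosages=G, n=n)
        g2 = rng.binomial(2, 0.3, 300).astype(float)
        G2 = np.column_stack([g2, g2, rng.binomial(2, 0.3, 300)])
        c2 = CohortScanData(
            y=0.8 * g2 + rng.normal(size=300), X=np.ones((300, 1)), dosages=G2, n=300
        )
        with pytest.warns(UserWarning, match="r\\^2"):
            out = recursive_conditioning("A", ["v0", "v1", "v2"], c1, c2)
        assert "v1" not in out.selected or "v0" not in out.selected


class TestLocalDistant:
    GENE = AnalyteMeta(
        "A", gene_symbol="GENE", gene_chromosome="1",
        gene_start=5_000_000, gene_end=5_010_000, lloq=1.0,
    )

    def _variant(self, chrom, pos):
        return VariantInfo("rs1", chrom, pos, "A", "G")

    def test_boundary_inside_window(self):
        v = self._variant("1", 5_000_000 - 999_999)
        assert classify_local_distant(v, self.GENE) == "local"

    def test_boundary_outside_window(self):
        v = self._variant("1", 5_000_000 - 1_000_001)
        assert classify_local_distant(v, self.GENE) == "distant"

    def test_exactly_one_megabase_is_local(self):
        v = self._variant("1", 5_010_000 + 1_000_000)
        assert classify_local_distant(v, self.GENE) == "local"

    def test_inside_gene_is_local(self):
        assert classify_local_distant(self._variant("1", 5_005_000), self.GENE) == "local"

    def test_other_chromosome_is_distant_regardless_of_position(self):
        assert classify_local_distant(self._variant("9", 5_005_000), self.GENE) == "distant"

    def test_unknown_locus(self):
        meta_na = AnalyteMeta("A", lloq=1.0)
        assert classify_local_distant(self._variant("1", 1), meta_na) == "unknown"


class TestMetaAnalyze:
    def test_round_trip_through_frames(self, rng):
        a = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "analyte": ["A", "A"],
                "beta": [0.5, -0.2],
                "p": [1e-6, 0.3],
                "n": [750, 750],
            }
        )
        b = a.assign(n=590)
        out = meta.meta_analyze(a, b, n1=750, n2=590)
        r = out.set_index("variant_id").loc["v1"]
        z = signed_z(1e-6, 0.5)
        Z, mp = stouffer_meta(z, 750, z, 590)
        assert r["Z"] == pytest.approx(Z)
        assert r["meta_p"] == pytest.approx(mp)

    def test_nonconverged_rows_excluded(self):
        a = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "analyte": ["A", "A"],
                "beta": [0.5, 0.2],
                "p": [1e-6, 1e-4],
                "n": [750, 750],
                "flag": ["", "nonconverged"],
            }
        )
        out = meta.meta_analyze(a, a.copy(), n1=750, n2=590)
        assert list(out["variant_id"]) == ["v1"]
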