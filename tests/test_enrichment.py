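import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synbreak.enrichment import (
    assign_genes,
    bh_fdr,
    coding_as_cne_control,
    density_ratio,
    flag_windows,
    load_features,
    make_windows,
    te_enrichment,
)
from synbreak.formats import Feature, GenomicInterval


def feat(chrom, lo, hi, name="fam"):
    return Feature(GenomicInterval(chrom, lo, hi), name)


class TestMakeWindows:
    @pytest.mark.parametrize("size,expect", [(25_000, 2), (20_000, 2), (9_999, 0)])
    def test_partial_windows_dropped(self, size, expect):
        t = make_windows({"chr1": size}, 10_000)
        assert len(t) == expect

    def test_oversized_window_warns_empty(self):
        with pytest.warns(UserWarning):
            t = make_windows({"chr1": 5_000}, 10_000)
        assert len(t) == 0

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 100}, 0)


class TestLoadFeatures:
    def test_bp_mode_splits_across_windows(self):
        t = make_windows({"chr1": 20_000}, 10_000)
        t = load_features(t, [feat("chr1", 5_000, 15_000)], mode="bp")
        assert list(t["fam"]) == [5_000.0, 5_000.0]

    def test_count_mode_uses_midpoint(self):
        t = make_windows({"chr1": 20_000}, 10_000)
        t = load_features(t, [feat("chr1", 5_000, 15_000)], mode="count")
        assert list(t["fam"]) == [0.0, 1.0]  # midpoint 10 000 lands in window 2

    def test_no_features_zero_loads(self):
        t = make_windows({"chr1": 20_000}, 10_000)
        t = load_features(t, [], mode="bp", column="fam")
        assert "fam" not in t.columns or t["fam"].sum() == 0

    def test_unknown_mode(self):
        t = make_windows({"chr1": 20_000}, 10_000)
        with pytest.raises(ValueError):
            load_features(t, [], mode="fraction")

    def test_bp_conservation_against_brute_force(self, rng):
        """Total window load equals brute-force feature overlap with the tiling."""
        sizes = {"chr1": 95_000, "chr2": 52_000}
        t = make_windows(sizes, 10_000)
        feats = []
        for _ in range(60):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            lo = int(rng.integers(0, sizes[chrom] - 1_000))
            feats.append(feat(chrom, lo, lo + int(rng.integers(100, 9_000)), "f"))
        t = load_features(t, feats, mode="bp")
        tiled = {"chr1": 90_000, "chr2": 50_000}
        want = sum(
            max(0, min(f.interval.end, tiled[f.interval.seq_id]) - f.interval.start)
            for f in feats
        )
        assert t["f"].sum() == want


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_constant(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([0.5] * 10), [0.5] * 10)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        want = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(ps), want)


class TestTeEnrichment:
    def _table(self, loads):
        t = make_windows({"chr1": 10_000 * len(loads)}, 10_000)
        t["fam"] = np.asarray(loads, dtype=float)
        return t

    def test_exact_separated_example(self):
        t = self._table([200, 220, 240, 10, 12, 14])
        ebrs = [GenomicInterval("chr1", 0, 30_000)]
        (r,) = te_enrichment(t, {"lin": ebrs}, ["fam"])
        assert r.p_raw == pytest.approx(0.1)  # all-EBR-above-all-other, exact MWU
        assert r.direction == "enriched" and r.abundant

    def test_low_abundance_family_excluded(self):
        t = self._table([50, 55, 60, 40, 45, 50])
        (r,) = te_enrichment(t, {"lin": [GenomicInterval("chr1", 0, 30_000)]}, ["fam"])
        assert not r.abundant and np.isnan(r.q_bh)

    def test_no_ebr_windows_warns_na(self):
        t = self._table([200, 210, 220, 230])
        with pytest.warns(UserWarning, match="no EBR windows"):
            (r,) = te_enrichment(t, {"lin": [GenomicInterval("chr2", 0, 10_000)]}, ["fam"])
        assert np.isnan(r.p_raw)

    def test_window_order_invariance(self, rng):
        loads = rng.integers(0, 400, size=40).astype(float)
        t = self._table(loads)
        ebrs = [GenomicInterval("chr1", 0, 100_000)]
        (r1,) = te_enrichment(t, {"lin": ebrs}, ["fam"])
        shuffled = t.sample(frac=1, random_state=3).reset_index(drop=True)
        (r2,) = te_enrichment(shuffled, {"lin": ebrs}, ["fam"])
        assert r1.p_raw == pytest.approx(r2.p_raw)


class TestDensityRatio:
    def _table_with_region(self, in_value, out_value, n_in=100, n_out=200):
        n = n_in + n_out
        t = make_windows({"chr1": 10_000 * n}, 10_000)
        loads = np.full(n, float(out_value))
        loads[:n_in] = in_value
        t["genes"] = loads
        region = [GenomicInterval("chr1", 0, 10_000 * n_in)]
        return t, region

    def test_reference_gene_ratio(self):
        t, region = self._table_with_region(0.14, 0.24)
        mi, mo, ratio, p = density_ratio(t, region, "genes")
        assert round(ratio, 2) == 0.58

    def test_reference_cne_ratio(self):
        t, region = self._table_with_region(2.20, 1.52)
        _, _, ratio, _ = density_ratio(t, region, "genes")
        assert round(ratio, 2) == 1.45

    def test_equal_loads_ratio_one(self):
        t, region = self._table_with_region(1.0, 1.0)
        assert density_ratio(t, region, "genes")[2] == pytest.approx(1.0)

    def test_size_floor_excludes_small_regions(self):
        t, _ = self._table_with_region(5.0, 1.0, n_in=100, n_out=200)
        small = [GenomicInterval("chr1", 0, 1_000_000)]  # 1 Mb < floor
        with_floor = flag_windows(t, small, "f", contained=True, size_floor=1_500_000)
        assert not with_floor["f"].any()

    def test_zero_outside_mean_rejected(self):
        t, region = self._table_with_region(1.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            density_ratio(t, region, "genes")

    def test_straddling_window_not_in_region(self):
        t = make_windows({"chr1": 40_000}, 10_000)
        t["x"] = 1.0
        region = [GenomicInterval("chr1", 5_000, 25_000)]
        flagged = flag_windows(t, region, "f", contained=True)
        assert list(flagged["f"]) == [False, True, False, False]


class TestCodingAsCneControl:
    def _table(self, cne, coding):
        t = make_windows({"chr1": 10_000 * len(cne)}, 10_000)
        t["cne_bp"] = np.asarray(cne, dtype=float)
        t["coding_bp"] = np.asarray(coding, dtype=float)
        return t

    def test_two_percent_increment(self):
        out = coding_as_cne_control(self._table([100, 100], [2, 2]))
        assert out["genome_wide"] == pytest.approx(1.02)

    def test_zero_coding_gives_one(self):
        out = coding_as_cne_control(self._table([50, 80, 10], [0, 0, 0]))
        assert out["genome_wide"] == pytest.approx(1.0)

    def test_strata_match_when_composition_identical(self):
        t = self._table([100, 100, 100, 100], [5, 5, 5, 5])
        out = coding_as_cne_control(
            t, mshsb_regions=[GenomicInterval("chr1", 0, 20_000)]
        )
        assert out["mshsb"] == pytest.approx(out["non_mshsb"])
        assert out["genome_wide"] == pytest.approx(1.05)

    def test_cne_free_windows_excluded_and_counted(self):
        out = coding_as_cne_control(self._table([100, 0], [2, 50]))
        assert out["n_windows_excluded"] == 1
        assert out["genome_wide"] == pytest.approx(1.02)

    def test_all_zero_cne_rejected(self):
        with pytest.raises(ValueError):
            coding_as_cne_control(self._table([0, 0], [1, 1]))


class TestAssignGenes:
    def test_flank_overlap(self):
        genes = [feat("chr1", 1_000_000, 1_010_000, "GENE1")]
        lists = assign_genes(genes, ebrs=[("e1", GenomicInterval("chr1", 1_200_000, 1_250_000))])
        assert lists["e1"] == ["GENE1"]  # within 300 kb of the EBR

    def test_gene_beyond_flank_excluded(self):
        genes = [feat("chr1", 0, 10_000, "FAR")]
        lists = assign_genes(genes, ebrs=[("e1", GenomicInterval("chr1", 1_200_000, 1_250_000))])
        assert lists["e1"] == []

    def test_mshsb_containment_rule(self):
        genes = [feat("chr1", 1_990_000, 2_010_000, "STRADDLE"),
                 feat("chr1", 500_000, 510_000, "INSIDE")]
        lists = assign_genes(genes, mshsbs=[("m1", GenomicInterval("chr1", 0, 2_000_000))])
        assert lists["m1"] == ["INSIDE"]

    def test_small_mshsb_contributes_no_genes(self):
        genes = [feat("chr1", 500_000, 510_000, "G")]
        lists = assign_genes(genes, mshsbs=[("m1", GenomicInterval("chr1", 0, 1_400_000))])
        assert lists["m1"] == []

    def test_gene_may_hit_multiple_ebrs(self):
        genes = [feat("chr1", 1_000_000, 1_010_000, "G")]
        lists = assign_genes(
            genes,
            ebrs=[
                ("e1", GenomicInterval("chr1", 900_000, 950_000)),
                ("e2", GenomicInterval("chr1", 1_100_000, 1_150_000)),
            ],
        )
        assert lists["e1"] == ["G"] and lists["e2"] == ["G"]
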