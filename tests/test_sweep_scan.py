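"""Pooling, MAF filtering, windowing, Hp/ZHp and sweep calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import write_mini_vcf
from sweepherd import sweep_scan as ss
from sweepherd.synthetic_data import GenomeSpec


def pooled_from_counts(counts, breed="X", chrom="chr1", start_pos=10_000, spacing=100):
    """PooledCounts with given (major, minor) read pairs at evenly spaced SNPs."""
    n = len(counts)
    maj, mnr = zip(*counts)
    return ss.PooledCounts(
        breed=breed,
        table=pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "pos": start_pos + spacing * np.arange(n),
                "ref": ["A"] * n,
                "alt": ["G"] * n,
                "major_allele": ["A"] * n,
                "minor_allele": ["G"] * n,
                "major_count": list(maj),
                "minor_count": list(mnr),
            }
        ),
    )


class TestPooling:
    def test_ad_sums_over_breed(self, tmp_path):
        vcf = write_mini_vcf(
            tmp_path / "m.vcf",
            [
                ("chr1", 100, "A", "G", [("0/1", (10, 2)), ("0/1", (8, 1)), ("0/0", (9, 0))]),
                ("chr1", 200, "C", "T", [("0/1", (5, 5)), ("0/0", (0, 0)), ("0/0", (0, 0))]),
                ("chr1", 300, "G", "A", [("./.", (0, 0)), ("./.", (0, 0)), ("./.", (0, 0))]),
                ("chr1", 400, "T", "C", [("1/1", (1, 9)), ("0/1", (2, 2)), ("0/1", (1, 3))]),
            ],
            ["s1", "s2", "s3"],
        )
        bm = pd.DataFrame({"sample": ["s1", "s2", "s3"], "breed": ["X"] * 3})
        pc = ss.pool_breed_counts(vcf, bm, "X")
        t = pc.table.set_index("pos")
        # column sums: ref 27, alt 3 -> major is ref
        assert t.loc[100, "major_allele"] == "A"
        assert (t.loc[100, "major_count"], t.loc[100, "minor_count"]) == (27, 3)
        # tie in pooled sums -> reference allele is major
        assert t.loc[200, "major_allele"] == "C"
        assert (t.loc[200, "major_count"], t.loc[200, "minor_count"]) == (5, 5)
        # zero total reads -> site dropped
        assert 300 not in t.index
        # alt-major site
        assert t.loc[400, "major_allele"] == "C"
        assert (t.loc[400, "major_count"], t.loc[400, "minor_count"]) == (14, 4)

    def test_multiallelic_skipped(self, tmp_path):
        path = tmp_path / "m.vcf"
        write_mini_vcf(path, [("chr1", 100, "A", "G", [("0/1", (4, 4))])], ["s1"])
        lines = open(path).read().replace("A\tG", "A\tG,T").replace(":4,4", ":4,2,2")
        path.write_text(lines)
        bm = pd.DataFrame({"sample": ["s1"], "breed": ["X"]})
        pc = ss.pool_breed_counts(str(path), bm, "X")
        assert len(pc) == 0 and pc.n_multiallelic_skipped == 1

    def test_unknown_breed_rejected(self, tmp_path):
        vcf = write_mini_vcf(
            tmp_path / "m.vcf", [("chr1", 100, "A", "G", [("0/1", (4, 4))])], ["s1"]
        )
        bm = pd.DataFrame({"sample": ["s1"], "breed": ["X"]})
        with pytest.raises(ValueError):
            ss.pool_breed_counts(vcf, bm, "Y")


class TestMafFilter:
    @pytest.mark.parametrize(
        "counts,kept",
        [((96, 4), False), ((95, 5), True), ((50, 50), True)],
        ids=["maf0.04-removed", "maf0.05-retained", "maf0.5-retained"],
    )
    def test_boundary(self, counts, kept):
        pc = pooled_from_counts([counts])
        assert len(ss.maf_filter(pc, 0.05)) == (1 if kept else 0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            ss.maf_filter(pooled_from_counts([(9, 1)]), 0.0)


class TestWindows:
    def test_enumeration_300kb(self):
        g = GenomeSpec((("c", 300_000),))
        w = ss.make_windows(g, 150_000, 75_000)
        assert list(zip(w["start"], w["end"])) == [
            (0, 150_000),
            (75_000, 225_000),
            (150_000, 300_000),
        ]

    @pytest.mark.parametrize(
        "length,n", [(150_000, 1), (149_999, 0), (151_000, 1), (225_000, 2)]
    )
    def test_boundaries(self, length, n):
        g = GenomeSpec((("c", length),))
        assert len(ss.make_windows(g)) == n

    def test_closed_form_matches_brute_force(self):
        rng = np.random.default_rng(123)
        size, step = 150_000, 75_000
        for length in rng.integers(100_000, 5_000_000, size=50):
            g = GenomeSpec((("c", int(length)),))
            got = len(ss.make_windows(g, size, step))
            brute = sum(
                1 for s in range(0, int(length), step) if s + size <= length
            )
            closed = 0 if length < size else (int(length) - size) // step + 1
            assert got == brute == closed

    def test_genome_wide_ordinals(self):
        g = GenomeSpec((("c1", 300_000), ("c2", 150_000)))
        w = ss.make_windows(g)
        assert list(w["index"]) == [0, 1, 2, 3]
        assert w.iloc[3]["chrom"] == "c2"


class TestWindowHp:
    def test_hand_computed_hp(self):
        pc = pooled_from_counts([(9, 3)] * 10)
        w = ss.make_windows(GenomeSpec((("chr1", 150_000),)))
        st = ss.window_hp(pc, w)
        assert st.loc[0, "n_snps"] == 10
        assert (st.loc[0, "sum_maj"], st.loc[0, "sum_min"]) == (90, 30)
        assert st.loc[0, "hp"] == pytest.approx(0.375)  # 2*90*30/120^2

    def test_fixed_window_hp_zero(self):
        pc = pooled_from_counts([(12, 0)] * 10)
        w = ss.make_windows(GenomeSpec((("chr1", 150_000),)))
        assert ss.window_hp(pc, w).loc[0, "hp"] == 0.0

    def test_min_snps_exclusion(self):
        w = ss.make_windows(GenomeSpec((("chr1", 150_000),)))
        st9 = ss.window_hp(pooled_from_counts([(9, 3)] * 9), w, min_snps=10)
        st10 = ss.window_hp(pooled_from_counts([(9, 3)] * 10), w, min_snps=10)
        assert bool(st9.loc[0, "excluded"]) and np.isnan(st9.loc[0, "hp"])
        assert not st10.loc[0, "excluded"]

    def test_membership_half_open_shifted(self):
        # 1-based p is in [s, e) window iff s < p <= e
        pc = pooled_from_counts([(8, 4)], start_pos=75_000)
        w = ss.make_windows(GenomeSpec((("chr1", 300_000),)))
        st = ss.window_hp(pc, w, min_snps=1)
        assert list(st["n_snps"]) == [1, 0, 0]  # pos 75000 belongs to [0,150000) only
        pc2 = pooled_from_counts([(8, 4)], start_pos=75_001)
        st2 = ss.window_hp(pc2, w, min_snps=1)
        assert list(st2["n_snps"]) == [1, 1, 0]

    def test_interior_snps_fall_in_two_windows(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(np.arange(150_001, 800_000), 300, replace=False))
        pc = ss.PooledCounts(
            "X",
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "major_allele": "A",
                    "minor_allele": "G",
                    "major_count": 9,
                    "minor_count": 3,
                }
            ),
        )
        w = ss.make_windows(GenomeSpec((("chr1", 950_000),)))
        st = ss.window_hp(pc, w, min_snps=1)
        # every SNP >= one full window from each end is counted exactly twice
        assert st["n_snps"].sum() == 2 * len(pos)


class TestZhp:
    def test_hand_computed_standardization(self):
        w = pd.DataFrame(
            {
                "chrom": "c",
                "start": [0, 75_000, 150_000],
                "end": [150_000, 225_000, 300_000],
                "index": [0, 1, 2],
                "breed": "X",
                "n_snps": 20,
                "sum_maj": 0,
                "sum_min": 0,
                "hp": [0.1, 0.2, 0.3],
                "excluded": False,
                "zhp": np.nan,
            }
        )
        out = ss.zhp_transform(w)
        assert np.allclose(out["zhp"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        base = dict(chrom="c", start=0, end=1, index=0, breed="X", n_snps=20,
                    sum_maj=0, sum_min=0, excluded=False, zhp=np.nan)
        flat = pd.DataFrame([{**base, "hp": 0.2}, {**base, "hp": 0.2}])
        with pytest.raises(ValueError):
            ss.zhp_transform(flat)
        single = pd.DataFrame([{**base, "hp": 0.2}])
        with pytest.raises(ValueError):
            ss.zhp_transform(single)

    def test_standardized_over_retained_only(self, study_scan):
        stats, _ = study_scan
        for breed, st in stats.items():
            z = st.loc[~st["excluded"], "zhp"].to_numpy()
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1) < 1e-9
            assert st.loc[st["excluded"], "zhp"].isna().all()


class TestCalls:
    def _stats(self, zhps):
        n = len(zhps)
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": 75_000 * np.arange(n),
                "end": 75_000 * np.arange(n) + 150_000,
                "index": np.arange(n),
                "breed": "X",
                "n_snps": 50,
                "sum_maj": 0,
                "sum_min": 0,
                "hp": 0.2,
                "excluded": False,
                "zhp": zhps,
            }
        )

    def test_strict_threshold_and_ordering(self):
        calls = ss.call_sweeps(self._stats([-2.0, -2.01, 0.5, -3.2]), threshold=-2.0)
        assert list(calls["zhp"]) == [-3.2, -2.01]  # -2.0 exactly is NOT called

    def test_empty_stats(self):
        assert len(ss.call_sweeps(self._stats([]))) == 0

    def test_gene_annotation_attached(self):
        from sweepherd.variant_annotation import GeneModelIndex, Transcript

        gm = GeneModelIndex(
            [Transcript("CLDN1", "tx1", "c", "+", ((10_000, 12_000), (14_000, 20_000)))]
        )
        calls = ss.call_sweeps(self._stats([-2.96, 0.0]), gene_models=gm)
        assert calls.loc[0, "genes"] == "CLDN1"


class TestPerSnpTrack:
    @pytest.mark.parametrize(
        "counts,expected", [((6, 6), 0.5), ((12, 0), 0.0), ((9, 3), 0.375)]
    )
    def test_hand_values(self, counts, expected):
        pc = pooled_from_counts([counts], start_pos=5_000)
        track = ss.per_snp_hp_track(pc, ("chr1", 0, 10_000))
        assert track["hp_snp"].iloc[0] == pytest.approx(expected)

    def test_empty_region(self):
        pc = pooled_from_counts([(6, 6)], start_pos=5_000)
        assert len(ss.per_snp_hp_track(pc, ("chr2", 0, 10_000))) == 0


class TestOracleEquivalence:
    def test_window_hp_matches_vcf_rereading_brute_force(self, small_cohort):
        """Window Hp equals an independent recomputation that re-reads the
        VCF and sums breed AD per window."""
        from cyvcf2 import VCF

        breed_map = ss.read_breed_map(small_cohort.breed_map)
        breed = "KNP"
        pooled = ss.maf_filter(ss.pool_breed_counts(small_cohort.vcf, breed_map, breed))
        windows = ss.make_windows(small_cohort.genome)
        st = ss.window_hp(pooled, windows)

        samples = list(VCF(small_cohort.vcf).samples)
        rows = [samples.index(s) for s in breed_map.loc[breed_map.breed == breed, "sample"]]
        per_site = {}
        for v in VCF(small_cohort.vcf):
            ad = v.format("AD")[rows]
            r, a = int(ad[:, 0].sum()), int(ad[:, 1].sum())
            if r + a == 0:
                continue
            maj, mnr = max(r, a), min(r, a)
            if mnr / (maj + mnr) < 0.05:
                continue
            per_site[(v.CHROM, v.POS)] = (maj, mnr)
        for _, w in st.iterrows():
            inside = [
                v
                for (c, p), v in per_site.items()
                if c == w["chrom"] and w["start"] < p <= w["end"]
            ]
            sm = sum(x[0] for x in inside)
            sn = sum(x[1] for x in inside)
            assert w["n_snps"] == len(inside)
            if len(inside) >= 10:
                assert w["hp"] == pytest.approx(2 * sm * sn / (sm + sn) ** 2, abs=1e-12)
            else:
                assert bool(w["excluded"])


class TestRangeInvariant:
    def test_hp_bounded_and_max_iff_balanced(self, study_scan):
        stats, _ = study_scan
        for st in stats.values():
            hp = st.loc[~st["excluded"], "hp"]
            assert ((hp >= 0) & (hp <= 0.5)).all()
            at_max = st.loc[hp.index][np.isclose(hp, 0.5)]
            assert (at_max["sum_maj"] == at_max["sum_min"]).all()
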