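import math

import numpy as np
import pytest

from museum_popgen import (
    FilterConfig,
    filter_samples,
    filter_sites,
    filter_within_population,
)

from conftest import make_gm, two_pop_map


def _vacuous_config(**overrides):
    base = dict(
        min_qual=0.0,
        min_minor_allele_count=0,
        max_site_missing_fraction=1.0,
        min_genotype_depth=0,
        qual_depth_ratio=0.0,
        paralog_sd_multiplier=math.inf,
        max_sample_missing_fraction=1.0,
    )
    base.update(overrides)
    return FilterConfig(**base)


class TestSiteCascade:
    def test_toy_cascade_keeps_exactly_one_record(self):
        """Hand-traced toy: a low-QUAL SNP, an indel, a triallelic SNP, a
        clean biallelic SNP (MAC 7, QUAL 60, depths 10) and a biallelic
        SNP with MAC 2 -> only the clean SNP survives."""
        # 10 samples, 5 sites (columns):
        # col0 QUAL=20; col3 genotypes give alt copies 7 (MAC 7);
        # col4 alt copies 2 (MAC 2)
        gt = np.zeros((10, 5), dtype=np.int8)
        gt[:, 0] = [1, 0] * 5
        gt[:, 1] = [0, 1] * 5
        gt[:, 2] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        gt[:, 3] = [1, 1, 1, 1, 1, 1, 1, 0, 0, 0]   # 7 alt / 13 ref
        gt[:, 4] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]   # 2 alt / 18 ref
        gm = make_gm(
            gt,
            depths=np.full((10, 5), 10),
            quals=[20.0, 60.0, 60.0, 60.0, 60.0],
            refs=["A", "AT", "A", "A", "A"],
            alts=["T", "A", "C,G", "T", "T"],
        )
        out, report = filter_sites(gm, FilterConfig())
        assert out.n_loci == 1
        assert out.loci.iloc[0]["chrom"] == gm.loci.iloc[3]["chrom"]
        removed = {s["stage"]: s["sites_removed"] for s in report.stages}
        assert removed == {
            "qual": 1, "indels": 1, "biallelic": 1, "genotype_depth_mask": 0,
            "site_missingness": 0, "minor_allele_count": 1,
            "qual_depth_ratio": 0, "paralog_depth": 0,
        }

    def test_vacuous_thresholds_are_identity(self):
        """With every threshold at its vacuous extreme the cascade returns
        its (all-SNP, biallelic) input unchanged."""
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        gt[rng.random(gt.shape) < 0.2] = -1
        gm = make_gm(gt, depths=np.where(gt == -1, 0, rng.integers(1, 30, gt.shape)))
        out, _ = filter_sites(gm, _vacuous_config())
        assert out.equals(gm)

    def test_cascade_is_idempotent(self, hyrad_like):
        gm, _, _ = hyrad_like
        cfg = FilterConfig()
        once, _ = filter_sites(gm, cfg)
        twice, rep2 = filter_sites(once, cfg)
        assert twice.equals(once)
        assert all(s["sites_removed"] == 0 for s in rep2.stages)

    def test_counts_telescope(self, hyrad_like):
        gm, _, _ = hyrad_like
        _, report = filter_sites(gm, FilterConfig())
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev["sites_in"] - prev["sites_removed"] == nxt["sites_in"]

    def test_depth_masking_precedes_allele_count(self):
        """Regression freezing the stage order: a site at MAC exactly 6
        drops below threshold once one low-depth carrier call is masked."""
        gt = np.zeros((12, 1), dtype=np.int8)
        gt[:6, 0] = 1          # six het carriers -> MAC 6 before masking
        depths = np.full((12, 1), 10)
        depths[0, 0] = 3       # one carrier below the DP>=6 requirement
        gm = make_gm(gt, depths=depths, quals=[60.0])
        cfg = FilterConfig(
            qual_depth_ratio=0.0, paralog_sd_multiplier=math.inf,
            max_site_missing_fraction=1.0,
        )
        out, report = filter_sites(gm, cfg)
        assert out.n_loci == 0
        removed = {s["stage"]: s["sites_removed"] for s in report.stages}
        assert removed["minor_allele_count"] == 1
        # with depth masking disabled the same site survives (MAC 6 kept)
        cfg2 = FilterConfig(
            min_genotype_depth=0, qual_depth_ratio=0.0,
            paralog_sd_multiplier=math.inf, max_site_missing_fraction=1.0,
        )
        out2, _ = filter_sites(gm, cfg2)
        assert out2.n_loci == 1

    def test_mac_six_is_kept(self):
        """'Minor allele count of six' reads as >= 6: a tie at 6 survives."""
        gt = np.zeros((12, 1), dtype=np.int8)
        gt[:3, 0] = 2          # 6 alt copies among 24
        gm = make_gm(gt, quals=[200.0])
        cfg = FilterConfig(qual_depth_ratio=0.0, paralog_sd_multiplier=math.inf)
        out, _ = filter_sites(gm, cfg)
        assert out.n_loci == 1

    def test_paralog_outlier_removed(self):
        rng = np.random.default_rng(1)
        gt = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        depths = np.full((8, 30), 12)
        depths[:, 0] = 400     # grossly over-covered site
        gm = make_gm(gt, depths=depths, quals=np.full(30, 1e4))
        out, report = filter_sites(gm, _vacuous_config(paralog_sd_multiplier=3.0))
        assert report.stages[-1]["sites_removed"] == 1
        assert "locus0000" not in set(out.loci["chrom"])


class TestSampleFilter:
    def test_high_missingness_sample_dropped(self):
        gt = np.zeros((2, 10), dtype=np.int8)
        gt[0, :9] = -1         # 9/10 missing > 0.8
        gm = make_gm(gt)
        out, report = filter_samples(gm, FilterConfig())
        assert report.samples_removed == ["s00"]
        assert out.sample_ids == ["s01"]

    def test_complete_samples_all_kept(self):
        gm = make_gm(np.ones((4, 5), dtype=np.int8))
        out, report = filter_samples(gm, FilterConfig())
        assert report.samples_removed == []
        assert out.n_samples == 4

    def test_zero_threshold_drops_any_missingness(self):
        gt = np.zeros((3, 4), dtype=np.int8)
        gt[1, 0] = -1
        gm = make_gm(gt)
        out, report = filter_samples(
            gm, FilterConfig(max_sample_missing_fraction=0.0)
        )
        assert report.samples_removed == ["s01"]
        assert out.n_samples == 2


class TestWithinPopulationFilter:
    def test_sparse_in_one_population_dropped(self):
        gt = np.zeros((8, 2), dtype=np.int8)
        gt[0:3, 0] = -1        # pop A (4 samples): 3/4 = 0.75 missing
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 4)
        out, report = filter_within_population(gm, popmap, FilterConfig())
        assert out.n_loci == 1
        assert report.stages[0]["sites_removed"] == 1

    def test_boundary_is_strict(self):
        """Missing fraction exactly at the 0.7 threshold is retained in
        both populations ('higher than' is a strict inequality)."""
        gt = np.zeros((20, 1), dtype=np.int8)
        gt[0:7, 0] = -1        # pop A: 7/10
        gt[10:17, 0] = -1      # pop B: 7/10
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 10)
        out, _ = filter_within_population(gm, popmap, FilterConfig())
        assert out.n_loci == 1

    def test_any_mode_is_weaker(self):
        gt = np.zeros((8, 1), dtype=np.int8)
        gt[0:4, 0] = -1        # pop A fully missing, pop B complete
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 4)
        dropped, _ = filter_within_population(gm, popmap, FilterConfig())
        assert dropped.n_loci == 0
        kept, _ = filter_within_population(
            gm, popmap, FilterConfig(within_pop_mode="any")
        )
        assert kept.n_loci == 1

    def test_unassigned_sample_rejected(self):
        gm = make_gm(np.zeros((3, 2), dtype=np.int8))
        popmap = two_pop_map(gm, 3).iloc[:2]
        with pytest.raises(ValueError, match="without population"):
            filter_within_population(gm, popmap, FilterConfig())


def test_hyrad_like_report_statistics(hyrad_like):
    """On the museum-style preset the filtered matrix lands in the
    documented completeness and depth brackets."""
    gm, _, _ = hyrad_like
    cfg = FilterConfig()
    out, _ = filter_sites(gm, cfg)
    out, report = filter_samples(out, cfg)
    assert 0.55 <= report.completeness <= 0.70
    assert 12.0 <= report.mean_site_depth <= 18.0
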