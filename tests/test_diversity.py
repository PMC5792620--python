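from itertools import combinations

import numpy as np
import pytest

from museum_popgen import (
    allelic_richness,
    individual_hobs,
    maf_spectrum,
    population_diversity,
    private_alleles,
    wc_theta,
)
from museum_popgen.diversity import _ar_locus_exact, default_rarefaction_size
from museum_popgen.synth import DegradationProfile, SampleDesign, degrade, sample_genotypes, simulate_truth

from conftest import make_gm, two_pop_map


def _brute_force_ar(n_ref: int, n_alt: int, g: int) -> float:
    """Mean number of distinct alleles over all subsets of g gene copies."""
    pool = [0] * n_ref + [1] * n_alt
    subsets = list(combinations(range(len(pool)), g))
    return float(np.mean([len({pool[i] for i in s}) for s in subsets]))


class TestIndividualHobs:
    def test_fraction_of_het_calls(self):
        gt = np.array([[1, 1, 1, 0, 0, 2, 2, 0, 0, 2, -1, -1]], dtype=np.int8)
        gm = make_gm(gt)
        assert individual_hobs(gm, "s00") == pytest.approx(0.3)

    @pytest.mark.parametrize("row,expected", [
        ([0, 2, 0, 2], 0.0),
        ([1, 1, 1, -1], 1.0),
    ])
    def test_extremes(self, row, expected):
        gm = make_gm(np.array([row], dtype=np.int8))
        assert individual_hobs(gm, "s00") == expected

    def test_all_missing_raises(self):
        gm = make_gm(np.full((1, 3), -1, dtype=np.int8))
        with pytest.raises(ValueError, match="no non-missing"):
            individual_hobs(gm, "s00")


class TestGeneDiversity:
    def test_small_sample_corrected_hexp(self):
        """n=2 with genotypes {AA, aa}: Hexp = 2(1 - 0.5 - 0) = 1.0;
        with {Aa, Aa}: Hexp = 2(1 - 0.5 - 0.25) = 0.5."""
        gm = make_gm(np.array([[0, 1], [2, 1]], dtype=np.int8))
        popmap = two_pop_map(gm, 2, pop_a="P")
        d = population_diversity(gm, popmap, "P")
        assert d["h_exp"][0] == pytest.approx(1.0)
        assert d["h_exp"][1] == pytest.approx(0.5)
        assert d["h_obs"][0] == 0.0 and d["h_obs"][1] == 1.0

    def test_monomorphic_locus_has_zero_hexp(self):
        gm = make_gm(np.zeros((5, 1), dtype=np.int8))
        d = population_diversity(gm, two_pop_map(gm, 5, pop_a="P"), "P")
        assert d["h_exp"][0] == 0.0

    def test_loci_with_one_genotyped_individual_skipped(self):
        gt = np.array([[1, 1], [-1, 1]], dtype=np.int8)
        gm = make_gm(gt)
        d = population_diversity(gm, two_pop_map(gm, 2, pop_a="P"), "P")
        assert list(d["locus_index"]) == [1]


class TestAllelicRichness:
    def test_even_split_example(self):
        # N=10 copies split 5/5, g=2: 2 (1 - C(5,2)/C(10,2)) = 14/9
        assert _ar_locus_exact(5, 5, 2) == pytest.approx(2 * (1 - 10 / 45))

    @pytest.mark.parametrize("n_ref,n_alt", [(12, 0), (0, 8)])
    def test_monomorphic_is_one(self, n_ref, n_alt):
        for g in range(1, n_ref + n_alt + 1):
            assert _ar_locus_exact(n_ref, n_alt, g) == 1.0

    def test_full_sample_counts_distinct_alleles(self):
        assert _ar_locus_exact(3, 5, 8) == 2.0
        assert _ar_locus_exact(8, 0, 8) == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            N = int(rng.integers(2, 13))
            n_alt = int(rng.integers(0, N + 1))
            g = int(rng.integers(1, N + 1))
            assert _ar_locus_exact(N - n_alt, n_alt, g) == pytest.approx(
                _brute_force_ar(N - n_alt, n_alt, g), abs=1e-12
            )

    def test_nondecreasing_in_g(self):
        for n_alt in range(0, 11):
            vals = [_ar_locus_exact(10 - n_alt, n_alt, g) for g in range(1, 11)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_population_level_defaults(self):
        gt = np.array([[0, 1], [1, 1], [2, 0], [-1, 0]], dtype=np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 4, pop_a="P")
        # smallest genotyped cell: locus0 has 3 individuals -> g = 6
        assert default_rarefaction_size(gm, popmap) == 6
        ar = allelic_richness(gm, popmap)
        assert 1.0 <= ar["P"] <= 2.0

    def test_per_locus_rarefaction_mode(self):
        gt = np.array([[0, 1], [1, 1], [2, 0], [-1, 0]], dtype=np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 4, pop_a="P")
        per_locus = allelic_richness(gm, popmap, g="per-locus")
        # locus0 rarefied to g=6, locus1 to g=8 (its own full sample)
        expected = np.mean([_ar_locus_exact(3, 3, 6), _ar_locus_exact(5, 3, 8)])
        assert per_locus["P"] == pytest.approx(expected)


class TestPrivateAlleles:
    def test_directional_private_allele(self):
        # locus0: A polymorphic, B fixed ref -> alt private to A
        gt = np.array([[1, 0], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 2)
        na, nb, detail = private_alleles(gm, popmap, "A", "B")
        assert (na, nb) == (1, 0)
        assert detail.iloc[0]["frequency"] == pytest.approx(0.25)

    def test_identical_allele_sets(self):
        gt = np.array([[1, 2], [1, 0], [1, 2], [1, 0]], dtype=np.int8)
        gm = make_gm(gt)
        na, nb, _ = private_alleles(gm, two_pop_map(gm, 2), "A", "B")
        assert (na, nb) == (0, 0)

    def test_rarefied_counts_reduce_to_raw_at_full_sample(self):
        """With g equal to both populations' full copy counts the rarefied
        expectation equals the raw presence/absence count."""
        rng = np.random.default_rng(17)
        gt = rng.binomial(2, rng.uniform(0.02, 0.5, 40), size=(12, 40)).astype(np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 6)
        raw_a, raw_b, _ = private_alleles(gm, popmap, "A", "B")
        rar_a, rar_b, _ = private_alleles(gm, popmap, "A", "B", rarefaction_g=12)
        assert rar_a == pytest.approx(raw_a)
        assert rar_b == pytest.approx(raw_b)

    def test_rarefied_weights_are_probabilities(self):
        rng = np.random.default_rng(18)
        gt = rng.binomial(2, rng.uniform(0.02, 0.5, 60), size=(12, 60)).astype(np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 6)
        _, _, detail = private_alleles(gm, popmap, "A", "B", rarefaction_g=4)
        assert (detail["weight"] > 0).all() and (detail["weight"] <= 1).all()

    def test_partition_identity(self):
        """privates(A) + privates(B) + shared = distinct alleles in A u B,
        locus by locus, on random sparse data."""
        rng = np.random.default_rng(4)
        gt = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        gt[rng.random(gt.shape) < 0.3] = -1
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 6)
        na, nb, detail = private_alleles(gm, popmap, "A", "B")
        priv_per_locus = detail.groupby("locus_index").size().to_dict()
        from museum_popgen.diversity import _locus_counts

        nn_a, _, alt_a = _locus_counts(gm, np.arange(6))
        nn_b, _, alt_b = _locus_counts(gm, np.arange(6, 12))
        for j in range(60):
            if nn_a[j] == 0 or nn_b[j] == 0:
                continue
            seen_a = {al for al, c in (("ref", 2 * nn_a[j] - alt_a[j]), ("alt", alt_a[j])) if c > 0}
            seen_b = {al for al, c in (("ref", 2 * nn_b[j] - alt_b[j]), ("alt", alt_b[j])) if c > 0}
            shared = len(seen_a & seen_b)
            total = len(seen_a | seen_b)
            assert priv_per_locus.get(j, 0) + shared == total


class TestWcTheta:
    def test_fixed_difference_gives_one(self):
        gt = np.concatenate([np.zeros((5, 1)), np.full((5, 1), 2)]).astype(np.int8)
        gm = make_gm(gt)
        res = wc_theta(gm, two_pop_map(gm, 5), "A", "B")
        assert res.theta == pytest.approx(1.0)

    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(11)
        freqs = rng.uniform(0.1, 0.9, size=150)
        half = rng.binomial(2, freqs, size=(30, 150)).astype(np.int8)
        gm = make_gm(np.vstack([half, half]))
        res = wc_theta(gm, two_pop_map(gm, 30), "A", "B")
        assert res.theta <= 0
        assert abs(res.theta) < 0.05

    def test_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        gm = make_gm(gt)
        flipped = make_gm((2 - gt).astype(np.int8))
        pm = two_pop_map(gm, 5)
        assert wc_theta(gm, pm, "A", "B").theta == pytest.approx(
            wc_theta(flipped, pm, "A", "B").theta, abs=1e-12
        )

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        gt = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        gm = make_gm(gt)
        pm = two_pop_map(gm, 5)
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(5)]
        gm2 = gm.take_samples(perm)
        assert wc_theta(gm, pm, "A", "B").theta == pytest.approx(
            wc_theta(gm2, pm, "A", "B").theta, abs=1e-12
        )


class TestMafSpectrum:
    def test_direct_count_and_folding(self):
        gt = np.array([[0, 2, 1], [0, 2, 2], [1, 2, 2]], dtype=np.int8)
        gm = make_gm(gt)
        popmap = two_pop_map(gm, 3, pop_a="P")
        maf = maf_spectrum(gm, popmap, "P").maf
        assert maf[0] == pytest.approx(1 / 6)
        assert maf[1] == 0.0                      # fixed alt folds to 0
        assert maf[2] == pytest.approx(1 / 6)     # alt freq 5/6 folds

    def test_bounds(self):
        rng = np.random.default_rng(8)
        gt = rng.integers(0, 3, size=(9, 80)).astype(np.int8)
        gm = make_gm(gt)
        maf = maf_spectrum(gm, two_pop_map(gm, 9, pop_a="P"), "P").maf
        assert (maf >= 0).all() and (maf <= 0.5).all()


class TestRecoveryFromSynthetic:
    def test_hobs_matches_hexp_without_degradation(self):
        """Under clean Hardy-Weinberg sampling the mean observed and
        expected heterozygosities agree within sampling error."""
        truth = simulate_truth(400, [5000], founder_beta=(2, 2), seed=6)
        gm, popmap = sample_genotypes(
            truth, [SampleDesign("P", era="historical", n=40)], seed=7
        )
        d = population_diversity(gm, popmap, "P")
        diff = d["mean_h_obs"] - d["mean_h_exp"]
        se = np.std(d["h_obs"] - d["h_exp"]) / np.sqrt(len(d["h_obs"]))
        assert abs(diff) < 3 * se + 1e-9

    def test_dropout_depresses_hobs_below_hexp(self):
        truth = simulate_truth(400, [5000], founder_beta=(2, 2), seed=6)
        gm, popmap = sample_genotypes(
            truth, [SampleDesign("P", era="historical", n=40)], seed=7
        )
        profile = DegradationProfile(
            museum_missing_mean=0.0, museum_missing_sd=0.0,
            fresh_missing_mean=0.0, fresh_missing_sd=0.0,
            dropout_prob=0.4, false_het_rate=0.0,
        )
        deg = degrade(gm, profile, seed=8)
        d = population_diversity(deg, popmap, "P")
        assert d["mean_h_obs"] < d["mean_h_exp"]
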