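import numpy as np
import pandas as pd
import pytest

from oracles import hwe_midp_enumeration, mendelian_impossible_set

from founder_enrich.io_formats import MISSING, GenotypeMatrix, Pedigree, read_bed
from founder_enrich.qc import (
    QCConfig,
    allele_balance_mask,
    depth_mask,
    hwe_midp,
    intersect_targets,
    kinship_matrix,
    mendelian_error_mask,
    select_unrelated,
    variant_filters,
)
from founder_enrich.simdata import simulate_genotypes


def _one_het(ad_ref, ad_alt, dosage=1):
    variants = pd.DataFrame({"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"]})
    return GenotypeMatrix(
        samples=["S1"],
        variants=variants,
        dosage=np.array([[dosage]], dtype=np.int8),
        depth=np.array([[ad_ref + ad_alt]], dtype=np.int32),
        ad_ref=np.array([[ad_ref]], dtype=np.int32),
        ad_alt=np.array([[ad_alt]], dtype=np.int32),
    )


class TestAlleleBalance:
    @pytest.mark.parametrize(
        "ad_ref,ad_alt,kept",
        [
            (5, 5, True),    # AB = 0.50
            (9, 1, False),   # AB = 0.10 < 0.30
            (7, 3, True),    # AB = 0.30, inclusive boundary
            (3, 7, True),    # AB = 0.70, inclusive boundary
            (2, 8, False),   # AB = 0.80 > 0.70
        ],
    )
    def test_het_boundaries(self, ad_ref, ad_alt, kept):
        out = allele_balance_mask(_one_het(ad_ref, ad_alt))
        assert (out.dosage[0, 0] == 1) == kept

    def test_homozygotes_untouched(self):
        out = allele_balance_mask(_one_het(1, 29, dosage=2))
        assert out.dosage[0, 0] == 2

    def test_het_without_ad_errors_unless_allowed(self):
        gm = _one_het(5, 5)
        gm.ad_ref = gm.ad_alt = None
        with pytest.raises(ValueError, match="AD"):
            allele_balance_mask(gm)
        out = allele_balance_mask(gm, QCConfig(ad_required=False))
        assert out.dosage[0, 0] == 1


class TestDepthMask:
    @pytest.mark.parametrize("dp,kept", [(10, True), (9, False), (40, True)])
    def test_boundary(self, dp, kept):
        gm = _one_het(dp // 2, dp - dp // 2)
        out = depth_mask(gm)
        assert (out.dosage[0, 0] == 1) == kept

    def test_absent_dp_configurable(self):
        gm = _one_het(5, 5)
        gm.depth = None
        assert depth_mask(gm).dosage[0, 0] == 1
        assert depth_mask(gm, QCConfig(depth_required=True)).dosage[0, 0] == MISSING


class TestMendelianMask:
    def _trio_gm(self, f, m, c):
        variants = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"]})
        return GenotypeMatrix(
            samples=["dad", "mom", "kid"],
            variants=variants,
            dosage=np.array([[f], [m], [c]], dtype=np.int8),
        )

    def test_flagged_set_equals_exhaustive_enumeration(self, trio_pedigree):
        """The 27 parent-parent-child dosage combinations flag exactly the
        Mendelian-impossible set."""
        impossible = mendelian_impossible_set()
        for f in range(3):
            for m in range(3):
                for c in range(3):
                    gm = self._trio_gm(f, m, c)
                    masked, errors = mendelian_error_mask(gm, trio_pedigree)
                    flagged = len(errors) == 1
                    assert flagged == ((f, m, c) in impossible), (f, m, c)
                    if flagged:
                        assert (masked.dosage == MISSING).all()
                    else:
                        np.testing.assert_array_equal(masked.dosage, gm.dosage)

    def test_missing_member_not_assessed(self, trio_pedigree):
        gm = self._trio_gm(0, 0, 1)
        gm.dosage[0, 0] = MISSING
        _, errors = mendelian_error_mask(gm, trio_pedigree)
        assert errors.empty


class TestHweMidp:
    def test_monomorphic_is_one(self):
        assert hwe_midp(50, 0, 0) == 1.0
        assert hwe_midp(0, 0, 50) == 1.0

    def test_symmetric_under_label_swap(self):
        assert hwe_midp(12, 5, 3) == pytest.approx(hwe_midp(3, 5, 12), abs=1e-15)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_midp(-1, 2, 3)

    def test_matches_exact_enumeration_on_random_grid(self):
        """Mid-p agrees with the exact-rational enumeration oracle to 1e-12
        over a randomized grid of count triples."""
        rng = np.random.default_rng(17)
        for _ in range(300):
            n_AA, n_Aa, n_aa = rng.integers(0, 60, size=3)
            if n_AA + n_Aa + n_aa == 0:
                continue
            expected = hwe_midp_enumeration(int(n_AA), int(n_Aa), int(n_aa))
            assert hwe_midp(int(n_AA), int(n_Aa), int(n_aa)) == pytest.approx(
                expected, abs=1e-12
            )


class TestVariantFilters:
    def _gm_with_missingness(self, n_missing, n_samples=100):
        # HWE-exact genotype pattern at p=0.5 (1:2:1), so only missingness bites
        dosage = np.tile([0, 1, 1, 2], n_samples // 4 + 1)[:n_samples]
        dosage = dosage.astype(np.int8).reshape(n_samples, 1)
        dosage[:n_missing, 0] = MISSING
        variants = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"]})
        return GenotypeMatrix(samples=[f"S{i}" for i in range(n_samples)],
                              variants=variants, dosage=dosage)

    def test_missingness_boundary_inclusive(self):
        kept, _ = variant_filters(self._gm_with_missingness(5))
        assert kept.n_variants == 1  # exactly 5% is kept
        dropped, report = variant_filters(self._gm_with_missingness(6))
        assert dropped.n_variants == 0
        assert report["dropped_missingness"] == 1

    def test_hwe_filter_drops_extreme_heterozygote_excess(self):
        variants = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"]})
        gm = GenotypeMatrix(samples=[f"S{i}" for i in range(100)],
                            variants=variants,
                            dosage=np.ones((100, 1), dtype=np.int8))
        out, report = variant_filters(gm)
        assert report["dropped_hwe"] == 1
        assert out.n_variants == 0

    def test_target_padding_boundary(self):
        variants = pd.DataFrame({
            "chrom": ["1", "1"], "pos": [250, 251],
            "ref": ["A", "A"], "alt": ["G", "G"]})
        dosage = np.tile(np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8), (10, 1))
        gm = GenotypeMatrix(samples=[f"S{i}" for i in range(30)],
                            variants=variants, dosage=dosage)
        targets = intersect_targets(
            [pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]})], pad=50)
        out, report = variant_filters(gm, targets=targets)
        # 200 + 50 = 250 is in; 251 is out
        assert out.variants["pos"].tolist() == [250]
        assert report["dropped_off_target"] == 1

    def test_filters_idempotent_and_leave_dosages_untouched(self):
        gm = simulate_genotypes(np.random.default_rng(0).uniform(0.05, 0.5, 50),
                                200, 1, missing_rate=0.03)
        once, _ = variant_filters(gm)
        twice, report = variant_filters(once)
        assert twice.n_variants == once.n_variants
        assert report["n_kept"] == report["n_input"]
        kept_keys = set(once.keys())
        idx = [i for i, k in enumerate(gm.keys()) if k in kept_keys]
        np.testing.assert_array_equal(once.dosage, gm.dosage[:, idx])


class TestTargetIntersection:
    def test_intersection_of_two_kits(self):
        kit1 = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [500]})
        kit2 = pd.DataFrame({"chrom": ["1"], "start": [300], "end": [800]})
        merged = intersect_targets([kit1, kit2], pad=0)
        assert merged[["start", "end"]].iloc[0].tolist() == [300, 500]

    def test_bed_read_feeds_intersection(self, tmp_path):
        path = tmp_path / "k.bed"
        path.write_text("1\t99\t500\n")
        merged = intersect_targets([read_bed(path)], pad=50)
        assert merged[["start", "end"]].iloc[0].tolist() == [50, 550]


class TestSelectUnrelated:
    def test_all_unrelated_returns_full_set(self):
        gm = simulate_genotypes(
            np.random.default_rng(2).uniform(0.1, 0.5, 3000), 40, 3)
        kept = select_unrelated(gm, variant_idx=np.arange(gm.n_variants))
        assert kept == gm.samples

    def test_duplicated_sample_pair_breaks_exactly_one(self):
        gm = simulate_genotypes(
            np.random.default_rng(4).uniform(0.1, 0.5, 3000), 20, 5)
        gm.dosage[1] = gm.dosage[0]  # duplicate pair (S00000, S00001)
        kept = select_unrelated(gm, variant_idx=np.arange(gm.n_variants))
        assert len(kept) == 19
        assert ("S00000" in kept) != ("S00001" in kept)

    def test_sib_pairs_broken_unrelateds_retained(self):
        """Simulated sib pairs (kinship ~0.25) are all broken while >= 95%
        of unrelated samples survive the pruning."""
        rng = np.random.default_rng(6)
        freq = rng.uniform(0.1, 0.5, 5000)
        n_pairs, n_unrel = 40, 120
        parents = rng.binomial(2, freq, size=(2 * n_pairs, 2, len(freq)))

        def child(pair_rng, pa, ma):
            t_f = np.where(pa == 1, pair_rng.integers(0, 2, len(freq)), pa // 2)
            t_m = np.where(ma == 1, pair_rng.integers(0, 2, len(freq)), ma // 2)
            return t_f + t_m

        rows, names = [], []
        for i in range(n_pairs):
            pa, ma = parents[2 * i]
            for j in range(2):
                rows.append(child(rng, pa, ma))
                names.append(f"SIB{i:03d}_{j}")
        rows.append(rng.binomial(2, freq, size=(n_unrel, len(freq))))
        names += [f"UNR{i:03d}" for i in range(n_unrel)]
        dosage = np.vstack([np.asarray(rows[:-1]), rows[-1]]).astype(np.int8)
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, len(freq) + 1) * 1000,
            "ref": "A", "alt": "G"})
        gm = GenotypeMatrix(samples=names, variants=variants, dosage=dosage)

        K = kinship_matrix(gm)
        sib_k = np.mean([K[2 * i, 2 * i + 1] for i in range(n_pairs)])
        assert sib_k == pytest.approx(0.25, abs=0.03)

        kept = set(select_unrelated(gm, variant_idx=np.arange(len(freq))))
        for i in range(n_pairs):
            assert not {f"SIB{i:03d}_0", f"SIB{i:03d}_1"} <= kept
        n_unrel_kept = sum(1 for s in kept if s.startswith("UNR"))
        assert n_unrel_kept >= 0.95 * n_unrel
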