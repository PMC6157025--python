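"""Genotype readers and marker QC (frequencies, HWE, LD pruning)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinherit as kh
from kinherit.genotype import GenotypeMatrix


def _tiny_matrix(dosages, chrom=None):
    n, m = np.asarray(dosages).shape
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom or ["1"] * m,
        "pos": np.arange(1, m + 1),
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps,
                          np.asarray(dosages, float))


class TestReaders:
    def test_ped_map_hand_fixture(self, tmp_path):
        (tmp_path / "toy.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "toy.ped").write_text(
            "f1 s1 0 0 1 -9 A A G G\n"
            "f1 s2 0 0 2 -9 A G G T\n"
            "f1 s3 0 0 1 -9 G G 0 0\n")
        g = kh.read_genotypes(tmp_path / "toy.ped", format="ped")
        assert g.sample_ids == ["s1", "s2", "s3"]
        # rs1: minor allele G -> dosages 0,1,2; rs2: minor T -> 0,1,missing
        np.testing.assert_array_equal(g.dosages[:, 0], [0, 1, 2])
        assert g.dosages[0, 1] == 0 and g.dosages[1, 1] == 1
        assert np.isnan(g.dosages[2, 1])

    def test_ped_sample_column_mismatch(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "bad.ped").write_text("f1 s1 0 0 1 -9 A A\n")
        with pytest.raises(ValueError, match="MAP declares"):
            kh.read_genotypes(tmp_path / "bad.ped", format="ped")

    def test_non_acgt_allele_rejected(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 rs1 0 100\n")
        (tmp_path / "bad.ped").write_text("f1 s1 0 0 1 -9 A X\n")
        with pytest.raises(ValueError, match="non-ACGT"):
            kh.read_genotypes(tmp_path / "bad.ped", format="ped")

    def test_vcf_multiallelic_skipped(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        header = ("##fileformat=VCFv4.2\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                  "##contig=<ID=1>\n"
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n")
        rows = [f"1\t{100 * (j + 1)}\trs{j}\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
                for j in range(4)]
        rows.insert(2, "1\t250\trsX\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\n")
        vcf.write_text(header + "".join(rows))
        g = kh.read_genotypes(vcf, format="vcf")
        assert g.n_snps == 4
        assert g.n_skipped == 1
        np.testing.assert_array_equal(g.dosages[0], [1, 1, 1, 1])

    def test_dosage_table_roundtrip_from_simulation(self, tmp_path,
                                                    small_study):
        _, _, geno, _ = small_study
        geno.write_dosage_table(tmp_path / "g")
        back = kh.read_genotypes(tmp_path / "g.tsv", format="dosage")
        assert back.sample_ids == geno.sample_ids
        pd.testing.assert_frame_equal(back.snps, geno.snps)
        np.testing.assert_allclose(back.dosages, geno.dosages)

    def test_ped_map_roundtrip_from_simulation(self, tmp_path):
        cfg = kh.SimulationConfig(n_families=3, n_snps=50, maf_low=0.2,
                                  maf_high=0.4, seed=13)
        _, geno, _ = kh.simulate_study(cfg)
        geno.write_ped_map(tmp_path / "g")
        back = kh.read_genotypes(tmp_path / "g.ped", format="ped")
        # dosages agree up to allele coding; minor-allele convention may flip
        for j in range(geno.n_snps):
            a, b = geno.dosages[:, j], back.dosages[:, j]
            assert np.allclose(a, b) or np.allclose(a, 2 - b)


class TestAlleleFrequencies:
    @pytest.mark.parametrize("col,expected", [
        ([0, 1, 2], 0.5),
        ([0, 0, 0], 0.0),
        ([2, 2, np.nan], 1.0),
    ])
    def test_hand_cases(self, col, expected):
        g = _tiny_matrix(np.array(col, dtype=float)[:, None])
        assert kh.allele_frequencies(g)[0] == pytest.approx(expected)

    def test_all_missing_snp_flagged_nan(self):
        g = _tiny_matrix([[0, np.nan], [1, np.nan]])
        f = kh.allele_frequencies(g)
        assert f[0] == pytest.approx(0.25) and np.isnan(f[1])

    def test_gene_drop_frequencies_converge(self):
        """Founder draws at 2,000 samples reproduce the input frequencies."""
        rows = [("1", str(i), None, None, "M") for i in range(2000)]
        ped = kh.Pedigree(pd.DataFrame(
            rows, columns=["family_id", "individual_id", "father_id",
                           "mother_id", "sex"]))
        freqs = np.array([0.1, 0.3, 0.5])
        g = kh.gene_drop(ped, freqs, seed=3)
        est = kh.allele_frequencies(g)
        se = np.sqrt(freqs * (1 - freqs) / (2 * 2000))
        assert np.all(np.abs(est - freqs) < 3 * se + 1e-9)


class TestHWE:
    @pytest.mark.parametrize("counts,expected,tol", [
        ((25, 50, 25), 1.0, 1e-12),        # exact HWE proportions
        ((30, 40, 30), 0.0455, 2e-4),      # chi2 = 4 by hand
        ((100, 0, 0), 1.0, 1e-12),         # monomorphic convention
    ])
    def test_hand_cases(self, counts, expected, tol):
        assert kh.hwe_test(*counts) == pytest.approx(expected, abs=tol)

    def test_complete_het_deficit_is_extreme(self):
        assert kh.hwe_test(50, 0, 50) < 1e-20

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            kh.hwe_test(0, 0, 0)

    @given(st.tuples(st.integers(0, 400), st.integers(0, 400),
                     st.integers(0, 400)).filter(lambda c: sum(c) > 0))
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval_and_symmetric(self, counts):
        p = kh.hwe_test(*counts)
        assert 0 < p <= 1
        # swapping which homozygote is 'ref' cannot change the test
        assert p == pytest.approx(kh.hwe_test(counts[2], counts[1], counts[0]))


class TestLDPrune:
    def test_duplicate_column_pruned_to_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50).astype(float)
        g = _tiny_matrix(np.column_stack([col, col]))
        assert len(kh.ld_prune(g, 10, 1, 0.1)) == 1

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(1)
        g = _tiny_matrix(rng.binomial(2, 0.4, size=(300, 40)).astype(float))
        kept = kh.ld_prune(g, 40, 5, 0.5)
        assert kept == g.snps["snp_id"].tolist()

    def test_output_is_subset(self, small_study):
        _, _, geno, _ = small_study
        kept = kh.ld_prune(geno, 200, 10, 0.2)
        assert 0 < len(kept) <= geno.n_snps
        assert set(kept) <= set(geno.snps["snp_id"])

    def test_idempotent(self, small_study):
        # window spanning the panel: re-pruning the survivors is a no-op
        _, _, geno, _ = small_study
        kept = kh.ld_prune(geno, geno.n_snps, 10, 0.2)
        again = kh.ld_prune(geno.subset_snps(kept), geno.n_snps, 10, 0.2)
        assert sorted(again) == sorted(kept)

    def test_block_ld_standard_parameters(self):
        """Pruning a 5,000-SNP block-LD chromosome with the conventional
        (2000, 10, 0.1) settings leaves no within-window pair above r²=0.1."""
        cfg = kh.SimulationConfig(n_families=8, n_snps=5000, maf_low=0.2,
                                  maf_high=0.4, ld_rho=0.9, seed=17)
        ped = kh.simulate_pedigree(cfg)
        rng = np.random.default_rng(17)
        freqs = np.repeat(rng.uniform(0.2, 0.4, size=500), 10)  # constant-p blocks
        geno = kh.gene_drop(ped, freqs, seed=18, ld_rho=0.9)
        kept = kh.ld_prune(geno, 2000, 10, 0.1)
        assert 0 < len(kept) < geno.n_snps
        sub = geno.subset_snps(kept)
        z = sub.dosages - sub.dosages.mean(axis=0)
        z /= np.maximum(z.std(axis=0), 1e-12)
        r2 = (z.T @ z / sub.n_samples) ** 2
        np.fill_diagonal(r2, 0.0)
        # the guarantee applies to pairs within a window of each other
        order = {s: i for i, s in enumerate(geno.snps["snp_id"])}
        kept_pos = np.array([order[s] for s in sub.snps["snp_id"]])
        within = np.abs(kept_pos[:, None] - kept_pos[None, :]) < 2000
        assert r2[within].max() <= 0.1 + 1e-9

    def test_parameter_validation(self, small_study):
        _, _, geno, _ = small_study
        with pytest.raises(ValueError):
            kh.ld_prune(geno, 5, 10, 0.1)
        with pytest.raises(ValueError):
            kh.ld_prune(geno, 10, 5, 0.0)
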