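"""Measured genotype association: OLS reduction, thresholds, plot series."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import kinherit as kh
from kinherit.kinship import KinshipMatrix


@pytest.fixture(scope="module")
def prepared(small_study, small_kinship):
    _, ped, geno, pheno = small_study
    y = kh.inverse_normal(
        kh.residualize(kh.average_visits(pheno, "trait", "pre"), pheno))
    return ped, geno, y


class TestOLSReduction:
    def test_identity_kinship_equals_ols_lrt(self):
        """Without relatedness the mixed model collapses to regression:
        per-SNP p-values agree with a plain OLS likelihood-ratio test."""
        rng = np.random.default_rng(51)
        n, m = 200, 40
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        snps = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)],
                             "chrom": "1", "pos": np.arange(1, m + 1),
                             "ref": "A", "alt": "G"})
        ids = [str(i) for i in range(n)]
        geno = kh.GenotypeMatrix(ids, snps, dos)
        k = KinshipMatrix(ids, np.eye(n))
        scan = kh.mga_scan(pd.Series(y, index=ids), geno, k, mode="exact")
        null = sm.OLS(y, np.ones((n, 1))).fit()
        for row in scan.table.itertuples():
            j = int(row.snp_id[1:])
            x = sm.add_constant(dos[:, j])
            full = sm.OLS(y, x).fit()
            lrt = 2 * (full.llf - null.llf)
            p_ols = stats.chi2.sf(lrt, df=1)
            assert row.p == pytest.approx(p_ols, abs=1e-6)
            assert row.beta == pytest.approx(full.params[1], abs=1e-8)


class TestScan:
    def test_dosage_flip_negates_beta(self, prepared, small_kinship):
        _, geno, y = prepared
        sub = geno.subset_snps(geno.snps["snp_id"][:30])
        from dataclasses import replace
        flipped_snps = sub.snps.copy()
        flipped_snps[["ref", "alt"]] = flipped_snps[["alt", "ref"]].to_numpy()
        flipped = kh.GenotypeMatrix(sub.sample_ids, flipped_snps,
                                    2.0 - sub.dosages)
        a = kh.mga_scan(y, sub, small_kinship, mode="fast")
        b = kh.mga_scan(y, flipped, small_kinship, mode="fast")
        np.testing.assert_allclose(a.table["beta"].to_numpy(),
                                   -b.table["beta"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(a.table["p"].to_numpy(),
                                   b.table["p"].to_numpy(), atol=1e-10)

    def test_monomorphic_snp_skipped(self, prepared, small_kinship):
        _, geno, y = prepared
        sub = geno.subset_snps(geno.snps["snp_id"][:10])
        d = sub.dosages.copy()
        d[:, 3] = 0.0
        mono = kh.GenotypeMatrix(sub.sample_ids, sub.snps, d)
        scan = kh.mga_scan(y, mono, small_kinship, mode="fast")
        skipped = scan.skipped
        assert sub.snps.at[3, "snp_id"] in set(skipped["snp_id"])
        assert (skipped.set_index("snp_id").loc[sub.snps.at[3, "snp_id"],
                                                "reason"] == "monomorphic")

    def test_exact_and_fast_agree_on_null_scan(self):
        # study scale: with ~800 samples the null variance components are
        # well determined and the fast path tracks per-SNP re-estimation
        cfg = kh.SimulationConfig(n_families=60, n_snps=400, seed=53)
        ped, geno, pheno = kh.simulate_study(cfg)
        k = kh.pedigree_kinship(ped)
        y = kh.inverse_normal(
            kh.residualize(kh.average_visits(pheno, "trait", "pre"), pheno))
        ex = kh.mga_scan(y, geno, k, mode="exact")
        fa = kh.mga_scan(y, geno, k, mode="fast")
        d = np.abs(np.log10(ex.table["p"].to_numpy())
                   - np.log10(fa.table["p"].to_numpy()))
        assert d.max() < 0.1

    def test_all_snps_filtered_errors(self, prepared, small_kinship):
        _, geno, y = prepared
        sub = geno.subset_snps(geno.snps["snp_id"][:5])
        with pytest.raises(ValueError, match="no SNPs pass"):
            kh.mga_scan(y, sub, small_kinship, maf_min=0.51)


class TestThresholds:
    def test_conventional_genomewide_cut(self):
        t = kh.AssociationTable(
            table=pd.DataFrame({"p": [5e-9, 5e-6, 1e-3],
                                "statistic": [34, 21, 11]}),
            n=800, mode="fast", h2_null=0.4)
        out = kh.apply_thresholds(t, alpha=0.05, m=718_407)
        assert out.bonferroni_threshold == pytest.approx(6.96e-8, rel=1e-3)
        assert out.table["significant"].tolist() == [True, False, False]
        assert out.table["suggestive"].tolist() == [True, True, False]

    def test_single_test_threshold_is_alpha(self):
        t = kh.AssociationTable(
            table=pd.DataFrame({"p": [0.04], "statistic": [4.2]}),
            n=100, mode="fast", h2_null=0.0)
        out = kh.apply_thresholds(t, alpha=0.05, m=1)
        assert out.bonferroni_threshold == 0.05
        assert out.table["significant"].all()

    def test_significant_implies_suggestive(self):
        t = kh.AssociationTable(
            table=pd.DataFrame({"p": [1e-30], "statistic": [130.0]}),
            n=100, mode="fast", h2_null=0.0)
        out = kh.apply_thresholds(t, alpha=0.05, m=10)
        assert (~out.table["significant"] | out.table["suggestive"]).all()

    def test_invalid_alpha(self):
        t = kh.AssociationTable(table=pd.DataFrame({"p": [0.5]}),
                                n=10, mode="fast", h2_null=0.0)
        with pytest.raises(ValueError):
            kh.apply_thresholds(t, alpha=1.5)


class TestPlotData:
    def _table(self, ps, chroms=None):
        m = len(ps)
        return kh.AssociationTable(
            table=pd.DataFrame({
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": chroms or ["1"] * m,
                "pos": np.arange(1, m + 1),
                "p": ps,
                "statistic": stats.chi2.isf(ps, df=1),
            }), n=100, mode="fast", h2_null=0.0)

    def test_uniform_p_on_diagonal(self):
        rng = np.random.default_rng(52)
        t = self._table(rng.uniform(size=4000))
        series = kh.plot_data(t)
        assert series["lambda"] == pytest.approx(1.0, abs=0.05)
        qq = series["qq"]
        assert np.corrcoef(qq["expected"], qq["observed"])[0, 1] > 0.99

    def test_peak_at_top_snp(self):
        ps = [0.5, 0.2, 1e-9, 0.7]
        t = self._table(ps, chroms=["1", "1", "2", "2"])
        series = kh.plot_data(t)
        man = series["manhattan"]
        top = man.loc[man["neglog10_p"].idxmax()]
        assert top["snp_id"] == "s2"
        assert set(man["color_index"]) == {0, 1}

    def test_empty_table_rejected(self):
        t = kh.AssociationTable(table=pd.DataFrame(), n=0, mode="fast",
                                h2_null=0.0)
        with pytest.raises(ValueError):
            kh.plot_data(t)
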