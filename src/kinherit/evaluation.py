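"""Study-condition evaluation runs.

Each function here sets up a synthetic study at the scale the package
targets (60 three-generation families, ~840 phenotyped individuals,
GOLDN-like), runs one analysis pipeline end to end, and returns summary
numbers. They back both the acceptance test suite and the
``scripts/acceptance.py`` reporting script, so the measured quantities
are computed one way only.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import numpy as np

from .empirical import grm, postprocess_kinship
from .genotype import allele_frequencies
from .kinship import KinshipMatrix
from .pedigree import pedigree_kinship
from .phenotype import average_visits, inverse_normal, residualize
from .polygenic import KinshipEigen, fit_polygenic
from .relatedness import moment_ibd_pairs, pedigree_discordance
from .simulate import (SimulationConfig, gene_drop, gene_drop_ibd,
                       random_pedigree, simulate_pedigree, simulate_study,
                       simulate_trait)

__all__ = [
    "bonferroni_threshold", "kinship_oracle_check", "h2_recovery",
    "lrt_calibration", "kinship_concordance", "mga_null_calibration",
    "mga_qtl_power", "relationship_screen", "postprocess_contract",
    "ols_reduction_check",
]

#: SNP panel size reported for the array data the pipeline targets
GENOMEWIDE_M = 718_407


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _prepare(pheno, phase: str = "pre"):
    y = average_visits(pheno, "trait", phase)
    return inverse_normal(residualize(y, pheno))


def bonferroni_threshold(alpha: float = 0.05, m: int = GENOMEWIDE_M) -> float:
    """Family-wise genome-wide significance cut α/m."""
    return alpha / m


def kinship_oracle_check(seed: int, n_pedigrees: int = 10,
                         n_drops: int = 20_000) -> dict:
    """Recursive kinship vs Monte-Carlo gene dropping on random pedigrees.

    Returns the largest entrywise |recursion − MC| expressed in MC
    standard errors, and the fraction of entries within 3 SE.
    """
    seeds = _seeds(seed, 2 * n_pedigrees)
    worst = 0.0
    n_entries = n_within = 0
    for p in range(n_pedigrees):
        ped = random_pedigree(max_members=20, seed=seeds[2 * p])
        k = pedigree_kinship(ped).values
        est, se = gene_drop_ibd(ped, n_drops=n_drops, seed=seeds[2 * p + 1])
        diff = np.abs(est - k)
        exact = se == 0
        assert np.all(diff[exact] < 1e-12)
        z = diff[~exact] / se[~exact]
        if z.size:
            worst = max(worst, float(z.max()))
        n_entries += diff.size
        n_within += int(np.sum(diff <= 3 * se + 1e-12))
    return {"max_z": worst, "fraction_within_3se": n_within / n_entries,
            "n_entries": n_entries}


def h2_recovery(seed: int, true_h2: float, n_replicates: int = 100,
                n_families: int = 60) -> dict:
    """Heritability recovery at study scale.

    Simulates the full phenotype pipeline (visit averaging, covariate
    residualization, inverse-normalization) per replicate and refits
    with the pedigree kinship; reports the mean estimate, empirical SD,
    and the mean delta-method SE over non-boundary fits.
    """
    cfg = SimulationConfig(n_families=n_families, true_h2=true_h2, seed=seed)
    ped = simulate_pedigree(cfg)
    k = pedigree_kinship(ped)
    eig = KinshipEigen.from_kinship(k)
    vals, vecs = np.linalg.eigh(k.values)
    ksqrt = vecs * np.sqrt(np.clip(vals, 0, None))
    ests, ses = [], []
    for s in _seeds(seed, n_replicates):
        ph = simulate_trait(ped, k, cfg, k_sqrt=ksqrt, seed=s)
        fit = fit_polygenic(_prepare(ph), k=k, eig=eig)
        ests.append(fit.h2)
        if not fit.boundary:
            ses.append(fit.h2_se)
    ests = np.array(ests)
    return {"true_h2": true_h2, "mean_h2": float(ests.mean()),
            "bias": float(ests.mean() - true_h2),
            "empirical_se": float(ests.std(ddof=1)),
            "mean_model_se": float(np.mean(ses)) if ses else float("nan"),
            "se_ratio": (float(np.mean(ses) / ests.std(ddof=1))
                         if ses else float("nan")),
            "n_replicates": n_replicates}


def lrt_calibration(seed: int, n_replicates: int = 1000,
                    n_families: int = 60, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the ½χ²₀+½χ²₁ boundary LRT under h²=0."""
    cfg = SimulationConfig(n_families=n_families, true_h2=0.0, seed=seed)
    ped = simulate_pedigree(cfg)
    k = pedigree_kinship(ped)
    eig = KinshipEigen.from_kinship(k)
    vals, vecs = np.linalg.eigh(k.values)
    ksqrt = vecs * np.sqrt(np.clip(vals, 0, None))
    rejections = 0
    for s in _seeds(seed + 1, n_replicates):
        ph = simulate_trait(ped, k, cfg, k_sqrt=ksqrt, seed=s)
        fit = fit_polygenic(_prepare(ph), k=k, eig=eig)
        rejections += fit.p_value <= alpha
    return {"type_i_error": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


def kinship_concordance(seed: int, n_replicates: int = 50,
                        n_families: int = 60, n_snps: int = 10_000,
                        true_h2: float = 0.5) -> dict:
    """ĥ² under the pedigree matrix vs under a postprocessed GRM.

    Each replicate simulates fresh genotypes and a fresh trait on the
    same pedigree, then fits the same prepared trait twice. Reports the
    mean |difference| of the paired estimates.
    """
    cfg = SimulationConfig(n_families=n_families, n_snps=n_snps,
                           true_h2=true_h2, seed=seed)
    ped = simulate_pedigree(cfg)
    k_ped = pedigree_kinship(ped)
    eig_ped = KinshipEigen.from_kinship(k_ped)
    vals, vecs = np.linalg.eigh(k_ped.values)
    ksqrt = vecs * np.sqrt(np.clip(vals, 0, None))
    gaps = []
    rng = np.random.default_rng(seed)
    for s in _seeds(seed + 2, n_replicates):
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, n_snps)
        geno = gene_drop(ped, freqs, seed=s)
        k_emp = postprocess_kinship(grm(geno).kinship)
        ph = simulate_trait(ped, k_ped, cfg, k_sqrt=ksqrt, seed=s + 1)
        y = _prepare(ph)
        fit_p = fit_polygenic(y, k=k_ped, eig=eig_ped)
        fit_e = fit_polygenic(y, k=k_emp)
        gaps.append(abs(fit_p.h2 - fit_e.h2))
    gaps = np.array(gaps)
    return {"mean_abs_gap": float(gaps.mean()), "max_abs_gap": float(gaps.max()),
            "n_replicates": n_replicates, "n_snps": n_snps}


def mga_null_calibration(seed: int, n_families: int = 60,
                         n_snps: int = 5000, true_h2: float = 0.4,
                         mode: str = "exact") -> dict:
    """Genomic inflation λ of a null genome scan in the mixed model."""
    from .association import mga_scan

    cfg = SimulationConfig(n_families=n_families, n_snps=n_snps,
                           true_h2=true_h2, seed=seed)
    ped, geno, pheno = simulate_study(cfg)
    k = pedigree_kinship(ped)
    scan = mga_scan(_prepare(pheno), geno, k, mode=mode)
    return {"lambda": scan.genomic_inflation(), "n_snps": len(scan.table),
            "mode": mode}


def mga_qtl_power(seed: int, n_replicates: int = 150, n_families: int = 60,
                  n_snps: int = 5000, qtl_frac: float = 0.05,
                  true_h2: float = 0.4) -> dict:
    """Detection of a planted QTL explaining ``qtl_frac`` of variance.

    The QTL SNP should be the scan minimum, with β̂ within 2 SE of the
    generating per-allele effect; reports the rate at which both hold,
    plus each marginal rate. Genotypes, trait, and covariates are all
    redrawn per replicate, so the rates are marginal over the whole
    generative process. Effect recovery is judged on the residualized
    trait (the generation scale); scans use the fast path.
    """
    from .association import mga_scan

    qtl_index = n_snps // 2
    cfg = SimulationConfig(n_families=n_families, n_snps=n_snps,
                           true_h2=true_h2, qtl=(qtl_index, qtl_frac),
                           seed=seed)
    ped = simulate_pedigree(cfg)
    k = pedigree_kinship(ped)
    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(k.values)
    ksqrt = vecs * np.sqrt(np.clip(vals, 0, None))

    top_hits = covered = joint = 0
    for s in _seeds(seed + 3, n_replicates):
        freqs = rng.uniform(cfg.maf_low, cfg.maf_high, n_snps)
        geno = gene_drop(ped, freqs, seed=s)
        qtl_id = geno.snps.at[qtl_index, "snp_id"]
        dos = geno.dosages[:, qtl_index]
        beta_true = np.sqrt(qtl_frac) / dos.std()
        ph = simulate_trait(ped, k, cfg, genotypes=geno, k_sqrt=ksqrt,
                            seed=s + 1)
        y = residualize(average_visits(ph, "trait", "pre"), ph)
        scan = mga_scan(y, geno, k, mode="fast")
        tab = scan.table
        hit = tab.loc[tab["p"].idxmin(), "snp_id"] == qtl_id
        row = tab.set_index("snp_id").loc[qtl_id]
        cov = abs(row["beta"] - beta_true) <= 2 * row["beta_se"]
        top_hits += hit
        covered += cov
        joint += hit and cov
    return {"top_hit_rate": top_hits / n_replicates,
            "beta_coverage_rate": covered / n_replicates,
            "joint_rate": joint / n_replicates,
            "n_replicates": n_replicates}


def relationship_screen(seed: int, n_families: int = 60,
                        n_snps: int = 10_000) -> dict:
    """Planted-swap detection plus relationship classification accuracy.

    Swaps the genotypes of two individuals from different families,
    infers IBD for every within-family pair plus a cross-family
    unrelated sample, and checks (a) that the discordance report
    proposes exactly the swapped pair and (b) the classification
    accuracy for 1st-degree / 2nd-degree / unrelated pairs uninvolved
    in the swap.
    """
    rng = np.random.default_rng(seed)
    fam_a, fam_b = (rng.choice(n_families, size=2, replace=False) + 1)
    swap = (f"{fam_a}_{rng.integers(1, 15)}", f"{fam_b}_{rng.integers(1, 15)}")
    cfg = SimulationConfig(n_families=n_families, n_snps=n_snps,
                           planted_swap=swap, seed=seed)
    ped, geno, _ = simulate_study(cfg)
    freqs = allele_frequencies(geno)
    fam = dict(zip(ped.sample_ids, ped.table["family_id"]))
    ids = geno.sample_ids
    within = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
              if fam[a] == fam[b]]
    calls = moment_ibd_pairs(geno, within, freqs=freqs)
    report = pedigree_discordance(ped, calls)

    t = report.table
    clean = ~(t["id1"].isin(swap) | t["id2"].isin(swap))
    first = t["expected_class"].isin(["parent-offspring", "full-sibling"])
    second = t["expected_class"] == "2nd-degree"
    within_acc = t[clean & (first | second)]
    n_correct = int((within_acc["expected_class"]
                     == within_acc["inferred_class"]).sum())
    n_pairs = len(within_acc)

    # unrelated: sample cross-family pairs
    cross = []
    while len(cross) < 500:
        a, b = rng.choice(ids, size=2, replace=False)
        if fam[a] != fam[b] and a not in swap and b not in swap:
            cross.append((a, b))
    cross_calls = moment_ibd_pairs(geno, cross, freqs=freqs)
    n_correct += int((cross_calls["inferred_class"] == "unrelated").sum())
    n_pairs += len(cross)

    return {"proposed_exclusions": report.proposed_exclusions,
            "swapped": sorted(swap),
            "swap_detected_exactly":
                sorted(report.proposed_exclusions) == sorted(swap),
            "classification_accuracy": n_correct / n_pairs,
            "n_pairs_classified": n_pairs}


def postprocess_contract(seed: int, n_samples: int = 150,
                         n_snps: int = 2000) -> dict:
    """Postprocessing contract on a freshly estimated GRM.

    Checks unit diagonal, non-negativity, and idempotence; returns the
    measured worst-case deviations.
    """
    import pandas as pd

    from .pedigree import Pedigree

    rng = np.random.default_rng(seed)
    rows = [("1", str(i), None, None, "M") for i in range(n_samples)]
    ped = Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id",
                       "mother_id", "sex"]))
    geno = gene_drop(ped, rng.uniform(0.05, 0.5, n_snps), seed=seed + 1)
    post = postprocess_kinship(grm(geno).kinship)
    again = postprocess_kinship(post)
    return {
        "max_diag_deviation": float(np.max(np.abs(np.diag(post.values) - 1))),
        "min_entry": float(post.values.min()),
        "idempotence_gap": float(np.max(np.abs(post.values - again.values))),
        "n_negatives_zeroed": post.n_negatives_zeroed,
    }


def ols_reduction_check(seed: int, n: int = 200, n_snps: int = 50) -> dict:
    """Mixed-model scan vs plain OLS likelihood-ratio under no relatedness."""
    import pandas as pd
    import statsmodels.api as sm
    from scipy import stats

    from .association import mga_scan
    from .genotype import GenotypeMatrix

    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, n_snps),
                       size=(n, n_snps)).astype(float)
    y = rng.standard_normal(n)
    ids = [str(i) for i in range(n)]
    snps = pd.DataFrame({"snp_id": [f"s{j}" for j in range(n_snps)],
                         "chrom": "1", "pos": np.arange(1, n_snps + 1),
                         "ref": "A", "alt": "G"})
    geno = GenotypeMatrix(ids, snps, dos)
    k = KinshipMatrix(ids, np.eye(n))
    scan = mga_scan(pd.Series(y, index=ids), geno, k, mode="exact")
    null = sm.OLS(y, np.ones((n, 1))).fit()
    max_diff = 0.0
    for row in scan.table.itertuples():
        j = int(row.snp_id[1:])
        full = sm.OLS(y, sm.add_constant(dos[:, j])).fit()
        p_ols = float(stats.chi2.sf(2 * (full.llf - null.llf), df=1))
        max_diff = max(max_diff, abs(row.p - p_ols))
    return {"max_abs_p_diff": max_diff, "n": n, "n_snps_compared": len(scan.table)}
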