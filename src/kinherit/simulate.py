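"""Synthetic family study generator.

Emulates the structure the analysis modules assume: multi-generation
pedigrees, biallelic SNP genotypes transmitted by Mendelian gene
dropping, and quantitative traits with a specified narrow-sense
heritability, covariate effects, optional single-QTL effect, and
replicate visit measurements in a pre- and a post-intervention phase.

Every generator is a pure function of its configuration and seed.
Gene dropping doubles as the Monte-Carlo oracle for expected
relatedness: dropping distinct founder allele labels and counting
identity-by-descent sharing converges to the pedigree kinship.

Default scale — 60 three-generation families of 14 (840 individuals,
GOLDN-like) and 10,000 independent markers — runs in minutes on one
CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .kinship import KinshipMatrix
from .pedigree import Pedigree
from .phenotype import PhenotypeTable

__all__ = ["SimulationConfig", "simulate_pedigree", "random_pedigree",
           "gene_drop", "gene_drop_ibd", "simulate_trait", "simulate_study"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    The family template is three generations: a founding couple, their
    three offspring each married to an unrelated founder, and two
    grandchildren per couple — 14 members, 5 of them founders, so 60
    families give an 840-person study. Traits decompose the non-QTL
    variance as true_h2 : (1 − true_h2) between a polygenic and an
    i.i.d. environmental component; each of the 2+2 visit measurements
    adds independent noise with SD ``visit_noise_sd``. ``qtl`` plants a
    single additive variant explaining the given fraction of total
    variance. ``subpop_divergence`` splits founders into two
    populations with frequency divergence for stratification tests;
    ``planted_swap`` exchanges two individuals' genotype (not
    phenotype) rows, the classic sample-handling error.
    """

    n_families: int = 60
    n_snps: int = 10_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    true_h2: float = 0.4
    qtl: tuple[int, float] | None = None      # (snp index, variance fraction)
    age_slope: float = 0.01
    sex_difference: float = 0.25
    center_offsets: tuple[float, ...] = (0.0, 0.1, -0.1)
    smoking_effect: float = 0.2
    visit_noise_sd: float = 0.2
    post_shift: float = -0.5                  # intervention effect on the mean
    subpop_divergence: float | None = None
    planted_swap: tuple[str, str] | None = None
    trait_name: str = "trait"
    n_chrom: int = 1
    ld_rho: float | None = None               # adjacent-marker copying prob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        qtl_frac = self.qtl[1] if self.qtl else 0.0
        if not (0 <= self.true_h2 <= 1) or self.true_h2 + qtl_frac > 1:
            raise ValueError("infeasible variance budget: true_h2 + qtl fraction > 1")


FAMILY_SIZE = 14


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Three-generation families of the default template (deterministic)."""
    rows = []
    for f in range(1, cfg.n_families + 1):
        fam = str(f)
        def iid(k):
            return f"{fam}_{k}"
        rows.append((fam, iid(1), None, None, "M"))   # founding father
        rows.append((fam, iid(2), None, None, "F"))   # founding mother
        for c in range(3):                            # their 3 offspring
            child = iid(3 + c)
            sex = "M" if c % 2 == 0 else "F"
            rows.append((fam, child, iid(1), iid(2), sex))
            spouse = iid(6 + c)                       # married-in founder
            rows.append((fam, spouse, None, None, "F" if sex == "M" else "M"))
            father, mother = (child, spouse) if sex == "M" else (spouse, child)
            for gkid in range(2):                     # two grandchildren
                rows.append((fam, iid(9 + 2 * c + gkid), father, mother,
                             "M" if gkid == 0 else "F"))
    return Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id",
                       "mother_id", "sex"]))


def random_pedigree(max_members: int, seed: int, n_generations: int = 4,
                    family_id: str = "1") -> Pedigree:
    """A random irregular pedigree of at most ``max_members`` members.

    Grows generation by generation: every couple has 1–3 children, each
    child marries a new founder with probability ½ and the new couple
    can reproduce in the next generation. Useful as an arbitrary-shape
    input for Monte-Carlo relatedness checks.
    """
    rng = np.random.default_rng(seed)
    rows = [(family_id, "1", None, None, "M"), (family_id, "2", None, None, "F")]
    couples = [("1", "2")]
    counter = 2

    def new_id():
        nonlocal counter
        counter += 1
        return str(counter)

    for _ in range(n_generations - 1):
        next_couples = []
        for father, mother in couples:
            for _ in range(int(rng.integers(1, 4))):
                if len(rows) >= max_members - 1:
                    break
                child = new_id()
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((family_id, child, father, mother, sex))
                if rng.random() < 0.5 and len(rows) < max_members:
                    spouse = new_id()
                    rows.append((family_id, spouse, None, None,
                                 "F" if sex == "M" else "M"))
                    next_couples.append((child, spouse) if sex == "M"
                                        else (spouse, child))
        couples = next_couples
        if not couples or len(rows) >= max_members - 1:
            break
    return Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id",
                       "mother_id", "sex"]))


def _founder_haplotype(rng, freqs: np.ndarray, ld_rho: float | None) -> np.ndarray:
    m = len(freqs)
    hap = (rng.random(m) < freqs).astype(np.int8)
    if ld_rho:
        # haplotype copying: carry the previous allele forward with prob rho
        carry = rng.random(m) < ld_rho
        carry[0] = False
        for s in np.flatnonzero(carry):
            hap[s] = hap[s - 1]
    return hap


def _drop_haplotypes(ped: Pedigree, rng, founder_draw, m: int, dtype=np.int8):
    """Generic Mendelian drop; founder_draw(rng) yields one haplotype."""
    n = ped.n
    fa, mo = ped.father_index, ped.mother_index
    pat = np.empty((n, m), dtype=dtype)
    mat = np.empty_like(pat)
    for i in ped.topological_order:
        if fa[i] < 0:
            pat[i] = founder_draw(rng)
            mat[i] = founder_draw(rng)
        else:
            pick = rng.integers(0, 2, size=m).astype(bool)
            pat[i] = np.where(pick, pat[fa[i]], mat[fa[i]])
            pick = rng.integers(0, 2, size=m).astype(bool)
            mat[i] = np.where(pick, pat[mo[i]], mat[mo[i]])
    return pat, mat


def gene_drop(ped: Pedigree, freqs: np.ndarray, seed: int,
              ld_rho: float | None = None,
              n_chrom: int = 1,
              subpop_divergence: float | None = None) -> GenotypeMatrix:
    """Drop biallelic SNPs through the pedigree.

    Founder haplotypes are Hardy-Weinberg draws at ``freqs`` (optionally
    with adjacent-marker LD via haplotype copying, or with founders
    split into two diverged subpopulations); children inherit one
    uniformly chosen allele per parent per SNP. Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("founder frequencies must lie in (0, 1)")
    m = len(freqs)

    if subpop_divergence:
        # families alternate between two diverged founder populations
        delta = rng.normal(0, subpop_divergence, size=m)
        f_a = np.clip(freqs + delta / 2, 0.01, 0.99)
        f_b = np.clip(freqs - delta / 2, 0.01, 0.99)
        fam_of = ped.table["family_id"].to_numpy()
        fam_pop = {f: i % 2 for i, f in enumerate(ped.families)}
        pat = np.empty((ped.n, m), dtype=np.int8)
        mat = np.empty_like(pat)
        fa, mo = ped.father_index, ped.mother_index
        for i in ped.topological_order:
            if fa[i] < 0:
                f = f_a if fam_pop[fam_of[i]] == 0 else f_b
                pat[i] = (rng.random(m) < f).astype(np.int8)
                mat[i] = (rng.random(m) < f).astype(np.int8)
            else:
                pick = rng.integers(0, 2, size=m).astype(bool)
                pat[i] = np.where(pick, pat[fa[i]], mat[fa[i]])
                pick = rng.integers(0, 2, size=m).astype(bool)
                mat[i] = np.where(pick, pat[mo[i]], mat[mo[i]])
    else:
        draw = lambda r: _founder_haplotype(r, freqs, ld_rho)
        pat, mat = _drop_haplotypes(ped, rng, draw, m)

    dosages = (pat + mat).astype(float)
    per_chrom = int(np.ceil(m / n_chrom))
    chroms = [str(1 + j // per_chrom) for j in range(m)]
    pos = [1000 * (j % per_chrom) + 1 for j in range(m)]
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + 1 + rng.integers(0, 3, size=m)) % 4
    snps = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(m)],
        "chrom": chroms, "pos": pos,
        "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
    })
    return GenotypeMatrix(ped.sample_ids, snps, dosages)


def gene_drop_ibd(ped: Pedigree, n_drops: int, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo relatedness: mean realized IBD sharing over drops.

    Unique founder allele labels are dropped ``n_drops`` times; for each
    pair the realized sharing (¼ Σ matches of the four allele
    comparisons, doubled onto the 2Φ scale; 1 + [maternal = paternal]
    on the diagonal) is averaged. Returns (estimate, standard error),
    both n × n arrays aligned to ``ped.sample_ids``.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    counter = {"next": 0}

    def draw(r):
        lab = counter["next"]
        counter["next"] += 1
        return np.full(n_drops, 2 * lab, dtype=np.int32) + (
            r.integers(0, 2, size=n_drops).astype(np.int32))

    pat, mat = _drop_haplotypes(ped, rng, draw, n_drops, dtype=np.int32)
    est = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                share = 1.0 + (pat[i] == mat[i]).astype(float)
            else:
                share = 0.5 * ((pat[i] == pat[j]).astype(float)
                               + (pat[i] == mat[j])
                               + (mat[i] == pat[j])
                               + (mat[i] == mat[j]))
            est[i, j] = est[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_drops)
    return est, se


def _symmetric_sqrt(k: KinshipMatrix) -> np.ndarray:
    vals, vecs = np.linalg.eigh(k.values)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_trait(ped: Pedigree, k: KinshipMatrix, cfg: SimulationConfig,
                   genotypes: GenotypeMatrix | None = None,
                   k_sqrt: np.ndarray | None = None,
                   seed: int | None = None) -> PhenotypeTable:
    """Simulate a GOLDN-style phenotype table for the pedigree.

    The latent trait is y = covariate effects + QTL + g + e with
    g ~ N(0, K·σ²g) sampled through a symmetric square root of K,
    σ²g/(σ²g + σ²e) = ``true_h2`` of the non-QTL variance budget; each
    of the four visit values (2 pre, 2 post) is the phase latent value
    plus independent N(0, visit_noise_sd²) measurement noise. Ages are
    drawn per generation band, centers are assigned per family, and
    smoking is an independent binary covariate — confounder-free by
    construction.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = ped.n
    ids = ped.sample_ids

    qtl_frac = cfg.qtl[1] if cfg.qtl else 0.0
    total_poly = 1.0 - qtl_frac
    sigma2_g = cfg.true_h2 * total_poly
    sigma2_e = (1.0 - cfg.true_h2) * total_poly

    if k_sqrt is None:
        k_sqrt = _symmetric_sqrt(k)
    g_val = k_sqrt @ rng.standard_normal(n) * np.sqrt(sigma2_g)
    e_val = rng.standard_normal(n) * np.sqrt(sigma2_e)

    qtl_val = np.zeros(n)
    if cfg.qtl:
        if genotypes is None:
            raise ValueError("qtl effect requested but no genotypes supplied")
        dos = genotypes.subset_samples(ids).dosages[:, cfg.qtl[0]]
        dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        sd = dos.std()
        if sd == 0:
            raise ValueError("QTL SNP is monomorphic")
        qtl_val = np.sqrt(qtl_frac) * (dos - dos.mean()) / sd

    # covariates: ages per generation band, center per family, smoking iid
    gen = ped.generation
    age_band = {0: (58, 75), 1: (35, 55), 2: (15, 30)}
    lo = np.array([age_band.get(int(b), (15, 30))[0] for b in gen], float)
    hi = np.array([age_band.get(int(b), (15, 30))[1] for b in gen], float)
    age = np.round(lo + rng.random(n) * (hi - lo), 1)
    sex = ped.table["sex"].to_numpy()
    male = (sex == "M").astype(float)
    centers = np.array([f"c{1 + (int(f) - 1) % len(cfg.center_offsets)}"
                        if f.isdigit() else "c1"
                        for f in ped.table["family_id"]])
    center_eff = np.array([cfg.center_offsets[int(c[1:]) - 1] for c in centers])
    smoking = (rng.random(n) < 0.25).astype(int)

    fixed = (cfg.age_slope * (age - age.mean())
             + cfg.sex_difference * male
             + center_eff + cfg.smoking_effect * smoking)
    latent_pre = fixed + qtl_val + g_val + e_val
    latent_post = latent_pre + cfg.post_shift

    t = pd.DataFrame({"family_id": ped.table["family_id"], "id": ids,
                      "age": age, "sex": sex, "center": centers,
                      "smoking": smoking})
    for phase, latent in (("pre", latent_pre), ("post", latent_post)):
        for visit in (1, 2):
            noise = rng.standard_normal(n) * cfg.visit_noise_sd
            t[f"{cfg.trait_name}_{phase}{visit}"] = latent + noise
    return PhenotypeTable(t)


def simulate_study(cfg: SimulationConfig):
    """Pedigree + genotypes + phenotypes in one call.

    Returns (Pedigree, GenotypeMatrix, PhenotypeTable). Genotype rows of
    a ``planted_swap`` pair are exchanged after the trait is simulated,
    so the phenotypes stay with the pedigree labels — exactly the error
    a relationship screen should catch.
    """
    from .pedigree import pedigree_kinship

    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg)
    freqs = cfg.maf_low + (cfg.maf_high - cfg.maf_low) * rng.random(cfg.n_snps)
    geno = gene_drop(ped, freqs, seed=int(rng.integers(2 ** 31)),
                     ld_rho=cfg.ld_rho, n_chrom=cfg.n_chrom,
                     subpop_divergence=cfg.subpop_divergence)
    k = pedigree_kinship(ped)
    pheno = simulate_trait(ped, k, cfg, genotypes=geno,
                           seed=int(rng.integers(2 ** 31)))
    if cfg.planted_swap:
        a, b = cfg.planted_swap
        lookup = {s: i for i, s in enumerate(geno.sample_ids)}
        ia, ib = lookup[a], lookup[b]
        d = geno.dosages.copy()
        d[[ia, ib]] = d[[ib, ia]]
        geno = replace(geno, dosages=d)
    return ped, geno, pheno
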