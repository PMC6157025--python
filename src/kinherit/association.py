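"""Measured genotype analysis: per-SNP mixed-model association.

Each SNP's alternate-allele dosage enters the polygenic model as a
fixed covariate,

    y ~ Normal(β₀ + β·g_s,  σ²g·K + σ²e·I),

and the SNP is tested by a 1-df likelihood-ratio against the no-SNP
model. The kinship is eigendecomposed once per scan; in the default
"exact" mode the variance components are re-estimated under every SNP
model, while the "fast" mode holds them at the null fit and reduces
each SNP to a weighted least-squares update (appropriate for large
scans, where the two modes agree closely).

Genome-wide flags follow the conventional thresholds: suggestive at
P ≤ 1×10⁻⁵ and significant at the Bonferroni cut α/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, allele_frequencies
from .kinship import KinshipMatrix
from .phenotype import ResidualizedTrait
from .polygenic import KinshipEigen, _fit_on_rotated, _profile_loglik

log = logging.getLogger(__name__)

__all__ = ["AssociationTable", "mga_scan", "apply_thresholds", "plot_data"]

SUGGESTIVE_P = 1.0e-5
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class AssociationTable:
    """Per-SNP association results plus scan-level metadata."""

    table: pd.DataFrame
    n: int
    mode: str
    h2_null: float
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)
    suggestive_threshold: float | None = None
    bonferroni_threshold: float | None = None

    def genomic_inflation(self) -> float:
        """λ = median observed statistic / median of χ²₁."""
        return float(np.median(self.table["statistic"]) / CHI2_1_MEDIAN)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _align(y, g: GenotypeMatrix, k: KinshipMatrix):
    if isinstance(y, ResidualizedTrait):
        ids, yv = list(y.ids), np.asarray(y.values, float)
    elif isinstance(y, pd.Series):
        ids, yv = [str(i) for i in y.index], y.to_numpy(float)
    else:
        yv = np.asarray(y, float)
        ids = list(g.sample_ids)[: len(yv)]
    ok = np.isfinite(yv)
    ids = [i for i, o in zip(ids, ok) if o]
    yv = yv[ok]
    common = [i for i in ids if i in set(g.sample_ids) and i in set(k.sample_ids)]
    sel = {i: j for j, i in enumerate(ids)}
    yv = yv[[sel[i] for i in common]]
    return common, yv, g.subset_samples(common), k.subset(common)


def mga_scan(y, g: GenotypeMatrix, k: KinshipMatrix, mode: str = "exact",
             maf_min: float = 0.01, max_missing: float = 0.1,
             alpha: float = 0.05) -> AssociationTable:
    """Scan every SNP for association with a prepared trait.

    SNPs below the MAF floor, above the missingness ceiling, or
    monomorphic are skipped with reasons recorded. Missing dosages are
    mean-imputed per SNP for the test. Returns an
    :class:`AssociationTable` with thresholds already applied at
    ``alpha`` / (number of SNPs tested).
    """
    if mode not in ("exact", "fast"):
        raise ValueError("mode must be 'exact' or 'fast'")
    ids, yv, g, k = _align(y, g, k)
    n = len(ids)

    freqs = allele_frequencies(g)
    miss = np.mean(np.isnan(g.dosages), axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    reasons = np.where(~np.isfinite(freqs) | (maf == 0), "monomorphic",
                       np.where(maf < maf_min, "maf_below_floor",
                                np.where(miss > max_missing,
                                         "missingness_above_ceiling", "")))
    tested = reasons == ""
    skipped = g.snps.loc[~tested, ["snp_id", "chrom", "pos"]].copy()
    skipped["reason"] = reasons[~tested]
    if skipped.shape[0]:
        log.info("skipped %d SNPs (%s)", skipped.shape[0],
                 dict(skipped["reason"].value_counts()))
    if not tested.any():
        raise ValueError("no SNPs pass the scan filters")

    eig = KinshipEigen.from_kinship(k)
    lam = eig.eigenvalues
    yt = eig.rotate(yv)
    ones_t = eig.rotate(np.ones((n, 1)))

    if eig.is_identity_like:
        h2_null, ll_null = 0.0, _profile_loglik(0.0, lam, yt, ones_t)[0]
    else:
        h2_null, ll_null = _fit_on_rotated(lam, yt, ones_t)

    d = g.dosages[:, tested]
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu, d)
    dt = eig.rotate(d)

    m = d.shape[1]
    beta = np.empty(m)
    beta_se = np.empty(m)
    statistic = np.empty(m)

    if mode == "fast" or eig.is_identity_like:
        w = 1.0 / (h2_null * lam + (1.0 - h2_null))
        x0 = ones_t[:, 0]
        # per-SNP weighted 2-covariate regression, fully vectorised
        s00 = np.sum(w * x0 * x0)
        s0y = np.sum(w * x0 * yt)
        syy = np.sum(w * yt * yt)
        s01 = (w * x0) @ dt
        s11 = np.sum(w[:, None] * dt * dt, axis=0)
        s1y = (w * yt) @ dt
        det = s00 * s11 - s01 ** 2
        beta = (s00 * s1y - s01 * s0y) / det
        b0 = (s11 * s0y - s01 * s1y) / det
        rss1 = syy - b0 * s0y - beta * s1y
        rss0 = syy - s0y ** 2 / s00
        statistic = n * np.log(rss0 / rss1)
        sigma2 = rss1 / n
        beta_se = np.sqrt(sigma2 * s00 / det)
    else:
        for j in range(m):
            xt = np.column_stack([ones_t[:, 0], dt[:, j]])
            h2_j, ll_j = _fit_on_rotated(lam, yt, xt, xatol=1e-6)
            statistic[j] = max(0.0, 2.0 * (ll_j - ll_null))
            _, b, sigma2_t = _profile_loglik(h2_j, lam, yt, xt)
            beta[j] = b[1]
            wj = 1.0 / (h2_j * lam + (1.0 - h2_j))
            xtwx = xt.T @ (xt * wj[:, None])
            beta_se[j] = float(np.sqrt(sigma2_t * np.linalg.inv(xtwx)[1, 1]))
        statistic = np.maximum(statistic, 0.0)

    p = stats.chi2.sf(statistic, df=1)
    snps = g.snps.loc[tested]
    table = pd.DataFrame({
        "snp_id": snps["snp_id"].to_numpy(),
        "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(),
        "ref": snps["ref"].to_numpy(),
        "alt": snps["alt"].to_numpy(),
        "n": n, "beta": beta, "beta_se": beta_se,
        "statistic": statistic, "p": np.clip(p, np.nextafter(0, 1), 1.0),
    })
    out = AssociationTable(table=table, n=n, mode=mode, h2_null=float(h2_null),
                           skipped=skipped)
    return apply_thresholds(out, alpha=alpha, m=len(table))


def apply_thresholds(t: AssociationTable, alpha: float = 0.05,
                     m: int | None = None) -> AssociationTable:
    """Flag suggestive (fixed P ≤ 1×10⁻⁵) and Bonferroni-significant hits.

    The Bonferroni cut is ``alpha / m``; ``m`` defaults to the number of
    rows in the table. Thresholds are stored on the table metadata.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m is None:
        m = len(t.table)
    if m < 1:
        raise ValueError("m must be >= 1")
    bonf = alpha / m
    t.table["suggestive"] = t.table["p"] <= SUGGESTIVE_P
    t.table["significant"] = t.table["p"] <= bonf
    # a genome-wide-significant hit is by construction also suggestive
    t.table.loc[t.table["significant"], "suggestive"] = True
    t.suggestive_threshold = SUGGESTIVE_P
    t.bonferroni_threshold = bonf
    return t


def plot_data(t: AssociationTable) -> dict:
    """Plot-ready Manhattan and Q-Q series plus the inflation factor λ.

    The Manhattan series carries a cumulative genome coordinate and a
    chromosome colour index; the Q-Q series pairs expected with observed
    −log₁₀ p quantiles. Rendering is left to the caller (or to
    :func:`render_plots`).
    """
    if len(t.table) == 0:
        raise ValueError("empty association table")
    tab = t.table
    chroms = list(dict.fromkeys(tab["chrom"]))
    offset = 0
    cum = np.empty(len(tab))
    color = np.empty(len(tab), dtype=int)
    centers = {}
    for ci, c in enumerate(chroms):
        sel = (tab["chrom"] == c).to_numpy()
        pos = tab.loc[sel, "pos"].to_numpy()
        cum[sel] = pos + offset
        color[sel] = ci % 2
        centers[c] = offset + (pos.min() + pos.max()) / 2
        offset += pos.max() + 1
    manhattan = pd.DataFrame({
        "snp_id": tab["snp_id"], "chrom": tab["chrom"],
        "genome_pos": cum, "neglog10_p": -np.log10(tab["p"]),
        "color_index": color,
    })
    obs = np.sort(-np.log10(tab["p"].to_numpy()))[::-1]
    mq = len(obs)
    exp = -np.log10((np.arange(1, mq + 1) - 0.5) / mq)
    qq = pd.DataFrame({"expected": exp, "observed": obs})
    return {"manhattan": manhattan, "qq": qq,
            "lambda": t.genomic_inflation(), "chrom_centers": centers}


def render_plots(t: AssociationTable, path_prefix: str) -> None:
    """Write Manhattan and Q-Q PNGs (thin matplotlib wrapper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = plot_data(t)
    man = series["manhattan"]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4),
                             gridspec_kw={"width_ratios": [3, 1]})
    for cidx, grp in man.groupby("color_index"):
        axes[0].scatter(grp["genome_pos"], grp["neglog10_p"], s=4,
                        c="C0" if cidx == 0 else "C1")
    for label, thr in (("suggestive", t.suggestive_threshold),
                       ("significant", t.bonferroni_threshold)):
        if thr:
            axes[0].axhline(-np.log10(thr), ls="--", lw=0.8, color="grey")
    axes[0].set_xlabel("genome position")
    axes[0].set_ylabel(r"$-\log_{10} p$")
    qq = series["qq"]
    axes[1].scatter(qq["expected"], qq["observed"], s=4)
    lim = max(qq["expected"].max(), qq["observed"].max())
    axes[1].plot([0, lim], [0, lim], c="grey", lw=0.8)
    axes[1].set_xlabel("expected")
    axes[1].set_ylabel("observed")
    axes[1].set_title(f"lambda = {series['lambda']:.3f}")
    fig.tight_layout()
    fig.savefig(f"{path_prefix}_mga.png", dpi=120)
    plt.close(fig)
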