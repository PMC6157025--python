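"""Trait preparation: visit averaging, founder PCA, residualization,
rank-based inverse-normal transform.

The preparation pipeline follows the usual family-study order: average
the replicate visit measurements within a phase, regress out fixed
covariates (age, sex, their interactions, study center, smoking, and
ancestry principal components fit on pedigree founders only), then
inverse-normalize the residuals so the trait entering the
variance-component model has mean 0 and unit SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix, allele_frequencies
from .pedigree import Pedigree

__all__ = ["PhenotypeTable", "ResidualizedTrait", "average_visits",
           "founder_pca", "residualize", "inverse_normal",
           "DEFAULT_COVARIATES", "read_phenotypes"]

DEFAULT_COVARIATES = ["age", "sex", "age_sex", "age2", "age2_sex",
                      "center", "smoking", "pc1", "pc2", "pc3", "pc4"]


@dataclass
class PhenotypeTable:
    """One row per individual: visit-level trait values plus covariates.

    Trait columns follow the ``<trait>_<phase><visit>`` convention, e.g.
    ``tg_pre1``, ``tg_pre2``, ``tg_post1``, ``tg_post2``. Covariate
    columns: ``age`` (years), ``sex`` ("M"/"F"), ``center``, ``smoking``,
    and optionally ``pc1``..``pcK`` once ancestry scores are attached.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if "id" not in t.columns:
            raise ValueError("phenotype table needs an 'id' column")
        t["id"] = t["id"].astype(str)
        if t["id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        if "age" in t.columns and (t["age"].dropna() <= 0).any():
            raise ValueError("ages must be positive")
        self.table = t

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def attach_pcs(self, scores: pd.DataFrame) -> "PhenotypeTable":
        """Merge PC score columns (indexed by sample id) onto the table."""
        t = self.table.drop(columns=[c for c in self.table.columns
                                     if c.startswith("pc")], errors="ignore")
        merged = t.merge(scores, left_on="id", right_index=True, how="left")
        return PhenotypeTable(merged)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, dtype={"id": str, "family_id": str}))


@dataclass
class ResidualizedTrait:
    """A prepared trait vector with its provenance."""

    ids: list[str]
    values: np.ndarray
    covariates: list[str]
    n: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids)


def average_visits(t: PhenotypeTable, trait: str, phase: str) -> pd.Series:
    """Mean of the phase's available visit values per sample.

    With both visits observed the two are averaged; with one observed
    the single measurement is used; with neither the sample is missing
    (and drops out downstream).
    """
    if phase not in ("pre", "post"):
        raise ValueError("phase must be 'pre' or 'post'")
    cols = [c for c in (f"{trait}_{phase}1", f"{trait}_{phase}2")
            if c in t.table.columns]
    if not cols:
        raise ValueError(f"no visit columns found for trait {trait!r} phase {phase!r}")
    out = t.table[cols].mean(axis=1, skipna=True)
    out.index = pd.Index(t.ids)
    return out


def founder_pca(g: GenotypeMatrix, ped: Pedigree, n_pcs: int = 4) -> pd.DataFrame:
    """Ancestry PCs fit on pedigree founders, projected to all samples.

    Dosages are standardized with founder allele frequencies; loadings
    come from an SVD of the standardized founder matrix, and every
    sample (founder or not) is scored by projecting its standardized
    dosages onto those loadings. Founders' projections coincide with
    their PCA scores by construction.
    """
    founders = [s for s in ped.founder_ids() if s in set(g.sample_ids)]
    if len(founders) < n_pcs:
        raise ValueError(f"{len(founders)} founders with genotypes < {n_pcs} PCs")
    gf = g.subset_samples(founders)
    p = allele_frequencies(gf)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    p = p[usable]
    scale = np.sqrt(2 * p * (1 - p))

    def standardize(d):
        z = (d[:, usable] - 2 * p) / scale
        return np.where(np.isnan(z), 0.0, z)

    zf = standardize(gf.dosages)
    _, _, vt = np.linalg.svd(zf, full_matrices=False)
    loadings = vt[:n_pcs].T                       # m × k
    scores = standardize(g.dosages) @ loadings    # all samples
    return pd.DataFrame(scores, index=pd.Index(g.sample_ids),
                        columns=[f"pc{i + 1}" for i in range(n_pcs)])


def _design_matrix(t: pd.DataFrame, covariates: list[str]
                   ) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(t))]
    names = ["intercept"]
    sex = None
    if "sex" in t.columns:
        sex = (t["sex"].astype(str).str.upper().isin(["M", "MALE", "1"])).to_numpy(float)
    for cov in covariates:
        if cov == "age":
            cols.append(t["age"].to_numpy(float)); names.append("age")
        elif cov == "sex":
            cols.append(sex); names.append("sex")
        elif cov == "age_sex":
            cols.append(t["age"].to_numpy(float) * sex); names.append("age_sex")
        elif cov == "age2":
            cols.append(t["age"].to_numpy(float) ** 2); names.append("age2")
        elif cov == "age2_sex":
            cols.append(t["age"].to_numpy(float) ** 2 * sex); names.append("age2_sex")
        elif cov in ("center", "smoking") and t[cov].dtype == object:
            dummies = pd.get_dummies(t[cov].astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float)); names.append(c)
        else:
            cols.append(t[cov].to_numpy(float)); names.append(cov)
    return np.column_stack(cols), names


def residualize(y: pd.Series, t: PhenotypeTable,
                covariates: list[str] | None = None) -> ResidualizedTrait:
    """OLS residuals of ``y`` on the covariate design (complete cases).

    Dummy-codes categorical center/smoking; raises on a rank-deficient
    design, naming the collinear columns.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES
                      if c.startswith(("age", "sex")) or c in t.table.columns]
    tab = t.table.set_index("id").loc[[i for i in y.index if i in set(t.ids)]]
    yv = y.reindex(tab.index)
    x, names = _design_matrix(tab.reset_index(), covariates)
    ok = np.isfinite(yv.to_numpy(float)) & np.all(np.isfinite(x), axis=1)
    x, yov = x[ok], yv.to_numpy(float)[ok]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        _, r = np.linalg.qr(x)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        bad = [n for n, s in zip(names, small) if s]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, yov, rcond=None)
    resid = yov - x @ beta
    ids = tab.index[ok].tolist()
    return ResidualizedTrait(ids=ids, values=resid, covariates=names,
                             n=int(ok.sum()))


def inverse_normal(x, blom_offset: float = 0.375) -> ResidualizedTrait:
    """Rank-based inverse-normal transform, standardized to mean 0 / SD 1.

    z_i = Φ⁻¹((r_i − c) / (n + 1 − 2c)) with the Blom constant c = 0.375
    and average ranks for ties, then exact re-standardization. Monotone
    and invariant to affine transforms of the input.
    """
    if isinstance(x, ResidualizedTrait):
        ids, v, covs = x.ids, x.values, x.covariates + ["inverse-normal"]
    elif isinstance(x, pd.Series):
        ids, v, covs = [str(i) for i in x.index], x.to_numpy(float), ["inverse-normal"]
    else:
        v = np.asarray(x, float)
        ids, covs = [str(i) for i in range(len(v))], ["inverse-normal"]
    ok = np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    vv = v[ok]
    if np.ptp(vv) == 0:
        raise ValueError("constant vector cannot be inverse-normalized")
    n = len(vv)
    ranks = stats.rankdata(vv, method="average")
    z = stats.norm.ppf((ranks - blom_offset) / (n + 1 - 2 * blom_offset))
    z = (z - z.mean()) / z.std()
    return ResidualizedTrait(ids=[i for i, o in zip(ids, ok) if o], values=z,
                             covariates=covs, n=n)
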