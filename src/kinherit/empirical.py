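"""Marker-based (empirical) relatedness estimation.

The built-in estimator is the allelic-correlation genetic relationship
matrix (GRM)

    K(i, j) = (1/m) Σ_s (g_is − 2p_s)(g_js − 2p_s) / (2 p_s (1 − p_s)),

whose off-diagonal expectation under Mendelian gene dropping equals the
pedigree relatedness 2Φ. Raw GRMs from finite marker panels have
diagonals spread around 1 and small negative off-diagonals;
:func:`postprocess_kinship` applies the conventional cleanup — zero the
negative entries, then rescale so the diagonal is exactly 1 — after
which the matrix is exchangeable with a pedigree-derived one in the
variance-component model (possibly at the cost of positive
semidefiniteness, which the report tracks via the minimum eigenvalue).

Externally computed matrices (e.g. LD-weighted or HMM-based kinships)
can be brought in through :func:`import_kinship` and run through the
same postprocessing and comparison utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, allele_frequencies
from .kinship import KinshipMatrix, read_kinship
from .pedigree import Pedigree, pedigree_kinship

log = logging.getLogger(__name__)

__all__ = ["EmpiricalKinshipReport", "grm", "postprocess_kinship",
           "compare_kinships", "import_kinship"]


@dataclass
class EmpiricalKinshipReport:
    """A marker-based kinship estimate plus its diagnostics."""

    kinship: KinshipMatrix
    n_snps_used: int
    n_snps_excluded: int
    diagonal_summary: dict  # min/max/mean/sd of the raw (unscaled) diagonal
    estimator: str = "allelic-correlation GRM"
    n_negatives_zeroed: int | None = None
    min_eigenvalue_post: float | None = None

    def postprocess(self) -> "EmpiricalKinshipReport":
        """Return a copy whose matrix has been cleaned to unit diagonal."""
        k = postprocess_kinship(self.kinship)
        return EmpiricalKinshipReport(
            kinship=k, n_snps_used=self.n_snps_used,
            n_snps_excluded=self.n_snps_excluded,
            diagonal_summary=self.diagonal_summary, estimator=self.estimator,
            n_negatives_zeroed=k.n_negatives_zeroed,
            min_eigenvalue_post=k.min_eigenvalue())


def grm(g: GenotypeMatrix, freqs: np.ndarray | None = None,
        maf_min: float = 0.01) -> EmpiricalKinshipReport:
    """Allelic-correlation GRM from dosages (unpostprocessed).

    SNPs with undefined frequency or minor-allele frequency below
    ``maf_min`` are excluded and counted. Missing dosages are
    mean-imputed to 2p, i.e. they contribute nothing after centering.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != g.n_snps:
        raise ValueError("freqs not aligned to genotype matrix")
    usable = np.isfinite(freqs) & (freqs >= maf_min) & (freqs <= 1 - maf_min)
    m = int(usable.sum())
    if m == 0:
        raise ValueError("no usable SNPs after MAF filtering")
    p = freqs[usable]
    d = g.dosages[:, usable]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.where(np.isnan(z), 0.0, z)
    k = (z @ z.T) / m
    diag = np.diag(k)
    report = EmpiricalKinshipReport(
        kinship=KinshipMatrix(sample_ids=list(g.sample_ids), values=k,
                              source="empirical"),
        n_snps_used=m,
        n_snps_excluded=g.n_snps - m,
        diagonal_summary={"min": float(diag.min()), "max": float(diag.max()),
                          "mean": float(diag.mean()), "sd": float(diag.std())},
    )
    return report


def postprocess_kinship(k: KinshipMatrix) -> KinshipMatrix:
    """Zero negative entries, then rescale to a unit diagonal.

    The rescale is per pair, K(i,j)/sqrt(K(i,i)·K(j,j)), because raw
    self-relatedness estimates are spread around 1 and a single global
    divisor could not fix every diagonal entry at once. Zeroing happens
    first; the operation is idempotent. A non-positive diagonal entry is
    a data error and is reported by sample id.
    """
    v = k.values.copy()
    diag = np.diag(v)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive self-relatedness for sample {k.sample_ids[bad[0]]!r}")
    neg = v < 0
    n_zeroed = int(np.count_nonzero(neg))
    v[neg] = 0.0
    d = np.sqrt(np.diag(v))
    v = v / np.outer(d, d)
    np.fill_diagonal(v, 1.0)
    return KinshipMatrix(sample_ids=list(k.sample_ids), values=v,
                         source=k.source, postprocessed=True,
                         n_negatives_zeroed=n_zeroed)


def import_kinship(path, postprocess: bool = False) -> KinshipMatrix:
    """Read an externally computed kinship matrix (square or long CSV)."""
    k = read_kinship(path, source="empirical")
    return postprocess_kinship(k) if postprocess else k


_RELATIONSHIP_BINS = [
    # (label, lower bound on 2Φ) — standard degrees, checked in order
    ("duplicate/MZ", 0.9),
    ("1st-degree", 0.354),
    ("2nd-degree", 0.177),
    ("3rd-degree", 0.0884),
    ("unrelated", -np.inf),
]


def _class_of(two_phi: float) -> str:
    for label, lo in _RELATIONSHIP_BINS:
        if two_phi >= lo:
            return label
    return "unrelated"  # pragma: no cover


def compare_kinships(k1: KinshipMatrix, k2: KinshipMatrix,
                     ped: Pedigree | None = None) -> dict:
    """Quantify agreement of two relatedness matrices on shared samples.

    Returns Pearson correlation, RMSE and mean difference over common
    off-diagonal pairs, per-matrix diagonal summaries, and — when a
    pedigree is supplied — the mean difference stratified by expected
    relationship class.
    """
    common = [s for s in k1.sample_ids if s in set(k2.sample_ids)]
    if len(common) < 2:
        raise ValueError("need at least 2 overlapping samples to compare")
    a = k1.subset(common).values
    b = k2.subset(common).values
    iu = np.triu_indices(len(common), k=1)
    x, y = a[iu], b[iu]
    diff = y - x
    out = {
        "n_samples": len(common),
        "n_pairs": len(x),
        "pearson_r": float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else np.nan,
        "rmse": float(np.sqrt(np.mean(diff ** 2))),
        "mean_difference": float(np.mean(diff)),
        "diagonal_k1": {"min": float(np.diag(a).min()), "max": float(np.diag(a).max()),
                        "mean": float(np.diag(a).mean()), "sd": float(np.diag(a).std())},
        "diagonal_k2": {"min": float(np.diag(b).min()), "max": float(np.diag(b).max()),
                        "mean": float(np.diag(b).mean()), "sd": float(np.diag(b).std())},
    }
    if ped is not None:
        expected = pedigree_kinship(ped).subset(common).values[iu]
        strata: dict[str, float] = {}
        labels = np.array([_class_of(t) for t in expected])
        for label in np.unique(labels):
            sel = labels == label
            strata[label] = float(np.mean(diff[sel]))
        out["mean_difference_by_class"] = strata
    return out
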