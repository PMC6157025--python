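"""Variance-components estimation of narrow-sense heritability.

Model:  y ~ Normal(Xβ, σ²g·K + σ²e·I), with K a relatedness matrix on
the 2Φ scale. Writing σ²t = σ²g + σ²e and h² = σ²g/σ²t, the covariance
is σ²t·(h²·K + (1−h²)·I); a single symmetric eigendecomposition
K = U·Λ·Uᵀ rotates the model to independent observations with variances
σ²t·(h²λᵢ + 1 − h²), so for fixed h² the GLS estimate of β and the ML
estimate of σ²t are closed-form and the profile log-likelihood is a
smooth 1-D function of h² maximized by Brent's method on [0, 1].

Inference follows the likelihood-ratio convention for a variance
component on the boundary of its space: Λ = 2(ℓ_full − ℓ_null) is
referred to the ½χ²₀ + ½χ²₁ mixture, i.e. p = ½·P(χ²₁ ≥ Λ), with Λ = 0
reported as p = 1. The standard error of ĥ² comes from the curvature of
the profile log-likelihood at the optimum and is reported as missing
when the optimum sits on a boundary.

K is internally normalised by its mean diagonal, which makes ĥ², Λ and
p invariant to any global rescaling of K (the Φ-vs-2Φ ambiguity); σ̂²g
is reported on the scale of the K actually supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix
from .phenotype import ResidualizedTrait

log = logging.getLogger(__name__)

__all__ = ["PolygenicFit", "KinshipEigen", "fit_polygenic", "lrt_h2",
           "UnidentifiableKinshipError"]

EIGEN_CLIP = 1e-8
_BOUNDARY_TOL = 1e-6


class UnidentifiableKinshipError(ValueError):
    """Kinship carries no relatedness signal (numerically an identity)."""


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix.

    Eigenvalues are normalised by the mean diagonal of K and clipped
    below at ``EIGEN_CLIP`` so that indefinite postprocessed matrices
    still yield a proper likelihood; the clip count is recorded.
    """

    sample_ids: list[str]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    diag_scale: float
    n_clipped: int

    @classmethod
    def from_kinship(cls, k: KinshipMatrix) -> "KinshipEigen":
        scale = float(np.mean(np.diag(k.values)))
        if scale <= 0:
            raise ValueError("kinship diagonal must be positive on average")
        vals, vecs = np.linalg.eigh(k.values / scale)
        n_clipped = int(np.sum(vals < EIGEN_CLIP))
        if n_clipped:
            log.info("clipped %d kinship eigenvalues below %.0e",
                     n_clipped, EIGEN_CLIP)
        vals = np.clip(vals, EIGEN_CLIP, None)
        return cls(sample_ids=list(k.sample_ids), eigenvalues=vals,
                   eigenvectors=vecs, diag_scale=scale, n_clipped=n_clipped)

    @property
    def is_identity_like(self) -> bool:
        return bool(np.max(np.abs(self.eigenvalues - 1.0)) < 1e-10)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ a


@dataclass
class PolygenicFit:
    """One heritability estimate: variance components, test, provenance."""

    h2: float
    h2_se: float            # NaN when the optimum is on a boundary
    sigma2_g: float         # on the scale of the supplied K
    sigma2_e: float
    loglik_full: float
    loglik_null: float
    p_value: float
    n: int
    kinship_source: str
    boundary: bool
    beta: np.ndarray | None = None
    n_eigen_clipped: int = 0

    @property
    def lrt_statistic(self) -> float:
        return max(0.0, 2.0 * (self.loglik_full - self.loglik_null))

    def to_dict(self) -> dict:
        return {"h2": self.h2, "h2_se": self.h2_se, "sigma2_g": self.sigma2_g,
                "sigma2_e": self.sigma2_e, "loglik_full": self.loglik_full,
                "loglik_null": self.loglik_null, "p_value": self.p_value,
                "n": self.n, "kinship_source": self.kinship_source,
                "boundary": self.boundary}


def _profile_loglik(h2: float, lam: np.ndarray, yt: np.ndarray,
                    xt: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood in h² with β and σ²t concentrated out."""
    n = len(yt)
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    xw = xt * w[:, None]
    a = xt.T @ xw
    b = xw.T @ yt
    beta = np.linalg.solve(a, b)
    r = yt - xt @ beta
    sigma2_t = float(np.sum(w * r * r) / n)
    if sigma2_t <= 0:
        return -np.inf, beta, sigma2_t
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2_t)
                 + np.sum(np.log(d)) + n)
    return float(ll), beta, sigma2_t


def _fit_on_rotated(lam: np.ndarray, yt: np.ndarray, xt: np.ndarray,
                    xatol: float = 1e-8):
    """Maximize the profile likelihood over h² in [0, 1]."""
    neg = lambda h2: -_profile_loglik(h2, lam, yt, xt)[0]
    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": xatol})
    candidates = [(float(res.x), -float(res.fun))]
    for h2 in (0.0, 1.0 - 1e-12):
        candidates.append((h2, _profile_loglik(h2, lam, yt, xt)[0]))
    h2_hat, ll = max(candidates, key=lambda c: c[1])
    return h2_hat, ll


def _h2_se(h2_hat: float, lam, yt, xt) -> float:
    """Delta-method SE from the numerical curvature of the profile ℓ."""
    eps = 1e-4
    if h2_hat < eps or h2_hat > 1 - eps:
        return float("nan")
    f = lambda h: _profile_loglik(h, lam, yt, xt)[0]
    d2 = (f(h2_hat + eps) - 2 * f(h2_hat) + f(h2_hat - eps)) / eps ** 2
    if d2 >= 0:
        return float("nan")
    return float(np.sqrt(-1.0 / d2))


def fit_polygenic(y, k: KinshipMatrix | None = None, x: np.ndarray | None = None,
                  eig: KinshipEigen | None = None,
                  allow_identity: bool = False) -> PolygenicFit:
    """Maximum-likelihood heritability of a prepared trait.

    ``y`` may be a :class:`ResidualizedTrait`, a pandas Series indexed by
    sample id, or a bare vector already aligned to the kinship. Fixed
    effects default to an intercept (traits are expected to be
    pre-residualized). Pass a precomputed :class:`KinshipEigen` as
    ``eig`` to amortise the eigendecomposition over many fits on the
    same samples.
    """
    import pandas as pd

    if isinstance(y, ResidualizedTrait):
        ids, yv = y.ids, np.asarray(y.values, float)
    elif isinstance(y, pd.Series):
        ids, yv = [str(i) for i in y.index], y.to_numpy(float)
    else:
        yv = np.asarray(y, float)
        ids = None

    source = "unknown"
    if eig is None:
        if k is None:
            raise ValueError("provide a kinship matrix or its eigendecomposition")
        if ids is not None:
            present = set(k.sample_ids)
            keep = [i for i in ids if i in present]
            sel = np.array([i in present for i in ids])
            yv, ids = yv[sel], keep
            k = k.subset(ids)
        eig = KinshipEigen.from_kinship(k)
        source = k.source
    elif k is not None:
        source = k.source
    else:
        source = "precomputed"
    if ids is not None and ids != eig.sample_ids:
        order = {s: i for i, s in enumerate(ids)}
        if set(ids) != set(eig.sample_ids):
            raise ValueError("trait samples do not match eigendecomposition")
        perm = [order[s] for s in eig.sample_ids]
        yv = yv[perm]
        ids = list(eig.sample_ids)

    n = len(yv)
    if n < 30:
        log.warning("only %d samples; heritability will be poorly resolved", n)
    if not allow_identity and eig.is_identity_like:
        raise UnidentifiableKinshipError(
            "kinship is numerically an identity matrix; h2 is unidentifiable")

    lam = eig.eigenvalues
    yt = eig.rotate(yv)
    if x is None:
        xm = np.ones((n, 1))
    else:
        xm = np.atleast_2d(np.asarray(x, float))
        if xm.shape[0] != n:
            xm = xm.T
    xt = eig.rotate(xm)

    h2_hat, ll_full = _fit_on_rotated(lam, yt, xt)
    ll_null, _, _ = _profile_loglik(0.0, lam, yt, xt)
    _, beta, sigma2_t = _profile_loglik(h2_hat, lam, yt, xt)

    boundary = h2_hat < _BOUNDARY_TOL or h2_hat > 1 - _BOUNDARY_TOL
    if boundary:
        h2_hat = 0.0 if h2_hat < 0.5 else 1.0
    se = _h2_se(h2_hat, lam, yt, xt) if not boundary else float("nan")

    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = 1.0 if lrt == 0.0 else float(0.5 * stats.chi2.sf(lrt, df=1))

    sigma2_g_norm = h2_hat * sigma2_t
    sigma2_e = (1.0 - h2_hat) * sigma2_t
    return PolygenicFit(
        h2=float(h2_hat), h2_se=se,
        sigma2_g=float(sigma2_g_norm / eig.diag_scale),
        sigma2_e=float(sigma2_e),
        loglik_full=float(ll_full), loglik_null=float(ll_null),
        p_value=p, n=n, kinship_source=source, boundary=boundary,
        beta=beta, n_eigen_clipped=eig.n_clipped)


def lrt_h2(fit: PolygenicFit) -> float:
    """Boundary-corrected LRT p-value: p = ½·P(χ²₁ ≥ Λ), p = 1 at Λ = 0."""
    lam = fit.lrt_statistic
    return 1.0 if lam == 0.0 else float(0.5 * stats.chi2.sf(lam, df=1))
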