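"""Twin-aware linear association models.

Two mixed models handle the within-pair correlation of twin samples:

* pair random-intercept model (LME): y = Xb + b_pair + e, with
  b_pair ~ N(0, sigma2_b) shared by co-twins;
* kinship-covariance model: y = Xb + g + e with cov(g) = sigma2_g * R,
  where R = 2*Phi is the relationship matrix (MZ co-twins 1, DZ 0.5).

Both are fitted by maximum likelihood through the same engine: a one-time
eigendecomposition of the structure matrix rotates the covariance to
diagonal, the variance ratio sigma2_g / sigma2_e is profiled on a log grid
(with optional scalar refinement), and the methylation coefficient is
tested with a two-sided Wald test.  The pair random intercept is exactly
the kinship model with a block-of-ones relationship matrix, so for MZ-only
cohorts the two models coincide.  ML (not REML) keeps per-probe fits
comparable and the rotation exact; the eigendecomposition is computed once
per cohort and reused across all CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

RATIO_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 1e4, 161)])


@dataclass
class KinshipStructure:
    """Relationship matrix R = 2*Phi with cached eigendecomposition."""

    relationship: np.ndarray
    eigvals: np.ndarray = field(default=None, repr=False)
    eigvecs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        R = np.asarray(self.relationship, float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(R, R.T):
            raise ValueError("relationship matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("relationship matrix must have unit diagonal")
        self.relationship = R
        if self.eigvals is None:
            vals, vecs = np.linalg.eigh(R)
            if vals.min() < -1e-8:
                raise ValueError("relationship matrix must be positive semidefinite")
            self.eigvals = np.maximum(vals, 0.0)
            self.eigvecs = vecs

    @property
    def n(self) -> int:
        return len(self.relationship)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.eigvecs.T @ v


@dataclass
class LinearFit:
    coef: float
    se: float
    p_value: float
    sigma2_g: float
    sigma2_e: float
    converged: bool = True


def _pair_blocks(pair_ids, values) -> np.ndarray:
    """Structure matrix with blocks of `values` for co-twins, 1 on diagonal."""
    pair_ids = np.asarray(pair_ids)
    n = len(pair_ids)
    R = np.eye(n)
    codes, _ = pd.factorize(pair_ids)
    for c in np.unique(codes):
        members = np.flatnonzero(codes == c)
        if len(members) > 2:
            raise ValueError(f"pair {pair_ids[members[0]]!r} has more than two members")
        if len(members) == 2:
            i, j = members
            R[i, j] = R[j, i] = values
    return R


def kinship_matrix(cohort) -> KinshipStructure:
    """Relationship matrix from pair/zygosity labels: R[i,j] = 1 for MZ
    co-twins (Phi = 1/2), 0.5 for DZ co-twins (Phi = 1/4), 0 otherwise."""
    df = cohort.samples
    R = _pair_blocks(df["pair_id"].to_numpy(), 1.0)
    dz = (df["zygosity"] == "DZ").to_numpy()
    off = (R == 1.0) & ~np.eye(len(R), dtype=bool)
    dz_pair = off & (dz[:, None] | dz[None, :])
    R[dz_pair] = 0.5
    return KinshipStructure(R)


def pair_structure(pair_ids) -> KinshipStructure:
    """Block-of-ones structure (ZZ') of the pair random-intercept model."""
    return KinshipStructure(_pair_blocks(pair_ids, 1.0))


# ---------------------------------------------------------------------------
# profiled-ML engine


def _profile_loglik(ratio, yt, Xt, d):
    """Profile ML log-likelihood at variance ratio sigma2_g/sigma2_e."""
    n = len(yt)
    w = 1.0 / (ratio * d + 1.0)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    beta = np.linalg.solve(A, b)
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n - np.log(w).sum())
    return ll, beta, sigma2, A


def fit_mixed(
    y,
    x,
    structure: KinshipStructure,
    covariates=None,
    ratio_grid: np.ndarray = RATIO_GRID,
    refine: bool = True,
) -> LinearFit:
    """ML fit of y = b0 + b1*x (+ covariates) + g + e with
    cov(g) = sigma2_g * R; Wald test of b1."""
    y = np.asarray(y, float).ravel()
    x = np.asarray(x, float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("methylation vector is constant")
    cols = [np.ones(len(y)), x]
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    d = structure.eigvals
    yt = structure.rotate(y)
    Xt = structure.rotate(X)

    lls = np.array([_profile_loglik(r, yt, Xt, d)[0] for r in ratio_grid])
    best = int(np.argmax(lls))
    ratio = float(ratio_grid[best])
    converged = True
    if refine and 0 < best < len(ratio_grid) - 1:
        res = optimize.minimize_scalar(
            lambda lr: -_profile_loglik(np.exp(lr), yt, Xt, d)[0],
            bounds=(np.log(ratio_grid[best - 1]), np.log(ratio_grid[best + 1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.success and -res.fun >= lls[best]:
            ratio = float(np.exp(res.x))
        else:
            converged = bool(res.success)
    _, beta, sigma2, A = _profile_loglik(ratio, yt, Xt, d)
    cov_beta = sigma2 * np.linalg.inv(A)
    se = float(np.sqrt(cov_beta[1, 1]))
    z = beta[1] / se
    return LinearFit(
        coef=float(beta[1]),
        se=se,
        p_value=float(2.0 * norm.sf(abs(z))),
        sigma2_g=ratio * sigma2,
        sigma2_e=sigma2,
        converged=converged,
    )


def fit_kinship(y, x, kin: KinshipStructure, covariates=None) -> LinearFit:
    """Kinship-covariance mixed model (cov = sigma2_g * R + sigma2_e * I)."""
    return fit_mixed(y, x, kin, covariates=covariates)


def fit_lme(y, x, pairs, covariates=None) -> LinearFit:
    """Pair random-intercept mixed model (twin pairing as random effect)."""
    pairs = np.asarray(pairs)
    if len(np.unique(pairs)) < 3:
        raise ValueError("need at least 3 pairs")
    return fit_mixed(y, x, pair_structure(pairs), covariates=covariates)


# ---------------------------------------------------------------------------
# vectorized scan: many predictors against one outcome


def mixed_scan(
    y,
    X_markers,
    structure: KinshipStructure,
    ratio_grid: np.ndarray = RATIO_GRID,
) -> pd.DataFrame:
    """Fit the mixed model for every column of ``X_markers`` (n x m) against
    the same outcome, profiling the variance ratio per marker on the grid.

    The rotation is applied once; per-ratio normal equations for the
    (intercept, marker) design are solved in closed form across all markers
    simultaneously.  Returns a DataFrame with coef, se, p_value, sigma2_g,
    sigma2_e per marker.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X_markers, float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    d = structure.eigvals
    yt = structure.rotate(y)
    Xt = structure.rotate(X)
    ones_t = structure.rotate(np.ones(n))

    n_r = len(ratio_grid)
    ll = np.empty((n_r, m))
    stats = []  # per-ratio tuples needed to recover estimates at the argmax
    for k, ratio in enumerate(ratio_grid):
        w = 1.0 / (ratio * d + 1.0)
        logdet = -np.log(w).sum()
        s11 = float(ones_t @ (w * ones_t))
        s1y = float(ones_t @ (w * yt))
        syy = float(yt @ (w * yt))
        s1x = (w * ones_t) @ Xt  # (m,)
        sxy = (w * yt) @ Xt
        sxx = w @ (Xt * Xt)
        det = s11 * sxx - s1x**2
        beta1 = (s11 * sxy - s1x * s1y) / det
        beta0 = (s1y - s1x * beta1) / s11
        rss = syy - beta0 * s1y - beta1 * sxy
        rss = np.maximum(rss, 1e-300)
        sigma2 = rss / n
        ll[k] = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
        stats.append((beta1, sigma2, s11 / det))
    best = np.argmax(ll, axis=0)
    beta1 = np.empty(m)
    sigma2 = np.empty(m)
    var_scale = np.empty(m)
    for k in np.unique(best):
        sel = best == k
        b1, s2, vs = stats[k]
        beta1[sel] = b1[sel]
        sigma2[sel] = s2[sel]
        var_scale[sel] = vs[sel]
    se = np.sqrt(sigma2 * var_scale)
    z = beta1 / se
    return pd.DataFrame(
        {
            "coef": beta1,
            "se": se,
            "p_value": 2.0 * norm.sf(np.abs(z)),
            "sigma2_g": ratio_grid[best] * sigma2,
            "sigma2_e": sigma2,
        }
    )
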