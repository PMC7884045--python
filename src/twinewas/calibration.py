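"""Type-I-error and power simulation harness, replication and overlap tests.

The calibration scheme mirrors the single-marker null experiment used to
vet the three association models: draw a marker i.i.d. N(0, 1) independent
of the cohort's (covariate-adjusted) cognitive score, test the
association, and record the rejection rate at the nominal level.  The
power harness implants effects of a chosen shape at a grid of sizes.
Replication evidence is summarized by the exact binomial upper tail, and
set overlaps by the exact hypergeometric upper tail; both are computed by
direct summation in exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from . import gcc as _gcc
from .linear import kinship_matrix, mixed_scan, pair_structure
from .preprocess import residualize
from .simulate import TwinCohort, shape_function

MODELS = ("gcc", "lme", "kinship")


@dataclass
class CalibrationReport:
    model: str
    n_reps: int
    alpha: float
    rejection_rate: float
    mc_se: float
    n_failed: int = 0


@dataclass
class ReplicationResult:
    n_tested: int
    n_replicated: int
    alpha: float
    p_binomial: float


def _adjusted_phenotype(cohort: TwinCohort) -> np.ndarray:
    return residualize(cohort.cognitive_score, cohort.covariates())


def _gcc_null_rejections(
    y_adj: np.ndarray, n_reps: int, alpha: float, n_perm: int, rng: np.random.Generator
) -> int:
    """Count GCC permutation-test rejections for i.i.d. N(0,1) markers.

    Each replicate runs its own permutation test; evaluation stops early
    once enough permuted statistics exceed the observed one for the
    decision p < alpha to be settled (the decision is identical to running
    all n_perm permutations).
    """
    n = len(y_adj)
    cache = _gcc._kernels(n)
    # the observed matching permutations for all replicates, in one batch
    markers = rng.normal(size=(n_reps, n))
    sigmas = np.empty((n_reps, n), dtype=np.int64)
    for r in range(n_reps):
        sigmas[r] = _gcc._matching_permutation(markers[r], y_adj)
    obs_ll = np.empty(n_reps)
    for start in range(0, n_reps, 250):
        obs_ll[start : start + 250] = _gcc._joint_ll(sigmas[start : start + 250], cache)

    # exceedances allowed while still rejecting: p = (1+e)/(n_perm+1) < alpha
    max_exceed = int(np.ceil(alpha * (n_perm + 1) - 1)) - 1
    if (1 + max_exceed + 1) / (n_perm + 1) < alpha:
        max_exceed += 1
    rejections = 0
    batch = 56
    for r in range(n_reps):
        exceed = 0
        done = 0
        while done < n_perm:
            count = min(batch, n_perm - done)
            exceed += _gcc._count_exceedances(
                _gcc._random_perms(rng, count, n), obs_ll[r], cache
            )
            done += count
            if exceed > max_exceed:
                break
        if exceed <= max_exceed:
            rejections += 1
    return rejections


def type1_error(
    model: str,
    cohort: TwinCohort,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 999,
) -> CalibrationReport:
    """Empirical type-I error of one model on null markers.

    For each replicate a single marker is drawn i.i.d. N(0, 1),
    independent of the phenotype, and tested against the cohort's
    covariate-adjusted cognitive score; the report gives the fraction of
    p-values below ``alpha`` with its Monte-Carlo standard error.
    Deterministic given seed.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    y_adj = _adjusted_phenotype(cohort)

    if model == "gcc":
        rejections = _gcc_null_rejections(y_adj, n_reps, alpha, n_perm, rng)
    else:
        structure = (
            kinship_matrix(cohort) if model == "kinship" else pair_structure(cohort.pair_ids)
        )
        markers = rng.normal(size=(len(y_adj), n_reps))
        p = np.empty(n_reps)
        chunk = 2000
        for start in range(0, n_reps, chunk):
            scan = mixed_scan(y_adj, markers[:, start : start + chunk], structure)
            p[start : start + chunk] = scan["p_value"].to_numpy()
        rejections = int((p < alpha).sum())

    rate = rejections / n_reps
    return CalibrationReport(
        model=model,
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1 - rate) / n_reps)),
    )


def power_curve(
    model: str,
    shape: str,
    effect_grid,
    cohort: TwinCohort,
    n_reps: int = 200,
    alpha: float = 1e-3,
    seed: int = 0,
    noise_sd: float = 1.0,
    gcc_null_size: int = 19999,
):
    """Rejection rate per effect size for markers built as
    effect * g(score) + N(0, noise_sd) noise.

    GCC uses the null reference table (exact for the rank statistic at
    fixed n), which resolves p-values well below the per-replicate
    permutation floor.  Returns a list of (effect, power) pairs.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    rng = np.random.default_rng(seed)
    y_adj = _adjusted_phenotype(cohort)
    n = len(y_adj)
    g = shape_function(shape, (y_adj - y_adj.mean()) / y_adj.std())
    out = []
    structure = None
    if model != "gcc":
        structure = (
            kinship_matrix(cohort) if model == "kinship" else pair_structure(cohort.pair_ids)
        )
    for effect in np.atleast_1d(effect_grid):
        if shape == "variance":
            markers = (
                rng.normal(size=(n_reps, n))
                * noise_sd
                * (1.0 + effect * np.abs(g))[None, :]
            )
        else:
            markers = effect * g[None, :] + rng.normal(size=(n_reps, n)) * noise_sd
        if model == "gcc":
            cache = _gcc._kernels(n)
            table = _gcc.null_reference(n, gcc_null_size)
            sigmas = np.empty((n_reps, n), dtype=np.int64)
            for r in range(n_reps):
                sigmas[r] = _gcc._matching_permutation(markers[r], y_adj)
            ll = np.empty(n_reps)
            for start in range(0, n_reps, 250):
                ll[start : start + 250] = _gcc._joint_ll(sigmas[start : start + 250], cache)
            p = _gcc.reference_pvalues(ll, table)
        else:
            p = mixed_scan(y_adj, markers.T, structure)["p_value"].to_numpy()
        out.append((float(effect), float((p < alpha).mean())))
    return out


# ---------------------------------------------------------------------------
# exact tail tests


def binomial_replication_p(k: int, n: int, alpha: float) -> float:
    """Exact upper tail P(X >= k), X ~ Binomial(n, alpha), by direct
    summation in exact rational arithmetic."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a = Fraction(alpha).limit_denominator(10**12)
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * a**j * (1 - a) ** (n - j)
    return float(total)


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for the overlap of a size-K set and a
    size-n draw from a universe of N."""
    if k > min(K, n) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return float(Fraction(total, denom))


def replication_test(
    n_tested: int, n_replicated: int, alpha: float = 0.05
) -> ReplicationResult:
    """Probability of observing at least the achieved number of
    replications if all tested sites were chance findings."""
    return ReplicationResult(
        n_tested=n_tested,
        n_replicated=n_replicated,
        alpha=alpha,
        p_binomial=binomial_replication_p(n_replicated, n_tested, alpha),
    )
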