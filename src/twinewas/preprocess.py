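"""Matrix-level QC, imputation, M-value transform and covariate adjustment.

Mirrors the usual array-methylation workflow once beta values are on disk:
drop flagged probes (sex-chromosome / SNP / cross-reactive), drop probes
missing in more than a given fraction of samples, impute the rest from the
probe median, logit2-transform to M values, and residualize phenotype and
methylation on the adjustment covariates before association testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_SCALES = ("beta", "M")
PROBE_FLAGS = ("sex_chrom", "snp_probe", "cross_reactive")


class AlignmentError(ValueError):
    """Matrix / manifest / phenotype misalignment."""


@dataclass
class MethylationMatrix:
    """Probes x samples matrix with a scale tag ('beta' or 'M').

    Beta entries live in (0, 1); M values are log2(beta / (1 - beta)).
    Missing entries are NaN.
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self):
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated probe id {dup!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return len(self.values)


@dataclass
class ProbeManifest:
    """Probe annotation: id, chromosome, 1-based position, gene, feature,
    island relation and exclusion flags."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "pos")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if not self.table["probe_id"].is_unique:
            dup = self.table["probe_id"][self.table["probe_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicated probe id {dup!r}")
        if "flags" not in self.table.columns:
            self.table = self.table.assign(flags="")
        self.table = self.table.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def aligned_to(self, matrix: MethylationMatrix) -> "ProbeManifest":
        if set(self.table["probe_id"]) != set(matrix.probe_ids):
            raise AlignmentError("manifest and matrix carry different probe sets")
        return self


def beta_to_m(matrix: MethylationMatrix, epsilon: float = 1e-6) -> MethylationMatrix:
    """logit2 transform: m = log2(b / (1 - b)) after clipping b into
    [epsilon, 1 - epsilon].  Missing entries stay missing; non-finite
    (non-NaN) entries are an error naming the offending probe/sample."""
    if matrix.scale != "beta":
        raise ValueError(f"expected a beta-scale matrix, got scale={matrix.scale!r}")
    if not (0.0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    vals = matrix.values.to_numpy(float)
    bad = np.isinf(vals)
    if bad.any():
        p, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite beta at probe {matrix.probe_ids[p]!r}, sample "
            f"{matrix.sample_ids[s]!r}"
        )
    clipped = np.clip(vals, epsilon, 1.0 - epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return MethylationMatrix(
        pd.DataFrame(m, index=matrix.probe_ids, columns=matrix.sample_ids), scale="M"
    )


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m` on the clipped range."""
    if matrix.scale != "M":
        raise ValueError(f"expected an M-scale matrix, got scale={matrix.scale!r}")
    m = matrix.values.to_numpy(float)
    beta = 1.0 / (1.0 + 2.0**(-m))
    return MethylationMatrix(
        pd.DataFrame(beta, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="beta",
    )


def filter_probes(
    matrix: MethylationMatrix,
    manifest: ProbeManifest,
    max_missing: float = 0.05,
    drop_flags: tuple[str, ...] = PROBE_FLAGS,
):
    """Remove flagged probes and probes missing in more than ``max_missing``
    of samples; impute remaining missing entries from the probe median.

    Returns ``(matrix, manifest, report)`` where report counts removals per
    rule: ``{"flag": k1, "missing": k2}``.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    manifest.aligned_to(matrix)
    man = (
        manifest.table.set_index("probe_id")
        .loc[matrix.probe_ids]
        .rename_axis("probe_id")
        .reset_index()
    )

    flag_sets = man["flags"].fillna("").map(lambda s: set(s.split(";")) - {""})
    flagged = flag_sets.map(lambda fs: bool(fs & set(drop_flags))).to_numpy()

    vals = matrix.values.to_numpy(float)
    miss_frac = np.isnan(vals).mean(axis=1)
    too_missing = (miss_frac > max_missing) & ~flagged

    keep = ~(flagged | too_missing)
    report = {"flag": int(flagged.sum()), "missing": int(too_missing.sum())}

    kept = vals[keep]
    if np.isnan(kept).any():
        med = np.nanmedian(kept, axis=1)
        idx = np.argwhere(np.isnan(kept))
        kept[idx[:, 0], idx[:, 1]] = med[idx[:, 0]]
    out_matrix = MethylationMatrix(
        pd.DataFrame(kept, index=matrix.probe_ids[keep], columns=matrix.sample_ids),
        scale=matrix.scale,
    )
    out_manifest = ProbeManifest(man.loc[keep].reset_index(drop=True))
    return out_matrix, out_manifest, report


def _design(covariates: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    X = np.column_stack([np.ones(len(X)), X])
    return X, ["intercept"] + names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns through pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in piv[diag < tol]] or [names[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


def residualize(values: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ordinary-least-squares residuals of ``values`` on intercept +
    covariates; the result is orthogonal to every covariate column."""
    y = np.asarray(values, float)
    X, names = _design(covariates)
    if len(y) != len(X):
        raise AlignmentError(f"{len(y)} values vs {len(X)} covariate rows")
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residualize_matrix(
    matrix: MethylationMatrix, covariates: pd.DataFrame | np.ndarray
) -> MethylationMatrix:
    """Residualize every probe row on the covariates in one pass."""
    X, names = _design(covariates)
    if matrix.values.shape[1] != len(X):
        raise AlignmentError(
            f"{matrix.values.shape[1]} samples vs {len(X)} covariate rows"
        )
    _check_rank(X, names)
    V = matrix.values.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, V.T, rcond=None)
    resid = V - (X @ coef).T
    return MethylationMatrix(
        pd.DataFrame(resid, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale=matrix.scale,
    )
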