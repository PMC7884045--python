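"""Per-CpG three-model scan, p-value combination and summaries.

Each probe is tested with the generalized correlation coefficient (GCC),
the kinship-covariance model and the pair random-intercept model (LME)
after phenotype and methylation have been residualized on the adjustment
covariates, so all three models see identical adjusted data.  GCC (the
nonlinear method) and kinship (the linear representative, chosen for its
consistency with LME) are combined by taking the per-probe minimum
p-value; BH FDR is applied directly to the combined p-values.  The LME
p-value is reported but excluded from the combination by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import gcc as _gcc
from .linear import kinship_matrix, mixed_scan, pair_structure
from .preprocess import MethylationMatrix, ProbeManifest, residualize, residualize_matrix

CHI2_MEDIAN_1DF = float(chi2.median(1))  # 0.4549364...
DEFAULT_THRESHOLDS = (1e-4, 1e-5, 1e-6)
KNOWN_FEATURES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic")


@dataclass
class EwasConfig:
    models: tuple[str, ...] = ("gcc", "kinship", "lme")
    combine_models: tuple[str, str] = ("gcc", "kinship")
    gcc_null: str = "reference"  # "reference" or "permutation"
    gcc_null_size: int = 19999
    gcc_n_perm: int = 999
    gcc_refine_top: int = 0  # re-run this many top GCC hits at higher n_perm
    gcc_refine_n_perm: int = 99999
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS


@dataclass
class EwasSummary:
    lambda_gc: dict
    counts: dict  # threshold -> number of probes with p_combined below it
    qq_table: pd.DataFrame
    n_probes: int
    n_overlap_top: int = 0  # probes passing the loosest threshold in both models


def combine_minp(p_gcc, p_kin):
    """Minimum of the two model p-values, with provenance.

    Returns ``(p_combined, winner)`` where winner is 'gcc', 'kinship', or
    the surviving model when the other is missing (NaN).
    """
    p_gcc = np.asarray(p_gcc, float)
    p_kin = np.asarray(p_kin, float)
    scalar = p_gcc.ndim == 0
    p_gcc, p_kin = np.atleast_1d(p_gcc), np.atleast_1d(p_kin)
    both_nan = np.isnan(p_gcc) & np.isnan(p_kin)
    if both_nan.any():
        raise ValueError("both model p-values missing")
    combined = np.where(
        np.isnan(p_gcc), p_kin, np.where(np.isnan(p_kin), p_gcc, np.minimum(p_gcc, p_kin))
    )
    winner = np.where(
        np.isnan(p_gcc),
        "kinship",
        np.where(np.isnan(p_kin), "gcc", np.where(p_gcc <= p_kin, "gcc", "kinship")),
    )
    if scalar:
        return float(combined[0]), str(winner[0])
    return combined, winner


def bh_fdr(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with an external test count.

    q_(i) = min_{j >= i} p_(j) * m_total / j, capped at 1.  ``m_total`` may
    exceed the number of supplied p-values (adjusting a printed top list
    against the full number of tests performed).
    """
    p = np.asarray(p_values, float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    k = len(p)
    if m_total is None:
        m_total = k
    if m_total < k:
        raise ValueError(f"m_total={m_total} smaller than number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total / np.arange(1, k + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def inflation_factor(p_values) -> float:
    """Genomic inflation factor: median of the implied 1-df chi-square
    statistics divided by the null median 0.4549."""
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any():
        import warnings

        warnings.warn("p-values of 0 clipped to machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_MEDIAN_1DF)


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for QQ plotting."""
    p = np.sort(np.asarray(p_values, float))
    k = len(p)
    expected = (np.arange(1, k + 1) - 0.5) / k
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )


def feature_distribution(records: pd.DataFrame, manifest: ProbeManifest, p_threshold: float):
    """Counts of sub-threshold probes per genomic feature, split by the
    direction of the linear coefficient (+ methylated / - demethylated),
    next to the all-manifest background."""
    man = manifest.table
    feats = man["feature"].where(man["feature"].isin(KNOWN_FEATURES), "other")
    background = feats.value_counts()
    hits = records[records["p_combined"] < p_threshold]
    hit_feats = hits["feature"].where(hits["feature"].isin(KNOWN_FEATURES), "other")
    out = pd.DataFrame(
        0,
        index=pd.Index(sorted(set(background.index) | set(KNOWN_FEATURES)), name="feature"),
        columns=["methylated", "demethylated", "background"],
    )
    for feat, direction in zip(hit_feats, hits["direction"]):
        out.loc[feat, "methylated" if direction == "+" else "demethylated"] += 1
    out["background"] = background.reindex(out.index).fillna(0).astype(int)
    return out


def run_ewas(
    matrix: MethylationMatrix,
    cohort,
    manifest: ProbeManifest | None = None,
    config: EwasConfig | None = None,
    seed: int = 0,
):
    """Run the per-CpG scan and return ``(records, summary)``.

    ``matrix`` must be on the M scale and fully observed (run
    :func:`~twinewas.preprocess.filter_probes` and
    :func:`~twinewas.preprocess.beta_to_m` first).
    """
    config = config or EwasConfig()
    if not config.models:
        raise ValueError("empty model list")
    unknown = set(config.models) - {"gcc", "kinship", "lme"}
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    if matrix.scale != "M":
        raise ValueError("run_ewas expects an M-scale matrix")
    if list(matrix.sample_ids) != list(cohort.sample_ids):
        raise ValueError("matrix samples and cohort samples are misaligned")

    cov = cohort.covariates()
    y_adj = residualize(cohort.cognitive_score, cov)
    m_adj = residualize_matrix(matrix, cov).values.to_numpy(float)
    n_probes = len(m_adj)

    records = pd.DataFrame({"probe_id": matrix.probe_ids})
    lambda_gc = {}

    if "gcc" in config.models:
        a, p_gcc = _gcc_scan(m_adj, y_adj, config, seed)
        records["a_score"], records["p_gcc"] = a, p_gcc
        lambda_gc["gcc"] = inflation_factor(p_gcc)
    else:
        records["a_score"] = np.nan
        records["p_gcc"] = np.nan

    kin_frame = None
    if "kinship" in config.models:
        kin = kinship_matrix(cohort)
        kin_frame = mixed_scan(y_adj, m_adj.T, kin)
        records["coef_lin"] = kin_frame["coef"].to_numpy()
        records["p_kin"] = kin_frame["p_value"].to_numpy()
        lambda_gc["kinship"] = inflation_factor(records["p_kin"])
    else:
        records["coef_lin"] = np.nan
        records["p_kin"] = np.nan

    if "lme" in config.models:
        lme_frame = mixed_scan(y_adj, m_adj.T, pair_structure(cohort.pair_ids))
        records["p_lme"] = lme_frame["p_value"].to_numpy()
        if "kinship" not in config.models:
            records["coef_lin"] = lme_frame["coef"].to_numpy()
        lambda_gc["lme"] = inflation_factor(records["p_lme"])
    else:
        records["p_lme"] = np.nan

    model_p = {"gcc": records["p_gcc"], "kinship": records["p_kin"], "lme": records["p_lme"]}
    pa = model_p[config.combine_models[0]].to_numpy(float)
    pb = model_p[config.combine_models[1]].to_numpy(float)
    combined, winner = combine_minp(pa, pb)
    records["p_combined"] = combined
    records["winner"] = winner
    records["q_value"] = bh_fdr(records["p_combined"], n_probes)
    records["direction"] = np.where(records["coef_lin"].to_numpy(float) >= 0, "+", "-")

    if manifest is not None:
        ann = manifest.table.set_index("probe_id").loc[records["probe_id"]]
        for col in ("chrom", "pos", "gene", "feature", "island"):
            if col in ann:
                records[col] = ann[col].to_numpy()

    thr = config.thresholds
    counts = {t: int((records["p_combined"] < t).sum()) for t in thr}
    loosest = max(thr)
    n_overlap = int(((pa < loosest) & (pb < loosest)).sum())
    summary = EwasSummary(
        lambda_gc=lambda_gc,
        counts=counts,
        qq_table=qq_table(records["p_combined"]),
        n_probes=n_probes,
        n_overlap_top=n_overlap,
    )
    return records, summary


def _gcc_scan(m_adj: np.ndarray, y_adj: np.ndarray, config: EwasConfig, seed: int):
    """A scores and p-values for every probe row of ``m_adj``."""
    n = m_adj.shape[1]
    cache = _gcc._kernels(n)
    sigmas = np.empty((len(m_adj), n), dtype=np.int64)
    degenerate = np.zeros(len(m_adj), bool)
    for i, row in enumerate(m_adj):
        if np.ptp(row) == 0 or _gcc._has_ties(row) or _gcc._has_ties(y_adj):
            degenerate[i] = True
            sigmas[i] = np.arange(n)
        else:
            sigmas[i] = _gcc._canonical(_gcc._matching_permutation(row, y_adj))
    obs_ll = np.empty(len(m_adj))
    chunk = 250
    for start in range(0, len(m_adj), chunk):
        obs_ll[start : start + chunk] = _gcc._joint_ll(sigmas[start : start + chunk], cache)
    a = np.asarray(_gcc._ll_to_a(obs_ll, cache.marginal_ll, n))

    if config.gcc_null == "reference":
        table = _gcc.null_reference(n, config.gcc_null_size)
        p = _gcc.reference_pvalues(obs_ll, table)
    elif config.gcc_null == "permutation":
        p = np.empty(len(m_adj))
        for i, row in enumerate(m_adj):
            p[i] = _gcc.gcc_pvalue(row, y_adj, config.gcc_n_perm, seed=seed + i).p_value
    else:
        raise ValueError(f"unknown gcc_null method {config.gcc_null!r}")

    if config.gcc_refine_top:
        top = np.argsort(p, kind="stable")[: config.gcc_refine_top]
        for i in top:
            if not degenerate[i]:
                res = _gcc.gcc_pvalue(
                    m_adj[i], y_adj, config.gcc_refine_n_perm, seed=seed + int(i), tail="gpd"
                )
                p[i] = res.p_value

    # degenerate probes: constant rows score 0 with p 1; tied rows fall back
    # to the general permutation path
    for i in np.flatnonzero(degenerate):
        if np.ptp(m_adj[i]) == 0:
            a[i], p[i] = 0.0, 1.0
        else:
            res = _gcc.gcc_pvalue(m_adj[i], y_adj, config.gcc_n_perm, seed=seed + int(i))
            a[i], p[i] = res.a_score, res.p_value
    return a, p
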