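"""Region calling from per-CpG p-values (comb-p style).

Pipeline: (1) estimate the autocorrelation of p-value z-scores as a
function of genomic distance; (2) smooth each probe's p-value by a
Stouffer-Liptak combination of its neighbours under that correlation;
(3) seed and extend candidate regions below a threshold; (4) score each
region by the Stouffer-Liptak combination of its members' original
p-values, apply a Sidak correction for the number of same-sized regions
the covered genome could host, and BH-adjust across candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_BIN_EDGES = (1, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500)
MIN_PAIRS_PER_BIN = 30
P_CLIP = 1e-15


@dataclass
class AcfModel:
    """Distance-binned autocorrelation of p-value z-scores.

    ``rho[k]`` is the correlation for pair distances in
    (bin_edges[k], bin_edges[k+1]]; distance 0 has implicit rho 1; bins
    flagged in ``empty`` had too few pairs and report rho 0.
    """

    bin_edges: np.ndarray
    rho: np.ndarray
    n_pairs: np.ndarray
    empty: np.ndarray

    def correlation(self, distance: np.ndarray) -> np.ndarray:
        """rho for arbitrary distances (0 beyond the last bin edge)."""
        distance = np.abs(np.asarray(distance, float))
        idx = np.searchsorted(self.bin_edges[1:], distance, side="left")
        out = np.zeros_like(distance, float)
        inside = distance <= self.bin_edges[-1]
        out[inside] = self.rho[np.minimum(idx[inside], len(self.rho) - 1)]
        out[distance == 0] = 1.0
        return out


@dataclass
class Region:
    chrom: str
    start: int  # 0-based half-open
    end: int
    probe_idx: np.ndarray
    n_probes: int
    p_slk: float = np.nan
    p_sidak: float = np.nan
    q_value: float = np.nan
    direction: str = ""


def _zscores(p: np.ndarray) -> np.ndarray:
    return norm.isf(np.clip(p, P_CLIP, 1 - P_CLIP))


def _sorted_positions(records: pd.DataFrame, manifest) -> pd.DataFrame:
    man = manifest.table.set_index("probe_id")
    df = records.set_index("probe_id")
    df = df.join(man[["chrom", "pos"]], how="inner", lsuffix="", rsuffix="_man")
    if "chrom_man" in df:
        df["chrom"] = df.pop("chrom_man")
    if "pos_man" in df:
        df["pos"] = df.pop("pos_man")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index()


def estimate_acf(
    records: pd.DataFrame,
    manifest,
    bin_edges=DEFAULT_BIN_EDGES,
    max_dist: int | None = None,
    p_column: str = "p_combined",
) -> AcfModel:
    """Correlation of p-value z-scores per distance bin, over all probe
    pairs on the same chromosome with distance inside the bin.  Bins with
    fewer than 30 pairs are flagged and report rho 0; rho is clipped to
    [0, 1] for combining."""
    edges = np.asarray(bin_edges, float)
    if max_dist is None:
        max_dist = edges[-1]
    df = _sorted_positions(records, manifest)
    z = _zscores(df[p_column].to_numpy(float))
    pos = df["pos"].to_numpy(np.int64)
    chrom = df["chrom"].to_numpy()

    n_bins = len(edges) - 1
    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]
    for i in range(len(df)):
        j = i + 1
        while j < len(df) and chrom[j] == chrom[i] and pos[j] - pos[i] <= max_dist:
            d = pos[j] - pos[i]
            k = int(np.searchsorted(edges[1:], d, side="left"))
            if k < n_bins:
                pairs_a[k].append(z[i])
                pairs_b[k].append(z[j])
            j += 1

    rho = np.zeros(n_bins)
    n_pairs = np.array([len(a) for a in pairs_a])
    empty = n_pairs < MIN_PAIRS_PER_BIN
    for k in range(n_bins):
        if not empty[k]:
            r = np.corrcoef(pairs_a[k], pairs_b[k])[0, 1]
            rho[k] = np.clip(r, 0.0, 1.0) if np.isfinite(r) else 0.0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} ACF bin(s) had fewer than {MIN_PAIRS_PER_BIN} pairs; "
            "their correlation is set to 0"
        )
    return AcfModel(bin_edges=edges, rho=rho, n_pairs=n_pairs, empty=empty)


def _nearest_psd(sigma: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() >= -1e-10:
        return sigma
    vals = np.maximum(vals, 1e-10)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def stouffer_liptak(ps, sigma=None) -> float:
    """Stouffer-Liptak combination of correlated p-values.

    z_c = sum(z_i) / sqrt(1' sigma 1) with z_i = Phi^{-1}(1 - p_i); returns
    1 - Phi(z_c).  With identity sigma this is the classical Stouffer
    combination; a non-PSD empirical sigma is repaired to the nearest PSD
    correlation matrix first."""
    ps = np.atleast_1d(np.asarray(ps, float))
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ((ps <= 0) | (ps >= 1)).any():
        warnings.warn("p-values at 0 or 1 clipped before z-transform")
    if len(ps) == 1:
        return float(ps[0])
    if sigma is None:
        sigma = np.eye(len(ps))
    sigma = np.asarray(sigma, float)
    if sigma.shape != (len(ps), len(ps)):
        raise ValueError("sigma dimension does not match number of p-values")
    sigma = _nearest_psd(sigma)
    z = _zscores(ps)
    denom = float(sigma.sum())
    if denom <= 0:
        raise ValueError("correlation matrix sums to a non-positive total")
    zc = z.sum() / np.sqrt(denom)
    return float(norm.sf(zc))


def slk_correct(
    records: pd.DataFrame,
    manifest,
    acf: AcfModel,
    window: int = 1000,
    p_column: str = "p_combined",
) -> pd.DataFrame:
    """Replace each probe's p-value by the Stouffer-Liptak combination of
    all probes within +-window/2, with pairwise correlations from the ACF
    model.  Isolated probes keep their p-value.  Returns the records sorted
    by (chrom, pos) with a ``p_slk`` column."""
    df = _sorted_positions(records, manifest)
    p = df[p_column].to_numpy(float)
    pos = df["pos"].to_numpy(np.int64)
    chrom = df["chrom"].to_numpy()
    half = window / 2.0
    out = np.empty(len(df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(df)):
            lo = i
            while lo > 0 and chrom[lo - 1] == chrom[i] and pos[i] - pos[lo - 1] <= half:
                lo -= 1
            hi = i
            while hi < len(df) - 1 and chrom[hi + 1] == chrom[i] and pos[hi + 1] - pos[i] <= half:
                hi += 1
            if hi == lo:
                out[i] = p[i]
                continue
            idx = np.arange(lo, hi + 1)
            dmat = np.abs(pos[idx][:, None] - pos[idx][None, :]).astype(float)
            sigma = acf.correlation(dmat)
            np.fill_diagonal(sigma, 1.0)
            out[i] = stouffer_liptak(p[idx], sigma)
    df["p_slk"] = out
    return df


def find_peaks(
    corrected: pd.DataFrame,
    seed_thresh: float = 1e-3,
    extend_thresh: float | None = None,
    max_gap: int = 500,
) -> list[Region]:
    """Candidate regions: seeded at probes with corrected p below
    ``seed_thresh``, extended bidirectionally over probes below
    ``extend_thresh`` separated by at most ``max_gap`` bp; regions with
    fewer than 2 probes are dropped."""
    if extend_thresh is None:
        extend_thresh = seed_thresh
    if not (0 < seed_thresh < 1 and 0 < extend_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    p = corrected["p_slk"].to_numpy(float)
    pos = corrected["pos"].to_numpy(np.int64)
    chrom = corrected["chrom"].to_numpy()
    regions: list[Region] = []
    n = len(corrected)
    i = 0
    while i < n:
        if p[i] >= extend_thresh:
            i += 1
            continue
        # run of extendable probes with gaps <= max_gap on one chromosome
        j = i
        while (
            j + 1 < n
            and chrom[j + 1] == chrom[i]
            and p[j + 1] < extend_thresh
            and pos[j + 1] - pos[j] <= max_gap
        ):
            j += 1
        members = np.arange(i, j + 1)
        if len(members) >= 2 and (p[members] < seed_thresh).any():
            regions.append(
                Region(
                    chrom=str(chrom[i]),
                    start=int(pos[i] - 1),
                    end=int(pos[j]),
                    probe_idx=members,
                    n_probes=len(members),
                )
            )
        i = j + 1
    return regions


def region_p(
    region: Region,
    corrected: pd.DataFrame,
    acf: AcfModel,
    total_covered_bases: int,
    p_column: str = "p_combined",
) -> tuple[float, float]:
    """(p_slk, p_sidak) for one region.

    p_slk combines the members' *original* p-values under the ACF-derived
    correlation; p_sidak = 1 - (1 - p_slk)^(total_covered_bases /
    region_span) penalizes the number of same-sized regions the covered
    extent could host."""
    if region.n_probes < 2:
        raise ValueError("region must contain at least 2 probes")
    span = region.end - region.start
    if span <= 0:
        raise ValueError("region has zero span")
    idx = region.probe_idx
    pos = corrected["pos"].to_numpy(np.int64)[idx]
    dmat = np.abs(pos[:, None] - pos[None, :]).astype(float)
    sigma = acf.correlation(dmat)
    np.fill_diagonal(sigma, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_slk = stouffer_liptak(corrected[p_column].to_numpy(float)[idx], sigma)
    exponent = max(total_covered_bases / span, 1.0)
    # 1 - (1 - p)^k via expm1/log1p so tiny p survive in float
    p_sidak = float(-np.expm1(exponent * np.log1p(-min(p_slk, 1.0 - 1e-16))))
    return p_slk, p_sidak


def region_fdr(regions: list[Region]) -> list[Region]:
    """BH q-values over the candidate regions' Sidak-corrected p-values."""
    from .ewas import bh_fdr

    if not regions:
        return regions
    q = bh_fdr([max(r.p_sidak, np.finfo(float).tiny) for r in regions])
    for r, qv in zip(regions, q):
        r.q_value = float(qv)
    return regions


@dataclass
class DmrConfig:
    window: int = 1000
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
    seed_thresh: float = 1e-3
    extend_thresh: float | None = None
    max_gap: int = 500
    p_column: str = "p_combined"


def call_dmrs(
    records: pd.DataFrame, manifest, config: DmrConfig | None = None
) -> tuple[pd.DataFrame, AcfModel]:
    """Full region pipeline; returns a region table and the ACF model.

    Direction is labelled hyper/hypo-methylated from the mean sign of the
    members' linear coefficients."""
    config = config or DmrConfig()
    acf = estimate_acf(records, manifest, config.bin_edges, p_column=config.p_column)
    corrected = slk_correct(records, manifest, acf, config.window, config.p_column)
    regions = find_peaks(corrected, config.seed_thresh, config.extend_thresh, config.max_gap)
    pos = corrected["pos"].to_numpy(np.int64)
    chrom = corrected["chrom"].to_numpy()
    total_covered = 0
    for c in pd.unique(chrom):
        sel = chrom == c
        total_covered += int(pos[sel].max() - pos[sel].min() + 1)
    coefs = corrected.get("coef_lin")
    for r in regions:
        r.p_slk, r.p_sidak = region_p(r, corrected, acf, total_covered, config.p_column)
        if coefs is not None:
            mean_sign = np.nanmean(np.asarray(coefs, float)[r.probe_idx])
            r.direction = "hyper" if mean_sign >= 0 else "hypo"
    region_fdr(regions)
    table = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_probes": [r.n_probes for r in regions],
            "p_slk": [r.p_slk for r in regions],
            "p_sidak": [r.p_sidak for r in regions],
            "q_value": [r.q_value for r in regions],
            "direction": [r.direction for r in regions],
            "probes": [";".join(corrected["probe_id"].iloc[r.probe_idx]) for r in regions],
        }
    )
    return table.sort_values("p_sidak", kind="stable").reset_index(drop=True), acf
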