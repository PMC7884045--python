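"""Synthetic twin cohorts and methylomes with known ground truth.

The generator emulates the statistical structure a twin EWAS assumes:
paired samples with a shared (zygosity-dependent) methylome component, a
standardized cognitive composite declining with age and higher in females,
bimodal beta values, spatial correlation among nearby CpGs, and implanted
single-CpG effects (linear and nonlinear) plus multi-CpG region blocks.
Every dataset comes with a truth table so downstream error and power are
measurable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

EFFECT_SHAPES = ("null", "linear", "quadratic", "sine", "step", "variance")

#: typical leukocyte subtype proportions (monocytes, lymphocytes, basophils,
#: neutrophils, eosinophils) in adult whole blood
_CELL_MEANS = np.array([0.08, 0.30, 0.005, 0.59, 0.025])
_CELL_CONCENTRATION = 300.0


class SimulationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class CohortConfig:
    """Parameters of the twin cohort generator.

    Defaults emulate the discovery cohort profile: 200 MZ pairs aged 56-80
    (sample mean 66.55, sd 5.96), 45% female individuals, a cognitive
    composite built from five standardized subscores with within-pair
    correlation ``pair_correlation``, declining with age and higher in
    females.
    """

    n_pairs: int = 200
    zygosity_mix: float = 1.0  # fraction of pairs that are MZ
    age_mean: float = 66.55
    age_sd: float = 5.96
    age_range: tuple[float, float] = (56.0, 80.0)
    sex_ratio: float = 0.45  # probability that a pair is female
    age_effect: float = -0.02  # subscore units per year (pre-standardization)
    sex_effect: float = 0.15  # female minus male subscore shift (pre-standardization)
    pair_correlation: float = 0.5

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise SimulationError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if not (0.0 <= self.pair_correlation < 1.0):
            raise SimulationError(
                f"pair_correlation must be in [0, 1), got {self.pair_correlation}"
            )
        if not (0.0 <= self.zygosity_mix <= 1.0):
            raise SimulationError(f"zygosity_mix must be in [0, 1], got {self.zygosity_mix}")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise SimulationError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if self.age_sd <= 0:
            raise SimulationError(f"age_sd must be positive, got {self.age_sd}")
        lo, hi = self.age_range
        if not lo < hi:
            raise SimulationError(f"age_range lower must be < upper, got {self.age_range}")
        if not (lo <= self.age_mean <= hi):
            raise SimulationError(
                f"age_mean {self.age_mean} outside age_range {self.age_range}"
            )


@dataclass
class TwinCohort:
    """A twin cohort: one row per sample, pair structure and covariates."""

    samples: pd.DataFrame

    CELL_COLUMNS = ("monocytes", "lymphocytes", "basophils", "neutrophils", "eosinophils")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    @property
    def cognitive_score(self) -> np.ndarray:
        return self.samples["cognitive_score"].to_numpy(float)

    @property
    def pair_ids(self) -> np.ndarray:
        return self.samples["pair_id"].to_numpy()

    def covariates(self) -> pd.DataFrame:
        """Adjustment covariates: age, sex (F=1), five cell fractions."""
        cov = pd.DataFrame(index=self.samples.index)
        cov["age"] = self.samples["age"]
        cov["sex"] = (self.samples["sex"] == "F").astype(float)
        for c in self.CELL_COLUMNS:
            cov[c] = self.samples[c]
        return cov

    def validate(self) -> None:
        counts = self.samples["pair_id"].value_counts()
        if (counts > 2).any():
            bad = counts[counts > 2].index[0]
            raise SimulationError(f"pair {bad!r} has more than two members")
        zyg = self.samples.groupby("pair_id")["zygosity"].nunique()
        if (zyg > 1).any():
            bad = zyg[zyg > 1].index[0]
            raise SimulationError(f"pair {bad!r} mixes zygosity labels")
        cells = self.samples[list(self.CELL_COLUMNS)].to_numpy(float)
        if (cells < 0).any() or (cells.sum(axis=1) > 1 + 1e-9).any():
            raise SimulationError("cell fractions must be non-negative and sum to <= 1")


def _truncnorm_params(mean: float, sd: float, lower: float, upper: float):
    """Underlying (mu, sigma) so the truncated distribution has the target
    mean and sd.

    The printed cohort statistics describe the bounded sample itself, so the
    generator moment-matches the truncation rather than truncating a normal
    with the target moments (which would shift the realized mean).
    """

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(moments, x0=[mean, np.log(sd)], full_output=False)
    mu, sigma = sol[0], float(np.exp(sol[1]))
    return mu, sigma


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> TwinCohort:
    """Generate a twin cohort with paired ages, sexes and a standardized
    cognitive composite.

    Co-twins share age and (for MZ pairs) sex; the composite is the
    standardized sum of five standardized subscores, each mixing a shared
    pair component (variance ``pair_correlation``) with individual noise,
    plus a negative age trend and a positive female shift.  Deterministic
    for a fixed seed.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_pairs = config.n_pairs
    lo, hi = config.age_range

    mu, sigma = _truncnorm_params(config.age_mean, config.age_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    pair_age = truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n_pairs, random_state=rng)

    n_mz = int(round(config.zygosity_mix * n_pairs))
    zygosity_pair = np.array(["MZ"] * n_mz + ["DZ"] * (n_pairs - n_mz))
    rng.shuffle(zygosity_pair)
    pair_sex = np.where(rng.random(n_pairs) < config.sex_ratio, "F", "M")

    age = np.repeat(pair_age, 2)
    sex = np.repeat(pair_sex, 2)
    # DZ co-twins may be opposite-sex
    dz_members = np.repeat(zygosity_pair == "DZ", 2) & (np.arange(2 * n_pairs) % 2 == 1)
    flip = dz_members & (rng.random(2 * n_pairs) < 0.5)
    sex = np.where(flip, np.where(sex == "F", "M", "F"), sex)

    rho = config.pair_correlation
    n = 2 * n_pairs
    female = (sex == "F").astype(float)
    age_c = age - age.mean()
    subscores = np.empty((5, n))
    for k in range(5):
        shared = np.repeat(rng.normal(size=n_pairs), 2)
        indiv = rng.normal(size=n)
        raw = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
        raw = raw + config.age_effect * age_c + config.sex_effect * female
        subscores[k] = (raw - raw.mean()) / raw.std()
    composite = subscores.sum(axis=0)
    composite = (composite - composite.mean()) / composite.std()

    # the five typed fractions deliberately sum to slightly below 1
    # (unclassified cells exist), which also keeps the covariate design
    # full-rank next to the intercept
    cells = rng.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)
    cells *= rng.beta(96.0, 4.0, size=n)[:, None]

    samples = pd.DataFrame(
        {
            "sample_id": [f"s{p:04d}_{t}" for p in range(n_pairs) for t in (1, 2)],
            "pair_id": np.repeat([f"p{p:04d}" for p in range(n_pairs)], 2),
            "zygosity": np.repeat(zygosity_pair, 2),
            "age": age,
            "sex": sex,
            "monocytes": cells[:, 0],
            "lymphocytes": cells[:, 1],
            "basophils": cells[:, 2],
            "neutrophils": cells[:, 3],
            "eosinophils": cells[:, 4],
            "cognitive_score": composite,
        }
    )
    cohort = TwinCohort(samples)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# methylome


@dataclass
class MethylomeConfig:
    """Parameters of the synthetic methylome generator.

    Probes sit on one synthetic chromosome with gaps drawn from a mixture of
    short island-like (~``island_gap_bp``) and long open-sea (~``open_sea_gap_bp``)
    spacings.  Beta values come from a two-mode baseline on the beta scale;
    noise, twin sharing and implanted effects act on the M-value scale and
    are mapped back through the inverse logit, so betas stay strictly
    inside (0, 1).
    """

    n_probes: int = 2000
    chrom: str = "chr1"
    start_bp: int = 10_000
    island_gap_bp: float = 50.0
    open_sea_gap_bp: float = 5000.0
    island_weight: float = 0.6
    baseline_modes: tuple[float, float] = (0.15, 0.85)
    baseline_sd: float = 0.05
    noise_sd_m: float = 0.5
    spatial_decay_bp: float = 200.0
    pair_share: float = 0.10  # mean MZ co-twin shared fraction of probe variance
    dz_share_ratio: float = 0.5  # DZ share = probe share * dz_share_ratio
    pair_share_shape: float = 0.5  # Beta shape a of the per-probe share law
    n_causal_per_shape: int = 0
    causal_shapes: tuple[str, ...] = ("linear", "quadratic", "sine", "step", "variance")
    effect_size: float = 0.25  # M units per sd of the (standardized) shape
    n_true_regions: int = 0
    region_n_probes: int = 5
    region_span_bp: float = 1000.0
    region_effect_size: float = 0.25
    missing_rate: float = 0.0
    n_flagged_probes: int = 0

    def validate(self) -> None:
        if self.n_probes < 10:
            raise SimulationError(f"n_probes must be >= 10, got {self.n_probes}")
        if self.spatial_decay_bp <= 0:
            raise SimulationError(
                f"spatial_decay_bp must be positive, got {self.spatial_decay_bp}"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (0.0 <= self.pair_share < 1.0):
            raise SimulationError(f"pair_share must be in [0, 1), got {self.pair_share}")
        unknown = set(self.causal_shapes) - set(EFFECT_SHAPES)
        if unknown:
            raise SimulationError(f"unknown effect shapes: {sorted(unknown)}")
        if self.region_n_probes < 3:
            raise SimulationError(
                f"region_n_probes must be >= 3, got {self.region_n_probes}"
            )


def shape_function(shape: str, score: np.ndarray) -> np.ndarray:
    """Standardized effect shapes g(c) with population mean 0 and variance 1.

    ``linear`` is the identity; ``quadratic`` and ``sine`` are orthogonal to
    it (the sine acts on the probability scale, cos(4*pi*Phi(c)), which has
    exactly zero linear correlation with c by symmetry); ``step`` is the
    sign; ``variance`` carries no mean effect (handled by the caller as a
    noise modifier) and returns |c| standardized.
    """
    from scipy.stats import norm

    c = np.asarray(score, float)
    if shape == "null":
        return np.zeros_like(c)
    if shape == "linear":
        return c
    if shape == "quadratic":
        return (c**2 - 1.0) / np.sqrt(2.0)
    if shape == "sine":
        return np.sqrt(2.0) * np.cos(4.0 * np.pi * norm.cdf(c))
    if shape == "step":
        return np.sign(c)
    if shape == "variance":
        absc = np.abs(c)
        return (absc - np.sqrt(2 / np.pi)) / np.sqrt(1 - 2 / np.pi)
    raise SimulationError(f"unknown effect shape {shape!r}")


def m_to_beta_array(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-np.asarray(m, float)))


def _positions(config: MethylomeConfig, rng: np.random.Generator) -> np.ndarray:
    short = rng.random(config.n_probes) < config.island_weight
    gaps = np.where(
        short,
        rng.exponential(config.island_gap_bp, config.n_probes),
        rng.exponential(config.open_sea_gap_bp, config.n_probes),
    )
    gaps = np.maximum(np.round(gaps), 2).astype(np.int64)
    pos = config.start_bp + np.cumsum(gaps)
    return pos


def _pick_region_runs(
    pos: np.ndarray, config: MethylomeConfig, rng: np.random.Generator, blocked: np.ndarray
) -> list[np.ndarray]:
    """Non-overlapping runs of consecutive probes that fit in region_span_bp."""
    k = config.region_n_probes
    n = len(pos)
    span = pos[k - 1 :] - pos[: n - k + 1]
    candidates = [
        i
        for i in range(n - k + 1)
        if span[i] <= config.region_span_bp and not blocked[i : i + k].any()
    ]
    rng.shuffle(candidates)
    runs: list[np.ndarray] = []
    taken = np.zeros(n, bool)
    for i in candidates:
        if len(runs) == config.n_true_regions:
            break
        if taken[max(0, i - 1) : i + k + 1].any():  # keep runs non-adjacent
            continue
        runs.append(np.arange(i, i + k))
        taken[i : i + k] = True
    if len(runs) < config.n_true_regions:
        raise SimulationError(
            f"region_span_bp={config.region_span_bp} too small to host "
            f"{config.n_true_regions} runs of {k} probes"
        )
    return runs


def generate_methylome(
    cohort: TwinCohort, config: MethylomeConfig | None = None, seed: int = 0
):
    """Generate a (beta-scale) methylation matrix, manifest and truth table.

    Returns ``(MethylationMatrix, ProbeManifest, SimulationTruth table)``.
    Spatial correlation between adjacent probes decays as
    exp(-gap / spatial_decay_bp) (first-order autoregression along the
    chromosome); co-twins share a fraction of probe variance (``pair_share``
    for MZ, scaled by ``dz_share_ratio`` for DZ).
    """
    from .preprocess import MethylationMatrix, ProbeManifest

    config = config or MethylomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_probes, n = config.n_probes, cohort.n
    pos = _positions(config, rng)
    probe_ids = np.array([f"cg{i:07d}" for i in range(n_probes)])

    # flags: sex-chromosome / SNP / cross-reactive stand-ins, no signal
    flags = np.array([""] * n_probes, dtype=object)
    chroms = np.array([config.chrom] * n_probes, dtype=object)
    if config.n_flagged_probes:
        idx = rng.choice(n_probes, size=config.n_flagged_probes, replace=False)
        kinds = rng.choice(["sex_chrom", "snp_probe", "cross_reactive"], size=len(idx))
        flags[idx] = kinds
        chroms[idx[kinds == "sex_chrom"]] = "chrX"

    # baseline bimodal betas -> M-value intercept
    mode = rng.random(n_probes) < 0.5
    base = np.where(
        mode,
        rng.normal(config.baseline_modes[0], config.baseline_sd, n_probes),
        rng.normal(config.baseline_modes[1], config.baseline_sd, n_probes),
    )
    base = np.clip(base, 0.02, 0.98)
    m0 = np.log2(base / (1.0 - base))

    # spatially correlated noise: AR(1) along probes, shared + individual
    gaps = np.diff(pos, prepend=pos[0])
    ar = np.exp(-gaps / config.spatial_decay_bp)
    ar[0] = 0.0

    def ou(cols: int) -> np.ndarray:
        z = rng.normal(size=(n_probes, cols))
        for p in range(1, n_probes):
            z[p] = ar[p] * z[p - 1] + np.sqrt(1.0 - ar[p] ** 2) * z[p]
        return z

    pair_index = pd.factorize(cohort.samples["pair_id"])[0]
    n_pairs = pair_index.max() + 1
    z_pair = ou(n_pairs)[:, pair_index]
    z_ind = ou(n)
    # per-probe twin-shared variance: right-skewed across probes (most CpGs
    # are noise-dominated; a minority carry substantial familial variance),
    # with mean pair_share
    if config.pair_share > 0:
        a = config.pair_share_shape
        b = a * (1.0 - config.pair_share) / config.pair_share
        probe_share = np.clip(rng.beta(a, b, size=n_probes), 0.0, 0.99)
    else:
        probe_share = np.zeros(n_probes)
    zyg_factor = np.where(
        cohort.samples["zygosity"].to_numpy() == "MZ", 1.0, config.dz_share_ratio
    )
    share = probe_share[:, None] * zyg_factor[None, :]
    noise = np.sqrt(share) * z_pair + np.sqrt(1.0 - share) * z_ind

    # implanted effects
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "effect_shape": "null",
            "effect_size": 0.0,
            "in_true_region": False,
            "region_id": "",
        }
    )
    score = cohort.cognitive_score
    effect_m = np.zeros((n_probes, n))
    noise_scale = np.ones((n_probes, n))
    blocked = flags != ""

    runs = (
        _pick_region_runs(pos, config, rng, blocked) if config.n_true_regions else []
    )
    for r, run in enumerate(runs):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effect_m[run] += sign * config.region_effect_size * score[None, :]
        truth.loc[run, ["effect_shape", "effect_size"]] = ["linear", config.region_effect_size]
        truth.loc[run, "in_true_region"] = True
        truth.loc[run, "region_id"] = f"region{r:03d}"
        blocked[run] = True

    if config.n_causal_per_shape:
        shapes = [s for s in config.causal_shapes if s != "null"]
        free = np.flatnonzero(~blocked)
        need = config.n_causal_per_shape * len(shapes)
        if need > len(free):
            raise SimulationError("not enough unflagged probes for requested causal effects")
        chosen = rng.choice(free, size=need, replace=False)
        for k, shape in enumerate(shapes):
            idx = chosen[k * config.n_causal_per_shape : (k + 1) * config.n_causal_per_shape]
            if shape == "variance":
                noise_scale[idx] = 1.0 + config.effect_size * np.abs(score)[None, :]
            else:
                effect_m[idx] += config.effect_size * shape_function(shape, score)[None, :]
            truth.loc[idx, ["effect_shape", "effect_size"]] = [shape, config.effect_size]

    m = m0[:, None] + config.noise_sd_m * noise * noise_scale + effect_m
    beta = m_to_beta_array(m)

    if config.missing_rate > 0:
        mask = rng.random(beta.shape) < config.missing_rate
        beta[mask] = np.nan

    values = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"),
                          columns=cohort.sample_ids)
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": pos,
            "gene": [f"GENE{i // 20:05d}" for i in range(n_probes)],
            "feature": rng.choice(
                ["TSS200", "TSS1500", "5'UTR", "Body", "3'UTR", "intergenic"],
                size=n_probes,
                p=[0.1, 0.1, 0.1, 0.35, 0.05, 0.3],
            ),
            "island": rng.choice(
                ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", ""],
                size=n_probes,
                p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4],
            ),
            "flags": flags,
        }
    )
    return (
        MethylationMatrix(values, scale="beta"),
        ProbeManifest(manifest),
        truth,
    )


def config_to_dict(config) -> dict:
    return asdict(config)
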