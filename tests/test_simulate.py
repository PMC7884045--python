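import io

import numpy as np
import pandas as pd
import pytest

import twinewas as tw
from twinewas.simulate import SimulationError, shape_function


def _pair_corr(cohort):
    pairs = cohort.samples.groupby("pair_id")["cognitive_score"].apply(list)
    pairs = [p for p in pairs if len(p) == 2]
    a, b = zip(*pairs)
    return np.corrcoef(a, b)[0, 1]


class TestCohort:
    def test_structure_invariants(self, madt_cohort):
        df = madt_cohort.samples
        assert (df["pair_id"].value_counts() <= 2).all()
        assert (df.groupby("pair_id")["zygosity"].nunique() == 1).all()
        cells = df[list(tw.TwinCohort.CELL_COLUMNS)].to_numpy()
        assert (cells >= 0).all() and (cells.sum(axis=1) <= 1).all()

    def test_score_standardized(self, madt_cohort):
        score = madt_cohort.cognitive_score
        assert abs(score.mean()) < 0.05
        assert abs(score.std() - 1) < 0.05

    def test_age_distribution_matches_target(self, madt_cohort):
        """Moment-matched truncated normal: sample mean/sd near the
        configured 66.55 / 5.96 within Monte-Carlo error (200 pair draws)."""
        age = madt_cohort.samples["age"]
        assert (age >= 56).all() and (age <= 80).all()
        assert abs(age.mean() - 66.55) < 3 * 5.96 / np.sqrt(200)
        assert abs(age.std() - 5.96) < 1.0

    def test_cotwins_share_age_and_mz_sex(self, madt_cohort):
        g = madt_cohort.samples.groupby("pair_id")
        assert (g["age"].nunique() == 1).all()
        assert (g["sex"].nunique() == 1).all()  # MZ-only cohort

    def test_determinism(self):
        a = tw.generate_cohort(seed=5).samples.to_csv()
        b = tw.generate_cohort(seed=5).samples.to_csv()
        assert a == b

    def test_independent_pairs_have_no_correlation(self):
        cfg = tw.CohortConfig(pair_correlation=0.0, age_effect=0.0, sex_effect=0.0)
        c = tw.generate_cohort(cfg, seed=3)
        assert abs(_pair_corr(c)) < 0.1

    def test_default_pair_correlation_near_half(self, madt_cohort):
        assert 0.35 < _pair_corr(madt_cohort) < 0.68

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_pairs": 0}, "n_pairs"),
            ({"pair_correlation": 1.0}, "pair_correlation"),
            ({"age_sd": -1.0}, "age_sd"),
            ({"age_range": (80.0, 56.0)}, "age_range"),
            ({"sex_ratio": 1.5}, "sex_ratio"),
        ],
    )
    def test_invalid_config_names_parameter(self, kwargs, match):
        with pytest.raises(SimulationError, match=match):
            tw.generate_cohort(tw.CohortConfig(**kwargs), seed=0)


class TestMethylome:
    @pytest.fixture(scope="class")
    def methylome(self, madt_cohort):
        cfg = tw.MethylomeConfig(
            n_probes=600,
            n_causal_per_shape=5,
            n_true_regions=2,
            missing_rate=0.02,
            n_flagged_probes=15,
        )
        return tw.generate_methylome(madt_cohort, cfg, seed=21)

    def test_betas_strictly_inside_unit_interval(self, methylome):
        matrix, _, _ = methylome
        vals = matrix.values.to_numpy()
        observed = vals[~np.isnan(vals)]
        assert (observed > 0).all() and (observed < 1).all()

    def test_missingness_and_flags_injected(self, methylome):
        matrix, manifest, _ = methylome
        frac = np.isnan(matrix.values.to_numpy()).mean()
        assert 0.01 < frac < 0.03
        assert (manifest.table["flags"] != "").sum() == 15

    def test_truth_regions_are_consecutive_runs(self, methylome):
        matrix, manifest, truth = methylome
        man = manifest.table.set_index("probe_id")
        for rid, grp in truth[truth["in_true_region"]].groupby("region_id"):
            assert len(grp) >= 3
            rows = man.loc[grp["probe_id"]]
            order = np.searchsorted(
                np.sort(man["pos"].to_numpy()), np.sort(rows["pos"].to_numpy())
            )
            assert (np.diff(order) == 1).all()

    def test_pass_through_when_clean(self, madt_cohort):
        cfg = tw.MethylomeConfig(n_probes=10, missing_rate=0.0, n_flagged_probes=0)
        matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=2)
        out, _, report = tw.filter_probes(matrix, manifest)
        assert out.n_probes == 10
        assert report == {"flag": 0, "missing": 0}

    def test_determinism(self, madt_cohort):
        cfg = tw.MethylomeConfig(n_probes=50)
        a, _, _ = tw.generate_methylome(madt_cohort, cfg, seed=4)
        b, _, _ = tw.generate_methylome(madt_cohort, cfg, seed=4)
        assert a.values.to_csv() == b.values.to_csv()

    def test_spatial_correlation_decays_with_distance(self, madt_cohort):
        """Adjacent-probe correlation beats distant-pair correlation when
        spatial_decay_bp=200."""
        cfg = tw.MethylomeConfig(n_probes=1200, spatial_decay_bp=200.0, pair_share=0.0)
        matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=6)
        m = tw.beta_to_m(matrix).values.to_numpy()
        m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
        pos = manifest.table["pos"].to_numpy()
        gaps = np.diff(pos)
        r_adj = np.array([np.dot(m[i], m[i + 1]) / m.shape[1] for i in range(len(m) - 1)])
        near = (gaps >= 1) & (gaps <= 200)
        far = (gaps >= 800) & (gaps <= 1000)
        assert r_adj[near].mean() > r_adj[far].mean() + 0.2

    def test_mz_pairs_share_more_than_dz(self, mixed_cohort):
        cfg = tw.MethylomeConfig(n_probes=400, pair_share=0.4)
        matrix, _, _ = tw.generate_methylome(mixed_cohort, cfg, seed=8)
        m = tw.beta_to_m(matrix).values.to_numpy()
        df = mixed_cohort.samples
        first = np.arange(0, len(df), 2)
        second = first + 1
        mz = (df["zygosity"].to_numpy() == "MZ")[first]

        def mean_icc(cols_a, cols_b):
            a = m[:, cols_a]
            b = m[:, cols_b]
            a = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
            b = (b - b.mean(1, keepdims=True)) / b.std(1, keepdims=True)
            return (a * b).mean()

        assert mean_icc(first[mz], second[mz]) > mean_icc(first[~mz], second[~mz]) + 0.1

    def test_shape_functions_standardized(self, rng):
        c = rng.normal(size=200_000)
        for shape in ("linear", "quadratic", "sine", "step", "variance"):
            g = shape_function(shape, c)
            assert abs(g.mean()) < 0.02, shape
            assert abs(g.std() - 1) < 0.02, shape
        # the nonlinear shapes carry (almost) no linear signal
        for shape in ("quadratic", "sine"):
            assert abs(np.corrcoef(c, shape_function(shape, c))[0, 1]) < 0.02

    def test_invalid_methylome_config(self, madt_cohort):
        with pytest.raises(SimulationError, match="missing_rate"):
            tw.generate_methylome(
                madt_cohort, tw.MethylomeConfig(missing_rate=1.5), seed=0
            )
        with pytest.raises(SimulationError, match="n_probes"):
            tw.generate_methylome(madt_cohort, tw.MethylomeConfig(n_probes=5), seed=0)
        with pytest.raises(SimulationError, match="region_span"):
            tw.generate_methylome(
                madt_cohort,
                tw.MethylomeConfig(
                    n_probes=60, n_true_regions=5, region_span_bp=4.0
                ),
                seed=0,
            )
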