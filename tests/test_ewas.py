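import numpy as np
import pandas as pd
import pytest

import twinewas as tw
from twinewas.ewas import qq_table
from twinewas.preprocess import ProbeManifest

from table1 import FDR, M_TOTAL, P_COMBINED, P_GCC, P_KIN, PROBE_IDS


class TestCombineMinp:
    def test_published_rows_alternating_winner(self):
        p, winner = tw.combine_minp(1.0173e-06, 0.2816)
        assert p == 1.0173e-06 and winner == "gcc"
        p, winner = tw.combine_minp(0.2832, 2.5999e-06)
        assert p == 2.5999e-06 and winner == "kinship"

    def test_equal_inputs(self):
        p, winner = tw.combine_minp(0.3, 0.3)
        assert p == 0.3 and winner == "gcc"

    def test_missing_input_returns_other(self):
        p, winner = tw.combine_minp(np.nan, 0.2)
        assert p == 0.2 and winner == "kinship"
        with pytest.raises(ValueError):
            tw.combine_minp(np.nan, np.nan)

    def test_output_bounded_by_inputs(self, rng):
        a, b = rng.uniform(size=(2, 100))
        combined, _ = tw.combine_minp(a, b)
        assert (combined <= a).all() and (combined <= b).all()


class TestBhFdr:
    def test_published_fdr_column(self):
        q = tw.bh_fdr(P_COMBINED, M_TOTAL)
        # ranks 1-14: the step-up minimum is attained inside the printed
        # list, so the published values are exactly reproducible
        np.testing.assert_allclose(q[:14], FDR[:14], atol=5.1e-5)
        # beyond that the minimum comes from unprinted p-values (ranks >30);
        # adjusting only the printed list can never undercut the truth
        assert (q[14:] >= np.asarray(FDR[14:]) - 5.1e-5).all()

    def test_all_equal(self):
        q = tw.bh_fdr([0.2] * 5)
        np.testing.assert_allclose(q, 0.2)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = tw.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()

    def test_external_m_errors(self):
        with pytest.raises(ValueError, match="m_total"):
            tw.bh_fdr([0.1, 0.2], m_total=1)
        with pytest.raises(ValueError):
            tw.bh_fdr([0.0, 0.2])


class TestInflationFactor:
    def test_all_half_is_exactly_one(self):
        assert tw.inflation_factor([0.5] * 7) == pytest.approx(1.0, abs=1e-12)

    def test_median_robust_to_tail(self):
        # median of transformed {.5,.5,.5,.01} is the chi2 median itself
        assert tw.inflation_factor([0.5, 0.5, 0.5, 0.01]) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null(self, rng):
        assert 0.95 < tw.inflation_factor(rng.uniform(size=10000)) < 1.05

    def test_qq_table_shape(self, rng):
        t = qq_table(rng.uniform(size=50))
        assert list(t.columns) == ["expected", "observed"]
        assert len(t) == 50


class TestFeatureDistribution:
    def _records(self):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(6)],
                "p_combined": [1e-6, 1e-6, 1e-6, 1e-6, 0.5, 0.9],
                "direction": ["+", "+", "+", "-", "+", "-"],
                "feature": ["Body", "Body", "Body", "TSS200", "Body", "3'UTR"],
            }
        )

    def _manifest(self):
        return ProbeManifest(
            pd.DataFrame(
                {
                    "probe_id": [f"cg{i}" for i in range(6)],
                    "chrom": "chr1",
                    "pos": np.arange(1, 7) * 10,
                    "feature": ["Body", "Body", "Body", "TSS200", "Body", "3'UTR"],
                }
            )
        )

    def test_hand_counts(self):
        out = tw.feature_distribution(self._records(), self._manifest(), 1e-4)
        assert out.loc["Body", "methylated"] == 3
        assert out.loc["TSS200", "demethylated"] == 1
        assert out["methylated"].sum() + out["demethylated"].sum() == 4
        assert out["background"].sum() == 6

    def test_no_hits_zero_table(self):
        out = tw.feature_distribution(self._records(), self._manifest(), 1e-9)
        assert out[["methylated", "demethylated"]].to_numpy().sum() == 0

    def test_threshold_one_counts_everything(self):
        out = tw.feature_distribution(self._records(), self._manifest(), 1.1)
        assert out[["methylated", "demethylated"]].to_numpy().sum() == 6


class TestRunEwas:
    @pytest.fixture(scope="class")
    def scan(self, madt_cohort):
        cfg = tw.MethylomeConfig(
            n_probes=300, n_causal_per_shape=10, causal_shapes=("linear", "sine")
        )
        matrix, manifest, truth = tw.generate_methylome(madt_cohort, cfg, seed=31)
        M = tw.beta_to_m(matrix)
        config = tw.EwasConfig(gcc_null_size=4999)
        records, summary = tw.run_ewas(M, madt_cohort, manifest, config, seed=0)
        return records, summary, truth

    def test_record_contract(self, scan):
        records, summary, _ = scan
        assert len(records) == 300
        np.testing.assert_allclose(
            records["p_combined"], np.minimum(records["p_gcc"], records["p_kin"])
        )
        assert (records["q_value"] >= records["p_combined"] - 1e-15).all()
        signs = np.where(records["coef_lin"] >= 0, "+", "-")
        assert (records["direction"] == signs).all()
        assert set(summary.lambda_gc) == {"gcc", "kinship", "lme"}
        counts = [summary.counts[t] for t in sorted(summary.counts, reverse=True)]
        assert (np.diff(counts) <= 0).all()

    def test_shape_separation_between_models(self, scan):
        """Nonlinear implants dominate the GCC side of the ranking, linear
        implants the kinship side."""
        records, _, truth = scan
        tr = truth.set_index("probe_id")["effect_shape"]
        top_gcc = tr.loc[records.nsmallest(20, "p_gcc")["probe_id"]]
        top_kin = tr.loc[records.nsmallest(20, "p_kin")["probe_id"]]
        assert (top_kin == "sine").sum() == 0
        assert (top_gcc == "sine").sum() >= 3
        assert (top_gcc == "sine").sum() > (top_kin == "sine").sum()

    def test_determinism(self, madt_cohort):
        cfg = tw.MethylomeConfig(n_probes=40)
        matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=5)
        M = tw.beta_to_m(matrix)
        config = tw.EwasConfig(gcc_null_size=999)
        r1, _ = tw.run_ewas(M, madt_cohort, manifest, config, seed=9)
        r2, _ = tw.run_ewas(M, madt_cohort, manifest, config, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_model_list_errors(self, madt_cohort):
        cfg = tw.MethylomeConfig(n_probes=20)
        matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=5)
        with pytest.raises(ValueError, match="empty model list"):
            tw.run_ewas(tw.beta_to_m(matrix), madt_cohort, manifest,
                        tw.EwasConfig(models=()))

    def test_beta_scale_rejected(self, madt_cohort):
        cfg = tw.MethylomeConfig(n_probes=20)
        matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=5)
        with pytest.raises(ValueError, match="M-scale"):
            tw.run_ewas(matrix, madt_cohort, manifest)

    def test_minp_selection_inflation_bounded(self, rng):
        """Under independence P(min(p1,p2) < a) = 1-(1-a)^2 < 2a; the
        combination inherits this selection inflation by design."""
        p1, p2 = rng.uniform(size=(2, 200_000))
        combined, _ = tw.combine_minp(p1, p2)
        for a in (0.05, 0.01):
            frac = (combined < a).mean()
            assert frac == pytest.approx(1 - (1 - a) ** 2, rel=0.1)
            assert frac < 2 * a
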