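import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import twinewas as tw
from twinewas.dmr import DEFAULT_BIN_EDGES, Region
from twinewas.preprocess import ProbeManifest


def _manifest(positions, chrom="chr1"):
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i:04d}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
            }
        )
    )


def _records(p_values, coefs=None):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:04d}" for i in range(len(p_values))],
            "p_combined": p_values,
            "coef_lin": coefs if coefs is not None else np.ones(len(p_values)),
        }
    )


class TestStoufferLiptak:
    def test_independent_pair_closed_form(self):
        # z = isf(0.05) = 1.6449 each; z_c = 2*1.6449/sqrt(2) -> p = 0.0100
        expected = norm.sf(2 * norm.isf(0.05) / np.sqrt(2))
        assert tw.stouffer_liptak([0.05, 0.05]) == pytest.approx(0.0100, abs=1e-3)
        assert tw.stouffer_liptak([0.05, 0.05]) == pytest.approx(expected, rel=1e-12)

    def test_perfect_dependence_no_gain(self):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        for p in (0.3, 0.01, 0.9):
            assert tw.stouffer_liptak([p, p], sigma) == pytest.approx(p, rel=1e-9)

    def test_single_p_unchanged(self):
        assert tw.stouffer_liptak([0.37]) == 0.37

    def test_identity_sigma_equals_classical_stouffer(self, rng):
        ps = rng.uniform(0.01, 0.99, size=6)
        z = norm.isf(ps)
        classical = norm.sf(z.sum() / np.sqrt(len(ps)))
        assert tw.stouffer_liptak(ps) == pytest.approx(classical, rel=1e-12)

    def test_non_psd_sigma_repaired(self):
        sigma = np.array([[1, 0.9, 0.0], [0.9, 1, 0.9], [0.0, 0.9, 1]])
        assert np.linalg.eigvalsh(sigma).min() < 0
        p = tw.stouffer_liptak([0.05, 0.05, 0.05], sigma)
        assert 0 < p < 0.05

    def test_extreme_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = tw.stouffer_liptak([0.0, 0.5])
        assert 0 < p < 1


class TestEstimateAcf:
    def test_correlated_z_in_first_bin(self):
        """Duplicated p-values at paired adjacent positions give rho ~ 1."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 200)
        pvals = np.repeat(p, 2)  # identical z for each adjacent pair
        pos = np.repeat(np.arange(200) * 10_000, 2) + np.tile([0, 10], 200)
        acf = tw.estimate_acf(_records(pvals), _manifest(pos), bin_edges=(1, 50, 100))
        assert acf.rho[0] > 0.95

    def test_shuffled_positions_no_correlation(self, rng):
        pvals = rng.uniform(0.001, 0.999, 2000)
        pos = np.sort(rng.choice(200_000, size=2000, replace=False))
        acf = tw.estimate_acf(_records(pvals), _manifest(pos), bin_edges=DEFAULT_BIN_EDGES)
        assert (np.abs(acf.rho[~acf.empty]) < 0.1).all()

    def test_sparse_bin_flagged_zero(self, rng):
        pvals = rng.uniform(size=10)
        pos = np.arange(10) * 10_000
        with pytest.warns(UserWarning, match="fewer than"):
            acf = tw.estimate_acf(_records(pvals), _manifest(pos))
        assert acf.empty.all()
        assert (acf.rho == 0).all()

    def test_correlation_lookup(self):
        acf = tw.AcfModel(
            bin_edges=np.array([1.0, 50, 100]),
            rho=np.array([0.6, 0.3]),
            n_pairs=np.array([100, 100]),
            empty=np.array([False, False]),
        )
        np.testing.assert_allclose(
            acf.correlation(np.array([0, 10, 60, 150])), [1.0, 0.6, 0.3, 0.0]
        )


class TestSlkCorrect:
    def _flat_acf(self, rho=0.0):
        return tw.AcfModel(
            bin_edges=np.asarray(DEFAULT_BIN_EDGES, float),
            rho=np.full(len(DEFAULT_BIN_EDGES) - 1, rho),
            n_pairs=np.full(len(DEFAULT_BIN_EDGES) - 1, 100),
            empty=np.zeros(len(DEFAULT_BIN_EDGES) - 1, bool),
        )

    def test_isolated_probe_unchanged(self):
        pos = [100, 50_000, 100_000]
        out = tw.slk_correct(_records([0.2, 0.01, 0.8]), _manifest(pos), self._flat_acf())
        np.testing.assert_allclose(out["p_slk"], [0.2, 0.01, 0.8])

    def test_run_of_small_p_amplified(self):
        """5 adjacent probes at p=0.01 with rho~0: the combined p matches
        the independent Stouffer closed form and is far below 0.01."""
        pos = [1000 + 100 * i for i in range(5)]
        out = tw.slk_correct(_records([0.01] * 5), _manifest(pos), self._flat_acf(),
                             window=1000)
        center = out["p_slk"].iloc[2]  # window covers all five
        closed = norm.sf(5 * norm.isf(0.01) / np.sqrt(5))
        assert center == pytest.approx(closed, rel=1e-9)
        assert center < 1e-5

    def test_flat_half_stays_flat(self):
        pos = [1000 + 100 * i for i in range(9)]
        out = tw.slk_correct(_records([0.5] * 9), _manifest(pos), self._flat_acf())
        np.testing.assert_allclose(out["p_slk"], 0.5, atol=1e-12)


class TestFindPeaks:
    def _corrected(self, p_slk, positions):
        df = _records(np.ones(len(p_slk)))
        df["pos"] = positions
        df["chrom"] = "chr1"
        df["p_slk"] = p_slk
        return df

    def test_no_probe_below_seed_empty(self):
        out = tw.find_peaks(self._corrected([0.5, 0.2, 0.9], [100, 200, 300]))
        assert out == []

    def test_single_block_recovered(self):
        p = [0.9] * 5 + [1e-4] * 5 + [0.8] * 5
        pos = list(range(1000, 1000 + 15 * 100, 100))
        regions = tw.find_peaks(self._corrected(p, pos))
        assert len(regions) == 1
        assert regions[0].n_probes == 5
        assert regions[0].start == pos[5] - 1 and regions[0].end == pos[9]

    def test_gap_splits_blocks(self):
        p = [1e-4] * 3 + [1e-4] * 3
        pos = [1000, 1100, 1200, 5000, 5100, 5200]  # 3.8 kb gap > max_gap
        regions = tw.find_peaks(self._corrected(p, pos), max_gap=500)
        assert len(regions) == 2

    def test_singleton_seeds_dropped(self):
        regions = tw.find_peaks(self._corrected([0.9, 1e-5, 0.9], [100, 200, 300]))
        assert regions == []


class TestRegionP:
    def _setup(self, ps, positions):
        df = _records(ps)
        df["pos"] = positions
        df["chrom"] = "chr1"
        region = Region("chr1", positions[0] - 1, positions[-1], np.arange(len(ps)),
                        len(ps))
        acf = TestSlkCorrect()._flat_acf()
        return region, df, acf

    def test_sidak_closed_form(self):
        """total/region = 10 at p_slk = 0.01 -> 1 - 0.99^10 = 0.09562."""
        region, df, acf = self._setup([0.5, 0.5], [1001, 2000])
        p_slk, p_sidak = tw.region_p(region, df, acf, total_covered_bases=10_000)
        manual = 1 - (1 - p_slk) ** 10
        assert p_sidak == pytest.approx(manual, rel=1e-9)
        ref = 1 - 0.99**10
        assert abs(ref - 0.09562) < 1e-5

    def test_whole_extent_exponent_one(self):
        region, df, acf = self._setup([0.2, 0.2], [1001, 2000])
        p_slk, p_sidak = tw.region_p(region, df, acf, total_covered_bases=999)
        assert p_sidak == pytest.approx(p_slk, rel=1e-12)

    def test_sidak_exceeds_slk_and_vanishes_together(self):
        region, df, acf = self._setup([1e-12, 1e-12], [1001, 2000])
        p_slk, p_sidak = tw.region_p(region, df, acf, total_covered_bases=100_000)
        assert p_sidak >= p_slk
        assert p_sidak < 1e-8  # tiny p survives the power transform

    def test_region_needs_two_probes(self):
        region, df, acf = self._setup([0.5, 0.5], [1001, 2000])
        region.n_probes = 1
        with pytest.raises(ValueError, match="at least 2"):
            tw.region_p(region, df, acf, 1000)


class TestRegionFdr:
    def _region(self, p_sidak):
        r = Region("chr1", 0, 100, np.arange(2), 2)
        r.p_sidak = p_sidak
        return r

    def test_single_region_q_equals_p(self):
        (r,) = tw.region_fdr([self._region(0.03)])
        assert r.q_value == pytest.approx(0.03)

    def test_all_ones(self):
        regions = tw.region_fdr([self._region(1.0) for _ in range(4)])
        assert all(r.q_value == 1.0 for r in regions)

    def test_q_dominates_p(self, rng):
        regions = tw.region_fdr([self._region(p) for p in rng.uniform(size=10)])
        assert all(r.q_value >= r.p_sidak - 1e-15 for r in regions)


class TestPipelineOnNull:
    def test_shuffled_null_positions_yield_no_regions(self, madt_cohort):
        """Null scans with shuffled probe positions stay clean at q<0.05."""
        clean = 0
        for seed in range(10):
            cfg = tw.MethylomeConfig(n_probes=700)
            matrix, manifest, _ = tw.generate_methylome(madt_cohort, cfg, seed=800 + seed)
            M = tw.beta_to_m(matrix)
            records, _ = tw.run_ewas(
                M, madt_cohort, manifest,
                tw.EwasConfig(models=("gcc", "kinship"), gcc_null_size=4999), seed=0,
            )
            rng = np.random.default_rng(seed)
            shuffled = ProbeManifest(
                manifest.table.assign(pos=rng.permutation(manifest.table["pos"].to_numpy()))
            )
            regions, _ = tw.call_dmrs(records, shuffled)
            n_sig = int((regions["q_value"] < 0.05).sum()) if len(regions) else 0
            clean += n_sig == 0
        assert clean >= 9
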