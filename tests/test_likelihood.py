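"""Likelihood core: map function, read probabilities, fits, scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import segdrive as sd
from segdrive.likelihood import ChromosomeScanner

from conftest import make_table


class TestRecombFraction:
    def test_values(self):
        assert sd.recomb_fraction(0.0) == 0.0
        assert sd.recomb_fraction(0.5) == pytest.approx((1 - np.exp(-1)) / 2,
                                                        abs=1e-12)
        assert sd.recomb_fraction(20.0) == pytest.approx(0.5, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sd.recomb_fraction(-0.1)

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert sd.recomb_fraction(lo) <= sd.recomb_fraction(hi) < 0.5


class TestMaternalReadProb:
    def test_no_distortion_is_half(self):
        for r in (0.0, 0.2, 0.5):
            for e in (0.0, 0.1, 0.4):
                assert sd.maternal_read_prob(0.0, r, e) == pytest.approx(0.5)

    def test_full_distortion(self):
        assert sd.maternal_read_prob(0.5, 0.0, 0.0) == pytest.approx(1.0)

    def test_specific_value(self):
        assert sd.maternal_read_prob(0.19, 0.1, 0.01) == pytest.approx(0.64896,
                                                                       abs=1e-10)

    @given(st.floats(-0.5, 0.5), st.floats(0, 0.5), st.floats(0, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_four_term_decomposition(self, k, r, e):
        """The collapsed formula equals the sum of the four transmission x
        error outcome probabilities, and the alternate-allele probability is
        its complement."""
        four = ((0.5 + k) * (1 - r) * (1 - e) + (0.5 - k) * r * (1 - e)
                + (0.5 - k) * (1 - r) * e + (0.5 + k) * r * e)
        q = sd.maternal_read_prob(k, r, e)
        assert q == pytest.approx(four, abs=1e-12)
        a_terms = ((0.5 - k) * (1 - r) * (1 - e) + (0.5 + k) * r * (1 - e)
                   + (0.5 + k) * (1 - r) * e + (0.5 - k) * r * e)
        assert q + a_terms == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sd.maternal_read_prob(0.6, 0.1, 0.0)
        with pytest.raises(ValueError):
            sd.maternal_read_prob(0.1, 0.6, 0.0)
        with pytest.raises(ValueError):
            sd.maternal_read_prob(0.1, 0.1, 0.5)


def _model_for(table, e=0.0, **kw):
    gmap = sd.GeneticMap({
        c: (sub["pos_bp"].to_numpy(float), sub["pos_cM"].to_numpy(float))
        for c, sub in table.data.groupby("chrom", sort=False)})
    return sd.LikelihoodModel(genetic_map=gmap, error_rate=e, **kw)


class TestChromosomeLoglik:
    def test_k0_closed_form(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 40, 30)
        pat = rng.integers(0, 40, 30)
        t = make_table(np.arange(1, 31) * 10_000, mat, pat)
        model = _model_for(t, e=0.01)
        got = sd.chromosome_loglik(t, 150_000, 0.0, model)
        n = mat + pat
        from scipy.special import gammaln
        expected = (gammaln(n + 1) - gammaln(mat + 1) - gammaln(pat + 1)
                    + n * np.log(0.5)).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_site_pmf(self):
        # m=7, n=10, r=0 (site at the locus), e=0, k=0.2 -> Binom(7;10,0.7)
        t = make_table([1_000_000], [7], [3])
        model = _model_for(t)
        got = sd.chromosome_loglik(t, 1_000_000, 0.2, model)
        assert got == pytest.approx(np.log(stats.binom.pmf(7, 10, 0.7)), abs=1e-12)
        assert got == pytest.approx(np.log(0.26683), abs=1e-4)

    def test_matches_scipy_binom(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 60, 25)
        pat = rng.integers(0, 60, 25)
        t = make_table(np.arange(1, 26) * 50_000, mat, pat)
        model = _model_for(t, e=0.005)
        i_bp, k = 700_000, 0.13
        morg = t.data["pos_cM"].to_numpy() / 100
        d = np.abs(morg - model.genetic_map.morgans("1", i_bp))
        q = sd.maternal_read_prob(k, sd.recomb_fraction(d), 0.005)
        expected = stats.binom.logpmf(mat, mat + pat, q).sum()
        assert sd.chromosome_loglik(t, i_bp, k, model) == pytest.approx(
            expected, abs=1e-9)

    def test_label_swap_negation_symmetry(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(0, 50, 20)
        pat = rng.integers(0, 50, 20)
        t = make_table(np.arange(1, 21) * 40_000, mat, pat)
        ts = make_table(np.arange(1, 21) * 40_000, pat, mat)
        model = _model_for(t, e=0.01)
        assert sd.chromosome_loglik(t, 300_000, 0.17, model) == pytest.approx(
            sd.chromosome_loglik(ts, 300_000, -0.17, model), abs=1e-9)


class TestFitK:
    def test_single_site_analytic(self):
        # one site at the candidate, no error: k_hat = m/n - 0.5
        t = make_table([1_000_000], [70], [30])
        model = _model_for(t)
        k, _ = sd.fit_k(t, 1_000_000, model)
        assert k == pytest.approx(0.2, abs=1e-6)

    def test_balanced_counts_zero(self):
        t = make_table(np.arange(1, 41) * 25_000, [50] * 40, [50] * 40)
        model = _model_for(t, e=0.005)
        k, _ = sd.fit_k(t, 500_000, model)
        assert k == pytest.approx(0.0, abs=1e-6)

    def test_matches_scalar_optimizer(self):
        """Newton solution agrees with scipy bounded scalar optimization."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = rng.integers(15, 60)
            mat = rng.integers(0, 80, n)
            pat = rng.integers(0, 80, n)
            if (mat + pat).sum() == 0:
                continue
            t = make_table(np.sort(rng.choice(5_000_000, n, replace=False) + 1),
                           mat, pat)
            model = _model_for(t, e=0.005)
            i_bp = int(t.data["pos_bp"].iloc[n // 2])
            k_newton, _ = sd.fit_k(t, i_bp, model)
            res = optimize.minimize_scalar(
                lambda k: -sd.chromosome_loglik(t, i_bp, k, model),
                bounds=(-0.5 + 1e-6, 0.5 - 1e-6), method="bounded",
                options={"xatol": 1e-8})
            assert k_newton == pytest.approx(res.x, abs=1e-3)


class TestScanChromosome:
    def test_identical_tissues_null(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(20_000_000, 60, replace=False) + 1)
        mat = rng.integers(20, 80, 60)
        pat = rng.integers(20, 80, 60)
        pollen = make_table(pos, mat, pat)
        leaf = make_table(pos, mat, pat, tissue="leaf")
        model = _model_for(pollen, e=0.005)
        scan = sd.scan_chromosome(pollen, leaf, model)
        assert np.allclose(scan.profile["lam"], 0.0, atol=1e-6)
        assert sd.call_effect(scan) == 0.0

    def test_label_swap_antisymmetry(self, sim_cross_k10):
        _, leaf, pollen, _, model = sim_cross_k10
        scan = sd.scan_chromosome(pollen, leaf, model)

        def swap(t):
            df = t.data.rename(columns={"mat_count": "pat_count",
                                        "pat_count": "mat_count"})
            return sd.SiteCountTable(df[["chrom", "pos_bp", "pos_cM",
                                         "mat_count", "pat_count"]],
                                     tissue=t.tissue, cross_id=t.cross_id)

        scan_sw = sd.scan_chromosome(swap(pollen), swap(leaf), model)
        np.testing.assert_allclose(scan_sw.profile["k_pollen"],
                                   -scan.profile["k_pollen"], atol=1e-5)
        np.testing.assert_allclose(scan_sw.profile["lam"], scan.profile["lam"],
                                   atol=1e-5)
        assert scan_sw.ml_pos_bp == scan.ml_pos_bp
        assert sd.call_effect(scan_sw) == pytest.approx(-sd.call_effect(scan))

    def test_recovers_simulated_distorter(self, sim_cross_k10):
        cfg, leaf, pollen, truth, model = sim_cross_k10
        scan = sd.scan_chromosome(pollen, leaf, model)
        eff = sd.call_effect(scan)
        assert eff == pytest.approx(0.10, abs=0.02)
        assert abs(scan.ml_pos_bp - 5_000_000) < 2_000_000
        assert scan.lambda_ml > 10  # decisive germline-vs-somatic signal

    def test_binned_matches_exact(self, sim_cross_k10):
        cfg, leaf, pollen, _, _ = sim_cross_k10
        exact = sd.LikelihoodModel(genetic_map=cfg.map(), error_rate=0.005,
                                   grid_thin=32, site_bin_cM=0.0)
        binned = sd.LikelihoodModel(genetic_map=cfg.map(), error_rate=0.005,
                                    grid_thin=32, site_bin_cM=0.1)
        s_exact = sd.scan_chromosome(pollen, leaf, exact)
        s_binned = sd.scan_chromosome(pollen, leaf, binned)
        np.testing.assert_allclose(s_binned.profile["k_pollen"],
                                   s_exact.profile["k_pollen"], atol=1e-3)
        assert s_binned.ml_pos_bp == s_exact.ml_pos_bp

    def test_too_few_sites(self):
        t = make_table([100, 200000], [5, 5], [5, 5])
        lt = make_table([100, 200000], [5, 5], [5, 5], tissue="leaf")
        with pytest.raises(ValueError, match="sites"):
            sd.scan_chromosome(t, lt, _model_for(t))

    def test_lambda_nonnegative_invariant(self, sim_cross_k10):
        _, leaf, pollen, _, model = sim_cross_k10
        scan = sd.scan_chromosome(pollen, leaf, model)
        assert (scan.profile["lam"] >= 0).all()

    def test_warm_start_consistency(self, sim_cross_k10):
        """A warm-started rescan under weights equals a cold scan."""
        _, leaf, pollen, _, model = sim_cross_k10
        scanner = ChromosomeScanner(pollen, leaf, model)
        scanner.scan()  # populate warm-start state
        rng = np.random.default_rng(0)
        w = np.bincount(rng.integers(0, scanner.n_sites, scanner.n_sites),
                        minlength=scanner.n_sites).astype(float)
        warm = scanner.scan(weights=w)
        cold = ChromosomeScanner(pollen, leaf, model).scan(weights=w)
        np.testing.assert_allclose(warm.profile["k_pollen"],
                                   cold.profile["k_pollen"], atol=1e-6)
        assert warm.ml_pos_bp == cold.ml_pos_bp


class TestCallEffect:
    @pytest.mark.parametrize("kp,kl,expected", [
        (0.191, 0.001, 0.19),
        (0.012, 0.000, 0.0),    # below the 0.02 threshold
        (-0.049, 0.021, -0.07),
        (0.014, -0.012, 0.03),
    ])
    def test_rounding_and_threshold(self, kp, kl, expected):
        import pandas as pd
        profile = pd.DataFrame({
            "pos_bp": [1], "pos_cM": [0.0], "k_pollen": [kp], "k_leaf": [kl],
            "ll_pollen_kp": [0.0], "ll_pollen_kl": [0.0], "lam": [0.0]})
        scan = sd.DistortionScan(chrom="1", profile=profile, ml_index=0)
        assert sd.call_effect(scan) == pytest.approx(expected)
        assert sd.call_effect(scan, mode="pollen") == pytest.approx(
            round(kp, 2) if abs(round(kp, 2)) >= 0.02 else 0.0)
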