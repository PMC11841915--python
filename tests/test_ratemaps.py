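import numpy as np
import pytest

from gridci.geometry import WaveBasis, hex_distance, sample_uniform
from gridci.metric import cis, metric_tensor
from gridci.model import GridModule, activity
from gridci.ratemaps import (
    RatemapStack,
    autocorrelogram,
    baselines,
    compute_ratemaps,
    distance_regression,
    fd_metric_tensor,
    filter_cells,
    grid_stats,
    infer_phase,
    module_cis_report,
    module_grid_stats,
    neural_distance_map,
    preprocess,
    synth_ratemaps,
)


@pytest.fixture(scope="module")
def truth(cell):
    return GridModule(sample_uniform(8, cell, 5))


@pytest.fixture(scope="module")
def clean(truth):
    return synth_ratemaps(truth, extent=3.0, bins=32, seed=0)


@pytest.fixture(scope="module")
def ci_stack(ci7):
    return synth_ratemaps(ci7.module, extent=3.0, bins=32, seed=0).stack


class TestSynth:
    def test_noiseless_equals_model_evaluation(self, truth, clean):
        st = clean.stack
        pts = st.bin_centres().reshape(-1, 2)
        assert np.allclose(
            st.rates.reshape(st.n_cells, -1), activity(truth, pts).T, atol=1e-14
        )

    def test_bit_identical_regeneration(self, truth):
        a = synth_ratemaps(truth, noise_sigma=0.1, missing_fraction=0.1, seed=4)
        b = synth_ratemaps(truth, noise_sigma=0.1, missing_fraction=0.1, seed=4)
        assert np.array_equal(a.stack.rates, b.stack.rates, equal_nan=True)

    def test_missing_bins_filled_and_smoothed(self, truth):
        ds = synth_ratemaps(truth, missing_fraction=0.2, seed=2)
        assert np.isnan(ds.stack.rates).any()
        st = preprocess(ds.stack)
        assert np.isfinite(st.rates).all()
        assert st.rates.min() >= 0.0

    def test_small_arena_rejected(self, truth):
        with pytest.raises(ValueError):
            synth_ratemaps(truth, extent=1.0)


class TestComputeRatemaps:
    def test_constant_signal_constant_map(self, rng):
        pos = rng.uniform(0, 3, (20000, 2))
        st = compute_ratemaps(pos, np.full(20000, 2.5), extent=3.0)
        assert np.allclose(st.rates, 2.5, atol=1e-9)

    def test_wrap_smoothing_spreads_mass_across_edges(self):
        raw = np.zeros((32, 32))
        raw[0, 0] = 1.0
        st = preprocess(RatemapStack(raw, 3.0), kernel_sd=2.0)
        sm = st.rates[0]
        # corner symmetric wrap: mass appears at all four map corners
        assert sm[-1, -1] == pytest.approx(sm[1, 1], abs=1e-10)
        assert sm[0, -2] == pytest.approx(sm[0, 2], abs=1e-10)

    def test_trajectory_rebinning_recovers_model_map(self, truth, clean, rng):
        pos = rng.uniform(0, 3, (60000, 2))
        sig = activity(truth, pos)
        st = compute_ratemaps(pos, sig, extent=3.0, kernel_sd=1.0)
        ref = preprocess(clean.stack, kernel_sd=1.0)
        err = np.abs(st.rates - ref.rates).max()
        assert err < 0.05

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            compute_ratemaps(np.empty((0, 2)), np.empty(0), extent=3.0)


class TestGridStats:
    def test_autocorrelogram_centre_and_symmetry(self, clean):
        ac = autocorrelogram(clean.stack.rates[0])
        c = (np.array(ac.shape) - 1) // 2
        assert ac[c[0], c[1]] == pytest.approx(1.0)
        assert np.allclose(ac, ac[::-1, ::-1], atol=1e-9)
        with pytest.raises(ValueError):
            autocorrelogram(np.ones((8, 8)))

    def test_spacing_matches_lattice_constant(self, clean):
        st = clean.stack
        s = grid_stats(st.rates[0], st.bin_size)
        assert s.spacing == pytest.approx(2.0 / np.sqrt(3.0), abs=st.bin_size)

    def test_orientation_recovered_for_rotated_module(self, cell):
        mod = GridModule(sample_uniform(4, cell, 5), WaveBasis(orientation_offset=np.radians(10)))
        st = preprocess(synth_ratemaps(mod, seed=0).stack)
        s = grid_stats(st.rates[0], st.bin_size)
        delta = (s.orientation - 10.0) % 60.0
        assert min(delta, 60.0 - delta) < 2.0

    def test_synthetic_cells_pass_score_threshold(self, clean):
        st = preprocess(clean.stack)
        for i in range(st.n_cells):
            assert grid_stats(st.rates[i], st.bin_size).grid_score > 0.4

    def test_white_noise_scores_low(self, rng):
        wn = rng.random((32, 32))
        assert grid_stats(wn, 3.0 / 32).grid_score < 0.2


class TestPhaseInference:
    def test_round_trip_recovery_within_one_bin(self, truth, clean, cell):
        st = preprocess(clean.stack)
        stats = module_grid_stats(st)
        for i, s in enumerate(stats):
            assert s.phase is not None
            assert hex_distance(s.phase, truth.phases[i], cell) < st.bin_size

    def test_lattice_translated_patterns_share_phase(self, cell):
        base = np.array([[0.21, 0.05]])
        mod1 = GridModule(base)
        mod2 = GridModule(base + cell.lattice_vectors[0])
        st1 = preprocess(synth_ratemaps(mod1, seed=0).stack)
        st2 = preprocess(synth_ratemaps(mod2, seed=0).stack)
        p1, c1 = infer_phase(st1.rates[0], 2 / np.sqrt(3), 0.0, 3.0)
        p2, _ = infer_phase(st2.rates[0], 2 / np.sqrt(3), 0.0, 3.0)
        assert hex_distance(p1, p2, c1) < 1e-9

    def test_filtering_keeps_grids_drops_noise(self, truth, rng):
        ds = synth_ratemaps(truth, seed=0)
        noise = rng.random((4, 32, 32))
        st = preprocess(RatemapStack(np.vstack([ds.stack.rates, noise]), 3.0))
        stats = module_grid_stats(st)
        kept, kept_stats, report = filter_cells(st, stats)
        assert report["n_input"] == 12
        assert report["n_kept"] == truth.n_cells
        assert report["n_removed"] == 4
        assert kept.n_cells == len(kept_stats)


class TestMetricFromRatemaps:
    def test_fd_converges_to_analytic_metric(self, ci7):
        errs = []
        for bins in (32, 64, 128):
            st = synth_ratemaps(ci7.module, extent=3.0, bins=bins, seed=0).stack
            f = fd_metric_tensor(st, exclude_border=2)
            errs.append(abs(f.Gxx.mean() - ci7.sigma) / ci7.sigma)
        assert errs[0] < 0.1
        order = np.log2(errs[0] / errs[1])
        assert order > 1.5
        assert errs[2] < errs[1] < errs[0]

    def test_ci_module_isotropic_offdiagonal_small(self, ci_stack):
        f = fd_metric_tensor(ci_stack, exclude_border=2)
        assert f.Gxx.mean() == pytest.approx(f.Gyy.mean(), rel=0.05)
        assert np.abs(f.Gxy).mean() < 0.05 * f.Gxx.mean()

    def test_rate_scaling_squares_metric(self, ci_stack):
        scaled = RatemapStack(3.0 * ci_stack.rates, ci_stack.extent)
        f1 = fd_metric_tensor(ci_stack)
        f2 = fd_metric_tensor(scaled)
        assert np.allclose(f2.Gxx, 9.0 * f1.Gxx, rtol=1e-12)

    def test_clustered_phases_far_from_ci(self, ci7, cell, ci_stack):
        clustered = GridModule(0.04 * np.random.default_rng(3).normal(size=(7, 2)))
        st = synth_ratemaps(clustered, extent=3.0, bins=32, seed=0).stack
        c_clustered = cis(fd_metric_tensor(st, 2))
        c_ci = cis(fd_metric_tensor(ci_stack, 2))
        assert c_clustered > 50 * c_ci


class TestDistancesAndBaselines:
    def test_neural_distance_zero_at_reference(self, ci_stack):
        d = neural_distance_map(ci_stack, (16, 16))
        assert d[16, 16] == 0.0
        assert d.min() == 0.0

    def test_regression_tight_at_short_range(self, ci_stack):
        df = distance_regression(ci_stack)
        assert df.r.iloc[0] > 0.99
        assert np.all(np.diff(df.r.to_numpy()) <= 1e-9)

    def test_shuffled_baseline_uncorrelated(self, ci_stack):
        sh = baselines(ci_stack, "space_shuffle", seed=0)
        df = distance_regression(sh)
        assert abs(df.r.iloc[0]) < 0.2

    def test_phase_shuffle_preserves_histograms(self, ci_stack):
        sh = baselines(ci_stack, "phase_shuffle", seed=1)
        for i in range(ci_stack.n_cells):
            assert np.array_equal(np.sort(sh.rates[i].ravel()), np.sort(ci_stack.rates[i].ravel()))

    def test_phase_cluster_aligns_phases(self, truth, clean, cell):
        st = preprocess(clean.stack)
        cl = baselines(st, "phase_cluster", seed=0)
        stats = module_grid_stats(cl)
        phases = np.array([s.phase for s in stats if s.phase is not None])
        d = [hex_distance(p, phases[0], cell) for p in phases[1:]]
        assert max(d) < 2.1 * st.bin_size

    def test_space_shuffle_destroys_grid_structure(self, clean):
        st = preprocess(clean.stack)
        sh = baselines(st, "space_shuffle", seed=0)
        assert grid_stats(sh.rates[0], st.bin_size).grid_score < 0.2

    def test_unknown_baseline_rejected(self, ci_stack):
        with pytest.raises(ValueError):
            baselines(ci_stack, "nonsense")


class TestCISReport:
    def test_ci_beats_destructive_baselines(self, ci_stack):
        conds = {
            "data": [ci_stack],
            "space_shuffle": [baselines(ci_stack, "space_shuffle", 0)],
            "phase_cluster": [baselines(ci_stack, "phase_cluster", 0)],
        }
        table, pvals = module_cis_report(conds, n_perms=200)
        assert len(table) == 3
        get = lambda c: table.loc[table.condition == c, "cis_normalised"].iloc[0]
        assert get("data") < get("space_shuffle")
        assert get("data") < get("phase_cluster")

    def test_identical_stacks_not_distinguished(self, ci_stack):
        conds = {"a": [ci_stack, ci_stack], "b": [ci_stack, ci_stack]}
        table, pvals = module_cis_report(conds, n_perms=200)
        assert len(table) == 4
        assert pvals.p.iloc[0] >= 0.9

    def test_roundtrip_npz(self, ci_stack, tmp_path):
        p = tmp_path / "stack.npz"
        ci_stack.to_npz(p)
        back = RatemapStack.from_npz(p)
        assert np.array_equal(back.rates, ci_stack.rates)
        assert back.extent == ci_stack.extent
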