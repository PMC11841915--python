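import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from gridci.geometry import hex_mesh, sample_uniform
from gridci.model import GridModule, activity, ring_tuning
from gridci.topology import (
    ambiguity_map,
    detect_torus,
    maxmin_subsample,
    rips_persistence,
    toroidal_loss,
)


def brute_rips_pairs(D, thr, maxdim=2):
    """Textbook full-boundary-matrix reduction over Z/2 (test oracle)."""
    n = D.shape[0]
    simp = [((i,), 0.0) for i in range(n)]
    for d in range(1, maxdim + 2):
        for c in itertools.combinations(range(n), d + 1):
            f = max(D[a][b] for a, b in itertools.combinations(c, 2))
            if f <= thr:
                simp.append((c, f))
    simp.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s[0]: i for i, s in enumerate(simp)}
    cols = []
    for c, f in simp:
        if len(c) == 1:
            cols.append(set())
        else:
            cols.append(
                {index[tuple(v for k, v in enumerate(c) if k != drop)] for drop in range(len(c))}
            )
    low, pairs = {}, []
    for j in range(len(cols)):
        col = cols[j]
        while col:
            l = max(col)
            if l in low:
                col ^= cols[low[l]]
            else:
                break
        cols[j] = col
        if col:
            l = max(col)
            low[l] = j
            b, d = simp[l][1], simp[j][1]
            if d > b:
                pairs.append((len(simp[l][0]) - 1, b, d))
    paired = set(low) | set(low.values())
    for i, (c, f) in enumerate(simp):
        if i not in paired and len(c) == 1:
            pairs.append((0, f, np.inf))
    return sorted(pairs)


class TestRipsEngine:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_reduction(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(11, 3))
        D = squareform(pdist(pts))
        thr = float(np.min(np.max(D, axis=1)))
        expected = brute_rips_pairs(D, thr)
        dia = rips_persistence(pts, maxdim=2, subsample=len(pts), seed=0)
        got = sorted(zip(dia.dims.tolist(), dia.births.tolist(), dia.deaths.tolist()))
        assert len(got) == len(expected)
        for (de, be, dde), (dg, bg, ddg) in zip(expected, got):
            assert de == dg
            assert be == pytest.approx(bg, abs=1e-12)
            assert dde == ddg or dde == pytest.approx(ddg, abs=1e-12)

    def test_matches_brute_force_with_exact_ties(self):
        g = np.stack(np.meshgrid(np.arange(3.0), np.arange(3.0)), -1).reshape(-1, 2)
        D = squareform(pdist(g))
        thr = float(np.min(np.max(D, axis=1)))
        expected = brute_rips_pairs(D, thr)
        dia = rips_persistence(g, subsample=9, seed=0)
        got = sorted(zip(dia.dims.tolist(), dia.births.tolist(), dia.deaths.tolist()))
        assert got == pytest.approx(expected)

    def test_circle_dominant_h1(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        dia = rips_persistence(pts, maxdim=1, subsample=100, seed=0)
        h1 = dia.top_persistences(1, 2)
        # a dense circle has one H1 class born near 0 and dying at sqrt(3)
        assert h1[0] == pytest.approx(np.sqrt(3.0), rel=0.1)
        assert h1[1] < 0.1 * h1[0]

    def test_permutation_invariance(self, rng):
        pts = rng.normal(size=(30, 3))
        d1 = rips_persistence(pts, subsample=30, seed=0)
        d2 = rips_persistence(pts[rng.permutation(30)], subsample=30, seed=0)
        for dim in (0, 1, 2):
            assert np.allclose(
                np.sort(d1.persistences[d1.dims == dim]),
                np.sort(d2.persistences[d2.dims == dim]),
                atol=1e-12,
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rips_persistence(np.zeros((3, 2)))

    def test_no_h2_from_three_points_subsample(self, rng):
        pts = rng.normal(size=(6, 2))
        dia = rips_persistence(pts, subsample=6, seed=0)
        # simplex dimension bound: H2 needs at least 4 points in a cycle
        assert (dia.dims == 2).sum() == 0 or dia.top_persistences(2, 1)[0] < np.inf

    def test_maxmin_subsample_deterministic_and_spread(self, rng):
        pts = rng.normal(size=(500, 2))
        i1 = maxmin_subsample(pts, 50, seed=3)
        i2 = maxmin_subsample(pts, 50, seed=3)
        assert np.array_equal(i1, i2)
        assert len(np.unique(i1)) == 50


class TestTorusDetection:
    def test_circle_is_not_a_torus(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        dia = rips_persistence(pts, subsample=60, seed=0)
        assert not detect_torus(dia).is_torus

    def test_random_modules_become_toroidal_around_twenty_cells(self, cell):
        # small modules never pass; ~20 random cells do for some seeds
        mesh = hex_mesh(24, cell)
        mod3 = GridModule(sample_uniform(3, cell, 0))
        dia3 = rips_persistence(activity(mod3, mesh), subsample=150, seed=0)
        assert not detect_torus(dia3).is_torus
        hits = []
        for seed in range(3):
            mod = GridModule(sample_uniform(20, cell, seed))
            dia = rips_persistence(activity(mod, mesh), subsample=150, seed=0)
            hits.append(detect_torus(dia).is_torus)
        assert any(hits)

    def test_ci_solution_torus_and_translation_invariance(self, ci7, cell):
        mesh = hex_mesh(24, cell)
        for shift in (np.zeros(2), np.array([0.21, -0.13])):
            mod = ci7.module.with_phases(ci7.phases + shift)
            dia = rips_persistence(activity(mod, mesh), subsample=150, seed=0)
            v = detect_torus(dia)
            assert v.is_torus
            assert v.h2_gap > 3.0


class TestToroidalLoss:
    def test_flat_torus_cloud_negative(self):
        t = np.linspace(0, 1, 20, endpoint=False)
        ring = ring_tuning(4, t)
        cloud = np.concatenate(
            [np.repeat(ring, 20, axis=0), np.tile(ring_tuning(4, t), (20, 1))], axis=1
        )
        assert toroidal_loss(cloud, subsample=120, seed=0) < 0

    def test_tight_cluster_is_zero(self, rng):
        cloud = 1e-9 * rng.normal(size=(30, 5))
        assert toroidal_loss(cloud, subsample=30, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_training_decreases_loss_from_random_init(self):
        from gridci.optimise import GridPhaseModel

        m = GridPhaseModel(6, "homology", mesh_resolution=12, subsample=100)
        r = m.fit(steps=60, learning_rate=0.01, seed=0)
        head = r.loss_history[:10].mean()
        tail = r.loss_history[-10:].mean()
        assert tail < head

    def test_edge_gradients_match_finite_differences(self, cell):
        from gridci.optimise import GridPhaseModel

        m = GridPhaseModel(6, "homology", subsample=150)
        ph = sample_uniform(6, cell, 3)
        batch = sample_uniform(40, cell, 4)
        loss, dph = m._homology_loss_grad(ph, batch)
        eps = 1e-6
        for i, a in [(0, 0), (2, 1), (5, 0)]:
            pp, pm = ph.copy(), ph.copy()
            pp[i, a] += eps
            pm[i, a] -= eps
            fd = (
                m._homology_loss_grad(pp, batch, grad=False)[0]
                - m._homology_loss_grad(pm, batch, grad=False)[0]
            ) / (2 * eps)
            assert fd == pytest.approx(dph[i, a], rel=1e-4, abs=1e-7)


class TestAmbiguity:
    def test_single_cell_has_ambiguous_contour(self, cell):
        mod = GridModule(sample_uniform(1, cell, 7))
        am = ambiguity_map(mod, hex_mesh(48, cell), np.array([0.05, 0.1]))
        assert len(am.ambiguous) > 0

    def test_three_generic_cells_resolve_ambiguity(self, cell):
        mesh = hex_mesh(48, cell)
        for seed in (7, 8, 9):
            mod = GridModule(sample_uniform(3, cell, seed))
            am = ambiguity_map(mod, mesh, np.array([0.05, 0.1]))
            assert len(am.ambiguous) == 0

    def test_zero_epsilon_marks_nothing_away_from_reference(self, cell):
        mod = GridModule(sample_uniform(2, cell, 3))
        am = ambiguity_map(mod, hex_mesh(32, cell), np.array([0.0, 0.0]), epsilon=0.0)
        assert len(am.ambiguous) == 0
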