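"""Grid decomposition and curvature-composition cross-correlation."""

import numpy as np
import pytest
from scipy import stats

import membranekit as mk
from membranekit.curvature import (
    curvature_composition_correlation,
    grid_decompose,
    interleaflet_correlation,
    local_thickness,
    pearson_correlation,
)
from membranekit.synth import _leaflet_molecules


def frame_with_planted_boxes(counts_per_box, z_per_box, dims=(4, 4), box_edge=200.0, species="GM3"):
    """Frame whose per-box species counts and surface heights are exact.

    One POPC per box defines the surface (interface bead displaced by the
    planted height); ``counts_per_box`` lipids of the target species are
    placed inside each box.
    """
    nx, ny = dims
    w = box_edge / nx
    molecules = []
    mid = 1
    for bx in range(nx):
        for by in range(ny):
            b = bx * ny + by
            cx, cy = (bx + 0.5) * w, (by + 0.5) * w
            mols = _leaflet_molecules(
                np.array([[cx, cy]]), np.array(["POPC"], dtype=object), "outer", 100.0, start_id=mid,
                z_shift=np.array([z_per_box[b]]),
            )
            molecules += mols
            mid += 1
            n = counts_per_box[b]
            if n:
                ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
                xy = np.column_stack([cx + 8 * np.cos(ang), cy + 8 * np.sin(ang)])
                molecules += _leaflet_molecules(
                    xy, np.array([species] * n, dtype=object), "outer", 100.0, start_id=mid
                )
                mid += n
    return mk.MembraneFrame.from_molecules(molecules, box=np.array([box_edge, box_edge, 100.0]))


class TestPearsonKernel:
    def test_exact_linear_counts_give_unit_correlation(self):
        z = np.array([1.0, 2.0, 3.0, 7.0, -2.0])
        assert pearson_correlation(3 * z + 5, z) == pytest.approx(1.0, abs=1e-12)
        assert pearson_correlation(-2 * z + 1, z) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pearson_correlation(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_zero_variance_returns_zero(self):
        assert pearson_correlation(np.ones(10), np.arange(10)) == 0.0


class TestGridDecompose:
    def test_uniform_flat_leaflet_has_constant_surface(self):
        f = mk.make_random_leaflet({"POPC": 1.0}, n=600, seed=1)
        z, valid = grid_decompose(f, "outer", (4, 4)).surface_z()
        assert valid.all()
        assert z[valid].std() == pytest.approx(0.0, abs=1e-9)

    def test_counts_sum_to_leaflet_total(self):
        f = mk.make_random_leaflet({"POPC": 0.6, "GM3": 0.4}, n=500, seed=2)
        gf = grid_decompose(f, "outer", (8, 8))
        assert gf.counts.sum() == 500

    def test_edge_point_goes_to_higher_box(self):
        # lipid exactly on the x boundary between box 0 and 1
        mols = _leaflet_molecules(
            np.array([[50.0, 25.0], [10.0, 25.0], [10.0, 75.0], [60.0, 75.0]]),
            np.array(["POPC"] * 4, dtype=object),
            "outer",
            100.0,
        )
        f = mk.MembraneFrame.from_molecules(mols, box=(100.0, 100.0, 100.0))
        gf = grid_decompose(f, "outer", (2, 2))
        assert gf.counts[0].tolist() == [1, 1, 1, 1]

    def test_too_small_grid_rejected(self):
        f = mk.make_random_leaflet({"POPC": 1.0}, n=50, seed=3)
        with pytest.raises(ValueError, match="2x2"):
            grid_decompose(f, "outer", (1, 4))


class TestCurvatureCorrelation:
    def test_exact_linear_counts_give_unit_R_end_to_end(self):
        z = np.arange(16, dtype=float)  # planted surface heights per box
        counts = (2 * z + 3).astype(int)  # counts exactly linear in height
        f = frame_with_planted_boxes(counts, z)
        cc = curvature_composition_correlation([f], "outer", "GM3", dims=(4, 4))
        assert cc.mean == pytest.approx(1.0, abs=1e-9)
        g = frame_with_planted_boxes((2 * (15 - z) + 3).astype(int), z)
        cc2 = curvature_composition_correlation([g], "outer", "GM3", dims=(4, 4))
        assert cc2.mean == pytest.approx(-1.0, abs=1e-9)

    def test_equals_brute_force_pearson(self):
        f, _ = mk.make_curved_frame(
            {"GM3": 0.25, "POPC": 0.75}, couplings={"GM3": -0.6}, n_per_leaflet=640, seed=4
        )
        gf = grid_decompose(f, "outer", (8, 8))
        z, valid = gf.surface_z(exclude="GM3")
        L = gf.species_counts("GM3")[valid]
        expect = stats.pearsonr(L.astype(float), z[valid])[0]
        cc = curvature_composition_correlation([f], "outer", "GM3")
        assert cc.mean == pytest.approx(expect, abs=1e-12)

    def test_negative_coupling_gives_negative_R(self):
        frames = [
            mk.make_curved_frame(
                {"GM3": 0.25, "POPC": 0.75}, couplings={"GM3": -0.9}, n_per_leaflet=1280, seed=10 + i
            )[0]
            for i in range(5)
        ]
        cc = curvature_composition_correlation(frames, "outer", "GM3")
        assert cc.mean < -0.5

    def test_null_coupling_gives_small_R(self):
        frames = [
            mk.make_curved_frame({"GM3": 0.25, "POPC": 0.75}, n_per_leaflet=640, seed=30 + i)[0]
            for i in range(10)
        ]
        cc = curvature_composition_correlation(frames, "outer", "GM3")
        assert abs(cc.mean) < 0.1

    def test_flat_frame_contributes_zero_with_flag(self):
        f = mk.make_random_leaflet({"GM3": 0.3, "POPC": 0.7}, n=400, seed=5)
        cc = curvature_composition_correlation([f], "outer", "GM3", dims=(4, 4))
        assert cc.mean == 0.0
        assert cc.zero_variance_frames == 1

    def test_invariant_to_uniform_translation(self):
        f, _ = mk.make_curved_frame(
            {"GM3": 0.25, "POPC": 0.75}, couplings={"GM3": -0.6}, n_per_leaflet=640, seed=6
        )
        cc = curvature_composition_correlation([f], "outer", "GM3")
        g = f.copy()
        g.coords[:, 2] += 7.5  # uniform vertical shift
        cc_z = curvature_composition_correlation([g], "outer", "GM3")
        assert cc_z.mean == pytest.approx(cc.mean, abs=1e-9)
        h = f.copy()
        h.coords[:, 0] = np.mod(h.coords[:, 0] + h.box[0] / 8, h.box[0])  # shift by one grid box
        cc_x = curvature_composition_correlation([h], "outer", "GM3")
        assert cc_x.mean == pytest.approx(cc.mean, abs=1e-9)


class TestInterleaflet:
    def test_independent_leaflets_are_uncorrelated(self):
        frames = [
            mk.make_curved_frame({"GM3": 0.3, "POPC": 0.7}, {"PIP2": 0.3, "POPC": 0.7}, n_per_leaflet=640, seed=40 + i)[0]
            for i in range(8)
        ]
        m = interleaflet_correlation(frames)
        assert abs(m.loc["GM3", "PIP2"]) < 0.12

    def test_opposite_coupling_gives_anticorrelation(self):
        frames = [
            mk.make_curved_frame(
                {"GM3": 0.3, "POPC": 0.7},
                {"PIP2": 0.3, "POPC": 0.7},
                couplings={"GM3": -0.9, "PIP2": 0.9},
                n_per_leaflet=1280,
                seed=50 + i,
            )[0]
            for i in range(5)
        ]
        m = interleaflet_correlation(frames)
        assert m.loc["GM3", "PIP2"] < -0.3

    def test_same_coupling_gives_positive_diagonal_analogue(self):
        frames = [
            mk.make_curved_frame(
                {"GM3": 0.3, "POPC": 0.7}, {"PIP2": 0.3, "POPC": 0.7},
                couplings={"GM3": -0.9, "PIP2": -0.9}, n_per_leaflet=1280, seed=60 + i,
            )[0]
            for i in range(5)
        ]
        m = interleaflet_correlation(frames)
        assert m.loc["GM3", "PIP2"] > 0.3


class TestThickness:
    def test_flat_bilayer_has_constant_thickness(self, pm_frame):
        th = local_thickness([pm_frame])
        assert th["thickness_sd_A"] < 1.0
        assert abs(th["height_correlation"]) < 0.6  # tiny residual jitter only

    def test_congruent_undulation_keeps_thickness(self):
        frames = [
            mk.make_curved_frame({"POPC": 1.0}, amplitude=20.0, n_per_leaflet=800, seed=70 + i)[0]
            for i in range(3)
        ]
        th = local_thickness(frames)
        assert th["thickness_sd_A"] < 1.5
        assert abs(th["height_correlation"]) < 0.3
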