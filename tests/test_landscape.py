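"""Combined landscapes and trade-off weight estimation."""

import numpy as np
import pytest

from tradescape import combined_landscape, estimate_w, log_fitness, species_w, w_surface
from tradescape.landscape import estimate_w_from_values
from tradescape.surfaces import fit_surface


def _gaussian_pair_values(positions, c1=(0.7, 0.7), c2=(-0.6, -0.5), s1=0.35, s2=0.9):
    """Two analytic peak fields, min-max scaled over the given positions."""
    pos = np.asarray(positions, float)

    def peak(c, s):
        v = np.exp(-((pos - c) ** 2).sum(axis=1) / (2 * s**2))
        return (v - v.min()) / (v.max() - v.min())

    return peak(c1, s1), peak(c2, s2)


@pytest.fixture(scope="module")
def gauss_grid():
    g = np.linspace(-1, 1, 8)
    gy, gx = np.meshgrid(g, g, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    f1, f2 = _gaussian_pair_values(grid)
    return grid, f1, f2


class TestCombinedLandscape:
    def test_endpoints_reproduce_surfaces(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        assert np.array_equal(combined_landscape(f1, f2, 1.0).height, f1)
        assert np.array_equal(combined_landscape(f1, f2, 0.0).height, f2)

    def test_identical_surfaces_mix_to_themselves(self, gauss_grid):
        _, f1, _ = gauss_grid
        for w in (0.2, 0.5, 0.9):
            assert np.allclose(combined_landscape(f1, f1, w).height, f1)

    def test_invalid_inputs(self, gauss_grid):
        _, f1, f2 = gauss_grid
        with pytest.raises(ValueError, match="mismatch"):
            combined_landscape(f1, f2[:-1], 0.5)
        with pytest.raises(ValueError, match="w must be"):
            combined_landscape(f1, f2, 1.5)


class TestLogFitness:
    def test_two_by_two_hand_computation(self):
        """Brute-force arithmetic on a 2x2 grid.

        With F1 = (0.2, 0.4, 0.6, 1.0), F2 = (1.0, 0.5, 0.3, 0.1) and w = 0.5
        the cell mixtures are (0.6, 0.45, 0.45, 0.55), so a specimen sitting
        at the third cell scores ln(0.45 / 0.6).
        """
        grid = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        f1 = np.array([0.2, 0.4, 0.6, 1.0])
        f2 = np.array([1.0, 0.5, 0.3, 0.1])
        # interpolating surfaces reproduce the stated cell values exactly
        m1 = fit_surface(grid, f1, "tps", 2, tps_smoothing=0.0)
        m2 = fit_surface(grid, f2, "tps", 2, tps_smoothing=0.0)
        lf = log_fitness(grid[2], 0.5, m1, m2, grid)
        assert lf == pytest.approx(np.log(0.45 / 0.6), abs=1e-9)

    def test_maximal_cell_scores_zero(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        m1 = fit_surface(grid, f1, "tps", 2, tps_smoothing=0.0)
        m2 = fit_surface(grid, f2, "tps", 2, tps_smoothing=0.0)
        w = 0.31
        heights = w * f1 + (1 - w) * f2
        top = grid[np.argmax(heights)]
        assert log_fitness(top, w, m1, m2, grid) == pytest.approx(0, abs=1e-9)

    def test_never_positive(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        m1 = fit_surface(grid, f1, "tps", 2, tps_smoothing=0.0)
        m2 = fit_surface(grid, f2, "tps", 2, tps_smoothing=0.0)
        rng = np.random.default_rng(0)
        for pos in grid[rng.integers(0, len(grid), 10)]:
            for w in (0.0, 0.3, 0.8, 1.0):
                assert log_fitness(pos, w, m1, m2, grid) <= 1e-12

    def test_nonpositive_combined_value_raises_without_floor(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        with pytest.raises(ValueError, match="floor"):
            estimate_w_from_values(
                np.array([0.0]), np.array([0.0]), f1, f2, resolution=0.01
            )

    def test_objective_is_numerically_continuous_in_w(self, gauss_grid):
        """The log-fitness curve is piecewise-smooth in w away from log blow-up."""
        grid, f1, f2 = gauss_grid
        # a position whose surface values are bounded away from zero, so the
        # logarithm does not steepen without bound near the endpoints
        idx = int(np.argmax(np.minimum(f1, f2)))
        est = estimate_w_from_values(f1[idx : idx + 1], f2[idx : idx + 1], f1, f2, resolution=1e-4)[0]
        from tradescape.landscape import _objective_curve

        w = np.linspace(0, 1, 10001)
        curve = _objective_curve(f1[idx : idx + 1], f2[idx : idx + 1], f1, f2, w, floor=None)[:, 0]
        assert np.abs(np.diff(curve)).max() < 5e-3
        assert est.w == pytest.approx(w[np.argmax(curve)], abs=1e-4)


class TestEstimateW:
    def test_species_at_exclusive_f1_maximum_tops_out_at_w_one(self, gauss_grid):
        """A species on the F1 peak reaches log-fitness 0, with w = 1 optimal.

        For every w where the F1-peak cell is itself the combined-landscape
        maximum the ratio is exactly 1, so the maximizing set is an interval
        ending at w = 1 and the tie convention reports its midpoint.
        """
        grid, f1, f2 = gauss_grid
        est = estimate_w_from_values(
            np.array([1.0]), f2[np.argmax(f1)][None], f1, f2, resolution=0.001
        )[0]
        assert est.log_fitness == pytest.approx(0, abs=1e-12)
        if est.tied:
            assert est.w_tie_set[1] == 1.0
            assert est.w == pytest.approx(0.5 * (est.w_tie_set[0] + 1.0))
        else:
            assert est.w == 1.0

    def test_identical_surfaces_tie_to_midpoint(self, gauss_grid):
        _, f1, _ = gauss_grid
        est = estimate_w_from_values(f1[3:4], f1[3:4], f1, f1, resolution=0.001)[0]
        assert est.tied
        assert est.w == pytest.approx(0.5)
        assert est.w_tie_set == (0.0, 1.0)

    def test_matches_finer_brute_force_scan(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        rng = np.random.default_rng(17)
        pos = rng.uniform(-1, 1, (200, 2))
        pf1, pf2 = _gaussian_pair_values(np.vstack([grid, pos]))
        z1, z2 = pf1[64:], pf2[64:]
        r1, r2 = pf1[:64], pf2[:64]
        coarse = estimate_w_from_values(z1, z2, r1, r2, resolution=0.001, floor=1e-9)
        fine = estimate_w_from_values(z1, z2, r1, r2, resolution=1e-4, floor=1e-9)
        diff = np.abs([c.w - f.w for c, f in zip(coarse, fine)])
        assert diff.max() <= 0.001 + 1e-12

    def test_scaling_both_surfaces_leaves_w_unchanged(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        base = estimate_w_from_values(f1[:10], f2[:10], f1, f2, resolution=0.01, floor=1e-12)
        scaled = estimate_w_from_values(
            3.7 * f1[:10], 3.7 * f2[:10], 3.7 * f1, 3.7 * f2, resolution=0.01, floor=1e-12
        )
        assert np.allclose([e.w for e in base], [e.w for e in scaled])

    def test_swapping_surfaces_mirrors_w(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        a = estimate_w_from_values(f1[:20], f2[:20], f1, f2, resolution=0.001, floor=1e-12)
        b = estimate_w_from_values(f2[:20], f1[:20], f2, f1, resolution=0.001, floor=1e-12)
        assert np.allclose([e.w for e in a], [1 - e.w for e in b], atol=1e-12)


class TestWSurface:
    def test_forty_grid_has_1600_cells_in_unit_interval(self, small_surfaces, small_study):
        m1, m2 = small_surfaces
        ws = w_surface(m1, m2, extent=small_study.grid, n=40, floor=1e-9)
        assert len(ws.w) == 1600
        assert ws.w.min() >= 0 and ws.w.max() <= 1

    def test_f1_peak_cell_outweighs_f2_peak_cell(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        m1 = fit_surface(grid, f1, "tps", 2, tps_smoothing=0.0)
        m2 = fit_surface(grid, f2, "tps", 2, tps_smoothing=0.0)
        ws = w_surface(m1, m2, extent=grid, n=20, reference_grid=grid, floor=1e-9)
        w_at_f1_peak = ws.w[np.argmin(((ws.grid - grid[np.argmax(f1)]) ** 2).sum(axis=1))]
        w_at_f2_peak = ws.w[np.argmin(((ws.grid - grid[np.argmax(f2)]) ** 2).sum(axis=1))]
        assert w_at_f1_peak >= w_at_f2_peak

    def test_species_at_grid_nodes_match_surface_cells(self, gauss_grid):
        grid, f1, f2 = gauss_grid
        m1 = fit_surface(grid, f1, "tps", 2, tps_smoothing=0.0)
        m2 = fit_surface(grid, f2, "tps", 2, tps_smoothing=0.0)
        ws = w_surface(m1, m2, extent=grid, n=8, reference_grid=grid, floor=1e-9)
        table = species_w(ws.grid, m1, m2, grid, floor=1e-9)
        assert np.allclose(table["w"].to_numpy(), ws.w)

    def test_duplicate_positions_get_identical_w(self, small_surfaces, small_study):
        m1, m2 = small_surfaces
        pos = np.tile(small_study.grid[10], (2, 1))
        table = species_w(pos, m1, m2, small_study.grid, floor=1e-9)
        assert table["w"].iloc[0] == table["w"].iloc[1]
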