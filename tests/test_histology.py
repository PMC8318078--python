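"""Laminar depth, density profiles, particle detection and polar statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skimage import measure

import obmark
from obmark.histology import (
    LaminarScene,
    dendritic_preference_index,
    depth_density_profile,
    detect_particles,
    linear_density,
    mcl_fraction,
    normalize_epl_depth,
    region_density,
    standardize_polar,
)


@pytest.fixture
def parallel_scene():
    """Straight horizontal boundaries 100 px apart (MCL at y=100)."""
    xs = np.linspace(0, 500, 6)
    return LaminarScene(
        mcl_boundary=np.column_stack([xs, np.full(6, 100.0)]),
        gl_boundary=np.column_stack([xs, np.full(6, 200.0)]),
        scale_um_per_px=1.0,
    )


@pytest.fixture
def circular_scene():
    th = np.linspace(0, 2 * np.pi, 400)
    mcl = np.column_stack([500 + 300 * np.cos(th), 500 + 300 * np.sin(th)])
    gl = np.column_stack([500 + 400 * np.cos(th), 500 + 400 * np.sin(th)])
    return mcl, gl


class TestNormalizeDepth:
    def test_point_on_mcl_is_zero(self, parallel_scene):
        assert normalize_epl_depth([250.0, 100.0], parallel_scene) == pytest.approx(0.0)

    def test_point_on_gl_is_one(self, parallel_scene):
        assert normalize_epl_depth([250.0, 200.0], parallel_scene) == pytest.approx(1.0)

    def test_proportionality(self, parallel_scene):
        assert normalize_epl_depth([250.0, 125.0], parallel_scene) == pytest.approx(0.25)

    def test_below_mcl_negative(self, parallel_scene):
        d = normalize_epl_depth([250.0, 80.0], parallel_scene)
        assert d == pytest.approx(-0.2)

    def test_beyond_gl_above_one(self, parallel_scene):
        d = normalize_epl_depth([250.0, 230.0], parallel_scene)
        assert d == pytest.approx(1.3)

    def test_outside_annotation_flagged(self, parallel_scene):
        d, valid = normalize_epl_depth([-50.0, 150.0], parallel_scene, return_valid=True)
        assert not valid and np.isnan(d)

    def test_curved_boundaries(self, circular_scene):
        mcl, gl = circular_scene
        scene = LaminarScene(mcl_boundary=mcl, gl_boundary=gl)
        # radial midpoint of the annulus
        assert normalize_epl_depth([850.0, 500.0], scene) == pytest.approx(0.5, abs=1e-3)

    def test_rigid_motion_invariance(self, rng):
        scene, depths = obmark.generate_laminar_scene(n_mc=50, n_tc=50, seed=1)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        t = np.array([123.0, -45.0])
        moved = LaminarScene(
            mcl_boundary=scene.mcl_boundary @ R.T + t,
            gl_boundary=scene.gl_boundary @ R.T + t,
            somata=scene.somata @ R.T + t,
            scale_um_per_px=scene.scale_um_per_px,
        )
        d0 = normalize_epl_depth(scene.somata, scene)
        d1 = normalize_epl_depth(moved.somata, moved)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_degenerate_boundary_rejected(self):
        bad = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 5.0], [5.0, -5.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            LaminarScene(mcl_boundary=bad, gl_boundary=np.array([[0.0, 50.0], [10.0, 50.0]]))


class TestDepthProfile:
    def _mask_scene(self, mask):
        h, w = mask.shape
        xs = np.array([0.0, w])
        return LaminarScene(
            mcl_boundary=np.column_stack([xs, [0.0, 0.0]]),
            gl_boundary=np.column_stack([xs, [float(h - 1), float(h - 1)]]),
            dendrite_mask=mask,
        )

    def test_half_filled_mask(self):
        mask = np.zeros((101, 60), bool)
        mask[:50] = True  # depths < ~0.5 (row index ~ depth here)
        prof = depth_density_profile(self._mask_scene(mask), "mask", n_bins=10)
        assert np.all(prof.loc[prof["depth"] < 0.45, "density"] > 0.95)
        assert np.all(prof.loc[prof["depth"] > 0.55, "density"] < 0.05)

    def test_empty_mask_zero_profile(self, caplog):
        mask = np.zeros((50, 40), bool)
        with caplog.at_level("WARNING"):
            prof = depth_density_profile(self._mask_scene(mask), "mask")
        assert (prof["density"] == 0).all()

    def test_planted_profile_recovered(self, rng):
        # plant signal with density 0.8 in lower half, 0.2 in upper half
        mask = np.zeros((101, 80), bool)
        mask[:50] = rng.uniform(size=(50, 80)) < 0.8
        mask[51:] = rng.uniform(size=(50, 80)) < 0.2
        prof = depth_density_profile(self._mask_scene(mask), "mask", n_bins=10)
        low = prof.loc[prof["depth"] < 0.5, "density"].mean()
        high = prof.loc[prof["depth"] > 0.5, "density"].mean()
        assert low == pytest.approx(0.8, abs=0.05)
        assert high == pytest.approx(0.2, abs=0.05)

    def test_point_profile(self):
        scene, depths = obmark.generate_laminar_scene(n_mc=0, n_tc=2000,
                                                      tc_depth_dist=stats.uniform(0, 1),
                                                      seed=8)
        prof = depth_density_profile(scene, "points", n_bins=10)
        assert prof["density"].sum() == pytest.approx(1.0)
        assert prof["density"].std() < 0.02  # near-uniform


class TestDPI:
    def _profile(self, lower, upper, n=10):
        d = np.linspace(0.05, 0.95, n)
        return pd.DataFrame({"depth": d, "density": np.where(d <= 0.5, lower, upper)})

    def test_symmetric_zero(self):
        assert dendritic_preference_index(self._profile(0.3, 0.3)) == pytest.approx(0.0)

    def test_upper_only_plus_one(self):
        assert dendritic_preference_index(self._profile(0.0, 0.4)) == pytest.approx(1.0)

    def test_printed_densities(self):
        # upper 0.10 vs lower 0.20 -> (0.10-0.20)/0.30 = -1/3
        assert dendritic_preference_index(self._profile(0.20, 0.10)) == pytest.approx(-1 / 3)

    def test_zero_signal_undefined(self):
        assert np.isnan(dendritic_preference_index(self._profile(0.0, 0.0)))

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 1, 2)
            assert dendritic_preference_index(self._profile(a, b)) == pytest.approx(
                -dendritic_preference_index(self._profile(b, a))
            )


class TestMCLFraction:
    def test_counting(self):
        assert mcl_fraction([0.1, 0.2, 0.5]) == pytest.approx(2 / 3)

    def test_all_at_mcl(self):
        assert mcl_fraction([0.0, 0.0]) == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            mcl_fraction([])

    def test_planted_proportion_recovered(self):
        # 300 MCs hugging the MCL + 300 TCs planted above the 30% cutoff
        scene, depths = obmark.generate_laminar_scene(
            n_mc=300, n_tc=300,
            mc_depth_dist=stats.uniform(0.0, 0.25),
            tc_depth_dist=stats.uniform(0.4, 0.5),
            seed=13,
        )
        rec, valid = normalize_epl_depth(scene.somata, scene, return_valid=True)
        assert abs(mcl_fraction(rec[valid]) - 0.5) < 0.02


def floodfill_oracle(mask, area_range=(70, 600), circ_range=(0.1, 1.0)):
    """Independent detector: BFS flood fill + the same area/circularity filter."""
    mask = mask.copy()
    h, w = mask.shape
    seen = np.zeros_like(mask)
    kept = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                area = len(comp)
                single = np.zeros_like(mask)
                single[tuple(np.array(comp).T)] = True
                perim = measure.perimeter_crofton(single)
                circ = 1.0 if perim == 0 else min(4 * np.pi * area / perim**2, 1.0)
                if area_range[0] <= area <= area_range[1] and circ_range[0] <= circ <= circ_range[1]:
                    kept.append((area, tuple(sorted(comp))[0]))
    return sorted(kept)


class TestDetectParticles:
    def test_disc_sizes(self):
        mask, _ = obmark.generate_particle_mask(
            [((60, 60), 8.0), ((160, 60), 5.0), ((60, 180), 4.0)]
        )
        det = detect_particles(mask)
        assert len(det) == 2  # radius-4 disc (49 px) rejected by area
        assert sorted(det["area_px"]) == [81, 197]

    def test_large_disc_rejected_by_area(self):
        mask, _ = obmark.generate_particle_mask([((100, 100), 16.0)])
        assert len(detect_particles(mask)) == 0

    def test_thin_line_rejected_by_circularity(self):
        mask = np.zeros((50, 150), bool)
        mask[25, 10:110] = True
        det = detect_particles(mask, area_range=(70, 600))
        assert len(det) == 0

    def test_matches_floodfill_oracle(self, rng):
        for _ in range(20):
            mask = np.zeros((64, 64), bool)
            # a few random discs plus salt noise
            for _ in range(rng.integers(0, 3)):
                r0, c0 = rng.integers(15, 49, 2)
                rad = rng.uniform(3, 9)
                rr, cc = np.indices(mask.shape)
                mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            mask |= rng.uniform(size=mask.shape) < 0.02
            det = detect_particles(mask)
            got = sorted(
                (int(a), (int(round(r)), int(round(c))))
                for a, r, c in zip(det["area_px"], det["row"], det["col"])
            )
            oracle = floodfill_oracle(mask)
            assert [a for a, _ in got] == [a for a, _ in oracle]


class TestPolar:
    def _scene(self, circular_scene, somata):
        mcl, gl = circular_scene
        return LaminarScene(mcl_boundary=mcl, gl_boundary=gl,
                            somata=np.asarray(somata, float), scale_um_per_px=1.2)

    def test_angle_conventions(self, circular_scene):
        scene = self._scene(circular_scene, [[900.0, 500.0], [500.0, 900.0]])
        pm = standardize_polar(scene)
        # tolerance set by the 400-vertex polygonal approximation of the ring
        assert pm.angles[0] == pytest.approx(0.0, abs=0.01)
        assert pm.angles[1] == pytest.approx(np.pi / 2, abs=0.01)

    def test_uniform_quadrants(self, circular_scene, rng):
        th = rng.uniform(0, 2 * np.pi, 400)
        somata = np.column_stack([500 + 310 * np.cos(th), 500 + 310 * np.sin(th)])
        pm = standardize_polar(self._scene(circular_scene, somata))
        counts = np.histogram(pm.angles, bins=[0, np.pi / 2, np.pi, 3 * np.pi / 2, 2 * np.pi])[0]
        # multinomial 99% CI per quadrant (normal approx)
        se = np.sqrt(400 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 100) < 2.81 * se)

    def test_collinear_mcl_rejected(self):
        line = np.column_stack([np.linspace(0, 100, 10), np.zeros(10)])
        scene = LaminarScene(mcl_boundary=line,
                             gl_boundary=np.column_stack([np.linspace(0, 100, 10), np.full(10, 50.0)]))
        with pytest.raises(ValueError, match="collinear"):
            standardize_polar(scene)


class TestDensities:
    def test_linear_density_overall(self, circular_scene):
        mcl, gl = circular_scene
        # scale chosen so the MCL circumference is ~2.26 mm
        scene = LaminarScene(mcl_boundary=mcl, gl_boundary=gl,
                             somata=np.array([[900.0, 500.0]] * 10), scale_um_per_px=1.2)
        dens = linear_density(scene)
        overall = dens.loc[dens["quadrant"] == "all"].iloc[0]
        circumference_mm = 2 * np.pi * 300 * 1.2 / 1000
        assert overall["density_per_mm"] == pytest.approx(10 / circumference_mm, rel=0.01)

    def test_ten_cells_two_mm(self):
        # half-circle MCL of arc length 2 mm
        th = np.linspace(0, np.pi, 300)
        r = 2000 / np.pi  # px; scale 1 um/px -> arc 2 mm
        mcl = np.column_stack([r * np.cos(th), r * np.sin(th)])
        gl = np.column_stack([1.3 * r * np.cos(th), 1.3 * r * np.sin(th)])
        somata = np.column_stack([1.05 * r * np.cos(np.linspace(0.3, 2.8, 10)),
                                  1.05 * r * np.sin(np.linspace(0.3, 2.8, 10))])
        scene = LaminarScene(mcl_boundary=mcl, gl_boundary=gl, somata=somata,
                             scale_um_per_px=1.0)
        dens = linear_density(scene)
        overall = dens.loc[dens["quadrant"] == "all"].iloc[0]
        assert overall["density_per_mm"] == pytest.approx(5.0, rel=0.01)

    def test_zero_cells(self, circular_scene):
        mcl, gl = circular_scene
        scene = LaminarScene(mcl_boundary=mcl, gl_boundary=gl, scale_um_per_px=1.0)
        dens = linear_density(scene)
        assert (dens["count"] == 0).all()

    def test_poisson_planted_linear_density(self, circular_scene, rng):
        mcl, gl = circular_scene
        length_mm = 2 * np.pi * 300 / 1000  # scale 1 um/px
        n = rng.poisson(10 * length_mm)
        th = rng.uniform(0, 2 * np.pi, n)
        somata = np.column_stack([500 + 305 * np.cos(th), 500 + 305 * np.sin(th)])
        scene = LaminarScene(mcl_boundary=mcl, gl_boundary=gl, somata=somata,
                             scale_um_per_px=1.0)
        d = linear_density(scene).iloc[-1]["density_per_mm"]
        lo, hi = stats.poisson.ppf([0.025, 0.975], 10 * length_mm) / length_mm
        assert lo <= d <= hi

    def test_region_density(self):
        square = [(0, 0), (0, 1000), (1000, 1000), (1000, 0)]  # 1 mm^2 at 1 um/px
        pts = np.column_stack([np.linspace(100, 900, 50), np.linspace(100, 900, 50)])
        out = region_density(pts, [square], scale_um_per_px=np.sqrt(0.5) * 1000 / 1000 * 1.0)
        # scale sqrt(0.5) um/px -> area 0.5 mm^2 -> 100 cells/mm^2
        assert out.iloc[0]["density_per_mm2"] == pytest.approx(100.0)

    def test_empty_region_and_edge_point(self):
        square = [(0, 0), (0, 100), (100, 100), (100, 0)]
        out = region_density(np.empty((0, 2)), [square], 1000.0)
        assert out.iloc[0]["count"] == 0
        out = region_density(np.array([[0.0, 50.0]]), [square], 1000.0)
        assert out.iloc[0]["count"] == 1  # on-edge counts as inside

    def test_zero_area_region(self):
        with pytest.raises(ValueError):
            region_density(np.empty((0, 2)), [[(0, 0), (0, 1), (0, 2)]], 1.0)
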