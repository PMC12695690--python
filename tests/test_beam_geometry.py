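import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autotan.beam_geometry import (
    AmbiguousPairing,
    NoLegitimatePair,
    angular_separation,
    bev_project,
    check_prerequisites,
    classify_beam,
    default_tangent_setup,
    find_tangent_pairs,
    lung_bite_depth,
)
from autotan.grids import VoxelGrid
from autotan.synthetic_phantom import PhantomConfig, build_phantom

from conftest import make_beam


class TestAngularSeparation:
    @pytest.mark.parametrize(
        "a,b,expected", [(300, 120, 180), (350, 10, 20), (90, 90, 0), (0, 200, 160)]
    )
    def test_examples(self, a, b, expected):
        assert angular_separation(a, b) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-720, 720), st.floats(-720, 720), st.integers(-3, 3))
    def test_symmetric_and_periodic(self, a, b, k):
        s = angular_separation(a, b)
        assert 0 <= s <= 180
        assert s == pytest.approx(angular_separation(b, a))
        assert s == pytest.approx(angular_separation(a + 360 * k, b), abs=1e-6)


class TestClassifyBeam:
    @pytest.mark.parametrize(
        "gantry,kind,quadrant",
        [
            (300, "TANGENT_CANDIDATE", 4),
            (120, "TANGENT_CANDIDATE", 2),
            (0, "AP_PA_LIKE", None),
            (183, "AP_PA_LIKE", None),
            (355, "AP_PA_LIKE", None),
            (90, "TANGENT_CANDIDATE", 2),  # boundary falls in the higher quadrant
        ],
    )
    def test_examples(self, gantry, kind, quadrant):
        assert classify_beam(make_beam(gantry)) == (kind, quadrant)


class TestFindTangentPairs:
    def test_opposed_quadrants_pair(self):
        beams = [make_beam(300, "m"), make_beam(120, "l")]
        assert find_tangent_pairs(beams) == [("m", "l")]

    def test_separation_160_accepted_155_rejected(self):
        assert find_tangent_pairs([make_beam(300, "m"), make_beam(140, "l")])
        with pytest.raises(NoLegitimatePair):
            find_tangent_pairs([make_beam(300, "m"), make_beam(95, "l")])

    def test_ap_pa_beams_are_not_paired(self):
        with pytest.raises(NoLegitimatePair):
            find_tangent_pairs([make_beam(5, "a"), make_beam(185, "p")])

    def test_mixed_energy_gives_two_pairs(self):
        beams = [
            make_beam(300, "m6", attenuation_mu=0.029),
            make_beam(120, "l6", attenuation_mu=0.029),
            make_beam(300, "m18", attenuation_mu=0.02),
            make_beam(120, "l18", attenuation_mu=0.02),
        ]
        assert sorted(find_tangent_pairs(beams)) == [("m18", "l18"), ("m6", "l6")]

    def test_ambiguous_partner_geometry_raises(self):
        beams = [make_beam(300, "m"), make_beam(120, "l1"), make_beam(125, "l2")]
        with pytest.raises(AmbiguousPairing):
            find_tangent_pairs(beams)

    def test_returned_pairs_satisfy_predicates(self):
        beams = [make_beam(295, "m"), make_beam(130, "l"), make_beam(2, "sc")]
        for a, b in find_tangent_pairs(beams):
            ka, qa = classify_beam(next(x for x in beams if x.id == a))
            kb, qb = classify_beam(next(x for x in beams if x.id == b))
            assert ka == kb == "TANGENT_CANDIDATE"
            assert {qa, qb} in ({1, 3}, {2, 4})
            sep = angular_separation(
                next(x for x in beams if x.id == a).gantry_angle,
                next(x for x in beams if x.id == b).gantry_angle,
            )
            assert 160 <= sep <= 180


def brute_force_bev(mask: VoxelGrid, beam, pixel_mm: float):
    """Naive per-voxel corner projection with the same pixel convention."""
    px = pixel_mm / 10.0
    hits = []
    for ijk in np.argwhere(mask.values):
        corners = [mask.origin + (ijk + np.array(c)) * mask.spacing for c in np.ndindex(2, 2, 2)]
        u, v, _ = beam.project_points(np.array(corners))
        hits.append((u.min(), u.max(), v.min(), v.max()))
    u0 = math.floor(min(h[0] for h in hits) / px) * px
    v0 = math.floor(min(h[2] for h in hits) / px) * px
    pixels = set()
    for umin, umax, vmin, vmax in hits:
        for iu in range(
            math.floor((umin - u0) / px), math.floor((umax - u0) / px - 1e-12) + 1
        ):
            for iv in range(
                math.floor((vmin - v0) / px), math.floor((vmax - v0) / px - 1e-12) + 1
            ):
                pixels.add((iu, iv))
    return u0, v0, pixels


class TestBevProject:
    def test_empty_mask_empty_map(self):
        grid = VoxelGrid(np.zeros(3), np.ones(3) * 5, np.zeros((4, 4, 4), dtype=bool))
        assert not bev_project(grid, make_beam(300)).values.any()

    def test_single_voxel_at_isocenter_lands_at_origin(self):
        vals = np.zeros((9, 9, 9), dtype=bool)
        vals[4, 4, 4] = True
        grid = VoxelGrid(np.array([-22.5] * 3), np.ones(3) * 5, vals)
        bev = bev_project(grid, make_beam(300), pixel_mm=5.0)
        iu, iv = np.nonzero(bev.values)
        u = bev.u_centers()[iu]
        v = bev.v_centers()[iv]
        assert np.all(np.abs(u) <= 0.5 + 1e-9) and np.all(np.abs(v) <= 0.5 + 1e-9)

    def test_sphere_projects_to_disc_of_same_radius(self):
        n, sp = 31, 2.0
        origin = -n * sp / 2
        grid = VoxelGrid(np.array([origin] * 3), np.array([sp] * 3), np.zeros((n,) * 3, dtype=bool))
        cx, cy, cz = grid.center_mesh()
        r = 20.0
        grid.values[:] = cx**2 + cy**2 + cz**2 <= r**2
        bev = bev_project(grid, make_beam(300), pixel_mm=2.0)
        iu, iv = np.nonzero(bev.values)
        radius = np.sqrt(bev.u_centers()[iu] ** 2 + bev.v_centers()[iv] ** 2).max()
        assert radius == pytest.approx(r / 10.0, abs=0.35)  # within ~1 pixel + divergence

    @pytest.mark.parametrize("gantry", [300.0, 118.7])
    def test_matches_brute_force_oracle(self, gantry):
        rng = np.random.default_rng(5)
        n = 16
        vals = rng.random((n, n, n)) < 0.05
        vals[7, 8, 6] = True
        grid = VoxelGrid(np.array([-40.0] * 3), np.array([5.0] * 3), vals)
        beam = make_beam(gantry)
        bev = bev_project(grid, beam, pixel_mm=4.0)
        u0, v0, pixels = brute_force_bev(grid, beam, pixel_mm=4.0)
        assert u0 == pytest.approx(bev.u0) and v0 == pytest.approx(bev.v0)
        got = {(int(i), int(j)) for i, j in zip(*np.nonzero(bev.values))}
        assert got == pixels


class TestLungBite:
    def _slab_setup(self, face_u_cm):
        """Flat-faced lung slab whose projected anterior face sits at u=face_u_cm."""
        n, sp = 40, 5.0
        grid = VoxelGrid(np.array([-100.0] * 3), np.array([sp] * 3), np.zeros((n,) * 3, dtype=bool))
        cx, cy, cz = grid.center_mesh()
        beam = make_beam(270, jaws=(-4.0, 6.0, -6.0, 6.0))  # beam along +x, +u = -y
        # keep the slab thin along the beam so divergence stays sub-pixel
        grid.values[:] = (cy >= -face_u_cm * 10.0) & (np.abs(cz) < 50) & (np.abs(cx) < 15)
        return grid, beam

    def test_border_tangent_to_lung_gives_zero(self):
        grid, beam = self._slab_setup(face_u_cm=-4.0)
        assert lung_bite_depth(beam, grid) <= 0.3

    def test_border_2p5cm_inside_flat_slab(self):
        grid, beam = self._slab_setup(face_u_cm=-1.5)  # 2.5 cm anterior of x1=-4
        assert lung_bite_depth(beam, grid) == pytest.approx(2.5, abs=0.3)

    def test_default_setup_bite_in_window_and_matches_scan(self, coarse_phantom):
        plan = default_tangent_setup(coarse_phantom)
        lung = coarse_phantom.masks["lung_ipsi"]
        for beam in plan.beams:
            bite = lung_bite_depth(beam, lung)
            assert 2.0 <= bite <= 3.0
            # brute-force BEV distance scan with the same row convention
            ap = beam.open_field.aperture
            bev = bev_project(lung, beam, 2.5)
            best = 0.0
            for iu, iv in zip(*np.nonzero(bev.values)):
                u = bev.u_centers()[iu]
                v = bev.v_centers()[iv]
                x1, x2, y1, y2 = ap.jaws
                if not (x1 <= u <= x2 and y1 <= v <= y2):
                    continue
                row = min(max(int((v - y1) // ap.leaf_width), 0), ap.n_rows - 1)
                lo, hi = ap.open_interval(row)
                if lo <= u <= hi:
                    best = max(best, u + bev.pixel_cm / 2 - lo)
            assert bite == pytest.approx(best, abs=1e-9)


class TestPrerequisites:
    def test_complete_valid_plan_passes(self, coarse_pipeline):
        report = check_prerequisites(
            coarse_pipeline["plan_open"], coarse_pipeline["phantom"], coarse_pipeline["open_dose"]
        )
        assert report.overall_pass, report.to_dict()

    def test_default_10x10_jaws_fail_field_size(self, coarse_pipeline):
        plan = coarse_pipeline["plan_open"].copy()
        for b in plan.beams:
            ap = b.open_field.aperture
            ap.jaws = (-5.0, 5.0, -5.0, 5.0)
            ap.leaf_pairs = [(-5.0, 5.0)] * ap.n_rows
        report = check_prerequisites(plan, coarse_pipeline["phantom"], coarse_pipeline["open_dose"])
        assert not report.checks["field_size_ok"][0]
        assert not report.overall_pass

    def test_missing_heart_contour_fails(self, coarse_pipeline):
        ph = coarse_pipeline["phantom"]
        masks = {k: v for k, v in ph.masks.items() if k != "heart"}
        stripped = type(ph)(density=ph.density, masks=masks, laterality=ph.laterality)
        report = check_prerequisites(coarse_pipeline["plan_open"], stripped, coarse_pipeline["open_dose"])
        assert not report.checks["contours_present"][0]

    def test_open_dose_absent_fails_that_check_only(self, coarse_pipeline):
        report = check_prerequisites(coarse_pipeline["plan_open"], coarse_pipeline["phantom"], None)
        assert not report.checks["open_dose_computed"][0]
        assert report.checks["tangent_pair_legitimate"][0]


class TestDefaultSetup:
    def test_left_phantom_quadrants_2_4(self, coarse_phantom):
        plan = default_tangent_setup(coarse_phantom)
        quads = sorted(classify_beam(b)[1] for b in plan.beams)
        assert quads == [2, 4]
        sep = angular_separation(plan.beams[0].gantry_angle, plan.beams[1].gantry_angle)
        assert 160 <= sep <= 180

    def test_right_phantom_mirrored(self):
        ph = build_phantom(PhantomConfig(spacing_mm=(5, 5, 5), laterality="right"))
        plan = default_tangent_setup(ph)
        quads = sorted(classify_beam(b)[1] for b in plan.beams)
        assert quads == [1, 3]
        find_tangent_pairs(plan.beams)
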