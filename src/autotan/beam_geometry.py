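"""Beam/plan data model, tangent legitimacy checks and BEV projection.

Machine angle convention (the one place it is defined): gantry 0 deg means
the beam enters from the patient's anterior, angles increase toward the
patient's left (IEC-like), rotation is about the superior axis.  The
beam's-eye-view (BEV) frame of every beam is oriented so that +u (the
leaf-travel axis) points toward the anterior field border and +v toward
superior; all aperture coordinates are cm at the isocenter plane.
Leaf rows are 1 cm wide and tile the y-jaw span.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .grids import BEVMap, VoxelGrid
from .synthetic_phantom import Phantom, breast_frame

LEAF_WIDTH_CM = 1.0
DEFAULT_SAD_CM = 100.0
AP_PA_CONE_DEG = 10.0  # +/- around 0 and 180: supraclavicular / posterior axillary
SEPARATION_WINDOW_DEG = (160.0, 180.0)  # circular separation for 180 +/- 20
LUNG_BITE_WINDOW_CM = (1.0, 4.0)  # checker tolerance around the 2-3 cm placement
LUNG_BITE_TARGET_CM = 2.5
FLASH_CM = 2.0  # anterior jaw overshoot beyond the skin
SUPINF_MARGIN_CM = 0.7


class NoLegitimatePair(Exception):
    """No beam pair satisfies the opposite-quadrant / separation test."""


class AmbiguousPairing(Exception):
    """A beam qualifies in more than one pair with different geometry."""


class GeometrySearchFailed(Exception):
    """No tangent setup satisfying legitimacy exists for this phantom."""


# ---------------------------------------------------------------------------
# data model


@dataclass
class BeamAperture:
    """Jaws plus one (lo, hi) leaf-opening interval per 1 cm leaf row.

    ``jaws = (x1, x2, y1, y2)`` cm at isocenter; x1 is the posterior jaw
    (+u anterior).  ``leaf_pairs[i]`` is the open interval of row i along
    the leaf-travel axis; rows tile [y1, y2] top-down from y1.
    """

    jaws: tuple[float, float, float, float]
    leaf_width: float = LEAF_WIDTH_CM
    leaf_pairs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        x1, x2, y1, y2 = self.jaws
        if not (x1 < x2 and y1 < y2):
            raise ValueError("jaws must satisfy x1 < x2 and y1 < y2")
        if self.leaf_width <= 0:
            raise ValueError("leaf width must be positive")
        if not self.leaf_pairs:
            self.leaf_pairs = [(x1, x2)] * self.n_rows
        if len(self.leaf_pairs) != self.n_rows:
            raise ValueError("leaf_pairs must provide one pair per leaf row")
        for lo, hi in self.leaf_pairs:
            if lo > hi + 1e-9:
                raise ValueError("leaf pair must have left_edge <= right_edge")

    @property
    def n_rows(self) -> int:
        _, _, y1, y2 = self.jaws
        return max(1, math.ceil((y2 - y1) / self.leaf_width - 1e-9))

    def row_bounds(self, i: int) -> tuple[float, float]:
        _, _, y1, y2 = self.jaws
        lo = y1 + i * self.leaf_width
        return lo, min(lo + self.leaf_width, y2)

    def open_interval(self, i: int) -> tuple[float, float]:
        """Row opening clipped to the x-jaws; collapsed if closed."""
        x1, x2, _, _ = self.jaws
        lo, hi = self.leaf_pairs[i]
        lo, hi = max(lo, x1), min(hi, x2)
        return (lo, hi) if lo < hi else (lo, lo)

    def row_of_v(self, v: np.ndarray) -> np.ndarray:
        _, _, y1, _ = self.jaws
        return np.floor((np.asarray(v) - y1) / self.leaf_width).astype(int)

    def is_default_10x10(self) -> bool:
        x1, x2, y1, y2 = self.jaws
        return abs((x2 - x1) - 10.0) < 1e-9 and abs((y2 - y1) - 10.0) < 1e-9

    def contains_rowwise(self, other: "BeamAperture", tol: float = 1e-6) -> bool:
        """True if ``other``'s open intervals are inside this aperture's."""
        if other.n_rows != self.n_rows:
            return False
        for i in range(self.n_rows):
            lo0, hi0 = self.open_interval(i)
            lo1, hi1 = other.open_interval(i)
            if hi1 - lo1 <= tol:  # closed row always fits
                continue
            if lo1 < lo0 - tol or hi1 > hi0 + tol:
                return False
        return True

    def copy(self) -> "BeamAperture":
        return BeamAperture(tuple(self.jaws), self.leaf_width, list(self.leaf_pairs))


@dataclass
class SegmentField:
    """One control point: an MLC aperture with a fractional MU weight."""

    aperture: BeamAperture
    weight: float

    def __post_init__(self) -> None:
        if self.weight < -1e-12:
            raise ValueError("control-point weight must be >= 0")


@dataclass
class Beam:
    id: str
    gantry_angle: float
    collimator_angle: float
    isocenter: np.ndarray  # mm
    sad: float = DEFAULT_SAD_CM  # cm
    attenuation_mu: float | None = None  # cm^2/g energy surrogate; None = engine default
    control_points: list[SegmentField] = field(default_factory=list)
    beam_mu: float = 100.0

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)

    @property
    def open_field(self) -> SegmentField:
        if not self.control_points:
            raise ValueError("beam has no control points")
        return self.control_points[0]

    def weights_sum(self) -> float:
        return float(sum(cp.weight for cp in self.control_points))

    # --- BEV frame --------------------------------------------------------

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit vectors (direction, e_u, e_v) of the BEV frame."""
        g = math.radians(self.gantry_angle)
        d = np.array([-math.sin(g), math.cos(g), 0.0])
        sign = 1.0 if math.sin(g) <= 0 else -1.0  # keep +u anterior
        e_u = sign * np.array([math.cos(g), math.sin(g), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        if self.collimator_angle:
            k = math.radians(self.collimator_angle)
            e_u, e_v = (
                math.cos(k) * e_u + math.sin(k) * e_v,
                -math.sin(k) * e_u + math.cos(k) * e_v,
            )
        return d, e_u, e_v

    def source_mm(self) -> np.ndarray:
        d, _, _ = self.frame()
        return self.isocenter - d * self.sad * 10.0

    def project_points(self, points_mm: np.ndarray):
        """Divergent projection of (N, 3) mm points onto the isocenter plane.

        Returns ``(u_cm, v_cm, dist_mm)``: BEV coordinates at isocenter
        scale and the Euclidean source distance of each point.
        """
        d, e_u, e_v = self.frame()
        rel = np.atleast_2d(points_mm) - self.source_mm()
        t_axis = rel @ d
        u = (rel @ e_u) / t_axis * self.sad
        v = (rel @ e_v) / t_axis * self.sad
        return u, v, np.linalg.norm(rel, axis=-1)


@dataclass
class Prescription:
    dose_per_fraction: float  # Gy
    n_fractions: int
    calc_point: np.ndarray  # mm
    normalization_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0 or self.n_fractions < 1:
            raise ValueError("invalid prescription")
        if self.normalization_pct <= 0:
            raise ValueError("normalization percentage must be positive")
        self.calc_point = np.asarray(self.calc_point, dtype=float)

    @property
    def total_dose(self) -> float:
        return self.dose_per_fraction * self.n_fractions


@dataclass
class Plan:
    beams: list[Beam]
    prescription: Prescription
    phantom_ref: str = ""

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("plan needs at least one beam")

    def copy(self) -> "Plan":
        return copy.deepcopy(self)

    def beam_by_id(self, beam_id: str) -> Beam:
        for b in self.beams:
            if b.id == beam_id:
                return b
        raise KeyError(beam_id)

    def total_mu(self) -> float:
        return float(sum(b.beam_mu for b in self.beams))


@dataclass
class LegitimacyReport:
    """Per-check outcome of the open-field prerequisite inspection."""

    checks: dict[str, tuple[bool, str]]

    CHECK_NAMES = (
        "fields_exist",
        "prescription_active",
        "contours_present",
        "tangent_pair_legitimate",
        "field_size_ok",
        "lung_block_ok",
        "open_dose_computed",
    )

    @property
    def overall_pass(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def to_dict(self) -> dict:
        out = {name: {"pass": ok, "message": msg} for name, (ok, msg) in self.checks.items()}
        out["overall_pass"] = self.overall_pass
        return out


# ---------------------------------------------------------------------------
# operations


def angular_separation(a: float, b: float) -> float:
    """Circular separation of two gantry angles, in [0, 180] degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_beam(beam: Beam) -> tuple[str, int | None]:
    """Classify a beam as tangent candidate or AP/PA-like.

    Beams within +/-10 deg of the cardinal 0/180 directions are flagged
    ``AP_PA_LIKE`` (anterior supraclavicular / posterior axillary types);
    any other beam is a ``TANGENT_CANDIDATE`` with its quadrant 1..4
    recorded (half-open quadrants [0, 90), [90, 180), ...).
    """
    g = beam.gantry_angle % 360.0
    if angular_separation(g, 0.0) <= AP_PA_CONE_DEG or angular_separation(g, 180.0) <= AP_PA_CONE_DEG:
        return "AP_PA_LIKE", None
    return "TANGENT_CANDIDATE", int(g // 90.0) + 1


def _geometry_key(beam: Beam) -> tuple:
    x1, x2, y1, y2 = beam.open_field.aperture.jaws
    return (
        round(beam.gantry_angle % 360.0, 3),
        tuple(np.round(beam.isocenter, 2)),
        round(x1, 3),
        round(x2, 3),
        round(y1, 3),
        round(y2, 3),
    )


def find_tangent_pairs(beams: list[Beam]) -> list[tuple[str, str]]:
    """Find legitimate tangential pairs (opposite quadrants, 180 +/- 20 deg).

    A mixed-energy plan carries several pairs of identical geometry but
    different attenuation; beams only pair within one energy.  Raises
    :class:`NoLegitimatePair` if nothing qualifies and
    :class:`AmbiguousPairing` if one beam could join geometrically
    distinct pairs.
    """
    if not beams:
        raise NoLegitimatePair("plan has no beams")
    cls = {b.id: classify_beam(b) for b in beams}
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(beams):
        for b in beams[i + 1 :]:
            ka, qa = cls[a.id]
            kb, qb = cls[b.id]
            if ka != "TANGENT_CANDIDATE" or kb != "TANGENT_CANDIDATE":
                continue
            if {qa, qb} not in ({1, 3}, {2, 4}):
                continue
            sep = angular_separation(a.gantry_angle, b.gantry_angle)
            if not SEPARATION_WINDOW_DEG[0] <= sep <= SEPARATION_WINDOW_DEG[1]:
                continue
            if (a.attenuation_mu or None) != (b.attenuation_mu or None):
                continue
            pairs.append((a.id, b.id))
    if not pairs:
        raise NoLegitimatePair("no beam pair passes quadrant and separation tests")
    by_id = {b.id: b for b in beams}
    for bid in by_id:
        partners = [p for pair in pairs for p in pair if bid in pair and p != bid]
        keys = {_geometry_key(by_id[p]) for p in partners}
        if len(keys) > 1:
            raise AmbiguousPairing(f"beam {bid} qualifies in pairs of different geometry")
    return pairs


def bev_project(mask: VoxelGrid, beam: Beam, pixel_mm: float = 2.5) -> BEVMap:
    """Project a binary mask into the beam's eye view at the isocenter plane.

    A BEV pixel is set iff it falls inside the axis-aligned bounding box of
    the eight projected corners of any set voxel (divergent projection
    through the source, rotated into the collimator frame).
    """
    pixel_cm = pixel_mm / 10.0
    idx = np.argwhere(np.asarray(mask.values, dtype=bool))
    if idx.size == 0:
        return BEVMap(0.0, 0.0, pixel_cm, np.zeros((1, 1), dtype=bool))
    us, vs = [], []
    for corner in np.ndindex(2, 2, 2):
        pts = mask.origin + (idx + np.asarray(corner)) * mask.spacing
        u, v, _ = beam.project_points(pts)
        us.append(u)
        vs.append(v)
    us = np.stack(us)  # (8, N) cm
    vs = np.stack(vs)
    umin, umax = us.min(axis=0), us.max(axis=0)
    vmin, vmax = vs.min(axis=0), vs.max(axis=0)
    u0 = math.floor(umin.min() / pixel_cm) * pixel_cm
    v0 = math.floor(vmin.min() / pixel_cm) * pixel_cm
    iu_min = np.floor((umin - u0) / pixel_cm).astype(int)
    iu_max = np.floor((umax - u0) / pixel_cm - 1e-12).astype(int)
    iv_min = np.floor((vmin - v0) / pixel_cm).astype(int)
    iv_max = np.floor((vmax - v0) / pixel_cm - 1e-12).astype(int)
    nu = int(iu_max.max()) + 1
    nv = int(iv_max.max()) + 1
    out = np.zeros((nu, nv), dtype=bool)
    max_du = int((iu_max - iu_min).max())
    max_dv = int((iv_max - iv_min).max())
    for du in range(max_du + 1):
        sel_u = iu_min + du <= iu_max
        for dv in range(max_dv + 1):
            sel = sel_u & (iv_min + dv <= iv_max)
            out[iu_min[sel] + du, iv_min[sel] + dv] = True
    return BEVMap(u0, v0, pixel_cm, out)


def lung_bite_depth(beam: Beam, lung_mask: VoxelGrid, pixel_mm: float = 2.5) -> float:
    """Depth (cm at isocenter scale) of lung inside the posterior border.

    Maximum BEV distance from the posterior aperture edge of each leaf row
    to the projected anterior lung surface among lung pixels lying inside
    the open aperture; 0 if no lung is in the field.
    """
    ap = beam.open_field.aperture
    x1, x2, y1, y2 = ap.jaws
    bev = bev_project(lung_mask, beam, pixel_mm)
    if not bev.values.any():
        return 0.0
    iu, iv = np.nonzero(bev.values)
    u = bev.u_centers()[iu]
    v = bev.v_centers()[iv]
    inside_jaws = (u >= x1) & (u <= x2) & (v >= y1) & (v <= y2)
    if not inside_jaws.any():
        return 0.0
    u, v = u[inside_jaws], v[inside_jaws]
    rows = np.clip(ap.row_of_v(v), 0, ap.n_rows - 1)
    depth = 0.0
    for row in np.unique(rows):
        lo, hi = ap.open_interval(int(row))
        if hi - lo <= 0:
            continue
        sel = rows == row
        uu = u[sel]
        in_open = (uu >= lo) & (uu <= hi)
        if not in_open.any():
            continue
        surface = uu[in_open].max() + bev.pixel_cm / 2.0  # anterior lung edge
        depth = max(depth, surface - lo)
    return max(0.0, depth)


def check_prerequisites(plan: Plan, phantom: Phantom, open_dose=None) -> LegitimacyReport:
    """Step-1 open-field check: evaluate every prerequisite independently.

    Failures are report entries (the script notifies the dosimetrist);
    nothing raises.
    """
    checks: dict[str, tuple[bool, str]] = {}

    ok = len(plan.beams) >= 2 and all(b.control_points for b in plan.beams)
    checks["fields_exist"] = (ok, "tangential fields present" if ok else "need >= 2 beams with defined fields")

    try:
        rx = plan.prescription
        ok = rx.dose_per_fraction > 0 and rx.n_fractions >= 1
    except Exception:
        ok = False
    checks["prescription_active"] = (ok, "active prescription" if ok else "prescription missing or invalid")

    missing = [
        name
        for name in Phantom.REQUIRED_MASKS
        if name not in phantom.masks or not phantom.masks[name].values.any()
    ]
    checks["contours_present"] = (
        not missing,
        "all contours present" if not missing else f"missing contours: {', '.join(missing)}",
    )

    pairs: list[tuple[str, str]] = []
    try:
        pairs = find_tangent_pairs(plan.beams)
        checks["tangent_pair_legitimate"] = (True, f"legitimate pair(s): {pairs}")
    except (NoLegitimatePair, AmbiguousPairing) as exc:
        checks["tangent_pair_legitimate"] = (False, str(exc))

    paired_ids = {p for pair in pairs for p in pair} or {b.id for b in plan.beams}
    bad_fs = [
        b.id
        for b in plan.beams
        if b.id in paired_ids
        and (not b.control_points or b.open_field.aperture.is_default_10x10())
    ]
    checks["field_size_ok"] = (
        not bad_fs,
        "field sizes customized" if not bad_fs else f"default 10x10 or undefined field: {bad_fs}",
    )

    lung = phantom.masks.get("lung_ipsi")
    if lung is None or not lung.values.any():
        checks["lung_block_ok"] = (False, "no ipsilateral lung contour to verify the block")
    else:
        bites = {
            b.id: lung_bite_depth(b, lung)
            for b in plan.beams
            if b.id in paired_ids and b.control_points
        }
        bad = {k: v for k, v in bites.items() if not LUNG_BITE_WINDOW_CM[0] <= v <= LUNG_BITE_WINDOW_CM[1]}
        checks["lung_block_ok"] = (
            not bad,
            f"lung bite depths {dict((k, round(v, 2)) for k, v in bites.items())} cm"
            if not bad
            else f"lung bite outside {LUNG_BITE_WINDOW_CM} cm: { {k: round(v, 2) for k, v in bad.items()} }",
        )

    ok = open_dose is not None and getattr(open_dose, "normalization_state", None) == "normalized"
    checks["open_dose_computed"] = (ok, "open-field dose computed" if ok else "open-field dose not computed")

    return LegitimacyReport(checks)


# ---------------------------------------------------------------------------
# default tangent setup


def _row_lung_edges(bev: BEVMap, aperture_jaws, n_rows, leaf_width):
    """Anterior lung-surface u (cm) per leaf row; nan where no lung."""
    x1, x2, y1, y2 = aperture_jaws
    edges = np.full(n_rows, np.nan)
    if not bev.values.any():
        return edges
    iu, iv = np.nonzero(bev.values)
    u = bev.u_centers()[iu] + bev.pixel_cm / 2.0
    v = bev.v_centers()[iv]
    rows = np.floor((v - y1) / leaf_width).astype(int)
    ok = (rows >= 0) & (rows < n_rows)
    for row in np.unique(rows[ok]):
        edges[row] = u[ok][rows[ok] == row].max()
    return edges


def default_tangent_setup(phantom: Phantom, prescription: Prescription | None = None) -> Plan:
    """Place two opposed tangential beams skimming the chest wall.

    The pair travels along the chest-wall tangent at the breast base, jaws
    fit the breast BEV projection with flash, and the CP1 MLC draws the
    lung block so each row keeps a 2.5 cm lung bite.  The resulting plan
    passes :func:`check_prerequisites` once the open dose is computed.
    """
    if phantom.config is not None:
        p0, n, t = breast_frame(phantom.config)
    elif "base_point_mm" in phantom.meta:
        p0 = np.asarray(phantom.meta["base_point_mm"], float)
        n = np.asarray(phantom.meta["base_normal"], float)
        t = np.asarray(phantom.meta["base_tangent"], float)
    else:  # estimate from masks: breast centroid vs body centroid, axial
        breast_idx = np.argwhere(phantom.masks["breast"].values)
        body_idx = np.argwhere(phantom.masks["body"].values)
        g = phantom.density
        cb = g.origin + (breast_idx.mean(axis=0) + 0.5) * g.spacing
        cd = g.origin + (body_idx.mean(axis=0) + 0.5) * g.spacing
        n = cb - cd
        n[2] = 0.0
        n /= np.linalg.norm(n)
        t = np.array([-n[1], n[0], 0.0])
        if t[1] < 0:
            t = -t
        p0 = cb - n * 25.0

    gantry_med = math.degrees(math.atan2(-t[0], t[1])) % 360.0
    gantry_lat = (gantry_med + 180.0) % 360.0

    if prescription is None:
        calc = p0 + n * (  # 1 cm posterior of the apex-axis midpoint
            (phantom.config.breast_height_mm / 2.0 - 10.0) if phantom.config else 15.0
        )
        prescription = Prescription(
            dose_per_fraction=2.67, n_fractions=15, calc_point=calc, normalization_pct=100.0
        )

    beams = []
    for bid, gantry in (("medial", gantry_med), ("lateral", gantry_lat)):
        beam = Beam(id=bid, gantry_angle=gantry, collimator_angle=0.0, isocenter=p0)
        breast_bev = bev_project(phantom.masks["breast"], beam)
        if not breast_bev.values.any():
            raise GeometrySearchFailed("breast mask projects to nothing")
        iu, iv = np.nonzero(breast_bev.values)
        u = breast_bev.u_centers()[iu]
        v = breast_bev.v_centers()[iv]
        x2 = float(u.max()) + FLASH_CM
        y1 = float(v.min()) - SUPINF_MARGIN_CM
        y2 = float(v.max()) + SUPINF_MARGIN_CM
        lung_bev = bev_project(phantom.masks["lung_ipsi"], beam)
        if not lung_bev.values.any():
            raise GeometrySearchFailed("no lung in the beam's eye view; cannot set the bite")
        n_rows = max(1, math.ceil((y2 - y1) / LEAF_WIDTH_CM - 1e-9))
        edges = _row_lung_edges(lung_bev, (0.0, 1.0, y1, y2), n_rows, LEAF_WIDTH_CM)
        if np.all(np.isnan(edges)):
            raise GeometrySearchFailed("no lung within the field's superior-inferior span")
        # straight posterior border biting the typical anterior lung surface;
        # the CP1 MLC contours rows where the lung bulges past the jaw
        x1 = float(np.nanmedian(edges)) - LUNG_BITE_TARGET_CM
        if x1 >= x2:
            raise GeometrySearchFailed("posterior jaw collapses the field")
        jaws = (x1, x2, y1, y2)
        pairs = []
        for row in range(n_rows):
            lo = x1 if np.isnan(edges[row]) else min(max(edges[row] - LUNG_BITE_TARGET_CM, x1), x2)
            pairs.append((float(lo), x2))
        aperture = BeamAperture(jaws=jaws, leaf_width=LEAF_WIDTH_CM, leaf_pairs=pairs)
        beam.control_points = [SegmentField(aperture=aperture, weight=1.0)]
        beams.append(beam)

    return Plan(beams=beams, prescription=prescription, phantom_ref=phantom.laterality)


def order_pair_medial_first(plan: Plan, phantom: Phantom, pair: tuple[str, str]) -> list[Beam]:
    """Return the tangent pair ordered medial tangent first.

    The medial beam is the one whose source lies on the contralateral side
    of the body midline.
    """
    body_idx = np.argwhere(phantom.masks["body"].values)
    g = phantom.density
    cx = (g.origin + (body_idx.mean(axis=0) + 0.5) * g.spacing)[0]
    lat = 1.0 if phantom.laterality == "left" else -1.0
    beams = [plan.beam_by_id(b) for b in pair]
    beams.sort(key=lambda b: lat * (b.source_mm()[0] - cx))  # medial = most contralateral
    return beams
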