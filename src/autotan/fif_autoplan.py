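"""Iterative hotspot-blocking segment generation and weight optimization.

The segment loop mirrors the forward-planning workflow of an experienced
dosimetrist: find the hotspot of the current dose distribution inside the
breast PTV, block it with an MLC segment on the next tangent (alternating
beams, medial first), give the segment twice the hotspot percentage as
its fractional weight, renormalize and repeat.  The hotspot threshold is
dynamic: it starts at 2.5% of the current plan maximum and falls linearly
to 1% at the last allowed segment, with the segment budget fixed up front
from the open-field maximum dose (``int((Dmax - 105%) / 2.5%)``).  The
loop stops early once no hotspot above 105% of prescription remains.
A final constrained weight optimization (uniform-dose and max-dose
objectives, both weighted 50, minimum 4 MU per retained segment) polishes
homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .beam_geometry import (
    Beam,
    BeamAperture,
    Plan,
    find_tangent_pairs,
    order_pair_medial_first,
)
from .dose_engine import DoseCalculator, DoseGrid, DoseModelParams
from .grids import VoxelGrid
from .synthetic_phantom import Phantom
from .target_volumes import TargetPartition


class DegenerateAperture(Exception):
    """Every leaf row would close: the hotspot covers the whole field."""


class InfeasibleWeights(Exception):
    """The minimum-MU constraints cannot all be satisfied."""


@dataclass
class AutoplanConfig:
    h_start: float = 2.5  # initial hotspot percent of current max
    h_end: float = 1.0  # hotspot percent at the last segment
    stop_level: float = 105.0  # % of prescription: no hotspot above this
    weight_factor: float = 2.0  # segment weight = factor x hotspot percent
    min_segment_mu: float = 4.0
    objective_weight_uniform: float = 50.0
    objective_weight_maxdose: float = 50.0
    min_hotspot_volume_cm3: float = 0.1

    def __post_init__(self) -> None:
        if not self.h_start >= self.h_end > 0:
            raise ValueError("need h_start >= h_end > 0")
        if self.stop_level <= 100:
            raise ValueError("stop level must exceed 100% of prescription")
        if self.weight_factor <= 0 or self.min_segment_mu < 0:
            raise ValueError("invalid weight factor or minimum MU")


@dataclass
class AutoplanTrace:
    """Per-iteration log of the segment loop."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def max_segments(dmax_pct: float) -> int:
    """Segment budget: int truncation of (Dmax - 105)/2.5, floored at 0."""
    if dmax_pct <= 0:
        raise ValueError("Dmax must be positive")
    return max(0, int((dmax_pct - 105.0) / 2.5))


def threshold_schedule(n_segments: int, config: AutoplanConfig | None = None) -> list[float]:
    """Hotspot percents h_k falling linearly from h_start to h_end."""
    cfg = config or AutoplanConfig()
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if n_segments == 1:
        return [cfg.h_start]
    return [
        cfg.h_start - (cfg.h_start - cfg.h_end) * k / (n_segments - 1)
        for k in range(n_segments)
    ]


def dmax_percent(dose: DoseGrid, ptv: VoxelGrid, rx_total: float) -> float:
    """Maximum dose over the PTV as percent of prescription."""
    sel = ptv.values.astype(bool)
    if not sel.any():
        raise ValueError("empty PTV")
    return float(dose.values[sel].max()) / rx_total * 100.0


def find_and_partition_hotspot(
    dose: DoseGrid, partition: TargetPartition, h_k: float
) -> tuple[VoxelGrid, VoxelGrid]:
    """Voxels within h_k percent of the PTV maximum, split tip vs base."""
    if dose.normalization_state != "normalized":
        raise ValueError("dose must be normalized")
    ptv = partition.ptv.values.astype(bool)
    dmax = float(dose.values[ptv].max())
    hot = ptv & (dose.values >= (1.0 - h_k / 100.0) * dmax)
    tip_hot = hot & partition.tip.values.astype(bool)
    base_hot = hot & partition.base.values.astype(bool)
    return partition.ptv.like(tip_hot), partition.ptv.like(base_hot)


def propose_segment(
    beam: Beam,
    tip_hotspot: VoxelGrid,
    base_hotspot: VoxelGrid,
    phantom: Phantom,
    pixel_mm: float = 2.5,
) -> BeamAperture:
    """Blocked aperture for one hotspot on one beam.

    The tip hotspot's BEV footprint is extended to the anterior field
    border and the base hotspot's to the posterior border; leaves advance
    from their CP1 positions to cover the blocked region, so each affected
    row keeps a single open interval and the CP1 lung block is preserved
    row-wise.  Raises :class:`DegenerateAperture` when every open row
    would close.
    """
    from .beam_geometry import bev_project  # local import avoids cycle at import time

    if not (tip_hotspot.values.any() or base_hotspot.values.any()):
        raise ValueError("both hotspot masks are empty")
    cp1 = beam.open_field.aperture
    x1, x2, y1, y2 = cp1.jaws
    n_rows = cp1.n_rows

    def row_extents(mask: VoxelGrid):
        """(umin, umax) of the mask's BEV footprint per leaf row."""
        lo = np.full(n_rows, np.nan)
        hi = np.full(n_rows, np.nan)
        if not mask.values.any():
            return lo, hi
        bev = bev_project(mask, beam, pixel_mm)
        iu, iv = np.nonzero(bev.values)
        u = bev.u_centers()[iu]
        v = bev.v_centers()[iv]
        rows = cp1.row_of_v(v)
        ok = (rows >= 0) & (rows < n_rows)
        for row in np.unique(rows[ok]):
            sel = ok & (rows == row)
            lo[row] = u[sel].min() - bev.pixel_cm / 2.0
            hi[row] = u[sel].max() + bev.pixel_cm / 2.0
        return lo, hi

    tip_lo, _ = row_extents(tip_hotspot)
    _, base_hi = row_extents(base_hotspot)

    pairs: list[tuple[float, float]] = []
    any_open = False
    for i in range(n_rows):
        lo1, hi1 = cp1.leaf_pairs[i]
        lo, hi = lo1, hi1
        if np.isfinite(tip_lo[i]):  # block [tip_lo, anterior border]
            hi = min(hi, tip_lo[i])
        if np.isfinite(base_hi[i]):  # block [posterior border, base_hi]
            lo = max(lo, base_hi[i])
        olo, ohi = max(lo, x1), min(hi, x2)
        if ohi - olo <= 1e-9:
            mid = min(max(lo1, x1), x2)
            pairs.append((mid, mid))  # closed row
        else:
            pairs.append((lo, hi))
            any_open = True
    if not any_open:
        raise DegenerateAperture("hotspot blocks every leaf row")
    return BeamAperture(jaws=cp1.jaws, leaf_width=cp1.leaf_width, leaf_pairs=pairs)


# ---------------------------------------------------------------------------
# segment-weight optimization


def optimize_weights_core(
    open_cols: np.ndarray,  # (n_beams, n_vox) per-fraction Gy at full open weight
    seg_cols: np.ndarray,  # (n_seg, n_vox)
    seg_beam: np.ndarray,  # (n_seg,) beam index of each segment
    open_calc: np.ndarray,  # (n_beams,) per-fraction Gy at the calc point
    seg_calc: np.ndarray,  # (n_seg,)
    rx_total: float,
    n_fractions: int,
    target_calc_per_fx: float,
    config: AutoplanConfig,
    w0: np.ndarray,
    lower_bounds: np.ndarray | None = None,
):
    """Minimize the 50/50 uniform/max-dose objective over segment weights.

    Dose is linear in the weights before renormalization; the objective is
    evaluated on the renormalized distribution.  Returns ``(w, objective)``.
    """
    n_beams = open_cols.shape[0]
    n_seg = len(seg_cols)
    lb = np.zeros(n_seg) if lower_bounds is None else np.asarray(lower_bounds, float)

    def raw(w):
        openw = np.ones(n_beams)
        np.subtract.at(openw, seg_beam, w)
        vox = openw @ open_cols + (w @ seg_cols if n_seg else 0.0)
        calc = openw @ open_calc + (w @ seg_calc if n_seg else 0.0)
        return vox, calc

    def dose_total(w):
        vox, calc = raw(w)
        return vox * (target_calc_per_fx / calc) * n_fractions

    def objective(w):
        d = dose_total(w)
        rel = (d - rx_total) / rx_total
        over = np.clip(d - 1.05 * rx_total, 0.0, None) / rx_total
        return float(
            config.objective_weight_uniform * np.mean(rel**2)
            + config.objective_weight_maxdose * np.mean(over**2)
        )

    if n_seg == 0:
        return np.zeros(0), objective(np.zeros(0))

    constraints = []
    for b in range(n_beams):
        sel = (seg_beam == b).astype(float)
        if sel.any():
            constraints.append(
                {"type": "ineq", "fun": (lambda w, s=sel: 1.0 - float(s @ w))}
            )
    bounds = [(float(l), 0.8) for l in lb]
    start = np.clip(w0, lb, 0.8)
    res = optimize.minimize(
        objective,
        start,
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    w = np.clip(res.x, lb, 0.8)
    cand = [(objective(w), w)]
    if np.all(start >= lb - 1e-12):
        cand.append((objective(start), start))
    obj, w = min(cand, key=lambda c: c[0])
    return w, obj


def _plan_segments(plan: Plan) -> list[tuple[int, int]]:
    return [
        (bi, ci)
        for bi, beam in enumerate(plan.beams)
        for ci in range(1, len(beam.control_points))
    ]


def optimize_segment_weights(
    plan: Plan,
    phantom: Phantom,
    ptv: VoxelGrid,
    params: DoseModelParams | None = None,
    config: AutoplanConfig | None = None,
    calculator: DoseCalculator | None = None,
) -> Plan:
    """Re-weight segments for homogeneity; retained segments carry >= 4 MU.

    Minimizes ``50 * mean(((D - Rx)/Rx)^2) + 50 * mean((relu(D - 1.05 Rx)/Rx)^2)``
    over the PTV subject to per-beam weight conservation.  Segments that
    fall below the minimum MU are dropped (weight exactly 0) and the rest
    re-solved with the minimum as a lower bound.  The objective at return
    never exceeds the objective at entry; the input plan is not mutated.
    """
    cfg = config or AutoplanConfig()
    out = plan.copy()
    segs = _plan_segments(out)
    if not segs:
        return out
    calc = calculator or DoseCalculator(phantom, params)
    rx = out.prescription
    ptv_flat = np.flatnonzero(ptv.values)
    pos = np.searchsorted(calc.body_flat, ptv_flat)
    if np.any(pos >= len(calc.body_flat)) or np.any(calc.body_flat[pos] != ptv_flat):
        raise ValueError("PTV must lie inside the body mask")

    n_beams = len(out.beams)
    open_cols = np.stack(
        [
            b.beam_mu * calc.cp_dose_per_mu(b, b.open_field.aperture)[pos]
            for b in out.beams
        ]
    )
    open_calc = np.array(
        [
            b.beam_mu * calc.cp_dose_at_point(b, b.open_field.aperture, rx.calc_point)
            for b in out.beams
        ]
    )
    seg_beam = np.array([bi for bi, _ in segs])
    seg_cols = np.stack(
        [
            out.beams[bi].beam_mu
            * calc.cp_dose_per_mu(out.beams[bi], out.beams[bi].control_points[ci].aperture)[pos]
            for bi, ci in segs
        ]
    )
    seg_calc = np.array(
        [
            out.beams[bi].beam_mu
            * calc.cp_dose_at_point(
                out.beams[bi], out.beams[bi].control_points[ci].aperture, rx.calc_point
            )
            for bi, ci in segs
        ]
    )
    target_calc = rx.normalization_pct / 100.0 * rx.dose_per_fraction
    w0 = np.array([out.beams[bi].control_points[ci].weight for bi, ci in segs])

    def norm_scale(w):
        openw = np.ones(n_beams)
        np.subtract.at(openw, seg_beam, w)
        return target_calc / float(openw @ open_calc + w @ seg_calc)

    active = np.ones(len(segs), dtype=bool)
    lb = np.zeros(len(segs))
    w = w0.copy()
    for _ in range(4):
        if not active.any():
            w = np.zeros(len(segs))
            break
        w_act, _ = optimize_weights_core(
            open_cols,
            seg_cols[active],
            seg_beam[active],
            open_calc,
            seg_calc[active],
            rx.total_dose,
            rx.n_fractions,
            target_calc,
            cfg,
            w[active],
            lb[active],
        )
        w = np.zeros(len(segs))
        w[active] = w_act
        scale = norm_scale(w)
        mu_per_seg = w * np.array([out.beams[bi].beam_mu for bi in seg_beam]) * scale
        low = active & (mu_per_seg < cfg.min_segment_mu - 1e-9)
        at_bound = active & (lb > 0)
        # drop segments that cannot honestly reach the minimum MU
        drop = low & (at_bound | (mu_per_seg < 0.5 * cfg.min_segment_mu))
        raise_lb = low & ~drop
        if not low.any():
            break
        active &= ~drop
        lb[~active] = 0.0
        if raise_lb.any():
            for j in np.flatnonzero(raise_lb & active):
                lb[j] = cfg.min_segment_mu / (out.beams[seg_beam[j]].beam_mu * scale)
        for b in range(n_beams):
            sel = active & (seg_beam == b)
            if lb[sel].sum() > 1.0:
                raise InfeasibleWeights(f"minimum-MU bounds exceed beam {b} capacity")
    else:
        scale = norm_scale(w)
        mu_per_seg = w * np.array([out.beams[bi].beam_mu for bi in seg_beam]) * scale
        if np.any((w > 0) & (mu_per_seg < cfg.min_segment_mu - 1e-6)):
            raise InfeasibleWeights("could not satisfy minimum MU per segment")

    # write back, pruning dropped segments
    for (bi, ci), wi in sorted(zip(segs, w), key=lambda t: (t[0][0], -t[0][1])):
        if wi <= 0:
            del out.beams[bi].control_points[ci]
        else:
            out.beams[bi].control_points[ci].weight = float(wi)
    for beam in out.beams:
        seg_sum = sum(cp.weight for cp in beam.control_points[1:])
        beam.control_points[0].weight = 1.0 - seg_sum
    return out


# ---------------------------------------------------------------------------
# the segment loop


def autoplan(
    plan: Plan,
    phantom: Phantom,
    partition: TargetPartition,
    params: DoseModelParams | None = None,
    config: AutoplanConfig | None = None,
    calculator: DoseCalculator | None = None,
) -> tuple[Plan, AutoplanTrace]:
    """Run the full segment loop plus weight optimization.

    Returns a new plan (the input is never mutated) whose beam MUs are
    back-computed from the final normalization, together with the
    per-iteration trace.
    """
    cfg = config or AutoplanConfig()
    calc = calculator or DoseCalculator(phantom, params)
    work = plan.copy()
    trace = AutoplanTrace()
    rx_total = work.prescription.total_dose

    dose = calc.plan_dose(work)
    open_dmax = dmax_percent(dose, partition.ptv, rx_total)
    budget = max_segments(open_dmax)
    trace.add(
        iteration=0, beam="", dmax_pct=open_dmax, h_pct=np.nan,
        threshold_gy=np.nan, hotspot_cm3=np.nan, weight=np.nan, n_segments=0,
    )
    if budget == 0:
        calc.plan_dose(work, update_beam_mu=True)
        return work, trace

    schedule = threshold_schedule(budget, cfg)
    pair = find_tangent_pairs(work.beams)[0]
    cycle = order_pair_medial_first(work, phantom, pair)
    voxel_cm3 = phantom.density.voxel_volume_cm3
    n_segments = 0

    for k in range(budget):
        dose = calc.plan_dose(work)
        dmax = dmax_percent(dose, partition.ptv, rx_total)
        if dmax <= cfg.stop_level:
            break
        h_k = schedule[k]
        tip_hot, base_hot = find_and_partition_hotspot(dose, partition, h_k)
        hot_cm3 = (np.count_nonzero(tip_hot.values) + np.count_nonzero(base_hot.values)) * voxel_cm3
        if hot_cm3 < cfg.min_hotspot_volume_cm3:
            break
        beam = cycle[k % len(cycle)]
        try:
            aperture = propose_segment(beam, tip_hot, base_hot, phantom)
        except DegenerateAperture:
            trace.add(
                iteration=k + 1, beam=beam.id, dmax_pct=dmax, h_pct=h_k,
                threshold_gy=(1 - h_k / 100.0) * dmax / 100.0 * rx_total,
                hotspot_cm3=hot_cm3, weight=0.0, n_segments=n_segments,
            )
            continue  # skip this iteration, advance the beam cycle
        from .beam_geometry import SegmentField

        w_k = cfg.weight_factor * h_k / 100.0
        open_cp = beam.control_points[0]
        w_k = min(w_k, max(0.0, open_cp.weight - 0.05))
        if w_k <= 0:
            break
        open_cp.weight -= w_k
        beam.control_points.append(SegmentField(aperture=aperture, weight=w_k))
        n_segments += 1
        trace.add(
            iteration=k + 1, beam=beam.id, dmax_pct=dmax, h_pct=h_k,
            threshold_gy=(1 - h_k / 100.0) * dmax / 100.0 * rx_total,
            hotspot_cm3=hot_cm3, weight=w_k, n_segments=n_segments,
        )

    if n_segments:
        work = optimize_segment_weights(
            work, phantom, partition.ptv, params, cfg, calculator=calc
        )
    dose = calc.plan_dose(work, update_beam_mu=True)
    trace.add(
        iteration=len(trace.records), beam="final",
        dmax_pct=dmax_percent(dose, partition.ptv, rx_total),
        h_pct=np.nan, threshold_gy=np.nan, hotspot_cm3=np.nan, weight=np.nan,
        n_segments=sum(len(b.control_points) - 1 for b in work.beams),
    )
    return work, trace
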