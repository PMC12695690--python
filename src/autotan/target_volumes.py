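"""PTV generation from the open-field 95% isodose and tip/base partition.

The breast PTV is grown from the 95% isodose of the open tangent pair
(prescription-relative by default), restricted to the body, excluding the
lungs and a 4 mm skin rind, keeping the largest connected component.
The anterior "tip" of the PTV is found by contracting the posterior field
border 3 cm anteriorly, recomputing dose and thresholding at 95% again;
the remainder of the PTV is the posterior "base".  Tip and base drive the
direction in which hotspot apertures are extended during segment design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .beam_geometry import Plan, find_tangent_pairs
from .dose_engine import DoseCalculator, DoseGrid, DoseModelParams
from .grids import VoxelGrid
from .synthetic_phantom import Phantom

SKIN_RIND_MM = 4.0
DEFAULT_CONTRACTION_CM = 3.0


class EmptyPTV(Exception):
    """No voxel reaches the isodose threshold."""


class ContractionCollapsesField(Exception):
    """The posterior contraction is at least the field's A-P extent."""


@dataclass
class TargetPartition:
    """PTV with its disjoint anterior (tip) / posterior (base) sub-masks."""

    ptv: VoxelGrid
    tip: VoxelGrid
    base: VoxelGrid

    def validate(self) -> None:
        p = self.ptv.values.astype(bool)
        t = self.tip.values.astype(bool)
        b = self.base.values.astype(bool)
        if np.any(t & b):
            raise ValueError("tip and base must be disjoint")
        if not np.array_equal(t | b, p):
            raise ValueError("tip and base must partition the PTV")


def generate_ptv(
    open_dose: DoseGrid,
    prescription,
    phantom: Phantom,
    threshold: float = 0.95,
    relative_to: str = "prescription",
) -> VoxelGrid:
    """Threshold the open-field dose at the 95% isodose to form the PTV.

    ``relative_to`` selects whether the isodose is a fraction of the
    prescription dose (clinical norm, default) or of the grid maximum.
    """
    if open_dose.normalization_state != "normalized":
        raise ValueError("open dose must be normalized before growing the PTV")
    dose = open_dose.values
    if relative_to == "prescription":
        level = threshold * prescription.total_dose
    elif relative_to == "max":
        level = threshold * float(dose.max())
    else:
        raise ValueError("relative_to must be 'prescription' or 'max'")
    body = phantom.masks["body"].values.astype(bool)
    mask = (dose >= level) & body
    mask &= ~phantom.masks["lung_ipsi"].values.astype(bool)
    mask &= ~phantom.masks["lung_contra"].values.astype(bool)
    # skin rind: drop voxels whose centre is within 4 mm of the body
    # surface (half a voxel inside the outermost background centre)
    dist = ndimage.distance_transform_edt(body, sampling=phantom.density.spacing)
    surface_dist = dist - 0.5 * float(np.mean(phantom.density.spacing))
    mask &= surface_dist >= SKIN_RIND_MM
    if not mask.any():
        raise EmptyPTV(f"no voxel at or above {level:.2f} Gy")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:  # largest 26-connected component; ties -> lowest voxel index
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        best = int(np.flatnonzero(sizes == sizes.max())[0]) + 1
        mask = labels == best
    return phantom.density.like(mask)


def contract_posterior_border(plan: Plan, contraction_cm: float) -> Plan:
    """Working copy of the plan with the posterior jaw moved anteriorly.

    The posterior border is the x1 jaw (the lung-bite side in the beam
    frame convention); leaf edges are clipped to the new jaw.  The input
    plan is never mutated.
    """
    out = plan.copy()
    for beam in out.beams:
        for cp in beam.control_points:
            x1, x2, y1, y2 = cp.aperture.jaws
            new_x1 = x1 + contraction_cm
            if new_x1 >= x2:
                raise ContractionCollapsesField(
                    f"contraction {contraction_cm} cm >= field extent {x2 - x1:.2f} cm"
                )
            cp.aperture.jaws = (new_x1, x2, y1, y2)
            cp.aperture.leaf_pairs = [
                (max(lo, new_x1), max(hi, max(lo, new_x1))) for lo, hi in cp.aperture.leaf_pairs
            ]
    return out


def split_tip_base(
    plan: Plan,
    phantom: Phantom,
    ptv: VoxelGrid,
    params: DoseModelParams | None = None,
    contraction_cm: float = DEFAULT_CONTRACTION_CM,
    calculator: DoseCalculator | None = None,
    threshold: float = 0.95,
) -> TargetPartition:
    """Partition the PTV into tip and base via posterior-border contraction.

    Builds a working copy of the tangent pair with the posterior jaw moved
    ``contraction_cm`` anteriorly, recomputes dose with the same
    normalization point, and takes tip = PTV voxels still at or above the
    95% isodose of the contracted fields; base is the rest of the PTV.
    """
    if not ptv.values.any():
        raise EmptyPTV("cannot partition an empty PTV")
    if contraction_cm <= 0:
        tip = phantom.density.like(ptv.values.astype(bool))
        base = phantom.density.like(np.zeros_like(ptv.values, dtype=bool))
        return TargetPartition(ptv=ptv, tip=tip, base=base)
    find_tangent_pairs(plan.beams)  # partition is defined for a legitimate pair
    calc = calculator or DoseCalculator(phantom, params)
    contracted = contract_posterior_border(plan, contraction_cm)
    dose_c = calc.plan_dose(contracted, normalize=True)
    level = threshold * plan.prescription.total_dose
    p = ptv.values.astype(bool)
    tip = p & (dose_c.values >= level)
    base = p & ~tip
    part = TargetPartition(
        ptv=ptv,
        tip=phantom.density.like(tip),
        base=phantom.density.like(base),
    )
    part.validate()
    return part
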