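"""File formats: NIfTI volumes, YAML plans/configs, JSON reports.

Volumes are written as NIfTI-1 with a diagonal affine carrying the
spacing and the voxel-(0,0,0)-centre translation, so round-tripping
preserves the lattice exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .beam_geometry import Beam, BeamAperture, Plan, Prescription, SegmentField
from .dose_engine import DoseGrid
from .grids import VoxelGrid
from .synthetic_phantom import Phantom, PhantomConfig


def save_volume(grid: VoxelGrid, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin + 0.5 * grid.spacing
    data = grid.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def load_volume(path: str | Path, as_bool: bool = False) -> VoxelGrid:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.diag(affine)[:3].copy()
    origin = affine[:3, 3] - 0.5 * spacing
    values = np.asarray(img.dataobj)
    if as_bool:
        values = values.astype(bool)
    return VoxelGrid(origin, spacing, values)


def save_phantom(phantom: Phantom, out_dir: str | Path) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"density": str(save_volume(phantom.density, out_dir / "density.nii"))}
    for name, mask in phantom.masks.items():
        manifest[name] = str(save_volume(mask, out_dir / f"mask_{name}.nii"))
    info = {"laterality": phantom.laterality}
    if phantom.config is not None:
        info["config"] = dataclasses.asdict(phantom.config)
    info["meta"] = {k: np.asarray(v).tolist() for k, v in phantom.meta.items()}
    (out_dir / "phantom.yaml").write_text(yaml.safe_dump(info))
    manifest["info"] = str(out_dir / "phantom.yaml")
    return manifest


def load_phantom(out_dir: str | Path) -> Phantom:
    out_dir = Path(out_dir)
    info = yaml.safe_load((out_dir / "phantom.yaml").read_text())
    cfg = None
    if "config" in info:
        raw = dict(info["config"])
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        cfg = PhantomConfig(**raw)
    density = load_volume(out_dir / "density.nii")
    masks = {
        name: load_volume(out_dir / f"mask_{name}.nii", as_bool=True)
        for name in Phantom.REQUIRED_MASKS
    }
    meta = {k: np.asarray(v) for k, v in info.get("meta", {}).items()}
    return Phantom(
        density=density, masks=masks, laterality=info["laterality"], config=cfg, meta=meta
    )


# --- plans ------------------------------------------------------------------


def plan_to_dict(plan: Plan) -> dict:
    f = float  # plain floats so YAML stays clean of numpy scalars
    return {
        "phantom_ref": plan.phantom_ref,
        "prescription": {
            "dose_per_fraction": f(plan.prescription.dose_per_fraction),
            "n_fractions": int(plan.prescription.n_fractions),
            "calc_point": [f(x) for x in plan.prescription.calc_point],
            "normalization_pct": f(plan.prescription.normalization_pct),
        },
        "beams": [
            {
                "id": b.id,
                "gantry_angle": f(b.gantry_angle),
                "collimator_angle": f(b.collimator_angle),
                "isocenter": [f(x) for x in b.isocenter],
                "sad": f(b.sad),
                "attenuation_mu": None if b.attenuation_mu is None else f(b.attenuation_mu),
                "beam_mu": f(b.beam_mu),
                "control_points": [
                    {
                        "weight": f(cp.weight),
                        "jaws": [f(x) for x in cp.aperture.jaws],
                        "leaf_width": f(cp.aperture.leaf_width),
                        "leaf_pairs": [[f(lo), f(hi)] for lo, hi in cp.aperture.leaf_pairs],
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }


def plan_from_dict(data: dict) -> Plan:
    rx = data["prescription"]
    beams = []
    for bd in data["beams"]:
        cps = [
            SegmentField(
                aperture=BeamAperture(
                    jaws=tuple(cpd["jaws"]),
                    leaf_width=cpd["leaf_width"],
                    leaf_pairs=[tuple(p) for p in cpd["leaf_pairs"]],
                ),
                weight=cpd["weight"],
            )
            for cpd in bd["control_points"]
        ]
        beams.append(
            Beam(
                id=bd["id"],
                gantry_angle=bd["gantry_angle"],
                collimator_angle=bd["collimator_angle"],
                isocenter=np.asarray(bd["isocenter"]),
                sad=bd["sad"],
                attenuation_mu=bd["attenuation_mu"],
                control_points=cps,
                beam_mu=bd["beam_mu"],
            )
        )
    return Plan(
        beams=beams,
        prescription=Prescription(
            dose_per_fraction=rx["dose_per_fraction"],
            n_fractions=rx["n_fractions"],
            calc_point=np.asarray(rx["calc_point"]),
            normalization_pct=rx["normalization_pct"],
        ),
        phantom_ref=data.get("phantom_ref", ""),
    )


def save_plan(plan: Plan, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(plan_to_dict(plan), sort_keys=False))
    return path


def load_plan(path: str | Path) -> Plan:
    return plan_from_dict(yaml.safe_load(Path(path).read_text()))


# --- dose -------------------------------------------------------------------


def save_dose(dose: DoseGrid, path: str | Path) -> Path:
    path = Path(path)
    save_volume(dose.grid, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"normalization_state": dose.normalization_state,
                    "meta": {k: float(v) for k, v in dose.meta.items()}})
    )
    return path


def load_dose(path: str | Path) -> DoseGrid:
    path = Path(path)
    grid = load_volume(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    state, meta = "raw", {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        state = info.get("normalization_state", "raw")
        meta = info.get("meta", {})
    return DoseGrid(grid, state, meta)
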