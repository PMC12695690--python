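import numpy as np
import pytest

from autotan.beam_geometry import Beam, BeamAperture, SegmentField, default_tangent_setup
from autotan.dose_engine import DoseCalculator
from autotan.fif_autoplan import autoplan
from autotan.grids import VoxelGrid
from autotan.synthetic_phantom import Phantom, PhantomConfig, build_phantom
from autotan.target_volumes import generate_ptv, split_tip_base

COARSE_SPACING = (5.0, 5.0, 5.0)  # keeps full-pipeline fixtures at a few seconds


@pytest.fixture(scope="session")
def coarse_phantom() -> Phantom:
    return build_phantom(PhantomConfig(spacing_mm=COARSE_SPACING))


@pytest.fixture(scope="session")
def coarse_calc(coarse_phantom) -> DoseCalculator:
    return DoseCalculator(coarse_phantom)


@pytest.fixture(scope="session")
def coarse_pipeline(coarse_phantom, coarse_calc) -> dict:
    """One full workflow run shared by the integration-level tests."""
    plan = default_tangent_setup(coarse_phantom)
    open_dose = coarse_calc.plan_dose(plan, update_beam_mu=True)
    ptv = generate_ptv(open_dose, plan.prescription, coarse_phantom)
    partition = split_tip_base(plan, coarse_phantom, ptv, calculator=coarse_calc)
    final, trace = autoplan(plan, coarse_phantom, partition, calculator=coarse_calc)
    final_dose = coarse_calc.plan_dose(final)
    return {
        "phantom": coarse_phantom,
        "calc": coarse_calc,
        "plan_open": plan,
        "open_dose": open_dose,
        "ptv": ptv,
        "partition": partition,
        "plan_final": final,
        "trace": trace,
        "final_dose": final_dose,
    }


def make_beam(gantry: float, beam_id: str = "b", jaws=(-5.0, 6.0, -6.0, 6.0),
              attenuation_mu=None, isocenter=(0.0, 0.0, 0.0)) -> Beam:
    """Minimal beam with an open rectangular CP1 for geometry-level tests."""
    ap = BeamAperture(jaws=jaws)
    return Beam(
        id=beam_id,
        gantry_angle=gantry,
        collimator_angle=0.0,
        isocenter=np.asarray(isocenter, float),
        attenuation_mu=attenuation_mu,
        control_points=[SegmentField(aperture=ap, weight=1.0)],
    )


def uniform_water_phantom(side_mm=200.0, spacing=2.0) -> Phantom:
    """Uniform water cube (body everywhere) for central-axis dose checks."""
    n = int(round(side_mm / spacing))
    grid = VoxelGrid(
        origin=np.array([-side_mm / 2] * 3),
        spacing=np.array([spacing] * 3),
        values=np.ones((n, n, n), dtype=np.float32),
    )
    full = grid.like(np.ones((n, n, n), dtype=bool))
    empty = grid.like(np.zeros((n, n, n), dtype=bool))
    return Phantom(
        density=grid,
        masks={"body": full, "breast": empty.copy(), "lung_ipsi": empty.copy(),
               "lung_contra": empty.copy(), "heart": empty.copy()},
        laterality="left",
    )
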