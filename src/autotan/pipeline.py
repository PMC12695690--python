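"""End-to-end orchestration of the three-step planning workflow.

phantom -> tangent setup -> open dose -> prerequisite check (gate) ->
PTV -> tip/base -> segment loop + weight optimization -> evaluation.
Every stage writes its artifact; the manifest lists them all.  The
pipeline aborts after the check stage (status 2) if any prerequisite
fails, mirroring the clinical script's gate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as tio
from .beam_geometry import Plan, check_prerequisites, default_tangent_setup
from .dose_engine import DoseCalculator, DoseModelParams
from .fif_autoplan import AutoplanConfig, autoplan
from .plan_evaluation import evaluate_plan
from .synthetic_phantom import Phantom, PhantomConfig, build_phantom
from .target_volumes import generate_ptv, split_tip_base

log = logging.getLogger("autotan")

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_PREREQ = 2


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    plan: str | Plan = "auto"  # 'auto' -> default_tangent_setup
    dose_params: DoseModelParams = field(default_factory=DoseModelParams)
    autoplan: AutoplanConfig = field(default_factory=AutoplanConfig)
    out_dir: str | Path = "autotan_out"
    seed: int = 0
    save_volumes: bool = True
    verbosity: int = 1


@dataclass
class PipelineResult:
    status: int
    manifest: dict
    phantom: Phantom | None = None
    plan_open: Plan | None = None
    plan_final: Plan | None = None
    report: dict | None = None
    partition: object = None
    dose_final: object = None
    metrics: object = None
    trace: object = None


@dataclass
class CaseResult:
    """In-memory result of the full workflow on one phantom."""

    phantom: Phantom
    plan_open: Plan
    open_dose: object
    ptv: object
    partition: object
    plan_final: Plan
    trace: object
    dose_final: object
    metrics: object
    open_dmax_pct: float
    final_dmax_pct: float


def run_case(
    phantom: Phantom,
    dose_params: DoseModelParams | None = None,
    autoplan_config: AutoplanConfig | None = None,
) -> CaseResult:
    """Run setup -> open dose -> PTV -> tip/base -> autoplan -> metrics.

    The in-memory counterpart of :func:`run_pipeline` for one phantom;
    raises if the prerequisite check fails.
    """
    from .fif_autoplan import dmax_percent

    plan_open = default_tangent_setup(phantom)
    calc = DoseCalculator(phantom, dose_params)
    open_dose = calc.plan_dose(plan_open, update_beam_mu=True)
    report = check_prerequisites(plan_open, phantom, open_dose)
    if not report.overall_pass:
        raise RuntimeError(f"prerequisites failed: {report.to_dict()}")
    ptv = generate_ptv(open_dose, plan_open.prescription, phantom)
    partition = split_tip_base(plan_open, phantom, ptv, calculator=calc)
    plan_final, trace = autoplan(
        plan_open, phantom, partition, dose_params, autoplan_config, calculator=calc
    )
    dose_final = calc.plan_dose(plan_final)
    rx_total = plan_open.prescription.total_dose
    return CaseResult(
        phantom=phantom,
        plan_open=plan_open,
        open_dose=open_dose,
        ptv=ptv,
        partition=partition,
        plan_final=plan_final,
        trace=trace,
        dose_final=dose_final,
        metrics=evaluate_plan(plan_final, phantom, partition, dose_final),
        open_dmax_pct=dmax_percent(open_dose, ptv, rx_total),
        final_dmax_pct=dmax_percent(dose_final, ptv, rx_total),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow; returns status plus artifact manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    t0 = time.time()

    cfg = dataclasses.replace(config.phantom, seed=config.phantom.seed or config.seed)
    phantom = build_phantom(cfg)
    if config.save_volumes:
        manifest["phantom"] = tio.save_phantom(phantom, out_dir / "phantom")
    log.info("phantom built in %.1fs", time.time() - t0)

    if config.plan == "auto":
        plan_open = default_tangent_setup(phantom)
    elif isinstance(config.plan, Plan):
        plan_open = config.plan.copy()
    else:
        plan_open = tio.load_plan(config.plan)
    manifest["plan_open"] = str(tio.save_plan(plan_open, out_dir / "plan_open.yaml"))

    calc = DoseCalculator(phantom, config.dose_params)
    open_dose = calc.plan_dose(plan_open, update_beam_mu=True)
    if config.save_volumes:
        manifest["dose_open"] = str(tio.save_dose(open_dose, out_dir / "dose_open.nii"))

    report = check_prerequisites(plan_open, phantom, open_dose)
    manifest["check_report"] = str(out_dir / "check_report.json")
    Path(manifest["check_report"]).write_text(json.dumps(report.to_dict(), indent=2))
    if not report.overall_pass:
        log.warning("prerequisites failed; stopping after the open-field check")
        return PipelineResult(EXIT_PREREQ, manifest, phantom, plan_open, report=report.to_dict())

    ptv = generate_ptv(open_dose, plan_open.prescription, phantom)
    partition = split_tip_base(plan_open, phantom, ptv, calculator=calc)
    if config.save_volumes:
        manifest["ptv"] = str(tio.save_volume(ptv, out_dir / "ptv.nii"))
        manifest["tip"] = str(tio.save_volume(partition.tip, out_dir / "tip.nii"))
        manifest["base"] = str(tio.save_volume(partition.base, out_dir / "base.nii"))

    plan_final, trace = autoplan(
        plan_open, phantom, partition, config.dose_params, config.autoplan, calculator=calc
    )
    manifest["plan_final"] = str(tio.save_plan(plan_final, out_dir / "plan_final.yaml"))
    trace_df = trace.to_dataframe()
    manifest["trace"] = str(out_dir / "trace.csv")
    trace_df.to_csv(manifest["trace"], index=False)

    dose_final = calc.plan_dose(plan_final)
    if config.save_volumes:
        manifest["dose_final"] = str(tio.save_dose(dose_final, out_dir / "dose_final.nii"))

    metrics = evaluate_plan(plan_final, phantom, partition, dose_final)
    manifest["metrics"] = str(out_dir / "metrics.json")
    Path(manifest["metrics"]).write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True))
    log.info("pipeline finished in %.1fs", time.time() - t0)

    return PipelineResult(
        EXIT_OK,
        manifest,
        phantom,
        plan_open,
        plan_final,
        report.to_dict(),
        partition,
        dose_final,
        metrics,
        trace,
    )
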