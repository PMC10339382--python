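"""End-to-end offline/online workflow.

Stages: build the cross-section mesh → generate finite-element snapshots on
the force grid → build the separated reduced model → report relative errors
at subdomain centers → extract response surfaces and force trends. Every
artifact is stamped with the configuration digest, and identical
configurations produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .config import PipelineConfig
from .errors import error_report
from .exceptions import PipelineError, ToothmorError
from .geometry import Region, build_toy_mesh, mesh_summary
from .hopgd import decompose, evaluate
from .io import (
    load_model,
    save_model,
    save_snapshots,
    write_mesh_text,
    write_vtk,
)
from .response import classify_trend, extreme_vms, region_node_mask
from .snapshots import ParameterGrid, generate_fe_snapshots

__all__ = ["run_pipeline", "predict"]

log = logging.getLogger("toothmor")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except ToothmorError as err:
                log.error("stage %s: FAILED: %s", name, err)
                raise PipelineError(name, str(err)) from err
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> Dict[str, Path]:
    """Run every stage; returns a name → path map of the artifacts written.

    Raises :class:`PipelineError` carrying the failing stage's name; partial
    artifacts written before the failure are left in place for debugging.
    """
    config.validate()
    digest = config.digest()
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    artifacts: Dict[str, Path] = {"log": out / "pipeline.log"}
    try:
        log.info("pipeline start, config digest %s", digest)
        config.to_yaml(out / "config.yaml")
        artifacts["config"] = out / "config.yaml"

        mesh = _stage("mesh")(build_toy_mesh)(config.geometry)
        write_mesh_text(out / "mesh.txt", mesh)
        write_vtk(out / "mesh.vtk", mesh, title=f"toothmor mesh cfg={digest}")
        mesh_summary(mesh).to_csv(out / "mesh_summary.csv", index=False)
        artifacts.update(
            mesh=out / "mesh.txt", mesh_vtk=out / "mesh.vtk",
            mesh_summary=out / "mesh_summary.csv",
        )

        grid = ParameterGrid.uniform(
            config.grid.min, config.grid.max, config.grid.n_fy, config.grid.n_fz
        )

        def progress(done, total, fy, fz):
            log.info("snapshot %d/%d at (Fy, Fz) = (%g, %g) N", done, total, fy, fz)

        tensor = _stage("snapshots")(generate_fe_snapshots)(
            mesh, config.materials, grid, config.solver,
            config_digest=digest, progress=progress,
        )
        save_snapshots(out / "snapshots.h5", tensor)
        artifacts["snapshots"] = out / "snapshots.h5"

        model = _stage("reduce")(decompose)(
            tensor,
            tol_modes=config.hopgd.tol_modes,
            max_modes=config.hopgd.max_modes,
            tol_fp=config.hopgd.tol_fp,
            max_sweeps=config.hopgd.max_sweeps,
            interp_scheme=config.hopgd.interp_scheme,
            init=config.hopgd.init,
        )
        log.info(
            "reduced model: %d modes, final residual %.3e",
            model.n_modes,
            model.residual_history[-1] if model.residual_history else 0.0,
        )
        save_model(out / "model.h5", model)
        artifacts["model"] = out / "model.h5"

        report = _stage("errors")(error_report)(
            model,
            reference_source=config.evaluation.reference,
            mesh=mesh,
            materials=config.materials,
            solver_opts=config.solver,
            mask=config.evaluation.mask,
        )
        report.to_csv(out / "errors.csv")
        artifacts["errors"] = out / "errors.csv"
        if report.any_flagged:
            raise PipelineError("errors", "one or more reference solves failed")

        surfaces, trends = _stage("surface")(_response_stage)(mesh, tensor)
        pd.concat([s.to_frame() for s in surfaces]).to_csv(
            out / "response_surface.csv", index=False
        )
        with open(out / "trends.json", "w") as f:
            json.dump(
                {"config_digest": digest, "trends": [t.to_dict() for t in trends]},
                f, indent=2, sort_keys=True,
            )
        artifacts["surface"] = out / "response_surface.csv"
        artifacts["trends"] = out / "trends.json"
        log.info("pipeline complete")
    finally:
        log.removeHandler(fh)
        fh.close()
    return artifacts


def _response_stage(mesh, tensor):
    """Extreme-stress surfaces for root dentin and ligament, plus trends.

    Trends traverse one force axis with the other held at its minimum grid
    value (recorded in the output); both regions are characterized.
    """
    surfaces = []
    trends = []
    for region, name in ((Region.DENTIN, "ROOT"), (Region.PDL, "PDL")):
        surf = extreme_vms(tensor, region_node_mask(mesh, region), region_name=name)
        surfaces.append(surf)
        trend_fz = classify_trend(surf.fz_values, surf.values[0, :], axis=f"{name}:fz@fy_min")
        trend_fy = classify_trend(surf.fy_values, surf.values[:, 0], axis=f"{name}:fy@fz_min")
        if surf.values.min() < surf.values[0, 0] - 1e-12:
            log.warning(
                "region %s: extreme stress is not minimal at the lowest loads "
                "(non-monotone response surface)", name,
            )
        trends += [trend_fz, trend_fy]
    return surfaces, trends


def predict(model_path, fy: float, fz: float, mesh_path=None, out_path=None):
    """Online query against a saved reduced model; no FE solve is issued.

    Returns the nodal von Mises field and, when the mesh is supplied, a
    summary dict with the extreme stress per tissue region. Optionally
    writes the field (plus region tags) as a legacy VTK file.
    """
    from .io import read_mesh_text  # local import to keep module load light

    model = load_model(model_path)
    field = evaluate(model, fy, fz)
    summary = {"fy_N": fy, "fz_N": fz, "max_vms_MPa": float(field.max())}
    if mesh_path is not None:
        mesh = read_mesh_text(mesh_path)
        for region, name in ((Region.DENTIN, "ROOT"), (Region.PDL, "PDL")):
            mask = region_node_mask(mesh, region)
            summary[f"max_vms_{name}_MPa"] = float(field[mask].max())
        if out_path is not None:
            write_vtk(out_path, mesh, point_data={"vms": field})
    return field, summary
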