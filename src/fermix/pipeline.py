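"""End-to-end pipeline: design -> fit -> optimize -> sensory -> VOC screen.

Each stage runs only when its inputs are configured; missing inputs mark
the stage "skipped" in the report rather than aborting, so partial
configurations run partial pipelines.  A stage that does fail aborts
with a stage-named error, but artifacts already written by earlier
stages are preserved on disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .fuzzy import fuzzy_score, panel_from_csv, score_panel
from .ga import GAConfig, ga_maximize, grid_maximize
from .mixture_design import augment_design, generate_simplex_lattice
from .scheffe import (
    fit_scheffe,
    model_from_json,
    model_to_json,
    predict_many,
    response_table_from_csv,
)
from .flavor import screen_key_compounds, voc_table_from_csv

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; unset inputs skip their stage."""

    out_dir: Path
    seed: int = 0
    # design stage
    q: int = 3
    lattice_degree: int = 3
    add_centroid: bool = True
    # fit stage: response CSVs (design columns + response column)
    response_csvs: tuple[Path, ...] = ()
    model_order: str = "special_cubic"
    # optimize stage: pre-fitted model JSONs (fitted models are added automatically)
    model_jsons: tuple[Path, ...] = ()
    ga: GAConfig | None = None
    grid_step: float = 0.005
    # sensory stage
    panel_csvs: tuple[Path, ...] = ()
    # flavor stage
    voc_csv: Path | None = None
    vip_cut: float = 1.0
    oav_cut: float = 1.0


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            report["stages"][name] = {"status": "running"}
            return report["stages"][name]

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report["stages"][name]["status"] = "failed"
                report["stages"][name]["error"] = str(exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name]["status"] = "done"

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write ``report.json`` to the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in [*config.response_csvs, *config.model_jsons, *config.panel_csvs] + (
        [config.voc_csv] if config.voc_csv else []
    ):
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "timestamps": {"start": time.strftime("%Y-%m-%dT%H:%M:%S")},
        "config": {
            "q": config.q,
            "lattice_degree": config.lattice_degree,
            "add_centroid": config.add_centroid,
            "model_order": config.model_order,
            "grid_step": config.grid_step,
            "vip_cut": config.vip_cut,
            "oav_cut": config.oav_cut,
        },
        "stages": {},
        "artifacts": {},
    }

    with _stage(report, "design") as st:
        design = generate_simplex_lattice(config.q, config.lattice_degree)
        if config.add_centroid:
            design = augment_design(design, centroid=True)
        from .mixture_design import design_to_csv

        path = out / "design.csv"
        design_to_csv(design, path)
        st["n_points"] = len(design)
        report["artifacts"]["design"] = str(path)

    model_paths: list[Path] = list(config.model_jsons)

    if config.response_csvs:
        with _stage(report, "fit") as st:
            st["models"] = []
            for rc in config.response_csvs:
                table = response_table_from_csv(rc)
                model, diag = fit_scheffe(table, config.model_order)
                mpath = out / f"model_{table.response_name}.json"
                model_to_json(model, mpath)
                model_paths.append(mpath)
                st["models"].append(
                    {
                        "response": table.response_name,
                        "r2": diag.r2,
                        "adj_r2": diag.adj_r2,
                        "model_p": diag.model_p,
                        "lof_p": diag.lof_p,
                        "path": str(mpath),
                    }
                )
    else:
        report["stages"]["fit"] = {"status": "skipped", "reason": "no response tables"}

    if model_paths:
        with _stage(report, "optimize") as st:
            st["results"] = []
            for i, mp in enumerate(model_paths):
                model = model_from_json(mp)
                cfg = config.ga or GAConfig(seed=config.seed + i)

                def fitness(x, _m=model):
                    return float(predict_many(_m, x[None, :])[0])

                res = ga_maximize(fitness, q=model.q, config=cfg)
                grid_best, grid_val = grid_maximize(
                    fitness, q=model.q, step=config.grid_step
                )
                entry = {
                    "model": str(mp),
                    "units": model.units,
                    "ga_best": list(res.best.proportions),
                    "ga_best_fitness": res.best_fitness,
                    "generations_run": res.generations_run,
                    "seed": res.seed,
                    "history": list(res.history),
                    "grid_best": list(grid_best.proportions),
                    "grid_best_fitness": grid_val,
                }
                st["results"].append(entry)
            rpath = out / "optimization.json"
            rpath.write_text(json.dumps(st["results"], indent=2), encoding="utf-8")
            report["artifacts"]["optimization"] = str(rpath)
    else:
        report["stages"]["optimize"] = {"status": "skipped", "reason": "no models"}

    if config.panel_csvs:
        with _stage(report, "sensory") as st:
            st["scores"] = []
            for pc in config.panel_csvs:
                panel = panel_from_csv(pc)
                result = score_panel(panel)
                st["scores"].append(
                    {
                        "panel": str(pc),
                        "score": result.score,
                        "attribute_scores": list(result.attribute_scores),
                    }
                )
    else:
        report["stages"]["sensory"] = {"status": "skipped", "reason": "no panel tables"}

    if config.voc_csv:
        with _stage(report, "flavor") as st:
            table = voc_table_from_csv(config.voc_csv)
            kept = screen_key_compounds(table, config.vip_cut, config.oav_cut)
            st["n_compounds"] = len(table)
            st["key_compounds"] = [r.name for r in kept]
    else:
        report["stages"]["flavor"] = {"status": "skipped", "reason": "no VOC table"}

    report["timestamps"]["end"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    rpath = out / "report.json"
    rpath.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    report["artifacts"]["report"] = str(rpath)
    return report
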