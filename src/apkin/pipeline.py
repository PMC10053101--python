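"""Declarative end-to-end pipeline.

A pipeline config is a TOML file with a seed, an output directory, the
significance/trend thresholds and an ordered list of ``[[step]]`` tables.
Each step names a kind (simulate, fit_mm, fit_sigmoid, fit_thermal,
thermostability, partition, inhibition) with explicit input/output paths —
no implicit defaults.  Steps run in declared order; a failing step stops the
run with prior outputs intact.  Re-running with identical inputs and seed
produces an identical manifest (every stage output is hashed).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import kinetic_models as km
from . import partition as pt
from . import synthetic_data as sd
from . import thermostability as th
from .core_io import (
    AnalysisResult,
    ApkinError,
    SchemaError,
    read_assay_table,
    result_to_dict,
    write_assay_table,
    write_result,
)

STEP_KINDS = (
    "simulate", "fit_mm", "fit_sigmoid", "fit_thermal",
    "thermostability", "partition", "inhibition",
)


class PipelineError(ApkinError):
    def __init__(self, step_name: str, cause: Exception):
        super().__init__(f"step {step_name!r} failed: {cause}")
        self.step_name = step_name
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    steps: tuple[dict, ...]
    out_dir: Path
    seed: int = 0
    significance: float = 0.05
    trend: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.significance < 1.0 and 0.0 < self.trend < 1.0):
            raise SchemaError("thresholds must lie in (0, 1)")
        names = [s.get("name") for s in self.steps]
        if len(names) != len(set(names)) or any(n is None for n in names):
            raise SchemaError("every step needs a unique 'name'")
        for s in self.steps:
            if s.get("kind") not in STEP_KINDS:
                raise SchemaError(
                    f"step {s.get('name')!r}: unknown kind {s.get('kind')!r}"
                )


def load_config(path) -> PipelineConfig:
    raw = tomllib.loads(Path(path).read_text())
    try:
        return PipelineConfig(
            steps=tuple(raw["step"]),
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            significance=float(raw.get("significance", 0.05)),
            trend=float(raw.get("trend", 0.10)),
        )
    except KeyError as err:
        raise SchemaError(f"config missing required key: {err}") from err


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_fit(name: str, model: str, n: int, converged: bool, r2, seed) -> str:
    return (f"fit name={name} model={model} n={n} converged={converged} "
            f"r2={r2} seed={seed}")


def _run_simulate(step, cfg):
    spec = sd.preset(step["preset"], seed=cfg.seed,
                     noise_sd=step.get("noise_sd"),
                     replicates=step.get("replicates"))
    if spec.model == "michaelis_menten":
        data = sd.gen_kinetic(spec)
    elif spec.model == "sigmoid_4pl":
        data = sd.gen_dose_response(spec)
    else:
        data = sd.gen_thermal(spec)
    out = cfg.out_dir / step["out"]
    write_assay_table(data, out)
    return AnalysisResult(
        stage="simulate",
        parameters={k: (v, None) for k, v in spec.parameters.items()},
        diagnostics={"model": spec.model, "noise_sd": spec.noise_sd,
                     "replicates": spec.replicates,
                     "n": len(spec.grid) * spec.replicates},
        provenance={"preset": step["preset"], "seed": cfg.seed},
    ), out


def _run_fit_mm(step, cfg):
    data = read_assay_table(cfg.out_dir / step["input"], "kinetic",
                            substrate_unit=step.get("unit", "uM"))
    on_means = bool(step.get("on_means", False))
    params = km.fit_michaelis_menten(data, on_means=on_means)
    res = km.mm_result(params, data, seed=cfg.seed, on_means=on_means)
    return res, None


def _run_fit_sigmoid(step, cfg):
    data = read_assay_table(cfg.out_dir / step["input"], "dose_response")
    p = km.fit_sigmoid_dose_response(data)
    res = AnalysisResult(
        stage="fit_sigmoid_dose_response",
        parameters={"Bo": (p.Bo, p.se_Bo), "To": (p.To, p.se_To),
                    "ED50": (p.ED50, p.se_ED50),
                    "hill_slope": (p.hill_slope, p.se_hill)},
        diagnostics={"r_squared": p.r_squared, "n": p.n,
                     "ed50_in_range": p.ed50_in_range},
        provenance={"seed": cfg.seed},
    )
    return res, None


def _run_fit_thermal(step, cfg):
    data = read_assay_table(cfg.out_dir / step["input"], "thermal")
    model = step.get("model", "quad")
    if model == "quad":
        p = km.fit_quadratic(data)
        params = {"c0": (p.c0, p.se_c0), "c1": (p.c1, p.se_c1),
                  "c2": (p.c2, p.se_c2)}
    elif model == "exp":
        p = km.fit_exponential(data)
        params = {"J0": (p.J0, p.se_J0), "b": (p.b, p.se_b)}
    else:
        raise SchemaError(f"fit_thermal model must be 'quad' or 'exp', got {model!r}")
    res = AnalysisResult(
        stage=f"fit_thermal_{model}", parameters=params,
        diagnostics={"r_squared": p.r_squared, "n": p.n},
        provenance={"seed": cfg.seed},
    )
    return res, None


def _run_thermostability(step, cfg):
    data = read_assay_table(cfg.out_dir / step["input"], "thermal")
    if "control_activity" in step:
        i_c = float(step["control_activity"])
    else:
        # control group = measurements at the lowest (room) temperature
        ctrl = data.control_temperature
        i_c = float(data.j[data.t == ctrl].mean())
    est = th.estimate_thermal_params(data, i_c)
    return th.thermostability_result(est, data, seed=cfg.seed), None


def _run_partition(step, cfg):
    total = read_assay_table(cfg.out_dir / step["total"], "kinetic",
                             substrate_unit=step.get("unit", "uM"))
    background = read_assay_table(cfg.out_dir / step["background"], "kinetic",
                                  substrate_unit=step.get("unit", "uM"))
    method = step.get("method", "pointwise")
    fit_total = km.fit_michaelis_menten(total)
    fit_bg = km.fit_michaelis_menten(background)
    if method == "params":
        part = pt.partition_parameters(fit_total, fit_bg)
        params = {"Vmax_specific": (part.Vmax, part.se),
                  "Vmax_total": (fit_total.Vmax, fit_total.se_Vmax),
                  "Vmax_background": (fit_bg.Vmax, fit_bg.se_Vmax)}
        diag = {"method": "parameter_difference"}
    elif method == "pointwise":
        diff = pt.partition_pointwise(total, background)
        fit_spec = km.fit_michaelis_menten(diff)
        out = cfg.out_dir / step["out_diff"]
        write_assay_table(diff, out)
        params = {"Km_specific": (fit_spec.Km, fit_spec.se_Km),
                  "Vmax_specific": (fit_spec.Vmax, fit_spec.se_Vmax)}
        diag = {"method": "pointwise", "r_squared": fit_spec.r_squared,
                "diff_table": str(out.name)}
    else:
        raise SchemaError(f"partition method must be 'pointwise' or 'params', got {method!r}")
    res = AnalysisResult(stage="partition", parameters=params,
                         diagnostics=diag, provenance={"seed": cfg.seed})
    return res, None


def _run_inhibition(step, cfg):
    table = read_assay_table(cfg.out_dir / step["input"], "inhibition")
    norm = pt.normalize_to_baseline(table)
    label = pt.classify_isoform_dominance(
        norm, threshold=float(step.get("threshold", pt.DOMINANCE_THRESHOLD)))
    params = {
        f"{r.inhibitor}@{r.conc_mM}mM_inhibited_pct": (r.inhibited_pct, None)
        for r in norm.itertuples()
    }
    res = AnalysisResult(
        stage="inhibition", parameters=params,
        diagnostics={"dominance": label.value,
                     "baseline_mean": norm.attrs["baseline_mean"]},
        provenance={"seed": cfg.seed},
    )
    return res, None


_RUNNERS = {
    "simulate": _run_simulate,
    "fit_mm": _run_fit_mm,
    "fit_sigmoid": _run_fit_sigmoid,
    "fit_thermal": _run_fit_thermal,
    "thermostability": _run_thermostability,
    "partition": _run_partition,
    "inhibition": _run_inhibition,
}


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Execute the configured stages in order; return the manifest.

    The manifest records, per stage, the serialized result, its file path and
    its SHA-256, plus the thresholds and seed, and is itself written to
    ``manifest.json`` in the output directory.
    """
    log = log or (lambda msg: None)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "significance": config.significance,
        "trend": config.trend,
        "stages": {},
    }
    for step in config.steps:
        name = step["name"]
        try:
            result, extra_out = _RUNNERS[step["kind"]](step, config)
        except Exception as err:
            # persist what we have before stopping at the failing stage
            (config.out_dir / "manifest.json").write_text(
                json.dumps(manifest, sort_keys=True, indent=1) + "\n")
            raise PipelineError(name, err) from err
        res_path = config.out_dir / f"{name}.result.json"
        write_result(result, res_path)
        diag = result.diagnostics
        log(_log_fit(name, result.stage, diag.get("n", 0),
                     diag.get("converged", True), diag.get("r_squared"),
                     config.seed))
        entry = {
            "stage": result.stage,
            "result": result_to_dict(result),
            "result_path": res_path.name,
            "sha256": _sha256(res_path),
        }
        if extra_out is not None:
            entry["output"] = Path(extra_out).name
            entry["output_sha256"] = _sha256(Path(extra_out))
        manifest["stages"][name] = entry
    payload = json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    (config.out_dir / "manifest.json").write_text(payload)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    return manifest
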