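"""YAML (de)serialization of the package's configuration objects.

Every structured input — population PK parameters, GI physiology,
dissolution scenarios, release/dissolution parameters and motility
scenarios — round-trips through plain mappings so that shipped default
files and user-edited configs are interchangeable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .ivivp import GIConfig, MotilityScenario
from .physiocell import DissolutionScenario, FlowProgram, ReleaseDissolutionParams, StressEvent
from .pkcore import AbsorptionParams, PopPKParams

__all__ = [
    "poppk_to_dict", "poppk_from_dict",
    "gi_to_dict", "gi_from_dict",
    "scenario_to_dict", "scenario_from_dict",
    "release_to_dict", "release_from_dict",
    "motility_to_dict", "motility_from_dict",
    "dump_yaml", "load_yaml",
]


def dump_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def poppk_to_dict(p: PopPKParams) -> dict[str, Any]:
    d: dict[str, Any] = {
        "cl_f": p.cl_f, "v1_f": p.v1_f, "q_f": p.q_f, "v2_f": p.v2_f,
        "beta_cl": p.beta_cl, "beta_v1": p.beta_v1,
        "bsv": dict(p.bsv), "sigma_add": p.sigma_add, "sigma_prop": p.sigma_prop,
        "absorption": {
            name: {"t_lag": a.t_lag, "k_a": a.k_a,
                   "bsv_t_lag": a.bsv_t_lag, "bsv_k_a": a.bsv_k_a}
            for name, a in p.absorption.items()
        },
    }
    if p.eta_corr is not None:
        d["eta_corr"] = np.asarray(p.eta_corr).tolist()
    return d


def poppk_from_dict(d: dict[str, Any]) -> PopPKParams:
    absorption = {
        name: AbsorptionParams(**a) for name, a in d.get("absorption", {}).items()
    }
    corr = d.get("eta_corr")
    return PopPKParams(
        cl_f=d["cl_f"], v1_f=d["v1_f"], q_f=d["q_f"], v2_f=d["v2_f"],
        beta_cl=d["beta_cl"], beta_v1=d["beta_v1"], bsv=d["bsv"],
        sigma_add=d["sigma_add"], sigma_prop=d["sigma_prop"],
        absorption=absorption,
        eta_corr=np.asarray(corr, dtype=float) if corr is not None else None,
    )


def gi_to_dict(c: GIConfig) -> dict[str, Any]:
    return {
        "k_ge": c.k_ge, "get_h": c.get_h, "post_get_k_ge": c.post_get_k_ge,
        "kt": list(c.kt), "k_colon": c.k_colon, "radius_cm": c.radius_cm,
        "peff": c.peff, "water_ml": c.water_ml, "v_basal_ml": c.v_basal_ml,
        "volume_coeffs": {k: list(v) for k, v in c.volume_coeffs.items()},
        "volume_plateau_h": c.volume_plateau_h, "kge_range": list(c.kge_range),
    }


def gi_from_dict(d: dict[str, Any]) -> GIConfig:
    return GIConfig(
        k_ge=d["k_ge"], get_h=d["get_h"], post_get_k_ge=d["post_get_k_ge"],
        kt=tuple(d["kt"]), k_colon=d["k_colon"], radius_cm=d["radius_cm"],
        peff=d["peff"], water_ml=d["water_ml"], v_basal_ml=d["v_basal_ml"],
        volume_coeffs={k: tuple(v) for k, v in d["volume_coeffs"].items()},
        volume_plateau_h=d["volume_plateau_h"], kge_range=tuple(d["kge_range"]),
    )


def scenario_to_dict(s: DissolutionScenario) -> dict[str, Any]:
    return {
        "group": s.group, "get_min": s.get_min,
        "stress_events": [
            {"time": e.time, "pressure": e.pressure, "kind": e.kind} for e in s.stress_events
        ],
        "flow": {"breakpoints": [list(b) for b in s.flow.breakpoints],
                 "pulses": [list(p) for p in s.flow.pulses]},
        "v_cell": s.v_cell, "v_reservoir": s.v_reservoir,
        "sampling_interval": s.sampling_interval, "duration_min": s.duration_min,
    }


def scenario_from_dict(d: dict[str, Any]) -> DissolutionScenario:
    flow = FlowProgram(
        breakpoints=tuple(tuple(b) for b in d["flow"]["breakpoints"]),
        pulses=tuple(tuple(p) for p in d["flow"]["pulses"]),
    )
    events = tuple(StressEvent(**e) for e in d.get("stress_events", []))
    return DissolutionScenario(
        group=d["group"], get_min=d["get_min"], stress_events=events, flow=flow,
        v_cell=d["v_cell"], v_reservoir=d["v_reservoir"],
        sampling_interval=d["sampling_interval"], duration_min=d.get("duration_min"),
    )


def release_to_dict(p: ReleaseDissolutionParams) -> dict[str, Any]:
    return {
        "kind": p.kind, "t_lag": p.t_lag,
        "phases": [list(ph) for ph in p.phases],
        "z": p.z, "c_s": p.c_s, "x0": p.x0,
    }


def release_from_dict(d: dict[str, Any]) -> ReleaseDissolutionParams:
    return ReleaseDissolutionParams(
        kind=d["kind"], t_lag=d["t_lag"],
        phases=tuple(tuple(ph) for ph in d["phases"]),
        z=d["z"], c_s=d["c_s"], x0=d["x0"],
    )


def motility_to_dict(s: MotilityScenario) -> dict[str, Any]:
    rule = list(s.kge_rule) if isinstance(s.kge_rule, tuple) else s.kge_rule
    return {"group": s.group, "get_h": s.get_h, "release_group": s.release_group,
            "kge_rule": rule}


def motility_from_dict(d: dict[str, Any]) -> MotilityScenario:
    rule = d["kge_rule"]
    return MotilityScenario(
        group=d["group"], get_h=d["get_h"], release_group=d["release_group"],
        kge_rule=tuple(rule) if isinstance(rule, list) else float(rule),
    )
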