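"""Synthetic data generation: virtual crossover trials with known motility
ground truth, noisy in vitro dissolution fixtures, and default config files.

The generators encode the study conditions: a crossover trial of 118
subjects dosed 100 mg (tablet 2x50 mg, capsule 1x100 mg) sampled at
0.5-24 h, individual parameters drawn log-normally around the published
typical values with the published between-subject variabilities and a
combined additive+proportional residual error; and triplicate in vitro
dissolution curves on a 2-min grid generated from known Weibull/z
parameters under the six motility-group programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import configio, ivivp, physiocell, pkcore, popsim
from .ivivp import GIConfig
from .physiocell import DissolutionScenario, ReleaseDissolutionParams
from .pkcore import CLINICAL_TIMES, PopPKParams

__all__ = [
    "VirtualTrialSpec",
    "default_release_params",
    "generate_virtual_trial",
    "generate_poppk_trial",
    "generate_invitro_fixtures",
    "make_default_configs",
]


def default_release_params() -> dict[int, ReleaseDissolutionParams]:
    """Ground-truth capsule release parameters per dissolution program
    (minute scale, z = 1.08 mL/mg/h, Cs = 27 mg/mL, dose 100 mg).

    Group 2's strong double stress opens the capsule completely and fast;
    group 3's single weak stress starts a partial, slow release with the
    balance flushed at GET (double-Weibull); groups 1 and 4 open slowly and
    spontaneously; groups 5 and 6 share the pooled spontaneous-opening
    profile that completes dissolution well before their late GET.
    """
    g5 = ReleaseDissolutionParams(kind="weibull", t_lag=10.0, phases=((12.0, 1.8, 1.0),))
    return {
        1: ReleaseDissolutionParams(kind="weibull", t_lag=10.0, phases=((30.0, 1.2, 1.0),)),
        2: ReleaseDissolutionParams(kind="weibull", t_lag=10.0, phases=((1.5, 2.0, 1.0),)),
        3: ReleaseDissolutionParams(
            kind="double_weibull", t_lag=5.0,
            phases=((8.0, 1.6, 0.45), (90.0, 1.2, 0.0)),
        ),
        4: ReleaseDissolutionParams(kind="weibull", t_lag=10.0, phases=((40.0, 1.2, 1.0),)),
        5: g5,
        6: g5,
    }


@dataclass(frozen=True)
class VirtualTrialSpec:
    """Conditions of the simulated crossover trial."""

    n: int = 118
    times: np.ndarray = field(default_factory=lambda: CLINICAL_TIMES.copy())
    dose: float = 100.0
    formulations: tuple[str, ...] = ("tablet", "capsule")
    prevalences: np.ndarray = field(default_factory=lambda: popsim.GROUP_PREVALENCES.copy())
    residual_error: bool = True
    between_subject: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalences, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("prevalences must sum to 1")
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "prevalences", p)


def _zero_bsv(pop: PopPKParams) -> PopPKParams:
    absn = {
        name: replace(a, bsv_t_lag=0.0, bsv_k_a=0.0) for name, a in pop.absorption.items()
    }
    return replace(pop, bsv={k: 0.0 for k in pop.bsv}, absorption=absn)


def generate_virtual_trial(
    spec: VirtualTrialSpec,
    pop: PopPKParams | None = None,
    cfg: GIConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a crossover trial through the mechanistic GI model.

    Tablet profiles use immediate release; capsule profiles use the
    subject's motility-group scenario under the final simulation rules.
    Returns (long-format PK table, ground-truth sidecar with group, k_GE
    and realized individual parameters).
    """
    pop = pop or pkcore.default_poppk()
    if not spec.between_subject:
        pop = _zero_bsv(pop)
    cfg = cfg or ivivp.default_gi_config()
    rng = np.random.default_rng(spec.seed)
    scenario_set = popsim.final_scenario_set()
    p_tab = ivivp.tablet_release_params()

    inds = pkcore.sample_individuals(pop, spec.n, rng, formulation="capsule")
    _, labels = popsim.allocate_population(spec.n, spec.prevalences, rng)

    pk_rows, truth_rows = [], []
    for ind, group in zip(inds, labels):
        scen, p_rel = scenario_set[int(group)]
        kge = popsim.assign_kge(int(group), rng, {g: s for g, (s, _) in scenario_set.items()})
        eta_abs = float(ind.eta[1]) if ind.eta is not None else 0.0
        cfg_i = replace(cfg, k_ge=kge, get_h=scen.get_h)
        for formulation in spec.formulations:
            p_form = p_tab if formulation == "tablet" else p_rel
            prof = ivivp.simulate_subject(
                ind, p_form, cfg_i, spec.times, dose=spec.dose, eta_abs=eta_abs,
                grid="clinical", rtol=1e-7, atol=1e-9,
            )
            prof = replace(prof, formulation=formulation)
            if spec.residual_error:
                prof = pkcore.add_residual_error(prof, pop, rng)
            for t, c in zip(prof.times, prof.concentrations):
                pk_rows.append(
                    {"subject": ind.subject, "time_h": t, "conc_ng_ml": c,
                     "formulation": formulation, "dose_mg": spec.dose}
                )
        truth_rows.append(
            {"subject": ind.subject, "group": int(group), "kge": kge,
             "weight": ind.weight, "t_lag": ind.t_lag, "k_a": ind.k_a,
             "cl_f": ind.cl_f, "v1_f": ind.v1_f, "q_f": ind.q_f, "v2_f": ind.v2_f,
             "eta_abs": eta_abs}
        )
    return pd.DataFrame(pk_rows), pd.DataFrame(truth_rows)


def generate_poppk_trial(
    n: int = 118,
    formulation: str = "tablet",
    pop: PopPKParams | None = None,
    times: np.ndarray = CLINICAL_TIMES,
    dose: float = 100.0,
    residual_error: bool = True,
    rng: np.random.Generator | int = 0,
) -> tuple[list[pkcore.PlasmaProfile], list[pkcore.IndividualPKParams]]:
    """Simulate profiles directly from the published population PK model
    (empirical first-order absorption, no GI mechanics).  This is the input
    generator for two-stage fitting recovery studies."""
    pop = pop or pkcore.default_poppk()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    inds = pkcore.sample_individuals(pop, n, rng, formulation=formulation)
    profiles = []
    for ind in inds:
        prof = pkcore.simulate_plasma(ind, dose, times, grid="clinical",
                                      formulation=formulation, method="analytic")
        if residual_error:
            prof = pkcore.add_residual_error(prof, pop, rng)
        profiles.append(prof)
    return profiles, inds


def generate_invitro_fixtures(
    scenarios: Mapping[int, DissolutionScenario] | None = None,
    true_params: Mapping[int, ReleaseDissolutionParams] | None = None,
    noise_sd: float = 2.0,
    replicates: int = 3,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Noisy dissolution curves (percent of dose) on the 2-min grid.

    Additive Gaussian noise (default SD 2% of dose) is applied per sample
    and clipped to [0, 100]%.  Columns: group, time_min, replicate,
    dissolved_pct.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    scenarios = scenarios or physiocell.default_scenarios()
    true_params = true_params or default_release_params()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for group, scen in scenarios.items():
        p = true_params[group]
        clean = physiocell.simulate_invitro(scen, p)
        pct = clean.dissolved / p.x0 * 100.0
        for rep in range(replicates):
            noisy = np.clip(pct + rng.standard_normal(pct.shape) * noise_sd, 0.0, 100.0)
            for t, d in zip(clean.times, noisy):
                rows.append({"group": group, "time_min": t, "replicate": rep,
                             "dissolved_pct": d})
    return pd.DataFrame(rows)


def make_default_configs(out_dir: str | Path) -> list[Path]:
    """Write the shipped default configuration files.

    Emits the population PK parameter file, the six in vitro dissolution
    scenario files, the ground-truth release parameter file, the final
    in vivo motility rules and the default GI physiology config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, payload: dict) -> None:
        path = out / name
        configio.dump_yaml(payload, path)
        written.append(path)

    emit("population_pk.yaml", configio.poppk_to_dict(pkcore.default_poppk()))
    emit("gi_default.yaml", configio.gi_to_dict(ivivp.default_gi_config()))
    for g, scen in physiocell.default_scenarios().items():
        emit(f"scenario_group{g}.yaml", configio.scenario_to_dict(scen))
    emit(
        "release_params.yaml",
        {g: configio.release_to_dict(p) for g, p in default_release_params().items()},
    )
    for g, p in default_release_params().items():
        emit(f"release_params_group{g}.yaml", configio.release_to_dict(p))
    emit(
        "final_motility_rules.yaml",
        {g: configio.motility_to_dict(s) for g, s in ivivp.final_scenarios().items()},
    )
    return written
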