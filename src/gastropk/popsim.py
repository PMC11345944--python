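"""Prevalence-weighted virtual-population simulation.

A virtual trial allocates n subjects to the six gastric-motility groups by
largest-remainder apportionment of the published prevalences, assigns each
subject a gastric-emptying rate according to the final simulation rules
(k_GE = 3 1/h for group 2, 2 1/h for the lazy-stomach groups 5/6, a uniform
3-14 1/h draw otherwise), simulates every subject through the mechanistic
absorption-transit model, and summarizes mean +/- SD concentration curves
per group and overall.  The whole procedure is repeated over independent
randomized draws (default 10), resampling the individual PK parameters in
each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ivivp, pkcore
from .ivivp import GIConfig, MotilityScenario
from .physiocell import ReleaseDissolutionParams
from .pkcore import CLINICAL_TIMES, IndividualPKParams, PopPKParams

__all__ = [
    "GROUP_PREVALENCES",
    "PopulationDraw",
    "allocate_population",
    "assign_kge",
    "run_virtual_trial",
    "compare_summaries",
    "final_scenario_set",
]

#: published group prevalences (fractions, groups 1..6)
GROUP_PREVALENCES = np.array([0.27, 0.22, 0.18, 0.13, 0.13, 0.07])


@dataclass
class PopulationDraw:
    """One randomized draw of a prevalence-weighted virtual population."""

    draw_id: int
    subjects: pd.DataFrame  # subject, group, kge, cl_f, v1_f, eta_abs, t_max, c_max, auc_last
    times: np.ndarray
    summaries: dict[str, tuple[np.ndarray, np.ndarray]]  # "overall" or "group{g}" -> (mean, sd)
    profiles: np.ndarray = field(repr=False, default=None)  # (n, n_times)
    errors: list[str] = field(default_factory=list)


def allocate_population(
    n: int,
    prevalences: Sequence[float] | np.ndarray = GROUP_PREVALENCES,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder apportionment of n subjects to groups.

    Returns (counts per group, shuffled per-subject group labels).  Counts
    are deterministic; only the label order is randomized.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    p = np.asarray(prevalences, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("prevalences must be >= 0 and sum to 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    quota = n * p
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(1, len(p) + 1), counts)
    rng.shuffle(labels)
    return counts, labels


def assign_kge(group: int, rng: np.random.Generator | int = 0,
               scenarios: Mapping[int, MotilityScenario] | None = None) -> float:
    """Draw a gastric-emptying rate for a subject of the given group."""
    if group not in range(1, 7):
        raise ValueError("group must be 1..6")
    scen = (scenarios or ivivp.final_scenarios())[group]
    rule = scen.kge_rule
    if isinstance(rule, tuple):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return float(rng.uniform(*rule))
    return float(rule)


def final_scenario_set() -> dict[int, tuple[MotilityScenario, ReleaseDissolutionParams]]:
    """Final-rule scenarios paired with their release parameters."""
    from .synthdata import default_release_params

    release = default_release_params()
    return {g: (scen, release[scen.release_group]) for g, scen in ivivp.final_scenarios().items()}


def run_virtual_trial(
    n: int = 100,
    n_draws: int = 10,
    cfg: GIConfig | None = None,
    scenario_set: Mapping[int, tuple[MotilityScenario, ReleaseDissolutionParams]] | None = None,
    rng: np.random.Generator | int = 0,
    pop: PopPKParams | None = None,
    prevalences: Sequence[float] = GROUP_PREVALENCES,
    times: np.ndarray = CLINICAL_TIMES,
    dose: float = 100.0,
) -> list[PopulationDraw]:
    """Run repeated prevalence-weighted capsule simulations.

    Individual PK parameters are resampled in every draw.  Per-subject
    simulation errors are collected on the draw rather than aborting it.
    """
    cfg = cfg or ivivp.default_gi_config()
    scenario_set = scenario_set or final_scenario_set()
    pop = pop or pkcore.default_poppk()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = np.asarray(times, dtype=float)

    draws: list[PopulationDraw] = []
    for d in range(n_draws):
        inds = pkcore.sample_individuals(pop, n, rng, formulation="capsule")
        _, labels = allocate_population(n, prevalences, rng)
        rows, profiles, errors = [], np.zeros((n, times.size)), []
        for i, (ind, group) in enumerate(zip(inds, labels)):
            scen, p_rel = scenario_set[int(group)]
            kge = assign_kge(int(group), rng, {g: s for g, (s, _) in scenario_set.items()})
            eta_abs = float(ind.eta[1]) if ind.eta is not None else 0.0
            cfg_i = replace(cfg, k_ge=kge, get_h=scen.get_h)
            try:
                prof = ivivp.simulate_subject(
                    ind, p_rel, cfg_i, times, dose=dose, eta_abs=eta_abs,
                    grid="clinical", rtol=1e-7, atol=1e-9,
                )
            except Exception as exc:
                errors.append(f"draw {d} subject {ind.subject}: {exc}")
                continue
            res = pkcore.nca(prof)
            profiles[i] = prof.concentrations
            rows.append(
                {
                    "subject": ind.subject, "group": int(group), "kge": kge,
                    "cl_f": ind.cl_f, "v1_f": ind.v1_f, "eta_abs": eta_abs,
                    "t_max": res.t_max, "c_max": res.c_max, "auc_last": res.auc_last,
                }
            )
        df = pd.DataFrame(rows)
        summaries: dict[str, tuple[np.ndarray, np.ndarray]] = {
            "overall": (profiles.mean(axis=0), profiles.std(axis=0, ddof=0))
        }
        for g in range(1, 7):
            sel = profiles[labels == g]
            if sel.size:
                summaries[f"group{g}"] = (sel.mean(axis=0), sel.std(axis=0, ddof=0))
        draws.append(
            PopulationDraw(draw_id=d, subjects=df, times=times, summaries=summaries,
                           profiles=profiles, errors=errors)
        )
    return draws


def compare_summaries(
    sim_times: np.ndarray,
    sim_mean: np.ndarray,
    obs_times: np.ndarray,
    obs_mean: np.ndarray,
) -> dict[str, float]:
    """Prediction-error metrics between simulated and observed mean curves.

    Returns per-curve average fold error (AFE), Cmax %PE and Tmax %PE.
    Grids must match exactly.
    """
    sim_times = np.asarray(sim_times, dtype=float)
    obs_times = np.asarray(obs_times, dtype=float)
    if sim_times.shape != obs_times.shape or not np.allclose(sim_times, obs_times):
        raise ValueError("time grids do not match")
    sim = np.asarray(sim_mean, dtype=float)
    obs = np.asarray(obs_mean, dtype=float)
    pos = (sim > 0) & (obs > 0)
    afe = float(10 ** np.mean(np.log10(sim[pos] / obs[pos]))) if pos.any() else np.nan
    cmax_pe = float((sim.max() - obs.max()) / obs.max() * 100.0)
    tmax_sim = float(sim_times[np.argmax(sim)])
    tmax_obs = float(obs_times[np.argmax(obs)])
    tmax_pe = float((tmax_sim - tmax_obs) / tmax_obs * 100.0)
    pe = np.full(sim.shape, np.nan)
    pe[pos] = (sim[pos] - obs[pos]) / obs[pos] * 100.0
    return {"afe": afe, "cmax_pe": cmax_pe, "tmax_pe": tmax_pe,
            "mean_abs_pe": float(np.nanmean(np.abs(pe)))}
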