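"""Digital twin of the closed-loop flow-through dissolution apparatus.

The apparatus circulates 500 mL of medium between a 34 mL main dissolution
cell (holding the dosage form, subject to programmable pressure waves) and
a 466 mL stirred reservoir.  A peristaltic pump drives a programmed flow,
starting at 50 mL/min and ramping down to 8 mL/min by 14 min; a simulated
complete-gastric-emptying (GET) event flushes the main cell into the
reservoir and refills it at 110 mL/min for 18 s.  Capsule opening is
described empirically by a (double-)Weibull cumulative release with a lag,
particle dissolution by the modified Noyes-Whitney (z-factor) model, and
dissolved-drug exchange between the two vessels by flow-derived first-order
transfer constants kT1a = Q(t)/V_cell and kT2a = Q(t)/V_res.

Mechanical stress events are not simulated mechanistically: their effect on
capsule opening is carried entirely by the fitted release parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "FlowProgram",
    "StressEvent",
    "DissolutionScenario",
    "ReleaseDissolutionParams",
    "InVitroProfile",
    "default_flow_program",
    "default_scenarios",
    "flow_rate",
    "release_fraction",
    "release_rate",
    "nw_rate",
    "simulate_invitro",
    "fit_release",
    "fit_z",
]

V_STRESSCELL_ML = 34.0
V_RESERVOIR_ML = 466.0
GET_REFILL_RATE = 110.0  # mL/min
GET_REFILL_DURATION_S = 18.0


@dataclass(frozen=True)
class FlowProgram:
    """Piecewise-linear pump program with override refill pulses.

    ``breakpoints`` maps time (min) to flow (mL/min); between breakpoints
    the flow is linearly interpolated and held flat beyond the ends.
    ``pulses`` are (start_min, rate_mL_min, duration_s) windows during
    which the pulse rate overrides the base program.
    """

    breakpoints: tuple[tuple[float, float], ...] = ((0.0, 50.0), (14.0, 8.0))
    pulses: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        times = [t for t, _ in self.breakpoints]
        if any(np.diff(times) <= 0):
            raise ValueError("breakpoint times must be increasing")
        if any(q < 0 for _, q in self.breakpoints) or any(p[1] < 0 for p in self.pulses):
            raise ValueError("flows must be >= 0")


@dataclass(frozen=True)
class StressEvent:
    """A programmed pressure wave on the dosage form."""

    time: float  # min
    pressure: float  # mbar
    kind: str = "phaseII"  # "phaseII" | "GET"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class DissolutionScenario:
    """One biopredictive dissolution program (motility group 1-6)."""

    group: int
    get_min: float
    stress_events: tuple[StressEvent, ...] = ()
    flow: FlowProgram = field(default_factory=FlowProgram)
    v_cell: float = V_STRESSCELL_ML
    v_reservoir: float = V_RESERVOIR_ML
    sampling_interval: float = 2.0  # min
    duration_min: float | None = None  # default: GET + 30 min

    def __post_init__(self) -> None:
        if not np.isclose(self.v_cell + self.v_reservoir, 500.0):
            raise ValueError("cell and reservoir volumes must total 500 mL")
        if self.get_min <= 0:
            raise ValueError("GET must be > 0")

    @property
    def total_minutes(self) -> float:
        return self.duration_min if self.duration_min is not None else self.get_min + 30.0

    def with_get_pulse(self) -> FlowProgram:
        """Flow program including the post-GET refill pulse."""
        return replace(
            self.flow,
            pulses=self.flow.pulses + ((self.get_min, GET_REFILL_RATE, GET_REFILL_DURATION_S),),
        )


def default_flow_program() -> FlowProgram:
    return FlowProgram()


def default_scenarios() -> dict[int, DissolutionScenario]:
    """The six dissolution programs: GET 15/30/30/30/60/90 min, stresses as
    programmed (two 300 mbar waves at 10 and 13 min for group 2, one
    200 mbar wave at 5 min for group 3, none otherwise)."""
    return {
        1: DissolutionScenario(group=1, get_min=15.0),
        2: DissolutionScenario(
            group=2,
            get_min=30.0,
            stress_events=(StressEvent(10.0, 300.0), StressEvent(13.0, 300.0)),
        ),
        3: DissolutionScenario(group=3, get_min=30.0, stress_events=(StressEvent(5.0, 200.0),)),
        4: DissolutionScenario(group=4, get_min=30.0),
        5: DissolutionScenario(group=5, get_min=60.0),
        6: DissolutionScenario(group=6, get_min=90.0),
    }


@dataclass(frozen=True)
class ReleaseDissolutionParams:
    """Capsule-release (Weibull) and particle-dissolution (z-factor) parameters.

    ``phases`` holds (tau_min, shape_b, weight) tuples; a single phase is the
    classical Weibull (weight ignored, treated as 1), two phases a
    double-Weibull whose weights are ``w`` and ``1-w`` (w taken from the
    first phase).  ``z`` is the lumped dissolution coefficient in mL/mg/h,
    ``c_s`` the solubility (mg/mL) and ``x0`` the dose strength (mg).
    """

    kind: str  # "weibull" | "double_weibull"
    t_lag: float  # min
    phases: tuple[tuple[float, float, float], ...]
    z: float = 1.08  # mL/mg/h
    c_s: float = 27.0  # mg/mL
    x0: float = 100.0  # mg

    def __post_init__(self) -> None:
        if self.kind not in ("weibull", "double_weibull"):
            raise ValueError("kind must be 'weibull' or 'double_weibull'")
        n_expected = 1 if self.kind == "weibull" else 2
        if len(self.phases) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} phase(s)")
        for tau, b, w in self.phases:
            if tau <= 0 or b <= 0:
                raise ValueError("Weibull scale and shape must be > 0")
            if not 0.0 <= w <= 1.0:
                raise ValueError("phase weight must be in [0, 1]")
        if self.t_lag < 0 or self.z <= 0 or self.c_s <= 0 or self.x0 <= 0:
            raise ValueError("t_lag >= 0 and z, c_s, x0 > 0 required")

    def weights(self) -> np.ndarray:
        if self.kind == "weibull":
            return np.array([1.0])
        w = self.phases[0][2]
        return np.array([w, 1.0 - w])


@dataclass(frozen=True)
class InVitroProfile:
    """Dissolved-drug time series on the 2-min sampling grid."""

    times: np.ndarray  # min
    dissolved: np.ndarray  # mg (or % of x0 if percent=True)
    replicate: int = 0
    percent: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.dissolved, dtype=float)
        if t.shape != d.shape:
            raise ValueError("times and dissolved must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dissolved", d)


def flow_rate(t: float | np.ndarray, program: FlowProgram) -> float | np.ndarray:
    """Instantaneous pump flow (mL/min) at time ``t`` (min)."""
    bp_t = np.array([p[0] for p in program.breakpoints])
    bp_q = np.array([p[1] for p in program.breakpoints])
    q = np.interp(t, bp_t, bp_q)
    for start, rate, dur_s in program.pulses:
        in_window = (np.asarray(t) >= start) & (np.asarray(t) < start + dur_s / 60.0)
        q = np.where(in_window, rate, q)
    return float(q) if np.isscalar(t) else q


def release_fraction(t: float | np.ndarray, p: ReleaseDissolutionParams) -> float | np.ndarray:
    """Cumulative released fraction of the dose at time ``t`` (min).

    0 for t <= t_lag; 1 - exp(-((t - t_lag)/tau)^b) per phase, mixed by the
    phase weights for the double-Weibull.
    """
    tp = np.clip(np.asarray(t, dtype=float) - p.t_lag, 0.0, None)
    out = np.zeros_like(tp)
    for (tau, b, _), w in zip(p.phases, p.weights()):
        out = out + w * (1.0 - np.exp(-((tp / tau) ** b)))
    return float(out) if np.isscalar(t) else out


def release_rate(t: float, p: ReleaseDissolutionParams) -> float:
    """d(release_fraction)/dt (1/min): the Weibull mixture density."""
    tp = t - p.t_lag
    if tp <= 0:
        return 0.0
    rate = 0.0
    for (tau, b, _), w in zip(p.phases, p.weights()):
        u = tp / tau
        rate += w * (b / tau) * u ** (b - 1.0) * np.exp(-(u**b))
    return rate


def nw_rate(x_s: float, x_d: float, v: float, p: ReleaseDissolutionParams) -> float:
    """Modified Noyes-Whitney (z-factor) dissolution rate in mg/h.

    dXd/dt = z * X0^(1/3) * Xs^(2/3) * (Cs - Xd/V), clipped at 0 when the
    local concentration reaches solubility (no precipitation is modelled).
    """
    if v <= 0:
        raise ValueError("volume must be > 0")
    if x_s <= 0:
        return 0.0
    rate = p.z * p.x0 ** (1.0 / 3.0) * x_s ** (2.0 / 3.0) * (p.c_s - x_d / v)
    return max(rate, 0.0)


# state indices for the apparatus ODE
_ENC, _SOL_C, _DIS_C, _SOL_R, _DIS_R = range(5)


def _invitro_rhs(t, y, scenario, p, program, pre_get):
    q = flow_rate(t, program)
    kt1a = q / scenario.v_cell  # 1/min, cell -> reservoir
    kt2a = q / scenario.v_reservoir  # 1/min, reservoir -> cell
    # capsule release stops at GET (remaining encapsulated drug is freed there)
    rel = p.x0 * release_rate(t, p) if pre_get else 0.0  # mg/min
    nw_c = nw_rate(y[_SOL_C], y[_DIS_C], scenario.v_cell, p) / 60.0  # mg/min
    nw_r = nw_rate(y[_SOL_R], y[_DIS_R], scenario.v_reservoir, p) / 60.0
    return [
        -rel,
        rel - nw_c,
        nw_c - kt1a * y[_DIS_C] + kt2a * y[_DIS_R],
        -nw_r,
        nw_r + kt1a * y[_DIS_C] - kt2a * y[_DIS_R],
    ]


def simulate_invitro(
    scenario: DissolutionScenario,
    p: ReleaseDissolutionParams,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> InVitroProfile:
    """Simulate the apparatus and sample total dissolved drug every 2 min.

    Free solid stays in the main cell until GET (the sampling cannulas pass
    dissolved drug only); at GET the remaining encapsulated and free solid
    is flushed to the reservoir where dissolution continues.  Raises if the
    mass balance drifts by more than 1e-6 * x0.
    """
    program = scenario.with_get_pulse()
    t_end = scenario.total_minutes
    grid = np.arange(0.0, t_end + 1e-9, scenario.sampling_interval)

    # integration must restart at every flow/release discontinuity; the
    # Weibull density is singular at t_lag for shape b < 1, so the first
    # eps after t_lag is bridged analytically (exact for release, O(eps)
    # for dissolution)
    eps = 1e-3  # min
    t_lag_eps = p.t_lag + eps
    breaks = {p.t_lag, t_lag_eps, scenario.get_min, t_end}
    breaks.update(bt for bt, _ in program.breakpoints)
    for start, _, dur_s in program.pulses:
        breaks.update((start, start + dur_s / 60.0))
    breaks = sorted(b for b in breaks if 0.0 < b <= t_end)

    y = np.array([p.x0, 0.0, 0.0, 0.0, 0.0])
    t0 = 0.0
    times_out, y_out = [0.0], [y.copy()]
    for tb in breaks:
        if (
            t0 < scenario.get_min - 1e-12
            and p.t_lag - 1e-15 <= t0 < t_lag_eps
            and tb <= t_lag_eps + 1e-12
        ):
            moved = min(p.x0 * float(release_fraction(tb, p)), y[_ENC])
            y[_ENC] -= moved
            y[_SOL_C] += moved
            t0 = tb
            continue
        seg_grid = grid[(grid > t0 + 1e-12) & (grid < tb - 1e-12)]
        t_eval = np.append(seg_grid, tb)
        sol = solve_ivp(
            _invitro_rhs, (t0, tb), y, t_eval=t_eval,
            args=(scenario, p, program, t0 < scenario.get_min - 1e-12),
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"dissolution integration failed: {sol.message}")
        y = sol.y[:, -1].copy()
        for i, tt in enumerate(sol.t):
            if np.any(np.isclose(grid, tt)):
                times_out.append(tt)
                y_out.append(sol.y[:, i].copy())
        t0 = tb
        if np.isclose(tb, scenario.get_min):
            # GET: remaining encapsulated drug opens and, with the second
            # pressure wave, all solid in the cell is flushed to the reservoir.
            # Total dissolved drug (the sampled quantity) is continuous here.
            y[_SOL_R] += y[_ENC] + y[_SOL_C]
            y[_ENC] = 0.0
            y[_SOL_C] = 0.0

    times_out = np.asarray(times_out)
    y_out = np.asarray(y_out)
    total = y_out.sum(axis=1)
    if np.max(np.abs(total - p.x0)) > 1e-6 * p.x0:
        raise RuntimeError("mass balance violated in apparatus simulation")
    dissolved = y_out[:, _DIS_C] + y_out[:, _DIS_R]
    # keep unique sample times (events may duplicate grid points)
    _, idx = np.unique(np.round(times_out, 9), return_index=True)
    return InVitroProfile(times=times_out[idx], dissolved=dissolved[idx], replicate=0)


def _profile_tlag(profile: InVitroProfile, x0: float) -> float:
    """Last sampling time with <= 1% of the dose dissolved."""
    thresh = 0.01 * x0
    below = profile.times[profile.dissolved <= thresh]
    return float(below[-1]) if below.size else 0.0


def fit_release(
    mean_profile: InVitroProfile,
    scenario: DissolutionScenario,
    kind: str = "weibull",
    p_ref: ReleaseDissolutionParams | None = None,
) -> ReleaseDissolutionParams:
    """Fit the (double-)Weibull release parameters to a pre-GET mean profile.

    The full apparatus model is refit by least squares over [t_lag, GET)
    with t_lag estimated as the last time with <= 1% dissolved; z, Cs and
    x0 are taken from ``p_ref`` (defaults if omitted).
    """
    ref = p_ref or ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((10.0, 1.0, 1.0),))
    mask = mean_profile.times < scenario.get_min
    t_obs = mean_profile.times[mask]
    d_obs = mean_profile.dissolved[mask]
    if t_obs.size < 4:
        raise ValueError("need >= 4 sampling points before GET to fit release")
    tlag = _profile_tlag(InVitroProfile(t_obs, d_obs), ref.x0)
    fit_mask = t_obs >= tlag
    t_fit, d_fit = t_obs[fit_mask], d_obs[fit_mask]

    def build(theta: np.ndarray) -> ReleaseDissolutionParams:
        if kind == "weibull":
            phases = ((theta[0], theta[1], 1.0),)
        else:
            phases = ((theta[0], theta[1], theta[2]), (theta[3], theta[4], 0.0))
        return ReleaseDissolutionParams(
            kind=kind, t_lag=tlag, phases=phases, z=ref.z, c_s=ref.c_s, x0=ref.x0
        )

    # only the pre-GET window enters the residual: truncate the simulation
    scen_fit = replace(scenario, duration_min=scenario.get_min)

    def resid(theta: np.ndarray) -> np.ndarray:
        sim = simulate_invitro(scen_fit, build(theta), rtol=1e-7, atol=1e-9)
        pred = np.interp(t_fit, sim.times, sim.dissolved)
        return pred - d_fit

    if kind == "weibull":
        theta0 = np.array([10.0, 1.2])
        lo, hi = np.array([0.1, 0.2]), np.array([500.0, 8.0])
    elif kind == "double_weibull":
        theta0 = np.array([8.0, 1.5, 0.5, 60.0, 1.2])
        lo = np.array([0.1, 0.2, 0.0, 1.0, 0.2])
        hi = np.array([100.0, 8.0, 1.0, 1000.0, 8.0])
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    res = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
    return build(res.x)


def fit_z(
    post_event_profile: InVitroProfile,
    scenario: DissolutionScenario,
    p_ref: ReleaseDissolutionParams | None = None,
    n_points: int = 3,
) -> float:
    """Estimate the z dissolution coefficient from the post-GET burst.

    The Noyes-Whitney submodel is fitted to the first ``n_points`` samples
    of the most pronounced GET-related release, with capsule release forced
    complete at GET (all undissolved drug is solid in the reservoir).
    """
    ref = p_ref or ReleaseDissolutionParams(kind="weibull", t_lag=0.0, phases=((10.0, 1.0, 1.0),))
    mask = post_event_profile.times > scenario.get_min
    t_seg = post_event_profile.times[mask][:n_points]
    d_seg = post_event_profile.dissolved[mask][:n_points]
    if t_seg.size < 3:
        raise ValueError("need >= 3 post-GET points to estimate z")
    # total dissolved is continuous at GET but jumps in slope; interpolating
    # across the burst would corrupt the initial condition when GET falls
    # between samples, so take the last pre-GET sample
    pre = post_event_profile.times <= scenario.get_min + 1e-9
    d_at_get = float(post_event_profile.dissolved[pre][-1]) if pre.any() else 0.0
    x_solid0 = ref.x0 - d_at_get

    def dissolved_at(z: float) -> np.ndarray:
        pz = ReleaseDissolutionParams(
            kind="weibull", t_lag=0.0, phases=((1.0, 1.0, 1.0),), z=z, c_s=ref.c_s, x0=ref.x0
        )

        def rhs(t, y):
            rate = nw_rate(y[0], y[1], scenario.v_reservoir, pz) / 60.0
            return [-rate, rate]

        sol = solve_ivp(
            rhs, (scenario.get_min, t_seg[-1]), [x_solid0, d_at_get],
            t_eval=t_seg, method="LSODA", rtol=1e-8, atol=1e-10,
        )
        return sol.y[1]

    res = least_squares(
        lambda th: dissolved_at(th[0]) - d_seg, x0=[1.0],
        bounds=([1e-4], [100.0]), method="trf", xtol=1e-12, ftol=1e-12,
    )
    return float(res.x[0])
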