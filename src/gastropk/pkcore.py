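"""Two-compartment oral population PK: typical values, covariate scaling,
individual sampling, simulation, residual error, NCA and two-stage fitting.

The disposition model is a standard two-compartment model with first-order
oral absorption and a lag time.  Apparent (oral) parameterization is used
throughout: CL/F, V1/F, Q/F, V2/F.  Body weight (centered at 70 kg) scales
CL/F and V1/F through power-law covariate relations.  Between-subject
variability is log-normal; residual error combines additive and
proportional components.

Plasma concentrations are expressed in ng/mL throughout the package
(amounts in mg, volumes in L; the mg/L -> ng/mL factor is 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "AbsorptionParams",
    "PopPKParams",
    "IndividualPKParams",
    "PlasmaProfile",
    "NCAResult",
    "FitResult",
    "ETA_ORDER",
    "default_poppk",
    "covariate_scale",
    "sample_individuals",
    "simulate_plasma",
    "two_compartment_oral_conc",
    "add_residual_error",
    "nca",
    "fit_individual",
]

#: order of parameters in eta vectors and correlation matrices
ETA_ORDER = ("t_lag", "k_a", "cl_f", "v1_f", "q_f", "v2_f")

MG_L_TO_NG_ML = 1000.0
REFERENCE_WEIGHT_KG = 70.0


@dataclass(frozen=True)
class AbsorptionParams:
    """Formulation-specific first-order absorption parameters."""

    t_lag: float  # h
    k_a: float  # 1/h
    bsv_t_lag: float = 0.0  # % CV
    bsv_k_a: float = 0.0  # % CV

    def __post_init__(self) -> None:
        if self.t_lag < 0 or self.k_a <= 0:
            raise ValueError("t_lag must be >= 0 and k_a > 0")
        if self.bsv_t_lag < 0 or self.bsv_k_a < 0:
            raise ValueError("BSV must be >= 0")


@dataclass(frozen=True)
class PopPKParams:
    """Population-level two-compartment oral PK model.

    Disposition typical values are per 70 kg; ``beta_cl`` and ``beta_v1``
    are the power-law exponents of the weight covariate on CL/F and V1/F.
    ``bsv`` maps parameter names (see :data:`ETA_ORDER`; absorption entries
    live on :class:`AbsorptionParams`) to percent coefficients of variation
    of the log-normal between-subject distribution.  ``sigma_add`` is in
    ng/mL; ``sigma_prop`` is a fraction.
    """

    cl_f: float = 75.23  # L/h per 70 kg
    v1_f: float = 86.69  # L per 70 kg
    q_f: float = 41.43  # L/h per 70 kg
    v2_f: float = 31.38  # L
    beta_cl: float = 1.21
    beta_v1: float = 0.73
    bsv: Mapping[str, float] = field(
        default_factory=lambda: {"cl_f": 37.61, "v1_f": 40.69, "q_f": 0.0, "v2_f": 25.75}
    )
    sigma_add: float = 0.70  # ng/mL
    sigma_prop: float = 0.12  # fraction
    absorption: Mapping[str, AbsorptionParams] = field(
        default_factory=lambda: {
            "tablet": AbsorptionParams(t_lag=0.157, k_a=5.08, bsv_t_lag=77.86, bsv_k_a=107.0),
            "capsule": AbsorptionParams(t_lag=0.36, k_a=4.88, bsv_t_lag=28.88, bsv_k_a=117.34),
        }
    )
    eta_corr: np.ndarray | None = None  # (6, 6) over ETA_ORDER

    def __post_init__(self) -> None:
        for name in ("cl_f", "v1_f", "q_f", "v2_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v < 0 for v in self.bsv.values()):
            raise ValueError("BSV values must be >= 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual error terms must be >= 0")
        if self.eta_corr is not None:
            corr = np.asarray(self.eta_corr, dtype=float)
            if corr.shape != (len(ETA_ORDER), len(ETA_ORDER)):
                raise ValueError("eta_corr must be 6x6 over ETA_ORDER")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError("eta_corr must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise ValueError("eta_corr must have unit diagonal")
            if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
                raise ValueError("eta_corr must be positive semidefinite")

    def bsv_vector(self, formulation: str) -> np.ndarray:
        """Percent CVs in :data:`ETA_ORDER` for the given formulation."""
        absn = self.absorption[formulation]
        return np.array(
            [
                absn.bsv_t_lag,
                absn.bsv_k_a,
                self.bsv.get("cl_f", 0.0),
                self.bsv.get("v1_f", 0.0),
                self.bsv.get("q_f", 0.0),
                self.bsv.get("v2_f", 0.0),
            ]
        )


def default_poppk() -> PopPKParams:
    """Published final population PK model for the 100 mg dose."""
    return PopPKParams()


@dataclass(frozen=True)
class IndividualPKParams:
    """Realized subject-level parameters (after covariate scaling and eta)."""

    subject: str
    weight: float  # kg
    t_lag: float  # h
    k_a: float  # 1/h
    cl_f: float  # L/h
    v1_f: float  # L
    q_f: float  # L/h
    v2_f: float  # L
    eta: np.ndarray | None = None  # log-scale deviations, ETA_ORDER

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        for name in ("k_a", "cl_f", "v1_f", "q_f", "v2_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_lag < 0:
            raise ValueError("t_lag must be >= 0")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        """(k10, k12, k21) in 1/h."""
        return self.cl_f / self.v1_f, self.q_f / self.v1_f, self.q_f / self.v2_f


@dataclass(frozen=True)
class PlasmaProfile:
    """Plasma concentration-time series for one subject and formulation."""

    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # ng/mL, >= 0
    grid: str = "dense"  # "dense" | "clinical"
    dose: float = 100.0  # mg
    formulation: str = "capsule"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


#: blood-sampling schedule of the crossover trial (h)
CLINICAL_TIMES = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 12.0, 16.0, 24.0])


@dataclass(frozen=True)
class NCAResult:
    c_max: float  # ng/mL
    t_max: float  # h
    auc_last: float  # ng*h/mL
    c_half_hour: float  # ng/mL


@dataclass(frozen=True)
class FitResult:
    """Outcome of a two-stage individual fit."""

    params: IndividualPKParams
    converged: bool
    cost: float
    message: str = ""
    n_starts: int = 1


def _omega_sd(bsv_percent: np.ndarray) -> np.ndarray:
    """Log-scale SD from % CV: omega = sqrt(ln(1 + CV^2))."""
    cv = np.asarray(bsv_percent, dtype=float) / 100.0
    return np.sqrt(np.log1p(cv**2))


def covariate_scale(
    pop: PopPKParams,
    weight: float,
    eta: Sequence[float] | np.ndarray | None = None,
    formulation: str = "capsule",
    subject: str = "typical",
) -> IndividualPKParams:
    """Realize individual parameters: theta_i = theta * exp(eta) * (W/70)^beta.

    The weight exponent applies to CL/F (beta_cl) and V1/F (beta_v1) only.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    eta_arr = np.zeros(len(ETA_ORDER)) if eta is None else np.asarray(eta, dtype=float)
    if eta_arr.shape != (len(ETA_ORDER),):
        raise ValueError(f"eta must have length {len(ETA_ORDER)} ({ETA_ORDER})")
    absn = pop.absorption[formulation]
    w_ratio = weight / REFERENCE_WEIGHT_KG
    e = np.exp(eta_arr)
    return IndividualPKParams(
        subject=subject,
        weight=weight,
        t_lag=absn.t_lag * e[0],
        k_a=absn.k_a * e[1],
        cl_f=pop.cl_f * e[2] * w_ratio**pop.beta_cl,
        v1_f=pop.v1_f * e[3] * w_ratio**pop.beta_v1,
        q_f=pop.q_f * e[4],
        v2_f=pop.v2_f * e[5],
        eta=eta_arr,
    )


def sample_individuals(
    pop: PopPKParams,
    n: int,
    rng: np.random.Generator | int,
    weight_source=None,
    formulation: str = "capsule",
) -> list[IndividualPKParams]:
    """Draw ``n`` subjects with multivariate log-normal between-subject variability.

    ``weight_source`` is either None (all 70 kg) or a callable
    ``(rng, n) -> array of kg``.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    omega = _omega_sd(pop.bsv_vector(formulation))
    corr = np.eye(len(ETA_ORDER)) if pop.eta_corr is None else np.asarray(pop.eta_corr)
    cov = corr * np.outer(omega, omega)
    etas = rng.multivariate_normal(np.zeros(len(ETA_ORDER)), cov, size=n, method="cholesky") \
        if np.min(np.linalg.eigvalsh(cov)) > 1e-12 else rng.standard_normal((n, len(ETA_ORDER))) * omega
    weights = np.full(n, REFERENCE_WEIGHT_KG) if weight_source is None else np.asarray(
        weight_source(rng, n), dtype=float
    )
    return [
        covariate_scale(pop, weights[i], etas[i], formulation, subject=f"S{i + 1:04d}")
        for i in range(n)
    ]


def lognormal_weights(median: float = 70.0, cv: float = 0.15):
    """Optional heterogeneous body-weight source (log-normal)."""

    def _draw(rng: np.random.Generator, n: int) -> np.ndarray:
        sd = np.sqrt(np.log1p(cv**2))
        return median * np.exp(rng.standard_normal(n) * sd)

    return _draw


def _disposition_matrix(ind: IndividualPKParams) -> np.ndarray:
    k10, k12, k21 = ind.micro_constants
    ka = ind.k_a
    return np.array(
        [
            [-ka, 0.0, 0.0],
            [ka, -(k10 + k12), k21],
            [0.0, k12, -k21],
        ]
    )


def simulate_plasma(
    ind: IndividualPKParams,
    dose: float,
    times: Sequence[float] | np.ndarray,
    grid: str = "dense",
    formulation: str = "capsule",
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PlasmaProfile:
    """Simulate the plasma profile of a single oral dose.

    States are amounts (mg) in the absorption depot, central and peripheral
    compartments; C = A_c / V1 (converted to ng/mL).  Absorption starts at
    ``t_lag``; the integration restarts there so the discontinuity is not
    smeared.  ``method="analytic"`` evaluates the closed-form solution
    instead of integrating.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if dose == 0 or times.size == 0:
        return PlasmaProfile(times, np.zeros_like(times), grid, dose, formulation)

    if method == "analytic":
        conc = two_compartment_oral_conc(times, ind, dose)
        return PlasmaProfile(times, conc, grid, dose, formulation)

    m = _disposition_matrix(ind)
    post = times[times > ind.t_lag]
    conc = np.zeros_like(times)
    if post.size:
        sol = solve_ivp(
            lambda t, y: m @ y,
            (ind.t_lag, post[-1]),
            [dose, 0.0, 0.0],
            t_eval=post,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - LSODA is robust on linear systems
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        conc[times > ind.t_lag] = sol.y[1] / ind.v1_f * MG_L_TO_NG_ML
    return PlasmaProfile(times, np.clip(conc, 0.0, None), grid, dose, formulation)


def two_compartment_oral_conc(
    times: np.ndarray, ind: IndividualPKParams, dose: float
) -> np.ndarray:
    """Closed-form triexponential solution of the lagged first-order oral model.

    C(t) = (ka*D/V1) * [A e^{-a t'} + B e^{-b t'} + C e^{-ka t'}], t' = t - t_lag,
    with a, b the roots of s^2 + (k10+k12+k21) s + k10 k21 = 0.  Used by the
    fitter (fast) and as a cross-check of the ODE route.
    """
    times = np.asarray(times, dtype=float)
    k10, k12, k21 = ind.micro_constants
    ka = ind.k_a
    s = k10 + k12 + k21
    disc = np.sqrt(max(s**2 - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    # nudge coincident rate constants apart to avoid 0/0 (removable singularities)
    eps = 1e-9 * max(ka, alpha, 1.0)
    if abs(alpha - beta) < eps:
        alpha += eps
    if abs(ka - alpha) < eps:
        ka += eps
    if abs(ka - beta) < eps:
        ka += 2 * eps
    tp = np.clip(times - ind.t_lag, 0.0, None)
    coef_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_k = (k21 - ka) / ((alpha - ka) * (beta - ka))
    c = (
        ka
        * dose
        / ind.v1_f
        * (coef_a * np.exp(-alpha * tp) + coef_b * np.exp(-beta * tp) + coef_k * np.exp(-ka * tp))
    )
    c = np.where(times <= ind.t_lag, 0.0, c)
    return np.clip(c, 0.0, None) * MG_L_TO_NG_ML


def add_residual_error(
    profile: PlasmaProfile, pop: PopPKParams, rng: np.random.Generator | int
) -> PlasmaProfile:
    """Apply combined residual error y = f*(1+eps_prop) + eps_add, floored at 0."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = profile.concentrations
    y = (
        f * (1.0 + rng.standard_normal(f.shape) * pop.sigma_prop)
        + rng.standard_normal(f.shape) * pop.sigma_add
    )
    return replace(profile, concentrations=np.clip(y, 0.0, None))


def nca(profile: PlasmaProfile) -> NCAResult:
    """Noncompartmental summary: Cmax, Tmax (earliest tie), AUC_last, C(0.5 h).

    AUC_last is the linear trapezoid over the observed grid.  C(0.5 h) is an
    exact grid lookup, else linear interpolation (0 outside the grid span).
    """
    t, c = profile.times, profile.concentrations
    if t.size < 2:
        raise ValueError("NCA needs at least 2 time points")
    imax = int(np.argmax(c))  # argmax returns the earliest maximal index
    auc = float(np.trapezoid(c, t))
    half = np.interp(0.5, t, c, left=0.0) if not np.isclose(t, 0.5).any() else float(
        c[np.isclose(t, 0.5)][0]
    )
    return NCAResult(c_max=float(c[imax]), t_max=float(t[imax]), auc_last=auc, c_half_hour=float(half))


def _fit_bounds(
    init: IndividualPKParams, tablet_ref: IndividualPKParams | None, t_first: float
) -> tuple[np.ndarray, np.ndarray]:
    # theta = (t_lag, k_a, cl_f, v1_f, q_f, v2_f)
    lo = np.array([0.0, 1e-2, 1e-2, 1e-1, 1e-2, 1e-1])
    hi = np.array([t_first, 100.0, 1e4, 1e4, 1e4, 1e4])
    if tablet_ref is not None:
        for i, name in enumerate(("cl_f", "v1_f", "q_f", "v2_f")):
            v = getattr(tablet_ref, name)
            lo[2 + i], hi[2 + i] = 0.8 * v, 1.2 * v
    return lo, hi


def fit_individual(
    observed: PlasmaProfile,
    init: IndividualPKParams,
    tablet_ref: IndividualPKParams | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | int = 0,
) -> FitResult:
    """Two-stage individual fit with 1/Ypred^2 weighting.

    When ``tablet_ref`` is given, clearances and distribution volumes are
    bounded to +/-20% of the tablet estimates (disposition is assumed
    formulation-independent).  t_lag is initialized at the midpoint of
    (t_first - 0.5 h, t_first).  Multi-start (default 3 jittered starts)
    guards against local minima in t_lag.  Non-convergence is flagged on
    the returned :class:`FitResult`, never raised.
    """
    t, y = observed.times, observed.concentrations
    if t.size < 6:
        raise ValueError("individual fitting needs >= 6 observations")
    if np.all(y <= 0):
        return FitResult(params=init, converged=False, cost=np.inf, message="all observations are zero")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    t_first = float(t[np.argmax(y > 0)])
    tlag0 = max(t_first - 0.25, 1e-3)
    theta0 = np.array([tlag0, init.k_a, init.cl_f, init.v1_f, init.q_f, init.v2_f])
    lo, hi = _fit_bounds(init, tablet_ref, t_first)
    theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)

    def residuals(theta: np.ndarray) -> np.ndarray:
        cand = IndividualPKParams(
            subject=init.subject, weight=init.weight,
            t_lag=theta[0], k_a=theta[1], cl_f=theta[2], v1_f=theta[3],
            q_f=theta[4], v2_f=theta[5],
        )
        pred = two_compartment_oral_conc(t, cand, observed.dose)
        w = np.maximum(pred, 1e-6)  # 1/Ypred^2 weighting
        return (y - pred) / w

    best = None
    for k in range(n_starts):
        start = theta0 if k == 0 else np.clip(
            theta0 * np.exp(rng.standard_normal(6) * 0.15), lo + 1e-12, hi - 1e-12
        )
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), method="trf", x_scale="jac")
        except Exception as exc:  # numerical failure in one start is not fatal
            if best is None:
                best = ("failed", None, str(exc))
            continue
        if best is None or best[0] == "failed" or res.cost < best[1].cost:
            best = ("ok", res, "")

    if best is None or best[0] == "failed":
        return FitResult(params=init, converged=False, cost=np.inf,
                         message=best[2] if best else "no start succeeded", n_starts=n_starts)
    res = best[1]
    th = res.x
    fitted = IndividualPKParams(
        subject=init.subject, weight=init.weight,
        t_lag=th[0], k_a=th[1], cl_f=th[2], v1_f=th[3], q_f=th[4], v2_f=th[5],
    )
    return FitResult(
        params=fitted, converged=bool(res.success), cost=float(res.cost),
        message=res.message, n_starts=n_starts,
    )
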