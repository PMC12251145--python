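"""Non-label observables and derived quantities of the lineage models.

Three quantities link the kinetic parameters to data beyond DNA labelling:

- ``theta`` — the difference in mean telomere length (bp) between naive T
  cells and the aggregate T_SCM pool, positive when T_SCM have divided more;
- the post-vaccination decay of the antigen-specific (yellow-fever tetramer+)
  T_SCM frequency, obtained by switching off naive inflow (delta_N = 0) in
  each model;
- clonal half-lives ln2/(d - p) — the persistence of a clone rather than of
  individual cells — and mean pool residency times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kinetic_models import InfeasibleParameters, KineticParams, equilibrium_loss_rates

__all__ = [
    "TelomereSettings",
    "CloneDecay",
    "telomere_theta",
    "yfv_frequency",
    "clonal_half_lives",
    "residency_times",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TelomereSettings:
    """Settings of the telomere observable.

    ``delta_tel`` is the number of base pairs lost per division (default
    50 bp). Models A/B never equilibrate, so their theta is evaluated at a
    reference donor age (default 34 years, the cohort median); models C-E are
    run to equilibrium.
    """

    delta_tel: float = 50.0
    age_for_ab_years: float = 34.0
    horizon_years: float = 100.0
    theta_rate_tol: float = 1e-8  # bp per day at the horizon

    def __post_init__(self):
        if self.delta_tel < 0:
            raise ValueError("delta_tel must be non-negative")
        if self.age_for_ab_years <= 0 or self.horizon_years <= 0:
            raise ValueError("ages and horizons must be positive")


@dataclass(frozen=True)
class CloneDecay:
    """Antigen-specific frequency trajectories after vaccination.

    ``A`` is the initial frequency of each T_SCM pool (so the total starts at
    2A); ``alpha`` and ``gamma`` are the clone decay rates of the two pools.
    """

    A: float
    alpha: float
    gamma: float
    t: np.ndarray
    T1: np.ndarray
    T2: np.ndarray

    @property
    def Y(self) -> np.ndarray:
        return self.T1 + self.T2


def _division_rate_offsets(params: KineticParams):
    """Per-day division-count excess rates of the nu system (models C-E).

    nu_i = (divisions of pool i) - (divisions of T_N); returns functions
    giving d(nu)/dt as an affine map M nu + c so equilibrium and transient
    solutions share one definition.
    """
    p_N, p_1, p_2 = params.p_N, params.p_1, params.p_2
    m = params.model_id
    k = params.k
    if m == "C":
        a1 = params.burst * params.delta_N * params.frac / params.R_1
        a2 = params.burst * params.delta_N * (1.0 - params.frac) / params.R_2
        M = np.array([[-a1, 0.0], [0.0, -a2]])
        c = np.array([2 * (p_1 - p_N) + a1 * k, 2 * (p_2 - p_N) + a2 * k])
    elif m == "D":
        a1 = params.burst * params.delta_N / params.R_1
        a2 = params.delta_1 * params.R_1 / params.R_2
        M = np.array([[-a1, 0.0], [a2, -a2]])
        c = np.array([2 * (p_1 - p_N) + a1 * k, 2 * (p_2 - p_N)])
    elif m == "E":
        a2 = params.burst * params.delta_N / params.R_2
        a1 = params.delta_1 * params.R_2 / params.R_1
        M = np.array([[-a1, a1], [0.0, -a2]])
        c = np.array([2 * (p_1 - p_N), 2 * (p_2 - p_N) + a2 * k])
    else:
        raise ValueError(f"nu system not defined for model {m}")
    return M, c


def telomere_theta(
    params: KineticParams,
    settings: TelomereSettings = TelomereSettings(),
    method: str = "ode",
) -> float:
    """Predicted T_N minus T_SCM mean telomere-length difference, in bp.

    Models A/B grow linearly with age and are evaluated at
    ``settings.age_for_ab_years``. Models C-E reach an equilibrium that is
    independent of age; ``method="ode"`` integrates the division-count system
    to the horizon and verifies the rate-of-change tolerance, while
    ``method="algebraic"`` solves the linear steady state directly.
    """
    w1 = params.R_1 / (params.R_1 + params.R_2)
    w2 = params.R_2 / (params.R_1 + params.R_2)
    if params.model_id in ("A", "B"):
        t_days = settings.age_for_ab_years * DAYS_PER_YEAR
        return float(
            (w1 * 2 * params.p_1 + w2 * 2 * params.p_2 - 2 * params.p_N)
            * settings.delta_tel
            * t_days
        )

    M, c = _division_rate_offsets(params)
    if method == "algebraic":
        nu = np.linalg.solve(M, -c)
    elif method == "ode":
        horizon = settings.horizon_years * DAYS_PER_YEAR
        sol = solve_ivp(
            lambda t, y: M @ y + c,
            (0.0, horizon),
            [0.0, 0.0],
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"telomere integration failed: {sol.message}")
        nu = sol.y[:, -1]
        rate = settings.delta_tel * abs(w1 * (M @ nu + c)[0] + w2 * (M @ nu + c)[1])
        if rate > settings.theta_rate_tol:
            raise RuntimeError(
                f"theta did not equilibrate within {settings.horizon_years} years "
                f"(|d theta/dt| = {rate:.3g} bp/day)"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(settings.delta_tel * (w1 * nu[0] + w2 * nu[1]))


def _two_pool_decay(A, alpha, gamma, delta_1, t):
    """Upstream pool A e^{-alpha t}; downstream fed at rate delta_1 (relative
    to its own size via the pool ratios, already folded into gamma)."""
    up = A * np.exp(-alpha * t)
    if np.isclose(alpha, gamma, rtol=1e-12, atol=1e-300):
        down = A * np.exp(-alpha * t) * (1.0 + delta_1 * t)
    else:
        down = (
            (gamma - alpha - delta_1) * A * np.exp(-gamma * t)
            + delta_1 * A * np.exp(-alpha * t)
        ) / (gamma - alpha)
    return up, down


def yfv_frequency(params: KineticParams, t) -> CloneDecay:
    """Antigen-specific T_SCM frequency trajectories at times ``t`` (days).

    Assumes no further naive inflow after vaccination. Models A/B predict a
    constant population; model C two independent exponentials; models D/E a
    fed two-pool cascade (with the removable alpha = gamma singularity
    resolved by its analytic limit).
    """
    if params.A is None or params.A <= 0:
        raise ValueError("params.A (initial antigen-specific frequency) must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    A = params.A
    m = params.model_id
    if m in ("A", "B"):
        const = np.full_like(t, A)
        return CloneDecay(A=A, alpha=0.0, gamma=0.0, t=t, T1=const, T2=const.copy())
    if m == "C":
        alpha = params.delta_N * params.frac * params.burst / params.R_1
        gamma = params.delta_N * (1.0 - params.frac) * params.burst / params.R_2
        return CloneDecay(
            A=A, alpha=alpha, gamma=gamma, t=t,
            T1=A * np.exp(-alpha * t), T2=A * np.exp(-gamma * t),
        )
    if m == "D":
        alpha = params.delta_N * params.burst / params.R_1
        gamma = params.delta_1 * params.R_1 / params.R_2
        T1, T2 = _two_pool_decay(A, alpha, gamma, params.delta_1, t)
        return CloneDecay(A=A, alpha=alpha, gamma=gamma, t=t, T1=T1, T2=T2)
    # model E: CD95hi decays upstream, CD95int is fed
    alpha = params.delta_N * params.burst / params.R_2
    gamma = params.delta_1 * params.R_2 / params.R_1
    T2, T1 = _two_pool_decay(A, alpha, gamma, params.delta_1, t)
    return CloneDecay(A=A, alpha=alpha, gamma=gamma, t=t, T1=T1, T2=T2)


def clonal_half_lives(params: KineticParams) -> tuple[float, float]:
    """Half-life (days) of a CD95int and a CD95hi T_SCM clone.

    Equal to ln2 over the clone's net loss rate; infinite when the pool has
    no net clonal loss. Undefined for models A/B, whose antigen-specific
    pools are constant.
    """
    m = params.model_id
    if m in ("A", "B"):
        raise ValueError(
            "clone half-life is undefined for the independent models (constant clones)"
        )
    ln2 = np.log(2.0)
    if m == "C":
        den1 = params.delta_N * params.frac * params.burst / params.R_1
        den2 = params.delta_N * (1.0 - params.frac) * params.burst / params.R_2
    elif m == "D":
        den1 = params.delta_N * params.burst / params.R_1
        den2 = params.delta_1 * params.R_1 / params.R_2
    else:  # E
        den1 = params.delta_1 * params.R_2 / params.R_1
        den2 = params.delta_N * params.burst / params.R_2
    t1 = ln2 / den1 if den1 > 0 else np.inf
    t2 = ln2 / den2 if den2 > 0 else np.inf
    return float(t1), float(t2)


def residency_times(params: KineticParams) -> tuple[float, float]:
    """Mean time (days) a cell remains in the CD95int / CD95hi pool (model D).

    The reciprocal of the total per-cell exit rate: d_1 + delta_1 for CD95int
    and d_2 for CD95hi, with the equilibrium-derived loss rates.
    """
    if params.model_id != "D":
        raise ValueError("residency times are reported for model D")
    d_N, d_1, d_2 = equilibrium_loss_rates(params)
    exit1 = d_1 + params.delta_1
    r1 = 1.0 / exit1 if exit1 > 0 else np.inf
    r2 = 1.0 / d_2 if d_2 > 0 else np.inf
    return float(r1), float(r2)
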