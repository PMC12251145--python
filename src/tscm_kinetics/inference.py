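"""Joint fitting of labelling, telomere and vaccine-cohort data.

One donor's labelling study (saliva, monocyte and three-pool label series plus
the flow-derived pool ratios) is combined with two shared cross-sectional
datasets — telomere-length differences from 5 donors and yellow-fever
tetramer+ T_SCM frequencies from a 37-donor cohort — into a single objective:
the sum of squared residuals, each residual normalised by the mean of the
observations of its data type so the three blocks are on a comparable scale.

The global optimisation mirrors the multi-start strategy used for this kind
of labelling data: seeded random starts inside box bounds in a log-rate
space, each polished with a derivative-free simplex search followed by a
trust-region least-squares pass that exploits the sum-of-squares structure of
the objective. Uncertainty comes
from a nonparametric bootstrap that resamples observation rows within each
data type and refits; clonal half-lives are summarised from the bootstrap
replicates rather than the point estimate because the parameters are
correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .calibration import (
    EnrichmentSeries,
    MonocyteParams,
    SalivaModel,
    fit_monocyte,
    fit_saliva,
)
from .kinetic_models import (
    InfeasibleParameters,
    KineticParams,
    MODEL_IDS,
    POOLS,
    fork_label_trajectories_pi,
    label_trajectories,
)
from .observables import (
    DAYS_PER_YEAR,
    TelomereSettings,
    clonal_half_lives,
    telomere_theta,
    yfv_frequency,
)

__all__ = [
    "StudyBundle",
    "AuxData",
    "FitResult",
    "BootstrapSummary",
    "FitConfig",
    "calibrate_bundle",
    "joint_objective",
    "joint_residuals",
    "fit_model",
    "bootstrap_fit",
    "compare_models",
    "predict_subset_decay",
]

_INF = float("inf")


@dataclass
class StudyBundle:
    """One labelled donor's data plus per-donor constants and calibrations."""

    donor_id: str
    saliva: EnrichmentSeries
    monocyte: EnrichmentSeries
    labels: dict[str, EnrichmentSeries]
    R_1: float
    R_2: float
    saliva_model: SalivaModel | None = None
    monocyte_params: MonocyteParams | None = None

    def __post_init__(self):
        missing = [p for p in POOLS if p not in self.labels]
        if missing:
            raise ValueError(f"label series missing for pools: {missing}")
        if self.R_1 <= 0 or self.R_2 <= 0:
            raise ValueError("pool ratios must be positive")

    @property
    def calibrated(self) -> bool:
        return self.saliva_model is not None and self.monocyte_params is not None


@dataclass
class AuxData:
    """Shared cross-sectional datasets: telomere thetas and the YFV cohort.

    ``telomere``: DataFrame with columns (age_years, theta_bp).
    ``yfv``: DataFrame with columns (years, frequency, multiple_vaccination),
    frequency as % of CD8 for the total antigen-specific T_SCM pool.
    """

    telomere: pd.DataFrame
    yfv: pd.DataFrame

    def __post_init__(self):
        for col in ("age_years", "theta_bp"):
            if col not in self.telomere.columns:
                raise ValueError(f"telomere table missing column {col!r}")
        for col in ("years", "frequency"):
            if col not in self.yfv.columns:
                raise ValueError(f"yfv table missing column {col!r}")
        if "multiple_vaccination" not in self.yfv.columns:
            self.yfv = self.yfv.assign(multiple_vaccination=False)
        if (self.yfv["years"] <= 0).any():
            raise ValueError("yfv years since vaccination must be positive")
        if (self.yfv["frequency"] < 0).any():
            raise ValueError("yfv frequencies must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the joint objective and optimiser."""

    weighted_labels: bool = False  # divide label residuals by analytic SDs as well
    per_pool_normalization: bool = False
    include_telomere: bool = True
    include_yfv: bool = True
    exclude_multiple_vaccination: bool = True
    telomere_settings: TelomereSettings = TelomereSettings()
    polish_maxiter: int = 400
    final_polish_maxiter: int = 4000
    ls_max_nfev: int = 400
    as_printed: bool = False


@dataclass
class FitResult:
    model_id: str
    params: KineticParams
    objective: float
    blocks: dict[str, float]
    param_names: tuple[str, ...]
    x: np.ndarray
    n_starts: int
    master_seed: int
    label_only: bool
    converged: bool
    start_objectives: list[float] = field(default_factory=list)


@dataclass
class BootstrapSummary:
    model_id: str
    n_boot: int
    n_failed: int
    median: dict[str, float]
    iqr_low: dict[str, float]
    iqr_high: dict[str, float]
    replicates: pd.DataFrame


def calibrate_bundle(bundle: StudyBundle, weighted: bool = False) -> StudyBundle:
    """Run the saliva and monocyte calibrations, returning a calibrated copy."""
    saliva_model, _ = fit_saliva(bundle.saliva, weighted=weighted)
    mono, _ = fit_monocyte(bundle.monocyte, saliva_model, weighted=weighted)
    return replace(bundle, saliva_model=saliva_model, monocyte_params=mono)


# ---------------------------------------------------------------------------
# objective

def _label_residuals(params, bundle, config, pi_vector=None):
    times = {p: bundle.labels[p].times for p in POOLS}
    all_times = np.unique(np.concatenate([t for t in times.values()]))
    if pi_vector is not None:
        pred = fork_label_trajectories_pi(
            *pi_vector,
            R_1=bundle.R_1,
            R_2=bundle.R_2,
            saliva=bundle.saliva_model,
            b_w=bundle.monocyte_params.b_w,
            times=all_times,
        )
    else:
        pred = label_trajectories(
            params,
            bundle.saliva_model,
            bundle.monocyte_params.b_w,
            all_times,
            as_printed=config.as_printed,
        )
    if config.per_pool_normalization:
        means = {p: np.mean(bundle.labels[p].values) for p in POOLS}
    else:
        pooled = np.concatenate([bundle.labels[p].values for p in POOLS])
        mean = np.mean(pooled)
        means = {p: mean for p in POOLS}
    parts = []
    for p in POOLS:
        obs = bundle.labels[p]
        idx = np.searchsorted(all_times, obs.times)
        resid = (obs.values - pred[p].values[idx]) / means[p]
        if config.weighted_labels and obs.sd is not None:
            sd = np.where(obs.sd > 0, obs.sd, np.min(obs.sd[obs.sd > 0], initial=1.0))
            resid = resid * (np.mean(sd) / sd)
        parts.append(resid)
    return np.concatenate(parts)


def _label_block(params, bundle, config, pi_vector=None):
    return float(np.sum(_label_residuals(params, bundle, config, pi_vector) ** 2))


def _telomere_residuals(params, aux, config):
    theta_pred = telomere_theta(
        params, config.telomere_settings,
        method="ode" if params.model_id in ("A", "B") else "algebraic",
    )
    obs = aux.telomere["theta_bp"].to_numpy(dtype=float)
    return (obs - theta_pred) / np.mean(obs)


def _telomere_block(params, aux, config):
    return float(np.sum(_telomere_residuals(params, aux, config) ** 2))


def _yfv_residuals(params, aux, config):
    df = aux.yfv
    if config.exclude_multiple_vaccination:
        df = df[~df["multiple_vaccination"].astype(bool)]
    t_days = df["years"].to_numpy(dtype=float) * DAYS_PER_YEAR
    obs = df["frequency"].to_numpy(dtype=float)
    pred = yfv_frequency(params, t_days).Y
    return (obs - pred) / np.mean(obs)


def _yfv_block(params, aux, config):
    return float(np.sum(_yfv_residuals(params, aux, config) ** 2))


def joint_residuals(
    params: KineticParams,
    bundle: StudyBundle,
    aux: AuxData | None = None,
    config: FitConfig = FitConfig(),
) -> np.ndarray:
    """Concatenated mean-normalised residual vector over the data types.

    ``joint_objective`` is the sum of squares of this vector; exposing the
    vector lets least-squares solvers exploit the problem structure.
    """
    parts = [_label_residuals(params, bundle, config)]
    if aux is not None and config.include_telomere:
        parts.append(_telomere_residuals(params, aux, config))
    if aux is not None and config.include_yfv:
        parts.append(_yfv_residuals(params, aux, config))
    return np.concatenate(parts)


def joint_objective(
    params: KineticParams,
    bundle: StudyBundle,
    aux: AuxData | None = None,
    config: FitConfig = FitConfig(),
) -> float:
    """Sum of squared mean-normalised residuals over the data types.

    Infeasible parameters (equilibrium implying a negative loss rate) return
    +inf so optimisers simply reject them.
    """
    if not bundle.calibrated:
        raise ValueError("bundle must be calibrated (saliva + monocyte) before fitting")
    try:
        blocks = joint_objective_blocks(params, bundle, aux, config)
    except (InfeasibleParameters, np.linalg.LinAlgError):
        return _INF
    return sum(blocks.values())


def joint_objective_blocks(params, bundle, aux=None, config=FitConfig()):
    blocks = {"labels": _label_block(params, bundle, config)}
    if aux is not None and config.include_telomere:
        blocks["telomere"] = _telomere_block(params, aux, config)
    if aux is not None and config.include_yfv:
        blocks["yfv"] = _yfv_block(params, aux, config)
    return blocks


# ---------------------------------------------------------------------------
# parameter spaces

RATE_BOUNDS = (1e-10, 0.5)  # per day
_LOG_RATE = (math.log10(RATE_BOUNDS[0]), math.log10(RATE_BOUNDS[1]))
_LOG_A = (-4.0, 0.0)  # A in (0, 1] % of CD8
_K_BOUNDS = (0.0, 15.0)
_FRAC_BOUNDS = (0.0, 1.0)


class _ParamSpace:
    """Flat transformed vector <-> KineticParams; rates live on a log10 scale."""

    def __init__(self, model_id, R_1, R_2, label_only=False, bounds=None):
        self.model_id = model_id
        self.R_1, self.R_2 = R_1, R_2
        self.label_only = label_only
        names: list[tuple[str, str]] = [("p_N", "rate")]
        if model_id == "C" and label_only:
            names = [("p_N", "rate"), ("Pi_1", "rate"), ("Pi_2", "rate"),
                     ("frac", "unit"), ("delta_N", "rate")]
        else:
            names += [("p_1", "rate"), ("p_2", "rate")]
            if model_id == "B":
                names += [("dstar_N", "rate"), ("dstar_1", "rate"), ("dstar_2", "rate")]
            elif model_id == "C":
                names += [("delta_N", "rate"), ("k", "k"), ("frac", "unit")]
            elif model_id in ("D", "E"):
                names += [("delta_N", "rate"), ("delta_1", "rate"), ("k", "k")]
            if not label_only:
                names += [("A", "logA")]
        self.names = tuple(n for n, _ in names)
        self.kinds = tuple(k for _, k in names)
        default = {"rate": _LOG_RATE, "unit": _FRAC_BOUNDS, "k": _K_BOUNDS, "logA": _LOG_A}
        self.bounds = [
            (bounds or {}).get(n, default[k]) for n, k in zip(self.names, self.kinds)
        ]

    @property
    def dim(self):
        return len(self.names)

    def to_params(self, x):
        vals = {}
        for name, kind, xi in zip(self.names, self.kinds, x):
            vals[name] = 10.0 ** xi if kind in ("rate", "logA") else float(xi)
        if self.model_id == "C" and self.label_only:
            return vals  # pi-space dict, consumed by fork_label_trajectories_pi
        return KineticParams(model_id=self.model_id, R_1=self.R_1, R_2=self.R_2, **vals)

    def to_x(self, params: KineticParams):
        x = []
        for name, kind in zip(self.names, self.kinds):
            v = getattr(params, name)
            x.append(math.log10(v) if kind in ("rate", "logA") else float(v))
        return np.array(x)

    def sample(self, rng):
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return lo + rng.random(self.dim) * (hi - lo)


# residuals returned for infeasible parameters: large enough that any
# feasible fit beats them, finite so least-squares solvers can back away
_PENALTY = 1e3


def _residual_count(bundle, aux, config, label_only):
    n = sum(len(bundle.labels[p]) for p in POOLS)
    if aux is not None and not label_only:
        if config.include_telomere:
            n += len(aux.telomere)
        if config.include_yfv:
            df = aux.yfv
            if config.exclude_multiple_vaccination:
                df = df[~df["multiple_vaccination"].astype(bool)]
            n += len(df)
    return n


def _make_funs(space, bundle, aux, config):
    """Scalar objective and residual-vector function over the transformed space."""
    label_only = space.label_only
    n_resid = _residual_count(bundle, aux, config, label_only)

    if space.model_id == "C" and label_only:
        def resid_fun(x):
            vals = space.to_params(x)
            try:
                return _label_residuals(
                    None, bundle, config,
                    pi_vector=(vals["p_N"], vals["Pi_1"], vals["Pi_2"],
                               vals["frac"], vals["delta_N"]),
                )
            except (InfeasibleParameters, np.linalg.LinAlgError):
                return np.full(n_resid, _PENALTY)
    else:
        cfg = replace(
            config,
            include_telomere=not label_only and config.include_telomere,
            include_yfv=not label_only and config.include_yfv,
        )

        def resid_fun(x):
            try:
                params = space.to_params(x)
                return joint_residuals(
                    params, bundle, aux if not label_only else None, cfg
                )
            except (ValueError, InfeasibleParameters, np.linalg.LinAlgError):
                return np.full(n_resid, _PENALTY)

    def fun(x):
        r = resid_fun(x)
        if r[0] == _PENALTY and np.all(r == _PENALTY):
            return _INF
        return float(np.sum(r**2))

    return fun, resid_fun


def fit_model(
    model_id: str,
    bundle: StudyBundle,
    aux: AuxData | None = None,
    n_starts: int = 30,
    bounds: dict | None = None,
    master_seed: int = 0,
    label_only: bool = False,
    config: FitConfig = FitConfig(),
    x0: np.ndarray | None = None,
) -> FitResult:
    """Best-of-restarts fit of one lineage model to a donor's data.

    Random starts are drawn inside the (transformed) bounds from a seed
    stream spawned off ``master_seed``; the first ``n`` children are the same
    for any larger ``n_starts``, so enlarging the search can only improve the
    returned objective. Each start is polished with bounded Nelder-Mead.
    ``x0``, when given, is polished in addition to the random starts (used by
    the bootstrap to warm-start from the point estimate).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if not bundle.calibrated:
        raise ValueError("calibrate the bundle before fitting")
    space = _ParamSpace(model_id, bundle.R_1, bundle.R_2, label_only, bounds)
    fun, resid_fun = _make_funs(space, bundle, aux, config)
    lo = np.array([b[0] for b in space.bounds])
    hi = np.array([b[1] for b in space.bounds])

    children = np.random.SeedSequence(master_seed).spawn(n_starts)
    starts = [space.sample(np.random.default_rng(c)) for c in children]
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))

    def _polish(x):
        """Simplex burn-in to find the basin, then trust-region least squares."""
        res = minimize(
            fun, x, method="Nelder-Mead", bounds=space.bounds,
            options={"maxiter": config.polish_maxiter, "xatol": 1e-8, "fatol": 1e-12},
        )
        x_best, f_best = res.x, float(res.fun)
        try:
            ls = least_squares(
                resid_fun, np.clip(x_best, lo, hi), bounds=(lo, hi),
                method="trf", x_scale="jac", max_nfev=config.ls_max_nfev,
            )
            f_ls = float(np.sum(ls.fun**2))
            if f_ls < f_best:
                x_best, f_best = ls.x, f_ls
        except (ValueError, np.linalg.LinAlgError):
            pass
        return x_best, f_best, bool(res.success)

    best_x, best_val = None, _INF
    start_objectives = []
    any_converged = False
    for s in starts:
        if not np.isfinite(fun(s)):
            # nudge towards the middle of the box until feasible
            mid = np.array([(lo_i + hi_i) / 2 for lo_i, hi_i in space.bounds])
            for frac in (0.5, 0.75, 0.9, 1.0):
                cand = s + frac * (mid - s)
                if np.isfinite(fun(cand)):
                    s = cand
                    break
            else:
                start_objectives.append(_INF)
                continue
        x_s, f_s, ok = _polish(s)
        start_objectives.append(f_s)
        any_converged = any_converged or ok
        if f_s < best_val:
            best_val, best_x = f_s, x_s
    if best_x is None:
        raise RuntimeError(
            f"all {len(starts)} starts for model {model_id} were infeasible "
            f"(equilibrium constraints violated everywhere in the search box)"
        )
    # deep re-polish of the winner: simplex restarts escape collapsed
    # simplices, and the closing least-squares pass sharpens the optimum
    for _ in range(2):
        res = minimize(
            fun, best_x, method="Nelder-Mead", bounds=space.bounds,
            options={"maxiter": config.final_polish_maxiter,
                     "xatol": 1e-10, "fatol": 1e-14},
        )
        improved = res.fun < best_val - 1e-10
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
        try:
            ls = least_squares(
                resid_fun, np.clip(best_x, lo, hi), bounds=(lo, hi),
                method="trf", x_scale="jac", max_nfev=config.ls_max_nfev,
            )
            f_ls = float(np.sum(ls.fun**2))
            if f_ls < best_val - 1e-10:
                best_val, best_x, improved = f_ls, ls.x, True
        except (ValueError, np.linalg.LinAlgError):
            pass
        if not improved:
            break

    if model_id == "C" and label_only:
        vals = space.to_params(best_x)
        params = KineticParams(
            model_id="C", p_N=vals["p_N"], p_1=vals["Pi_1"], p_2=vals["Pi_2"],
            delta_N=vals["delta_N"], k=0.0, frac=vals["frac"],
            R_1=bundle.R_1, R_2=bundle.R_2,
        )
        blocks = {"labels": best_val}
    else:
        params = space.to_params(best_x)
        blocks = joint_objective_blocks(
            params, bundle, None if label_only else aux, config
        )
    return FitResult(
        model_id=model_id,
        params=params,
        objective=best_val,
        blocks={k: float(v) for k, v in blocks.items()},
        param_names=space.names,
        x=np.asarray(best_x, dtype=float),
        n_starts=n_starts,
        master_seed=master_seed,
        label_only=label_only,
        converged=any_converged,
        start_objectives=start_objectives,
    )


# ---------------------------------------------------------------------------
# bootstrap

def _resample_series(series: EnrichmentSeries, idx) -> EnrichmentSeries:
    idx = np.sort(idx)
    # strict monotonicity is relaxed for bootstrap replicates by jittering
    # duplicated times an infinitesimal amount; predictions use exact times.
    times = series.times[idx]
    tweak = np.arange(len(idx)) * 1e-9
    return EnrichmentSeries(
        times=times + tweak,
        values=series.values[idx],
        sd=None if series.sd is None else series.sd[idx],
        population=series.population,
    )


def _resample_bundle_and_aux(bundle, aux, rng):
    rows = [(p, i) for p in POOLS for i in range(len(bundle.labels[p]))]
    pick = rng.integers(0, len(rows), size=len(rows))
    per_pool: dict[str, list[int]] = {p: [] for p in POOLS}
    for j in pick:
        p, i = rows[j]
        per_pool[p].append(i)
    labels = {}
    for p in POOLS:
        idx = per_pool[p]
        if not idx:  # keep at least one observation per pool
            idx = [int(rng.integers(0, len(bundle.labels[p])))]
        labels[p] = _resample_series(bundle.labels[p], np.array(idx))
    new_bundle = replace(bundle, labels=labels)

    new_aux = None
    if aux is not None:
        tel = aux.telomere.sample(
            n=len(aux.telomere), replace=True, random_state=int(rng.integers(2**31))
        ).reset_index(drop=True)
        yfv = aux.yfv.sample(
            n=len(aux.yfv), replace=True, random_state=int(rng.integers(2**31))
        ).reset_index(drop=True)
        new_aux = AuxData(telomere=tel, yfv=yfv)
    return new_bundle, new_aux


def bootstrap_fit(
    model_id: str,
    bundle: StudyBundle,
    aux: AuxData | None = None,
    n_boot: int = 100,
    master_seed: int = 0,
    n_starts: int = 30,
    point_fit: FitResult | None = None,
    config: FitConfig = FitConfig(),
    label_only: bool = False,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the joint fit.

    Each replicate resamples observation rows with replacement within each
    data type (keeping the number of points), refits, and records the
    parameters plus — for the lineage models — the derived clonal half-lives.
    Medians and interquartile ranges are taken over successful replicates.
    """
    if point_fit is None:
        point_fit = fit_model(
            model_id, bundle, aux, n_starts=n_starts, master_seed=master_seed,
            config=config, label_only=label_only,
        )
    children = np.random.SeedSequence(master_seed).spawn(2 * n_boot)
    records = []
    n_failed = 0
    for b in range(n_boot):
        rng = np.random.default_rng(children[2 * b])
        fit_seed = int(np.random.default_rng(children[2 * b + 1]).integers(2**31))
        rep_bundle, rep_aux = _resample_bundle_and_aux(bundle, aux, rng)
        try:
            rep = fit_model(
                model_id, rep_bundle, rep_aux, n_starts=n_starts,
                master_seed=fit_seed, config=config, label_only=label_only,
                x0=point_fit.x,
            )
        except (RuntimeError, InfeasibleParameters):
            n_failed += 1
            continue
        rec = dict(zip(rep.param_names, [
            10.0 ** v if kind in ("rate", "logA") else v
            for v, kind in zip(
                rep.x,
                _ParamSpace(model_id, bundle.R_1, bundle.R_2, label_only).kinds,
            )
        ]))
        rec["objective"] = rep.objective
        if model_id in ("C", "D", "E") and not label_only:
            t1, t2 = clonal_half_lives(rep.params)
            rec["half_life_CD95int"] = t1
            rec["half_life_CD95hi"] = t2
        records.append(rec)
    if not records:
        raise RuntimeError("every bootstrap replicate failed to fit")
    reps = pd.DataFrame.from_records(records)
    q = reps.quantile([0.25, 0.5, 0.75])
    return BootstrapSummary(
        model_id=model_id,
        n_boot=n_boot,
        n_failed=n_failed,
        median=q.loc[0.5].to_dict(),
        iqr_low=q.loc[0.25].to_dict(),
        iqr_high=q.loc[0.75].to_dict(),
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# model comparison and prediction

def compare_models(
    bundle: StudyBundle,
    aux: AuxData | None = None,
    models=MODEL_IDS,
    n_starts: int = 30,
    master_seed: int = 0,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Objective per model plus a flag for whether the model can produce a
    declining antigen-specific population (the independent models cannot)."""
    rows = []
    for m in models:
        row = {"model": m, "can_decline_yfv": m in ("C", "D", "E")}
        try:
            fit = fit_model(m, bundle, aux, n_starts=n_starts,
                            master_seed=master_seed, config=config)
            row["objective"] = fit.objective
            row["n_params"] = len(fit.param_names)
            row["error"] = ""
        except (RuntimeError, InfeasibleParameters) as exc:
            row["objective"] = np.nan
            row["n_params"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def predict_subset_decay(
    fit: FitResult,
    init_cd95int: float,
    init_cd95hi: float,
    horizon_years: float = 35.0,
    n_points: int = 200,
    bootstrap: BootstrapSummary | None = None,
) -> pd.DataFrame:
    """Predicted antigen-specific CD95int/CD95hi frequencies over time.

    The closed-form clone trajectories are rescaled so each subset starts at
    the supplied initial frequency (taken in practice from the cohort medians
    within a year of vaccination). With a bootstrap summary, per-replicate
    trajectories give pointwise 2.5/97.5% bands.
    """
    if fit.model_id not in ("C", "D", "E"):
        raise ValueError("subset decay predictions require a lineage model (C, D or E)")
    if init_cd95int <= 0 or init_cd95hi <= 0:
        raise ValueError("initial frequencies must be positive")
    t_days = np.linspace(0.0, horizon_years * DAYS_PER_YEAR, n_points)
    params = replace(fit.params, A=1.0)
    decay = yfv_frequency(params, t_days)
    out = pd.DataFrame({
        "years": t_days / DAYS_PER_YEAR,
        "CD95int": init_cd95int * decay.T1,
        "CD95hi": init_cd95hi * decay.T2,
    })
    if bootstrap is not None:
        t1s, t2s = [], []
        for _, rep in bootstrap.replicates.iterrows():
            try:
                p = _params_from_record(fit.params, rep)
                d = yfv_frequency(p, t_days)
            except (ValueError, InfeasibleParameters):
                continue
            t1s.append(init_cd95int * d.T1)
            t2s.append(init_cd95hi * d.T2)
        if t1s:
            t1s, t2s = np.array(t1s), np.array(t2s)
            out["CD95int_lo"] = np.quantile(t1s, 0.025, axis=0)
            out["CD95int_hi"] = np.quantile(t1s, 0.975, axis=0)
            out["CD95hi_lo"] = np.quantile(t2s, 0.025, axis=0)
            out["CD95hi_hi"] = np.quantile(t2s, 0.975, axis=0)
    return out


def _params_from_record(template: KineticParams, rec) -> KineticParams:
    fields = {}
    for name in ("p_N", "p_1", "p_2", "delta_N", "delta_1", "k", "frac",
                 "dstar_N", "dstar_1", "dstar_2", "A"):
        if name in rec.index and np.isfinite(rec[name]):
            fields[name] = float(rec[name])
    return replace(template, A=1.0, **{k: v for k, v in fields.items() if k != "A"})
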