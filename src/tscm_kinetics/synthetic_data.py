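"""Synthetic studies with the statistical structure the analysis assumes.

Emulates the labelling protocol (full dose for 1 day, half dose to day 49,
washout, sampling to day 140, four analytic replicates per GC/MS point), the
5-donor telomere cohort and the 37-donor cross-sectional yellow-fever cohort
(0.27-35.02 years post-vaccination, four multiple-vaccinees flagged), so that
every stage of the pipeline can be exercised and validated without any
external data. Every generator is a pure function of (truth, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import EnrichmentSeries, MonocyteParams, SalivaModel, monocyte_trajectory
from .cohort_stats import DifferentiationProfile
from .inference import AuxData, StudyBundle
from .kinetic_models import KineticParams, label_trajectories, POOLS
from .observables import DAYS_PER_YEAR, TelomereSettings, telomere_theta, yfv_frequency

__all__ = [
    "StudyDesign",
    "default_truth",
    "default_saliva_truth",
    "default_monocyte_truth",
    "generate_study",
    "generate_yfv_cohort",
    "generate_telomere_cohort",
    "generate_aux_data",
    "generate_differentiation_counts",
]

# sampling grid: during labelling (to day 49) and washout, to day 140
_LABEL_DAYS = (4.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0, 63.0, 77.0, 98.0, 119.0, 140.0)
_SALIVA_DAYS = (0.5, 1.0, 2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0, 52.0, 56.0, 63.0, 77.0, 98.0)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout and noise levels of a simulated labelling study."""

    t_switch: float = 1.0
    t_end: float = 49.0
    saliva_days: tuple = _SALIVA_DAYS
    sample_days: tuple = _LABEL_DAYS
    replicates: int = 4
    label_noise_sd: float = 0.0005  # M+1 units per analytic replicate
    saliva_noise_sd: float = 0.0005
    monocyte_noise_sd: float = 0.002
    yfv_n: int = 37
    yfv_n_multiple: int = 4
    yfv_year_range: tuple = (0.27, 35.02)
    yfv_lognorm_sigma: float = 0.4  # multiplicative (natural-log) noise
    telomere_n: int = 5
    telomere_ages: tuple = (26.0, 31.0, 34.0, 41.0, 52.0)
    telomere_noise_sd_bp: float = 150.0
    master_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one analytic replicate")
        for name in ("label_noise_sd", "saliva_noise_sd", "monocyte_noise_sd",
                     "yfv_lognorm_sigma", "telomere_noise_sd_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def default_saliva_truth() -> SalivaModel:
    """Body-water plateau ~1.8% with ~6%/day water turnover."""
    return SalivaModel(f=0.018, delta=0.06)


def default_monocyte_truth() -> MonocyteParams:
    """Amplification factor ~5 and blood-monocyte disappearance ~0.7/day."""
    return MonocyteParams(b_w=5.2, r2=0.7)


def default_truth(model_id: str = "D") -> KineticParams:
    """Plausible ground truth at the rate scale of human T_SCM turnover.

    Naive inflow is scaled up (delta_N = 1e-6 rather than ~5e-9) so the
    differentiation flux is identifiable over a 140-day study; pool ratios
    R_1, R_2 are plausible flow-derived constants (per-donor inputs, not
    fitted quantities).
    """
    base = dict(p_N=0.00031, p_1=0.0008, p_2=0.002, R_1=0.05, R_2=0.01, A=0.03)
    if model_id == "A":
        return KineticParams(model_id="A", **base)
    if model_id == "B":
        return KineticParams(model_id="B", dstar_N=0.0005, dstar_1=0.0012,
                             dstar_2=0.003, **base)
    if model_id == "C":
        return KineticParams(model_id="C", delta_N=1e-6, k=10.3, frac=0.5, **base)
    if model_id in ("D", "E"):
        return KineticParams(model_id=model_id, delta_N=1e-6, delta_1=0.001,
                             k=10.3, **base)
    raise ValueError(f"unknown model {model_id!r}")


def _noisy_series(times, truth_values, noise_sd, replicates, rng, population):
    reps = truth_values[None, :] + noise_sd * rng.standard_normal(
        (replicates, truth_values.size)
    )
    values = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(values)
    return EnrichmentSeries(times=np.asarray(times, dtype=float), values=values,
                            sd=sd, population=population)


def generate_study(
    model_id: str,
    true_params: KineticParams,
    saliva_truth: SalivaModel,
    monocyte_truth: MonocyteParams,
    design: StudyDesign = StudyDesign(),
    seed: int | None = None,
    donor_id: str = "SIM01",
) -> StudyBundle:
    """Forward-simulate one donor's full labelling study.

    Saliva, monocyte and three-pool label series are generated from the
    forward models; each label point is the mean of ``design.replicates``
    noisy analytic replicates with the replicate SD recorded per point.
    """
    if true_params.model_id != model_id:
        raise ValueError("model_id does not match true_params.model_id")
    rng = np.random.default_rng(design.master_seed if seed is None else seed)

    saliva_days = np.asarray(design.saliva_days, dtype=float)
    s_true = saliva_truth(saliva_days)
    saliva = _noisy_series(saliva_days, s_true, design.saliva_noise_sd, 1, rng, "saliva")

    days = np.asarray(design.sample_days, dtype=float)
    mono_true = monocyte_trajectory(days, monocyte_truth, saliva_truth).values
    monocyte = _noisy_series(days, mono_true, design.monocyte_noise_sd,
                             design.replicates, rng, "monocytes")

    traj = label_trajectories(true_params, saliva_truth, monocyte_truth.b_w, days)
    labels = {
        pool: _noisy_series(days, traj[pool].values, design.label_noise_sd,
                            design.replicates, rng, pool)
        for pool in POOLS
    }
    return StudyBundle(
        donor_id=donor_id, saliva=saliva, monocyte=monocyte, labels=labels,
        R_1=true_params.R_1, R_2=true_params.R_2,
    )


def generate_yfv_cohort(
    true_params: KineticParams,
    design: StudyDesign = StudyDesign(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Cross-sectional antigen-specific frequencies vs years since vaccination.

    Sampling times are log-uniform over the cohort's range; observed
    frequencies carry multiplicative lognormal noise. Returns total (% of
    CD8) and per-subset frequencies, with ``design.yfv_n_multiple`` donors
    flagged as multiple vaccinees.
    """
    rng = np.random.default_rng(design.master_seed if seed is None else seed)
    lo, hi = design.yfv_year_range
    years = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=design.yfv_n)))
    decay = yfv_frequency(true_params, years * DAYS_PER_YEAR)
    noise = lambda n: np.exp(design.yfv_lognorm_sigma * rng.standard_normal(n))
    n = design.yfv_n
    multiple = np.zeros(n, dtype=bool)
    if design.yfv_n_multiple:
        multiple[rng.choice(n, size=min(design.yfv_n_multiple, n), replace=False)] = True
    return pd.DataFrame({
        "years": years,
        "frequency": decay.Y * noise(n),
        "frequency_cd95int": decay.T1 * noise(n),
        "frequency_cd95hi": decay.T2 * noise(n),
        "multiple_vaccination": multiple,
    })


def generate_telomere_cohort(
    true_params: KineticParams,
    design: StudyDesign = StudyDesign(),
    delta_tel: float = 50.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed telomere-length differences (bp) for the telomere donors."""
    rng = np.random.default_rng(design.master_seed if seed is None else seed)
    ages = np.asarray(design.telomere_ages, dtype=float)[: design.telomere_n]
    if ages.size < design.telomere_n:
        ages = np.concatenate([ages, np.linspace(25, 55, design.telomere_n - ages.size)])
    thetas = []
    for age in ages:
        settings = TelomereSettings(delta_tel=delta_tel, age_for_ab_years=age)
        method = "ode" if true_params.model_id in ("A", "B") else "algebraic"
        thetas.append(telomere_theta(true_params, settings, method=method))
    theta_obs = np.asarray(thetas) + design.telomere_noise_sd_bp * rng.standard_normal(
        ages.size
    )
    return pd.DataFrame({"age_years": ages, "theta_bp": theta_obs})


def generate_aux_data(
    true_params: KineticParams,
    design: StudyDesign = StudyDesign(),
    delta_tel: float = 50.0,
    seed: int | None = None,
) -> AuxData:
    """Telomere and YFV tables packaged for the joint fit."""
    base = design.master_seed if seed is None else seed
    tel = generate_telomere_cohort(true_params, design, delta_tel, seed=base + 1)
    yfv = generate_yfv_cohort(true_params, design, seed=base + 2)
    return AuxData(
        telomere=tel,
        yfv=yfv[["years", "frequency", "multiple_vaccination"]].copy(),
    )


def generate_differentiation_counts(
    true_proportions: dict[str, float],
    n_cells: int,
    seed: int = 0,
    source: str = "CD95int",
) -> DifferentiationProfile:
    """Multinomial divided-cell counts from true destination proportions."""
    labels = list(true_proportions)
    p = np.asarray([true_proportions[k] for k in labels], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("true proportions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p)
    table = dict(zip(labels, counts.astype(float)))
    table.setdefault(source, 0.0)
    return DifferentiationProfile(source=source, counts=table)
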