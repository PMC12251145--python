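"""IO, configuration and the end-to-end pipeline driver.

All tabular IO is plain CSV. Schemas:

- saliva.csv:    donor_id, day, enrichment
- monocyte.csv:  donor_id, day, enrichment, sd
- labels.csv:    donor_id, day, population, enrichment, sd
- telomere.csv:  age_years, theta_bp
- yfv.csv:       years, frequency, multiple_vaccination
- constants: per-donor R_1/R_2 in the config file

Outputs are a parameter table (one row per donor/model with rates,
half-lives and residency times), a JSON fit report stamped with the config
hash and master seed, and optional diagnostic plots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import EnrichmentSeries
from .inference import (
    AuxData,
    FitConfig,
    StudyBundle,
    bootstrap_fit,
    calibrate_bundle,
    compare_models,
    fit_model,
)
from .kinetic_models import POOLS
from .observables import clonal_half_lives, residency_times

__all__ = ["RunConfig", "SchemaError", "load_tables", "write_report", "run_all",
           "read_s1_workbook"]

log = logging.getLogger("tscm_kinetics")


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    data_dir: str = "."
    output_dir: str = "results"
    models: tuple = ("C", "D", "E")
    donors: dict = field(default_factory=dict)  # donor_id -> {"R_1": .., "R_2": ..}
    n_starts: int = 30
    n_boot: int = 100
    master_seed: int = 0
    m_over_b: float = 2.6
    delay_days: float = 1.6
    t_switch: float = 1.0
    t_end: float = 49.0
    delta_tel: float = 50.0
    age_for_ab_years: float = 34.0
    exclude_multiple_vaccination: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require_columns(df: pd.DataFrame, cols, name: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}; found {list(df.columns)}")
    for c in cols:
        if c in ("donor_id", "population"):
            continue
        bad = df[~np.isfinite(pd.to_numeric(df[c], errors="coerce"))]
        if len(bad):
            raise SchemaError(
                f"{name}: non-numeric value in column {c!r} at row(s) "
                f"{bad.index.tolist()[:5]}"
            )


def _series_from_rows(rows: pd.DataFrame, population: str) -> EnrichmentSeries:
    rows = rows.sort_values("day")
    sd = rows["sd"].to_numpy(dtype=float) if "sd" in rows.columns else None
    return EnrichmentSeries(
        times=rows["day"].to_numpy(dtype=float),
        values=rows["enrichment"].to_numpy(dtype=float),
        sd=sd,
        population=population,
    )


def load_tables(config: RunConfig) -> tuple[list[StudyBundle], AuxData]:
    """Read the study CSVs and assemble per-donor bundles plus shared data."""
    d = Path(config.data_dir)
    saliva = pd.read_csv(d / "saliva.csv")
    monocyte = pd.read_csv(d / "monocyte.csv")
    labels = pd.read_csv(d / "labels.csv")
    telomere = pd.read_csv(d / "telomere.csv")
    yfv = pd.read_csv(d / "yfv.csv")

    _require_columns(saliva, ("donor_id", "day", "enrichment"), "saliva.csv")
    _require_columns(monocyte, ("donor_id", "day", "enrichment"), "monocyte.csv")
    _require_columns(labels, ("donor_id", "day", "population", "enrichment"), "labels.csv")
    _require_columns(telomere, ("age_years", "theta_bp"), "telomere.csv")
    _require_columns(yfv, ("years", "frequency"), "yfv.csv")

    bundles = []
    for donor_id, constants in config.donors.items():
        if "R_1" not in constants or "R_2" not in constants:
            raise SchemaError(f"donor {donor_id}: config must give R_1 and R_2")
        lab = labels[labels["donor_id"] == donor_id]
        pools = {}
        for pool in POOLS:
            rows = lab[lab["population"] == pool]
            if rows.empty:
                raise SchemaError(f"donor {donor_id}: no label rows for pool {pool!r}")
            pools[pool] = _series_from_rows(rows, pool)
        bundles.append(StudyBundle(
            donor_id=donor_id,
            saliva=_series_from_rows(saliva[saliva["donor_id"] == donor_id], "saliva"),
            monocyte=_series_from_rows(
                monocyte[monocyte["donor_id"] == donor_id], "monocytes"
            ),
            labels=pools,
            R_1=float(constants["R_1"]),
            R_2=float(constants["R_2"]),
        ))
    aux = AuxData(telomere=telomere, yfv=yfv)
    return bundles, aux


def write_bundle_csvs(bundle: StudyBundle, aux: AuxData | None, out_dir):
    """Write a bundle (and optional shared data) in the input CSV schemas."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "donor_id": bundle.donor_id,
        "day": bundle.saliva.times,
        "enrichment": bundle.saliva.values,
    }).to_csv(out / "saliva.csv", index=False)
    pd.DataFrame({
        "donor_id": bundle.donor_id,
        "day": bundle.monocyte.times,
        "enrichment": bundle.monocyte.values,
        "sd": bundle.monocyte.sd if bundle.monocyte.sd is not None else np.nan,
    }).to_csv(out / "monocyte.csv", index=False)
    rows = []
    for pool in POOLS:
        s = bundle.labels[pool]
        for i in range(len(s)):
            rows.append({
                "donor_id": bundle.donor_id, "day": s.times[i], "population": pool,
                "enrichment": s.values[i],
                "sd": s.sd[i] if s.sd is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    if aux is not None:
        aux.telomere.to_csv(out / "telomere.csv", index=False)
        aux.yfv.to_csv(out / "yfv.csv", index=False)


def _fit_row(donor_id, fit, boot=None):
    p = fit.params
    row = {
        "donor_id": donor_id, "model": fit.model_id, "objective": fit.objective,
        "p_N": p.p_N, "p_1": p.p_1, "p_2": p.p_2,
        "delta_N": p.delta_N, "delta_1": p.delta_1, "k": p.k, "frac": p.frac,
        "A": p.A,
    }
    if fit.model_id in ("C", "D", "E"):
        t1, t2 = clonal_half_lives(p)
        row["half_life_CD95int"] = t1
        row["half_life_CD95hi"] = t2
        if fit.model_id == "D":
            r1, r2 = residency_times(p)
            row["residency_CD95int"] = r1
            row["residency_CD95hi"] = r2
    if boot is not None:
        for key, med in boot.median.items():
            row[f"{key}_boot_median"] = med
            row[f"{key}_iqr_low"] = boot.iqr_low[key]
            row[f"{key}_iqr_high"] = boot.iqr_high[key]
    return row


def write_report(results: list[dict], config: RunConfig, out_dir=None) -> Path:
    """Write the parameter CSV and JSON fit report; returns the output dir."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [_fit_row(r["donor_id"], r["fit"], r.get("bootstrap")) for r in results]
    pd.DataFrame(rows).to_csv(out / "parameters.csv", index=False)
    report = {
        "config_digest": config.digest(),
        "master_seed": config.master_seed,
        "fits": [
            {
                "donor_id": r["donor_id"],
                "model": r["fit"].model_id,
                "objective": r["fit"].objective,
                "blocks": r["fit"].blocks,
                "params": {k: v for k, v in zip(
                    r["fit"].param_names,
                    [float(x) for x in r["fit"].x],
                )},
                "converged": r["fit"].converged,
            }
            for r in results
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if config.make_plots:
        _plot_fits(results, out)
    return out


def _plot_fits(results, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinetic_models import label_trajectories

    for r in results:
        fit, bundle = r["fit"], r.get("bundle")
        if bundle is None or not bundle.calibrated or fit.label_only:
            continue
        t = np.linspace(0, 140, 200)
        traj = label_trajectories(fit.params, bundle.saliva_model,
                                  bundle.monocyte_params.b_w, t)
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=False)
        for ax, pool in zip(axes, POOLS):
            obs = bundle.labels[pool]
            ax.errorbar(obs.times, obs.values, yerr=obs.sd, fmt="ko", ms=3)
            ax.plot(t, traj[pool].values, "-")
            ax.set_title(pool)
            ax.set_xlabel("day")
        axes[0].set_ylabel("M+1 enrichment")
        fig.suptitle(f"{r['donor_id']} model {fit.model_id}")
        fig.tight_layout()
        fig.savefig(out / f"fit_{r['donor_id']}_{fit.model_id}.png", dpi=120)
        plt.close(fig)


def run_all(config: RunConfig) -> list[dict]:
    """Calibrate, fit and (optionally) bootstrap every donor and model."""
    bundles, aux = load_tables(config)
    fit_cfg = FitConfig(
        exclude_multiple_vaccination=config.exclude_multiple_vaccination,
    )
    results = []
    for bundle in bundles:
        log.info("calibrating donor %s", bundle.donor_id)
        bundle = calibrate_bundle(bundle)
        for model in config.models:
            log.info("fitting model %s for donor %s", model, bundle.donor_id)
            fit = fit_model(model, bundle, aux, n_starts=config.n_starts,
                            master_seed=config.master_seed, config=fit_cfg)
            entry = {"donor_id": bundle.donor_id, "fit": fit, "bundle": bundle}
            if config.n_boot > 0 and model in ("C", "D", "E"):
                entry["bootstrap"] = bootstrap_fit(
                    model, bundle, aux, n_boot=config.n_boot,
                    master_seed=config.master_seed, n_starts=max(2, config.n_starts // 5),
                    point_fit=fit, config=fit_cfg,
                )
            results.append(entry)
    write_report(results, config)
    return results


def read_s1_workbook(path) -> dict[str, pd.DataFrame]:
    """Read a local copy of the study's underlying-data workbook (xlsx).

    Returns one DataFrame per sheet; mapping sheets onto the CSV schemas
    above is left to the caller because the workbook layout groups tabs by
    figure rather than by data type.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: the underlying-data workbook is not distributed with this "
            "package; supply a local copy"
        )
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    return sheets
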