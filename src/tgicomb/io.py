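"""File formats and the reproducible command-line workflow.

Plain-text formats only: YAML (or JSON) configuration, CSV for tabular data,
JSON for machine-readable results.  Every output embeds the seed and a hash of
the configuration it was produced from, and reruns of the same configuration
produce identical files.

Dataset CSV columns: arm_id, arm_type, time_days, mean_weight_g, se_g.
Regimen CSV columns: drug_id, time_days, dose_umol_per_kg, route.

Configuration layout (YAML or JSON)::

    seed: 1
    pk:
      "Drug C2": {central_volume: 5.0, elimination_rate: 8.0,
                  absorption_rate: 12.0, bioavailability: 0.8}
      "CPT-11":  {central_volume: 4.0, elimination_rate: 8.0,
                  n_compartments: 2, k12: 5.0, k21: 2.5}
    arms:
      combination:
        regimens:
          "Drug C2": [{time: 10, amount: 84.5, route: oral}, ...]
          "CPT-11":  [{time: 9,  amount: 72.9, route: iv_bolus}, ...]
    solver: {rtol: 1.0e-8, atol: 1.0e-10}
    parameters:            # optional: enables simulation-only mode / prediction
      w0: 0.05
      ...
      gamma: 0.8
    predict:               # optional: extra regimen set to predict after fitting
      regimens: {...}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import ArmType, CombinationTGIModel, TumorArm, TumorDataset
from .exceptions import ConfigurationError
from .models import (CombinationModelSpec, DrugEffectParameters,
                     TumorGrowthParameters)
from .pk import DoseEvent, DosingRegimen, PKParameters, Route

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_regimens_csv",
    "write_regimens_csv",
    "regimen_to_dicts",
    "regimen_from_dicts",
    "pk_from_dict",
    "pk_to_dict",
    "load_config",
    "config_hash",
    "spec_from_parameters",
    "run_pipeline",
]

DATASET_COLUMNS = ("arm_id", "arm_type", "time_days", "mean_weight_g", "se_g")
REGIMEN_COLUMNS = ("drug_id", "time_days", "dose_umol_per_kg", "route")


# ---------------------------------------------------------------------------
# datasets


def read_dataset(path, config: dict | None = None) -> TumorDataset:
    """Read a dataset CSV; arm regimens and the PK library come from ``config``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"dataset {path} is missing column(s): {missing}")
    pk_library = {}
    arm_regimens: dict[str, dict[str, DosingRegimen]] = {}
    if config:
        pk_library = {d: pk_from_dict(v) for d, v in config.get("pk", {}).items()}
        for arm_id, arm_cfg in config.get("arms", {}).items():
            arm_regimens[arm_id] = {
                d: regimen_from_dicts(d, evs)
                for d, evs in (arm_cfg or {}).get("regimens", {}).items()
            }
    arms = []
    for arm_id, grp in df.groupby("arm_id", sort=False):
        grp = grp.sort_values("time_days")
        arms.append(TumorArm(
            arm_id=str(arm_id),
            arm_type=ArmType(grp["arm_type"].iloc[0]),
            regimens=arm_regimens.get(str(arm_id), {}),
            times=grp["time_days"].to_numpy(float),
            weights=grp["mean_weight_g"].to_numpy(float),
            ses=grp["se_g"].to_numpy(float),
        ))
    return TumorDataset(tuple(arms), pk_library)


def write_dataset(dataset: TumorDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regimens and PK


def regimen_to_dicts(regimen: DosingRegimen) -> list[dict]:
    return [{"time": e.time, "amount": e.amount, "route": e.route.value}
            for e in regimen.events]


def regimen_from_dicts(drug_id: str, events: list[dict]) -> DosingRegimen:
    return DosingRegimen(drug_id, tuple(
        DoseEvent(float(e["time"]), float(e["amount"]), Route(e.get("route", "iv_bolus")))
        for e in events))


def read_regimens_csv(path) -> dict[str, DosingRegimen]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REGIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"regimen file {path} is missing column(s): {missing}")
    out = {}
    for drug_id, grp in df.groupby("drug_id", sort=False):
        grp = grp.sort_values("time_days")
        out[str(drug_id)] = DosingRegimen(str(drug_id), tuple(
            DoseEvent(float(r.time_days), float(r.dose_umol_per_kg), Route(r.route))
            for r in grp.itertuples()))
    return out


def write_regimens_csv(regimens: dict[str, DosingRegimen], path) -> None:
    rows = [{"drug_id": d, "time_days": e.time, "dose_umol_per_kg": e.amount,
             "route": e.route.value}
            for d, reg in regimens.items() for e in reg.events]
    pd.DataFrame(rows, columns=list(REGIMEN_COLUMNS)).to_csv(path, index=False)


def pk_from_dict(d: dict) -> PKParameters:
    return PKParameters(**d)


def pk_to_dict(pk: PKParameters) -> dict:
    out = dataclasses.asdict(pk)
    return {k: v for k, v in out.items() if v is not None}


# ---------------------------------------------------------------------------
# config


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    text = Path(path_or_dict).read_text()
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def spec_from_parameters(params: dict, psi: float = 20.0) -> CombinationModelSpec:
    return CombinationModelSpec(
        growth=TumorGrowthParameters(params["w0"], params["lambda0"], params["lambda1"],
                                     psi=params.get("psi", psi)),
        drug_a=DrugEffectParameters(params["k1a"], params["k2a"]),
        drug_b=DrugEffectParameters(params["k1b"], params["k2b"]),
        gamma=params.get("gamma", 0.0),
    )


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config, data_path=None, outdir="tgicomb_out") -> dict:
    """Stage 1 -> stage 2 -> indexes -> optional prediction, with files on disk.

    ``config`` is a path or dict (see module docstring); ``data_path`` the
    dataset CSV (may also be given as ``config['data']``).  If ``parameters``
    (including gamma) are supplied in the config, the fitting stages are
    skipped and the pipeline runs in simulation mode.  Returns the report
    bundle that was written.
    """
    cfg = load_config(config)
    chash = config_hash(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data_path = data_path or cfg.get("data")

    meta = {"config_hash": chash, "seed": seed, "tgicomb_version": __version__,
            "python": platform.python_version(),
            "solver": cfg.get("solver", {"rtol": 1e-8, "atol": 1e-10})}
    report: dict = {"meta": meta}

    if cfg.get("parameters", {}).get("gamma") is not None and data_path is None:
        # simulation-only mode: no data, no fitting
        from . import indexes as _indexes
        from .pk import concentration_profile
        spec = spec_from_parameters(cfg["parameters"])
        pk_library = {d: pk_from_dict(v) for d, v in cfg.get("pk", {}).items()}
        arm_cfg = next(iter(cfg["arms"].values()))
        regs = {d: regimen_from_dicts(d, evs)
                for d, evs in arm_cfg["regimens"].items()}
        drug_a, drug_b = cfg.get("drug_a"), cfg.get("drug_b")
        if drug_a is None or drug_b is None:
            drug_a, drug_b = sorted(regs)
        conc_a = concentration_profile(pk_library[drug_a], regs[drug_a])
        conc_b = concentration_profile(pk_library[drug_b], regs[drug_b])
        idx = _indexes.combination_indexes(spec, conc_a, conc_b, method="closed_form")
        report["indexes"] = idx.to_dict()
        report["mode"] = "simulate"
        _dump_json({**report["indexes"], **meta}, out / "indexes.json")
        _dump_json(report, out / "pipeline_log.json")
        return report

    if data_path is None:
        raise ConfigurationError("run_pipeline needs a dataset CSV unless gamma is fixed "
                                 "in config['parameters'] (simulation mode)")
    dataset = read_dataset(data_path, cfg)
    model = CombinationTGIModel(dataset, drug_a=cfg.get("drug_a"), drug_b=cfg.get("drug_b"))
    staged = model.fit(seed=seed, n_starts=int(cfg.get("n_starts", 8)))
    report["mode"] = "fit"
    report["fit_single"] = {**staged.single_agent.to_dict(), **meta}
    report["fit_gamma"] = {**staged.interaction.to_dict(), **meta}
    _dump_json(report["fit_single"], out / "fit_single.json")
    _dump_json(report["fit_gamma"], out / "fit_gamma.json")

    idx = staged.interaction_indexes()
    report["indexes"] = {**idx.to_dict(), **meta}
    _dump_json(report["indexes"], out / "indexes.json")

    for arm_id, traj in staged.interaction.fitted_curves.items():
        traj.to_csv(out / f"curve_{arm_id}.csv")
    for arm_id, traj in staged.single_agent.fitted_curves.items():
        traj.to_csv(out / f"curve_{arm_id}.csv")

    if "predict" in cfg:
        regs = {d: regimen_from_dicts(d, evs)
                for d, evs in cfg["predict"]["regimens"].items()}
        horizon = float(cfg["predict"].get("horizon",
                                           max(a.times[-1] for a in dataset.arms)))
        times = np.linspace(0.0, horizon, 241)
        traj, pidx = staged.predict(regs, times)
        traj.to_csv(out / "predicted_curve.csv")
        report["prediction"] = {**pidx.to_dict(), **meta}
        _dump_json(report["prediction"], out / "predicted_indexes.json")

    _dump_json(report, out / "pipeline_log.json")
    return report
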