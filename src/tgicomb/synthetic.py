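"""Synthetic xenograft combination experiments with known ground truth.

The raw animal data behind published combination TGI analyses live in figures,
not repositories, so every estimation stage in this package is exercised on
simulated experiments instead: per-arm true mean curves come from the ODE
models, per-animal observations are drawn with proportional (constant-CV)
noise, and group mean +/- SE is reported exactly as a tumor-growth table would
be.  Proportional noise is the deliberate choice because the estimator weights
residuals by 1/y^2 (constant relative error); n = 8 animals per group and
sampling every ~3 days from day 8 to day 41 mirror common xenograft practice.

``experiment_fixture`` returns the published dosing schedules (drug, route,
uM/kg dose, administration days) of the eleven explored combination arms, so a
realistic design is always one call away.  The PK parameter values and the
tumor/drug effect parameters shipped here (``example_pk_library``,
``example_model_spec``) are plausible synthetic placeholders chosen for
realistic mouse-PK magnitudes -- they are NOT estimates from any real
experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import models as _models
from .estimation import ArmType, TumorArm, TumorDataset
from .exceptions import ValidationError
from .models import (CombinationModelSpec, DrugEffectParameters,
                     TumorGrowthParameters)
from .pk import DosingRegimen, PKParameters, Route, concentration_profile

__all__ = [
    "NoiseModel",
    "ExperimentFixture",
    "generate_tumor_dataset",
    "generate_experiment",
    "experiment_fixture",
    "FIXTURE_NAMES",
    "example_pk_library",
    "example_model_spec",
    "default_sample_times",
]

logger = logging.getLogger(__name__)

#: floor for truncated negative animal-level draws (g)
WEIGHT_FLOOR = 1e-4


@dataclass(frozen=True)
class NoiseModel:
    """Proportional observation noise: obs = truth * (1 + cv*N(0,1)) per animal."""

    cv: float = 0.10
    n_animals: int = 8
    seed: int = 0
    type: str = "proportional"

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.type != "proportional":
            raise ValidationError("only proportional noise is supported")


def default_sample_times() -> np.ndarray:
    """Every 3 days from day 8 to day 41 (12 measurement occasions)."""
    return np.arange(8.0, 42.0, 3.0)


def _true_curve(spec: CombinationModelSpec, arm_type: ArmType,
                regimens: dict[str, DosingRegimen], pk_library, drug_a, drug_b,
                times, rtol, atol) -> np.ndarray:
    grid = np.unique(np.concatenate([[0.0], np.asarray(times, float)]))

    def prof(drug):
        if drug in regimens:
            return concentration_profile(pk_library[drug], regimens[drug])
        from .pk import ConcentrationProfile
        return ConcentrationProfile.zero()

    if arm_type is ArmType.control:
        traj = _models.unperturbed_growth(spec.growth, grid, rtol=rtol, atol=atol)
    elif arm_type is ArmType.single_a:
        traj = _models.simulate_single_agent(spec.growth, spec.drug_a, prof(drug_a),
                                             grid, rtol=rtol, atol=atol)
    elif arm_type is ArmType.single_b:
        traj = _models.simulate_single_agent(spec.growth, spec.drug_b, prof(drug_b),
                                             grid, rtol=rtol, atol=atol)
    else:
        traj = _models.simulate_combination(spec, prof(drug_a), prof(drug_b),
                                            grid, rtol=rtol, atol=atol)
    return np.interp(times, traj.times, traj.total)


def generate_tumor_dataset(spec: CombinationModelSpec,
                           arm_plan: dict[str, tuple[ArmType | str, dict[str, DosingRegimen]]],
                           pk_library: dict[str, PKParameters], times, noise: NoiseModel,
                           *, drug_a: str, drug_b: str,
                           rtol=1e-8, atol=1e-10) -> tuple[TumorDataset, dict]:
    """Simulate a multi-arm experiment; returns (dataset, truth).

    ``arm_plan`` maps arm_id -> (arm_type, regimens).  ``truth`` records the
    generating parameters and each arm's noise-free mean curve.  With cv = 0
    the reported group means equal the model truth exactly and all SEs are 0.
    Reproducible for a fixed ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(times, dtype=float)
    arms, truth_curves = [], {}
    n_truncated = 0
    for arm_id, (arm_type, regimens) in arm_plan.items():
        arm_type = ArmType(arm_type)
        mu = _true_curve(spec, arm_type, regimens, pk_library, drug_a, drug_b,
                         times, rtol, atol)
        truth_curves[arm_id] = mu.copy()
        if noise.cv == 0:
            mean, se = mu, np.zeros_like(mu)
        else:
            draws = mu[None, :] * (1.0 + noise.cv * rng.standard_normal((noise.n_animals, mu.size)))
            n_truncated += int((draws < WEIGHT_FLOOR).sum())
            draws = np.maximum(draws, WEIGHT_FLOOR)
            mean = draws.mean(axis=0)
            se = (draws.std(axis=0, ddof=1) / np.sqrt(noise.n_animals)
                  if noise.n_animals > 1 else np.zeros_like(mu))
        arms.append(TumorArm(arm_id=arm_id, arm_type=arm_type, regimens=regimens,
                             times=times, weights=mean, ses=se))
    if n_truncated:
        logger.info("truncated %d negative animal-level draws at %.0e g",
                    n_truncated, WEIGHT_FLOOR)
    truth = {
        "gamma": spec.gamma,
        "params": {
            "w0": spec.growth.w0, "lambda0": spec.growth.lambda0,
            "lambda1": spec.growth.lambda1, "psi": spec.growth.psi,
            "k1a": spec.drug_a.k1, "k2a": spec.drug_a.k2,
            "k1b": spec.drug_b.k1, "k2b": spec.drug_b.k2,
        },
        "curves": truth_curves,
        "n_truncated": n_truncated,
        "noise": {"cv": noise.cv, "n_animals": noise.n_animals, "seed": noise.seed},
    }
    return TumorDataset(tuple(arms), pk_library), truth


def generate_experiment(spec: CombinationModelSpec, regimen_a: DosingRegimen,
                        regimen_b: DosingRegimen, pk_library, *, times=None,
                        noise: NoiseModel | None = None,
                        rtol=1e-8, atol=1e-10) -> tuple[TumorDataset, dict]:
    """Standard four-arm design: control, each single agent, and the combination,
    all on the same schedules."""
    times = default_sample_times() if times is None else times
    noise = NoiseModel() if noise is None else noise
    a, b = regimen_a.drug_id, regimen_b.drug_id
    plan = {
        "control": (ArmType.control, {}),
        f"single_{a}": (ArmType.single_a, {a: regimen_a}),
        f"single_{b}": (ArmType.single_b, {b: regimen_b}),
        "combination": (ArmType.combination, {a: regimen_a, b: regimen_b}),
    }
    return generate_tumor_dataset(spec, plan, pk_library, times, noise,
                                  drug_a=a, drug_b=b, rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# published schedule fixtures


@dataclass(frozen=True)
class ExperimentFixture:
    """One published combination arm: its two dosing regimens."""

    name: str
    cell_line: str
    regimen_a: DosingRegimen
    regimen_b: DosingRegimen

    @property
    def drug_a(self) -> str:
        return self.regimen_a.drug_id

    @property
    def drug_b(self) -> str:
        return self.regimen_b.drug_id

    @property
    def regimens(self) -> dict[str, DosingRegimen]:
        return {self.drug_a: self.regimen_a, self.drug_b: self.regimen_b}


_TRIPLE_CYCLE = [t for c in (10, 14, 18) for t in np.arange(c, c + 3, 0.5)]


def _fixtures() -> dict[str, ExperimentFixture]:
    iv, po = Route.iv_bolus, Route.oral
    R = DosingRegimen.from_times
    # Drug C5 daily days 9-16, pushed 6 h (0.25 d) later on the days it is
    # co-administered with CPT-11 (days 12 and 16)
    c5_days = [9, 10, 11, 12.25, 13, 14, 15, 16.25]
    f = {
        "a1": ("BxPC3", R("Drug C1", _TRIPLE_CYCLE, 29.4, iv),
               R("Gemcitabine", [9, 13, 17], 267.0, iv)),
        "b1": ("A2780", R("Drug C1", np.arange(8.0, 13.0, 0.5), 58.7, iv),
               R("Cisplatin", [13], 26.7, iv)),
        "b2": ("A2780", R("Drug C1", np.arange(9.0, 14.0, 0.5), 58.7, iv),
               R("Cisplatin", [8], 26.7, iv)),
        "c1": ("HT29", R("Drug C2", [10, 11, 12, 14, 15, 16], 84.5, po),
               R("CPT-11", [9, 13, 17], 72.9, iv)),
        "c2": ("HT29", R("Drug C2", [10, 11, 12, 14, 15, 16], 113.0, po),
               R("CPT-11", [9, 13, 17], 72.9, iv)),
        "d1": ("HT29", R("Drug C2", [10, 11, 12, 14, 15, 16], 84.5, po),
               R("5-FU", [9, 13, 17], 384.0, iv)),
        "d2": ("HT29", R("Drug C2", [10, 11, 12, 14, 15, 16], 113.0, po),
               R("5-FU", [9, 13, 17], 384.0, iv)),
        "e1": ("BxPC3", R("Drug C4", _TRIPLE_CYCLE, 37.5, po),
               R("Gemcitabine", [9, 13, 17], 267.0, iv)),
        "e2": ("BxPC3", R("Drug C4", _TRIPLE_CYCLE, 75.0, po),
               R("Gemcitabine", [9, 13, 17], 267.0, iv)),
        "f1": ("HT29", R("Drug C5", c5_days, 25.1, iv),
               R("CPT-11", [8, 12, 16], 72.9, iv)),
        "f2": ("HT29", R("Drug C5", c5_days, 50.3, iv),
               R("CPT-11", [8, 12, 16], 72.9, iv)),
    }
    return {name: ExperimentFixture(name, cell, ra, rb)
            for name, (cell, ra, rb) in f.items()}


FIXTURE_NAMES = tuple(sorted(_fixtures()))


def experiment_fixture(name: str) -> ExperimentFixture:
    """Published schedule and uM/kg doses for one combination arm (a1..f2)."""
    fixtures = _fixtures()
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; valid names: {', '.join(sorted(fixtures))}")
    return fixtures[name]


def example_pk_library(*drug_ids: str) -> dict[str, PKParameters]:
    """Plausible synthetic mouse PK parameters for the fixture drugs.

    These are placeholders with realistic magnitudes (half-lives of hours,
    volumes of a few L/kg), NOT published estimates; real analyses must supply
    their own PK configuration.
    """
    lib = {
        "Drug C1": PKParameters(central_volume=5.0, elimination_rate=10.0),
        "Drug C2": PKParameters(central_volume=5.0, elimination_rate=8.0,
                                absorption_rate=12.0, bioavailability=0.8),
        "Drug C4": PKParameters(central_volume=4.0, elimination_rate=9.0,
                                absorption_rate=10.0, bioavailability=0.7),
        "Drug C5": PKParameters(central_volume=5.0, elimination_rate=12.0),
        "Gemcitabine": PKParameters(central_volume=2.0, elimination_rate=15.0),
        "Cisplatin": PKParameters(central_volume=1.0, elimination_rate=6.0,
                                  n_compartments=2, k12=3.0, k21=1.5),
        "CPT-11": PKParameters(central_volume=4.0, elimination_rate=8.0,
                               n_compartments=2, k12=5.0, k21=2.5),
        "5-FU": PKParameters(central_volume=2.5, elimination_rate=25.0),
    }
    if not drug_ids:
        return lib
    return {d: lib[d] for d in drug_ids}


def example_model_spec(gamma: float = 0.8) -> CombinationModelSpec:
    """Plausible ground-truth PD parameters for simulation studies.

    Chosen once for a realistic xenograft picture: exponential-to-linear
    switch around day 23 in controls, single-agent growth delays of ~5 days,
    and an interaction shift of ~10 days at the default gamma.
    """
    return CombinationModelSpec(
        growth=TumorGrowthParameters(w0=0.05, lambda0=0.15, lambda1=0.25, psi=20.0),
        drug_a=DrugEffectParameters(k1=0.9, k2=0.08),
        drug_b=DrugEffectParameters(k1=1.4, k2=0.06),
        gamma=gamma,
    )
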