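"""Staged weighted least-squares identification of the combination TGI model.

The estimation strategy mirrors standard preclinical practice: first the seven
single-agent parameters (w0, lambda0, lambda1, k1a, k2a, k1b, k2b) are fitted
simultaneously to the control and single-agent arms, sharing the tumor-related
parameters across arms; then, with those fixed, the single interaction
parameter gamma is fitted to the control and combination arms.  A joint
8-parameter fit is available for comparison but is not the default path, since
the staged route concentrates all the interaction information in gamma.

Weighting: residuals are scaled by 1/y_observed (weights 1/y^2 in the squared
objective, i.e. constant relative error) and each arm's contribution is divided
by its observation count so that every arm carries the same weight regardless
of sampling density:

    objective = sum_arms (1/n_arm) * sum_obs ((y - yhat)^2 / y^2)

Uncertainties are asymptotic: covariance s^2 (J'J)^-1 from the Jacobian of the
scaled residuals at the optimum, reported as CV% = 100*se/|estimate|.  RMSE is
reported unweighted in grams over the arm(s) being fitted.

The API follows the model/results idiom: build a :class:`CombinationTGIModel`
from a :class:`TumorDataset`, call ``fit()`` (staged), ``fit_single_agents()``,
``fit_interaction()`` or ``fit_joint()``, and read estimates, CV%, RMSE and
``summary()`` off the returned results object.  ``StagedFitResult.predict``
simulates a new dose/schedule combination arm from the fitted parameters and
scores its predicted interaction indexes without any refitting.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import indexes as _indexes
from . import models as _models
from .exceptions import (ConfigurationError, ModelValidityWarning,
                         NonIdentifiableError, ValidationError)
from .models import (CombinationModelSpec, DrugEffectParameters, StateTrajectory,
                     TumorGrowthParameters)
from .pk import DosingRegimen, PKParameters, concentration_profile

__all__ = [
    "ArmType",
    "TumorArm",
    "TumorDataset",
    "CombinationTGIModel",
    "TGIFitResult",
    "StagedFitResult",
    "wls_objective",
    "parameter_cv",
    "rmse",
    "predict_combination_arm",
]

STAGE1_NAMES = ("w0", "lambda0", "lambda1", "k1a", "k2a", "k1b", "k2b")
PARAM_UNITS = {
    "w0": "g", "lambda0": "1/day", "lambda1": "g/day",
    "k1a": "1/day", "k2a": "1/(uM day)", "k1b": "1/day", "k2b": "1/(uM day)",
    "gamma": "1/(uM^2 day^2)",
}
DEFAULT_BOUNDS = {
    "w0": (1e-4, 2.0), "lambda0": (0.005, 2.0), "lambda1": (0.005, 10.0),
    "k1a": (0.02, 50.0), "k2a": (1e-5, 100.0), "k1b": (0.02, 50.0), "k2b": (1e-5, 100.0),
}
GAMMA_BOUNDS = (-100.0, 100.0)


class ArmType(str, enum.Enum):
    control = "control"
    single_a = "single_a"
    single_b = "single_b"
    combination = "combination"


@dataclass(frozen=True)
class TumorArm:
    """One treatment group: regimens plus (time, mean weight, SE) observations."""

    arm_id: str
    arm_type: ArmType
    regimens: dict[str, DosingRegimen]
    times: np.ndarray
    weights: np.ndarray
    ses: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "arm_type", ArmType(self.arm_type))
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        s = np.asarray(self.ses, dtype=float)
        if not (t.shape == w.shape == s.shape) or t.ndim != 1:
            raise ValidationError(f"arm {self.arm_id!r}: times/weights/ses must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"arm {self.arm_id!r}: observation times must be strictly increasing")
        if np.any(w <= 0):
            raise ValidationError(f"arm {self.arm_id!r}: tumor weights must be > 0 (1/y^2 weights)")
        if np.any(s < 0):
            raise ValidationError(f"arm {self.arm_id!r}: standard errors must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "ses", s)

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TumorDataset:
    """All arms of one combination experiment plus the per-drug PK library."""

    arms: tuple[TumorArm, ...]
    pk_library: dict[str, PKParameters] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(self.arms))
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate arm_id in dataset")
        for arm in self.arms:
            for drug_id in arm.regimens:
                if drug_id not in self.pk_library:
                    raise ConfigurationError(
                        f"arm {arm.arm_id!r} doses drug {drug_id!r} which is missing "
                        "from the PK library")

    def arm(self, arm_id: str) -> TumorArm:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    def by_type(self, arm_type: ArmType | str) -> list[TumorArm]:
        arm_type = ArmType(arm_type)
        return [a for a in self.arms if a.arm_type is arm_type]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            for t, w, s in zip(a.times, a.weights, a.ses):
                rows.append({"arm_id": a.arm_id, "arm_type": a.arm_type.value,
                             "time_days": t, "mean_weight_g": w, "se_g": s})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective pieces


def wls_objective(dataset: TumorDataset, evaluate, params) -> float:
    """Per-arm-normalized weighted SSR: sum_arms mean_obs ((y-yhat)^2/y^2).

    ``evaluate(arm, params)`` must return predicted mean weights at the arm's
    observation times.  Two arms with identical relative misfit contribute
    equally regardless of how many observations each carries.
    """
    total = 0.0
    for arm in dataset.arms:
        yhat = np.asarray(evaluate(arm, params), dtype=float)
        total += float(np.mean(((arm.weights - yhat) / arm.weights) ** 2))
    return total


def _scaled_residuals(arms: list[TumorArm], preds: list[np.ndarray]) -> np.ndarray:
    """Residual vector r with sum(r^2) equal to the per-arm-normalized WLS objective."""
    parts = [(a.weights - p) / (a.weights * np.sqrt(a.n_obs)) for a, p in zip(arms, preds)]
    return np.concatenate(parts)


def rmse(observed, predicted) -> float:
    """Unweighted root-mean-square error in grams."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def parameter_cv(jacobian: np.ndarray, residuals: np.ndarray, estimates: np.ndarray):
    """Asymptotic per-parameter CV% from the scaled-residual Jacobian.

    covariance = s^2 (J'J)^-1 with s^2 = SSR/(N-p).  Returns (cv_percent, se,
    cov, ok); a rank-deficient Jacobian yields NaN CVs and ok=False rather than
    an exception, so callers can surface the diagnostic.
    """
    J = np.asarray(jacobian, dtype=float)
    r = np.asarray(residuals, dtype=float)
    theta = np.asarray(estimates, dtype=float)
    n, p = J.shape
    dof = max(n - p, 1)
    s2 = float(r @ r) / dof
    jtj = J.T @ J
    ok = np.linalg.matrix_rank(jtj) == p and np.linalg.cond(jtj) < 1e12
    if not ok:
        nan = np.full(p, np.nan)
        return nan, nan, np.full((p, p), np.nan), False
    cov = s2 * np.linalg.inv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * se / np.abs(theta)
    return cv, se, cov, True


# ---------------------------------------------------------------------------
# results containers


@dataclass
class TGIFitResult:
    """Estimates with asymptotic uncertainty and goodness-of-fit diagnostics."""

    params: pd.Series
    bse: pd.Series
    cv_percent: pd.Series
    cov: pd.DataFrame
    objective: float
    rmse: float
    nobs: int
    df_resid: int
    residuals: dict[str, np.ndarray]
    fitted_curves: dict[str, StateTrajectory]
    convergence: dict
    stage: str
    seed: int | None = None

    @property
    def conf_int(self) -> pd.DataFrame:
        z = 1.96
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def summary(self) -> str:
        head = [
            "Combination TGI model fit",
            f"  stage: {self.stage}    nobs: {self.nobs}    df_resid: {self.df_resid}",
            f"  objective (per-arm-normalized WLS): {self.objective:.6g}",
            f"  RMSE (g, fitted arms): {self.rmse:.4g}",
        ]
        tab = pd.DataFrame({
            "estimate": self.params,
            "unit": [PARAM_UNITS.get(k, "") for k in self.params.index],
            "std err": self.bse,
            "CV%": self.cv_percent,
            "[0.025": self.conf_int["lower"],
            "0.975]": self.conf_int["upper"],
        })
        return "\n".join(head) + "\n" + tab.to_string(float_format=lambda v: f"{v:.4g}") + "\n"

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "estimates": {k: float(v) for k, v in self.params.items()},
            "cv_percent": {k: (None if not np.isfinite(v) else float(v))
                           for k, v in self.cv_percent.items()},
            "rmse_g": float(self.rmse),
            "objective": float(self.objective),
            "nobs": int(self.nobs),
            "seed": self.seed,
            "convergence": {k: (v if isinstance(v, (str, bool)) else float(v))
                            for k, v in self.convergence.items()},
        }


@dataclass
class StagedFitResult:
    """Bundle of the two estimation stages with the assembled model spec."""

    single_agent: TGIFitResult
    interaction: TGIFitResult
    model: "CombinationTGIModel"

    @property
    def params(self) -> pd.Series:
        return pd.concat([self.single_agent.params, self.interaction.params])

    @property
    def cv_percent(self) -> pd.Series:
        return pd.concat([self.single_agent.cv_percent, self.interaction.cv_percent])

    @property
    def gamma(self) -> float:
        return float(self.interaction.params["gamma"])

    @property
    def gamma_se(self) -> float:
        return float(self.interaction.bse["gamma"])

    @property
    def spec(self) -> CombinationModelSpec:
        p = self.params
        return CombinationModelSpec(
            growth=TumorGrowthParameters(p["w0"], p["lambda0"], p["lambda1"],
                                         psi=self.model.psi),
            drug_a=DrugEffectParameters(p["k1a"], p["k2a"]),
            drug_b=DrugEffectParameters(p["k1b"], p["k2b"]),
            gamma=p["gamma"],
        )

    def interaction_indexes(self, regimens: dict[str, DosingRegimen] | None = None,
                            method: str = "closed_form") -> _indexes.InteractionIndexes:
        """Index set for the fitted combination arm (or a supplied regimen set)."""
        if regimens is None:
            combo = self.model.dataset.by_type(ArmType.combination)[0]
            regimens = combo.regimens
        conc_a, conc_b = self.model.profiles_for(regimens)
        return _indexes.combination_indexes(self.spec, conc_a, conc_b,
                                            method=method, gamma_se=self.gamma_se)

    def predict(self, regimens: dict[str, DosingRegimen], times):
        """Simulate a new combination arm from the fitted spec (no refitting)."""
        return predict_combination_arm(self.spec, regimens, self.model.dataset.pk_library,
                                       times, drug_a=self.model.drug_a,
                                       drug_b=self.model.drug_b, gamma_se=self.gamma_se)

    def summary(self) -> str:
        return self.single_agent.summary() + "\n" + self.interaction.summary()

    def to_dict(self) -> dict:
        return {"single_agent": self.single_agent.to_dict(),
                "interaction": self.interaction.to_dict()}


# ---------------------------------------------------------------------------
# the model object


class CombinationTGIModel:
    """Combination TGI model bound to a tumor-growth dataset.

    Parameters
    ----------
    dataset : TumorDataset
        Control, single-agent and combination arms with the PK library.
    drug_a, drug_b : str, optional
        Drug identifiers; inferred from the single-agent arms when omitted.
    psi : float
        Switching sharpness of the growth law (fixed, not estimated).
    fit_solver / final_solver : dict
        ODE tolerances used during optimization and for the reported curves.
    """

    def __init__(self, dataset: TumorDataset, *, drug_a: str | None = None,
                 drug_b: str | None = None, psi: float = 20.0,
                 fit_solver: dict | None = None, final_solver: dict | None = None):
        self.dataset = dataset
        self.psi = float(psi)
        self.fit_solver = {"rtol": 1e-6, "atol": 1e-9, **(fit_solver or {})}
        self.final_solver = {"rtol": 1e-8, "atol": 1e-10, **(final_solver or {})}
        self.drug_a, self.drug_b = self._infer_drugs(drug_a, drug_b)
        self._profiles: dict[str, dict[str, object]] = {}
        for arm in dataset.arms:
            self._profiles[arm.arm_id] = {
                d: concentration_profile(dataset.pk_library[d], reg)
                for d, reg in arm.regimens.items()
            }

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, pk_library: dict[str, PKParameters],
                       regimens: dict[str, dict[str, DosingRegimen]], **kwargs):
        """Build from a long-format observation table.

        ``data`` needs columns arm_id, arm_type, time_days, mean_weight_g, se_g;
        ``regimens`` maps arm_id -> {drug_id: DosingRegimen} (missing or empty
        for control arms).
        """
        required = {"arm_id", "arm_type", "time_days", "mean_weight_g", "se_g"}
        missing = required - set(data.columns)
        if missing:
            raise ConfigurationError(f"dataset is missing column(s): {sorted(missing)}")
        arms = []
        for arm_id, grp in data.groupby("arm_id", sort=False):
            grp = grp.sort_values("time_days")
            arms.append(TumorArm(
                arm_id=str(arm_id),
                arm_type=ArmType(grp["arm_type"].iloc[0]),
                regimens=regimens.get(str(arm_id), {}),
                times=grp["time_days"].to_numpy(float),
                weights=grp["mean_weight_g"].to_numpy(float),
                ses=grp["se_g"].to_numpy(float),
            ))
        return cls(TumorDataset(tuple(arms), pk_library), **kwargs)

    def _infer_drugs(self, drug_a, drug_b):
        def sole_drug(arms, what):
            ids = {d for a in arms for d in a.regimens}
            if len(ids) == 1:
                return ids.pop()
            return None
        if drug_a is None:
            drug_a = sole_drug(self.dataset.by_type(ArmType.single_a), "single_a")
        if drug_b is None:
            drug_b = sole_drug(self.dataset.by_type(ArmType.single_b), "single_b")
        if drug_a is None or drug_b is None:
            combos = self.dataset.by_type(ArmType.combination)
            if combos and len(combos[0].regimens) == 2 and drug_a is None and drug_b is None:
                drug_a, drug_b = sorted(combos[0].regimens)
        return drug_a, drug_b

    def profiles_for(self, regimens: dict[str, DosingRegimen]):
        """(conc_a, conc_b) profiles for an arbitrary regimen set."""
        from .pk import ConcentrationProfile
        lib = self.dataset.pk_library
        conc_a = (concentration_profile(lib[self.drug_a], regimens[self.drug_a])
                  if self.drug_a in regimens else ConcentrationProfile.zero())
        conc_b = (concentration_profile(lib[self.drug_b], regimens[self.drug_b])
                  if self.drug_b in regimens else ConcentrationProfile.zero())
        return conc_a, conc_b

    # -- arm prediction ------------------------------------------------------

    def _arm_conc(self, arm: TumorArm, drug: str):
        from .pk import ConcentrationProfile
        return self._profiles[arm.arm_id].get(drug, ConcentrationProfile.zero())

    def _predict_arm(self, arm: TumorArm, growth: TumorGrowthParameters,
                     da: DrugEffectParameters, db: DrugEffectParameters,
                     gamma: float, solver: dict, times=None) -> np.ndarray:
        times = arm.times if times is None else np.asarray(times, float)
        grid = np.unique(np.concatenate([[0.0], times]))
        if arm.arm_type is ArmType.control:
            traj = _models.unperturbed_growth(growth, grid, **solver)
        elif arm.arm_type is ArmType.single_a:
            traj = _models.simulate_single_agent(growth, da, self._arm_conc(arm, self.drug_a),
                                                 grid, **solver)
        elif arm.arm_type is ArmType.single_b:
            traj = _models.simulate_single_agent(growth, db, self._arm_conc(arm, self.drug_b),
                                                 grid, **solver)
        else:
            spec = CombinationModelSpec(growth, da, db, gamma)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ModelValidityWarning)
                traj = _models.simulate_combination(spec, self._arm_conc(arm, self.drug_a),
                                                    self._arm_conc(arm, self.drug_b),
                                                    grid, **solver)
        return np.interp(times, traj.times, traj.total)

    def _predictions(self, arms, theta: dict, solver) -> list[np.ndarray]:
        growth = TumorGrowthParameters(theta["w0"], theta["lambda0"], theta["lambda1"],
                                       psi=self.psi)
        da = DrugEffectParameters(theta["k1a"], theta["k2a"])
        db = DrugEffectParameters(theta["k1b"], theta["k2b"])
        return [self._predict_arm(a, growth, da, db, theta.get("gamma", 0.0), solver)
                for a in arms]

    # -- stage 1 -------------------------------------------------------------

    def _heuristic_start(self, control: TumorArm, arms) -> np.ndarray:
        lo = np.log([DEFAULT_BOUNDS[k][0] for k in STAGE1_NAMES])
        hi = np.log([DEFAULT_BOUNDS[k][1] for k in STAGE1_NAMES])
        t, w = control.times, control.weights
        k = min(4, len(t))
        slope, intercept = np.polyfit(t[:k], np.log(w[:k]), 1)
        lam0 = slope if slope > 0 else 0.1
        w0 = float(np.exp(intercept))
        lam1 = max((w[-1] - w[-2]) / (t[-1] - t[-2]), 1e-3) if len(t) > 1 else 0.2
        # potency scale: order-of-magnitude from mean exposure of each drug
        k2 = {}
        for role, drug in (("a", self.drug_a), ("b", self.drug_b)):
            cavg = 0.0
            for arm in arms:
                prof = self._profiles[arm.arm_id].get(drug)
                if prof is not None and prof.n_terms:
                    cavg = max(cavg, prof.auc(np.inf) / max(arm.times[-1] - arm.times[0], 1.0))
            k2[role] = lam0 / cavg if cavg > 0 else 0.01
        x0 = np.log([w0, lam0, lam1, 1.0, k2["a"], 1.0, k2["b"]])
        return np.clip(x0, lo, hi)

    def fit_single_agents(self, *, seed: int = 0, n_starts: int = 8,
                          bounds: dict | None = None) -> TGIFitResult:
        """Stage 1: simultaneous WLS fit of the 7 single-agent parameters.

        Tumor-related parameters are shared across the control and the two
        single-agent arms; multi-start (one data-driven start plus seeded
        log-uniform random starts) guards against local optima.
        """
        ds = self.dataset
        controls = ds.by_type(ArmType.control)
        if not controls:
            raise NonIdentifiableError("stage 1 requires at least one control arm")
        arms = controls + ds.by_type(ArmType.single_a) + ds.by_type(ArmType.single_b)
        if self.drug_a is not None and not ds.by_type(ArmType.single_a):
            raise NonIdentifiableError(
                f"no single-agent arm for drug {self.drug_a!r}: k1a/k2a are not identifiable")
        if self.drug_b is not None and not ds.by_type(ArmType.single_b):
            raise NonIdentifiableError(
                f"no single-agent arm for drug {self.drug_b!r}: k1b/k2b are not identifiable")
        if len(arms) < 2:
            raise NonIdentifiableError("stage 1 needs a control plus single-agent arms")
        bnds = {**DEFAULT_BOUNDS, **(bounds or {})}
        lo = np.log([bnds[k][0] for k in STAGE1_NAMES])
        hi = np.log([bnds[k][1] for k in STAGE1_NAMES])

        def resid(x):
            theta = dict(zip(STAGE1_NAMES, np.exp(x)))
            preds = self._predictions(arms, theta, self.fit_solver)
            return _scaled_residuals(arms, preds)

        rng = np.random.default_rng(seed)
        starts = [self._heuristic_start(controls[0], arms)]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(lo + rng.random(len(STAGE1_NAMES)) * (hi - lo))
        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                    x_scale="jac", diff_step=1e-4,
                                    ftol=1e-10, xtol=1e-10, gtol=1e-10)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("stage-1 optimization failed from every start")
        return self._package(best, STAGE1_NAMES, arms, log_scale=np.ones(7, bool),
                             stage="single_agent", seed=seed,
                             extra={"n_starts": len(starts)})

    # -- stage 2 -------------------------------------------------------------

    def fit_interaction(self, fixed, *, seed: int = 0,
                        gamma_bounds: tuple[float, float] = GAMMA_BOUNDS) -> TGIFitResult:
        """Stage 2: one-dimensional WLS for gamma with stage-1 parameters fixed.

        ``fixed`` is a stage-1 :class:`TGIFitResult` or a mapping with the seven
        single-agent parameters.  The objective includes the control and all
        combination arms (the control contributes no gamma information but
        enters the residual normalization as fitted data).
        """
        theta_fixed = self._fixed_dict(fixed)
        ds = self.dataset
        combos = ds.by_type(ArmType.combination)
        if not combos:
            raise NonIdentifiableError("stage 2 requires at least one combination arm")
        controls = ds.by_type(ArmType.control)
        arms = controls + combos
        # control predictions are gamma-free: simulate them once
        control_preds = self._predictions(controls, {**theta_fixed, "gamma": 0.0},
                                          self.fit_solver)

        def resid(x):
            theta = {**theta_fixed, "gamma": float(x[0])}
            preds = control_preds + self._predictions(combos, theta, self.fit_solver)
            return _scaled_residuals(arms, preds)

        # coarse bracket then local refinement
        grid = np.concatenate([-np.geomspace(abs(gamma_bounds[0]), 1e-3, 8), [0.0],
                               np.geomspace(1e-3, gamma_bounds[1], 8)])
        costs = []
        for g in grid:
            r = resid([g])
            costs.append(float(r @ r))
        g0 = float(grid[int(np.argmin(costs))])
        sol = least_squares(resid, [g0], bounds=([gamma_bounds[0]], [gamma_bounds[1]]),
                            method="trf", x_scale=[max(abs(g0), 0.1)], diff_step=1e-4,
                            ftol=1e-12, xtol=1e-12, gtol=1e-12)
        if np.isclose(sol.x[0], gamma_bounds, atol=1e-9).any():
            warnings.warn(f"gamma estimate hit the search bound {sol.x[0]:.3g}; "
                          "widen gamma_bounds", UserWarning, stacklevel=2)
        res = self._package(sol, ("gamma",), arms, log_scale=np.zeros(1, bool),
                            stage="interaction", seed=seed,
                            extra={"fixed": True}, theta_fixed=theta_fixed,
                            rmse_arms=combos)
        return res

    def fit(self, *, seed: int = 0, n_starts: int = 8) -> StagedFitResult:
        """Default staged pipeline: stage 1 then stage 2."""
        s1 = self.fit_single_agents(seed=seed, n_starts=n_starts)
        s2 = self.fit_interaction(s1, seed=seed)
        return StagedFitResult(single_agent=s1, interaction=s2, model=self)

    # -- joint ---------------------------------------------------------------

    def fit_joint(self, *, seed: int = 0, n_starts: int = 4,
                  gamma_bounds: tuple[float, float] = GAMMA_BOUNDS) -> TGIFitResult:
        """Simultaneous 8-parameter WLS over all arms (comparison path)."""
        ds = self.dataset
        if not ds.by_type(ArmType.control) or not ds.by_type(ArmType.combination):
            raise NonIdentifiableError("joint fit requires control and combination arms")
        if not ds.by_type(ArmType.single_a) or not ds.by_type(ArmType.single_b):
            raise NonIdentifiableError("joint fit requires both single-agent arms")
        arms = list(ds.arms)
        names = STAGE1_NAMES + ("gamma",)
        lo = np.append(np.log([DEFAULT_BOUNDS[k][0] for k in STAGE1_NAMES]), gamma_bounds[0])
        hi = np.append(np.log([DEFAULT_BOUNDS[k][1] for k in STAGE1_NAMES]), gamma_bounds[1])

        def resid(x):
            theta = dict(zip(STAGE1_NAMES, np.exp(x[:7])))
            theta["gamma"] = float(x[7])
            return _scaled_residuals(arms, self._predictions(arms, theta, self.fit_solver))

        rng = np.random.default_rng(seed)
        controls = ds.by_type(ArmType.control)
        starts = [np.append(self._heuristic_start(controls[0], arms), 0.0)]
        for _ in range(max(n_starts - 1, 0)):
            x = lo[:7] + rng.random(7) * (hi[:7] - lo[:7])
            starts.append(np.append(x, rng.uniform(-1.0, 1.0)))
        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                    x_scale="jac", diff_step=1e-4,
                                    ftol=1e-10, xtol=1e-10, gtol=1e-10)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("joint optimization failed from every start")
        log_scale = np.append(np.ones(7, bool), False)
        return self._package(best, names, arms, log_scale=log_scale, stage="joint",
                             seed=seed, extra={"n_starts": len(starts)})

    # -- shared packaging ----------------------------------------------------

    def _fixed_dict(self, fixed) -> dict:
        if isinstance(fixed, TGIFitResult):
            fixed = dict(fixed.params)
        elif isinstance(fixed, pd.Series):
            fixed = dict(fixed)
        missing = [k for k in STAGE1_NAMES if k not in fixed]
        if missing:
            raise ConfigurationError(f"fixed parameter set incomplete, missing {missing}")
        return {k: float(fixed[k]) for k in STAGE1_NAMES}

    def _package(self, sol, names, arms, *, log_scale, stage, seed, extra,
                 theta_fixed=None, rmse_arms=None) -> TGIFitResult:
        x = sol.x
        theta = np.where(log_scale, np.exp(x), x)
        # chain rule back to the natural scale for log-fitted coordinates
        J = sol.jac / np.where(log_scale, theta, 1.0)[None, :]
        cv, se, cov, ok = parameter_cv(J, sol.fun, theta)
        full = dict(zip(names, theta))
        if theta_fixed is not None:
            full = {**theta_fixed, **full}
        # final curves and unweighted RMSE at reporting tolerance
        rmse_arms = arms if rmse_arms is None else rmse_arms
        preds = self._predictions(rmse_arms, full, self.final_solver)
        rm = rmse(np.concatenate([a.weights for a in rmse_arms]), np.concatenate(preds))
        residuals, curves = {}, {}
        for arm in arms:
            yhat = self._predict_arm(
                arm,
                TumorGrowthParameters(full["w0"], full["lambda0"], full["lambda1"], psi=self.psi),
                DrugEffectParameters(full["k1a"], full["k2a"]),
                DrugEffectParameters(full["k1b"], full["k2b"]),
                full.get("gamma", 0.0), self.final_solver)
            residuals[arm.arm_id] = arm.weights - yhat
            dense = np.linspace(0.0, float(arm.times[-1]), 241)
            curves[arm.arm_id] = self._trajectory(arm, full, dense)
        nobs = int(sum(a.n_obs for a in arms))
        conv = {"status": str(sol.status), "nfev": float(sol.nfev),
                "optimality": float(sol.optimality), "success": bool(sol.success),
                "cv_defined": ok, **extra}
        idx = pd.Index(names, name="parameter")
        return TGIFitResult(
            params=pd.Series(theta, index=idx),
            bse=pd.Series(se, index=idx),
            cv_percent=pd.Series(cv, index=idx),
            cov=pd.DataFrame(cov, index=idx, columns=idx),
            objective=float(2.0 * sol.cost),
            rmse=rm, nobs=nobs, df_resid=nobs - len(names),
            residuals=residuals, fitted_curves=curves,
            convergence=conv, stage=stage, seed=seed,
        )

    def _trajectory(self, arm: TumorArm, theta: dict, times) -> StateTrajectory:
        growth = TumorGrowthParameters(theta["w0"], theta["lambda0"], theta["lambda1"],
                                       psi=self.psi)
        da = DrugEffectParameters(theta["k1a"], theta["k2a"])
        db = DrugEffectParameters(theta["k1b"], theta["k2b"])
        if arm.arm_type is ArmType.control:
            return _models.unperturbed_growth(growth, times, **self.final_solver)
        if arm.arm_type is ArmType.single_a:
            return _models.simulate_single_agent(growth, da, self._arm_conc(arm, self.drug_a),
                                                 times, **self.final_solver)
        if arm.arm_type is ArmType.single_b:
            return _models.simulate_single_agent(growth, db, self._arm_conc(arm, self.drug_b),
                                                 times, **self.final_solver)
        spec = CombinationModelSpec(growth, da, db, theta.get("gamma", 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            return _models.simulate_combination(spec, self._arm_conc(arm, self.drug_a),
                                                self._arm_conc(arm, self.drug_b),
                                                times, **self.final_solver)


def predict_combination_arm(spec: CombinationModelSpec,
                            regimens: dict[str, DosingRegimen],
                            pk_library: dict[str, PKParameters], times, *,
                            drug_a: str, drug_b: str, gamma_se: float | None = None,
                            rtol=1e-8, atol=1e-10):
    """Pure simulation of a new combination arm plus its predicted index set.

    No fitting: the spec (including gamma) comes from a previous experiment and
    is transported to a new dose/schedule.  Returns (StateTrajectory,
    InteractionIndexes).
    """
    conc_a = concentration_profile(pk_library[drug_a], regimens[drug_a])
    conc_b = concentration_profile(pk_library[drug_b], regimens[drug_b])
    times = np.asarray(times, dtype=float)
    grid = np.unique(np.concatenate([[0.0], times]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelValidityWarning)
        traj = _models.simulate_combination(spec, conc_a, conc_b, grid, rtol=rtol, atol=atol)
    idx = _indexes.combination_indexes(spec, conc_a, conc_b, method="closed_form",
                                       gamma_se=gamma_se)
    return traj, idx
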