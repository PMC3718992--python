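"""Linear compartmental pharmacokinetics under multi-dose regimens.

Plasma concentration profiles are represented exactly as sums of (optionally
polynomial-weighted) decaying exponentials anchored at the dose times.  Because
the PK is linear, the multi-dose profile is the superposition of closed-form
single-dose responses: no ODE integration is involved and no integration
tolerance propagates into downstream fits.  Areas under the curve -- including
the area under the *product* of two profiles, which drives the drug-interaction
term of the tumor model -- are computed analytically term by term.

Units are fixed throughout the package: time in days, concentration in uM,
dose in umol/kg (written uM/kg in the field), volume in L/kg, rates in 1/day.
Doses quoted in mg/kg must be converted with the compound's molar mass before
they enter this module; there is no silent unit guessing.

Supported structures: one- or two-compartment disposition, iv bolus or
first-order oral absorption with bioavailability F.  Michaelis-Menten
elimination and PK drug-drug interaction are out of scope (the combination
tumor model assumes the PK of the two drugs do not interact).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate as _sci_integrate
from scipy import special as _sp

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "Route",
    "DoseEvent",
    "DosingRegimen",
    "PKParameters",
    "ConcentrationProfile",
    "concentration_profile",
    "auc",
    "auc_product",
]

#: relative gap below which two rate constants are treated as confluent
#: (degenerate ka == k handled by the limiting t*exp(-k t) form)
RATE_CONFLUENCE_RTOL = 1e-8


class Route(str, enum.Enum):
    iv_bolus = "iv_bolus"
    oral = "oral"


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time (days), amount (uM/kg) and route."""

    time: float
    amount: float
    route: Route = Route.iv_bolus

    def __post_init__(self):
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"dose time must be finite and >= 0, got {self.time}")
        if not math.isfinite(self.amount) or self.amount < 0:
            raise ValidationError(f"dose amount must be >= 0, got {self.amount}")
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class DosingRegimen:
    """Ordered dose events for one drug.  An empty event list means untreated."""

    drug_id: str
    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self):
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(f"dose events for {self.drug_id!r} must be sorted by time")
        object.__setattr__(self, "events", events)

    @classmethod
    def from_times(cls, drug_id: str, times, amount: float, route: Route | str = Route.iv_bolus):
        """Regimen with the same amount/route at each of ``times``."""
        return cls(drug_id, tuple(DoseEvent(float(t), float(amount), Route(route)) for t in times))

    @property
    def dose_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def total_dose(self) -> float:
        return float(sum(e.amount for e in self.events))

    def scaled(self, factor: float) -> "DosingRegimen":
        """Same schedule with every amount multiplied by ``factor``."""
        return DosingRegimen(
            self.drug_id,
            tuple(DoseEvent(e.time, e.amount * factor, e.route) for e in self.events),
        )


@dataclass(frozen=True)
class PKParameters:
    """Linear compartmental PK parameterization of one drug.

    ``elimination_rate`` is the elimination micro-constant from the central
    compartment (k or k10), ``central_volume`` the central volume of
    distribution.  ``k12``/``k21`` are required iff ``n_compartments == 2``;
    ``absorption_rate`` (ka) is required for oral dosing.
    """

    central_volume: float
    elimination_rate: float
    n_compartments: int = 1
    k12: float | None = None
    k21: float | None = None
    absorption_rate: float | None = None
    bioavailability: float = 1.0

    def __post_init__(self):
        if self.n_compartments not in (1, 2):
            raise ValidationError("n_compartments must be 1 or 2")
        if not self.central_volume > 0:
            raise ValidationError("central_volume must be > 0")
        if not self.elimination_rate > 0:
            raise ValidationError("elimination_rate must be > 0")
        if self.n_compartments == 2:
            if self.k12 is None or self.k21 is None:
                raise ValidationError("two-compartment PK requires k12 and k21")
            if not (self.k12 > 0 and self.k21 > 0):
                raise ValidationError("inter-compartment rates must be > 0")
        elif self.k12 is not None or self.k21 is not None:
            raise ValidationError("k12/k21 only apply to two-compartment PK")
        if self.absorption_rate is not None and not self.absorption_rate > 0:
            raise ValidationError("absorption_rate must be > 0 where present")
        if not 0.0 <= self.bioavailability <= 1.0:
            raise ValidationError("bioavailability must lie in [0, 1]")

    def macro_rates(self) -> tuple[float, float]:
        """Hybrid (alpha, beta) disposition rates of the two-compartment model."""
        if self.n_compartments != 2:
            raise ValidationError("macro_rates only defined for two-compartment PK")
        s = self.elimination_rate + self.k12 + self.k21
        p = self.elimination_rate * self.k21
        disc = math.sqrt(s * s - 4.0 * p)
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta


def _confluent(r1: float, r2: float) -> bool:
    return abs(r1 - r2) <= RATE_CONFLUENCE_RTOL * max(abs(r1), abs(r2))


def _impulse_terms(pk: PKParameters, route: Route, amount: float):
    """Closed-form unit response of one dose at t=0 as (coef, rate, power) terms.

    Each term contributes coef * t**power * exp(-rate*t) for t >= 0.
    """
    v = pk.central_volume
    k = pk.elimination_rate
    if route is Route.iv_bolus:
        if pk.n_compartments == 1:
            return [(amount / v, k, 0)]
        alpha, beta = pk.macro_rates()
        d = alpha - beta
        return [
            (amount / v * (alpha - pk.k21) / d, alpha, 0),
            (amount / v * (pk.k21 - beta) / d, beta, 0),
        ]
    # oral, first-order absorption
    if pk.absorption_rate is None:
        raise ConfigurationError(
            "oral dose event requires PKParameters.absorption_rate (ka)"
        )
    ka = pk.absorption_rate
    scale = pk.bioavailability * amount * ka / v
    if pk.n_compartments == 1:
        if _confluent(ka, k):
            r = 0.5 * (ka + k)
            return [(scale, r, 1)]  # limiting F*D*ka/V * t * exp(-k t)
        a = scale / (ka - k)
        return [(a, k, 0), (-a, ka, 0)]
    alpha, beta = pk.macro_rates()
    q = pk.k21
    rates = (ka, alpha, beta)
    if _confluent(ka, alpha) or _confluent(ka, beta):
        # double pole at r = (ka + matching macro rate)/2, simple pole at r3
        rm = alpha if _confluent(ka, alpha) else beta
        r3 = beta if _confluent(ka, alpha) else alpha
        r = 0.5 * (ka + rm)
        return [
            (scale * (q - r) / (r3 - r), r, 1),
            (scale * (r3 - q) / (r3 - r) ** 2, r, 0),
            (scale * (q - r3) / (r - r3) ** 2, r3, 0),
        ]
    terms = []
    for ri in rates:
        denom = 1.0
        for rj in rates:
            if rj is not ri:
                denom *= rj - ri
        terms.append((scale * (q - ri) / denom, ri, 0))
    return terms


class ConcentrationProfile:
    """Plasma concentration c(t) as an exact sum of dose-anchored exponential terms.

    Callable at arbitrary times (vectorized); ``at`` is the scalar fast path used
    inside ODE right-hand sides.  The profile is zero before the first dose and
    non-negative everywhere.
    """

    def __init__(self, t0, coef, rate, power, grid=None):
        self.t0 = np.asarray(t0, dtype=float)
        self.coef = np.asarray(coef, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.power = np.asarray(power, dtype=int)
        self.grid = None if grid is None else np.asarray(grid, dtype=float)

    @classmethod
    def zero(cls, grid=None) -> "ConcentrationProfile":
        return cls([], [], [], [], grid=grid)

    @property
    def n_terms(self) -> int:
        return self.t0.size

    @property
    def breakpoints(self) -> np.ndarray:
        """Dose times: points where c or its derivative is discontinuous."""
        return np.unique(self.t0)

    @property
    def values(self) -> np.ndarray:
        """Concentrations on the evaluation grid passed at construction."""
        if self.grid is None:
            raise ValidationError("profile was built without an evaluation grid")
        return self(self.grid)

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.n_terms == 0:
            return np.zeros_like(t)
        dt = t[:, None] - self.t0[None, :]
        active = dt >= 0.0
        dt = np.where(active, dt, 0.0)
        vals = self.coef * dt**self.power * np.exp(-self.rate * dt)
        out = np.where(active, vals, 0.0).sum(axis=1)
        return np.maximum(out, 0.0)

    def at(self, t: float) -> float:
        """Scalar evaluation (fast path for ODE right-hand sides)."""
        if self.n_terms == 0:
            return 0.0
        dt = t - self.t0
        m = dt >= 0.0
        if not m.any():
            return 0.0
        d = dt[m]
        v = float((self.coef[m] * d ** self.power[m] * np.exp(-self.rate[m] * d)).sum())
        return v if v > 0.0 else 0.0

    def __add__(self, other: "ConcentrationProfile") -> "ConcentrationProfile":
        return ConcentrationProfile(
            np.concatenate([self.t0, other.t0]),
            np.concatenate([self.coef, other.coef]),
            np.concatenate([self.rate, other.rate]),
            np.concatenate([self.power, other.power]),
            grid=self.grid if self.grid is not None else other.grid,
        )

    def scaled(self, factor: float) -> "ConcentrationProfile":
        return ConcentrationProfile(self.t0, self.coef * factor, self.rate, self.power, grid=self.grid)

    def auc(self, horizon: float = np.inf) -> float:
        """Analytic integral of c over [0, horizon] (uM*day)."""
        if self.n_terms == 0:
            return 0.0
        if np.any(self.rate <= 0):
            raise ValidationError("AUC undefined: non-positive elimination rate term")
        if np.isinf(horizon):
            frac = np.ones(self.n_terms)
        else:
            span = np.maximum(horizon - self.t0, 0.0)
            frac = _sp.gammainc(self.power + 1.0, self.rate * span)
        vals = self.coef * _sp.gamma(self.power + 1.0) / self.rate ** (self.power + 1.0) * frac
        return float(vals.sum())

    def _local_terms(self, s: float):
        """Re-anchor all terms active at time s to tau = t - s.

        A term c*(t-t0)^p*exp(-r(t-t0)) with d = s - t0 >= 0 becomes, in tau,
        c*exp(-r d) * (tau + d)^p * exp(-r tau); binomial expansion keeps the
        (coef, rate, power) representation exact.
        """
        coefs, rates, powers = [], [], []
        for c, r, p, t0 in zip(self.coef, self.rate, self.power, self.t0):
            d = s - t0
            if d < 0:
                continue
            base = c * math.exp(-r * d)
            for q in range(p + 1):
                coefs.append(base * math.comb(p, q) * d ** (p - q))
                rates.append(r)
                powers.append(q)
        return np.array(coefs), np.array(rates), np.array(powers, dtype=int)


def concentration_profile(pk: PKParameters, regimen: DosingRegimen, times=None) -> ConcentrationProfile:
    """Multi-dose concentration profile by superposition of single-dose responses.

    Exact (closed form); the optional ``times`` grid is stored for convenience
    (``profile.values``) but the returned object evaluates at arbitrary t.
    """
    if times is not None:
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValidationError("evaluation times must be sorted ascending")
    t0s, coefs, rates, powers = [], [], [], []
    for ev in regimen.events:
        for c, r, p in _impulse_terms(pk, ev.route, ev.amount):
            t0s.append(ev.time)
            coefs.append(c)
            rates.append(r)
            powers.append(p)
    return ConcentrationProfile(t0s, coefs, rates, powers, grid=times)


def auc(pk: PKParameters, regimen: DosingRegimen, horizon: float = np.inf) -> float:
    """Area under the concentration curve over [0, horizon] (uM*day).

    Analytic: for a one-compartment model and infinite horizon this reduces to
    F * (total dose) / (k * V), i.e. dose over clearance.
    """
    if not np.isinf(horizon) and regimen.events:
        last = max(e.time for e in regimen.events)
        if horizon <= last:
            raise ValidationError(f"horizon {horizon} must exceed the last dose time {last}")
    return concentration_profile(pk, regimen).auc(horizon)


def _segment_product_integral(pa: ConcentrationProfile, pb: ConcentrationProfile,
                              s: float, length: float) -> float:
    ca, ra, qa = pa._local_terms(s)
    cb, rb, qb = pb._local_terms(s)
    if ca.size == 0 or cb.size == 0:
        return 0.0
    C = ca[:, None] * cb[None, :]
    R = ra[:, None] + rb[None, :]
    P = qa[:, None] + qb[None, :]
    if np.isinf(length):
        frac = 1.0
    else:
        frac = _sp.gammainc(P + 1.0, R * length)
    return float((C * _sp.gamma(P + 1.0) / R ** (P + 1.0) * frac).sum())


def auc_product(profile_a, profile_b, horizon: float = np.inf) -> float:
    """Integral of c_a(t)*c_b(t) over [0, horizon] (uM^2*day).

    For :class:`ConcentrationProfile` inputs the integral is computed
    analytically segment by segment between dose times (the product of two
    exponential sums is again an exponential sum on each segment).  Arbitrary
    callables fall back to adaptive quadrature, which requires a finite horizon.
    """
    analytic = isinstance(profile_a, ConcentrationProfile) and isinstance(profile_b, ConcentrationProfile)
    if not analytic:
        if np.isinf(horizon):
            raise ValidationError("callable profiles require a finite horizon")
        val, _ = _sci_integrate.quad(
            lambda t: float(np.atleast_1d(profile_a(t))[0]) * float(np.atleast_1d(profile_b(t))[0]),
            0.0, horizon, limit=400)
        return max(val, 0.0)
    bps = np.unique(np.concatenate([profile_a.breakpoints, profile_b.breakpoints, [0.0]]))
    bps = bps[bps < horizon] if not np.isinf(horizon) else bps
    total = 0.0
    for i, s in enumerate(bps):
        e = bps[i + 1] if i + 1 < len(bps) else horizon
        if e <= s:
            continue
        total += _segment_product_integral(profile_a, profile_b, float(s), float(e - s))
    return max(total, 0.0)
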