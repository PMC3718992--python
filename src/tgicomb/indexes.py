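"""Drug-effect interaction indexes for combination TGI experiments.

The Time Efficacy Index (TEI) is the asymptotic horizontal delay between the
growth curves of treated and untreated tumors: after washout both curves run
into the same linear regime, so their time distance at any large reference
weight is well defined.  For a combination regimen it is well approximated in
closed form by

    TEI_comb ~ (k2a*AUC_a + k2b*AUC_b + gamma*AUC_ab) / lambda0

with AUC_a/AUC_b the areas under the two concentration curves and AUC_ab the
area under their product, all taken to infinity (full washout).  The portion of
the delay attributable to the interaction alone is the shift of the combination
curve against the zero-interaction reference curve (PTGC),

    Delta ~ gamma * AUC_ab / lambda0          (signed; sign(Delta) = sign(gamma))

and two normalized percentages summarize it: the synergistic combination index
SC = 100*Delta/TEI_comb (for Delta > 0) and the antagonistic combination index
AC = 100*(-Delta)/TEI_add (for Delta < 0), TEI_add being the delay of the PTGC
itself.  Both closed-form and fully numeric (curve-interpolation) routes are
provided; the numeric route serves as the independent oracle for the
closed-form approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .exceptions import ValidationError, WindowTooShortError
from .models import CombinationModelSpec, StateTrajectory
from .pk import auc_product

__all__ = [
    "InteractionIndexes",
    "tei_combination",
    "tei_additive",
    "interaction_shift",
    "synergy_index",
    "antagonism_index",
    "classify_interaction",
    "time_at_weight",
    "asymptotic_delay",
    "combination_indexes",
]

#: |Delta| below this (days) is numerical zero: neither SC nor AC is reported.
DELTA_EPS = 1e-6


def tei_combination(k2a, auc_a, k2b, auc_b, gamma, auc_ab, lambda0) -> float:
    """Closed-form combination Time Efficacy Index (days)."""
    if not lambda0 > 0:
        raise ValidationError("lambda0 must be > 0")
    if auc_a < 0 or auc_b < 0 or auc_ab < 0:
        raise ValidationError("AUCs must be >= 0")
    return (k2a * auc_a + k2b * auc_b + gamma * auc_ab) / lambda0


def tei_additive(k2a, auc_a, k2b, auc_b, lambda0) -> float:
    """Closed-form TEI of the zero-interaction reference (gamma = 0)."""
    return tei_combination(k2a, auc_a, k2b, auc_b, 0.0, 0.0, lambda0)


def interaction_shift(gamma, auc_ab, lambda0) -> float:
    """Closed-form Delta (days): shift of the combination curve vs the PTGC."""
    if not lambda0 > 0:
        raise ValidationError("lambda0 must be > 0")
    return gamma * auc_ab / lambda0


def synergy_index(delta: float, tei_comb: float) -> float:
    """SC = 100 * Delta / TEI_comb, defined for Delta > 0; lies in (0, 100]."""
    if delta <= 0:
        raise ValidationError("SC is defined for Delta > 0; use antagonism_index for Delta < 0")
    if not tei_comb > 0:
        raise ValidationError("TEI_comb must be > 0")
    if delta > tei_comb * (1 + 1e-12):
        raise ValidationError("Delta cannot exceed TEI_comb")
    return 100.0 * delta / tei_comb


def antagonism_index(delta: float, tei_add: float) -> float:
    """AC = 100 * (-Delta) / TEI_add, defined for Delta < 0."""
    if delta >= 0:
        raise ValidationError("AC is defined for Delta < 0; use synergy_index for Delta > 0")
    if not tei_add > 0:
        raise ValidationError("TEI_add must be > 0")
    return 100.0 * (-delta) / tei_add


def classify_interaction(gamma_est: float, gamma_se: float, z: float = 1.96) -> str:
    """'synergistic' / 'antagonistic' / 'additive' from the estimate and its SE."""
    if gamma_se < 0:
        raise ValidationError("gamma_se must be >= 0")
    if gamma_est - z * gamma_se > 0:
        return "synergistic"
    if gamma_est + z * gamma_se < 0:
        return "antagonistic"
    return "additive"


def time_at_weight(traj: StateTrajectory, w_ref: float) -> float:
    """Time (days) at which the total-weight curve finally crosses w_ref.

    Uses the last upcrossing (treated curves may shrink before regrowing) and
    linear interpolation between the bracketing grid points.
    """
    w = traj.total
    t = traj.times
    below = np.nonzero(w < w_ref)[0]
    if below.size == 0:
        return float(t[0])  # already above w_ref at the start
    k = below[-1]
    if k == len(w) - 1:
        slope = (w[-1] - w[-2]) / (t[-1] - t[-2]) if len(w) > 1 else 0.0
        ext = (w_ref - w[-1]) / slope if slope > 0 else None
        raise WindowTooShortError(
            f"curve never reaches w_ref = {w_ref:.4g} g within the window "
            f"(final weight {w[-1]:.4g} g at t = {t[-1]:.4g} d); extend the window "
            + (f"by about {ext:.1f} days" if ext is not None else "(no regrowth detected)"),
            required_extension=ext,
        )
    t0, t1, w0, w1 = t[k], t[k + 1], w[k], w[k + 1]
    return float(t0 + (w_ref - w0) * (t1 - t0) / (w1 - w0))


def asymptotic_delay(treated: StateTrajectory, reference: StateTrajectory, w_ref: float) -> float:
    """Numeric delay (days): t_treated(w_ref) - t_reference(w_ref)."""
    return time_at_weight(treated, w_ref) - time_at_weight(reference, w_ref)


@dataclass
class InteractionIndexes:
    """TEI_comb, TEI_add, Delta (days), and exactly one of SC/AC (percent).

    SC is present iff Delta > 0, AC iff Delta < 0; both are absent when Delta
    is numerically zero (|Delta| < 1e-6 days), and the classification of the
    interaction ('synergistic'/'antagonistic'/'additive') follows the sign of
    gamma against its standard error when one is supplied.
    """

    tei_comb: float
    tei_add: float
    delta: float
    gamma_used: float
    method: str
    sc: float | None = None
    ac: float | None = None
    classification: str | None = None

    def __post_init__(self):
        if self.sc is not None and self.ac is not None:
            raise ValidationError("at most one of SC/AC may be present")
        if abs(self.delta) < DELTA_EPS:
            if self.sc is not None or self.ac is not None:
                raise ValidationError("SC/AC must be absent for Delta ~ 0")
        elif self.delta > 0 and self.sc is None:
            raise ValidationError("SC must be present for Delta > 0")
        elif self.delta < 0 and self.ac is None:
            raise ValidationError("AC must be present for Delta < 0")

    def to_dict(self) -> dict:
        return {
            "tei_comb_days": self.tei_comb,
            "tei_add_days": self.tei_add,
            "delta_days": self.delta,
            "sc_percent": self.sc,
            "ac_percent": self.ac,
            "gamma_used": self.gamma_used,
            "method": self.method,
            "classification": self.classification,
        }


def _assemble(tei_comb, tei_add, delta, gamma, method, gamma_se=None) -> InteractionIndexes:
    sc = ac = None
    if delta > DELTA_EPS:
        sc = synergy_index(delta, tei_comb) if tei_comb > 0 else None
    elif delta < -DELTA_EPS:
        ac = antagonism_index(delta, tei_add) if tei_add > 0 else None
    if gamma_se is not None:
        cls = classify_interaction(gamma, gamma_se)
    else:
        cls = ("synergistic" if delta > DELTA_EPS
               else "antagonistic" if delta < -DELTA_EPS else "additive")
    return InteractionIndexes(tei_comb=tei_comb, tei_add=tei_add, delta=delta,
                              gamma_used=gamma, method=method, sc=sc, ac=ac,
                              classification=cls)


def combination_indexes(spec: CombinationModelSpec, conc_a, conc_b, *,
                        method: str = "closed_form", gamma_se: float | None = None,
                        w_ref: float | None = None, horizon: float | None = None,
                        rtol=1e-8, atol=1e-10) -> InteractionIndexes:
    """Compute the full index set for one regimen.

    closed_form: AUCs to infinity plugged into the approximations above.
    numeric: simulate combination, PTGC and control curves out to the linear
    regrowth regime and measure horizontal shifts at the reference weight
    (default w_ref = 2*lambda1/lambda0, well inside the linear regime).
    """
    if method == "closed_form":
        auc_a = conc_a.auc(np.inf)
        auc_b = conc_b.auc(np.inf)
        auc_ab = auc_product(conc_a, conc_b, np.inf)
        lam0 = spec.growth.lambda0
        tc = tei_combination(spec.drug_a.k2, auc_a, spec.drug_b.k2, auc_b,
                             spec.gamma, auc_ab, lam0)
        ta = tei_additive(spec.drug_a.k2, auc_a, spec.drug_b.k2, auc_b, lam0)
        dl = interaction_shift(spec.gamma, auc_ab, lam0)
        return _assemble(tc, ta, dl, spec.gamma, "closed_form", gamma_se)
    if method != "numeric":
        raise ValidationError("method must be 'closed_form' or 'numeric'")

    g = spec.growth
    if w_ref is None:
        w_ref = 2.0 * g.threshold_weight
    if horizon is None:
        # control reaches w_ref at roughly t_exp + linear time; pad by the
        # closed-form TEI guess so treated curves also regrow past w_ref
        t_ctrl = (np.log(g.threshold_weight / g.w0) / g.lambda0
                  + (w_ref - g.threshold_weight) / g.lambda1)
        guess = combination_indexes(spec, conc_a, conc_b, method="closed_form")
        horizon = t_ctrl + 2.0 * max(abs(guess.tei_comb), abs(guess.tei_add), 5.0) + 30.0
    times = np.linspace(0.0, float(horizon), max(int(horizon * 8), 400))
    control = models.unperturbed_growth(g, times, rtol=rtol, atol=atol)
    comb = models.simulate_combination(spec, conc_a, conc_b, times, rtol=rtol, atol=atol)
    ptgc = models.simulate_zero_interaction(spec, conc_a, conc_b, times, rtol=rtol, atol=atol)
    tc = asymptotic_delay(comb, control, w_ref)
    ta = asymptotic_delay(ptgc, control, w_ref)
    dl = time_at_weight(comb, w_ref) - time_at_weight(ptgc, w_ref)
    return _assemble(tc, ta, dl, spec.gamma, "numeric", gamma_se)
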