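"""Fitted-vs-observed tumor growth plots."""

from __future__ import annotations

from .estimation import StagedFitResult


def plot_fit(result, arm_ids=None, ax=None):
    """Observed means +/- SE with the fitted curve for each arm.

    ``result`` may be a stage result or a staged bundle; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    if isinstance(result, StagedFitResult):
        stages = [result.single_agent, result.interaction]
        model = result.model
    else:
        stages = [result]
        model = None
    seen = set()
    for res in stages:
        for arm_id, traj in res.fitted_curves.items():
            if arm_id in seen or (arm_ids is not None and arm_id not in arm_ids):
                continue
            seen.add(arm_id)
            line, = ax.plot(traj.times, traj.total, label=arm_id)
            if model is not None:
                arm = model.dataset.arm(arm_id)
                ax.errorbar(arm.times, arm.weights, yerr=arm.ses, fmt="o",
                            color=line.get_color(), capsize=2, ms=4)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("tumor weight (g)")
    ax.legend()
    return ax
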