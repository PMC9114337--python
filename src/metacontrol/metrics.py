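"""Behavioral summaries: baseline-corrected performance and metacontrol.

Task performance on a trial is the reward obtained (before any stakes
multiplication) minus the mean of the rewards available at the two planets
on that same trial — the excess over the expected reward of a random
decision maker, so a uniformly random policy scores 0 in expectation.

The metacontrol index of a fitted participant is the difference between
the model-based weight on high-stakes and low-stakes trials, per
transition condition: positive values mean more model-based control when
the stakes are amplified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agent import ModelParams
from .task import TrialPlan


def task_performance(data: pd.DataFrame, plan: TrialPlan) -> pd.DataFrame:
    """Mean baseline-corrected reward per condition cell.

    Trials with a missing first- or second-stage response contribute no
    performance term (no reward was collected). ``data`` and ``plan`` must
    be aligned by trial index.
    """
    if len(data) != plan.n_trials:
        raise ValueError(
            f"behavior table has {len(data)} rows but the plan has "
            f"{plan.n_trials} trials"
        )
    baseline = plan.reward_walk.displayed.mean(axis=1)
    valid = (data["a1"].to_numpy() >= 0) & (~data["missing_stage2"].to_numpy(bool))
    corrected = data["reward"].to_numpy(float) - baseline
    df = pd.DataFrame(
        {
            "transition_condition": data["transition_condition"],
            "stakes": data["stakes"],
            "corrected_reward": corrected,
        }
    )[valid]
    out = (
        df.groupby(["transition_condition", "stakes"], sort=True)["corrected_reward"]
        .agg(mean_corrected_reward="mean", n_trials="size")
        .reset_index()
    )
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def metacontrol_index(params: ModelParams | dict) -> dict[str, float]:
    """omega(high stakes) − omega(low stakes), per transition condition.

    Accepts a fitted/generating :class:`ModelParams` or a bare omega
    mapping. Values lie in [−1, 1] because each weight lies in [0, 1].
    """
    omega = params.omega if isinstance(params, ModelParams) else dict(params)
    index: dict[str, float] = {}
    if "low" in omega or "high" in omega:
        if not {"low", "high"} <= set(omega):
            raise ValueError("omega must contain both 'low' and 'high' cells")
        index["stable"] = omega["high"] - omega["low"]
        return index
    for cond in ("stable", "variable"):
        hi, lo = f"{cond}_high", f"{cond}_low"
        if hi in omega or lo in omega:
            if not {hi, lo} <= set(omega):
                raise ValueError(f"omega is missing a stakes cell for {cond!r}")
            index[cond] = omega[hi] - omega[lo]
    if not index:
        raise ValueError(f"no recognizable condition cells in {set(omega)}")
    return index


def stakes_performance_gain(performance: pd.DataFrame) -> dict[str, float]:
    """High-stakes minus low-stakes mean performance per transition condition."""
    gains = {}
    for cond, grp in performance.groupby("transition_condition"):
        by = grp.set_index("stakes")["mean_corrected_reward"]
        if not {"low", "high"} <= set(by.index):
            raise ValueError(f"missing stakes cell in condition {cond!r}")
        gains[str(cond)] = float(by["high"] - by["low"])
    return gains
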