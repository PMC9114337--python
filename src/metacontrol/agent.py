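"""Hybrid model-free / model-based learner for the two-stage stakes task.

The learner combines two valuation systems at the first stage:

* a model-free system holding cached reward expectations ``Q_MF(s, a)``
  updated by temporal-difference errors with a within-trial eligibility
  trace (decay ``lam``), and
* a model-based system that learns the action→planet transition
  probabilities ``T(planet | s1, a1)`` from state prediction errors (rates
  ``eta`` for the chosen action, ``eta_cf`` for the counterfactual update
  of the unchosen action) and plans first-stage values as the expectation
  of the planets' reward estimates under ``T``.

Both values are mixed with a condition-specific model-based weight
``omega`` and passed through a softmax with inverse temperature ``beta``,
plus stimulus-perseveration (``pi``) and key-perseveration (``rho``)
bonuses. The same update engine drives generative simulation and the
trial-wise choice likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import (
    N_ACTIONS,
    N_FIRST_STAGE_STATES,
    N_PLANETS,
    STAKES_MULTIPLIERS,
    TaskLayout,
    TrialPlan,
)

Q_INIT = 4.5  # mean of the 0..9 reward range
T_INIT = 0.5


@dataclass
class ModelParams:
    """One participant's parameter vector.

    ``omega`` maps condition cells (e.g. ``"stable_low"`` or ``"low"``) to
    model-based weights in [0, 1]; it must have exactly one entry per cell
    of the layout it is used with.
    """

    alpha: float
    beta: float
    omega: dict[str, float]
    lam: float = 0.0
    eta: float = 1.0
    eta_cf: float = 1.0
    pi: float = 0.0
    rho: float = 0.0

    def validate(self, layout: TaskLayout | None = None) -> None:
        for name in ("alpha", "lam", "eta", "eta_cf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        for cell, w in self.omega.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"omega[{cell}]={w} outside [0, 1]")
        if layout is not None and set(self.omega) != set(layout.omega_cells):
            raise ValueError(
                f"omega cells {set(self.omega)} do not match layout cells "
                f"{set(layout.omega_cells)}"
            )

    def copy(self) -> "ModelParams":
        return replace(self, omega=dict(self.omega))


@dataclass
class AgentState:
    """The learner's mutable beliefs.

    ``trans[s, a]`` stores the probability that action ``a`` in first-stage
    state ``s`` leads to the red planet (index 0); the purple probability is
    its complement, so rows always sum to one.
    """

    q_mf1: np.ndarray  # (2, 2) first-stage cached values
    q_mf2: np.ndarray  # (2,)   planet values (single response per planet)
    trans: np.ndarray  # (2, 2) P(red | s1, a1)
    elig1: np.ndarray  # (2, 2)
    elig2: np.ndarray  # (2,)
    prev_state: int = -1  # previous trial's first-stage state (-1 = none)
    prev_action: int = -1
    prev_key: int = -1  # 0 = left, 1 = right


def init_agent_state(
    layout: TaskLayout, true_map: np.ndarray | None = None
) -> AgentState:
    """Fresh beliefs: all reward expectations at 4.5, transitions at 0.5.

    For layouts without transition changes the agent is instructed about
    the structure, so ``true_map`` (state × action → planet) may be given
    to initialize ``trans`` at the true deterministic probabilities.
    """
    trans = np.full((N_FIRST_STAGE_STATES, N_ACTIONS), T_INIT)
    if true_map is not None:
        trans = (np.asarray(true_map) == 0).astype(float)
    return AgentState(
        q_mf1=np.full((N_FIRST_STAGE_STATES, N_ACTIONS), Q_INIT),
        q_mf2=np.full(N_PLANETS, Q_INIT),
        trans=trans,
        elig1=np.zeros((N_FIRST_STAGE_STATES, N_ACTIONS)),
        elig2=np.zeros(N_PLANETS),
    )


def reset_eligibility(state: AgentState) -> None:
    """Traces are zeroed at the start of every trial (within-trial credit only)."""
    state.elig1[:] = 0.0
    state.elig2[:] = 0.0


def mf_update(
    state: AgentState,
    stage: int,
    s: int,
    a: int,
    r: float,
    next_value: float,
    alpha: float,
    lam: float,
) -> AgentState:
    """One temporal-difference backup for the pair just visited.

    Sets the visited pair's eligibility to 1, applies
    ``Q_MF += alpha * e * delta`` with ``delta = r + next_value - Q_MF(s, a)``
    to every state–action pair, then decays all traces by ``lam``.
    ``r`` is 0 after first-stage choices; ``next_value`` is 0 after
    second-stage events (planets are terminal).
    """
    if stage == 1:
        state.elig1[s, a] = 1.0
        delta = r + next_value - state.q_mf1[s, a]
    else:
        state.elig2[s] = 1.0
        delta = r + next_value - state.q_mf2[s]
    state.q_mf1 += alpha * state.elig1 * delta
    state.q_mf2 += alpha * state.elig2 * delta
    state.elig1 *= lam
    state.elig2 *= lam
    return state


def transition_update(
    state: AgentState,
    s1: int,
    a1: int,
    observed_planet: int,
    eta: float,
    eta_cf: float,
) -> AgentState:
    """State-prediction-error update of the transition beliefs.

    The chosen action's probability of the observed planet moves toward 1
    by ``eta * (1 - T)`` and the complement is rescaled by ``(1 - eta)``.
    Because the two actions of a first-stage state always lead to different
    planets, the unchosen action is updated toward the other planet with
    ``eta_cf``.
    """

    def _toward(p_red: float, planet: int, rate: float) -> float:
        if planet == 0:
            return p_red + rate * (1.0 - p_red)
        return p_red * (1.0 - rate)

    state.trans[s1, a1] = _toward(state.trans[s1, a1], observed_planet, eta)
    state.trans[s1, 1 - a1] = _toward(
        state.trans[s1, 1 - a1], 1 - observed_planet, eta_cf
    )
    return state


def mb_first_stage_values(state: AgentState) -> np.ndarray:
    """Planning values: expectation of planet values under learned transitions.

    Second-stage model-based values coincide with the model-free planet
    estimates, so ``Q_MB(s1, a1) = T(red|s1,a1) q2[red] + T(purple|s1,a1) q2[purple]``.
    """
    return state.trans * state.q_mf2[0] + (1.0 - state.trans) * state.q_mf2[1]


def choice_probabilities(
    state: AgentState,
    s1: int,
    cell: str,
    params: ModelParams,
    left_action: int = 0,
) -> np.ndarray:
    """Softmax policy over the two first-stage actions.

    Mixes model-free and model-based values with the cell's ``omega``, adds
    the stickiness bonuses ``pi * rep(a)`` (same stimulus chosen on the
    previous trial) and ``rho * resp(a)`` (same response key pressed on the
    previous trial), and applies a softmax with inverse temperature ``beta``.
    """
    if cell not in params.omega:
        raise ValueError(f"unknown condition cell {cell!r}")
    om = params.omega[cell]
    q_mb = mb_first_stage_values(state)
    v = (1.0 - om) * state.q_mf1[s1] + om * q_mb[s1]
    v = v.copy()
    if state.prev_state == s1 and state.prev_action >= 0:
        v[state.prev_action] += params.pi
    if state.prev_key >= 0:
        for a in range(N_ACTIONS):
            key = 0 if a == left_action else 1
            if key == state.prev_key:
                v[a] += params.rho
    x = params.beta * v
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def _effective_eta(params: ModelParams, transition_condition: str) -> tuple[float, float]:
    # transition learning applies only where the structure can change;
    # in stable blocks a single observation pins the mapping (rate 1)
    if transition_condition == "stable":
        return 1.0, 1.0
    return params.eta, params.eta_cf


def _observe_trial(
    state: AgentState,
    params: ModelParams,
    s1: int,
    a1: int,
    s2: int,
    reward: float | None,
    transition_condition: str,
    learn_transitions: bool,
) -> None:
    """Apply one trial's learning updates in their within-trial order.

    Order: first-stage TD backup (r = 0, successor value = current planet
    estimate) at transition time, then the transition update on observing
    the planet, then — if a reward was collected — the second-stage reward
    backup, whose prediction error also reaches the first-stage pair
    through the eligibility trace.
    """
    mf_update(state, 1, s1, a1, 0.0, state.q_mf2[s2], params.alpha, params.lam)
    if learn_transitions:
        eta, eta_cf = _effective_eta(params, transition_condition)
        transition_update(state, s1, a1, s2, eta, eta_cf)
    if reward is not None:
        mf_update(state, 2, s2, 0, float(reward), 0.0, params.alpha, params.lam)


BEHAVIOR_COLUMNS = [
    "trial", "block", "transition_condition", "stakes", "s1", "a1", "key1",
    "s2", "reward", "points", "missing_stage1", "missing_stage2", "left_action",
]


def simulate_agent(
    params: ModelParams,
    plan: TrialPlan,
    seed: int = 0,
    missing_rate: float = 0.0,
    record_probs: bool = False,
) -> pd.DataFrame:
    """Play the task trial by trial with the hybrid learner.

    Missing responses are injected independently at each stage with
    probability ``missing_rate``. A missing first-stage response cancels
    the trial (no transition, no reward, perseveration markers reset); a
    missing second-stage response forfeits the reward but the observed
    transition still informs the transition beliefs.

    Returns a behavior table (one row per trial). With ``record_probs``
    an extra column ``p_choice`` holds the probability of the sampled
    action — useful for checking likelihood replays.
    """
    layout = plan.layout
    params.validate(layout)
    rng = np.random.default_rng(seed)
    learn = layout.has_variable_blocks
    true_map = None if learn else plan.transition_map[0]
    state = init_agent_state(layout, true_map=true_map)

    rows = []
    for t in range(plan.n_trials):
        s1 = int(plan.first_stage_state[t])
        stakes = plan.stakes[t]
        cond = plan.transition_condition[t]
        cell = layout.cell(cond, stakes)
        left = int(plan.left_action[t])
        reset_eligibility(state)

        miss1 = missing_rate > 0 and rng.random() < missing_rate
        if miss1:
            state.prev_state = state.prev_action = state.prev_key = -1
            rows.append(
                (t, plan.block[t], cond, stakes, s1, -1, -1, -1, -1, 0, True, False, left)
                + ((np.nan,) if record_probs else ())
            )
            continue

        p = choice_probabilities(state, s1, cell, params, left_action=left)
        a1 = int(rng.random() < p[1])
        key1 = 0 if a1 == left else 1
        s2 = int(plan.transition_map[t, s1, a1])

        miss2 = missing_rate > 0 and rng.random() < missing_rate
        reward = None if miss2 else int(plan.reward_walk.displayed[t, s2])
        points = 0 if reward is None else reward * STAKES_MULTIPLIERS[stakes]

        _observe_trial(state, params, s1, a1, s2, reward, cond, learn)
        state.prev_state, state.prev_action, state.prev_key = s1, a1, key1
        rows.append(
            (t, plan.block[t], cond, stakes, s1, a1, key1, s2,
             -1 if reward is None else reward, points, False, miss2, left)
            + ((float(p[a1]),) if record_probs else ())
        )

    cols = BEHAVIOR_COLUMNS + (["p_choice"] if record_probs else [])
    return pd.DataFrame(rows, columns=cols)


def infer_static_map(data: pd.DataFrame) -> np.ndarray:
    """Recover a constant action→planet map from observed transitions."""
    mapping = np.full((N_FIRST_STAGE_STATES, N_ACTIONS), -1, dtype=int)
    for s in range(N_FIRST_STAGE_STATES):
        sub = data[(data["s1"] == s) & (data["a1"] >= 0) & (data["s2"] >= 0)]
        if len(sub) == 0:
            # state never visited: its map never enters the likelihood
            mapping[s] = (0, 1)
            continue
        a1 = int(sub["a1"].iloc[0])
        s2 = int(sub["s2"].iloc[0])
        mapping[s, a1] = s2
        mapping[s, 1 - a1] = 1 - s2
    return mapping


class SessionData:
    """Pre-extracted plain arrays of one behavior table, for fast replay."""

    def __init__(self, data: pd.DataFrame, layout: TaskLayout):
        if len(data) == 0:
            raise ValueError("empty behavior table")
        self.layout = layout
        self.n = len(data)
        self.s1 = data["s1"].to_numpy(int).tolist()
        self.a1 = data["a1"].to_numpy(int).tolist()
        self.s2 = data["s2"].to_numpy(int).tolist()
        self.reward = data["reward"].to_numpy(int).tolist()
        self.left = data["left_action"].to_numpy(int).tolist()
        self.miss2 = data["missing_stage2"].to_numpy(bool).tolist()
        cells = list(layout.omega_cells)
        self.cell_names = cells
        self.cell_idx = [
            cells.index(layout.cell(c, s))
            for c, s in zip(data["transition_condition"], data["stakes"])
        ]
        self.stable = [c == "stable" for c in data["transition_condition"]]
        self.learn = layout.has_variable_blocks
        self.true_map = None if self.learn else infer_static_map(data)
        self.n_valid = int((data["a1"] >= 0).sum())


def log_likelihood(
    params: ModelParams,
    data: pd.DataFrame | SessionData,
    layout: TaskLayout | None = None,
    return_trace: bool = False,
) -> float | tuple[float, list[float]]:
    """Log-likelihood of the observed first-stage choices.

    Replays the learning updates along the recorded behavior exactly as in
    :func:`simulate_agent`. Trials with a missing first-stage response
    contribute no likelihood term and no update (and reset the
    perseveration markers); trials with a missing second-stage response
    contribute the choice term and the transition update but no
    reward backup.
    """
    if isinstance(data, pd.DataFrame):
        if layout is None:
            raise ValueError("layout required when passing a DataFrame")
        data = SessionData(data, layout)
    sd = data
    alpha, lam, beta = params.alpha, params.lam, params.beta
    pi, rho = params.pi, params.rho
    eta, eta_cf = params.eta, params.eta_cf
    if any(not math.isfinite(v) for v in (alpha, lam, beta, pi, rho, eta, eta_cf)):
        raise ValueError("non-finite parameter")
    om_by_cell = [params.omega[c] for c in sd.cell_names]
    if any(not math.isfinite(v) for v in om_by_cell):
        raise ValueError("non-finite omega")

    q1 = [Q_INIT] * 4  # index s1 * 2 + a
    q2 = [Q_INIT, Q_INIT]
    if sd.learn:
        tr = [T_INIT] * 4  # P(red | s1, a1)
    else:
        m = sd.true_map
        tr = [1.0 - float(m[s, a]) for s in range(2) for a in range(2)]
    prev_s1 = prev_a1 = prev_key = -1
    ll = 0.0
    trace: list[float] = []
    exp_, log_ = math.exp, math.log

    for t in range(sd.n):
        a1 = sd.a1[t]
        if a1 < 0:
            prev_s1 = prev_a1 = prev_key = -1
            continue
        s1 = sd.s1[t]
        base = s1 * 2
        t0, t1 = tr[base], tr[base + 1]
        qmb0 = t0 * q2[0] + (1.0 - t0) * q2[1]
        qmb1 = t1 * q2[0] + (1.0 - t1) * q2[1]
        om = om_by_cell[sd.cell_idx[t]]
        v0 = (1.0 - om) * q1[base] + om * qmb0
        v1 = (1.0 - om) * q1[base + 1] + om * qmb1
        if prev_s1 == s1:
            if prev_a1 == 0:
                v0 += pi
            else:
                v1 += pi
        if prev_key >= 0:
            left = sd.left[t]
            if (0 if left == 0 else 1) == prev_key:
                v0 += rho
            if (0 if left == 1 else 1) == prev_key:
                v1 += rho
        x0, x1 = beta * v0, beta * v1
        mx = x0 if x0 > x1 else x1
        e0, e1 = exp_(x0 - mx), exp_(x1 - mx)
        p = (e0 if a1 == 0 else e1) / (e0 + e1)
        # guard underflow at extreme inverse temperatures: log of the
        # smallest positive double keeps the objective finite for the optimizer
        ll += log_(p) if p > 0.0 else -745.0
        if return_trace:
            trace.append(p)

        # learning updates (same order as the generative engine)
        s2 = sd.s2[t]
        j = base + a1
        q1[j] += alpha * (q2[s2] - q1[j])  # first-stage backup, r = 0
        if sd.learn:
            et, ec = (1.0, 1.0) if sd.stable[t] else (eta, eta_cf)
            if s2 == 0:
                tr[j] += et * (1.0 - tr[j])
            else:
                tr[j] *= 1.0 - et
            j2 = base + 1 - a1
            if s2 == 1:  # counterfactual action leads to the other planet
                tr[j2] += ec * (1.0 - tr[j2])
            else:
                tr[j2] *= 1.0 - ec
        if not sd.miss2[t]:
            d2 = sd.reward[t] - q2[s2]
            q2[s2] += alpha * d2
            q1[j] += alpha * lam * d2  # credit via the eligibility trace
        prev_s1, prev_a1 = s1, a1
        prev_key = 0 if a1 == sd.left[t] else 1

    if return_trace:
        return ll, trace
    return ll
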