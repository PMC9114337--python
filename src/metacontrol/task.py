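"""Two-stage sequential decision task: schedules, reward walks, transitions.

The task has two first-stage states (two pairs of spaceships). In each
first-stage state one of two actions is chosen; each action leads
deterministically to one of two planets (red / purple), and within a
first-stage state the two actions always lead to different planets. Each
planet offers a slowly drifting reward in 0..9 points, and a per-trial
stakes cue multiplies earned rewards by 1 (low) or 5 (high).

Two session layouts are supported:

* ``study1`` — 320 trials in four 80-trial blocks, alternating between
  stable-transition blocks (the action→planet map is fixed) and
  variable-transition blocks (every 6–14 trials one pair of spaceships
  swaps destinations).
* ``study2`` — 280 trials, all with a stable transition structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FIRST_STAGE_STATES = 2
N_ACTIONS = 2
N_PLANETS = 2
PLANET_NAMES = ("red", "purple")
STAKES_MULTIPLIERS = {"low": 1, "high": 5}

SWAP_GAP_MIN = 6
SWAP_GAP_MAX = 14


@dataclass(frozen=True)
class TaskLayout:
    """Session layout: trial counts, block structure, condition schedule."""

    study_id: str
    n_trials: int
    block_length: int
    transition_condition_per_block: tuple[str, ...]
    stakes_multipliers: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.block_length <= 0:
            raise ValueError("n_trials and block_length must be positive")
        if self.n_trials != self.block_length * len(self.transition_condition_per_block):
            raise ValueError("block structure does not cover n_trials")
        for cond in self.transition_condition_per_block:
            if cond not in ("stable", "variable"):
                raise ValueError(f"unknown transition condition {cond!r}")
        if tuple(sorted(self.stakes_multipliers)) != (1, 5):
            raise ValueError("stakes multipliers must be exactly {1, 5}")

    @property
    def n_blocks(self) -> int:
        return len(self.transition_condition_per_block)

    @property
    def has_variable_blocks(self) -> bool:
        return "variable" in self.transition_condition_per_block

    @property
    def omega_cells(self) -> tuple[str, ...]:
        """Condition cells that carry a separate model-based weight."""
        if self.has_variable_blocks:
            return (
                "stable_low", "stable_high", "variable_low", "variable_high",
            )
        return ("low", "high")

    def cell(self, transition_condition: str, stakes: str) -> str:
        if self.has_variable_blocks:
            return f"{transition_condition}_{stakes}"
        return stakes

    @property
    def n_counterbalance_cells(self) -> int:
        # block-order flip only exists when both conditions occur
        return 4 if self.has_variable_blocks else 2


def study1_layout() -> TaskLayout:
    """320 trials, four blocks of 80, alternating stable/variable."""
    return TaskLayout(
        study_id="study1",
        n_trials=320,
        block_length=80,
        transition_condition_per_block=("stable", "variable", "stable", "variable"),
    )


def study2_layout() -> TaskLayout:
    """280 trials, one stable transition structure throughout."""
    return TaskLayout(
        study_id="study2",
        n_trials=280,
        block_length=280,
        transition_condition_per_block=("stable",),
    )


def get_layout(study_id: str) -> TaskLayout:
    if study_id == "study1":
        return study1_layout()
    if study_id == "study2":
        return study2_layout()
    raise ValueError(f"unknown study_id {study_id!r}")


@dataclass(frozen=True)
class RewardWalk:
    """Independent bounded Gaussian random walks, one per planet.

    ``latent`` holds the continuous walk values (n_trials × n_planets);
    ``displayed`` the integer rewards shown to the participant, obtained by
    rounding the latent value. Reflection at the bounds acts on the latent
    value; rounding is display-side only.
    """

    latent: np.ndarray
    displayed: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return self.latent.shape[0]


def _reflect(v: float, lower: float, upper: float) -> float:
    # fold excursions back into [lower, upper]; iterate for large jumps
    while v < lower or v > upper:
        if v > upper:
            v = 2.0 * upper - v
        if v < lower:
            v = 2.0 * lower - v
    return v


def generate_reward_walk(
    seed: int,
    n_trials: int,
    sd: float = 2.0,
    lower: float = 0.0,
    upper: float = 9.0,
    n_planets: int = N_PLANETS,
) -> RewardWalk:
    """Gaussian random walk with reflecting boundaries, rounded for display.

    Each planet's walk evolves as ``x[t+1] = reflect(x[t] + eps)`` with
    ``eps ~ Normal(0, sd^2)``. Start values are drawn uniformly on
    [lower, upper]. Distinct sub-streams per planet keep the walks
    statistically independent; the same seed reproduces the walk exactly.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not lower < upper:
        raise ValueError("lower must be < upper")
    latent = np.empty((n_trials, n_planets))
    for p in range(n_planets):
        rng = np.random.default_rng([seed, p])
        x = rng.uniform(lower, upper)
        steps = rng.normal(0.0, sd, size=n_trials - 1) if sd > 0 else np.zeros(n_trials - 1)
        latent[0, p] = x
        for t in range(1, n_trials):
            x = _reflect(x + steps[t - 1], lower, upper)
            latent[t, p] = x
    displayed = np.rint(latent).astype(int)
    return RewardWalk(latent=latent, displayed=displayed, seed=seed)


@dataclass
class TrialPlan:
    """Experimenter-side schedule of one session.

    Arrays are indexed by trial. ``transition_map[t, s, a]`` gives the
    planet (0=red, 1=purple) reached by action ``a`` in first-stage state
    ``s`` on trial ``t``. ``left_action[t]`` is the action index displayed
    on the left of the screen (defines the response key of each action).
    """

    layout: TaskLayout
    first_stage_state: np.ndarray  # (n,) int in {0,1}
    stakes: np.ndarray  # (n,) str "low"/"high"
    block: np.ndarray  # (n,) int
    transition_condition: np.ndarray  # (n,) str
    transition_map: np.ndarray  # (n, 2, 2) int planet ids
    left_action: np.ndarray  # (n,) int in {0,1}
    reward_walk: RewardWalk
    swap_trials: dict[int, int] = field(default_factory=dict)  # trial -> swapped state
    counterbalance_id: int = 0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.layout.n_trials

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, serializable as CSV."""
        n = self.n_trials
        return pd.DataFrame(
            {
                "trial": np.arange(n),
                "block": self.block,
                "transition_condition": self.transition_condition,
                "stakes": self.stakes,
                "first_stage_state": self.first_stage_state,
                "action0_dest": self.transition_map[:, 0, 0] * (
                    self.first_stage_state == 0
                ) + self.transition_map[:, 1, 0] * (self.first_stage_state == 1),
                "action1_dest": self.transition_map[:, 0, 1] * (
                    self.first_stage_state == 0
                ) + self.transition_map[:, 1, 1] * (self.first_stage_state == 1),
                "left_action": self.left_action,
                "reward_planet_red": self.reward_walk.displayed[:, 0],
                "reward_planet_purple": self.reward_walk.displayed[:, 1],
            }
        )


def _swap_schedule(block_length: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """(within-block trial index, swapped first-stage state) pairs.

    Gaps between consecutive swaps are uniform on {6, ..., 14}; a pending
    swap past the block end is dropped.
    """
    swaps = []
    t = int(rng.integers(SWAP_GAP_MIN, SWAP_GAP_MAX + 1))
    while t < block_length:
        swaps.append((t, int(rng.integers(0, N_FIRST_STAGE_STATES))))
        t += int(rng.integers(SWAP_GAP_MIN, SWAP_GAP_MAX + 1))
    return swaps


def _balanced_labels(n: int, labels: tuple, rng: np.random.Generator) -> np.ndarray:
    half = n // 2
    vec = np.array([labels[0]] * half + [labels[1]] * (n - half), dtype=object)
    rng.shuffle(vec)
    return vec


def generate_trial_plan(
    layout: TaskLayout,
    counterbalance_id: int = 0,
    seed: int = 0,
) -> TrialPlan:
    """Build the complete schedule of a session.

    The reward walk and first-stage-state sequence depend only on ``seed``
    and are shared across participants; stakes assignment and block-order
    counterbalancing depend on ``counterbalance_id``. The stakes labels are
    perfectly balanced within each block.
    """
    if not 0 <= counterbalance_id < layout.n_counterbalance_cells:
        raise ValueError(
            f"counterbalance_id must be in [0, {layout.n_counterbalance_cells})"
        )
    n = layout.n_trials

    # shared-across-participants components
    shared_rng = np.random.default_rng([seed, 1000])
    walk = generate_reward_walk(seed, n)
    first_stage = _balanced_labels(n, (0, 1), shared_rng).astype(int)
    left_action = shared_rng.integers(0, 2, size=n)

    # counterbalanced components
    flip_blocks = bool(counterbalance_id & 1) and layout.has_variable_blocks
    conds = list(layout.transition_condition_per_block)
    if flip_blocks:
        conds = conds[::-1]
    cb_rng = np.random.default_rng([seed, 2000, counterbalance_id])
    stakes = np.concatenate(
        [
            _balanced_labels(layout.block_length, ("low", "high"), cb_rng)
            for _ in range(layout.n_blocks)
        ]
    )

    block = np.repeat(np.arange(layout.n_blocks), layout.block_length)
    transition_condition = np.repeat(np.array(conds, dtype=object), layout.block_length)

    # initial action->planet map per state: one action to red, the other purple
    plan_rng = np.random.default_rng([seed, 3000, counterbalance_id])
    current = np.empty((N_FIRST_STAGE_STATES, N_ACTIONS), dtype=int)
    for s in range(N_FIRST_STAGE_STATES):
        red_action = int(plan_rng.integers(0, 2))
        current[s, red_action] = 0
        current[s, 1 - red_action] = 1

    transition_map = np.empty((n, N_FIRST_STAGE_STATES, N_ACTIONS), dtype=int)
    swap_trials: dict[int, int] = {}
    for b, cond in enumerate(conds):
        start = b * layout.block_length
        swaps = (
            dict(_swap_schedule(layout.block_length, plan_rng))
            if cond == "variable"
            else {}
        )
        for i in range(layout.block_length):
            t = start + i
            if i in swaps:
                s = swaps[i]
                current[s] = current[s, ::-1]
                swap_trials[t] = s
            transition_map[t] = current

    return TrialPlan(
        layout=layout,
        first_stage_state=first_stage,
        stakes=stakes,
        block=block,
        transition_condition=transition_condition,
        transition_map=transition_map,
        left_action=np.asarray(left_action),
        reward_walk=walk,
        swap_trials=swap_trials,
        counterbalance_id=counterbalance_id,
        seed=seed,
    )
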