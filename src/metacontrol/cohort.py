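"""Synthetic participant cohorts with known generating parameters.

Stands in for a study sample: each participant gets a parameter vector
drawn from a population distribution, plays the task (via the generative
hybrid agent) on a counterbalanced plan, and receives a Need-for-Cognition
(NFC) total score constructed to have an exact target population
correlation with the generating metacontrol index. Cohorts are fully
reproducible from their spec and seed.

NFC scales: the 16-item scale scored −3..+3 per item (totals in [−48, 48])
and the 18-item scale scored 1..5 per item (totals in [18, 90]). Totals
are generated directly on the scale's range — no item-level simulation —
and kept continuous so that the exact-correlation construction holds to
floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .agent import ModelParams, simulate_agent
from .metrics import metacontrol_index
from .task import TaskLayout, generate_trial_plan, get_layout

NFC_SCALES = {
    "german16": {"lower": -48.0, "upper": 48.0, "mean": 14.63, "sd": 13.48},
    "english18": {"lower": 18.0, "upper": 90.0, "mean": 64.81, "sd": 9.68},
}


@dataclass
class ParameterPopulation:
    """Population distributions for per-participant generating parameters.

    Defaults are wide, compatible with the fitting priors, and produce
    mostly-positive metacontrol effects (scatter on or above the identity
    line when plotting omega_high against omega_low).
    """

    alpha_beta_ab: tuple[float, float] = (3.0, 3.0)  # Beta for alpha
    beta_shape: float = 4.0  # Gamma for inverse temperature
    beta_scale: float = 0.25
    stickiness_sd: float = 0.3  # Normal(0, sd) for pi and rho
    omega_low_ab: tuple[float, float] = (2.0, 3.0)  # Beta for omega_low
    effect_mean: float = 0.15  # omega_high - omega_low, truncated normal
    effect_sd: float = 0.15
    lam_ab: tuple[float, float] = (2.0, 2.0)  # Beta for lam (if the variant uses it)


@dataclass
class CohortSpec:
    n_participants: int
    layout: TaskLayout | str = "study2"
    population: ParameterPopulation = field(default_factory=ParameterPopulation)
    nfc_scale: str = "german16"
    rho_nfc_metacontrol: float = 0.0
    missing_rate: float = 0.0
    plan_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.layout, str):
            self.layout = get_layout(self.layout)
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.nfc_scale not in NFC_SCALES:
            raise ValueError(f"unknown NFC scale {self.nfc_scale!r}")
        if not abs(self.rho_nfc_metacontrol) < 1:
            raise ValueError("|rho_nfc_metacontrol| must be < 1")


@dataclass
class SyntheticParticipant:
    id: int
    params: ModelParams
    behavior: pd.DataFrame
    nfc_total: float
    counterbalance_id: int

    @property
    def missing_fraction(self) -> float:
        missing = (self.behavior["missing_stage1"] | self.behavior["missing_stage2"])
        return float(missing.mean())

    @property
    def key_repetition_fraction(self) -> float:
        keys = self.behavior.loc[self.behavior["key1"] >= 0, "key1"].to_numpy()
        if len(keys) < 2:
            return 0.0
        return float((keys[1:] == keys[:-1]).mean())

    def generating_metacontrol(self) -> float:
        """Mean of the per-condition metacontrol indices of the true params."""
        idx = metacontrol_index(self.params)
        return float(np.mean(list(idx.values())))


def _draw_params(
    spec: CohortSpec, rng: np.random.Generator
) -> ModelParams:
    pop = spec.population
    layout = spec.layout
    alpha = float(rng.beta(*pop.alpha_beta_ab))
    beta = float(rng.gamma(pop.beta_shape, pop.beta_scale))
    pi = float(rng.normal(0.0, pop.stickiness_sd))
    rho = float(rng.normal(0.0, pop.stickiness_sd))
    lam = float(rng.beta(*pop.lam_ab)) if layout.has_variable_blocks else 0.0
    omega: dict[str, float] = {}
    conds = (
        ("stable", "variable") if layout.has_variable_blocks else (None,)
    )
    for cond in conds:
        lo = float(rng.beta(*pop.omega_low_ab))
        # truncated so the high-stakes weight stays in [0, 1]
        while True:
            effect = float(rng.normal(pop.effect_mean, pop.effect_sd))
            if 0.0 <= lo + effect <= 1.0:
                break
        hi = lo + effect
        if cond is None:
            omega["low"], omega["high"] = lo, hi
        else:
            omega[f"{cond}_low"], omega[f"{cond}_high"] = lo, hi
    return ModelParams(
        alpha=alpha, beta=beta, omega=omega, lam=lam, eta=1.0, eta_cf=1.0,
        pi=pi, rho=rho,
    )


def _exact_correlation_scores(
    anchor: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Standardized scores with exact sample correlation rho to ``anchor``."""
    n = len(anchor)
    xc = anchor - anchor.mean()
    sx = xc.std()
    if sx == 0:
        raise ValueError(
            "anchor variable has zero variance; a nonzero target correlation "
            "is infeasible"
        )
    x = xc / sx
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - x * (x @ e) / (x @ x)
    e = e / e.std()
    return rho * x + np.sqrt(1.0 - rho * rho) * e


def _nfc_totals(
    metacontrol: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    scale = NFC_SCALES[spec.nfc_scale]
    z = _exact_correlation_scores(metacontrol, spec.rho_nfc_metacontrol, rng)
    # affine rescaling preserves the correlation exactly; shrink the spread
    # if a draw would leave the scale's admissible range
    center, sd = scale["mean"], scale["sd"]
    lim_hi = (scale["upper"] - center) / z.max() if z.max() > 0 else np.inf
    lim_lo = (scale["lower"] - center) / z.min() if z.min() < 0 else np.inf
    s = min(sd, lim_hi, lim_lo)
    return center + s * z


def generate_cohort(spec: CohortSpec) -> list[SyntheticParticipant]:
    """Draw a full synthetic cohort: parameters, behavior, NFC scores.

    The population correlation between the NFC totals and the generating
    metacontrol index equals ``spec.rho_nfc_metacontrol`` exactly (up to
    floating point). Plans are counterbalanced round-robin across
    participants and share the reward walk / state sequence given by
    ``plan_seed``.
    """
    layout = spec.layout
    rng = np.random.default_rng(spec.seed)
    plans = {
        cb: generate_trial_plan(layout, counterbalance_id=cb, seed=spec.plan_seed)
        for cb in range(layout.n_counterbalance_cells)
    }
    participants = []
    for i in range(spec.n_participants):
        params = _draw_params(spec, rng)
        cb = i % layout.n_counterbalance_cells
        behavior = simulate_agent(
            params, plans[cb], seed=int(rng.integers(2**31)),
            missing_rate=spec.missing_rate,
        )
        participants.append(
            SyntheticParticipant(
                id=i, params=params, behavior=behavior, nfc_total=np.nan,
                counterbalance_id=cb,
            )
        )
    metacontrol = np.array([p.generating_metacontrol() for p in participants])
    if spec.n_participants >= 3:
        nfc = _nfc_totals(metacontrol, spec, rng)
    else:  # too few points to orthogonalize; uncorrelated draws
        scale = NFC_SCALES[spec.nfc_scale]
        nfc = np.clip(
            rng.normal(scale["mean"], scale["sd"], spec.n_participants),
            scale["lower"], scale["upper"],
        )
    for p, v in zip(participants, nfc):
        p.nfc_total = float(v)
    return participants


def exclusion_filter(
    cohort: list[SyntheticParticipant],
    max_missing_fraction: float = 0.20,
    max_key_repetition_fraction: float | None = None,
) -> tuple[list[SyntheticParticipant], list[dict]]:
    """Apply the study's exclusion rules.

    Participants are excluded when their fraction of trials with a missing
    first- or second-stage response is *strictly greater* than
    ``max_missing_fraction`` (a participant at exactly the threshold is
    retained). Optionally, participants repeating the same response key in
    strictly more than ``max_key_repetition_fraction`` of consecutive valid
    trials are excluded as well.
    """
    if not cohort:
        raise ValueError("empty cohort")
    retained, log = [], []
    for p in cohort:
        reasons = []
        if p.missing_fraction > max_missing_fraction:
            reasons.append(
                f"missing responses in {p.missing_fraction:.1%} of trials"
            )
        if (
            max_key_repetition_fraction is not None
            and p.key_repetition_fraction > max_key_repetition_fraction
        ):
            reasons.append(
                f"key repetitions in {p.key_repetition_fraction:.1%} of trials"
            )
        if reasons:
            log.append({"id": p.id, "reasons": reasons})
        else:
            retained.append(p)
    return retained, log
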