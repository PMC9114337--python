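"""Bayes factors for correlations and paired mean differences.

Correlation tests put a stretched beta prior on the population correlation
rho: a Beta(1/kappa, 1/kappa) density rescaled from (0, 1) to (−1, 1).
kappa = 1 is uniform over (−1, 1); smaller kappa concentrates mass near 0.
The Bayes factor integrates the exact sampling density of the Pearson
correlation under bivariate normality over this prior,

    BF10 = ∫ p(r | rho, n) pi_kappa(rho) d rho / p(r | 0, n),

so it depends on the data only through (r, n). One-sided tests restrict
and renormalize the prior to the requested half-line.

Mean-difference tests use the Jeffreys–Zellner–Siow (JZS) default: a
Cauchy prior with scale ``rscale`` on the standardized effect size,
integrated against the noncentral-t sampling density of the paired
t statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats

_QUAD_OPTS = dict(epsabs=1e-10, epsrel=1e-10, limit=300)

SIDES = ("two_sided", "negative", "positive")

#: conventional evidence categories, with boundaries at 1/10, 1/3, 3, 10
EVIDENCE_LABELS = (
    (0.1, "strong_null"),
    (1.0 / 3.0, "moderate_null"),
    (3.0, "anecdotal"),
    (10.0, "moderate_alt"),
    (math.inf, "strong_alt"),
)


def evidence_label(bf10: float) -> str:
    if not bf10 > 0:
        raise ValueError("bf10 must be positive")
    for bound, label in EVIDENCE_LABELS:
        if bf10 < bound:
            return label
    return "strong_alt"  # pragma: no cover


@dataclass(frozen=True)
class BayesConfig:
    """Prior settings: stretched-beta scale, test side, JZS Cauchy scale."""

    kappa: float = 1.0
    side: str = "two_sided"
    jzs_rscale: float = math.sqrt(2.0) / 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa <= 1.0:
            raise ValueError("kappa must be in (0, 1]")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.jzs_rscale <= 0:
            raise ValueError("jzs_rscale must be positive")


@dataclass(frozen=True)
class BFResult:
    bf10: float
    statistic: float
    n: int
    config: BayesConfig
    kind: str
    evidence: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", evidence_label(self.bf10))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "bf10": self.bf10,
            "statistic": self.statistic,
            "n": self.n,
            "kappa": self.config.kappa,
            "side": self.config.side,
            "jzs_rscale": self.config.jzs_rscale,
            "evidence": self.evidence,
        }


def log_pearson_r_density(r: float, rho: float, n: int) -> float:
    """Log sampling density of the Pearson correlation of a size-n bivariate
    normal sample with population correlation rho (exact, via 2F1)."""
    lg = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2.0 * math.log1p(-rho * rho)
        + (n - 4) / 2.0 * math.log1p(-r * r)
        - 0.5 * math.log(2.0 * math.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * math.log1p(-rho * r)
    )
    return lg + math.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))


def stretched_beta_logpdf(rho: np.ndarray | float, kappa: float) -> np.ndarray | float:
    """Log density of the stretched beta prior on (−1, 1)."""
    a = 1.0 / kappa
    rho = np.asarray(rho, dtype=float)
    out = (
        (a - 1.0) * (np.log1p(rho) + np.log1p(-rho) - 2.0 * math.log(2.0))
        - math.log(2.0)
        - special.betaln(a, a)
    )
    return out if out.ndim else float(out)


def bf_correlation(r: float, n: int, config: BayesConfig | None = None) -> BFResult:
    """Stretched-beta Bayes factor for a Pearson correlation.

    ``side='negative'`` (or ``'positive'``) restricts the prior to rho < 0
    (rho > 0) and renormalizes, testing a directional alternative against
    the point null.
    """
    config = config if config is not None else BayesConfig()
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    l0 = log_pearson_r_density(r, 0.0, n)

    def integrand(rho: float) -> float:
        return math.exp(
            log_pearson_r_density(r, rho, n)
            - l0
            + stretched_beta_logpdf(rho, config.kappa)
        )

    if config.side == "two_sided":
        lo, hi, prior_mass = -1.0, 1.0, 1.0
    elif config.side == "negative":
        lo, hi, prior_mass = -1.0, 0.0, 0.5
    else:
        lo, hi, prior_mass = 0.0, 1.0, 0.5
    num, _ = integrate.quad(integrand, lo, hi, **_QUAD_OPTS)
    return BFResult(
        bf10=num / prior_mass, statistic=r, n=n, config=config, kind="correlation"
    )


def bf_ttest_paired(t: float, n: int, config: BayesConfig | None = None) -> BFResult:
    """JZS Bayes factor for a paired (one-sample-on-differences) t test.

    Integrates the noncentral-t density of the observed statistic against a
    Cauchy(0, rscale) prior on the standardized effect size delta, divided
    by the central-t density (the point null).
    """
    config = config if config is not None else BayesConfig()
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    sqrt_n = math.sqrt(n)
    log_null = stats.t.logpdf(t, nu)

    def integrand(delta: float) -> float:
        return math.exp(
            stats.nct.logpdf(t, nu, delta * sqrt_n)
            + stats.cauchy.logpdf(delta, 0.0, config.jzs_rscale)
            - log_null
        )

    if config.side == "two_sided":
        lo, hi, prior_mass = -np.inf, np.inf, 1.0
    elif config.side == "negative":
        lo, hi, prior_mass = -np.inf, 0.0, 0.5
    else:
        lo, hi, prior_mass = 0.0, np.inf, 0.5
    num, _ = integrate.quad(integrand, lo, hi, **_QUAD_OPTS)
    return BFResult(bf10=num / prior_mass, statistic=t, n=n, config=config, kind="ttest")


def bf_robustness(
    r: float,
    n: int,
    kappa_grid,
    side: str = "two_sided",
) -> list[tuple[float, float]]:
    """Bayes-factor robustness curve over prior scales.

    Evaluates :func:`bf_correlation` for every kappa in ``kappa_grid``
    (each must lie in (0, 1]); output order follows the grid order.
    """
    grid = list(kappa_grid)
    if not grid:
        raise ValueError("kappa grid must be non-empty")
    curve = []
    for kappa in grid:
        res = bf_correlation(r, n, BayesConfig(kappa=float(kappa), side=side))
        curve.append((float(kappa), res.bf10))
    return curve
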