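"""Independent brute-force oracles used by the tests.

Everything here is a deliberately plain, literal transcription of the
model equations and integral definitions, structured differently from the
package implementation (dict-keyed tables, dense-grid quadrature), so that
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

STATES = [0, 1]
ACTIONS = [0, 1]
PLANETS = [0, 1]


# --------------------------------------------------------------------------
# model-free / transition update replay (dict-based, literal equations)
# --------------------------------------------------------------------------

def fresh_tables():
    q = {("s1", s, a): 4.5 for s in STATES for a in ACTIONS}
    q.update({("s2", p): 4.5 for p in PLANETS})
    T = {(s, a, p): 0.5 for s in STATES for a in ACTIONS for p in PLANETS}
    return q, T


def oracle_mf_episode(episode, alpha, lam):
    """Replay (s1, a1, s2, r) trials through the displayed TD equations.

    Eligibility traces are zeroed at trial start; each backup sets the
    visited pair's trace to 1, updates every table entry by
    alpha * e * delta, then decays all traces by lam.
    """
    q, _ = fresh_tables()
    keys = list(q.keys())
    for (s1, a1, s2, r) in episode:
        e = {k: 0.0 for k in keys}
        # first-stage backup: r = 0, successor value = current planet estimate
        e[("s1", s1, a1)] = 1.0
        delta = 0.0 + q[("s2", s2)] - q[("s1", s1, a1)]
        for k in keys:
            q[k] = q[k] + alpha * e[k] * delta
        for k in keys:
            e[k] = e[k] * lam
        # second-stage backup: terminal, successor value = 0
        e[("s2", s2)] = 1.0
        delta = r + 0.0 - q[("s2", s2)]
        for k in keys:
            q[k] = q[k] + alpha * e[k] * delta
        for k in keys:
            e[k] = e[k] * lam
    return q


def oracle_transition_episode(episode, eta, eta_cf):
    """Replay transition observations through the SPE update equations,
    keeping explicit two-planet probability vectors."""
    _, T = fresh_tables()
    for (s1, a1, s2) in episode:
        spe = 1.0 - T[(s1, a1, s2)]
        T[(s1, a1, s2)] = T[(s1, a1, s2)] + eta * spe
        T[(s1, a1, 1 - s2)] = T[(s1, a1, 1 - s2)] * (1.0 - eta)
        other = 1 - a1  # leads to the other planet with certainty
        spe_cf = 1.0 - T[(s1, other, 1 - s2)]
        T[(s1, other, 1 - s2)] = T[(s1, other, 1 - s2)] + eta_cf * spe_cf
        T[(s1, other, s2)] = T[(s1, other, s2)] * (1.0 - eta_cf)
    return T


def oracle_softmax(q_mf, q_mb, omega, beta, pi, rho, rep, resp):
    """P(a | s1) for two actions, literal formula."""
    x = []
    for a in ACTIONS:
        qa = (1.0 - omega) * q_mf[a] + omega * q_mb[a]
        x.append(beta * (qa + pi * rep[a] + rho * resp[a]))
    x = np.asarray(x)
    ex = np.exp(x - x.max())
    return ex / ex.sum()


# --------------------------------------------------------------------------
# full-session likelihood oracle
# --------------------------------------------------------------------------

def oracle_session_loglik(rows, params, learn_transitions, true_map=None):
    """Straight-line likelihood replay of a session.

    ``rows`` is a list of dicts with keys s1, a1, s2, reward,
    missing_stage2, left_action, omega (the trial's model-based weight) and
    stable (bool). a1 < 0 marks a missing first-stage response.
    """
    q, T = fresh_tables()
    if not learn_transitions:
        for s in STATES:
            for a in ACTIONS:
                for p in PLANETS:
                    T[(s, a, p)] = 1.0 if true_map[s][a] == p else 0.0
    prev = {"s1": None, "a1": None, "key": None}
    ll = 0.0
    for row in rows:
        if row["a1"] < 0:
            prev = {"s1": None, "a1": None, "key": None}
            continue
        s1, a1 = row["s1"], row["a1"]
        q_mf = [q[("s1", s1, a)] for a in ACTIONS]
        q_mb = [
            sum(T[(s1, a, p)] * q[("s2", p)] for p in PLANETS) for a in ACTIONS
        ]
        rep = [
            1.0 if (prev["s1"] == s1 and prev["a1"] == a) else 0.0 for a in ACTIONS
        ]
        key_of = {a: (0 if a == row["left_action"] else 1) for a in ACTIONS}
        resp = [
            1.0 if (prev["key"] is not None and key_of[a] == prev["key"]) else 0.0
            for a in ACTIONS
        ]
        p = oracle_softmax(
            q_mf, q_mb, row["omega"], params["beta"], params["pi"], params["rho"],
            rep, resp,
        )
        ll += np.log(p[a1])

        s2 = row["s2"]
        # first-stage backup at transition time
        e = {k: 0.0 for k in q}
        e[("s1", s1, a1)] = 1.0
        delta = q[("s2", s2)] - q[("s1", s1, a1)]
        for k in q:
            q[k] += params["alpha"] * e[k] * delta
        for k in q:
            e[k] *= params["lam"]
        if learn_transitions:
            eta = 1.0 if row["stable"] else params["eta"]
            eta_cf = 1.0 if row["stable"] else params["eta_cf"]
            spe = 1.0 - T[(s1, a1, s2)]
            T[(s1, a1, s2)] += eta * spe
            T[(s1, a1, 1 - s2)] *= 1.0 - eta
            other = 1 - a1
            T[(s1, other, 1 - s2)] += eta_cf * (1.0 - T[(s1, other, 1 - s2)])
            T[(s1, other, s2)] *= 1.0 - eta_cf
        if not row["missing_stage2"]:
            e[("s2", s2)] = 1.0
            delta = row["reward"] - q[("s2", s2)]
            for k in q:
                q[k] += params["alpha"] * e[k] * delta
        prev = {"s1": s1, "a1": a1, "key": key_of[a1]}
    return ll


def rows_from_behavior(data, layout):
    rows = []
    for rec in data.to_dict("records"):
        cell = layout.cell(rec["transition_condition"], rec["stakes"])
        rows.append(
            {
                "s1": rec["s1"], "a1": rec["a1"], "s2": rec["s2"],
                "reward": rec["reward"], "missing_stage2": bool(rec["missing_stage2"]),
                "left_action": rec["left_action"], "cell": cell,
                "stable": rec["transition_condition"] == "stable",
            }
        )
    return rows


def oracle_loglik_from_table(data, params_obj, layout):
    rows = rows_from_behavior(data, layout)
    for row in rows:
        row["omega"] = params_obj.omega[row.pop("cell")]
    learn = layout.has_variable_blocks
    true_map = None
    if not learn:
        from metacontrol.agent import infer_static_map

        true_map = infer_static_map(data).tolist()
    p = {
        "alpha": params_obj.alpha, "lam": params_obj.lam, "beta": params_obj.beta,
        "pi": params_obj.pi, "rho": params_obj.rho, "eta": params_obj.eta,
        "eta_cf": params_obj.eta_cf,
    }
    return oracle_session_loglik(rows, p, learn, true_map)


# --------------------------------------------------------------------------
# Bayes-factor quadrature oracles (dense grids)
# --------------------------------------------------------------------------

def _r_density_grid(r, rho, n):
    """Vectorized exact Pearson-r sampling density over a rho grid."""
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2.0 * np.log1p(-rho**2)
        + (n - 4) / 2.0 * np.log1p(-r**2)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(lg) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def oracle_bf_correlation(r, n, kappa, side="two_sided", n_grid=100_000):
    """Trapezoidal quadrature of the BF integrand on a dense rho grid."""
    eps = 1e-9
    if side == "two_sided":
        lo, hi, mass = -1 + eps, 1 - eps, 1.0
    elif side == "negative":
        lo, hi, mass = -1 + eps, 0.0, 0.5
    else:
        lo, hi, mass = 0.0, 1 - eps, 0.5
    rho = np.linspace(lo, hi, n_grid)
    a = 1.0 / kappa
    prior = ((1 + rho) / 2) ** (a - 1) * ((1 - rho) / 2) ** (a - 1) / (
        2 * special.beta(a, a)
    )
    like = _r_density_grid(r, rho, n)
    num = np.trapezoid(like * prior, rho)
    return num / (_r_density_grid(r, np.array([0.0]), n)[0] * mass)


def oracle_bf_ttest(t, n, rscale, n_grid=200_001, delta_max=15.0):
    """Dense-grid integration of the JZS integrand over the effect size."""
    delta = np.linspace(-delta_max, delta_max, n_grid)
    like = stats.nct.pdf(t, n - 1, delta * np.sqrt(n))
    prior = stats.cauchy.pdf(delta, 0, rscale)
    num = np.trapezoid(like * prior, delta)
    return num / stats.t.pdf(t, n - 1)
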