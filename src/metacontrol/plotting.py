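"""Diagnostic plots for fitted cohorts."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np


def metacontrol_scatter(omega_low, omega_high, ax=None, label=None):
    """Model-based weights on high-stakes vs low-stakes trials.

    Points on the identity line are participants who did not adapt their
    model-based weight to the stakes; points above it upregulated
    model-based control when rewards were amplified.
    """
    omega_low = np.asarray(omega_low, float)
    omega_high = np.asarray(omega_high, float)
    if omega_low.shape != omega_high.shape:
        raise ValueError("omega_low and omega_high must have the same shape")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], color="0.6", lw=1, zorder=1)
    ax.scatter(omega_low, omega_high, s=18, alpha=0.7, zorder=2, label=label)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(r"$\omega$ (low stakes)")
    ax.set_ylabel(r"$\omega$ (high stakes)")
    ax.set_aspect("equal")
    return ax


def power_curve_plot(curve, ax=None):
    """Evidence probabilities against the true population correlation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.rho_grid, curve.prob_alt_evidence,
            label=r"P(BF$_{10}\geq 3$)")
    ax.plot(curve.rho_grid, curve.prob_null_evidence,
            label=r"P(BF$_{10}\leq 1/3$)")
    ax.axhline(0.8, color="0.6", lw=1, ls="--")
    ax.set_xlabel(r"true population correlation $\rho$")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax
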