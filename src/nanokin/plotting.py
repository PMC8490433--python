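"""Matplotlib helpers for traces, event scatter plots and decision regions."""

from __future__ import annotations

import numpy as np


def plot_trace(trace, ax=None, *, t_range=None, show_truth=False):
    """Current vs time, optionally with the ground-truth state path overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    t = trace.times
    sel = slice(None)
    if t_range is not None:
        sel = (t >= t_range[0]) & (t <= t_range[1])
    ax.plot(t[sel], trace.samples[sel], lw=0.4, color="0.2")
    if show_truth and trace.truth is not None and trace.state_means:
        means = np.array([trace.state_means[s.state] for s in trace.truth.segments])
        idx = trace.truth.state_indices(trace.sampling_rate, trace.samples.size)
        ax.plot(t[sel], means[idx][sel], lw=1.0, color="tab:red", alpha=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (pA)")
    return ax


def plot_event_scatter(table, ax=None, *, log_x=True):
    """Blockage amplitude dI against dwell time t_off, one point per event."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    df = table.to_dataframe()
    ax.scatter(df["t_off_s"], df["delta_I_pA"], s=8, alpha=0.5)
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(r"$t_\mathrm{off}$ (s)")
    ax.set_ylabel(r"$\Delta I$ (pA)")
    return ax


def plot_titration(results, ax=None):
    """1/tau_on against concentration with the fitted association line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    pc = results.per_condition
    c = pc["concentration_molar"]
    r = 1.0 / pc["tau_on_s"]
    ax.errorbar(c * 1e3, r, yerr=pc["se_tau_on_s"] / pc["tau_on_s"] ** 2, fmt="o")
    rc = results.rate_constants
    cc = np.linspace(0, float(c.max()) * 1.05, 50)
    ax.plot(cc * 1e3, rc.intercept + rc.k_on * cc, "-", color="tab:red")
    ax.set_xlabel("concentration (mM)")
    ax.set_ylabel(r"$1/\tau_\mathrm{on}$ (s$^{-1}$)")
    return ax


def plot_decision_boundary(model, features_df, ax=None, *, resolution=200):
    """Decision regions in (lp_sd, hp_sd) space with the events overlaid."""
    import matplotlib.pyplot as plt

    from .discriminate import decision_boundary_grid

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    lp = features_df["lp_sd_pA"]
    hp = features_df["hp_sd_pA"]
    pad_lp = 0.1 * (lp.max() - lp.min() + 1e-9)
    pad_hp = 0.1 * (hp.max() - hp.min() + 1e-9)
    glp, ghp, labels = decision_boundary_grid(
        model,
        (float(lp.min() - pad_lp), float(lp.max() + pad_lp)),
        (float(hp.min() - pad_hp), float(hp.max() + pad_hp)),
        resolution,
    )
    classes = sorted(np.unique(labels.ravel()))
    codes = np.vectorize({c: i for i, c in enumerate(classes)}.get)(labels)
    ax.pcolormesh(glp, ghp, codes, alpha=0.25, shading="auto", cmap="Set2")
    for cls in classes:
        sel = features_df["label"] == cls
        ax.scatter(lp[sel], hp[sel], s=10, label=str(cls))
    ax.set_xlabel("low-pass SD (pA)")
    ax.set_ylabel("high-pass SD (pA)")
    ax.legend(fontsize=8)
    return ax
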