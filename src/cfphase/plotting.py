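"""Simple figures: aggregated WPS profiles and volcano plots."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_profile", "plot_volcano"]


def plot_profile(aggregate, fit=None, ax=None, label=None):
    """Aggregated WPS profile with its 95% confidence band.

    ``fit`` may be a PhasingOscillatorResults; its prediction is overlaid
    on the fit region.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(aggregate.distances, aggregate.ci_low, aggregate.ci_high, alpha=0.3, lw=0)
    ax.plot(aggregate.distances, aggregate.mean, lw=1, label=label or f"{aggregate.n_genes} genes")
    if fit is not None:
        lo, hi = fit.fit_region
        d = np.arange(lo, hi + 1)
        ax.plot(d, fit.predict(d), "--", lw=1, label=f"model (period {fit.params.period:.0f} bp)")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("WPS")
    ax.legend(frameon=False)
    return ax


def plot_volcano(results, effect_col="lfc", q_col="q", q_threshold=0.05, ax=None):
    """Effect size vs -log10(q) for a differential-test table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    q = results[q_col].to_numpy(dtype=float)
    x = results[effect_col].to_numpy(dtype=float)
    y = -np.log10(np.clip(q, 1e-300, None))
    sig = q <= q_threshold
    ax.scatter(x[~sig], y[~sig], s=8, c="grey", alpha=0.6)
    ax.scatter(x[sig], y[sig], s=10, c="crimson")
    ax.axhline(-np.log10(q_threshold), color="grey", lw=0.5, ls="--")
    ax.set_xlabel(effect_col)
    ax.set_ylabel(f"-log10({q_col})")
    return ax
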