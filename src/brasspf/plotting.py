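"""Convenience plots: schedule comparisons and P/F ratio bars."""

from __future__ import annotations


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_pf_ratios(table, ax=None):
    """Bar chart of P/F ratios by age group."""
    ax = _get_ax(ax)
    ax.bar(table.grid.labels, table.ratio)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("age group")
    ax.set_ylabel("P/F ratio")
    return ax


def plot_adjustment(results, ax=None):
    """Observed vs adjusted ASFR by age, with bounds when present."""
    ax = _get_ax(ax)
    grid = results.model.fertility.grid
    x = grid.midpoints
    ax.plot(x, results.model.fertility.f, marker="o", label="observed ASFR")
    ax.plot(x, results.f_adj, marker="s", label="adjusted ASFR")
    adj = results.adjusted
    if adj.lower is not None and adj.upper is not None:
        ax.fill_between(x, adj.lower, adj.upper, alpha=0.25, label="95% bounds")
    ax.set_xlabel("age")
    ax.set_ylabel("births per woman per 5-year interval")
    ax.legend()
    return ax
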