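"""Plot helpers: trajectory renderings, pruning learning curves, ensemble
box/bar charts and per-input connectivity distributions.

All functions draw onto a supplied (or fresh) matplotlib Axes and return
the figure, so they compose into panels; nothing is shown or saved here.
"""

from __future__ import annotations

import numpy as np

from .dynamics import BodyParams, Trajectory


def _get_ax(ax):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: Trajectory, params: BodyParams, ax=None,
                    n_poses: int = 5):
    """Render a stroke: joint path plus body-segment poses along the way."""
    ax = _get_ax(ax)
    ax.plot(traj.states[:, 0], traj.states[:, 1], "r:", lw=1, label="joint")
    a1, a2 = params.L1 / 2, params.L2 / 2
    idx = np.linspace(0, traj.times.size - 1, n_poses).astype(int)
    for i in idx:
        x, y, th, ph = traj.states[i, :4]
        head = (x + params.L1 * np.cos(th), y + params.L1 * np.sin(th))
        tail = (x - params.L2 * np.cos(ph), y - params.L2 * np.sin(ph))
        ax.plot([x, head[0]], [y, head[1]], "-", color="0.4", lw=2)
        ax.plot([x, tail[0]], [y, tail[1]], "-", color="0.7", lw=2)
        ax.plot([x + a1 * np.cos(th), x - a2 * np.cos(ph)],
                [y + a1 * np.sin(th), y - a2 * np.sin(ph)],
                "k.", ms=4)  # segment centroids
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    return ax.figure


def plot_prune_curve(records, pre_history=None, threshold: float = 1e-3,
                     ax=None):
    """Loss vs cumulative training batches with sparsity-step markers."""
    ax = _get_ax(ax)
    offset = 0
    if pre_history is not None:
        ax.plot(pre_history.batches, pre_history.losses, "b-", lw=1,
                label="fully connected")
        offset = pre_history.batches[-1]
    xs, ys = [], []
    for r in records:
        offset += max(r.retrain_batches, 1)
        xs.append(offset)
        ys.append(r.loss)
        ax.annotate(f"{r.target_sparsity:.0%}", (offset, r.loss), fontsize=6,
                    rotation=90, textcoords="offset points", xytext=(0, 4))
    ax.plot(xs, ys, "g.-", lw=1, label="pruned")
    ax.axhline(threshold, color="r", ls="--", lw=1, label="threshold")
    ax.set_yscale("log")
    ax.set_xlabel("training batches")
    ax.set_ylabel("MSE loss")
    ax.legend(fontsize=7)
    return ax.figure


def plot_breakdown(result, ax=None):
    """Box plot of losses per sparsity with the optimal-sparsity bar chart."""
    import matplotlib.pyplot as plt

    from .ensemble import breakdown_summary

    summary = breakdown_summary(result)
    ss, arr = result.loss_matrix()
    fig, (ax_bar, ax_box) = plt.subplots(
        2, 1, sharex=True, height_ratios=[1, 3], figsize=(7, 5))
    labels = [f"{s:.0%}" for s in ss]
    ax_box.boxplot([arr[:, j] for j in range(arr.shape[1])], tick_labels=labels)
    ax_box.axhline(result.config.threshold, color="r", ls="--", lw=1)
    ax_box.set_yscale("log")
    ax_box.set_ylabel("MSE loss")
    ax_box.set_xlabel("sparsity")
    ax_box.tick_params(axis="x", rotation=60)
    counts = [summary["histogram"][s] for s in ss]
    ax_bar.bar(range(1, len(ss) + 1), counts, color="0.5")
    ax_bar.set_ylabel("n optimal")
    return fig


def plot_input_connectivity(result, sparsity: float, ax=None):
    """Per-input distribution of remaining first-layer connections."""
    from .datagen import INPUT_NAMES

    ax = _get_ax(ax)
    rows = np.array([nr.input_connectivity[sparsity]
                     for nr in result.ok_networks()])
    ax.boxplot([rows[:, j] for j in range(rows.shape[1])],
               tick_labels=list(INPUT_NAMES))
    ax.set_ylabel("connections into hidden layer 1")
    ax.tick_params(axis="x", rotation=60)
    return ax.figure
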