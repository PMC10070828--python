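"""Diagnostic plots: block-diagonal affinity heatmaps and convergence traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def sorted_affinity_heatmap(M: np.ndarray, labels, path: str | Path,
                            title: str = "label-sorted affinity") -> Path:
    """Save a heatmap of |M| with rows/columns sorted by cluster label.

    For a well-recovered union of subspaces the image shows one bright
    block per cluster along the diagonal.
    """
    labels = np.asarray(labels)
    idx = np.argsort(labels, kind="stable")
    A = np.abs(np.asarray(M, dtype=float))[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(A, cmap="viridis", interpolation="nearest")
    ax.set_title(title)
    ax.set_xlabel("items (sorted by cluster)")
    ax.set_ylabel("items (sorted by cluster)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def fitness_trace_plot(trace, path: str | Path,
                       title: str = "confidence optimization") -> Path:
    """Save the best-so-far fitness trace of one swarm run."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(np.arange(len(trace)), trace)
    ax.set_xlabel("time step")
    ax.set_ylabel("best fitness")
    ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
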