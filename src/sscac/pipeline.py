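"""End-to-end self-training subspace clustering.

The run proceeds as: (1) density-peak selection orders for every unlabeled
item; (2) one low-rank-representation solve on the whole matrix, whose
affinity graph is reused by every subsequent step; (3) an initial
label-propagation solve with confidence 1 on the initially labeled items;
then per wave r — (4) items with selection order r are labeled with their
current predicted classes, (5) their confidence vector is optimized by
gravitational search (or fixed at 1 in the ablation mode), (6) the labeled
set is expanded, the propagation re-solved, and the stopping rule checked.
Confidences of past waves are frozen once set.  When stopping before the
unlabeled pool is exhausted, remaining items take their labels from the
final prediction matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import density, lrradp, metrics, propagation
from .config import Config
from .gsa import ConfidenceProblem, optimize_confidence
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class WaveRecord:
    r: int                       # wave index (selection order value)
    indices: np.ndarray          # newly labeled item indices
    labels: np.ndarray           # their assigned classes, 1-based
    confidences: np.ndarray      # optimized mu^r, in (0, 1]
    acc: float | None            # accuracy vs truth after this wave, if known


@dataclass
class RunResult:
    final_labels: np.ndarray     # (n,) 1-based classes
    per_wave: list[WaveRecord]
    stop_reason: str             # exhausted | accuracy_plateau | max_waves
    seed: int
    confidences: np.ndarray      # (n,) final per-item label confidences
    order: np.ndarray            # (n,) selection orders (0 = initially labeled)
    W: np.ndarray                # affinity used for propagation
    F: np.ndarray | None = None  # final prediction matrix
    acc_history: list[float] = field(default_factory=list)


def split_labeled(labels: Sequence[int], fraction: float, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sample round(fraction * n) labeled indices.

    Warns if a class ends up with no labeled item; errors on an empty
    sample.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.floor(fraction * n + 0.5))   # round half up: 10% of 205 -> 21
    if k == 0:
        raise ValueError(f"fraction {fraction} yields 0 labeled items for n={n}")
    rng = np.random.default_rng(seed)
    labeled = np.sort(rng.choice(n, size=k, replace=False))
    covered = set(labels[labeled])
    missing = set(labels) - covered
    if missing:
        import warnings
        warnings.warn(f"classes with no initially labeled item: {sorted(missing)}",
                      RuntimeWarning, stacklevel=2)
    unlabeled = np.setdiff1d(np.arange(n), labeled)
    return labeled, unlabeled


def check_stop(previous_acc: float | None, current_acc: float | None,
               n_unlabeled: int, mode: str) -> tuple[bool, str | None]:
    """Stopping rule: unlabeled pool empty, or (plateau mode) accuracy no
    longer increasing — read as current <= previous."""
    if n_unlabeled == 0:
        return True, "exhausted"
    if mode == "accuracy_plateau":
        if current_acc is None:
            raise ValueError("accuracy_plateau stopping requires ground-truth "
                             "labels")
        if previous_acc is not None and current_acc <= previous_acc:
            return True, "accuracy_plateau"
    return False, None


def _full_labels(assigned: np.ndarray, labeled_mask: np.ndarray,
                 yhat: np.ndarray) -> np.ndarray:
    """Current 1-based labeling: assigned classes where labeled, predictions
    elsewhere."""
    out = np.where(labeled_mask, assigned, yhat) + 1
    return out.astype(int)


def run_sscac(X: ExpressionMatrix | np.ndarray,
              initial_labels: Mapping[int, int],
              config: Config,
              n_clusters: int | None = None,
              truth: Sequence[int] | None = None,
              W: np.ndarray | None = None,
              Dmat: np.ndarray | None = None,
              forced_labels: Mapping[int, int] | None = None) -> RunResult:
    """Run the full self-training loop.

    Parameters
    ----------
    X : matrix with items as columns (``ExpressionMatrix`` or ndarray).
    initial_labels : map column index -> 1-based class for the initially
        labeled items; their labels and unit confidence are never revised.
    n_clusters : number of clusters c; inferred from the labels/truth when
        omitted.
    truth : optional 1-based ground-truth labels, required for the
        accuracy-plateau stopping mode and for per-wave accuracy records.
    W, Dmat : optional precomputed affinity / distance matrices (the
        low-rank solve is skipped when ``W`` is given), useful when
        repeating runs on one dataset with different label splits.
    forced_labels : map column index -> 1-based class that overrides the
        predicted label when that item's wave is labeled; a mislabel
        injection hook for robustness experiments.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    m, n = values.shape
    if not initial_labels:
        raise ValueError("need at least one initially labeled item")
    truth_arr = None if truth is None else np.asarray(truth, dtype=int)
    classes = set(initial_labels.values())
    if truth_arr is not None:
        classes |= set(truth_arr.tolist())
    c = n_clusters if n_clusters is not None else max(classes)
    if min(classes) < 1 or max(classes) > c:
        raise ValueError("classes must be 1-based and <= n_clusters")

    rng = np.random.default_rng(config.seed)
    wave_seeds = rng.integers(2 ** 31, size=max(n, 1))

    # Step 2: density-pointing selection orders
    if Dmat is None:
        Dmat = lrradp.pairwise_distances(values)
    labeled_mask = np.zeros(n, dtype=bool)
    assigned = np.full(n, -1, dtype=int)          # 0-based classes
    for i, lab in initial_labels.items():
        labeled_mask[i] = True
        assigned[i] = lab - 1
    dorder = density.density_order(Dmat, labeled_mask, config.dc_fraction)
    order = dorder.order

    # Step 3: one low-rank solve on all of X; W reused across waves
    if W is None:
        _, _, graph = lrradp.solve_lrradp(values, config, Dmat=Dmat)
        W = graph.W
    lap = propagation.build_laplacian(W).Lap

    conf = np.zeros(n)
    conf[labeled_mask] = 1.0
    U_diag = np.where(labeled_mask, config.lambda_inf, 0.0)
    Y, mu = propagation.indicator_matrices(assigned, conf, labeled_mask, c)
    F = propagation.solve_F(lap, U_diag, mu, Y)
    yhat = propagation.predict_labels(F)

    acc_history: list[float] = []
    if truth_arr is not None:
        acc_history.append(metrics.acc(truth_arr,
                                       _full_labels(assigned, labeled_mask, yhat)))
    per_wave: list[WaveRecord] = []
    stop_reason = "exhausted" if labeled_mask.all() else None
    max_waves = config.max_waves if config.max_waves is not None else n
    forced = dict(forced_labels or {})

    wave_values = sorted(set(order[order > 0]))
    for wi, r in enumerate(wave_values):
        if stop_reason is not None:
            break
        if wi >= max_waves:
            stop_reason = "max_waves"
            break
        idx = np.flatnonzero((order == r) & ~labeled_mask)
        if idx.size == 0:
            continue
        # Step 4: pseudo-label the wave with current predictions
        wave_labels = yhat[idx].copy()
        for j, i in enumerate(idx):
            if i in forced:
                wave_labels[j] = forced[i] - 1
        assigned[idx] = wave_labels
        labeled_mask[idx] = True
        U_diag = np.where(labeled_mask, config.lambda_inf, 0.0)
        Y, mu = propagation.indicator_matrices(assigned, conf, labeled_mask, c)
        # Step 5: confidence vector for the wave
        if config.confidence_mode == "adaptive":
            problem = ConfidenceProblem(lap, U_diag, Y, mu, idx, wave_labels)
            mu_r, _ = optimize_confidence(problem, config,
                                          seed=int(wave_seeds[wi]))
        else:                                   # fixed_one ablation
            mu_r = np.ones(idx.size)
        conf[idx] = mu_r
        # Step 6: expand, re-solve, check stop
        Y, mu = propagation.indicator_matrices(assigned, conf, labeled_mask, c)
        F = propagation.solve_F(lap, U_diag, mu, Y)
        yhat = propagation.predict_labels(F)
        wave_acc = None
        if truth_arr is not None:
            wave_acc = metrics.acc(truth_arr,
                                   _full_labels(assigned, labeled_mask, yhat))
        prev = per_wave[-1].acc if per_wave else None   # one-wave minimum
        per_wave.append(WaveRecord(r=r, indices=idx, labels=wave_labels + 1,
                                   confidences=np.asarray(mu_r, float),
                                   acc=wave_acc))
        if wave_acc is not None:
            acc_history.append(wave_acc)
        stop, reason = check_stop(prev, wave_acc, int((~labeled_mask).sum()),
                                  config.stop_mode)
        if stop:
            stop_reason = reason

    if stop_reason is None:
        stop_reason = "exhausted" if labeled_mask.all() else "max_waves"
    final = _full_labels(assigned, labeled_mask, yhat)
    logger.info("run finished: %d wave(s), stop=%s", len(per_wave), stop_reason)
    return RunResult(final_labels=final, per_wave=per_wave,
                     stop_reason=stop_reason, seed=config.seed,
                     confidences=conf, order=order, W=W, F=F,
                     acc_history=acc_history)
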