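"""Density-peak quantities and the self-training selection schedule.

For every item, its local density rho counts neighbors closer than a cut-off
distance d_c, and delta is the distance to its nearest strictly denser item
(the "next" pointer).  Following next pointers always climbs toward the
unique global density peak, so the pointers form a spanning tree.  The
selection schedule assigns each initially unlabeled item a wave number:
breadth-first waves climb the tree from the labeled set along "next"
pointers first; once exhausted, waves descend along "previous" pointers
from everything already selected.  Items sharing a wave number form one
batch of newly labeled data during self-training.

Density ties are broken by item index (lower index counts as denser) so
"strictly denser" is well defined and the pointer graph is acyclic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class DensityOrder:
    rho: np.ndarray                    # (n,) neighbor counts
    delta: np.ndarray                  # (n,) distance to nearest denser item
    next_ptr: np.ndarray               # (n,) int, -1 for the density peak
    prev_ptrs: list[list[int]]         # inverse of next_ptr
    order: np.ndarray                  # (n,) wave number, 0 for labeled items


def cutoff_distance(Dmat: np.ndarray, fraction: float = 0.02) -> float:
    """d_c = the ``fraction`` quantile (ascending) of the unordered pair distances."""
    n = Dmat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    pairs = np.sort(Dmat[np.triu_indices(n, k=1)])
    if pairs[-1] == 0:
        warnings.warn("all pairwise distances are zero; d_c = 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    idx = max(math.ceil(fraction * len(pairs)), 1) - 1
    return float(pairs[idx])


def local_density(Dmat: np.ndarray, d_c: float) -> np.ndarray:
    """rho_i = #{j != i : d_ij < d_c} (strict comparison, self excluded)."""
    if d_c < 0:
        raise ValueError("d_c must be non-negative")
    close = Dmat < d_c
    np.fill_diagonal(close, False)
    return close.sum(axis=1).astype(int)


def _denser(rho: np.ndarray, i: int, j: int) -> bool:
    """Is j strictly denser than i, with index tie-break?"""
    return rho[j] > rho[i] or (rho[j] == rho[i] and j < i)


def delta_and_pointers(Dmat: np.ndarray, rho: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Nearest-denser distances and the "next"/"previous" pointer structure.

    The tie-broken density maximum has ``next = -1`` and
    ``delta = max_j d_ij``; every other item points to its nearest strictly
    denser item (distance ties broken by lowest index).
    """
    n = Dmat.shape[0]
    rho = np.asarray(rho)
    delta = np.zeros(n)
    next_ptr = np.full(n, -1, dtype=int)
    for i in range(n):
        denser = [j for j in range(n) if j != i and _denser(rho, i, j)]
        if not denser:
            delta[i] = Dmat[i].max() if n > 1 else 0.0
        else:
            dists = Dmat[i, denser]
            k = int(np.argmin(dists))          # lowest index wins on ties
            next_ptr[i] = denser[k]
            delta[i] = dists[k]
    prev_ptrs: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if next_ptr[i] >= 0:
            prev_ptrs[next_ptr[i]].append(i)
    return delta, next_ptr, prev_ptrs


def selection_orders(next_ptr: np.ndarray, prev_ptrs: list[list[int]],
                     labeled_mask: np.ndarray) -> np.ndarray:
    """Assign every initially unlabeled item a wave number >= 1.

    Phase 1 climbs the density tree: wave 1 = unlabeled "next" items of the
    labeled set; wave r+1 = unlabeled "next" items of wave r.  Phase 2 then
    descends: the first descending wave contains every unselected
    "previous" item of anything selected so far, and subsequent waves the
    "previous" items of the preceding wave.  Wave numbers are consecutive.
    """
    n = len(next_ptr)
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    order = np.zeros(n, dtype=int)
    selected = labeled_mask.copy()

    r = 0
    frontier = np.flatnonzero(labeled_mask)
    while True:                                  # phase 1: climb "next"
        wave = sorted({int(next_ptr[i]) for i in frontier
                       if next_ptr[i] >= 0 and not selected[next_ptr[i]]})
        if not wave:
            break
        r += 1
        order[wave] = r
        selected[wave] = True
        frontier = np.array(wave)

    frontier = np.flatnonzero(selected)          # phase 2: descend "previous"
    while True:
        wave = sorted({j for i in frontier for j in prev_ptrs[i]
                       if not selected[j]})
        if not wave:
            break
        r += 1
        order[wave] = r
        selected[wave] = True
        frontier = np.array(wave)

    if not selected.all():
        missing = np.flatnonzero(~selected).tolist()
        raise RuntimeError(f"items unreachable along the density pointer tree: "
                           f"{missing}")
    return order


def density_order(Dmat: np.ndarray, labeled_mask: np.ndarray,
                  dc_fraction: float = 0.02) -> DensityOrder:
    """Convenience wrapper computing the full :class:`DensityOrder`."""
    d_c = cutoff_distance(Dmat, dc_fraction)
    rho = local_density(Dmat, d_c)
    delta, next_ptr, prev_ptrs = delta_and_pointers(Dmat, rho)
    order = selection_orders(next_ptr, prev_ptrs, labeled_mask)
    return DensityOrder(rho=rho, delta=delta, next_ptr=next_ptr,
                        prev_ptrs=prev_ptrs, order=order)
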