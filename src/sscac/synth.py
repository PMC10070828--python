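"""Synthetic datasets with the structure the algorithm assumes.

The main generator draws a union of ``c`` low-dimensional linear subspaces
embedded in ``R^m`` with additive Gaussian noise — the data model under
which low-rank representation provably yields a block-diagonal affinity.
Default dimensions (``n=205`` items, ``m=80`` features, ``c=4`` clusters)
mirror a classic galactose-pathway yeast expression compendium so that
end-to-end experiments run at a realistic problem size.  Two-dimensional
non-spherical shapes exercise the density-peak selection schedule, and
:func:`plant_mislabels` corrupts labels for robustness experiments.

No attempt is made to emulate count distributions or dropout of real
expression data; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix


@dataclass
class SubspaceDataset:
    """A labeled synthetic dataset; ``true_labels`` are 1-based."""

    X: ExpressionMatrix
    true_labels: np.ndarray          # shape (n,), ints in 1..c
    bases: list[np.ndarray]          # c orthonormal (m, d) matrices ([] for 2-D shapes)
    noise_sigma: float


def _balanced_sizes(n: int, c: int) -> list[int]:
    base, extra = divmod(n, c)
    return [base + (1 if k < extra else 0) for k in range(c)]


def make_subspace_data(n: int = 205, m: int = 80, c: int = 4, d: int = 5,
                       noise_sigma: float = 0.05, orthogonal: bool = True,
                       seed: int = 0) -> SubspaceDataset:
    """Draw ``n`` points from a union of ``c`` ``d``-dimensional subspaces.

    With ``orthogonal=True`` the subspaces are mutually orthogonal
    (consecutive ``d``-column blocks of one random orthogonal frame, so
    ``c*d <= m`` is required); otherwise each basis is an independent QR
    factor of a Gaussian matrix.  Coefficients are i.i.d. standard normal
    and noise is i.i.d. ``N(0, noise_sigma^2)`` in ambient space.  Cluster
    sizes are balanced (differ by at most one).
    """
    if n < c:
        raise ValueError(f"need n >= c, got n={n}, c={c}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if orthogonal:
        if c * d > m:
            raise ValueError(f"orthogonal subspaces need c*d <= m, "
                             f"got c*d={c * d} > m={m}")
        frame, _ = np.linalg.qr(rng.standard_normal((m, m)))
        bases = [frame[:, k * d:(k + 1) * d] for k in range(c)]
    else:
        bases = []
        for _ in range(c):
            q, _ = np.linalg.qr(rng.standard_normal((m, d)))
            bases.append(q)

    sizes = _balanced_sizes(n, c)
    cols, labels = [], []
    for k, nk in enumerate(sizes):
        coeffs = rng.standard_normal((d, nk))
        cols.append(bases[k] @ coeffs)
        labels.extend([k + 1] * nk)
    X = np.concatenate(cols, axis=1)
    if noise_sigma > 0:
        X = X + noise_sigma * rng.standard_normal(X.shape)

    em = ExpressionMatrix(values=X,
                          item_ids=[f"g{i + 1}" for i in range(n)],
                          feature_ids=[f"f{j + 1}" for j in range(m)])
    return SubspaceDataset(X=em, true_labels=np.array(labels, dtype=int),
                           bases=bases, noise_sigma=noise_sigma)


def make_nonspherical_2d(shape: str, n: int = 100, noise: float = 0.0,
                         seed: int = 0) -> SubspaceDataset:
    """2-D point sets with known labels for density-ordering tests.

    ``two_moons``: two interleaving half-circles, balanced labels.
    ``chain``: collinear points whose spacing widens away from the center,
    so local density is monotone toward the middle of the chain.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    if shape == "two_moons":
        from sklearn.datasets import make_moons
        pts, lab = make_moons(n_samples=n, noise=noise,
                              random_state=int(rng.integers(2 ** 31)))
        labels = lab + 1
    elif shape == "chain":
        # positions +-(|k|^1.5) around 0: gaps grow away from the center
        offs = np.arange(n) - (n - 1) / 2.0
        xs = np.sign(offs) * np.abs(offs) ** 1.5
        pts = np.column_stack([xs, np.zeros(n)])
        if noise > 0:
            pts = pts + noise * rng.standard_normal(pts.shape)
        labels = np.ones(n, dtype=int)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    em = ExpressionMatrix(values=pts.T,
                          item_ids=[f"p{i + 1}" for i in range(n)],
                          feature_ids=["x", "y"])
    return SubspaceDataset(X=em, true_labels=np.asarray(labels, dtype=int),
                           bases=[], noise_sigma=noise)


def plant_mislabels(labels: np.ndarray, indices, seed: int = 0) -> np.ndarray:
    """Reassign each listed index to a uniformly drawn *wrong* class.

    Labels are 1-based; all other positions are untouched.  Raises if only
    one class exists (no wrong class to draw).
    """
    labels = np.asarray(labels, dtype=int)
    out = labels.copy()
    classes = np.unique(labels)
    if len(indices) and len(classes) < 2:
        raise ValueError("cannot mislabel with a single class present")
    rng = np.random.default_rng(seed)
    for i in indices:
        wrong = classes[classes != labels[i]]
        out[i] = rng.choice(wrong)
    return out
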