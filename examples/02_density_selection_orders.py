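"""Density-peak pointers and the self-training selection schedule.

On a two-moons point set (non-spherical clusters, where centroid-based
selection fails), every point gets a local density rho and a pointer to its
nearest denser neighbor.  Starting from a few labeled points, waves first
climb the pointer tree toward density peaks, then descend to cover the
rest; the wave number is the self-training iteration in which a point will
be pseudo-labeled.
"""

import numpy as np

import sscac

ds = sscac.make_nonspherical_2d("two_moons", n=60, noise=0.05, seed=0)
D = sscac.pairwise_distances(ds.X.values)

labeled = np.zeros(60, dtype=bool)
labeled[[0, 30]] = True          # one labeled point per moon

do = sscac.density_order(D, labeled, dc_fraction=0.1)
print(f"density rho: min={do.rho.min()}, max={do.rho.max()} "
      f"(neighbors within the cut-off distance)")
peak = int(np.flatnonzero(do.next_ptr < 0)[0])
print(f"global density peak: point {peak} (rho={do.rho[peak]})")
for r in range(1, do.order.max() + 1):
    print(f"wave {r}: {int((do.order == r).sum())} point(s)")
print("  (each wave is one batch of newly pseudo-labeled points; together "
      "the waves partition the unlabeled set)")
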