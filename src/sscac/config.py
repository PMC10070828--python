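"""Hyperparameter container for the SSCAC pipeline.

All stages of the algorithm — the low-rank representation solver, the
density-peak selection schedule, the confidence-weighted label propagation
and the gravitational-search confidence optimizer — read their tunables from
a single :class:`Config`.  Defaults follow the published operating point of
the method: ``lambda1=100``, ``lambda2=1``, ``lambda_inf=1e5``,
``beta_max=1e4``, ``xi=1e-5``, ``rho_admm=1.01``, swarm size ``N=50`` run
for ``T=100`` steps with ``G0=100``, ``alpha=20``, and a cut-off distance
taken at the 2% quantile of pairwise distances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

_STOP_MODES = ("exhaust_unlabeled", "accuracy_plateau")
_CONFIDENCE_MODES = ("adaptive", "fixed_one")
_H_PENALTIES = ("weighted_l1", "linear")


@dataclass(frozen=True)
class Config:
    """Validated hyperparameter set.

    Every field is range-checked on construction; violations raise
    ``ValueError`` naming the offending field.
    """

    # balance parameters of the low-rank representation with distance penalty
    lambda1: float = 100.0
    lambda2: float = 1.0
    # weight of the label-fit term in the propagation objective
    lambda_inf: float = 1e5
    # augmented-Lagrangian penalty schedule
    beta0: float = 1.0
    beta_max: float = 1e4
    rho_admm: float = 1.01
    # relative-change stopping tolerance of the solver
    xi: float = 1e-5
    # density-peak cut-off distance quantile
    dc_fraction: float = 0.02
    # gravitational search
    gsa_T: int = 100
    gsa_N: int = 50
    gsa_G0: float = 100.0
    gsa_alpha: float = 20.0
    epsilon: float = 2.2204e-16
    # experiment setup
    labeled_fraction: float = 0.10
    seed: int = 0
    stop_mode: str = "exhaust_unlabeled"
    confidence_mode: str = "adaptive"
    # solver guards and literal-reading switches
    solver_max_iter: int = 500
    max_waves: int | None = None
    literal_eq2: bool = False
    literal_final_population: bool = False
    h_penalty: str = "weighted_l1"
    # exclude self-representation (diagonal of the representation matrix);
    # the unconstrained form collapses to the trivial Z ~ I on noisy data
    zero_diagonal: bool = True

    def __post_init__(self) -> None:
        pos = ("lambda1", "lambda2", "lambda_inf", "beta0", "beta_max",
               "xi", "gsa_G0", "gsa_alpha", "epsilon")
        for name in pos:
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name!r} must be positive, "
                                 f"got {getattr(self, name)}")
        if not self.rho_admm > 1:
            raise ValueError(f"config field 'rho_admm' must be > 1, got {self.rho_admm}")
        if not 0 < self.dc_fraction < 1:
            raise ValueError(f"config field 'dc_fraction' must lie in (0,1), "
                             f"got {self.dc_fraction}")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError(f"config field 'labeled_fraction' must lie in (0,1], "
                             f"got {self.labeled_fraction}")
        for name in ("gsa_T", "gsa_N", "solver_max_iter"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"config field {name!r} must be a positive integer, got {v}")
        if self.max_waves is not None and self.max_waves < 1:
            raise ValueError(f"config field 'max_waves' must be >= 1, got {self.max_waves}")
        if self.stop_mode not in _STOP_MODES:
            raise ValueError(f"config field 'stop_mode' must be one of {_STOP_MODES}, "
                             f"got {self.stop_mode!r}")
        if self.confidence_mode not in _CONFIDENCE_MODES:
            raise ValueError(f"config field 'confidence_mode' must be one of "
                             f"{_CONFIDENCE_MODES}, got {self.confidence_mode!r}")
        if self.h_penalty not in _H_PENALTIES:
            raise ValueError(f"config field 'h_penalty' must be one of {_H_PENALTIES}, "
                             f"got {self.h_penalty!r}")

    def replace(self, **overrides: Any) -> "Config":
        """Return a copy with ``overrides`` applied (re-validated)."""
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path | None = None, **overrides: Any) -> Config:
    """Build a :class:`Config` from an optional YAML/JSON file plus overrides.

    With no file, defaults are used.  Unknown keys raise ``ValueError``.
    """
    values: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if loaded:
            values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return Config(**values)
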