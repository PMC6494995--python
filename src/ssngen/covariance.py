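"""Tail-up, tail-down and Euclidean autocovariance mixtures for stream networks.

All models are parameterised by a partial sill σ² and a range α (metres).
The range is the *effective* range: the distance at which autocorrelation
is practically (exponential-type forms, factor e⁻³) or exactly (compactly
supported forms) zero.  With r = h/α:

tail-up (flow-connected pairs only, entry multiplied by the tail-up
weight W; zero for flow-unconnected or cross-basin pairs):

====================  ===================================================
exponential           σ² e^{−3r}
spherical             σ² (1 − 3/2·r + 1/2·r³)           for r ≤ 1, else 0
linearsill            σ² (1 − r)                        for r ≤ 1, else 0
mariah                σ² ln(90r + 1)/(90r)              (σ² at r = 0)
====================  ===================================================

tail-down models use the same forms in h for flow-connected pairs and,
for flow-unconnected pairs with downstream legs a ≤ b (ra = a/α,
rb = b/α):

====================  ===================================================
exponential           σ² e^{−3(ra+rb)}
spherical             σ² (1 − 3/2·ra + 1/2·rb)(1 − rb)² for rb ≤ 1, else 0
linearsill            σ² (1 − rb)                       for rb ≤ 1, else 0
mariah                σ² (ln(90ra+1) − ln(90rb+1))/(90(ra − rb)),
                      σ²/(90ra + 1) when a = b
====================  ===================================================

Euclidean models use d/α: exponential σ²e^{−3d/α}, spherical as above,
gaussian σ²e^{−3(d/α)²}, cauchy σ²/(1 + (d/α)²).

Both stream components are exactly zero between points in different
basins (hydrologically disjoint catchments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .network import DistanceSet

__all__ = [
    "STREAM_FUNCTIONS",
    "EUCLID_FUNCTIONS",
    "COMPONENT_TYPES",
    "CovarianceComponent",
    "CovarianceSpec",
    "component_matrix",
    "correlation_matrix",
    "mixture_matrix",
]

STREAM_FUNCTIONS = ("exponential", "spherical", "mariah", "linearsill")
EUCLID_FUNCTIONS = ("exponential", "spherical", "gaussian", "cauchy")
COMPONENT_TYPES = ("tailup", "taildown", "euclidean")


@dataclass(frozen=True)
class CovarianceComponent:
    ctype: str
    fn: str
    sill: float = 1.0
    range_: float = 1.0

    def __post_init__(self):
        if self.ctype not in COMPONENT_TYPES:
            raise ValueError(f"unknown component type {self.ctype!r}")
        legal = EUCLID_FUNCTIONS if self.ctype == "euclidean" else STREAM_FUNCTIONS
        if self.fn not in legal:
            raise ValueError(f"function {self.fn!r} not legal for {self.ctype!r} components")
        if self.sill < 0:
            raise ValueError("sill must be >= 0")
        if not self.range_ > 0:
            raise ValueError("range must be > 0")


@dataclass(frozen=True)
class CovarianceSpec:
    """A covariance mixture: up to one component per type, plus a nugget."""

    components: tuple[CovarianceComponent, ...] = ()
    nugget: float = 0.0

    def __post_init__(self):
        types = [c.ctype for c in self.components]
        if len(types) != len(set(types)):
            raise ValueError("at most one component per ctype")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")

    @property
    def n_params(self) -> int:
        """Free covariance parameters: (sill, range) per component + nugget."""
        return 2 * len(self.components) + 1

    def label(self) -> str:
        parts = [f"{c.fn}.{ {'tailup': 'TU', 'taildown': 'TD', 'euclidean': 'EUC'}[c.ctype] }"
                 for c in self.components]
        parts.append("nugget")
        return "+".join(parts)

    def with_params(self, sills, ranges, nugget) -> "CovarianceSpec":
        comps = tuple(
            replace(c, sill=float(s), range_=float(r))
            for c, s, r in zip(self.components, sills, ranges)
        )
        return CovarianceSpec(components=comps, nugget=float(nugget))

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [
                    {"ctype": c.ctype, "fn": c.fn, "sill": c.sill, "range": c.range_}
                    for c in self.components
                ],
                "nugget": self.nugget,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CovarianceSpec":
        obj = json.loads(text)
        comps = tuple(
            CovarianceComponent(c["ctype"], c["fn"], c.get("sill", 1.0), c.get("range", 1.0))
            for c in obj.get("components", ())
        )
        return cls(components=comps, nugget=obj.get("nugget", 0.0))


def _stream_connected(fn: str, r: np.ndarray) -> np.ndarray:
    """Unit-sill stream autocorrelation in total stream distance, r = h/α."""
    if fn == "exponential":
        return np.exp(-3.0 * r)
    if fn == "spherical":
        return np.where(r <= 1.0, 1.0 - 1.5 * r + 0.5 * r**3, 0.0)
    if fn == "linearsill":
        return np.where(r <= 1.0, 1.0 - r, 0.0)
    if fn == "mariah":
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log(90.0 * r + 1.0) / (90.0 * r)
        return np.where(r <= 0.0, 1.0, v)
    raise ValueError(fn)


def _taildown_unconnected(fn: str, ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Unit-sill tail-down autocorrelation for flow-unconnected pairs, ra <= rb."""
    if fn == "exponential":
        return np.exp(-3.0 * (ra + rb))
    if fn == "spherical":
        return np.where(rb <= 1.0, (1.0 - 1.5 * ra + 0.5 * rb) * (1.0 - rb) ** 2, 0.0)
    if fn == "linearsill":
        return np.where(rb <= 1.0, 1.0 - rb, 0.0)
    if fn == "mariah":
        near = np.isclose(ra, rb, rtol=1e-12, atol=1e-15)
        rb_safe = np.where(near, ra + 1.0, rb)
        with np.errstate(divide="ignore", invalid="ignore"):
            gen = (np.log(90.0 * ra + 1.0) - np.log(90.0 * rb_safe + 1.0)) / (
                90.0 * (ra - rb_safe)
            )
        return np.where(near, 1.0 / (90.0 * ra + 1.0), gen)
    raise ValueError(fn)


def _euclid(fn: str, rd: np.ndarray) -> np.ndarray:
    if fn == "exponential":
        return np.exp(-3.0 * rd)
    if fn == "spherical":
        return np.where(rd <= 1.0, 1.0 - 1.5 * rd + 0.5 * rd**3, 0.0)
    if fn == "gaussian":
        return np.exp(-3.0 * rd**2)
    if fn == "cauchy":
        return 1.0 / (1.0 + rd**2)
    raise ValueError(fn)


def correlation_matrix(ctype: str, fn: str, dset: DistanceSet, range_: float) -> np.ndarray:
    """Unit-sill covariance matrix of one component (diagonal exactly 1)."""
    if not range_ > 0:
        raise ValueError("range must be > 0")
    n = len(dset)
    if ctype == "euclidean":
        C = _euclid(fn, dset.E / range_)
    elif ctype == "tailup":
        h = np.where(dset.same_basin, dset.h, np.inf)
        with np.errstate(invalid="ignore"):
            C = np.where(dset.connected, _stream_connected(fn, h / range_) * dset.W, 0.0)
    elif ctype == "taildown":
        h = np.where(dset.same_basin, dset.h, np.inf)
        a = np.where(dset.same_basin, dset.a, np.inf)
        b = np.where(dset.same_basin, dset.b, np.inf)
        with np.errstate(invalid="ignore"):
            C = np.where(
                dset.connected,
                _stream_connected(fn, h / range_),
                np.where(
                    dset.same_basin,
                    _taildown_unconnected(fn, a / range_, b / range_),
                    0.0,
                ),
            )
    else:
        raise ValueError(f"unknown component type {ctype!r}")
    C = np.asarray(C, dtype=float)
    np.fill_diagonal(C, 1.0)
    return C


def component_matrix(comp: CovarianceComponent, dset: DistanceSet) -> np.ndarray:
    """Covariance matrix of a single mixture component (diagonal = sill)."""
    return comp.sill * correlation_matrix(comp.ctype, comp.fn, dset, comp.range_)


def mixture_matrix(spec: CovarianceSpec, dset: DistanceSet) -> np.ndarray:
    """Total covariance Σ = Σ_c component + nugget·I (symmetric PSD)."""
    n = len(dset)
    S = np.zeros((n, n))
    for comp in spec.components:
        S += component_matrix(comp, dset)
    S[np.diag_indices(n)] += spec.nugget
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("non-finite entries in covariance mixture")
    return 0.5 * (S + S.T)
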