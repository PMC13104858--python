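"""Core data model shared by every TFCE engine.

Functional-connectivity (FC) statistics arrive as a symmetric ``N x N``
matrix of edgewise test statistics (one per ROI pair); the diagonal is
ignored.  All engines operate on the positive tail only — a statistic at or
below zero contributes no TFCE mass.  Threshold discretization follows the
non-strict convention ``stat >= k*dh``: an edge whose statistic equals a
threshold exactly belongs to the cluster at that threshold, which makes the
bin assignment ``floor(stat/dh)`` exact at multiples of ``dh``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ValidationError",
    "EmptyGridError",
    "StatMatrix",
    "EdgeRecord",
    "TFCEParams",
    "ThresholdGrid",
    "TFCEMap",
    "matrix_to_edges",
    "edge_arrays",
    "build_threshold_grid",
    "bin_index",
    "bin_indices",
    "edge_count",
]

#: symmetry tolerance for StatMatrix validation
SYMMETRY_TOL = 1e-12


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class EmptyGridError(ValueError):
    """No positive statistics: the threshold grid is empty.

    Callers catch this and return an all-zero TFCE map.
    """


class EdgeRecord(NamedTuple):
    """One undirected FC edge, ``0 <= u < v < N``."""

    u: int
    v: int
    stat: float


@dataclass(frozen=True)
class StatMatrix:
    """Symmetric ROI-by-ROI test-statistic matrix.

    Parameters
    ----------
    values
        ``N x N`` real matrix, symmetric within 1e-12, all entries finite,
        ``N >= 2``.  The diagonal is ignored by every operation.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"statistic matrix must be square, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValidationError(f"need at least 2 ROIs, got N={arr.shape[0]}")
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(f"non-finite statistic at entry ({i}, {j}): {arr[i, j]!r}")
        asym = np.abs(arr - arr.T)
        worst = np.unravel_index(np.argmax(asym), asym.shape)
        if asym[worst] > SYMMETRY_TOL:
            i, j = worst
            raise ValidationError(
                f"matrix not symmetric: |m[{i},{j}] - m[{j},{i}]| = {asym[worst]:.3g} "
                f"exceeds tolerance {SYMMETRY_TOL:g}"
            )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE integration parameters.

    ``extent_exponent`` (E) weights cluster extent, ``height_exponent`` (H)
    weights threshold height, and ``dh`` is the discretization step of the
    TFCE integral.  Field defaults are the standard FC choice E=0.4, H=3.0,
    dh=0.1; voxel analyses conventionally use E=0.5, H=2.0.
    """

    extent_exponent: float = 0.4
    height_exponent: float = 3.0
    dh: float = 0.1

    def __post_init__(self) -> None:
        if not self.extent_exponent > 0:
            raise ValidationError(f"extent exponent must be > 0, got {self.extent_exponent}")
        if self.height_exponent < 0:
            raise ValidationError(f"height exponent must be >= 0, got {self.height_exponent}")
        if self.height_exponent == -1:
            raise ValidationError("height exponent -1 is unsupported")
        if not self.dh > 0:
            raise ValidationError(f"dh must be > 0, got {self.dh}")

    # short aliases matching the conventional symbols
    @property
    def E(self) -> float:
        return self.extent_exponent

    @property
    def H(self) -> float:
        return self.height_exponent


@dataclass(frozen=True)
class ThresholdGrid:
    """Discretized thresholds ``h_k = k*dh`` for ``k = 1..nth``.

    ``nth = ceil(tmax/dh)`` so the map's maximum statistic is always covered
    by the topmost threshold.
    """

    tmax: float
    dh: float
    nth: int
    thresholds: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class TFCEMap:
    """Per-edge TFCE values as a symmetric ``N x N`` matrix, zero diagonal."""

    values: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def edge_value(self, u: int, v: int) -> float:
        return float(self.values[u, v])

    @staticmethod
    def from_edge_values(n: int, iu: np.ndarray, iv: np.ndarray, vals: np.ndarray) -> "TFCEMap":
        out = np.zeros((n, n), dtype=float)
        out[iu, iv] = vals
        out[iv, iu] = vals
        return TFCEMap(values=out)


def edge_count(n: int) -> int:
    """Number of FC edges in a complete graph on ``n`` ROIs: n(n-1)/2."""
    return n * (n - 1) // 2


def edge_arrays(m: StatMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edge arrays ``(iu, iv, stats)`` in (u, v)-lexicographic order.

    The vectorized counterpart of :func:`matrix_to_edges`; engines operate on
    these arrays directly.
    """
    iu, iv = np.triu_indices(m.n_rois, k=1)
    return iu, iv, m.values[iu, iv]


def matrix_to_edges(m: StatMatrix) -> list[EdgeRecord]:
    """Extract the ``N(N-1)/2`` undirected edges of an FC matrix.

    One record per unordered ROI pair with ``u < v``, ordered
    lexicographically by ``(u, v)``; statistics read from the upper triangle.
    """
    iu, iv, stats = edge_arrays(m)
    return [EdgeRecord(int(u), int(v), float(s)) for u, v, s in zip(iu, iv, stats)]


def build_threshold_grid(tmax: float, dh: float) -> ThresholdGrid:
    """Build the discretized threshold ladder for a map with maximum ``tmax``.

    Raises
    ------
    EmptyGridError
        If ``tmax <= 0`` (no positive statistics); the caller should return
        an all-zero TFCE map.
    """
    if not dh > 0:
        raise ValidationError(f"dh must be > 0, got {dh}")
    if tmax <= 0:
        raise EmptyGridError(f"no positive statistics (tmax={tmax}); TFCE map is all zero")
    nth = int(math.ceil(tmax / dh))
    thresholds = dh * np.arange(1, nth + 1)
    return ThresholdGrid(tmax=float(tmax), dh=float(dh), nth=nth, thresholds=thresholds)


def bin_index(stat: float, dh: float) -> int:
    """Number of thresholds ``k*dh`` satisfied under the non-strict rule.

    Equals ``floor(stat/dh)`` with exact float floor semantics (no tolerance);
    0 for ``stat < dh``, including negative statistics.  An edge in bin 0
    contributes no TFCE mass and is excluded from clustering.
    """
    if not dh > 0:
        raise ValidationError(f"dh must be > 0, got {dh}")
    return max(int(math.floor(stat / dh)), 0)


def bin_indices(stats: np.ndarray, dh: float) -> np.ndarray:
    """Vectorized :func:`bin_index` over an array of statistics."""
    if not dh > 0:
        raise ValidationError(f"dh must be > 0, got {dh}")
    b = np.floor(np.asarray(stats, dtype=float) / dh).astype(np.int64)
    return np.maximum(b, 0)
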