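"""Ensemble statistics, quasi-potential landscapes and attractor counting.

The quasi-potential surrogate follows the standard occupancy convention:
bin the ensemble states in two dimensions, normalise to a frequency
``P``, and set ``U = -ln(P + eps)``.  Minima of ``U`` (maxima of ``P``)
mark metastable phenotypic states; a small pseudo-frequency ``eps``
keeps ``U`` finite on empty bins without reordering occupied ones.

``count_attractors`` probes the deterministic skeleton instead: it
integrates an ODE right-hand side from many random initial states and
clusters the endpoints, which is how bistability windows are mapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .engines.base import Ensemble

__all__ = [
    "LandscapeGrid",
    "AttractorReport",
    "ensemble_snapshot",
    "estimate_landscape",
    "count_local_minima",
    "count_attractors",
]


@dataclass
class LandscapeGrid:
    """2-D occupancy histogram with its derived quasi-potential."""

    axis_species: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray  # normalised frequency, shape (n_bins_x, n_bins_y)
    U: np.ndarray  # -ln(P + eps)
    epsilon: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def minimum_location(self) -> tuple[float, float]:
        """Bin-center coordinates of the global potential minimum."""
        i, j = np.unravel_index(np.argmin(self.U), self.U.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])

    def local_minima(self) -> list[tuple[int, int]]:
        return count_local_minima(self.U, return_locations=True)


@dataclass
class AttractorReport:
    """Distinct ODE fixed points found by multi-start integration."""

    attractors: np.ndarray   # (n_attractors, n_species)
    basin_counts: np.ndarray
    merge_radius: float
    n_failed: int = 0

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)


def ensemble_snapshot(trajectories: Ensemble, t: float) -> np.ndarray:
    """All trajectory states at time ``t`` (piecewise-constant lookup)."""
    return trajectories.snapshot(t)


def estimate_landscape(
    samples: np.ndarray,
    axis_species: tuple[str, str] = ("x", "y"),
    axis_indices: tuple[int, int] = (0, 1),
    n_bins: int = 30,
    epsilon: float | None = None,
    ranges=None,
) -> LandscapeGrid:
    """Quasi-potential estimate from pooled state samples.

    ``epsilon`` defaults to ``1/(2 * n_samples)``, a pseudo-frequency that
    keeps the potential finite on empty bins while vanishing as sampling
    grows.  A degenerate (zero-range) axis collapses to a single bin with
    a warning.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or len(samples) < 1:
        raise ValueError("samples must be a non-empty 2-D array of states")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = samples[:, axis_indices[0]]
    y = samples[:, axis_indices[1]]
    if epsilon is None:
        epsilon = 1.0 / (2.0 * len(samples))

    def axis_edges(v, lo_hi):
        lo, hi = (v.min(), v.max()) if lo_hi is None else lo_hi
        if hi <= lo:
            warnings.warn("degenerate landscape axis (zero range); using a single bin")
            return np.array([lo - 0.5, lo + 0.5])
        return np.linspace(lo, hi, n_bins + 1)

    x_edges = axis_edges(x, ranges[0] if ranges else None)
    y_edges = axis_edges(y, ranges[1] if ranges else None)
    H, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    P = H / H.sum()
    U = -np.log(P + epsilon)
    return LandscapeGrid(tuple(axis_species), x_edges, y_edges, P, U, epsilon)


def count_local_minima(U: np.ndarray, return_locations: bool = False):
    """Local minima of a 2-D surface under the 8-neighbour definition.

    Boundary bins are excluded (sparse-histogram edge artifacts).  A bin
    is a minimum when strictly smaller than every neighbour.
    """
    U = np.asarray(U, dtype=float)
    locs = []
    for i in range(1, U.shape[0] - 1):
        for j in range(1, U.shape[1] - 1):
            window = U[i - 1:i + 2, j - 1:j + 2]
            c = U[i, j]
            neigh = np.delete(window.ravel(), 4)
            if (c < neigh).all():
                locs.append((i, j))
    if return_locations:
        return locs
    return len(locs)


def count_attractors(
    ode_rhs: Callable[[float, np.ndarray], np.ndarray],
    n_starts: int = 100,
    init_box: Sequence[tuple[float, float]] = ((0.0, 5.0),) * 4,
    t_long: float = 200.0,
    merge_radius: float = 0.05,
    seed: int = 0,
    rtol: float = 1e-8,
) -> AttractorReport:
    """Cluster long-time ODE endpoints from random initial conditions.

    Starts that fail to integrate are excluded with a warning; if every
    start fails an error is raised.  ``merge_radius`` is the Euclidean
    distance below which endpoints are treated as the same attractor.
    """
    if n_starts < 10:
        raise ValueError("n_starts must be >= 10")
    rng = np.random.default_rng(seed)
    box = np.asarray(init_box, dtype=float)
    ends = []
    n_failed = 0
    for _ in range(n_starts):
        x0 = rng.uniform(box[:, 0], box[:, 1])
        sol = solve_ivp(ode_rhs, (0.0, t_long), x0, rtol=rtol, atol=rtol * 1e-2)
        if not sol.success:
            n_failed += 1
            warnings.warn(f"integration failed from start {x0}; excluded")
            continue
        ends.append(sol.y[:, -1])
    if not ends:
        raise RuntimeError("all starts failed to integrate")
    attractors: list[np.ndarray] = []
    counts: list[int] = []
    for e in ends:
        for k, a in enumerate(attractors):
            if np.linalg.norm(e - a) <= merge_radius:
                # running mean keeps the representative centred
                attractors[k] = (a * counts[k] + e) / (counts[k] + 1)
                counts[k] += 1
                break
        else:
            attractors.append(np.asarray(e))
            counts.append(1)
    return AttractorReport(np.asarray(attractors), np.asarray(counts),
                           float(merge_radius), n_failed)
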