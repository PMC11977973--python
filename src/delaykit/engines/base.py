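"""Shared driver contract: requests, piecewise-constant output sampling,
trajectories and ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ..network import ReactionNetwork


@dataclass
class SimulationRequest:
    """One trajectory's worth of inputs.

    ``output_times`` is the sorted grid the piecewise-constant state path
    is sampled onto; the reported state at grid time ``t`` is the state
    after all events with event time <= ``t``.
    """

    network: ReactionNetwork
    initial_counts: Sequence[int]
    t_final: float
    output_times: Sequence[float]
    seed: int | np.random.Generator = 0

    def __post_init__(self) -> None:
        self.initial_counts = np.asarray(self.initial_counts, dtype=np.int64)
        if self.initial_counts.shape != (self.network.n_species,):
            raise ValueError("initial_counts length must equal the number of species")
        if (self.initial_counts < 0).any():
            raise ValueError("initial counts must be >= 0")
        if self.t_final <= 0:
            raise ValueError("t_final must be > 0")
        self.output_times = np.asarray(self.output_times, dtype=np.float64)
        if self.output_times.ndim != 1 or len(self.output_times) == 0:
            raise ValueError("output_times must be a non-empty 1-D grid")
        if (np.diff(self.output_times) < 0).any():
            raise ValueError("output_times must be sorted")
        if self.output_times[0] < 0 or self.output_times[-1] > self.t_final:
            raise ValueError("output_times must lie within [0, t_final]")

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)

    @staticmethod
    def with_grid(network, initial_counts, t_final, n_points=200, seed=0) -> "SimulationRequest":
        grid = np.linspace(0.0, t_final, n_points)
        return SimulationRequest(network, initial_counts, t_final, grid, seed)


@dataclass
class Trajectory:
    """Piecewise-constant state path sampled on the output grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species), int64
    species: tuple[str, ...] = ()

    def state_at(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0 or t > self.times[-1]:
            raise ValueError(f"t={t} outside the sampled grid")
        return self.states[idx]


@dataclass
class Ensemble:
    """Stack of trajectories on a common grid, plus summary helpers."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, n_times, n_species)
    species: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    def snapshot(self, t: float) -> np.ndarray:
        """States of all trajectories at time ``t`` (one row per sample)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0 or t > self.times[-1]:
            raise ValueError(f"t={t} outside the sampled grid")
        return self.states[:, idx, :]

    def mean(self) -> np.ndarray:
        """Ensemble mean per (time, species)."""
        return self.states.mean(axis=0)

    def var(self) -> np.ndarray:
        return self.states.var(axis=0, ddof=1)

    def pooled(self, times: Sequence[float]) -> np.ndarray:
        """Snapshots at several times pooled into one (n*k, n_species) sample."""
        return np.concatenate([self.snapshot(t) for t in times], axis=0)

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(self.times, self.states[i], self.species)


def fill_grid(states, grid, gi, t_next, counts) -> int:
    """Fill grid rows with the current state for all grid times < t_next."""
    n = len(grid)
    while gi < n and grid[gi] < t_next:
        states[gi] = counts
        gi += 1
    return gi


# Registry is populated lazily to avoid circular imports.
ENGINES: dict[str, Callable[[SimulationRequest], Trajectory]] = {}

NON_DELAY_ENGINES = ("direct", "first_reaction", "mnr")
DELAY_ENGINES = ("delay_rejection", "delay_direct", "delay_mnr")


def get_engine(name: str) -> Callable[[SimulationRequest], Trajectory]:
    if not ENGINES:
        _populate()
    try:
        return ENGINES[name]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {name!r}; valid names: {', '.join(NON_DELAY_ENGINES + DELAY_ENGINES)}"
        ) from None


def _populate() -> None:
    from . import markov, delayed

    ENGINES.update({
        "direct": markov.simulate_direct,
        "first_reaction": markov.simulate_first_reaction,
        "mnr": markov.simulate_mnr,
        "delay_rejection": delayed.simulate_delay_rejection,
        "delay_direct": delayed.simulate_delay_direct,
        "delay_mnr": delayed.simulate_delay_mnr,
    })


def run_ensemble(
    network: ReactionNetwork,
    initial_counts,
    t_final: float,
    output_times,
    n_samples: int,
    seed: int = 0,
    engine: str | Callable = "direct",
) -> Ensemble:
    """Simulate ``n_samples`` independent trajectories.

    Replicate ``i`` uses its own generator seeded with ``seed + i`` so that
    ensembles are reproducible and trivially partitionable.
    """
    fn = get_engine(engine) if isinstance(engine, str) else engine
    grid = np.asarray(output_times, dtype=np.float64)
    states = np.empty((n_samples, len(grid), len(initial_counts)), dtype=np.int64)
    species = network.species.names
    for i in range(n_samples):
        req = SimulationRequest(network, initial_counts, t_final, grid, seed=int(seed) + i)
        states[i] = fn(req).states
    return Ensemble(times=grid, states=states, species=species)
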