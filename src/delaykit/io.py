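"""Tabular writers/readers for trajectories, landscapes and attractor reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engines.base import Ensemble
from .landscape import AttractorReport, LandscapeGrid

__all__ = [
    "ensemble_to_frame",
    "write_trajectories",
    "read_trajectories",
    "write_landscape",
    "write_attractor_report",
]

_SEP = {"tsv": "\t", "csv": ","}


def ensemble_to_frame(ensemble: Ensemble) -> pd.DataFrame:
    """Long-format table: sample_id, time, one integer column per species."""
    s, t, n = ensemble.states.shape
    df = pd.DataFrame({
        "sample_id": np.repeat(np.arange(s), t),
        "time": np.tile(ensemble.times, s),
    })
    flat = ensemble.states.reshape(s * t, n)
    for j, name in enumerate(ensemble.species or [f"species_{j}" for j in range(n)]):
        df[name] = flat[:, j]
    return df


def write_trajectories(ensemble: Ensemble, path, fmt: str = "tsv") -> None:
    """Write an ensemble as a delimited long-format table (counts stay integers)."""
    if ensemble.states.size == 0:
        raise ValueError("refusing to write an empty ensemble")
    if fmt not in _SEP:
        raise ValueError(f"format must be one of {sorted(_SEP)}")
    ensemble_to_frame(ensemble).to_csv(path, sep=_SEP[fmt], index=False)


def read_trajectories(path, fmt: str | None = None) -> Ensemble:
    """Read a table written by :func:`write_trajectories` back into an ensemble."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix == ".csv" else "tsv"
    df = pd.read_csv(path, sep=_SEP[fmt])
    species = tuple(c for c in df.columns if c not in ("sample_id", "time"))
    ids = df["sample_id"].to_numpy()
    n_samples = int(ids.max()) + 1
    times = df.loc[ids == 0, "time"].to_numpy(dtype=float)
    states = df[list(species)].to_numpy(dtype=np.int64).reshape(
        n_samples, len(times), len(species))
    return Ensemble(times=times, states=states, species=species)


def write_landscape(grid: LandscapeGrid, path) -> None:
    """TSV export of a landscape: bin centers with frequency P and potential U."""
    xs, ys = grid.x_centers, grid.y_centers
    xi, yi = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), indexing="ij")
    # species named P or U would shadow the frequency/potential columns
    cols = [n if n not in ("P", "U") else f"{n}_center" for n in grid.axis_species]
    df = pd.DataFrame({
        cols[0]: xs[xi.ravel()],
        cols[1]: ys[yi.ravel()],
        "P": grid.P.ravel(),
        "U": grid.U.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def write_attractor_report(report: AttractorReport, path, species=None) -> None:
    """JSON export of the attractor report."""
    obj = {
        "n_attractors": report.n_attractors,
        "merge_radius": report.merge_radius,
        "n_failed_starts": report.n_failed,
        "attractors": [
            {
                "state": (dict(zip(species, map(float, a))) if species
                          else [float(v) for v in a]),
                "basin_count": int(c),
            }
            for a, c in zip(report.attractors, report.basin_counts)
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
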