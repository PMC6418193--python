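"""Population-level simulation protocol and the k_unlock grid scan.

The protocol runs many independent single-promoter cells (default 500) for a
fixed duration (default 75 min) sampling counts on a regular grid (default
every 15 min), with per-cell initial RNA numbers drawn from a Poisson
distribution (default mean 0.7/cell) to emulate spurious pre-induction
production.  Trajectories are normalized to the mean at the final sample
time; a one-dimensional scan over ``k_unlock`` fits the normalized curve to
a target, ignoring the t = 0 point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transcription_model import (
    ParameterError,
    PopulationRun,
    TranscriptionModelParams,
    cell_rng,
    simulate_cell,
)

__all__ = [
    "RelativeTrajectory",
    "KUnlockScanResult",
    "run_protocol",
    "relative_to_last",
    "scan_k_unlock",
]


@dataclass(frozen=True)
class RelativeTrajectory:
    """Mean RNA numbers divided by the mean at the final sample time."""

    sample_times: np.ndarray
    rel_means: np.ndarray
    ci90_halfwidths: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.sample_times, dtype=float)
        rm = np.asarray(self.rel_means, dtype=float)
        hw = np.asarray(self.ci90_halfwidths, dtype=float)
        if not (st.shape == rm.shape == hw.shape):
            raise ParameterError("trajectory fields must have matching shapes")
        if np.any(rm < 0) or np.any(hw < 0):
            raise ParameterError("relative means and CI halfwidths must be >= 0")
        if not math.isclose(rm[-1], 1.0, rel_tol=0, abs_tol=1e-12):
            raise ParameterError("relative mean at the final time must equal 1")
        object.__setattr__(self, "sample_times", st)
        object.__setattr__(self, "rel_means", rm)
        object.__setattr__(self, "ci90_halfwidths", hw)


@dataclass(frozen=True)
class KUnlockScanResult:
    k_unlock_grid: np.ndarray
    trajectories: list
    objective_values: np.ndarray
    best_k_unlock: float

    def __post_init__(self) -> None:
        best = self.k_unlock_grid[int(np.argmin(self.objective_values))]
        if best != self.best_k_unlock:
            raise ParameterError("best_k_unlock must minimize the objective")


def run_protocol(
    params: TranscriptionModelParams,
    n_cells: int = 500,
    t_end: float = 75.0,
    sample_every: float = 15.0,
    init_rna_poisson_mean: float = 0.7,
    seed: int = 0,
) -> PopulationRun:
    """Simulate ``n_cells`` independent cells on a regular sampling grid.

    Each cell starts with one free promoter, zero of every other species,
    and an initial RNA count drawn Poisson(``init_rna_poisson_mean``) from
    its own generator (derived from ``seed`` and the cell index).
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if t_end <= 0 or sample_every <= 0:
        raise ParameterError("t_end and sample_every must be > 0")
    n_steps = t_end / sample_every
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParameterError(
            f"sample_every ({sample_every}) must divide t_end ({t_end})"
        )
    if init_rna_poisson_mean < 0:
        raise ParameterError("init_rna_poisson_mean must be >= 0")
    sample_times = np.arange(0, int(round(n_steps)) + 1) * float(sample_every)
    trajectories = []
    for i in range(n_cells):
        rng = cell_rng(seed, i)
        init = int(rng.poisson(init_rna_poisson_mean)) if init_rna_poisson_mean > 0 else 0
        traj = simulate_cell(params, t_end, sample_times, seed=seed,
                             initial_rna=init, rng=rng)
        trajectories.append(traj)
    return PopulationRun(params=params, trajectories=trajectories, seed=seed)


def relative_to_last(run: PopulationRun) -> RelativeTrajectory:
    """Normalize a population run to the mean at the final sample time.

    Confidence-interval halfwidths are two-tailed Student-t at 90% from the
    per-cell counts, divided by the same final mean.
    """
    counts = run.counts_matrix()
    means = counts.mean(axis=0)
    final = means[-1]
    if final <= 0:
        raise ParameterError("final-time mean is zero; normalization undefined")
    n = counts.shape[0]
    if n > 1:
        sem = counts.std(axis=0, ddof=1) / math.sqrt(n)
        tcrit = stats.t.ppf(0.95, df=n - 1)
        halfwidths = tcrit * sem / final
    else:
        halfwidths = np.zeros_like(means)
    return RelativeTrajectory(
        sample_times=run.sample_times,
        rel_means=means / final,
        ci90_halfwidths=halfwidths,
    )


def scan_k_unlock(
    base_params: TranscriptionModelParams,
    k_unlock_grid,
    target: RelativeTrajectory,
    n_cells: int = 500,
    t_end: float = 75.0,
    sample_every: float = 15.0,
    init_rna_poisson_mean: float = 0.7,
    seed: int = 0,
    weight_by_ci: bool = False,
) -> KUnlockScanResult:
    """Fit ``k_unlock`` by grid search against a target relative trajectory.

    The objective is the sum of squared errors between relative means at
    sample times strictly greater than zero (the t = 0 point is excluded).
    With ``weight_by_ci`` each squared error is divided by the target CI
    halfwidth squared (floored to its smallest positive value).
    """
    grid = np.asarray(list(k_unlock_grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("k_unlock_grid must be non-empty")
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ParameterError("k_unlock_grid must be strictly descending")
    n_steps = int(round(t_end / sample_every))
    expected_times = np.arange(0, n_steps + 1) * float(sample_every)
    if target.sample_times.shape != expected_times.shape or not np.allclose(
        target.sample_times, expected_times
    ):
        raise ParameterError("target sample times do not match the protocol grid")

    mask = target.sample_times > 0
    if weight_by_ci:
        hw = target.ci90_halfwidths[mask]
        positive = hw[hw > 0]
        floor = positive.min() if positive.size else 1.0
        weights = 1.0 / np.maximum(hw, floor) ** 2
    else:
        weights = np.ones(int(mask.sum()))

    trajectories = []
    objectives = np.empty(grid.size)
    for j, ku in enumerate(grid):
        params = base_params.with_(k_unlock=ku)
        run = run_protocol(
            params,
            n_cells=n_cells,
            t_end=t_end,
            sample_every=sample_every,
            init_rna_poisson_mean=init_rna_poisson_mean,
            seed=seed,
        )
        rel = relative_to_last(run)
        resid = rel.rel_means[mask] - target.rel_means[mask]
        objectives[j] = float(np.sum(weights * resid**2))
        trajectories.append(rel)
    best = float(grid[int(np.argmin(objectives))])
    return KUnlockScanResult(
        k_unlock_grid=grid,
        trajectories=trajectories,
        objective_values=objectives,
        best_k_unlock=best,
    )
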