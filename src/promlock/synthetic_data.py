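"""Generators for every input the pipeline consumes, with known ground truth.

Three families: cross-sectional single-cell count tables driven by the
mechanistic simulator (plus a plain Poisson generator for isolated stats
tests), noisy Lineweaver-Burk condition sets with recorded truth fractions,
and a gene universe reproducing fixed genome-wide counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .transcription_model import (
    DEFAULT_PARAMS,
    ParameterError,
    TranscriptionModelParams,
    cell_rng,
    simulate_cell,
)
from .single_cell_stats import CountTable
from .initiation_decomposition import LBDataset
from .coldshock_enrichment import GeneUniverse

__all__ = [
    "SCENARIOS",
    "SyntheticSpec",
    "generate_count_table",
    "generate_poisson_table",
    "generate_lb_dataset",
    "generate_gene_universe",
]

#: Scenario presets.  "chromosome_30C" uses the calibrated defaults
#: (fast unlocking), "chromosome_10C" the same kinetics with slow unlocking
#: (long-lived locked states), "plasmid_any" disables locking entirely.
SCENARIOS: dict[str, TranscriptionModelParams] = {
    "chromosome_30C": DEFAULT_PARAMS,
    "chromosome_10C": DEFAULT_PARAMS.with_(k_unlock=0.002),
    "plasmid_any": DEFAULT_PARAMS.with_(k_unlock=math.inf),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a cross-sectional synthetic count table."""

    scenario: str = "chromosome_30C"
    params: TranscriptionModelParams | None = None
    n_cells: int = 200
    sample_times: Sequence[float] = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0)
    init_rna_poisson_mean: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario == "custom":
            if self.params is None:
                raise ParameterError("custom scenario requires explicit params")
        elif self.scenario in SCENARIOS:
            if self.params is None:
                object.__setattr__(self, "params", SCENARIOS[self.scenario])
        else:
            raise ParameterError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(SCENARIOS)} or 'custom'"
            )
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        st = np.asarray(self.sample_times, dtype=float)
        if st.size == 0 or np.any(st < 0) or np.any(np.diff(st) <= 0):
            raise ParameterError("sample_times must be ascending and >= 0")
        if self.init_rna_poisson_mean < 0:
            raise ParameterError("init_rna_poisson_mean must be >= 0")


def generate_count_table(spec: SyntheticSpec) -> CountTable:
    """Cross-sectional count table: an independent cohort per time point.

    Each cohort of ``n_cells`` is simulated from t = 0 up to its own sample
    time (cells are never reused across time points, matching a
    measurement design where new cells are drawn at every time point).
    """
    rows = []
    for j, t in enumerate(np.asarray(spec.sample_times, dtype=float)):
        for i in range(spec.n_cells):
            rng = cell_rng(spec.seed, j * spec.n_cells + i)
            init = int(rng.poisson(spec.init_rna_poisson_mean)) \
                if spec.init_rna_poisson_mean > 0 else 0
            if t == 0:
                count = init
            else:
                traj = simulate_cell(spec.params, t_end=t, sample_times=[t],
                                     seed=spec.seed, initial_rna=init, rng=rng)
                count = int(traj.rna_counts[-1])
            rows.append((f"c{j}_{i}", spec.scenario, t, count, "r1"))
    df = pd.DataFrame(rows, columns=["cell_id", "condition", "time_min",
                                     "rna_count", "replicate"])
    return CountTable(df)


def generate_poisson_table(
    means_by_condition: dict, n_cells: int, seed: int
) -> CountTable:
    """Plain Poisson counts per condition — for stats tests in isolation."""
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mu in means_by_condition.items():
        if mu < 0:
            raise ParameterError("Poisson means must be >= 0")
        counts = rng.poisson(mu, size=n_cells)
        for i, c in enumerate(counts):
            rows.append((f"{cond}_{i}", cond, 0.0, int(c), "r1"))
    df = pd.DataFrame(rows, columns=["cell_id", "condition", "time_min",
                                     "rna_count", "replicate"])
    return CountTable(df)


#: Default inverse relative RNAP concentrations: 0.5X, 1X, 1.5X, 2X.
DEFAULT_INV_RNAP_POINTS = (2.0, 1.0, 2.0 / 3.0, 0.5)


def generate_lb_dataset(
    t_prior_ref: float,
    t_after_ref: float,
    inv_rnap_points: Sequence[float] = DEFAULT_INV_RNAP_POINTS,
    noise_cv: float = 0.0,
    seed: int = 0,
    inv_rnap_ref: float = 1.0,
) -> tuple[LBDataset, dict]:
    """Noisy Lineweaver-Burk points with known ground truth.

    The noiseless line is ``inv_rate = t_after_ref +
    (t_prior_ref / inv_rnap_ref) * inv_rnap``; multiplicative lognormal
    noise with the given coefficient of variation (unit mean) perturbs each
    point.  Returns the dataset and a truth record with the generating
    slope, intercept and fractions.
    """
    if t_prior_ref <= 0 or t_after_ref <= 0:
        raise ParameterError("reference durations must be > 0")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    x = np.asarray(inv_rnap_points, dtype=float)
    if x.size < 2 or np.any(x <= 0):
        raise ParameterError("need >= 2 positive inv_rnap points")
    if inv_rnap_ref <= 0:
        raise ParameterError("inv_rnap_ref must be > 0")
    slope = t_prior_ref / inv_rnap_ref
    y = t_after_ref + slope * x
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = math.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=x.size)
        y = y * noise
    ref_candidates = np.nonzero(np.isclose(x, inv_rnap_ref))[0]
    ref_idx = int(ref_candidates[0]) if ref_candidates.size else int(np.argmin(np.abs(x - inv_rnap_ref)))
    dt = t_prior_ref + t_after_ref
    truth = {
        "slope": slope,
        "intercept": t_after_ref,
        "delta_t_ref": dt,
        "t_prior_frac": t_prior_ref / dt,
        "t_after_frac": t_after_ref / dt,
    }
    return LBDataset(inv_rnap=x, inv_rate=y, reference_index=ref_idx), truth


def generate_gene_universe(
    n_genes: int = 4452,
    n_sensitive: int = 306,
    transient_size: int = 70,
    transient_sensitive: int = 10,
    longterm_size: int = 35,
    longterm_sensitive: int = 0,
    seed: int = 0,
) -> GeneUniverse:
    """Gene universe with exact flag counts and two constrained subsets.

    The transient and long-term sets are disjoint; sensitivity flags inside
    each set are fixed to the requested counts and the remaining flags are
    placed uniformly at random among the unconstrained genes.
    """
    if transient_size + longterm_size > n_genes:
        raise ParameterError("subsets exceed the universe")
    if transient_sensitive > transient_size or longterm_sensitive > longterm_size:
        raise ParameterError("subset sensitive counts exceed subset sizes")
    remaining = n_sensitive - transient_sensitive - longterm_sensitive
    free = n_genes - transient_size - longterm_size
    if remaining < 0 or remaining > free:
        raise ParameterError("infeasible sensitivity counts")

    gene_ids = tuple(f"g{i:05d}" for i in range(n_genes))
    sensitive = np.zeros(n_genes, dtype=bool)
    transient = gene_ids[:transient_size]
    longterm = gene_ids[transient_size:transient_size + longterm_size]
    sensitive[:transient_sensitive] = True
    sensitive[transient_size:transient_size + longterm_sensitive] = True
    rng = np.random.default_rng(seed)
    free_idx = np.arange(transient_size + longterm_size, n_genes)
    chosen = rng.choice(free_idx, size=remaining, replace=False)
    sensitive[chosen] = True

    return GeneUniverse(
        gene_ids=gene_ids,
        sensitive=sensitive,
        set_memberships={"transient": transient, "long_term": longterm},
    )
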