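"""Bootstrap enrichment of gene sets against a supercoiling-sensitivity flag.

Given a gene universe with a boolean sensitivity flag and named gene sets,
the test asks how often a random set of the same size, resampled with
replacement from the universe, contains at least (or at most) as many
flagged genes as observed.  An exact binomial tail provides a deterministic
cross-check of the bootstrap probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .transcription_model import ParameterError

__all__ = [
    "GeneUniverse",
    "EnrichmentResult",
    "exact_binomial_tail",
    "bootstrap_null",
    "enrichment_test",
]


@dataclass(frozen=True)
class GeneUniverse:
    """Genome-wide sensitivity flags plus named gene subsets."""

    gene_ids: tuple
    sensitive: np.ndarray
    set_memberships: dict

    def __post_init__(self) -> None:
        ids = tuple(self.gene_ids)
        flags = np.asarray(self.sensitive, dtype=bool)
        if flags.shape != (len(ids),):
            raise ParameterError("sensitive flags must match gene_ids in length")
        if len(set(ids)) != len(ids):
            raise ParameterError("gene_ids must be unique")
        index = {g: i for i, g in enumerate(ids)}
        sets = {}
        for name, members in self.set_memberships.items():
            members = tuple(members)
            bad = [g for g in members if g not in index]
            if bad:
                raise ParameterError(f"set {name!r} has genes outside the universe: {bad[:5]}")
            if len(set(members)) != len(members):
                raise ParameterError(f"set {name!r} has duplicate genes")
            sets[name] = members
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "sensitive", flags)
        object.__setattr__(self, "set_memberships", sets)
        object.__setattr__(self, "_index", index)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_sensitive(self) -> int:
        return int(self.sensitive.sum())

    @property
    def baseline_frac(self) -> float:
        return self.n_sensitive / self.n_genes

    def set_size(self, name: str) -> int:
        return len(self._set(name))

    def sensitive_in_set(self, name: str) -> int:
        idx = [self._index[g] for g in self._set(name)]
        return int(self.sensitive[idx].sum())

    def _set(self, name: str):
        try:
            return self.set_memberships[name]
        except KeyError:
            raise ParameterError(f"unknown gene set {name!r}") from None


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    set_size: int
    observed_sensitive: int
    observed_frac: float
    baseline_frac: float
    tail: str  # "ge_observed" or "le_observed"
    boot_p: float
    exact_p: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        for p in (self.boot_p, self.exact_p):
            if not (0.0 <= p <= 1.0):
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.tail not in ("ge_observed", "le_observed"):
            raise ParameterError(f"unknown tail {self.tail!r}")


def exact_binomial_tail(n: int, k_obs: int, p: float, tail: str) -> float:
    """P(X >= k_obs) or P(X <= k_obs) for X ~ Binomial(n, p)."""
    if not (0 <= k_obs <= n):
        raise ParameterError("require 0 <= k_obs <= n")
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    if tail == "ge_observed":
        return float(stats.binom.sf(k_obs - 1, n, p))
    if tail == "le_observed":
        return float(stats.binom.cdf(k_obs, n, p))
    raise ParameterError(f"unknown tail {tail!r}")


def bootstrap_null(
    universe: GeneUniverse, set_size: int, n_resamples: int, seed: int
) -> np.ndarray:
    """Sensitive-gene counts in random sets resampled with replacement.

    Genes are resampled uniformly with replacement under a canonical
    ordering (sensitive genes first), so the null distribution depends only
    on the flag counts, not on gene labels or their order.
    """
    if universe.n_genes == 0:
        raise ParameterError("empty universe")
    if set_size < 1 or n_resamples < 1:
        raise ParameterError("set_size and n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, universe.n_genes, size=(n_resamples, set_size))
    return (idx < universe.n_sensitive).sum(axis=1)


def enrichment_test(
    universe: GeneUniverse,
    set_name: str,
    n_resamples: int = 10_000,
    seed: int = 0,
    resample_size: int | None = None,
    strict_tail: bool = False,
) -> EnrichmentResult:
    """Bootstrap tail probability of the observed sensitive count.

    The tail direction is chosen by comparing the observed sensitive
    fraction with the genome-wide baseline: upper tail when enriched, lower
    tail when depleted.  Ties are included ("at least / at most as
    extreme") unless ``strict_tail`` is set, in which case the upper tail
    counts draws strictly above the observation (and the lower tail draws
    strictly below).  ``resample_size`` defaults to the observed set size.
    """
    k_obs = universe.sensitive_in_set(set_name)
    size = universe.set_size(set_name)
    n = resample_size if resample_size is not None else size
    observed_frac = k_obs / size
    baseline = universe.baseline_frac
    tail = "ge_observed" if observed_frac >= baseline else "le_observed"

    null_counts = bootstrap_null(universe, n, n_resamples, seed)
    # when resampling at a size other than the observed set, compare at the
    # equivalent count for that size (fractions, rounded to a count)
    k_cmp = k_obs if n == size else int(round(observed_frac * n))
    if tail == "ge_observed":
        boot_p = float(np.mean(null_counts > k_cmp if strict_tail else null_counts >= k_cmp))
        exact_k = k_cmp + 1 if strict_tail else k_cmp
        exact_p = 0.0 if exact_k > n else exact_binomial_tail(n, exact_k, baseline, "ge_observed")
    else:
        boot_p = float(np.mean(null_counts < k_cmp if strict_tail else null_counts <= k_cmp))
        exact_k = k_cmp - 1 if strict_tail else k_cmp
        exact_p = 0.0 if exact_k < 0 else exact_binomial_tail(n, exact_k, baseline, "le_observed")

    return EnrichmentResult(
        set_name=set_name,
        set_size=size,
        observed_sensitive=k_obs,
        observed_frac=observed_frac,
        baseline_frac=baseline,
        tail=tail,
        boot_p=boot_p,
        exact_p=exact_p,
        n_resamples=n_resamples,
        seed=seed,
    )
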