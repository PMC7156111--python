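"""Forward-in-time stochastic simulation of coevolutionary frequency paths.

Each host generation applies, in order: the deterministic gene-for-gene
update (selection), binomial drift at the fixed haploid population size of
each species, and recurrent functional mutation drawn as binomial counts of
switching individuals.  The recorded path entry is the post-drift,
post-mutation allele count at the start of each host generation -- the
quantity consumed by the backward conditioned coalescent.

Replicate histories ("repetitions of the same coevolutionary history") use
independent child RNG streams spawned deterministically from one master
seed, so every experiment is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._kernels import forward_kernel
from .dynamics import GFGParams

__all__ = [
    "PopulationConfig",
    "SimulationSettings",
    "FrequencyPath",
    "drift_and_mutate",
    "simulate_frequency_path",
    "simulate_history_replicates",
]

#: per-site per-generation neutral mutation rate (shared default)
DEFAULT_MU_SITE = 1e-7
#: coevolutionary locus length in base pairs
DEFAULT_LOCUS_LENGTH = 2500
#: sample size per species
DEFAULT_SAMPLE_SIZE = 50


@dataclass(frozen=True)
class PopulationConfig:
    """Population and locus configuration for both species.

    ``theta`` values are always derived as ``2 * N * L * mu_site`` (haploid
    populations), never set freely; with the defaults (L = 2500 bp,
    mu_site = 1e-7) a population of N = 10,000 has theta = 5.
    """

    N_H: int
    N_P: int
    n_H: int = DEFAULT_SAMPLE_SIZE
    n_P: int = DEFAULT_SAMPLE_SIZE
    L: int = DEFAULT_LOCUS_LENGTH
    mu_site: float = DEFAULT_MU_SITE

    def __post_init__(self) -> None:
        if self.N_H < 1 or self.N_P < 1:
            raise ValueError("population sizes must be >= 1")
        if not (0 < self.n_H <= self.N_H) or not (0 < self.n_P <= self.N_P):
            raise ValueError("sample sizes must satisfy 0 < n <= N")
        if self.L < 1 or self.mu_site < 0:
            raise ValueError("invalid locus configuration")

    @property
    def theta_H(self) -> float:
        return 2.0 * self.N_H * self.L * self.mu_site

    @property
    def theta_P(self) -> float:
        return 2.0 * self.N_P * self.L * self.mu_site


@dataclass(frozen=True)
class SimulationSettings:
    """Run-length, initial conditions and replication settings.

    ``g_max`` defaults to ``max(3 N_H, 3 N_P)`` host generations, long
    enough for sweep and balancing signatures to establish; pass an
    explicit value to override (scaled-down runs should record it).
    """

    R0: float = 0.2
    a0: float = 0.2
    g_max: Optional[int] = None
    r: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.R0 <= 1.0 and 0.0 <= self.a0 <= 1.0):
            raise ValueError("initial frequencies must lie in [0, 1]")
        if self.g_max is not None and self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        if self.r < 1:
            raise ValueError("replicate count r must be >= 1")

    def resolve_g_max(self, config: PopulationConfig) -> int:
        return self.g_max if self.g_max is not None else max(3 * config.N_H, 3 * config.N_P)


@dataclass(frozen=True)
class FrequencyPath:
    """Per-generation functional-allele counts for one species.

    ``counts[g]`` is the number of derived-allele carriers (``RES`` for the
    host, ``INF`` for the parasite) at the start of host generation ``g``;
    ``counts[0]`` is ``round(N * initial frequency)`` and the last entry is
    the present.
    """

    counts: np.ndarray
    N: int
    species: str  # "host" or "parasite"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a non-empty 1-d array")
        if c.min() < 0 or c.max() > self.N:
            raise ValueError("counts must lie in [0, N]")
        if self.species not in ("host", "parasite"):
            raise ValueError("species must be 'host' or 'parasite'")

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.N

    def __len__(self) -> int:
        return len(self.counts)


def drift_and_mutate(
    freq_after_selection: float,
    N: int,
    mu_gain: float,
    mu_loss: float,
    rng: np.random.Generator,
) -> int:
    """One generation of binomial drift followed by recurrent mutation.

    Drift draws ``count ~ Binomial(N, freq)``; mutation then switches
    ``Binomial(N - count, mu_gain)`` individuals in and
    ``Binomial(count, mu_loss)`` out, keeping the state integer-valued (the
    per-individual interpretation of the functional mutation rates).  The
    result is clamped to [0, N].
    """
    if not (0.0 <= freq_after_selection <= 1.0):
        raise ValueError("frequency out of [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    count = int(rng.binomial(N, freq_after_selection))
    count += int(rng.binomial(N - count, mu_gain)) - int(rng.binomial(count, mu_loss))
    return min(max(count, 0), N)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_frequency_path(
    params: GFGParams,
    config: PopulationConfig,
    settings: SimulationSettings,
    rng: np.random.Generator,
) -> Tuple[FrequencyPath, FrequencyPath]:
    """Simulate one coevolutionary history.

    Per host generation: deterministic gene-for-gene update from the
    current frequencies, then drift and functional mutation applied once
    per species (host gains ``RES`` at ``mu_rtoR`` / loses at ``mu_Rtor``;
    the parasite path applies its drift/mutation to the carried state
    ``a_{g+1,1}``, the second-cycle frequency being deterministic within
    the generation).  Returns (host, parasite) paths of length
    ``g_max + 1``.
    """
    g_max = settings.resolve_g_max(config)
    host, para = forward_kernel(
        _kernel_seed(rng),
        int(g_max),
        int(config.N_H),
        int(config.N_P),
        params.s,
        params.c_H,
        params.c_P,
        params.mu_Rtor,
        params.mu_rtoR,
        params.mu_ntoI,
        params.mu_Iton,
        float(settings.R0),
        float(settings.a0),
    )
    return (
        FrequencyPath(counts=host, N=config.N_H, species="host"),
        FrequencyPath(counts=para, N=config.N_P, species="parasite"),
    )


def simulate_history_replicates(
    params: GFGParams,
    config: PopulationConfig,
    settings: SimulationSettings,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[FrequencyPath, FrequencyPath]]:
    """Simulate ``settings.r`` mutually independent coevolutionary histories.

    Child RNG streams are spawned deterministically from
    ``settings.seed`` (or from ``rng`` when given), so the replicate list
    is replayable bit-identically from the master seed; ``r = 1`` reduces
    exactly to :func:`simulate_frequency_path` on the first child stream.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    streams = rng.spawn(settings.r)
    return [
        simulate_frequency_path(params, config, settings, stream)
        for stream in streams
    ]
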