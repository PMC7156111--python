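"""Backward-in-time coalescent conditioned on a forward frequency path.

For one species, the sample of size ``n`` is partitioned between the two
functional allelic classes by hypergeometric draws from the present-day
allele count.  Backward through the recorded path, lineages coalesce only
within their class (Wright-Fisher parent choice inside a class of the size
the path dictates at that generation), and jump between classes as the
backward shadow of forward functional mutation -- the two classes behave
like two demes of a structured coalescent whose sizes follow the
trajectory.  When a class size drops to zero backwards in time (the allele
origin), its last lineage migrates into the other class.  Older than the
conditioned history, all surviving lineages are exchangeable and coalesce
in a single neutral Kingman class of size ``N``.

Neutral mutations are then dropped on the genealogy (infinite-sites,
Poisson per branch with rate ``L * mu_site`` per generation) to produce a
polarized 0/1 haplotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ._kernels import genealogy_kernel
from .dynamics import GFGParams
from .forward import FrequencyPath, PopulationConfig

__all__ = [
    "Genealogy",
    "SNPMatrix",
    "assign_sample_classes",
    "simulate_genealogy",
    "neutral_genealogy",
    "drop_mutations",
]


@dataclass(frozen=True)
class Genealogy:
    """A rooted (possibly multifurcating) genealogy of ``n`` sampled lineages.

    Nodes ``0 .. n-1`` are the leaves (time 0 = present); ``parent[v]`` is
    -1 for the root; ``time[v]`` is in generations before present.
    ``conditioned_steps`` records how many backward generations were spent
    inside the conditioned phase (at most the path length minus one;
    fewer only when the MRCA is reached within the path).
    """

    parent: np.ndarray
    time: np.ndarray
    n: int
    root: int
    conditioned_steps: int
    species: str = "host"

    def __post_init__(self) -> None:
        if self.n >= 2 and self.parent[self.root] != -1:
            raise ValueError("root must have no parent")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Length (generations) of the branch above each non-root node."""
        lengths = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                lengths[v] = self.time[p] - self.time[v]
        return lengths

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def leaf_sets(self) -> np.ndarray:
        """Boolean (n_nodes, n) matrix: leaves descending from each node."""
        desc = np.zeros((self.n_nodes, self.n), dtype=bool)
        desc[np.arange(self.n), np.arange(self.n)] = True
        order = np.argsort(self.time, kind="stable")
        for v in order:
            p = self.parent[v]
            if p >= 0:
                desc[p] |= desc[v]
        return desc


@dataclass(frozen=True)
class SNPMatrix:
    """Polarized binary haplotype-by-site matrix for one species sample.

    Rows are sampled haplotypes, columns segregating sites (0 = ancestral,
    1 = derived), ordered by their unit-interval positions (ms convention:
    the physical locus length enters only through the mutation rate).
    Invariant columns are rejected at construction.
    """

    matrix: np.ndarray
    positions: np.ndarray
    species: str = "host"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-d (haplotypes x sites)")
        if m.shape[1] != len(self.positions):
            raise ValueError("positions must match the number of sites")
        if m.shape[1] > 0:
            csum = m.sum(axis=0)
            if np.any(csum == 0) or np.any(csum == m.shape[0]):
                raise ValueError("invariant columns are not allowed")
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("positions must be sorted")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


def assign_sample_classes(
    n: int, final_count: int, N: int, rng: np.random.Generator
) -> Tuple[int, int]:
    """Partition a random sample of ``n`` individuals between allele classes.

    Sampling is without replacement from the ``N`` individuals alive at
    present, of which ``final_count`` carry the derived functional allele:
    ``k_derived ~ Hypergeometric(N, final_count, n)``.  Returns
    ``(k_derived, k_ancestral)``.
    """
    if not (0 <= final_count <= N):
        raise ValueError("final_count must lie in [0, N]")
    if not (1 <= n <= N):
        raise ValueError("sample size must satisfy 1 <= n <= N")
    k_der = int(rng.hypergeometric(final_count, N - final_count, n))
    return k_der, n - k_der


def _mu_rates_for(path_species: str, params: GFGParams) -> Tuple[float, float]:
    # (gain into derived class, loss out of derived class), forward rates
    if path_species == "host":
        return params.mu_rtoR, params.mu_Rtor
    return params.mu_ntoI, params.mu_Iton


def simulate_genealogy(
    path: FrequencyPath,
    params: GFGParams,
    n: int,
    rng: np.random.Generator,
) -> Genealogy:
    """Sample one genealogy conditioned on a species' frequency path.

    The tree shape and length are conditioned on the recorded
    allele-frequency changes, including fixations and losses; functional
    mutations appear backward in time as lineage migration between the two
    allelic classes at probability ``min(1, mu * X_other(g-1) / X_own(g))``
    per lineage per generation.  Class sizes are the integer counts stored
    in the path (no rounding ambiguity).  One backward step is taken per
    recorded host generation for both species.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = np.ascontiguousarray(path.counts, dtype=np.int64)
    k_der, k_anc = assign_sample_classes(n, int(counts[-1]), path.N, rng)
    mu_gain, mu_loss = _mu_rates_for(path.species, params)
    parent, time, n_nodes, root, steps = genealogy_kernel(
        int(rng.integers(0, 2**31 - 1)),
        counts,
        int(path.N),
        float(mu_gain),
        float(mu_loss),
        int(k_der),
        int(k_anc),
    )
    return Genealogy(
        parent=parent,
        time=time,
        n=n,
        root=int(root),
        conditioned_steps=int(steps),
        species=path.species,
    )


def neutral_genealogy(
    N: int, n: int, rng: np.random.Generator, species: str = "host"
) -> Genealogy:
    """Unconditioned discrete Kingman genealogy at constant size ``N``.

    Equivalent to conditioning on a length-1 path: the whole history is the
    exchangeable single-class phase.  Used for the neutral (no coevolution)
    model of the ABC reference table.
    """
    parent, time, n_nodes, root, steps = genealogy_kernel(
        int(rng.integers(0, 2**31 - 1)),
        np.array([N], dtype=np.int64),
        int(N),
        0.0,
        0.0,
        int(n),
        0,
    )
    return Genealogy(parent=parent, time=time, n=n, root=int(root),
                     conditioned_steps=0, species=species)


def drop_mutations(
    tree: Genealogy,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> SNPMatrix:
    """Throw neutral mutations on a genealogy (infinite-sites model).

    Each branch of length ``b`` generations receives
    ``Poisson(b * L * mu_site)`` mutations; every mutation gets a uniform
    position in [0, 1) (collisions re-drawn) and assigns the derived state
    to the leaves below it.  Columns are sorted by position; branches above
    the root carry no mutations, so no column is invariant.
    """
    if tree.n < 2:
        return SNPMatrix(
            matrix=np.zeros((tree.n, 0), dtype=np.int8),
            positions=np.zeros(0),
            species=tree.species,
        )
    lengths = tree.branch_lengths()
    rate = config.L * config.mu_site
    n_mut = rng.poisson(lengths * rate)
    total = int(n_mut.sum())
    if total == 0:
        return SNPMatrix(
            matrix=np.zeros((tree.n, 0), dtype=np.int8),
            positions=np.zeros(0),
            species=tree.species,
        )
    desc = tree.leaf_sets()
    cols = np.zeros((total, tree.n), dtype=np.int8)
    j = 0
    for v in range(tree.n_nodes):
        for _ in range(n_mut[v]):
            cols[j] = desc[v]
            j += 1
    positions = rng.random(total)
    while len(np.unique(positions)) < total:  # infinite sites: re-draw clashes
        positions = rng.random(total)
    order = np.argsort(positions)
    return SNPMatrix(
        matrix=np.ascontiguousarray(cols[order].T),
        positions=positions[order],
        species=tree.species,
    )
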