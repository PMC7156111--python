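"""Summary statistics of polarized SNP data.

Eight per-species statistics computed from the unfolded site frequency
spectrum (SFS) -- S, Watterson's theta, nucleotide diversity pi, Tajima's
D, Fu & Li's D and F (unfolded, derived singletons as the external class),
Fay & Wu's theta_H and Zeng's normalized H' -- plus one cross-species
statistic, the Pairwise Manhattan Distance (PMD) between the
proportion-normalized host and parasite spectra.  Monomorphic samples
(S = 0) yield all statistics equal to 0 by convention so that replicate
averages are always defined over exactly r values.

Only unfolded-SFS statistics are used; haplotype and LD statistics are
deliberately excluded (they are hard to obtain unbiasedly from many
sequencing designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coalescent import SNPMatrix

__all__ = [
    "UnfoldedSFS",
    "SumStatVector",
    "SPECIES_STAT_NAMES",
    "STAT_COLUMNS",
    "unfolded_sfs",
    "sfs_statistics",
    "pairwise_manhattan_distance",
    "replicate_average",
]

#: the 8 per-species statistics, in canonical column order
SPECIES_STAT_NAMES = (
    "S", "theta_w", "pi", "tajimas_d", "fu_li_d", "fu_li_f", "theta_h", "h_prime",
)

#: all 17 statistic columns in canonical order: host 8, parasite 8, PMD
STAT_COLUMNS = tuple(
    [f"host_{s}" for s in SPECIES_STAT_NAMES]
    + [f"para_{s}" for s in SPECIES_STAT_NAMES]
    + ["pmd"]
)


@dataclass(frozen=True)
class UnfoldedSFS:
    """Counts ``xi[i-1]`` of sites with ``i`` derived copies, i = 1..n-1."""

    xi: np.ndarray
    n: int

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi)
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if xi.shape != (self.n - 1,):
            raise ValueError(f"xi must have length n-1 = {self.n - 1}")
        if np.any(xi < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def S(self) -> int:
        return int(np.sum(self.xi))


@dataclass(frozen=True)
class SumStatVector:
    """The 17 statistics of one replicate (or their average over replicates)."""

    host_S: float = 0.0
    host_theta_w: float = 0.0
    host_pi: float = 0.0
    host_tajimas_d: float = 0.0
    host_fu_li_d: float = 0.0
    host_fu_li_f: float = 0.0
    host_theta_h: float = 0.0
    host_h_prime: float = 0.0
    para_S: float = 0.0
    para_theta_w: float = 0.0
    para_pi: float = 0.0
    para_tajimas_d: float = 0.0
    para_fu_li_d: float = 0.0
    para_fu_li_f: float = 0.0
    para_theta_h: float = 0.0
    para_h_prime: float = 0.0
    pmd: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in STAT_COLUMNS], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "SumStatVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(STAT_COLUMNS),):
            raise ValueError(f"expected {len(STAT_COLUMNS)} values")
        return cls(**dict(zip(STAT_COLUMNS, values)))

    @classmethod
    def from_species(cls, host: dict, parasite: dict, pmd: float) -> "SumStatVector":
        kw = {f"host_{k}": v for k, v in host.items()}
        kw.update({f"para_{k}": v for k, v in parasite.items()})
        kw["pmd"] = pmd
        return cls(**kw)


def unfolded_sfs(data: SNPMatrix) -> UnfoldedSFS:
    """Tally the unfolded SFS of a polarized SNP matrix.

    ``xi_i`` counts the columns with exactly ``i`` derived alleles; fixed
    columns cannot occur (rejected by :class:`SNPMatrix`).
    """
    n = data.n
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    xi = np.zeros(n - 1, dtype=np.int64)
    if data.S > 0:
        counts = data.matrix.sum(axis=0)
        binned = np.bincount(counts, minlength=n)
        xi[:] = binned[1:n]
    return UnfoldedSFS(xi=xi, n=n)


def _harmonics(n: int) -> tuple:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    return a1, a2


def sfs_statistics(sfs: UnfoldedSFS) -> dict:
    """The eight per-species statistics from one unfolded SFS.

    Estimators of the population mutation rate:

    * ``theta_w = S / a1`` (Watterson) with ``a1 = sum_{i<n} 1/i``;
    * ``pi = sum_i xi_i i (n - i) / C(n, 2)`` (Nei-Tajima pairwise diversity);
    * ``theta_h = sum_i xi_i i^2 / C(n, 2)`` (Fay-Wu, weighted toward
      high-frequency derived variants).

    Normalized contrasts: Tajima's D (pi vs theta_w, 1989 normalization),
    Fu & Li's unfolded D and F (singletons ``xi_1`` as the external-branch
    class, 1993 normalization with the Simonsen-corrected F variance), and
    Zeng et al.'s H' (pi vs theta_L, the normalized Fay-Wu H).  All eight
    are 0 when S = 0.
    """
    n = sfs.n
    xi = np.asarray(sfs.xi, dtype=float)
    S = float(sfs.S)
    zero = dict.fromkeys(SPECIES_STAT_NAMES, 0.0)
    if S == 0:
        return dict(zero)
    i = np.arange(1, n)
    a1, a2 = _harmonics(n)
    nC2 = n * (n - 1) / 2.0
    theta_w = S / a1
    pi = float(np.sum(xi * i * (n - i)) / nC2)
    theta_h = float(np.sum(xi * i**2) / nC2)
    theta_l = float(np.sum(xi * i) / (n - 1))
    xi1 = float(xi[0])

    # Tajima's D
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var_d = e1 * S + e2 * S * (S - 1)
    taj_d = (pi - theta_w) / np.sqrt(var_d) if var_d > 0 else 0.0

    # Fu & Li's D and F (unfolded; external branch mutations ~ singletons)
    if n == 2:
        cn = 1.0
    else:
        cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + a1**2 / (a2 + a1**2) * (cn - (n + 1) / (n - 1))
    u_d = a1 - 1.0 - v_d
    var_fld = u_d * S + v_d * S * S
    fu_li_d = (S - a1 * xi1) / np.sqrt(var_fld) if var_fld > 0 else 0.0

    an1 = a1 + 1.0 / n
    v_f = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a1**2 + a2)
    u_f = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / a1 - v_f
    var_flf = u_f * S + v_f * S * S
    fu_li_f = (pi - xi1) / np.sqrt(var_flf) if var_flf > 0 else 0.0

    # Zeng et al. normalized Fay-Wu H
    bn1 = a2 + 1.0 / n**2
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var_h = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n * n * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n * n - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    h_prime = (pi - theta_l) / np.sqrt(var_h) if var_h > 0 else 0.0

    return {
        "S": S,
        "theta_w": theta_w,
        "pi": pi,
        "tajimas_d": float(taj_d),
        "fu_li_d": float(fu_li_d),
        "fu_li_f": float(fu_li_f),
        "theta_h": theta_h,
        "h_prime": float(h_prime),
    }


def pairwise_manhattan_distance(sfs_host: UnfoldedSFS, sfs_parasite: UnfoldedSFS) -> float:
    """L1 distance between proportion-normalized host and parasite spectra.

    ``PMD = sum_i | xi_H,i / S_H - xi_P,i / S_P |``.  Proportions (rather
    than raw counts) keep the statistic comparable across population sizes
    and prevent it from degenerating into another theta estimator.  A
    species with S = 0 contributes a zero vector, so PMD lies in [0, 2] and
    equals 1 when exactly one species is monomorphic.
    """
    if sfs_host.n != sfs_parasite.n:
        raise ValueError("PMD requires equal sample sizes in both species")
    h = np.asarray(sfs_host.xi, dtype=float)
    p = np.asarray(sfs_parasite.xi, dtype=float)
    hp = h / sfs_host.S if sfs_host.S > 0 else np.zeros_like(h)
    pp = p / sfs_parasite.S if sfs_parasite.S > 0 else np.zeros_like(p)
    return float(np.abs(hp - pp).sum())


def statistics_from_matrices(host: SNPMatrix, parasite: SNPMatrix) -> SumStatVector:
    """All 17 statistics of one replicate from the two SNP matrices."""
    sfs_h = unfolded_sfs(host)
    sfs_p = unfolded_sfs(parasite)
    return SumStatVector.from_species(
        sfs_statistics(sfs_h),
        sfs_statistics(sfs_p),
        pairwise_manhattan_distance(sfs_h, sfs_p),
    )


def replicate_average(stats: Iterable[SumStatVector]) -> SumStatVector:
    """Elementwise mean of the 17 statistics across replicate histories.

    The averaged vector is one ABC datapoint; averaging over r replicates
    integrates out the drift-induced variability of the frequency path.
    """
    arrays = [s.to_array() for s in stats]
    if not arrays:
        raise ValueError("replicate_average requires at least one replicate")
    return SumStatVector.from_array(np.mean(arrays, axis=0))
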