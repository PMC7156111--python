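"""Deterministic gene-for-gene (GFG) host-parasite dynamics.

The model couples one bi-allelic host locus (resistant ``RES`` vs
susceptible ``res``) to one bi-allelic parasite locus (infective ``INF`` vs
non-infective ``ninf``) through a gene-for-gene infection matrix: ``INF``
parasites infect every host, ``ninf`` parasites infect only susceptible
hosts.  A host generation contains two parasite infection cycles
(auto-infection: the second cycle re-infects the host attacked in the
first).  Infection in the first cycle costs the host ``s1 = s``; escaping
the first cycle but being infected in the second costs ``s2 = s/2``.
Carrying ``RES`` costs ``c_H`` (cost of resistance); carrying ``INF`` costs
``c_P`` (cost of infectivity).

This module is pure computation on frequencies: the one-generation
recursion, long-run iteration, the closed-form internal equilibrium, and
the classification of a simulated history into trench-warfare, arms-race or
degenerate dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Tuple

import numpy as np

from ._kernels import gfg_step, iterate_kernel

__all__ = [
    "GFGParams",
    "HostParasiteState",
    "EquilibriumPoint",
    "GFGDomainError",
    "step_deterministic",
    "iterate_to_equilibrium",
    "equilibrium_closed_form",
    "classify_dynamics",
]

#: default per-individual per-host-generation functional mutation rate
DEFAULT_FUNCTIONAL_MU = 1e-5


class GFGDomainError(ValueError):
    """Raised when a recursion denominator degenerates (all fitnesses zero)."""


def _check_freq(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0) or not np.isfinite(x):
        raise ValueError(f"{name} must be a frequency in [0, 1], got {x!r}")


@dataclass(frozen=True)
class GFGParams:
    """Selection costs and functional mutation rates of the GFG model.

    Parameters
    ----------
    s
        Cost of infection: host fitness loss when infected in the first
        infection cycle (``s1 = s``); second-cycle infection costs
        ``s2 = s/2``.
    c_H
        Cost of resistance (constitutive fitness penalty of ``RES``).
    c_P
        Cost of infectivity (constitutive fitness penalty of ``INF``).
    mu_Rtor, mu_rtoR
        Host functional mutation probabilities per individual per host
        generation (``RES``->``res`` loss, ``res``->``RES`` gain).
    mu_ntoI, mu_Iton
        Parasite functional mutation probabilities (``ninf``->``INF`` gain,
        ``INF``->``ninf`` loss).

    Coevolutionary cycling requires ``s > c_H``; parameter sets with
    ``s <= c_H`` are accepted (the susceptible host allele then fixes and
    the dynamics are degenerate).
    """

    s: float
    c_H: float
    c_P: float
    mu_Rtor: float = DEFAULT_FUNCTIONAL_MU
    mu_rtoR: float = DEFAULT_FUNCTIONAL_MU
    mu_ntoI: float = DEFAULT_FUNCTIONAL_MU
    mu_Iton: float = DEFAULT_FUNCTIONAL_MU

    def __post_init__(self) -> None:
        for name in ("s", "c_H", "c_P"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")
        for name in ("mu_Rtor", "mu_rtoR", "mu_ntoI", "mu_Iton"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v!r}")

    @property
    def s1(self) -> float:
        return self.s

    @property
    def s2(self) -> float:
        return self.s / 2.0


@dataclass(frozen=True)
class HostParasiteState:
    """Frequencies at the start of one host generation.

    ``R`` is the frequency of resistant hosts, ``a1`` the frequency of
    infective parasites in the first infection cycle and ``a2`` the derived
    within-generation frequency in the second cycle (``nan`` until a step
    has been taken).  Complements are implicit (``r = 1 - R``,
    ``A_t = 1 - a_t``).
    """

    R: float
    a1: float
    a2: float = float("nan")

    def __post_init__(self) -> None:
        _check_freq(self.R, "R")
        _check_freq(self.a1, "a1")
        if not np.isnan(self.a2):
            _check_freq(self.a2, "a2")


@dataclass(frozen=True)
class EquilibriumPoint:
    """Internal equilibrium (a_hat, R_hat); ``valid`` iff both in (0, 1)."""

    a_hat: float
    R_hat: float
    valid: bool


def step_deterministic(state: HostParasiteState, params: GFGParams) -> HostParasiteState:
    """Advance the deterministic recursion by one host generation.

    Computes the within-generation second-cycle parasite frequency ``a2``
    and returns the next-generation state ``(R', a1', a2)`` under infinite
    population size (no drift, no mutation).

    Raises
    ------
    GFGDomainError
        If a recursion denominator vanishes while its numerator does not
        (all-fitness-zero degeneracy; unreachable for ``s, c_H, c_P < 1``).
    """
    R, a1 = state.R, state.a1
    s1, s2, c_h, c_p = params.s1, params.s2, params.c_H, params.c_P
    A1, r = 1.0 - a1, 1.0 - R
    # explicit denominator guards before delegating to the fast kernel
    den_a = a1 * (1.0 - c_p) + A1 * r
    if den_a <= 1e-300 and a1 * (1.0 - c_p) > 0.0:
        raise GFGDomainError("second-cycle denominator degenerates")
    a2, a1n, Rn = gfg_step(R, a1, s1, s2, c_h, c_p)
    num_b = (1.0 - c_p) * (R * ((1.0 - a1) * a2 + a1) + r * a1)
    if num_b + r * A1 <= 1e-300 and num_b > 0.0:
        raise GFGDomainError("parasite mean fitness is zero")
    num_c = R * (1.0 - c_h) * (A1 * (1 - a2) + A1 * a2 * (1 - s2) + a1 * (1 - s1))
    if num_c + r * (1.0 - s1) <= 1e-300 and num_c > 0.0:
        raise GFGDomainError("host mean fitness is zero")
    return HostParasiteState(R=Rn, a1=a1n, a2=a2)


def iterate_to_equilibrium(
    params: GFGParams,
    R0: float,
    a0: float,
    g_max: int,
) -> List[HostParasiteState]:
    """Iterate the deterministic recursion for ``g_max`` host generations.

    Returns the trajectory of length ``g_max + 1`` including the initial
    state.  The long-run behaviour is either convergence to the internal
    equilibrium, sustained cycling around it (trench warfare), or escape to
    a boundary (arms race / degenerate loss).  Because cycles may persist,
    summarise the equilibrium as the mean over the trailing window (see
    :func:`terminal_mean`) rather than the final point.
    """
    if g_max < 1:
        raise ValueError("g_max must be >= 1")
    _check_freq(R0, "R0")
    _check_freq(a0, "a0")
    R_tr, a1_tr, a2_tr = iterate_kernel(
        int(g_max), params.s, params.c_H, params.c_P, float(R0), float(a0)
    )
    return [
        HostParasiteState(R=R_tr[g], a1=a1_tr[g], a2=a2_tr[g])
        for g in range(g_max + 1)
    ]


def terminal_mean(trajectory: List[HostParasiteState], frac: float = 0.1) -> Tuple[float, float]:
    """Mean (R, a1) over the trailing ``frac`` of a trajectory.

    The internal equilibrium is the centre of the coevolutionary cycles, so
    a trailing-window average is the right numerical summary; a pointwise
    terminal value would alias the cycle phase.
    """
    k = max(1, int(round(frac * len(trajectory))))
    tail = trajectory[-k:]
    return (
        float(np.mean([st.R for st in tail])),
        float(np.mean([st.a1 for st in tail])),
    )


def equilibrium_closed_form(params: GFGParams) -> EquilibriumPoint:
    """Closed-form internal equilibrium of the GFG recursion.

    With ``s1 = s`` and ``s2 = s/2``::

        a_hat = [s2 + s1 - sqrt((s2 + s1)^2 - 4 s2 (s1 - c_H))] / (2 s2 (1 - c_H))
        R_hat = c_P / (2 - c_P - a_hat)

    The two frequencies satisfy the identity ``R_hat * (2 - c_P - a_hat) =
    c_P`` exactly.  The expressions are an approximation to the true fixed
    point of the recursion (they drop O(c_P) terms in the host equation),
    accurate to a few percent in the trench-warfare regime.

    A negative discriminant, or an equilibrium outside (0, 1) in either
    coordinate, is reported with ``valid=False`` (no exception): without a
    resistance cost (``c_H = 0``) the radical collapses and ``a_hat = 1``,
    i.e. there is no interior equilibrium.
    """
    if params.s <= 0.0:
        raise ValueError("equilibrium requires s > 0")
    s1, s2, c_h, c_p = params.s1, params.s2, params.c_H, params.c_P
    disc = (s2 + s1) ** 2 - 4.0 * s2 * (s1 - c_h)
    if disc < 0.0:
        return EquilibriumPoint(a_hat=float("nan"), R_hat=float("nan"), valid=False)
    a_hat = (s2 + s1 - np.sqrt(disc)) / (2.0 * s2 * (1.0 - c_h))
    den = 2.0 - c_p - a_hat
    R_hat = c_p / den if abs(den) > 1e-300 else float("inf")
    valid = bool(0.0 < a_hat < 1.0 and 0.0 < R_hat < 1.0)
    return EquilibriumPoint(a_hat=float(a_hat), R_hat=float(R_hat), valid=valid)


DynamicsLabel = Literal["trench_warfare", "arms_race", "degenerate"]


def classify_dynamics(
    host_counts: np.ndarray,
    parasite_counts: np.ndarray,
    N_H: int,
    N_P: int,
) -> DynamicsLabel:
    """Classify a coevolutionary history from its two allele-count paths.

    * ``trench_warfare`` -- both species still segregate for their
      functional allele at the final generation (balancing-selection
      regime).
    * ``arms_race`` -- at least one species is fixed or lost at the end and
      at least one derived allele swept to fixation at some point during
      the history (recurrent selective sweeps).
    * ``degenerate`` -- polymorphism was never established: alleles were
      lost without any completed sweep (e.g. ``s < c_H``, where the
      susceptible host allele fixes immediately).

    Deterministic trajectories may be classified by passing frequencies
    scaled to counts; fixation then means frequency < 1/(2N) or
    > 1 - 1/(2N), which makes the label identical for matched
    deterministic/stochastic runs.
    """
    hc = np.asarray(host_counts)
    pc = np.asarray(parasite_counts)
    if hc.size == 0 or pc.size == 0:
        raise ValueError("empty path")
    host_interior = 0 < hc[-1] < N_H
    para_interior = 0 < pc[-1] < N_P
    if host_interior and para_interior:
        return "trench_warfare"
    swept = bool(np.any(hc >= N_H) or np.any(pc >= N_P))
    return "arms_race" if swept else "degenerate"


def classify_deterministic(
    trajectory: List[HostParasiteState], N_H: int, N_P: int
) -> DynamicsLabel:
    """Classify a deterministic trajectory using 1/(2N) fixation bands."""
    R = np.array([st.R for st in trajectory])
    a = np.array([st.a1 for st in trajectory])
    to_counts = lambda f, N: np.where(
        f < 1.0 / (2 * N), 0, np.where(f > 1.0 - 1.0 / (2 * N), N, np.round(f * N))
    ).astype(np.int64)
    return classify_dynamics(to_counts(R, N_H), to_counts(a, N_P), N_H, N_P)
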