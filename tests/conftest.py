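"""Shared fixtures and independent oracles.

The Wright-Fisher genealogy oracle below is written independently of the
package's coalescent engine (per-generation numpy parent assignment with
label relabelling) and is used to check the conditioned coalescent
distributionally on monomorphic paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from gfgcoal import GFGParams


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def neutral_mu_params():
    """GFG parameters with all functional mutation switched off."""
    return GFGParams(s=0.5, c_H=0.05, c_P=0.1,
                     mu_Rtor=0.0, mu_rtoR=0.0, mu_ntoI=0.0, mu_Iton=0.0)


def wf_genealogy_oracle(n: int, N: int, rng: np.random.Generator):
    """Plain haploid Wright-Fisher genealogy, one generation at a time.

    Tracks the partition of the sample into surviving ancestral lineages by
    relabelling: each generation every lineage draws a uniform parent among
    the N individuals; lineages drawing the same parent merge.  Returns
    (tmrca, total_branch_length) in generations.
    """
    k = n
    total = 0.0
    t = 0
    while k > 1:
        t += 1
        total += k
        parents = rng.integers(0, N, size=k)
        k = len(np.unique(parents))
    return float(t), float(total)


def random_snp_matrix(n: int, S: int, rng: np.random.Generator):
    """Random polarized matrix with no invariant columns."""
    from gfgcoal import SNPMatrix

    m = np.zeros((n, S), dtype=np.int8)
    for j in range(S):
        k = int(rng.integers(1, n))  # derived count in 1..n-1
        rows = rng.choice(n, size=k, replace=False)
        m[rows, j] = 1
    pos = np.sort(rng.random(S))
    return SNPMatrix(matrix=m, positions=pos, species="host")
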