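"""Shared oracles and tiny designs used by several test modules."""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import binom

from seqelim.design_core import DesignSpec, PairwiseBoundary

# enumerable two-arm toy design: 2 patients/arm/interim, 2 interims,
# stop at interim 1 when |Z| reaches 1 (upper inclusive at Z=1, lower
# just below -1)
TOY_BOUNDARY = PairwiseBoundary(1.0, 0.0, 0.001, symmetric=False)
TOY_DESIGN = DesignSpec(
    name="toy_two_arm", n_arms=2, boundary=TOY_BOUNDARY,
    per_arm_increment=2, max_total_n=100, max_interims=2,
)


def _continues(s1: int, s2: int, n: int, rule: PairwiseBoundary) -> bool:
    """Strict interior of the one-sided continuation region at equal n/arm."""
    tot = s1 + s2
    z = (s1 - s2) * n / (2 * n)
    v = n * n * tot * (2 * n - tot) / (2 * n) ** 3
    return (-rule.a + rule.b_inner * v) < z < (rule.a + rule.b_outer * v)


def forward_conditional_first_interim(s_terminal: tuple, p: float,
                                      n_per_interim: int = 2) -> dict:
    """Exact conditional law of first-interim successes in the toy design.

    Enumerates every forward path of the two-interim toy trial —
    first-interim successes and second-interim increments drawn
    Binomial(n, p) per arm — keeps the paths that continue at interim 1
    and land on the given terminal success counts, and returns the
    normalized distribution of (S_11, S_21).  This is the ground truth
    the hypergeometric back-sampling plus consistency filtering must
    reproduce; by sufficiency it must not depend on ``p``.
    """
    n = n_per_interim
    t1, t2 = s_terminal
    probs: dict = {}
    for s1, s2 in itertools.product(range(n + 1), repeat=2):
        d1, d2 = t1 - s1, t2 - s2
        if not (0 <= d1 <= n and 0 <= d2 <= n):
            continue
        if not _continues(s1, s2, n, TOY_BOUNDARY):
            continue
        w = (binom.pmf(s1, n, p) * binom.pmf(d1, n, p)
             * binom.pmf(s2, n, p) * binom.pmf(d2, n, p))
        probs[(s1, s2)] = probs.get((s1, s2), 0.0) + w
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def normal_path_mc(lower, upper, v, z_n, delta_z, t, n_paths, seed):
    """Forward Monte Carlo of the normal-increment group-sequential model.

    Returns the fraction of paths that stay strictly inside the
    continuation regions (the first shifted by ``t``) at interims
    1..n-1 and land within ``delta_z`` of ``z_n`` at interim n.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    n = len(v)
    z = rng.normal(0.0, np.sqrt(v[0]), n_paths)
    keep = (z > lower[0] + t) & (z < upper[0])
    for k in range(1, n):
        z = z + rng.normal(0.0, np.sqrt(v[k] - v[k - 1]), n_paths)
        if k < n - 1:
            keep &= (z > lower[k]) & (z < upper[k])
    keep &= np.abs(z - z_n) < delta_z
    return keep.mean(), keep.std(ddof=1) / np.sqrt(n_paths)
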