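"""Decision-rule geometry and interim test statistics.

A sequential elimination trial compares treatment arms with binary
(success/failure) outcomes.  At each interim analysis every pair of
remaining arms (i, j) is summarised by the efficient score ``Z`` and
Fisher information ``V`` for the log-odds ratio theta_ij::

    Z = (n_j S_i - n_i S_j) / (n_i + n_j)
    V = n_i n_j (S_i + S_j)(n_i + n_j - S_i - S_j) / (n_i + n_j)^3

where ``n`` and ``S`` are cumulative patient and success counts.  Under
small theta, E(Z) ~ theta V and var(Z) ~ V, so the pair (Z, V) supports
a straight-line stopping rule in the (V, Z) plane: a triangular (or
double-triangular) continuation region whose edges are the elimination
and no-difference boundaries.

In a stratified trial the statistics are computed within each stratum
and summed over strata.

This module provides the statistic computations, the boundary rules and
their classification of a (Z, V) point, and small pieces of design
arithmetic (boundary intersections, implied per-interim sample sizes).
All numeric kernels accept scalars or numpy arrays so that the Monte
Carlo modules can broadcast over replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "I_BETTER",
    "J_BETTER",
    "J_NO_BETTER",
    "NO_DIFFERENCE",
    "CONTINUE",
    "PairwiseBoundary",
    "DesignSpec",
    "PairStats",
    "pair_statistics",
    "adjusted_information",
    "classify_pair",
    "boundary_geometry",
    "implied_sample_increment",
    "stratum_scores",
    "get_design",
    "PRESETS",
]

# decision labels
I_BETTER = "i_better"
J_BETTER = "j_better"
J_NO_BETTER = "j_no_better"  # one-sided lower boundary: "i no better than j"
NO_DIFFERENCE = "no_difference"
CONTINUE = "continue"


@dataclass(frozen=True)
class PairwiseBoundary:
    """Straight-line stopping boundaries for one treatment pair.

    Parameters
    ----------
    a : float
        Intercept of the boundaries; must be positive.
    b_outer : float
        Slope of the elimination (outer) boundaries.
    b_inner : float
        Slope of the inner (no-difference / futility) boundaries; must
        exceed ``b_outer`` so that the boundaries eventually meet.
    symmetric : bool
        ``True`` for the double-triangular pairwise rule used in the
        multi-arm designs: eliminate j if Z >= a + b_outer*V, eliminate
        i if Z <= -(a + b_outer*V), declare no difference if Z lies in
        the open interval (-(b_inner*V - a), b_inner*V - a), which is
        nonempty only once V > a/b_inner.  ``False`` for the one-sided
        two-arm triangular test: conclude "i better" if
        Z >= a + b_outer*V and "i no better" if Z <= -a + b_inner*V.
    """

    a: float
    b_outer: float
    b_inner: float
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("boundary intercept a must be positive")
        if not self.b_inner > self.b_outer >= 0:
            raise ValueError("require b_inner > b_outer >= 0")

    # boundary lines ---------------------------------------------------
    def upper(self, v):
        """Upper elimination boundary u(V) = a + b_outer*V."""
        return self.a + self.b_outer * np.asarray(v, dtype=float)

    def lower(self, v):
        """Lower stopping boundary.

        For the symmetric rule this is the mirror elimination line
        -(a + b_outer*V); for the one-sided rule it is the "no better"
        line -a + b_inner*V.
        """
        v = np.asarray(v, dtype=float)
        if self.symmetric:
            return -(self.a + self.b_outer * v)
        return -self.a + self.b_inner * v

    def nodiff_halfwidth(self, v):
        """Half-width of the symmetric no-difference interval, b_inner*V - a.

        Negative values mean the interval is empty at that information.
        """
        return self.b_inner * np.asarray(v, dtype=float) - self.a


@dataclass(frozen=True)
class DesignSpec:
    """Full configuration of a sequential elimination design."""

    name: str
    n_arms: int
    boundary: PairwiseBoundary
    per_arm_increment: int
    max_total_n: int
    max_interims: int
    n_strata: int = 1
    nominal_v_increment: Optional[float] = None
    planned_interims: Optional[int] = None  # two-arm: 20, extendable to max_interims

    def __post_init__(self) -> None:
        if self.per_arm_increment < 1:
            raise ValueError("per_arm_increment must be >= 1")
        if self.max_total_n < self.n_arms * self.per_arm_increment:
            raise ValueError("max_total_n too small for a first interim analysis")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")

    def with_strata(self, n_strata: int) -> "DesignSpec":
        return DesignSpec(
            name=self.name,
            n_arms=self.n_arms,
            boundary=self.boundary,
            per_arm_increment=self.per_arm_increment,
            max_total_n=self.max_total_n,
            max_interims=self.max_interims,
            n_strata=n_strata,
            nominal_v_increment=self.nominal_v_increment,
            planned_interims=self.planned_interims,
        )


@dataclass
class PairStats:
    """Efficient score and information for one pair, per stratum and totalled."""

    i: int
    j: int
    z: float
    v: float
    z_c: np.ndarray
    v_c: np.ndarray
    v_prime_c: Optional[np.ndarray] = None
    interim: Optional[int] = None

    @property
    def v_prime(self) -> float:
        if self.v_prime_c is None:
            raise ValueError("adjusted information not computed for this pair")
        return float(np.sum(self.v_prime_c))


def stratum_scores(n_i, s_i, n_j, s_j):
    """Per-stratum (Z, V), broadcasting over array inputs.

    Strata with no patients on either arm contribute (0, 0).
    """
    n_i = np.asarray(n_i, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    n = n_i + n_j
    s = s_i + s_j
    denom = np.where(n > 0, n, 1.0)
    z = (n_j * s_i - n_i * s_j) / denom
    v = n_i * n_j * s * (n - s) / denom**3
    z = np.where(n > 0, z, 0.0)
    v = np.where(n > 0, v, 0.0)
    return z, v


def _as_counts(counts) -> tuple[np.ndarray, np.ndarray]:
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    if arr.shape[-1] != 2:
        raise ValueError("counts must be (n, S) pairs, one per stratum")
    n, s = arr[:, 0], arr[:, 1]
    if np.any(n < 0) or np.any(s < 0):
        raise ValueError("negative counts")
    if np.any(s > n):
        raise ValueError("successes exceed sample size in some stratum")
    return n, s


def pair_statistics(counts_i, counts_j, pair=(1, 2), interim=None,
                    adjusted: bool = False) -> PairStats:
    """Compute Z and V for a pair from per-stratum (n, S) counts.

    Parameters
    ----------
    counts_i, counts_j : sequence of (n, S)
        Cumulative patient and success counts per stratum for each arm.
    adjusted : bool
        Also compute the small-sample adjusted information V' per
        stratum (see :func:`adjusted_information`).
    """
    n_i, s_i = _as_counts(counts_i)
    n_j, s_j = _as_counts(counts_j)
    if n_i.shape != n_j.shape:
        raise ValueError("arms must share the stratification")
    if not np.any(n_i + n_j > 0):
        raise ValueError("no patients in any stratum")
    z_c, v_c = stratum_scores(n_i, s_i, n_j, s_j)
    v_prime_c = None
    if adjusted:
        v_prime_c = _v_prime(n_i, s_i, n_j, s_j)
    return PairStats(
        i=pair[0], j=pair[1],
        z=float(np.sum(z_c)), v=float(np.sum(v_c)),
        z_c=z_c, v_c=v_c, v_prime_c=v_prime_c, interim=interim,
    )


def _v_prime(n_i, s_i, n_j, s_j) -> np.ndarray:
    n = n_i + n_j
    s = s_i + s_j
    denom = np.where(n > 1, n * n * (n - 1), 1.0)
    vp = n_i * n_j * s * (n - s) / denom
    # a stratum with 0 or 1 patients carries no usable information
    return np.where(n > 1, vp, 0.0)


def adjusted_information(counts_i, counts_j) -> tuple[np.ndarray, float]:
    """Small-sample adjusted information V' per stratum and its total.

    V'_c = n_i n_j S (n - S) / (n^2 (n - 1)) with n = n_i + n_j and
    S = S_i + S_j pooled within the stratum; identically V' = V * n/(n-1).
    The adjustment matters when within-stratum samples are small, as at a
    first interim analysis of a stratified trial: E(Z) is closer to
    theta*V' than to theta*V and var(Z) closer to V', which keeps the
    Rao-Blackwell standard errors well defined.  Strata with fewer than
    two patients contribute zero.
    """
    n_i, s_i = _as_counts(counts_i)
    n_j, s_j = _as_counts(counts_j)
    vp = _v_prime(n_i, s_i, n_j, s_j)
    return vp, float(np.sum(vp))


def classify_pair(stats, rule: PairwiseBoundary) -> str:
    """Classify a pair's total (Z, V) against the boundary rule.

    Accepts a :class:`PairStats` or a (z, v) tuple.  Elimination
    comparisons are inclusive (>= / <=); the no-difference interval is
    open and only checked when nonempty (V > a/b_inner).  A point with
    V = 0 carries no information and yields ``continue``.  When, past
    the meeting point of a one-sided rule, both conditions hold, the
    upper (efficacy) boundary takes precedence.
    """
    if isinstance(stats, PairStats):
        z, v = stats.z, stats.v
    else:
        z, v = stats
    if v < 0:
        raise ValueError("information V must be nonnegative")
    if v == 0:
        return CONTINUE
    if not rule.symmetric:
        if z >= rule.a + rule.b_outer * v:
            return I_BETTER
        if z <= -rule.a + rule.b_inner * v:
            return J_NO_BETTER
        return CONTINUE
    thr = rule.a + rule.b_outer * v
    if z >= thr:
        return I_BETTER
    if z <= -thr:
        return J_BETTER
    half = rule.b_inner * v - rule.a
    if half > 0 and -half < z < half:
        return NO_DIFFERENCE
    return CONTINUE


def boundary_geometry(rule: PairwiseBoundary) -> dict:
    """Characteristic information levels of a boundary rule.

    Returns a dict with ``v_meet`` — the information at which the
    elimination and inner boundaries intersect, 2a/(b_inner - b_outer)
    (the triangle apex of a one-sided rule) — and, for symmetric rules,
    ``v_nodiff_min`` = a/b_inner, the smallest information at which the
    no-difference interval is nonempty.
    """
    if rule.b_inner == rule.b_outer:
        raise ValueError("parallel boundaries never meet")
    out = {"v_meet": 2.0 * rule.a / (rule.b_inner - rule.b_outer)}
    if rule.symmetric:
        out["v_nodiff_min"] = rule.a / rule.b_inner
    return out


def implied_sample_increment(v_increment: float, p_i: float, p_j: float) -> float:
    """Patients per arm needed for an information increment ``v_increment``.

    For two equal arms of size n with success probabilities p_i, p_j,
    V ~ (n/2) pbar (1 - pbar) with pbar the average probability; invert
    for n.
    """
    if not (0 < p_i < 1 and 0 < p_j < 1):
        raise ValueError("success probabilities must lie strictly in (0, 1)")
    pbar = 0.5 * (p_i + p_j)
    return 2.0 * v_increment / (pbar * (1.0 - pbar))


# ---------------------------------------------------------------------------
# design presets

def _make_presets() -> dict:
    four_arm_sepsis = DesignSpec(
        name="four_arm_sepsis",
        n_arms=4,
        boundary=PairwiseBoundary(10.90266, 0.12380, 0.37140, symmetric=True),
        per_arm_increment=36,
        max_total_n=2772,
        max_interims=40,
        n_strata=1,
        nominal_v_increment=4.40337,
    )
    two_arm_tri = DesignSpec(
        name="two_arm_tri",
        n_arms=2,
        boundary=PairwiseBoundary(10.93898, 0.123134, 0.369402, symmetric=False),
        per_arm_increment=36,
        max_total_n=25 * 72,
        max_interims=25,
        planned_interims=20,
        n_strata=1,
        nominal_v_increment=4.4419,
    )
    four_arm_simple = DesignSpec(
        name="four_arm_simple",
        n_arms=4,
        boundary=PairwiseBoundary(4.9261, 0.2470, 0.7411, symmetric=True),
        per_arm_increment=32,
        max_total_n=640,
        max_interims=8,
        n_strata=1,
        nominal_v_increment=None,
    )
    return {d.name: d for d in (four_arm_sepsis, two_arm_tri, four_arm_simple)}


PRESETS: dict = _make_presets()


def get_design(name: str, n_strata: Optional[int] = None) -> DesignSpec:
    """Look up a named design preset, optionally re-stratified."""
    try:
        design = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown design preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if n_strata is not None and n_strata != design.n_strata:
        design = design.with_strata(n_strata)
    return design
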