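"""Reverse-simulation Rao-Blackwellization (RB2).

The estimate ``theta_hat_1 = Z_1/V_1`` from the first interim analysis
is unbiased for the log-odds ratio because no stopping rule has yet
acted.  Its conditional expectation given the terminal sufficient
statistics (the final per-arm, per-stratum patient and success counts)
is therefore also unbiased, with smaller variance.  That conditional
expectation is computed by Monte Carlo:

1.  *Back-sampling.*  Working backwards from each arm's final ("anchor")
    counts, the cumulative successes at interim k are drawn as a
    hypergeometric variable — the number of successes among n_k
    responses drawn without replacement from the n_{k+1} responses of
    which S_{k+1} were successes — independently per arm and stratum,
    down to the first interim analysis.  Arms eliminated earlier are
    anchored at their own last interim.

2.  *Consistency filtering.*  A back-filled path is kept only if it is
    consistent with the trial having run as observed: at every earlier
    interim, for every pair of arms then remaining, the replicate must
    not produce an elimination that did not happen, must reproduce the
    eliminations that did happen, and must not make the whole remaining
    set stop for no difference.  For the two-arm triangular test this
    reduces to (Z_k, V_k) lying strictly inside the continuation region
    for every k before the stopping analysis.

3.  *Moments.*  Over the consistent replicates, the mean of
    theta_hat_1 gives the Rao-Blackwellized estimate theta_tilde and
    the variance gives var(theta_hat_1 | data).  The standard error is

        SE(theta_tilde) = sqrt( E[1/V_1] - var(theta_hat_1 | data) )

    where E[1/V_1] is the mean reciprocal first-interim information
    over the same replicates (it estimates var(theta_hat_1) = 1/V_1,
    which varies across replicates because V_1 depends on the simulated
    counts).  An approximate 95% interval is theta_tilde +/- 1.96 SE.

In the stratified case the per-stratum information entering the
estimate and SE is replaced by the small-sample adjusted V' = V n/(n-1)
(see :func:`seqelim.design_core.adjusted_information`); consistency
checks always use the plain V, as during the conduct of the trial.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design_core import (
    CONTINUE,
    I_BETTER,
    J_BETTER,
    DesignSpec,
    PairwiseBoundary,
    stratum_scores,
)
from .estimators import RBEstimate, Z_CRIT
from .trial_engine import TrialHistory

__all__ = [
    "ReverseStartSpec",
    "ReplicateBatch",
    "reverse_start",
    "two_arm_start",
    "reverse_fill",
    "is_consistent",
    "rb2_estimate",
]

DEFAULT_MIN_COMPLETE = 1000


@dataclass
class ReverseStartSpec:
    """Everything a reverse simulation needs.

    Arrays are indexed [arm, stratum, interim] with 0-based axes for
    1-based arms/interims.  ``n_sched`` holds the observed cumulative
    sample sizes (the patient accrual is fixed; only successes are
    back-sampled); entries beyond an arm's anchor repeat the anchor
    value and are never used.  ``conclusions`` maps (interim, i, j)
    with i < j to the real trial's non-continue decision at that
    interim, which the filter must reproduce.
    """

    design: DesignSpec
    anchors: np.ndarray          # (A,) anchor interim per arm
    n_sched: np.ndarray          # (A, C, K_check) cumulative n
    s_anchor: np.ndarray         # (A, C) observed successes at anchor
    last_interim: np.ndarray     # (A,) real final interim per arm
    conclusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_sched, axis=2) < 0):
            raise ValueError("cumulative sample sizes must be nondecreasing")
        n_at_anchor = np.take_along_axis(
            self.n_sched, (self.anchors - 1)[:, None, None], axis=2)[:, :, 0]
        if np.any(self.s_anchor < 0) or np.any(self.s_anchor > n_at_anchor):
            raise ValueError("anchor successes outside [0, n]")

    @property
    def n_arms(self) -> int:
        return self.n_sched.shape[0]

    @property
    def n_strata(self) -> int:
        return self.n_sched.shape[1]

    @property
    def k_check(self) -> int:
        """The latest anchored interim; filtering checks interims 1..k_check-1."""
        return int(self.anchors.max())


@dataclass
class ReplicateBatch:
    """Back-filled cumulative success paths and their consistency mask."""

    s: np.ndarray        # (R, A, C, K_check) cumulative successes
    complete: np.ndarray  # (R,) bool


def reverse_start(history: TrialHistory, pair: Optional[tuple] = None,
                  option: int = 2) -> ReverseStartSpec:
    """Build a reverse-simulation start from a trial history.

    Under Option 2 with a target ``pair``, every arm is anchored at the
    earlier of (the pair's comparison interim, its own last interim) —
    the three-start scheme of the worked four-arm example.  Under
    Option 1 (or with no pair) each arm is anchored at its own last
    interim, so a single replicate set serves all comparisons.
    """
    A = history.design.n_arms
    C = history.design.n_strata
    last = np.array([history.arm(a).last_interim for a in range(1, A + 1)])
    if option == 2 and pair is not None:
        k0 = min(last[pair[0] - 1], last[pair[1] - 1])
    else:
        k0 = int(last.max())
    anchors = np.minimum(last, k0)
    kc = int(anchors.max())
    n_sched = np.zeros((A, C, kc), dtype=np.int64)
    s_anchor = np.zeros((A, C), dtype=np.int64)
    for a in range(1, A + 1):
        h = history.arm(a)
        ka = anchors[a - 1]
        n_sched[a - 1, :, :ka] = h.cum_n[:, :ka]
        n_sched[a - 1, :, ka:] = h.cum_n[:, ka - 1][:, None]
        s_anchor[a - 1] = h.cum_s[:, ka - 1]
    conclusions = {}
    for rec in history.decisions:
        if rec.decision != CONTINUE:
            conclusions[(rec.interim, rec.i, rec.j)] = rec.decision
    return ReverseStartSpec(
        design=history.design, anchors=anchors, n_sched=n_sched,
        s_anchor=s_anchor, last_interim=last, conclusions=conclusions,
    )


def two_arm_start(design: DesignSpec, k_stop: int, s1: int, s2: int,
                  per_arm: Optional[int] = None) -> ReverseStartSpec:
    """Start spec for a two-arm trial observed only through its terminal data.

    Assumes equal per-arm accrual of ``per_arm`` patients per interim
    (the design's increment by default), the situation of the published
    two-arm worked examples.
    """
    inc = per_arm if per_arm is not None else design.per_arm_increment
    sched = inc * np.arange(1, k_stop + 1, dtype=np.int64)
    n_sched = np.broadcast_to(sched, (2, 1, k_stop)).copy()
    return ReverseStartSpec(
        design=design,
        anchors=np.array([k_stop, k_stop]),
        n_sched=n_sched,
        s_anchor=np.array([[s1], [s2]], dtype=np.int64),
        last_interim=np.array([k_stop, k_stop]),
    )


def reverse_fill(spec: ReverseStartSpec, n_sims: int, rng) -> np.ndarray:
    """Hypergeometric back-sampling of success paths.

    Returns an (n_sims, A, C, k_check) array of cumulative successes.
    For each arm and stratum, working backwards from the anchor,
    S_k | S_{k+1} ~ Hypergeometric(population n_{k+1}, successes
    S_{k+1}, draw n_k).  Degenerate cases (all successes or all
    failures at k+1, or no accrual between interims) resolve
    deterministically, as the hypergeometric law dictates.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    A, C, kc = spec.n_sched.shape
    s = np.zeros((n_sims, A, C, kc), dtype=np.int64)
    for a in range(A):
        ka = int(spec.anchors[a])
        s[:, a, :, ka - 1:] = spec.s_anchor[a][None, :, None]
        for k in range(ka - 1, 0, -1):  # fill interim k given k+1 (1-based)
            for c in range(C):
                n_hi = int(spec.n_sched[a, c, k])
                n_lo = int(spec.n_sched[a, c, k - 1])
                s_hi = s[:, a, c, k]
                s[:, a, c, k - 1] = rng.hypergeometric(
                    s_hi, n_hi - s_hi, n_lo) if n_lo > 0 else 0
    return s


def _pair_totals(s: np.ndarray, spec: ReverseStartSpec, i: int, j: int,
                 k: int) -> tuple[np.ndarray, np.ndarray]:
    """Total (Z, V) for 1-based pair (i, j) at 1-based interim k, per replicate."""
    z_c, v_c = stratum_scores(
        spec.n_sched[i - 1, :, k - 1][None, :], s[:, i - 1, :, k - 1],
        spec.n_sched[j - 1, :, k - 1][None, :], s[:, j - 1, :, k - 1],
    )
    return z_c.sum(axis=1), v_c.sum(axis=1)


def is_consistent(s: np.ndarray, spec: ReverseStartSpec) -> np.ndarray:
    """Boolean mask of replicates consistent with the observed trial.

    Checks every interim k = 1 .. k_check - 1.  For each pair (i, j) of
    arms still remaining at k in the real trial:

    * k final for both arms: the data are the observed data and the
      real conclusions follow automatically — no constraint;
    * k final for exactly one arm (it was eliminated then): if the real
      trial found the other arm better at k, the replicate must
      reproduce that conclusion; if the arm fell to a third arm, the
      replicate must find neither arm better;
    * k final for neither: the replicate must find neither arm better.

    In addition a replicate in which every pair among the remaining
    arms is declared no different at k (a whole-set stop that did not
    happen) is deleted.  For the one-sided two-arm rule the constraint
    is strict interiority of (Z_k, V_k) in the continuation region,
    the boundaries being inclusive stopping sets.
    """
    R = s.shape[0]
    ok = np.ones(R, dtype=bool)
    rule = spec.design.boundary
    last = spec.last_interim
    for k in range(1, spec.k_check):
        remaining = [a for a in range(1, spec.n_arms + 1) if last[a - 1] >= k]
        if len(remaining) < 2:
            continue
        nodiff_all = np.ones(R, dtype=bool)
        for i, j in itertools.combinations(remaining, 2):
            z, v = _pair_totals(s, spec, i, j, k)
            if not rule.symmetric:
                # two-arm triangular test: strictly inside continuation region
                ok &= (z < rule.a + rule.b_outer * v) & \
                      (z > -rule.a + rule.b_inner * v)
                nodiff_all[:] = False
                continue
            thr = rule.a + rule.b_outer * v
            i_beats = z >= thr
            j_beats = z <= -thr
            half = rule.b_inner * v - rule.a
            nodiff_all &= (half > 0) & (np.abs(z) < half)
            li, lj = last[i - 1] == k, last[j - 1] == k
            if li and lj:
                continue  # observed data, conclusions as in the real trial
            if li or lj:
                real = spec.conclusions.get((k, i, j), CONTINUE)
                if real == I_BETTER:
                    ok &= i_beats
                elif real == J_BETTER:
                    ok &= j_beats
                else:  # eliminated by a third arm: this pair stayed open
                    ok &= ~(i_beats | j_beats)
            else:
                ok &= ~(i_beats | j_beats)
        ok &= ~nodiff_all
    return ok


def _first_interim_theta(s: np.ndarray, spec: ReverseStartSpec, pair: tuple,
                         stratified: bool):
    """Per-replicate first-interim theta_hat_1 and information.

    Returns (theta1, v1, valid) where ``v1`` is the (possibly adjusted)
    total first-interim information and ``valid`` flags replicates with
    positive information.
    """
    i, j = pair
    n_i = spec.n_sched[i - 1, :, 0].astype(float)
    n_j = spec.n_sched[j - 1, :, 0].astype(float)
    s_i = s[:, i - 1, :, 0]
    s_j = s[:, j - 1, :, 0]
    z_c, v_c = stratum_scores(n_i[None, :], s_i, n_j[None, :], s_j)
    if stratified:
        n = n_i + n_j
        factor = np.where(n > 1, n / np.maximum(n - 1, 1), 0.0)
        v_c = v_c * factor[None, :]
    z1 = z_c.sum(axis=1)
    v1 = v_c.sum(axis=1)
    valid = v1 > 0
    theta1 = np.where(valid, z1 / np.where(valid, v1, 1.0), np.nan)
    return theta1, v1, valid


def rb2_estimate(spec: ReverseStartSpec, pairs: Sequence[tuple],
                 n_sims: int, rng, stratified: Optional[bool] = None,
                 min_complete: int = DEFAULT_MIN_COMPLETE,
                 chunk_size: int = 250_000) -> dict:
    """RB2 estimates for the requested pairs from one reverse-simulation run.

    Parameters
    ----------
    spec : ReverseStartSpec
    pairs : sequence of (i, j)
        Pairs to estimate; all share the replicate set and its filter.
    n_sims : int
        Total reverse simulations, generated in chunks of
        ``chunk_size`` to bound memory.
    rng : seed or Generator
    stratified : bool, optional
        Use the adjusted information V' in the estimate and SE
        (defaults to ``True`` whenever the design has more than one
        stratum).  Consistency filtering always uses the plain V.
    min_complete : int
        Below this many consistent replicates the estimate is flagged
        unreliable.

    Returns
    -------
    dict mapping each pair to an :class:`~seqelim.estimators.RBEstimate`.
    """
    rng = np.random.default_rng(rng)
    if stratified is None:
        stratified = spec.n_strata > 1
    pairs = [tuple(p) for p in pairs]
    acc = {p: {"n": 0, "sum": 0.0, "sumsq": 0.0, "sum_inv_v": 0.0}
           for p in pairs}
    arm_num = np.zeros(spec.n_arms)
    arm_den = np.zeros(spec.n_arms)
    n_done = 0
    n_complete = 0
    while n_done < n_sims:
        m = min(chunk_size, n_sims - n_done)
        s = reverse_fill(spec, m, rng)
        mask = is_consistent(s, spec)
        n_done += m
        n_complete += int(mask.sum())
        if not mask.any():
            continue
        sc = s[mask]
        for p in pairs:
            theta1, v1, valid = _first_interim_theta(sc, spec, p, stratified)
            a = acc[p]
            a["n"] += int(valid.sum())
            a["sum"] += float(theta1[valid].sum())
            a["sumsq"] += float((theta1[valid] ** 2).sum())
            a["sum_inv_v"] += float((1.0 / v1[valid]).sum())
        # unbiased success-probability estimates from interim 1
        n1 = spec.n_sched[:, :, 0].sum(axis=1).astype(float)  # (A,)
        s1 = sc[:, :, :, 0].sum(axis=2)                       # (R, A)
        arm_num += s1.sum(axis=0)
        arm_den += n1 * sc.shape[0]

    results = {}
    prop = n_complete / n_sims
    p_hat = {a + 1: (arm_num[a] / arm_den[a]) if arm_den[a] > 0 else np.nan
             for a in range(spec.n_arms)}
    for p in pairs:
        a = acc[p]
        n = a["n"]
        if n == 0:
            raise RuntimeError(
                f"no consistent reverse simulations for pair {p}; "
                f"increase n_sims")
        mean = a["sum"] / n
        var = max(a["sumsq"] / n - mean**2, 0.0)
        if n > 1:  # unbiased sample variance
            var *= n / (n - 1)
        mean_inv_v = a["sum_inv_v"] / n
        radicand = mean_inv_v - var
        if radicand >= 0:
            se = float(np.sqrt(radicand))
            ci_lo, ci_hi = mean - Z_CRIT * se, mean + Z_CRIT * se
        else:
            se = ci_lo = ci_hi = None
        results[p] = RBEstimate(
            theta_tilde=mean, se=se, ci_lo=ci_lo, ci_hi=ci_hi,
            n_sims=n_sims, n_complete=n_complete, prop_complete=prop,
            mean_inv_v1=mean_inv_v, var_theta1=var, p_hat=p_hat,
            reliable=n_complete >= min_complete, method="rb2",
        )
    return results
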