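"""Forward simulation of sequential elimination trials.

The engine simulates the accrual of binary outcomes between interim
analyses and applies the pairwise boundary rules at each interim:

* every pair of remaining arms is classified on the same cumulative
  data; any arm found worse than any other remaining arm is eliminated
  (simultaneous evaluation, so an arm can be eliminated by an arm that
  is itself eliminated at the same interim);
* the trial stops with a sole winner when one arm remains, or with
  joint winners when every remaining pair is declared no different;
* the trial stops, unresolved, before an interim analysis that would
  push the total sample size over the cap, or past the maximum number
  of interim analyses.

The two-arm variant implements the one-sided triangular test: stop when
Z crosses the upper efficacy boundary or the lower "no better"
boundary, both inclusive, with interim analyses continuing past the 20
planned up to 25 if no boundary has been reached.

Histories record, per arm and stratum, the cumulative sample sizes and
success counts at every interim at which the arm was present, plus the
full log of non-continue pairwise decisions — everything the
reverse-simulation estimator needs.
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
    J_NO_BETTER,
    NO_DIFFERENCE,
    DesignSpec,
    classify_pair,
    stratum_scores,
)

__all__ = [
    "ArmHistory",
    "TrialOutcome",
    "TrialHistory",
    "DecisionRecord",
    "apply_interim",
    "simulate_multiarm_trial",
    "simulate_two_arm_trial",
]


@dataclass
class ArmHistory:
    """Cumulative counts for one arm over the interims it was present.

    ``cum_n`` and ``cum_s`` have shape (n_strata, last_interim); column
    k-1 holds the cumulative counts at interim k (1-based).
    """

    arm: int
    cum_n: np.ndarray
    cum_s: np.ndarray
    last_interim: int
    eliminated_by: Optional[int] = None
    elim_interim: Optional[int] = None

    def totals(self) -> tuple[int, int]:
        return int(self.cum_n[:, -1].sum()), int(self.cum_s[:, -1].sum())


@dataclass(frozen=True)
class DecisionRecord:
    interim: int
    i: int
    j: int
    decision: str


@dataclass(frozen=True)
class TrialOutcome:
    kind: str  # sole_winner | joint_winners | unresolved
    winners: tuple
    total_n: int
    stop_reason: str  # boundary | no_difference | cap_reached | max_interims
    boundary_crossed: Optional[int] = None  # two-arm: 1 upper, 0 lower


@dataclass
class TrialHistory:
    design: DesignSpec
    arms: list
    K: int
    outcome: TrialOutcome
    decisions: list = field(default_factory=list)

    def arm(self, a: int) -> ArmHistory:
        for h in self.arms:
            if h.arm == a:
                return h
        raise KeyError(f"arm {a} not in history")

    def conclusion(self, interim: int, i: int, j: int) -> str:
        """The recorded decision for pair (i, j) at an interim, oriented i-vs-j."""
        for rec in self.decisions:
            if rec.interim != interim:
                continue
            if (rec.i, rec.j) == (i, j):
                return rec.decision
            if (rec.i, rec.j) == (j, i):
                return {I_BETTER: J_BETTER, J_BETTER: I_BETTER}.get(
                    rec.decision, rec.decision)
        return CONTINUE


def apply_interim(counts: dict, design: DesignSpec, interim: int):
    """Classify all active pairs at one interim analysis.

    Parameters
    ----------
    counts : dict
        ``{arm: (n_c, s_c)}`` cumulative per-stratum counts for every
        active arm at this interim.
    design : DesignSpec
    interim : int

    Returns
    -------
    decisions : dict mapping (i, j), i < j, to a decision label
    eliminated : dict mapping eliminated arm to the arm that beat it
    stop : bool
    outcome_kind : str or None  ("sole_winner" / "joint_winners")
    """
    active = sorted(counts)
    if not active:
        raise RuntimeError("no active arms at interim analysis")
    rule = design.boundary
    decisions = {}
    margins = {}
    for i, j in itertools.combinations(active, 2):
        n_i, s_i = counts[i]
        n_j, s_j = counts[j]
        z_c, v_c = stratum_scores(n_i, s_i, n_j, s_j)
        z, v = float(np.sum(z_c)), float(np.sum(v_c))
        decisions[(i, j)] = classify_pair((z, v), rule)
        margins[(i, j)] = abs(z) - (rule.a + rule.b_outer * v)

    eliminated = {}
    for a in active:
        # arms that beat a, with the margin by which they crossed
        beaters = []
        for (i, j), d in decisions.items():
            if d == I_BETTER and j == a:
                beaters.append((margins[(i, j)], i))
            elif d == J_BETTER and i == a:
                beaters.append((margins[(i, j)], j))
        if beaters:
            eliminated[a] = max(beaters)[1]

    remaining = [a for a in active if a not in eliminated]
    if len(remaining) == 1:
        return decisions, eliminated, True, "sole_winner"
    if len(remaining) >= 2 and all(
        decisions[pair] == NO_DIFFERENCE
        for pair in itertools.combinations(remaining, 2)
    ):
        return decisions, eliminated, True, "joint_winners"
    return decisions, eliminated, False, None


def _norm_probs(p, n_arms: int, n_strata: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        if p.shape != (n_arms,):
            raise ValueError(f"expected {n_arms} success probabilities")
        p = np.repeat(p[:, None], n_strata, axis=1)
    elif p.shape != (n_arms, n_strata):
        raise ValueError("probabilities must be per arm or per arm x stratum")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    return p


def simulate_multiarm_trial(design: DesignSpec, p, rng) -> TrialHistory:
    """Simulate one run of the multi-arm elimination design.

    ``p`` is either one success probability per arm or an
    (n_arms, n_strata) array for a multi-centre trial; in the latter
    case each arm's per-interim patients are distributed among centres
    at random (multinomial with equal centre probabilities) and the
    interim statistics are stratified by centre.

    ``rng`` is a seed or a ``numpy.random.Generator``.  Stream order:
    at each interim, arms in index order; per arm, one multinomial
    centre allocation (if stratified) then binomial responses stratum
    by stratum.
    """
    rng = np.random.default_rng(rng)
    A, C = design.n_arms, design.n_strata
    p = _norm_probs(p, A, C)
    inc = design.per_arm_increment

    active = list(range(1, A + 1))
    cum_n = {a: [np.zeros(C, dtype=np.int64)] for a in active}
    cum_s = {a: [np.zeros(C, dtype=np.int64)] for a in active}
    elim: dict = {}
    log: list = []
    total_n = 0
    k = 0
    outcome = None
    while True:
        if k >= design.max_interims:
            outcome = TrialOutcome("unresolved", tuple(active), total_n,
                                   "max_interims")
            break
        if total_n + len(active) * inc > design.max_total_n:
            outcome = TrialOutcome("unresolved", tuple(active), total_n,
                                   "cap_reached")
            break
        k += 1
        for a in active:
            if C > 1:
                alloc = rng.multinomial(inc, np.full(C, 1.0 / C))
            else:
                alloc = np.array([inc], dtype=np.int64)
            succ = rng.binomial(alloc, p[a - 1])
            cum_n[a].append(cum_n[a][-1] + alloc)
            cum_s[a].append(cum_s[a][-1] + succ)
            total_n += inc
        counts = {a: (cum_n[a][-1], cum_s[a][-1]) for a in active}
        decisions, eliminated, stop, kind = apply_interim(counts, design, k)
        for pair, d in decisions.items():
            if d != CONTINUE:
                log.append(DecisionRecord(k, pair[0], pair[1], d))
        for a, by in eliminated.items():
            elim[a] = (k, by)
            active.remove(a)
        if stop:
            winners = tuple(active)
            reason = "boundary" if kind == "sole_winner" else "no_difference"
            outcome = TrialOutcome(kind, winners, total_n, reason)
            break

    arms = []
    for a in range(1, A + 1):
        last = elim[a][0] if a in elim else k
        arms.append(ArmHistory(
            arm=a,
            cum_n=np.stack(cum_n[a][1:last + 1], axis=1),
            cum_s=np.stack(cum_s[a][1:last + 1], axis=1),
            last_interim=last,
            eliminated_by=elim[a][1] if a in elim else None,
            elim_interim=elim[a][0] if a in elim else None,
        ))
    return TrialHistory(design=design, arms=arms, K=k, outcome=outcome,
                        decisions=log)


def simulate_two_arm_trial(design: DesignSpec, p1: float, p2: float,
                           rng) -> TrialHistory:
    """Simulate one run of the one-sided two-arm triangular test.

    Arm 1 is the experimental treatment, arm 2 the control.  Stops when
    the cumulative (Z, V) crosses the upper boundary (arm 1 better,
    ``boundary_crossed=1``) or the lower boundary (arm 1 no better,
    ``boundary_crossed=0``), both inclusive.  If no boundary is reached
    by ``max_interims`` the run is unresolved.
    """
    if design.n_arms != 2 or design.boundary.symmetric:
        raise ValueError("two-arm simulation requires a one-sided two-arm design")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    inc = design.per_arm_increment
    n1 = n2 = 0
    s1 = s2 = 0
    hist_n1, hist_s1, hist_n2, hist_s2 = [], [], [], []
    k = 0
    outcome = None
    while True:
        if k >= design.max_interims:
            outcome = TrialOutcome("unresolved", (1, 2), n1 + n2,
                                   "max_interims")
            break
        k += 1
        s1 += int(rng.binomial(inc, p1))
        s2 += int(rng.binomial(inc, p2))
        n1 += inc
        n2 += inc
        hist_n1.append(n1); hist_s1.append(s1)
        hist_n2.append(n2); hist_s2.append(s2)
        z_c, v_c = stratum_scores(n1, s1, n2, s2)
        z, v = float(z_c), float(v_c)
        d = classify_pair((z, v), design.boundary)
        if d == I_BETTER:
            outcome = TrialOutcome("sole_winner", (1,), n1 + n2, "boundary",
                                   boundary_crossed=1)
            break
        if d == J_NO_BETTER:
            outcome = TrialOutcome("joint_winners", (1, 2), n1 + n2,
                                   "boundary", boundary_crossed=0)
            break

    log = []
    if outcome.stop_reason == "boundary":
        label = I_BETTER if outcome.boundary_crossed == 1 else J_NO_BETTER
        log.append(DecisionRecord(k, 1, 2, label))
    arms = [
        ArmHistory(1, np.array(hist_n1, dtype=np.int64)[None, :],
                   np.array(hist_s1, dtype=np.int64)[None, :], k),
        ArmHistory(2, np.array(hist_n2, dtype=np.int64)[None, :],
                   np.array(hist_s2, dtype=np.int64)[None, :], k),
    ]
    return TrialHistory(design=design, arms=arms, K=k, outcome=outcome,
                        decisions=log)
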