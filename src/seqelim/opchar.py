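"""Monte Carlo operating characteristics and estimator evaluation.

Operating characteristics of a design under a scenario of true success
probabilities: expected total sample size, per-arm sole-winner and
elimination proportions, the proportion of runs ending in a specified
joint no-difference declaration, and the proportion left unresolved at
the sample-size cap.  Monte Carlo standard errors sqrt(p(1-p)/nreps)
accompany every proportion.

Estimator evaluation replays an estimator (naive, RB1 or RB2) over
replicated simulated trials and reports bias, spread, mean reported SE
and confidence-interval coverage per pairwise comparison.  RB2 analyses
whose reverse simulations yield fewer than a minimum number of
consistent replicates are excluded from the aggregates, and the
exclusion count is reported.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design_core import DesignSpec
from .estimators import naive_analysis
from .rb1 import RB1Config, rb1_estimate
from .rb2 import DEFAULT_MIN_COMPLETE, reverse_start, rb2_estimate
from .trial_engine import simulate_multiarm_trial, simulate_two_arm_trial

__all__ = [
    "OpChar",
    "EstimatorEvaluation",
    "operating_characteristics",
    "evaluate_estimators",
    "theta_pairs",
]


@dataclass
class OpChar:
    e_n: float
    win: dict
    elim: dict
    nod: float
    still: float
    nreps: int
    nod_set: tuple
    mc_se: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"E_n": self.e_n}
        row.update({f"win_{a}": p for a, p in self.win.items()})
        row.update({f"elim_{a}": p for a, p in self.elim.items()})
        row.update({"nod": self.nod, "still": self.still,
                    "nreps": self.nreps})
        return row


@dataclass
class EstimatorEvaluation:
    pair: tuple
    theta_true: float
    mean_estimate: float
    sd: float
    mean_se: float
    mean_ci_lo: float
    mean_ci_hi: float
    coverage: float
    nreps_used: int
    n_excluded: int
    n_unresolved: int
    method: str


def _mc_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def operating_characteristics(design: DesignSpec, p, nreps: int, rng,
                              nod_set: Optional[Sequence[int]] = None
                              ) -> OpChar:
    """Estimate a design's operating characteristics by simulation.

    ``nod_set`` names the joint no-difference event tallied as "nod":
    the run terminates with exactly that set declared joint winners.
    By default it is the set of arms sharing the best marginal success
    probability (averaged over strata), the event of interest in the
    scenario families of the published tables.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    rng = np.random.default_rng(rng)
    A = design.n_arms
    parr = np.asarray(p, dtype=float)
    marg = parr if parr.ndim == 1 else parr.mean(axis=1)
    if nod_set is None:
        best = marg.max()
        nod_set = tuple(a + 1 for a in range(A) if np.isclose(marg[a], best))
    nod_set = tuple(sorted(nod_set))

    total = 0.0
    win = np.zeros(A)
    elim = np.zeros(A)
    nod = 0
    still = 0
    for _ in range(nreps):
        h = simulate_multiarm_trial(design, p, rng)
        total += h.outcome.total_n
        if h.outcome.kind == "sole_winner":
            win[h.outcome.winners[0] - 1] += 1
        elif h.outcome.kind == "unresolved":
            still += 1
        if h.outcome.kind == "joint_winners" and \
                tuple(sorted(h.outcome.winners)) == nod_set:
            nod += 1
        for arm in h.arms:
            if arm.eliminated_by is not None:
                elim[arm.arm - 1] += 1

    win_p = {a + 1: win[a] / nreps for a in range(A)}
    elim_p = {a + 1: elim[a] / nreps for a in range(A)}
    nod_p = nod / nreps
    still_p = still / nreps
    mc = {f"win_{a}": _mc_se(v, nreps) for a, v in win_p.items()}
    mc.update({f"elim_{a}": _mc_se(v, nreps) for a, v in elim_p.items()})
    mc["nod"] = _mc_se(nod_p, nreps)
    mc["still"] = _mc_se(still_p, nreps)
    return OpChar(e_n=total / nreps, win=win_p, elim=elim_p, nod=nod_p,
                  still=still_p, nreps=nreps, nod_set=nod_set, mc_se=mc)


def theta_pairs(p) -> dict:
    """True log-odds ratios theta_ij for every ordered pair i < j."""
    parr = np.asarray(p, dtype=float)
    if parr.ndim > 1:
        parr = parr.mean(axis=1)
    logit = np.log(parr / (1.0 - parr))
    return {(i + 1, j + 1): float(logit[i] - logit[j])
            for i, j in itertools.combinations(range(len(parr)), 2)}


def evaluate_estimators(design: DesignSpec, p, method: str, nreps: int,
                        rng, n_reverse: int = 50_000,
                        min_complete: int = DEFAULT_MIN_COMPLETE,
                        option: int = 1,
                        rb1_config: RB1Config = RB1Config()) -> dict:
    """Sampling properties of an estimator over replicated trials.

    ``method`` is one of ``naive``, ``rb1``, ``rb2``.  For a two-arm
    design ``p`` is (p1, p2) and the single comparison (1, 2) is
    evaluated; for a multi-arm design all pairs are evaluated, with the
    comparison data chosen per ``option`` (RB2 always anchors each arm
    at its own last interim here — Option 1 — so one replicate set
    serves all pairs).

    Returns a dict mapping pairs to :class:`EstimatorEvaluation`.
    Unresolved runs, and (for RB2) runs with fewer than
    ``min_complete`` consistent reverse simulations or an undefined SE,
    are excluded from the aggregates and counted.
    """
    if method not in {"naive", "rb1", "rb2"}:
        raise ValueError(f"unknown method {method!r}")
    if method == "rb1" and design.n_arms != 2:
        raise ValueError("RB1 is defined for two-arm designs only")
    rng = np.random.default_rng(rng)
    truth = theta_pairs(p)
    two_arm = design.n_arms == 2
    pairs = [(1, 2)] if two_arm else sorted(truth)
    rec = {pr: {"est": [], "se": [], "lo": [], "hi": [], "cover": []}
           for pr in pairs}
    n_unresolved = 0
    n_excluded = 0
    for _ in range(nreps):
        if two_arm:
            h = simulate_two_arm_trial(design, p[0], p[1], rng)
        else:
            h = simulate_multiarm_trial(design, p, rng)
        if h.outcome.kind == "unresolved":
            n_unresolved += 1
            continue
        if method == "rb2":
            spec = reverse_start(h, option=1)
            try:
                ests = rb2_estimate(spec, pairs, n_reverse, rng,
                                    min_complete=min_complete)
            except RuntimeError:
                n_excluded += 1
                continue
            if any(not e.reliable or e.se is None for e in ests.values()):
                n_excluded += 1
                continue
            for pr in pairs:
                e = ests[pr]
                _push(rec[pr], e.theta_tilde, e.se, e.ci_lo, e.ci_hi,
                      truth[pr])
        elif method == "rb1":
            z_star, v_star = _terminal_zv(h)
            e = rb1_estimate(z_star, h.K, design, rb1_config,
                             v_terminal=v_star)
            if e.se is None:
                n_excluded += 1
                continue
            _push(rec[(1, 2)], e.theta_tilde, e.se, e.ci_lo, e.ci_hi,
                  truth[(1, 2)])
        else:
            for pr in pairs:
                est, _ = naive_analysis(h, pr, option=option)
                _push(rec[pr], est.theta_hat, est.se, est.ci_lo, est.ci_hi,
                      truth[pr])

    out = {}
    for pr in pairs:
        r = rec[pr]
        n = len(r["est"])
        if n == 0:
            raise RuntimeError("no usable replicates; increase nreps")
        est = np.array(r["est"])
        out[pr] = EstimatorEvaluation(
            pair=pr, theta_true=truth[pr],
            mean_estimate=float(est.mean()),
            sd=float(est.std(ddof=1)) if n > 1 else 0.0,
            mean_se=float(np.mean(r["se"])),
            mean_ci_lo=float(np.mean(r["lo"])),
            mean_ci_hi=float(np.mean(r["hi"])),
            coverage=float(np.mean(r["cover"])),
            nreps_used=n, n_excluded=n_excluded,
            n_unresolved=n_unresolved, method=method,
        )
    return out


def _push(r: dict, est, se, lo, hi, truth) -> None:
    r["est"].append(est)
    r["se"].append(se)
    r["lo"].append(lo)
    r["hi"].append(hi)
    r["cover"].append(1.0 if lo <= truth <= hi else 0.0)


def _terminal_zv(history) -> tuple[float, float]:
    h1, h2 = history.arm(1), history.arm(2)
    n1, s1 = h1.totals()
    n2, s2 = h2.totals()
    n, s = n1 + n2, s1 + s2
    z = (n2 * s1 - n1 * s2) / n
    v = n1 * n2 * s * (n - s) / n**3
    return z, v
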