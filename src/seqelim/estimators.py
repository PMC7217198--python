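"""Unadjusted (naive) post-trial estimation and shared estimate containers.

The naive analysis of a pair of arms takes the terminal score and
information (Z*, V*) and ignores the sequential design::

    theta_hat = Z*/V*,   SE = 1/sqrt(V*),   CI = theta_hat +/- 1.96 SE

This is biased after data-dependent stopping; it is the baseline the
Rao-Blackwellized estimators are compared against.

``select_comparison_data`` chooses which data enter a pairwise
comparison in a multi-arm trial:

* Option 1 — all data available on each arm (each arm at its own final
  interim), so one reverse-simulation run serves every comparison;
* Option 2 — only data from patients randomized while both arms were
  still in contention (both arms at the earlier of their two final
  interims), which protects against temporal trends.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design_core import pair_statistics, PairStats
from .trial_engine import TrialHistory

__all__ = [
    "NaiveEstimate",
    "RBEstimate",
    "naive_estimate",
    "select_comparison_data",
    "naive_analysis",
    "Z_CRIT",
]

# fixed 95% normal quantile used throughout the worked examples
Z_CRIT = 1.96


@dataclass(frozen=True)
class NaiveEstimate:
    theta_hat: float
    se: float
    ci_lo: float
    ci_hi: float
    z_star: float
    v_star: float


@dataclass
class RBEstimate:
    """Rao-Blackwellized estimate for one pairwise comparison.

    ``se`` is ``None`` when the variance decomposition produced a
    negative radicand (the conditional variance of the first-interim
    estimate exceeded its unconditional variance estimate); in that
    case the diagnostic pieces ``mean_inv_v1`` and ``var_theta1`` are
    still reported.
    """

    theta_tilde: float
    se: Optional[float]
    ci_lo: Optional[float]
    ci_hi: Optional[float]
    n_sims: int
    n_complete: int
    prop_complete: float
    mean_inv_v1: float
    var_theta1: float
    p_hat: Optional[dict] = None
    reliable: bool = True
    method: str = "rb2"


def naive_estimate(z_star: float, v_star: float, alpha_quantile: float = Z_CRIT
                   ) -> NaiveEstimate:
    """Naive log-odds-ratio estimate from terminal (Z*, V*)."""
    if not v_star > 0:
        raise ValueError("terminal information V* must be positive")
    theta = z_star / v_star
    se = 1.0 / np.sqrt(v_star)
    return NaiveEstimate(
        theta_hat=theta,
        se=se,
        ci_lo=theta - alpha_quantile * se,
        ci_hi=theta + alpha_quantile * se,
        z_star=z_star,
        v_star=v_star,
    )


def select_comparison_data(history: TrialHistory, pair: tuple, option: int = 2):
    """Terminal per-stratum counts for a pairwise comparison.

    Returns ``(counts_i, counts_j, interim)`` where the counts are
    (n_strata, 2) arrays of (n, S) and ``interim`` is the analysis the
    comparison is evaluated at (Option 2) or each arm's own last
    interim (Option 1, in which case ``interim`` is the later of the
    two).
    """
    i, j = pair
    hi, hj = history.arm(i), history.arm(j)
    if option == 2:
        k = min(hi.last_interim, hj.last_interim)
        ki = kj = k
    elif option == 1:
        ki, kj = hi.last_interim, hj.last_interim
        k = max(ki, kj)
    else:
        raise ValueError("option must be 1 or 2")
    counts_i = np.stack([hi.cum_n[:, ki - 1], hi.cum_s[:, ki - 1]], axis=1)
    counts_j = np.stack([hj.cum_n[:, kj - 1], hj.cum_s[:, kj - 1]], axis=1)
    return counts_i, counts_j, k


def naive_analysis(history: TrialHistory, pair: tuple, option: int = 2
                   ) -> tuple[NaiveEstimate, PairStats]:
    """Naive estimate for a pair of a trial history under Option 1 or 2."""
    counts_i, counts_j, k = select_comparison_data(history, pair, option)
    stats = pair_statistics(counts_i, counts_j, pair=pair, interim=k)
    return naive_estimate(stats.z, stats.v), stats
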