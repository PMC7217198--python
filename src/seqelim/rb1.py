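"""Analytic two-arm Rao-Blackwellization (RB1).

For a two-arm group-sequential test the conditional distribution of the
first-interim score Z_1 given the terminal statistics can be computed
by numerical integration rather than simulation.  Under the canonical
group-sequential model the score increments Z_k - Z_{k-1} are
independent N(theta * dV_k, dV_k); at theta = 0 they are mean-zero.

Let the continuation region at interim k be (l_k, u_k) and suppose the
trial stopped at interim n with Z_n = z_n.  Pinch the n-th continuation
region to the small interval (z_n - dz, z_n + dz) and define the
survivor ratio

    S(t) = P(reach the pinch | first region (l_1 + t, u_1))
           / P(reach the pinch | first region (l_1, u_1)),

for t in (0, u_1 - l_1).  Because the likelihood factor
exp(theta z_n - theta^2 V_n / 2) cancels in the ratio, S(t) can be
evaluated at theta = 0 yet equals P(Z_1 > l_1 + t | K = n, Z_n ~ z_n)
for every theta — which is exactly the statement that (K, Z_n) are
sufficient.  The conditional moments of Z_1 follow from

    E[Z_1 - l_1 | .]     = integral of S(t) dt,
    E[(Z_1 - l_1)^2 | .] = 2 * integral of t S(t) dt,

whence theta_tilde = E[Z_1 | .]/V_1, var(theta_hat_1 | .) =
var(Z_1 | .)/V_1^2 and the standard error
sqrt(1/V_1 - var(theta_hat_1 | .)).

The recursion needs an information value at every interim, but the
estimator is meant to depend only on the terminal statistics; by
default the realized terminal information V* is spread equally over
the interims performed, V_k = k V*/n.  (Using the design's nominal
schedule instead systematically understates the adjustment whenever
the realized information ran ahead of or behind plan, because the
boundaries sit at the wrong information levels relative to the data.)

The reach probabilities are computed by the standard recursion: the
(sub-)density of Z_k on its continuation interval is propagated through
the normal increment kernel on a uniform grid, with trapezoidal
quadrature.  The method does not extend to more than two arms (there is
no single scalar statistic to recurse over); that is what the
reverse-simulation estimator (RB2) is for.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .design_core import DesignSpec
from .estimators import RBEstimate, Z_CRIT

__all__ = [
    "RB1Config",
    "nominal_v_schedule",
    "boundary_schedule",
    "continuation_mass",
    "survivor_curve",
    "rb1_estimate",
]


@dataclass(frozen=True)
class RB1Config:
    """Numerical settings for the RB1 recursion.

    ``delta_z`` is the half-width of the pinched final continuation
    region (dimensionless, on the Z scale); ``t_grid_points`` the number
    of points at which the survivor ratio is evaluated beyond t = 0;
    ``z_grid_points`` the grid resolution per continuation interval in
    the density recursion.
    """

    delta_z: float = 0.01
    t_grid_points: int = 100
    z_grid_points: int = 400

    def __post_init__(self) -> None:
        if not self.delta_z > 0:
            raise ValueError("delta_z must be positive")
        if self.t_grid_points < 2 or self.z_grid_points < 8:
            raise ValueError("grids too coarse")


def nominal_v_schedule(design: DesignSpec, n: int) -> np.ndarray:
    """Nominal information at interims 1..n, k * V_increment."""
    if design.nominal_v_increment is None:
        raise ValueError("design has no nominal information increment")
    return design.nominal_v_increment * np.arange(1, n + 1, dtype=float)


def boundary_schedule(design: DesignSpec, v: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) stopping limits at the given information values."""
    b = design.boundary
    lo = np.asarray(b.lower(v), dtype=float)
    hi = np.asarray(b.upper(v), dtype=float)
    return lo, hi


def continuation_mass(lower: Sequence[float], upper: Sequence[float],
                      v: Sequence[float], z_n: float,
                      t: float = 0.0, config: RB1Config = RB1Config()
                      ) -> float:
    """P(stay in continuation regions 1..n-1 and land in the pinch at n).

    The first continuation region is (lower[0] + t, upper[0]); the n-th
    is the pinch (z_n - dz, z_n + dz).  Evaluated at theta = 0.
    """
    g, grid = _terminal_density(lower, upper, v, z_n, config)
    if t < 0 or t > upper[0] - lower[0]:
        raise ValueError("t outside [0, u_1 - l_1]")
    return _tail_integral(g, grid, lower[0] + t)


def _terminal_density(lower, upper, v, z_n, config):
    """Density-times-reach-probability g(z_1) on a grid over (l_1, u_1).

    g(z_1) = phi(z_1; 0, V_1) * P(reach pinch at n | Z_1 = z_1), so that
    the mass through a first region (l_1 + t, u_1) is the integral of g
    over that interval.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(v)
    if not (len(lower) == len(upper) == n):
        raise ValueError("boundary and information schedules must align")
    if n >= 2 and np.any(np.diff(v) <= 0):
        raise ValueError("information schedule must be strictly increasing")
    if np.any(upper[:max(n - 1, 1)] <= lower[:max(n - 1, 1)]):
        raise ValueError("empty continuation region before the final interim")
    dz = config.delta_z
    m = config.z_grid_points

    if n == 1:
        # single interim: density restricted to the pinch, resolved on a
        # grid with explicit breakpoints so the indicator edges are sharp
        lo0, hi0 = lower[0], upper[0]
        a_, b_ = max(lo0, z_n - dz), min(hi0, z_n + dz)
        if b_ <= a_:
            grid = np.linspace(lo0, hi0, m)
            return np.zeros(m), grid
        eps = 1e-12 * max(1.0, abs(hi0 - lo0))
        pinch = np.linspace(a_, b_, m)
        pieces_x = [np.array([lo0]), np.array([a_ - eps]), pinch,
                    np.array([b_ + eps]), np.array([hi0])]
        pieces_g = [np.zeros(1), np.zeros(1),
                    norm.pdf(pinch, scale=np.sqrt(v[0])),
                    np.zeros(1), np.zeros(1)]
        grid = np.concatenate(pieces_x)
        g = np.concatenate(pieces_g)
        keep = (grid >= lo0) & (grid <= hi0)
        order = np.argsort(grid[keep], kind="stable")
        return g[keep][order], grid[keep][order]

    # backward recursion: w_k(z) = P(reach pinch | Z_k = z)
    sig = np.sqrt(np.diff(v))
    w = None
    y = None
    for k in range(n - 1, 0, -1):  # interims n-1 .. 1
        grid_k = np.linspace(lower[k - 1], upper[k - 1], m)
        s = sig[k - 1]  # sd of the increment from interim k to k+1
        if k == n - 1:
            w_k = (norm.cdf((z_n + dz - grid_k) / s)
                   - norm.cdf((z_n - dz - grid_k) / s))
        else:
            kern = norm.pdf((y[None, :] - grid_k[:, None]) / s) / s
            w_k = np.trapezoid(kern * w[None, :], y, axis=1)
        w, y = w_k, grid_k
    g = norm.pdf(y, scale=np.sqrt(v[0])) * w
    return g, y


def _tail_integral(g: np.ndarray, grid: np.ndarray, a: float) -> float:
    """Integral of the gridded function g over [a, grid[-1]]."""
    if a >= grid[-1]:
        return 0.0
    if a <= grid[0]:
        return float(np.trapezoid(g, grid))
    idx = np.searchsorted(grid, a)
    ga = np.interp(a, grid, g)
    x = np.concatenate([[a], grid[idx:]])
    f = np.concatenate([[ga], g[idx:]])
    return float(np.trapezoid(f, x))


def survivor_curve(lower, upper, v, z_n, config: RB1Config = RB1Config()
                   ) -> tuple[np.ndarray, np.ndarray]:
    """S(t) on the t-grid, with S(0) = 1 prepended.

    Returns (t, S).  Degenerate terminal points (zero mass at t = 0)
    raise a ValueError.
    """
    g, grid = _terminal_density(lower, upper, v, z_n, config)
    width = upper[0] - lower[0]
    t = width * np.arange(config.t_grid_points + 1) / config.t_grid_points
    denom = _tail_integral(g, grid, lower[0])
    if denom <= 0:
        raise ValueError("zero continuation mass at the terminal point")
    s_vals = np.array([_tail_integral(g, grid, lower[0] + ti) for ti in t])
    s_vals /= denom
    s_vals[0] = 1.0
    return t, s_vals


def rb1_estimate(z_terminal: float, k_terminal: int, design: DesignSpec,
                 config: RB1Config = RB1Config(),
                 v_terminal: Optional[float] = None,
                 v_schedule: Optional[Sequence[float]] = None) -> RBEstimate:
    """Analytic Rao-Blackwellized estimate after a two-arm triangular test.

    Parameters
    ----------
    z_terminal, k_terminal : float, int
        Terminal score and stopping interim.
    design : DesignSpec
        A two-arm one-sided design supplying the boundary lines.
    v_terminal : float, optional
        Realized terminal information V*; the recursion then runs on
        the equally spaced schedule V_k = k V*/n, which reproduces the
        published worked examples.  If omitted (and no ``v_schedule``
        given) the design's nominal schedule V_k = k * V_increment is
        used.
    v_schedule : sequence of float, optional
        Explicit information values at interims 1..n, overriding both
        of the above.
    """
    if design.n_arms != 2 or design.boundary.symmetric:
        raise ValueError("RB1 applies to the one-sided two-arm design only")
    if k_terminal < 1:
        raise ValueError("terminal interim must be >= 1")
    if v_schedule is not None:
        v = np.asarray(v_schedule, dtype=float)
        if len(v) != k_terminal:
            raise ValueError("v_schedule must cover interims 1..k_terminal")
    elif v_terminal is not None:
        if not v_terminal > 0:
            raise ValueError("terminal information must be positive")
        v = v_terminal * np.arange(1, k_terminal + 1) / k_terminal
    else:
        v = nominal_v_schedule(design, k_terminal)
    v1 = float(v[0])
    if k_terminal == 1:
        # conditioning is vacuous: the estimate is the first-interim MLE
        theta = z_terminal / v1
        se = 1.0 / np.sqrt(v1)
        return RBEstimate(
            theta_tilde=theta, se=se, ci_lo=theta - Z_CRIT * se,
            ci_hi=theta + Z_CRIT * se, n_sims=0, n_complete=0,
            prop_complete=1.0, mean_inv_v1=1.0 / v1, var_theta1=0.0,
            method="rb1",
        )
    lo, hi = boundary_schedule(design, v)
    t, s_vals = survivor_curve(lo, hi, v, z_terminal, config)
    e_excess = float(np.trapezoid(s_vals, t))          # E[Z_1 - l_1 | .]
    e_excess2 = 2.0 * float(np.trapezoid(t * s_vals, t))
    var_z1 = max(e_excess2 - e_excess**2, 0.0)
    e_z1 = lo[0] + e_excess
    theta = e_z1 / v1
    var_theta1 = var_z1 / v1**2
    radicand = 1.0 / v1 - var_theta1
    if radicand >= 0:
        se = float(np.sqrt(radicand))
        ci_lo, ci_hi = theta - Z_CRIT * se, theta + Z_CRIT * se
    else:
        se = ci_lo = ci_hi = None
    return RBEstimate(
        theta_tilde=theta, se=se, ci_lo=ci_lo, ci_hi=ci_hi,
        n_sims=0, n_complete=0, prop_complete=1.0,
        mean_inv_v1=1.0 / v1, var_theta1=var_theta1, method="rb1",
    )
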