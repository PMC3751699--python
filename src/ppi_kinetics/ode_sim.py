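"""Deterministic mean-field trajectories of the kinetic model.

Three linear initial-value problems, each integrated numerically and also
available in closed form (the systems are 2x2 linear or scalar linear, so
the closed forms double as independent oracles for the integrator):

* the full proteome (N(t), Y(t)) relaxing to its steady state,
* a small synchronized sample of proteins decaying away while a fraction
  differentiates into the essential class,
* a single protein's node degree growing exponentially with age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core_model import (KineticParameters, degree_kinetics, degree_trajectory,
                         spectral_decomposition, steady_state)

__all__ = [
    "ProteomeTrajectory",
    "SampleTrajectory",
    "simulate_proteome",
    "proteome_closed_form",
    "simulate_sample",
    "sample_closed_form",
    "simulate_degree",
]

_RTOL = 1e-10
_ATOL = 1e-12


@dataclass
class ProteomeTrajectory:
    """Total and essential protein counts on a time grid."""

    t: np.ndarray
    N: np.ndarray
    Y: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "N": self.N, "Y": self.Y})


@dataclass
class SampleTrajectory:
    """Survival of a synchronized protein cohort along its age axis."""

    tau: np.ndarray
    dN: np.ndarray
    dY: np.ndarray
    dN0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau, "dN": self.dN, "dY": self.dY})


def _decay_matrix(kp: KineticParameters) -> np.ndarray:
    return np.array([[-(kp.ki - kp.k2), kp.ki],
                     [kp.kXY, -(kp.kXY + kp.kYX)]])


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def simulate_proteome(kp: KineticParameters, N0: float, Y0: float,
                      t_grid) -> ProteomeTrajectory:
    """Integrate d(N,Y)/dt = M (N,Y) + (f0, 0) on the given grid.

    The trajectory converges to the steady state (N_inf, Y_inf) from any
    admissible initial condition (N0 >= Y0 >= 0).
    """
    if not (N0 >= Y0 >= 0):
        raise ValueError("need N0 >= Y0 >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    M = _decay_matrix(kp)

    sol = solve_ivp(lambda _, y: M @ y + np.array([kp.f0, 0.0]),
                    (t_grid[0], t_grid[-1]), [N0, Y0],
                    t_eval=t_grid, rtol=_RTOL, atol=_ATOL, method="RK45")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return ProteomeTrajectory(t=sol.t, N=sol.y[0], Y=sol.y[1])


def proteome_closed_form(kp: KineticParameters, N0: float, Y0: float,
                         t_grid) -> ProteomeTrajectory:
    """Analytic solution: fixed point plus eigen-decaying deviation."""
    t_grid = np.asarray(t_grid, dtype=float)
    M = _decay_matrix(kp)
    ss = steady_state(kp)
    fixed = np.array([ss.N_inf, ss.Y_inf])
    evals, evecs = np.linalg.eig(M)
    coef = np.linalg.solve(evecs, np.array([N0, Y0]) - fixed)
    modes = coef[None, :] * np.exp(np.outer(t_grid - t_grid[0], evals))
    traj = fixed[None, :] + modes @ evecs.T
    return ProteomeTrajectory(t=t_grid, N=traj[:, 0].real, Y=traj[:, 1].real)


# ---------------------------------------------------------------------------
# synchronized sample
# ---------------------------------------------------------------------------

def simulate_sample(kp: KineticParameters, dN0: float, t_grid) -> SampleTrajectory:
    """Integrate the homogeneous decay of a cohort born at age 0.

    Initial condition (dN, dY) = (dN0, 0): newborn proteins are all class
    X. The total matches the two-exponential closed form
    ``dN(tau) = (a1 e^{-gamma1 tau} + a2 e^{-gamma2 tau}) dN0``.
    """
    if dN0 <= 0:
        raise ValueError("dN0 must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    M = _decay_matrix(kp)
    sol = solve_ivp(lambda _, y: M @ y, (t_grid[0], t_grid[-1]), [dN0, 0.0],
                    t_eval=t_grid, rtol=_RTOL, atol=_ATOL, method="RK45")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return SampleTrajectory(tau=sol.t, dN=sol.y[0], dY=sol.y[1], dN0=dN0)


def sample_closed_form(kp: KineticParameters, dN0: float, t_grid) -> SampleTrajectory:
    """Analytic cohort decay via the spectral decomposition."""
    t_grid = np.asarray(t_grid, dtype=float)
    sd = spectral_decomposition(kp)
    tau = t_grid - t_grid[0]
    dN = dN0 * (sd.a1 * np.exp(-sd.gamma1 * tau) + sd.a2 * np.exp(-sd.gamma2 * tau))
    # Y component from the eigenvector structure: y_i = (ki-k2+lambda_i)/ki
    alpha = kp.ki - kp.k2
    y1 = (alpha + sd.lambda1) / kp.ki
    y2 = (alpha + sd.lambda2) / kp.ki
    dY = dN0 * (sd.a1 * y1 * np.exp(-sd.gamma1 * tau)
                + sd.a2 * y2 * np.exp(-sd.gamma2 * tau))
    return SampleTrajectory(tau=t_grid, dN=dN, dY=dY, dN0=dN0)


# ---------------------------------------------------------------------------
# single-node degree
# ---------------------------------------------------------------------------

def simulate_degree(kp: KineticParameters, N_inf: float, tau_grid,
                    xi0: float | None = None) -> pd.DataFrame:
    """Integrate dxi/dtau = g + v xi for one protein.

    Starts from ``xi0`` (defaults to the newborn degree in ``kp``) and
    returns a tidy frame (tau, xi). Strictly increasing for v > 0: older
    proteins have more interactions.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    dk = degree_kinetics(kp, N_inf)
    x0 = kp.xi0 if xi0 is None else xi0
    sol = solve_ivp(lambda _, y: dk.g + dk.v * y, (tau_grid[0], tau_grid[-1]),
                    [x0], t_eval=tau_grid, rtol=_RTOL, atol=_ATOL, method="RK45")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return pd.DataFrame({"tau": sol.t, "xi": sol.y[0],
                         "xi_closed_form": degree_trajectory(dk, x0, sol.t - sol.t[0])})
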