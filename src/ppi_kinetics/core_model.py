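"""Closed-form observables of a two-class kinetic model of interactome evolution.

The model describes a proteome split into two classes: X (proteins needed
only for ecological adaptation, which can be inactivated) and Y (proteins
essential for basic processes, protected from direct loss). New X proteins
originate at rate ``f0``, X proteins are inactivated at rate ``ki``,
proteins transit X->Y at ``kXY`` and Y->X at ``kYX``, and every protein is
duplicated at ``k2`` (duplicates are always class X). On top of the
proteome kinetics, each protein's node degree xi (number of interaction
partners) grows through links to newborn proteins, pairwise link creation
at per-non-partner rate ``mu`` with a "rich get richer" preference
``delta_eps`` per existing link, link inheritance through partner
duplication, and shrinks through partner inactivation and spontaneous link
loss at per-link rate ``r``.

At the steady state of the proteome these rules yield, in closed form:

* an exponential-mixture age density ``dn/dtau``,
* an exponential degree trajectory ``xi(tau) = (xi_r+xi0) e^{v tau} - xi_r``,
* a degree distribution that is a sum of two shifted power laws
  ``dn/dxi = A1 (1+xi/xi_r)^{-beta1} + A2 (1+xi/xi_r)^{-beta2}``,
* a parabolic link law ``L = p1 N + p2 N (N-1) / 2``.

Every function here is pure arithmetic on the nine rate constants; the
modules for fitting, rate estimation and simulation are built on top of it.

Notes on exactness
------------------
The two-mode decay constants gamma_i, amplitudes a_i and the essential
fraction kappa come from the 2x2 linear proteome system. The per-protein
steady-state turnover is taken as the exact fixed-point relation
``phi = f0/N_inf = c/(kXY+kYX) = 1/(a1/gamma1 + a2/gamma2)``; its familiar
first-order form ``(1-kappa)(ki-k2)`` drops a ``kappa*k2`` cross term
(class-Y duplicates feeding X) and is accurate to ~0.03% in the fitted
regime. Using the exact turnover makes the mass-conservation identity
``f0 * integral(dn/dtau) = N_inf`` and the link-law quadrature identity
exact rather than approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "KineticParameters",
    "SteadyState",
    "SpectralDecomposition",
    "DegreeKinetics",
    "ObservableParameters",
    "InvalidRegimeError",
    "NoSteadyStateError",
    "NonDecayingRegimeError",
    "ShrinkingDegreeRegimeError",
    "DivergentTailError",
    "steady_state",
    "f0_from_steady_state",
    "spectral_decomposition",
    "age_density",
    "degree_kinetics",
    "degree_trajectory",
    "age_from_degree",
    "degree_distribution_params",
    "degree_distribution_eval",
    "double_exponential_approx",
    "link_probabilities",
    "total_links",
]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class InvalidRegimeError(ValueError):
    """Kinetic parameters outside the regime where the closed forms hold."""


class NoSteadyStateError(InvalidRegimeError):
    """ki <= k2: net growth never balances, no finite steady state."""


class NonDecayingRegimeError(InvalidRegimeError):
    """Eigenvalues not both real and negative: protein samples do not decay."""


class ShrinkingDegreeRegimeError(InvalidRegimeError):
    """v <= 0: node degrees do not grow; the distribution derivation fails."""


class DivergentTailError(InvalidRegimeError):
    """beta2 <= 2: the first moment of the degree distribution diverges."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """The nine rate constants driving the model.

    All rates are per model-time unit (dimensionless model time; roughly
    one unit per 1e9 years when mapped onto the fossil record, a
    documentation constant never used in computation).

    f0        : origination rate of entirely new class-X proteins.
    ki        : inactivation rate per class-X protein.
    k2        : duplication rate per protein (copies are class X).
    kXY, kYX  : class-transition rates X->Y and Y->X.
    xi0       : degree of an entirely new protein (may be fractional;
                realized as a Poisson mean by the stochastic simulator).
    mu        : link-gain rate per non-partner protein.
    delta_eps : extra link-gain rate per existing link (preferential
                attachment strength).
    r         : spontaneous link-loss rate per link.
    """

    f0: float
    ki: float
    k2: float
    kXY: float
    kYX: float
    xi0: float
    mu: float
    delta_eps: float
    r: float

    def __post_init__(self) -> None:
        for name in ("f0", "ki", "k2", "kXY", "kYX", "xi0", "mu", "delta_eps", "r"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value!r}")

    def free(self) -> Tuple[float, ...]:
        """The eight rates that are free during estimation (f0 is derived)."""
        return (self.ki, self.k2, self.kXY, self.kYX,
                self.xi0, self.mu, self.delta_eps, self.r)

    def with_f0(self, f0: float) -> "KineticParameters":
        return replace(self, f0=f0)


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the proteome equations.

    N_inf : total number of interacting proteins.
    Y_inf : number of essential (class Y) proteins.
    kappa : essential fraction Y_inf/N_inf = kXY/(kXY+kYX).
    phi   : exact per-protein turnover f0/N_inf; equals
            (1-kappa)(ki-k2) to first order in kappa*k2.
    """

    N_inf: float
    Y_inf: float
    kappa: float
    phi: float


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigen-structure of the 2x2 linear system for a synchronized sample.

    A small cohort born together decays as
    ``a1 exp(-gamma1 tau) + a2 exp(-gamma2 tau)`` with a1 + a2 = 1.
    gamma1 >= gamma2 > 0 (fast and slow modes).
    """

    b: float
    c: float
    lambda1: float
    lambda2: float
    gamma1: float
    gamma2: float
    s: float
    a1: float
    a2: float


@dataclass(frozen=True)
class DegreeKinetics:
    """Linear degree ODE ``dxi/dtau = g + v xi`` and derived scales.

    g    : degree source (links gained per unit time at xi = 0).
    v    : net exponential degree-growth rate.
    xi_r : reference degree g/v, the crossover scale of the distribution.
    w    : xi_r/(xi_r+xi0), in (0, 1).
    """

    g: float
    v: float
    xi_r: float
    w: float


@dataclass(frozen=True)
class ObservableParameters:
    """Parameters of the fit-facing observables.

    Degree distribution: amplitudes A1, A2, exponents beta1 >= beta2 and
    shift scale xi_r of the two shifted power laws; eps_i = beta_i/xi_r are
    the rates of the small-degree double-exponential approximation. Link
    law: p1 (per-protein) and p2 (per-pair) probabilities. p1/p2 are None
    for parameter sets fitted from a histogram alone.
    """

    A1: float
    A2: float
    beta1: float
    beta2: float
    xi_r: float
    eps1: float | None = None
    eps2: float | None = None
    p1: float | None = None
    p2: float | None = None

    def __post_init__(self) -> None:
        if self.xi_r <= 0:
            raise ValueError("xi_r must be positive")
        if self.eps1 is None:
            object.__setattr__(self, "eps1", self.beta1 / self.xi_r)
        if self.eps2 is None:
            object.__setattr__(self, "eps2", self.beta2 / self.xi_r)


# ---------------------------------------------------------------------------
# proteome steady state
# ---------------------------------------------------------------------------

def _bc(kp: KineticParameters) -> Tuple[float, float]:
    b = (kp.ki - kp.k2) + (kp.kXY + kp.kYX)
    c = (kp.ki - kp.k2) * (kp.kXY + kp.kYX) - kp.kXY * kp.ki
    return b, c


def steady_state(kp: KineticParameters) -> SteadyState:
    """Exact fixed point of the proteome system.

    ``N_inf = f0 (kXY+kYX)/c`` with ``c`` the determinant of the decay
    matrix; ``kappa = kXY/(kXY+kYX)``; ``phi = f0/N_inf``.

    Raises
    ------
    NoSteadyStateError
        if ki <= k2 (duplication outruns inactivation) or the determinant
        is not positive, so no finite positive steady state exists.
    """
    if kp.kXY + kp.kYX <= 0:
        raise InvalidRegimeError("kXY + kYX must be positive")
    if kp.ki <= kp.k2:
        raise NoSteadyStateError(
            f"ki={kp.ki} <= k2={kp.k2}: duplication outruns inactivation")
    _, c = _bc(kp)
    if c <= 0:
        raise NoSteadyStateError("decay-matrix determinant c <= 0: unbounded growth")
    kappa = kp.kXY / (kp.kXY + kp.kYX)
    phi = c / (kp.kXY + kp.kYX)
    N_inf = kp.f0 / phi
    return SteadyState(N_inf=N_inf, Y_inf=kappa * N_inf, kappa=kappa, phi=phi)


def f0_from_steady_state(N_inf: float, kp: KineticParameters) -> float:
    """Origination rate implied by a steady-state proteome size.

    Inverts the fixed-point relation: ``f0 = N_inf * phi``. Round-trips
    exactly with :func:`steady_state` (its f0 field is ignored here).
    """
    if N_inf <= 0:
        raise ValueError("N_inf must be positive")
    ss = steady_state(kp if kp.f0 > 0 else kp.with_f0(1.0))
    return N_inf * ss.phi


# ---------------------------------------------------------------------------
# spectral decomposition of the sample-decay system
# ---------------------------------------------------------------------------

def spectral_decomposition(kp: KineticParameters) -> SpectralDecomposition:
    """Eigenvalues and mode amplitudes of the 2x2 sample-decay matrix.

    The matrix is ``[[-(ki-k2), ki], [kXY, -(kXY+kYX)]]``; with
    ``b = (ki-k2)+(kXY+kYX)`` and ``c`` its determinant, the eigenvalues
    are ``lambda_{1,2} = (-b -/+ sqrt(b^2-4c))/2`` (lambda1 the more
    negative, so gamma1 >= gamma2). Amplitudes follow from the initial
    condition (dN, dY) = (1, 0): a1 = 1/(1-s), a2 = -s/(1-s) with
    s = (ki-k2+lambda1)/(ki-k2+lambda2).
    """
    b, c = _bc(kp)
    disc = b * b - 4.0 * c
    if b <= 0 or c <= 0 or disc <= 0:
        raise NonDecayingRegimeError(
            f"need b > 0 and b^2 > 4c > 0 for two negative eigenvalues "
            f"(b={b:.6g}, c={c:.6g})")
    root = math.sqrt(disc)
    lambda1 = 0.5 * (-b - root)
    lambda2 = 0.5 * (-b + root)
    alpha = kp.ki - kp.k2
    # amplitudes from the initial condition (dN, dY) = (1, 0); this form
    # only divides by lambda1 - lambda2 = -root, never zero here
    a1 = (alpha + lambda2) / (lambda2 - lambda1)
    a2 = (alpha + lambda1) / (lambda1 - lambda2)
    s = (alpha + lambda1) / (alpha + lambda2) \
        if alpha + lambda2 != 0 else math.inf
    return SpectralDecomposition(b=b, c=c, lambda1=lambda1, lambda2=lambda2,
                                 gamma1=-lambda1, gamma2=-lambda2,
                                 s=s, a1=a1, a2=a2)


def age_density(kp: KineticParameters, tau):
    """Steady-state protein-age density ``dn/dtau``.

    ``dn/dtau = f0 (a1 exp(-gamma1 tau) + a2 exp(-gamma2 tau))``: the
    number of surviving proteins per unit age. Integrates to N_inf.
    Accepts scalar or array ``tau``.
    """
    sd = spectral_decomposition(kp)
    tau = np.asarray(tau, dtype=float)
    out = kp.f0 * (sd.a1 * np.exp(-sd.gamma1 * tau) + sd.a2 * np.exp(-sd.gamma2 * tau))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# degree kinetics
# ---------------------------------------------------------------------------

def degree_kinetics(kp: KineticParameters, N_inf: float) -> DegreeKinetics:
    """Coefficients of the per-protein degree ODE ``dxi/dtau = g + v xi``.

    ``g = f0 xi0/N_inf + mu (N_inf - 1)`` collects degree gains that do not
    scale with the protein's own degree (newborn partners and the uniform
    part of pair formation); ``v = delta_eps + k2 - ki(1-kappa) - r - mu``
    is the net per-link growth rate (preference plus partner duplication,
    minus partner inactivation, spontaneous loss, and the mu term already
    counted in g).
    """
    ss = steady_state(kp if kp.f0 > 0 else kp.with_f0(1.0))
    v = kp.delta_eps + kp.k2 - kp.ki * (1.0 - ss.kappa) - kp.r - kp.mu
    if v <= 0:
        raise ShrinkingDegreeRegimeError(
            f"v={v:.6g} <= 0: degrees shrink, distribution derivation invalid")
    g = kp.f0 * kp.xi0 / N_inf + kp.mu * (N_inf - 1.0)
    if g <= 0:
        raise InvalidRegimeError("degree source g must be positive (xi0 or mu > 0)")
    xi_r = g / v
    return DegreeKinetics(g=g, v=v, xi_r=xi_r, w=xi_r / (xi_r + kp.xi0))


def degree_trajectory(dk: DegreeKinetics, xi0: float, tau):
    """Degree of a protein of age tau: ``xi = (xi_r+xi0) e^{v tau} - xi_r``."""
    tau = np.asarray(tau, dtype=float)
    out = (dk.xi_r + xi0) * np.exp(dk.v * tau) - dk.xi_r
    return out if out.ndim else float(out)


def age_from_degree(dk: DegreeKinetics, xi0: float, xi):
    """Inverse of :func:`degree_trajectory`: ``tau = ln[w (1+xi/xi_r)]/v``.

    ``w`` is evaluated for the supplied starting degree ``xi0``.
    """
    xi = np.asarray(xi, dtype=float)
    w = dk.xi_r / (dk.xi_r + xi0)
    out = np.log(w * (1.0 + xi / dk.xi_r)) / dk.v
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# degree distribution and link law
# ---------------------------------------------------------------------------

def degree_distribution_params(kp: KineticParameters, N_inf: float) -> ObservableParameters:
    """All observable parameters implied by the kinetics at size N_inf.

    ``beta_i = gamma_i/v + 1``, ``A_i = a_i w^{1-beta_i} f0/(xi_r v)``,
    ``eps_i = beta_i/xi_r``, plus the link-law probabilities p1 and p2.
    """
    sd = spectral_decomposition(kp)
    dk = degree_kinetics(kp, N_inf)
    beta1 = sd.gamma1 / dk.v + 1.0
    beta2 = sd.gamma2 / dk.v + 1.0
    amp = kp.f0 / (dk.xi_r * dk.v)
    A1 = sd.a1 * dk.w ** (1.0 - beta1) * amp
    A2 = sd.a2 * dk.w ** (1.0 - beta2) * amp
    p1 = p2 = None
    if beta2 > 2.0:
        p1, p2 = link_probabilities(kp, N_inf)
    return ObservableParameters(A1=A1, A2=A2, beta1=beta1, beta2=beta2,
                                xi_r=dk.xi_r, p1=p1, p2=p2)


def degree_distribution_eval(obs: ObservableParameters, xi):
    """Sum-of-two-shifted-power-laws degree density ``dn/dxi``."""
    xi = np.asarray(xi, dtype=float)
    u = 1.0 + xi / obs.xi_r
    out = obs.A1 * u ** (-obs.beta1) + obs.A2 * u ** (-obs.beta2)
    return out if out.ndim else float(out)


def double_exponential_approx(obs: ObservableParameters, xi):
    """Small-degree (xi << xi_r) double-exponential approximation.

    ``dn/dxi ~ A1 exp(-eps1 xi) + A2 exp(-eps2 xi)`` with
    ``eps_i = beta_i/xi_r``; shares value and slope with the full
    distribution at xi = 0.
    """
    xi = np.asarray(xi, dtype=float)
    out = obs.A1 * np.exp(-obs.eps1 * xi) + obs.A2 * np.exp(-obs.eps2 * xi)
    return out if out.ndim else float(out)


def link_probabilities(kp: KineticParameters, N_inf: float) -> Tuple[float, float]:
    """Link-law probabilities (p1, p2) implied by the kinetics.

    Obtained in closed form from ``L = 0.5 * integral_{xi0}^{inf} xi dn/dxi``:

    ``p1 = phi xi0/(2 v^2) * sum_i a_i (gamma_i + phi) / ((beta_i-1)(beta_i-2))``
    ``p2 = phi mu / v^2   * sum_i a_i / ((beta_i-1)(beta_i-2))``

    with ``phi = f0/N_inf`` the exact turnover, so the closed form matches
    numeric quadrature of the distribution to machine precision.
    """
    sd = spectral_decomposition(kp)
    dk = degree_kinetics(kp, N_inf)
    beta1 = sd.gamma1 / dk.v + 1.0
    beta2 = sd.gamma2 / dk.v + 1.0
    if beta2 <= 2.0:
        raise DivergentTailError(
            f"beta2={beta2:.6g} <= 2: the link integral diverges")
    phi = kp.f0 / N_inf
    d1 = (beta1 - 1.0) * (beta1 - 2.0)
    d2 = (beta2 - 1.0) * (beta2 - 2.0)
    v2 = dk.v * dk.v
    p1 = phi * kp.xi0 / (2.0 * v2) * (sd.a1 * (sd.gamma1 + phi) / d1
                                      + sd.a2 * (sd.gamma2 + phi) / d2)
    p2 = phi * kp.mu / v2 * (sd.a1 / d1 + sd.a2 / d2)
    return p1, p2


def total_links(p1: float, p2: float, N: float) -> float:
    """Parabolic link law: ``L = p1 N + p2 N (N-1)/2``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return p1 * N + p2 * N * (N - 1.0) / 2.0
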