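"""Recovering the kinetic rate constants from fitted observables.

The inverse problem: given the seven fitted observables (A1, A2, beta1,
beta2, xi_r of the degree distribution and p1, p2 of the link law) with
their standard errors, find the eight free rates (ki, k2, kXY, kYX, xi0,
mu, delta_eps, r) whose model-computed observables minimize

    chi^2 = sum_j ((computed_j - reference_j) / SE_j)^2 .

The origination rate f0 is not free: it is eliminated through the
steady-state relation f0 = N_inf * phi at a fixed interactome size
(N_inf = 4135 for the budding-yeast reference) and reported afterwards.

With seven observables and eight rates the problem is formally
under-determined; the minimizer is a multi-start random walk in log
parameter space (multiplicative Gaussian proposals, greedy acceptance with
an optional annealing temperature) that reports the best parameter set and
mean/spread over the top-k sets, which is the honest summary for a flat
chi^2 valley.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import KineticParameters

__all__ = [
    "OBSERVABLE_NAMES",
    "FREE_PARAM_NAMES",
    "ChiSquareReference",
    "SearchConfig",
    "EstimationResult",
    "observables_from_rates",
    "chi_square",
    "feasibility",
    "random_walk_minimize",
]

OBSERVABLE_NAMES = ("A1", "A2", "beta1", "beta2", "xi_r", "p1", "p2")
FREE_PARAM_NAMES = ("ki", "k2", "kXY", "kYX", "xi0", "mu", "delta_eps", "r")

# broad log-uniform start ranges (decades around biologically plausible
# rate scales in model-time units); purely a search prior, not a constraint
_START_RANGES = {
    "ki": (0.5, 50.0),
    "k2": (1e-3, 5.0),
    "kXY": (1e-3, 5.0),
    "kYX": (0.1, 50.0),
    "xi0": (0.01, 5.0),
    "mu": (1e-5, 0.1),
    "delta_eps": (0.5, 50.0),
    "r": (1e-3, 2.0),
}


# ---------------------------------------------------------------------------
# reference and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChiSquareReference:
    """Fitted observables and absolute standard errors, in a fixed order."""

    values: tuple[float, ...]
    se: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 7 or len(self.se) != 7:
            raise ValueError("exactly 7 observables required "
                             f"({', '.join(OBSERVABLE_NAMES)})")
        if any(s <= 0 for s in self.se):
            raise ValueError("all standard errors must be positive")

    @classmethod
    def from_percent(cls, estimates: dict[str, float],
                     se_percent: dict[str, float]) -> "ChiSquareReference":
        """Build from estimates and percent standard errors (SE% of estimate)."""
        vals = tuple(float(estimates[k]) for k in OBSERVABLE_NAMES)
        ses = tuple(abs(float(estimates[k])) * float(se_percent[k]) / 100.0
                    for k in OBSERVABLE_NAMES)
        return cls(vals, ses)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {k: (v, s) for k, v, s in zip(OBSERVABLE_NAMES, self.values, self.se)}


@dataclass
class SearchConfig:
    """Random-walk settings.

    step_size      : relative width of the multiplicative log-space proposal.
    anneal         : factor applied to step_size every anneal_every proposals
                     within one restart (geometric cooling of the walk).
    temperature    : Metropolis temperature for accepting uphill moves
                     (0 = strictly greedy).
    n_restarts     : independent starting points.
    n_steps        : proposal evaluations per restart.
    top_k          : number of best parameter sets summarized.
    max_start_tries: sampling budget for one feasible starting point.
    """

    n_restarts: int = 32
    n_steps: int = 4000
    step_size: float = 0.2
    anneal: float = 0.95
    anneal_every: int = 250
    temperature: float = 0.0
    top_k: int = 10
    max_start_tries: int = 20000

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EstimationResult:
    """Outcome of one random-walk estimation run."""

    best_params: KineticParameters
    best_chi2: float
    top: list[tuple[float, KineticParameters]]
    top_mean: dict[str, float]
    top_se_percent: dict[str, float]
    n_eval: int
    acceptance_rate: float
    seed: int | None
    config: SearchConfig
    restart_best: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        names = FREE_PARAM_NAMES + ("f0",)
        def row(kp: KineticParameters) -> dict[str, float]:
            return {n: getattr(kp, n) for n in names}
        return {
            "best": {"chi2": self.best_chi2, **row(self.best_params)},
            "top_mean": self.top_mean,
            "top_se_percent": self.top_se_percent,
            "top": [{"chi2": c, **row(kp)} for c, kp in self.top],
            "n_eval": self.n_eval,
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "restart_best_chi2": self.restart_best,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# fast observable evaluation on raw 8-tuples
# ---------------------------------------------------------------------------

def _observables8(p: Sequence[float], N_inf: float) -> tuple[float, ...] | None:
    """(A1, A2, beta1, beta2, xi_r, p1, p2) for 8 free rates, else None.

    Mirrors the core-model chain (exact turnover phi = f0/N_inf used for f0
    elimination and the link law) but works on bare floats: the random walk
    calls this hundreds of thousands of times.
    """
    ki, k2, kXY, kYX, xi0, mu, de, r = p
    if min(p) < 0 or ki <= k2:
        return None
    ktot = kXY + kYX
    if kXY <= 0 or kYX <= 0:
        return None
    alpha = ki - k2
    b = alpha + ktot
    c = alpha * ktot - kXY * ki
    disc = b * b - 4.0 * c
    if b <= 0 or c <= 0 or disc <= 0:
        return None
    root = math.sqrt(disc)
    l1 = 0.5 * (-b - root)
    l2 = 0.5 * (-b + root)
    g1, g2 = -l1, -l2
    kappa = kXY / ktot
    v = de + k2 - ki * (1.0 - kappa) - r - mu
    if v <= 0:
        return None
    beta2 = g2 / v + 1.0
    if beta2 <= 2.0:
        return None
    beta1 = g1 / v + 1.0
    phi = c / ktot                      # exact turnover f0/N_inf
    f0 = N_inf * phi
    g = phi * xi0 + mu * (N_inf - 1.0)
    if g <= 0:
        return None
    xi_r = g / v
    w = xi_r / (xi_r + xi0)
    a1 = (alpha + l2) / (l2 - l1)
    a2 = (alpha + l1) / (l1 - l2)
    amp = f0 / (xi_r * v)
    A1 = a1 * w ** (1.0 - beta1) * amp
    A2 = a2 * w ** (1.0 - beta2) * amp
    d1 = (beta1 - 1.0) * (beta1 - 2.0)
    d2 = (beta2 - 1.0) * (beta2 - 2.0)
    v2 = v * v
    p1 = phi * xi0 / (2.0 * v2) * (a1 * (g1 + phi) / d1 + a2 * (g2 + phi) / d2)
    p2 = phi * mu / v2 * (a1 / d1 + a2 / d2)
    return (A1, A2, beta1, beta2, xi_r, p1, p2)


def observables_from_rates(free_params: Sequence[float] | KineticParameters,
                           N_inf: float) -> dict[str, float]:
    """Named model observables at the given rates and interactome size."""
    p = free_params.free() if isinstance(free_params, KineticParameters) \
        else tuple(free_params)
    obs = _observables8(p, N_inf)
    if obs is None:
        raise ValueError("parameters outside the valid regime")
    return dict(zip(OBSERVABLE_NAMES, obs))


def chi_square(free_params: Sequence[float] | KineticParameters,
               ref: ChiSquareReference, N_inf: float) -> float:
    """Standardized squared deviation of model from reference observables.

    Infeasible parameter sets return +inf (an optimizer-friendly sentinel,
    never an exception).
    """
    p = free_params.free() if isinstance(free_params, KineticParameters) \
        else tuple(free_params)
    obs = _observables8(p, N_inf)
    if obs is None:
        return math.inf
    total = 0.0
    for o, v, s in zip(obs, ref.values, ref.se):
        d = (o - v) / s
        total += d * d
    return total


def feasibility(free_params: Sequence[float] | KineticParameters) -> tuple[bool, list[str]]:
    """Whether the rates lie in the regime all closed forms presume.

    Checks, with reasons on failure: non-negative rates; ki > k2 (finite
    steady state); two real negative eigenvalues; kappa strictly inside
    (0, 1); growing-degree regime v > 0; convergent link integral
    beta2 > 2.
    """
    p = free_params.free() if isinstance(free_params, KineticParameters) \
        else tuple(free_params)
    ki, k2, kXY, kYX, xi0, mu, de, r = p
    reasons: list[str] = []
    if min(p) < 0:
        reasons.append("negative rate")
    if ki <= k2:
        reasons.append("no steady state (ki <= k2)")
    if kXY <= 0 or kYX <= 0:
        reasons.append("kappa not in (0, 1) (kXY and kYX must be positive)")
    if not reasons:
        ktot = kXY + kYX
        alpha = ki - k2
        b = alpha + ktot
        c = alpha * ktot - kXY * ki
        if b <= 0 or c <= 0 or b * b - 4.0 * c <= 0:
            reasons.append("non-decaying regime (eigenvalues not real negative)")
        else:
            kappa = kXY / ktot
            v = de + k2 - ki * (1.0 - kappa) - r - mu
            if v <= 0:
                reasons.append("shrinking-degree regime (v <= 0)")
            else:
                g2 = -0.5 * (-b + math.sqrt(b * b - 4.0 * c))
                if g2 / v + 1.0 <= 2.0:
                    reasons.append("divergent tail (beta2 <= 2)")
                if xi0 <= 0 and mu <= 0:
                    reasons.append("no degree source (xi0 = mu = 0)")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# random-walk minimizer
# ---------------------------------------------------------------------------

def _sample_start(rng: np.random.Generator, ref: ChiSquareReference,
                  N_inf: float, max_tries: int) -> np.ndarray:
    lo = np.array([_START_RANGES[n][0] for n in FREE_PARAM_NAMES])
    hi = np.array([_START_RANGES[n][1] for n in FREE_PARAM_NAMES])
    log_lo, log_hi = np.log(lo), np.log(hi)
    for _ in range(max_tries):
        p = np.exp(rng.uniform(log_lo, log_hi))
        if _observables8(tuple(p), N_inf) is not None:
            return p
    raise RuntimeError(f"no feasible starting point found in {max_tries} draws")


def random_walk_minimize(ref: ChiSquareReference, N_inf: float,
                         config: SearchConfig | None = None,
                         seed: int | None = None) -> EstimationResult:
    """Multi-start random-walk minimization of the chi^2 objective.

    Each restart draws a feasible start from broad log-uniform ranges and
    walks with per-parameter multiplicative Gaussian proposals; moves that
    lower chi^2 are always accepted, uphill moves with probability
    exp(-delta/temperature) when a positive temperature is configured. The
    proposal width anneals geometrically with accepted moves. Fully
    reproducible for a given seed.
    """
    cfg = config or SearchConfig()
    rng = np.random.default_rng(seed)
    n_eval = 0
    n_accept = 0
    pool: list[tuple[float, tuple[float, ...]]] = []
    restart_best: list[float] = []

    for _ in range(cfg.n_restarts):
        current = _sample_start(rng, ref, N_inf, cfg.max_start_tries)
        cur_chi2 = chi_square(tuple(current), ref, N_inf)
        n_eval += 1
        step = cfg.step_size
        best_here = cur_chi2
        for k in range(1, cfg.n_steps + 1):
            prop = current * np.exp(step * rng.standard_normal(8))
            chi2 = chi_square(tuple(prop), ref, N_inf)
            n_eval += 1
            accept = chi2 <= cur_chi2
            if not accept and cfg.temperature > 0 and math.isfinite(chi2):
                accept = rng.random() < math.exp(-(chi2 - cur_chi2) / cfg.temperature)
            if accept:
                current, cur_chi2 = prop, chi2
                n_accept += 1
                best_here = min(best_here, cur_chi2)
            if k % cfg.anneal_every == 0:
                step *= cfg.anneal
        restart_best.append(best_here)
        pool.append((cur_chi2, tuple(current)))

    pool.sort(key=lambda item: item[0])
    top = pool[:cfg.top_k]

    def to_kp(p: tuple[float, ...]) -> KineticParameters:
        named = dict(zip(FREE_PARAM_NAMES, p))
        kp = KineticParameters(f0=1.0, **named)
        from .core_model import f0_from_steady_state
        return kp.with_f0(f0_from_steady_state(N_inf, kp))

    top_kp = [(c, to_kp(p)) for c, p in top]
    names = FREE_PARAM_NAMES + ("f0",)
    arr = np.array([[getattr(kp, n) for n in names] for _, kp in top_kp])
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros(arr.shape[1])
    top_mean = dict(zip(names, mean.tolist()))
    top_se_percent = {n: (100.0 * s / abs(m) if m else math.nan)
                      for n, m, s in zip(names, mean, se)}

    return EstimationResult(
        best_params=top_kp[0][1], best_chi2=top_kp[0][0], top=top_kp,
        top_mean=top_mean, top_se_percent=top_se_percent,
        n_eval=n_eval, acceptance_rate=n_accept / max(n_eval - cfg.n_restarts, 1),
        seed=seed, config=cfg, restart_best=restart_best)
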