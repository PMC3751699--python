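"""Degree histograms and least-squares fits of the network observables.

Builds empirical node-degree histograms from integer degree lists (unit
bins at small degree, a few wide logarithmic bins in the sparse tail, each
normalized per unit degree) and fits:

* the model degree distribution (sum of two shifted power laws),
* comparator families: pure power law (PL), generalized power law with
  exponential cut-off (PL-EC), and the double exponential (2E),
* the parabolic link law L = p1 N + p2 N(N-1)/2 across species summaries.

Histogram fits minimize least squares on log(count) - the count spans four
decades and the log objective weights the tail sensibly - while the
reported goodness numbers (mean relative error on the linear scale,
Pearson correlation of log predictions) match how such fits are usually
judged. The link-law fit is ordinary least squares, linear in (p1, p2),
solved in closed form.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .core_model import ObservableParameters

__all__ = [
    "DegreeHistogram",
    "InteractomeSummary",
    "FitResult",
    "build_degree_histogram",
    "fit_degree_distribution",
    "fit_power_law",
    "fit_power_law_cutoff",
    "fit_double_exponential",
    "fit_links_model",
    "goodness_metrics",
    "sample_degrees",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DegreeHistogram:
    """Empirical counterpart of the degree density dn/dxi.

    abscissa  : representative degree of each bin (mean member degree for
                aggregated tail bins, hence possibly fractional).
    count     : proteins per unit degree at each abscissa.
    bin_edges : inclusive integer ranges (lo, hi) of each bin.
    n_proteins: total number of proteins binned.
    """

    abscissa: np.ndarray
    count: np.ndarray
    bin_edges: list[tuple[int, int]] = field(default_factory=list)
    n_proteins: int = 0

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.abscissa.shape != self.count.shape:
            raise ValueError("abscissa and count must have equal length")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.count < 0):
            raise ValueError("counts must be >= 0")

    def widths(self) -> np.ndarray:
        if self.bin_edges:
            return np.array([hi - lo + 1 for lo, hi in self.bin_edges], dtype=float)
        return np.ones_like(self.abscissa)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"degree": self.abscissa, "count_per_degree": self.count})
        if self.bin_edges:
            df["bin_lo"] = [lo for lo, _ in self.bin_edges]
            df["bin_hi"] = [hi for _, hi in self.bin_edges]
        return df


@dataclass(frozen=True)
class InteractomeSummary:
    """One species' interactome in two numbers: size and link count."""

    species: str
    N_inf: int
    L: int

    def __post_init__(self) -> None:
        if self.N_inf < 1:
            raise ValueError("N_inf must be >= 1")
        if not 0 <= self.L <= self.N_inf * (self.N_inf - 1) // 2:
            raise ValueError("L must lie in [0, N(N-1)/2]")


@dataclass
class FitResult:
    """Estimates, asymptotic errors and goodness numbers of one fit."""

    model_name: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    stderr_percent: dict[str, float | None]
    mean_relative_error: float
    correlation: float
    success: bool
    message: str
    n_points: int
    n_eval: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": self.params,
            "stderr": self.stderr,
            "stderr_percent": self.stderr_percent,
            "mean_relative_error": self.mean_relative_error,
            "correlation": self.correlation,
            "success": self.success,
            "message": self.message,
            "n_points": self.n_points,
            "n_eval": self.n_eval,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# histogram construction
# ---------------------------------------------------------------------------

def build_degree_histogram(degrees: Sequence[int], tail_bin_count: int = 4,
                           tail_threshold: int = 20) -> DegreeHistogram:
    """Bin integer degrees: unit bins up to a threshold, log bins beyond.

    Degrees <= ``tail_threshold`` occupy one bin per integer value; larger
    degrees are aggregated into up to ``tail_bin_count`` logarithmically
    spaced integer ranges (the sparse tail of a heavy-tailed histogram).
    Tail-bin counts are divided by the bin width so every bin is proteins
    per unit degree, and the abscissa of a tail bin is the mean degree of
    its member proteins. Total protein count is conserved:
    ``sum(count * width) == len(degrees)``.
    """
    deg = np.asarray(degrees, dtype=int)
    if deg.size == 0:
        raise ValueError("empty degree list")
    if deg.min() < 1:
        raise ValueError("degrees must be >= 1 (interacting proteins only)")
    if tail_threshold < 1:
        raise ValueError("tail_threshold must be >= 1")

    if tail_bin_count <= 0:
        tail_threshold = int(deg.max())

    head = deg[deg <= tail_threshold]
    tail = deg[deg > tail_threshold]

    abscissa: list[float] = []
    count: list[float] = []
    edges: list[tuple[int, int]] = []

    values, counts = np.unique(head, return_counts=True)
    for val, cnt in zip(values, counts):
        abscissa.append(float(val))
        count.append(float(cnt))
        edges.append((int(val), int(val)))

    if tail.size:
        lo, hi = tail_threshold + 1, int(tail.max())
        n_bins = min(tail_bin_count, hi - lo + 1)
        raw = np.logspace(math.log10(lo), math.log10(hi + 1), n_bins + 1)
        cuts = np.unique(np.round(raw).astype(int))
        cuts[0], cuts[-1] = lo, hi + 1
        for a, b in zip(cuts[:-1], cuts[1:]):
            members = tail[(tail >= a) & (tail < b)]
            if members.size == 0:
                continue
            width = b - a
            abscissa.append(float(members.mean()))
            count.append(members.size / width)
            edges.append((int(a), int(b - 1)))

    return DegreeHistogram(np.array(abscissa), np.array(count),
                           bin_edges=edges, n_proteins=int(deg.size))


# ---------------------------------------------------------------------------
# goodness metrics
# ---------------------------------------------------------------------------

def goodness_metrics(observed, predicted) -> tuple[float, float]:
    """Mean relative error (linear scale) and log-scale Pearson correlation.

    Points with non-positive observed count are excluded with a warning
    (they carry no information on a log scale and break relative error).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    mask = obs > 0
    if not mask.all():
        warnings.warn(f"excluding {int((~mask).sum())} non-positive observed counts")
    obs, pred = obs[mask], pred[mask]
    if obs.size == 0:
        raise ValueError("no positive observations")
    mre = float(np.mean(np.abs(pred - obs) / obs))
    pos = pred > 0
    if pos.sum() < 2:
        return mre, float("nan")
    corr = float(np.corrcoef(np.log(obs[pos]), np.log(pred[pos]))[0, 1])
    return mre, corr


# ---------------------------------------------------------------------------
# nonlinear histogram fits
# ---------------------------------------------------------------------------

def _run_fit(model_name: str, predict, param_sets: list[lmfit.Parameters],
             hist: DegreeHistogram, report_map) -> FitResult:
    """Weighted least squares on log(count), best over several starts.

    Residuals are ``(log pred - log count) * sqrt(bin protein count)``: for
    Poisson bin counts n the variance of log n is ~1/n, so this weighting
    makes the asymptotic standard errors calibrated while keeping the
    log-scale objective that handles the histogram's multi-decade range.
    ``predict(x, params) -> density``; ``report_map(result) -> (params,
    stderr)`` converts internal parameters to the reported ones.
    """
    mask = hist.count > 0
    if not mask.all():
        warnings.warn("ignoring zero-count histogram bins in fit")
    x, y = hist.abscissa[mask], hist.count[mask]
    weight = np.sqrt(y * hist.widths()[mask])
    logy = np.log(y)

    def residual(p):
        pred = predict(x, p)
        if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
            return np.full_like(logy, 1e6)
        return (np.log(pred) - logy) * weight

    best = None
    for params in param_sets:
        try:
            res = lmfit.minimize(residual, params, method="leastsq",
                                 nan_policy="raise", scale_covar=False)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return FitResult(model_name, {}, {}, {}, math.nan, math.nan,
                         False, "all starting points failed", int(x.size))

    est, err = report_map(best)
    pred = predict(x, best.params)
    mre, corr = goodness_metrics(y, pred)
    pct = {k: (100.0 * err[k] / abs(v) if err.get(k) and v else None)
           for k, v in est.items()}
    message = best.message or ""
    return FitResult(model_name, est, err, pct, mre, corr,
                     bool(best.success), message, int(x.size),
                     n_eval=int(best.nfev))


def _stderr(res: lmfit.minimizer.MinimizerResult, name: str) -> float | None:
    p = res.params[name]
    return float(p.stderr) if p.stderr is not None else None


def fit_degree_distribution(hist: DegreeHistogram,
                            init: ObservableParameters | None = None) -> FitResult:
    """Fit the sum of two shifted power laws to a degree histogram.

    Five free parameters (A1, A2, beta1, beta2, xi_r); beta1 >= beta2 is
    enforced by parameterizing beta1 = beta2 + dbeta with dbeta >= 0, which
    removes the label-switching degeneracy, and beta2 > 1 is required so
    both components carry finite protein mass (normalizability). A
    near-zero fitted dbeta is flagged as a degenerate (single power law)
    solution.
    """
    if np.count_nonzero(hist.count > 0) < 6:
        raise ValueError("need at least 6 positive histogram points for 5 parameters")

    def predict(x, p):
        b2 = p["beta2"].value
        b1 = b2 + p["dbeta"].value
        u = 1.0 + x / p["xi_r"].value
        return p["A1"].value * u ** (-b1) + p["A2"].value * u ** (-b2)

    c0 = float(hist.count[0])
    starts = []
    if init is not None:
        p = lmfit.Parameters()
        p.add("A1", value=max(init.A1, 1e-9), min=1e-12)
        p.add("A2", value=max(init.A2, 1e-9), min=1e-12)
        p.add("beta2", value=min(max(init.beta2, 1.1), 11.5), min=1.05, max=12)
        p.add("dbeta", value=max(init.beta1 - init.beta2, 1e-3), min=0, max=12)
        p.add("xi_r", value=init.xi_r, min=1e-3, max=1e4)
        starts.append(p)
    else:
        # moment-based guesses: tail log-log slope for beta2, a few xi_r scales
        x, y = hist.abscissa, np.where(hist.count > 0, hist.count, np.nan)
        upper = slice(len(x) // 2, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slope = np.polyfit(np.log(x[upper]), np.log(y[upper]), 1)[0]
        b2_guess = float(np.clip(-slope, 1.3, 8.0))
        for xi_r in (2.0, 6.0, 15.0):
            for dbeta in (1.0, 3.0):
                p = lmfit.Parameters()
                p.add("A1", value=0.9 * c0 * (1 + 1 / xi_r) ** (b2_guess + dbeta),
                      min=1e-12)
                p.add("A2", value=0.1 * c0 * (1 + 1 / xi_r) ** b2_guess, min=1e-12)
                p.add("beta2", value=b2_guess, min=1.05, max=12)
                p.add("dbeta", value=dbeta, min=0, max=12)
                p.add("xi_r", value=xi_r, min=1e-3, max=1e4)
                starts.append(p)

    def report(res):
        b2 = res.params["beta2"].value
        db = res.params["dbeta"].value
        est = {"A1": res.params["A1"].value, "A2": res.params["A2"].value,
               "beta1": b2 + db, "beta2": b2, "xi_r": res.params["xi_r"].value}
        err = {k: _stderr(res, k) for k in ("A1", "A2", "beta2", "xi_r")}
        se_b2, se_db = _stderr(res, "beta2"), _stderr(res, "dbeta")
        err["beta1"] = None
        if se_b2 is not None and se_db is not None:
            cov = 0.0
            if res.covar is not None:
                names = [n for n in res.params if res.params[n].vary]
                i, j = names.index("beta2"), names.index("dbeta")
                cov = float(res.covar[i, j])
            err["beta1"] = math.sqrt(max(se_b2 ** 2 + se_db ** 2 + 2 * cov, 0.0))
        return est, err

    result = _run_fit("shifted-double-power-law", predict, starts, hist, report)
    if result.success and result.params.get("beta1", 1) - result.params.get("beta2", 0) < 1e-3:
        result.message = (result.message + "; degenerate fit: beta1 ~= beta2").strip("; ")
    return result


def fit_power_law(hist: DegreeHistogram) -> FitResult:
    """Fit a pure power law ``A xi^-c`` (the PL comparator)."""
    def predict(x, p):
        return p["A"].value * x ** (-p["c"].value)

    c0 = float(hist.count[0])
    starts = []
    for c in (1.5, 2.5, 4.0):
        p = lmfit.Parameters()
        p.add("A", value=c0, min=1e-12)
        p.add("c", value=c, min=0, max=12)
        starts.append(p)

    def report(res):
        est = {"A": res.params["A"].value, "c": res.params["c"].value}
        return est, {k: _stderr(res, k) for k in est}

    return _run_fit("power-law", predict, starts, hist, report)


def fit_power_law_cutoff(hist: DegreeHistogram) -> FitResult:
    """Fit a generalized power law with exponential cut-off (PL-EC).

    ``A (xi + c1)^{-c2} exp(-xi/c3)``; nests the pure power law at
    c1 = 0, c3 -> infinity.
    """
    def predict(x, p):
        return (p["A"].value * (x + p["c1"].value) ** (-p["c2"].value)
                * np.exp(-x / p["c3"].value))

    c0 = float(hist.count[0])
    xmax = float(hist.abscissa[-1])
    starts = []
    for c2 in (1.5, 3.0):
        for c3 in (5.0 * xmax, 50.0 * xmax):
            p = lmfit.Parameters()
            p.add("A", value=c0, min=1e-12)
            p.add("c1", value=1.0, min=0, max=1e3)
            p.add("c2", value=c2, min=0, max=12)
            p.add("c3", value=c3, min=1e-2, max=1e8)
            starts.append(p)

    def report(res):
        est = {k: res.params[k].value for k in ("A", "c1", "c2", "c3")}
        return est, {k: _stderr(res, k) for k in est}

    return _run_fit("power-law-cutoff", predict, starts, hist, report)


def fit_double_exponential(hist: DegreeHistogram) -> FitResult:
    """Fit the double-exponential comparator ``A1 e^{-e1 xi} + A2 e^{-e2 xi}``.

    e1 >= e2 enforced via e1 = e2 + de, de >= 0 (same anti-label-switching
    trick as the main fit).
    """
    def predict(x, p):
        e2 = p["eps2"].value
        e1 = e2 + p["deps"].value
        return p["A1"].value * np.exp(-e1 * x) + p["A2"].value * np.exp(-e2 * x)

    c0 = float(hist.count[0])
    xmax = float(hist.abscissa[-1])
    starts = []
    for e2 in (0.5 / xmax, 5.0 / xmax):
        for de in (0.3, 1.0):
            p = lmfit.Parameters()
            p.add("A1", value=0.9 * c0, min=1e-12)
            p.add("A2", value=0.1 * c0, min=1e-12)
            p.add("eps2", value=e2, min=1e-9, max=1e3)
            p.add("deps", value=de, min=0, max=1e3)
            starts.append(p)

    def report(res):
        e2 = res.params["eps2"].value
        est = {"A1": res.params["A1"].value, "A2": res.params["A2"].value,
               "eps1": e2 + res.params["deps"].value, "eps2": e2}
        err = {"A1": _stderr(res, "A1"), "A2": _stderr(res, "A2"),
               "eps1": None, "eps2": _stderr(res, "eps2")}
        se_e2, se_de = _stderr(res, "eps2"), _stderr(res, "deps")
        if se_e2 is not None and se_de is not None:
            err["eps1"] = math.sqrt(se_e2 ** 2 + se_de ** 2)
        return est, err

    return _run_fit("double-exponential", predict, starts, hist, report)


# ---------------------------------------------------------------------------
# link-law fit
# ---------------------------------------------------------------------------

def fit_links_model(data: Sequence[InteractomeSummary] | pd.DataFrame) -> FitResult:
    """Ordinary least squares of L on (N, N(N-1)/2) across interactomes.

    The link law is linear in (p1, p2), so the fit is the exact solution of
    the normal equations; repeated calls are bitwise identical. Standard
    errors come from the usual linear-model covariance.
    """
    if isinstance(data, pd.DataFrame):
        N = data["N_inf"].to_numpy(dtype=float)
        L = data["L"].to_numpy(dtype=float)
    else:
        N = np.array([s.N_inf for s in data], dtype=float)
        L = np.array([s.L for s in data], dtype=float)
    if N.size < 2:
        raise ValueError("need at least 2 (N, L) pairs")
    X = np.column_stack([N, N * (N - 1.0) / 2.0])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < 2:
        raise np.linalg.LinAlgError("collinear design: N values do not separate "
                                    "the linear and quadratic terms")
    coef = np.linalg.solve(xtx, X.T @ L)
    pred = X @ coef
    resid = L - pred
    dof = N.size - 2
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.array([math.nan, math.nan])
    mre, corr = goodness_metrics(L, pred)
    est = {"p1": float(coef[0]), "p2": float(coef[1])}
    err = {"p1": float(se[0]), "p2": float(se[1])}
    pct = {k: (100.0 * err[k] / abs(v) if v else None) for k, v in est.items()}
    return FitResult("link-law", est, err, pct, mre, corr, True,
                     "closed-form OLS", int(N.size))


# ---------------------------------------------------------------------------
# synthetic degree sampling
# ---------------------------------------------------------------------------

def sample_degrees(obs: ObservableParameters, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw n integer degrees (>= 1) from the model distribution.

    Each shifted power law is a Lomax density on xi >= 0 with shape
    ``beta_i - 1`` and scale ``xi_r``; component masses are
    ``A_i xi_r/(beta_i - 1)``. Continuous inverse-CDF draws are rounded to
    the nearest integer, so integer degree d represents xi in
    (d-1/2, d+1/2] and a histogram of the draws aligns with the density
    evaluated at integer abscissas; draws that round to zero (fractional
    degrees below 1/2) are non-interacting and redrawn.
    """
    if obs.beta1 <= 1 or obs.beta2 <= 1:
        raise ValueError("need beta_i > 1 for normalizable components")
    m1 = obs.A1 * obs.xi_r / (obs.beta1 - 1.0)
    m2 = obs.A2 * obs.xi_r / (obs.beta2 - 1.0)
    out: list[int] = []
    while len(out) < n:
        k = n - len(out)
        comp = rng.random(k) < m1 / (m1 + m2)
        shape = np.where(comp, obs.beta1 - 1.0, obs.beta2 - 1.0)
        xi = obs.xi_r * ((1.0 - rng.random(k)) ** (-1.0 / shape) - 1.0)
        d = np.rint(xi).astype(int)
        out.extend(d[d >= 1].tolist())
    return np.asarray(out[:n], dtype=int)
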