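"""Weighted sum-of-exponentials fitting with a physical-decay rate floor.

The fitted function is f(t) = sum_i A_i exp(-lambda_i t) where every
effective rate constant lambda_i = lambda_bio,i + lambda_phys is bounded
below by the physical decay constant of the nuclide.  Three candidate
forms are supported:

* ``mono``       A exp(-lambda t)                       (2 free parameters)
* ``bi``         A1 exp(-l1 t) + A2 exp(-l2 t), A_i>=0  (4)
* ``bi_uptake``  A (exp(-l1 t) - exp(-l2 t)), l2>l1     (3), f(0)=0

Fits minimise the weighted residual sum of squares with per-point sigmas
taken from the curve; the covariance of the free parameters is the inverse
Gauss-Newton normal matrix of the sigma-weighted Jacobian (known-sigma
convention, no reduced-chi-square rescaling).  Model selection is by the
corrected Akaike information criterion, ties broken toward fewer
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .curves import TimeActivityCurve

__all__ = [
    "LU177_HALF_LIFE_H",
    "LU177_LAMBDA_PHYS",
    "CANDIDATE_FORMS",
    "ExponentialModel",
    "FitResult",
    "FitError",
    "InsufficientPointsError",
    "model_from_params",
    "n_free_params",
    "initial_params",
    "fit_candidates",
    "select_model",
    "aicc",
]

#: Lu-177 physical half-life, hours (6.647 d)
LU177_HALF_LIFE_H = 6.647 * 24.0
#: Lu-177 physical decay constant, 1/h
LU177_LAMBDA_PHYS = math.log(2.0) / LU177_HALF_LIFE_H

CANDIDATE_FORMS = ("mono", "bi", "bi_uptake")

#: free-parameter count per candidate form
_N_PARAMS = {"mono": 2, "bi": 4, "bi_uptake": 3}

#: absolute sigma floor (curve units) guarding against infinite weights
SIGMA_FLOOR = 1e-9

#: rate-floor slack used when validating models (floating-point headroom)
_RATE_TOL = 1e-12


class FitError(RuntimeError):
    """No candidate converged; carries per-candidate diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientPointsError(FitError):
    """Curve has too few points for every requested candidate."""


@dataclass(frozen=True)
class ExponentialModel:
    """Sum of exponentials with effective rates bounded by physical decay.

    ``terms`` are (amplitude, effective rate 1/h) pairs.  An uptake model
    is represented with a negative amplitude on the faster term, so
    f(0) ~ 0 and f(t) >= 0 everywhere.
    """

    terms: tuple[tuple[float, float], ...]
    lambda_phys: float = LU177_LAMBDA_PHYS

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 2:
            raise ValueError(f"model must have 1 or 2 terms, got {len(self.terms)}")
        for _, lam in self.terms:
            if lam < self.lambda_phys - _RATE_TOL:
                raise ValueError(
                    f"effective rate {lam} below physical decay constant {self.lambda_phys}"
                )
        if self.value_at_zero < -1e-9 * self.amplitude_scale:
            raise ValueError("model is negative at t=0")
        negatives = [(a, l) for a, l in self.terms if a < 0]
        if negatives:
            # a negative amplitude must belong to the fastest term, else f<0 at large t
            (a_neg, l_neg), = negatives
            if any(l >= l_neg for a, l in self.terms if a > 0):
                raise ValueError("negative-amplitude term must have the largest rate")

    @property
    def value_at_zero(self) -> float:
        return sum(a for a, _ in self.terms)

    @property
    def amplitude_scale(self) -> float:
        return max(abs(a) for a, _ in self.terms)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in self.terms:
            out = out + a * np.exp(-lam * t)
        return out


@dataclass(frozen=True)
class FitResult:
    """A converged fit: model, free parameters, covariance and AICc.

    ``params`` holds the canonical free-parameter vector of ``form``
    (mono: A, l; bi: A1, l1, A2, l2 with l1 > l2; bi_uptake: A, l1, l2
    with l2 > l1) and ``covariance`` is in the same coordinates.
    """

    model: ExponentialModel
    form: str
    params: np.ndarray
    covariance: np.ndarray
    aicc: float
    n_points: int
    weights_cv: float | None = None
    converged: bool = True
    species: str | None = None
    region: str | None = None
    unit: str | None = None
    cost: float = float("nan")

    def __post_init__(self) -> None:
        k = n_free_params(self.form)
        if self.n_points < k + 1:
            raise ValueError(f"{self.form}: need >= {k + 1} points, got {self.n_points}")
        c = np.asarray(self.covariance, dtype=float)
        if c.shape != (k, k):
            raise ValueError(f"covariance shape {c.shape} != ({k}, {k})")
        eig = np.linalg.eigvalsh((c + c.T) / 2.0)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("covariance is not positive semi-definite")

    @property
    def group(self) -> str:
        return f"{self.species}/{self.region}"


def n_free_params(form: str) -> int:
    try:
        return _N_PARAMS[form]
    except KeyError:
        raise ValueError(f"unknown model form {form!r}") from None


def model_from_params(form: str, params: Sequence[float], lambda_phys: float = LU177_LAMBDA_PHYS) -> ExponentialModel:
    """Build an ExponentialModel from a canonical free-parameter vector."""
    p = [float(v) for v in params]
    if form == "mono":
        (a, lam) = p
        terms = ((a, lam),)
    elif form == "bi":
        a1, l1, a2, l2 = p
        terms = ((a1, l1), (a2, l2))
    elif form == "bi_uptake":
        a, l1, l2 = p
        if l2 <= l1:
            raise ValueError("bi_uptake requires l2 > l1")
        terms = ((a, l1), (-a, l2))
    else:
        raise ValueError(f"unknown model form {form!r}")
    return ExponentialModel(terms=terms, lambda_phys=lambda_phys)


def aicc(ssr: float, n: int, k: int) -> float:
    """Corrected Akaike criterion for least squares with n points, k parameters.

    The weighted SSR is floored to keep the criterion finite on noiseless
    data, where both candidates reach machine-zero residuals and only the
    parameter-count penalty should decide.
    """
    if n - k - 1 <= 0:
        return float("inf")
    ssr = max(float(ssr), n * 1e-24)
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------- starts


def _loglinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-linear regression y ~ A exp(-lam t); returns (A, lam)."""
    res = linregress(t, np.log(y))
    return float(math.exp(res.intercept)), float(-res.slope)


def initial_params(curve: TimeActivityCurve, form: str, lambda_phys: float = LU177_LAMBDA_PHYS) -> np.ndarray:
    """Curve-peeling start values for a candidate form.

    The slow term comes from a log-linear regression on the tail; the fast
    term from a log-linear fit to the positive early residual.  Zero values
    are excluded from log steps; results are clipped into the fit bounds.
    """
    t, y = curve.t, curve.y
    pos = y > 0
    if not pos.any():
        raise FitError(f"{curve.group}: all values are zero, cannot initialize")
    tp, yp = t[pos], y[pos]
    n = len(tp)

    if n == 1:
        a_slow, l_slow = yp[0], 10.0 * lambda_phys
    else:
        n_tail = max(2, n // 2)
        a_slow, l_slow = _loglinear(tp[-n_tail:], yp[-n_tail:])
    l_slow = max(l_slow, lambda_phys)
    a_slow = max(a_slow, SIGMA_FLOOR)

    if form == "mono":
        if n >= 2:
            a_slow, l_slow = _loglinear(tp, yp)
        return np.array([max(a_slow, SIGMA_FLOOR), max(l_slow, lambda_phys)])

    # peel: residual of the early points above the slow component
    resid = yp - a_slow * np.exp(-l_slow * tp)
    early = resid > 0
    if early.sum() >= 2:
        a_fast, l_fast = _loglinear(tp[early], resid[early])
        l_fast = max(l_fast, 1.01 * l_slow)
        a_fast = max(a_fast, SIGMA_FLOOR)
    else:
        a_fast, l_fast = max(yp.max() - a_slow, 0.1 * a_slow), 10.0 * l_slow

    if form == "bi":
        return np.array([a_fast, l_fast, a_slow, l_slow])
    if form == "bi_uptake":
        # tail behaves like A exp(-l1 t); fast rate from the rising edge
        t_peak = tp[np.argmax(yp)]
        l2 = max(10.0 * l_slow, 2.0 / max(t_peak, 1e-6))
        return np.array([a_slow, l_slow, l2])
    raise ValueError(f"unknown model form {form!r}")


# ----------------------------------------------------------------- fitting


def _pack(form: str, params: np.ndarray) -> np.ndarray:
    """Canonical params -> internal optimizer coordinates."""
    if form == "bi_uptake":
        a, l1, l2 = params
        return np.array([a, l1, l2 - l1])
    return np.asarray(params, dtype=float)


def _unpack(form: str, x: np.ndarray) -> np.ndarray:
    if form == "bi_uptake":
        a, l1, d = x
        return np.array([a, l1, l1 + d])
    return np.asarray(x, dtype=float)


def _bounds(form: str, lambda_phys: float):
    inf = np.inf
    if form == "mono":
        return ([0.0, lambda_phys], [inf, inf])
    if form == "bi":
        return ([0.0, lambda_phys, 0.0, lambda_phys], [inf, inf, inf, inf])
    if form == "bi_uptake":
        # internal coords (A, l1, delta); delta > 0 keeps l2 > l1
        return ([0.0, lambda_phys, 1e-10], [inf, inf, inf])
    raise ValueError(f"unknown model form {form!r}")


def _residual_fn(form: str, t: np.ndarray, y: np.ndarray, sig: np.ndarray, lambda_phys: float):
    def resid(x):
        p = _unpack(form, x)
        m = model_from_params(form, p, lambda_phys)
        return (y - m(t)) / sig

    return resid


def _canonicalize(form: str, params: np.ndarray) -> np.ndarray:
    """Order bi terms fast-first so the parameter labelling is unique."""
    if form == "bi" and params[1] < params[3]:
        return np.array([params[2], params[3], params[0], params[1]])
    return params


def _covariance(form: str, jac: np.ndarray) -> np.ndarray:
    """Inverse Gauss-Newton normal matrix, mapped to canonical coordinates."""
    jtj = jac.T @ jac
    cov = np.linalg.pinv(jtj, hermitian=True)
    if form == "bi_uptake":
        # internal (A, l1, delta) -> canonical (A, l1, l2=l1+delta)
        tmat = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        cov = tmat @ cov @ tmat.T
    return (cov + cov.T) / 2.0


def _fit_one(
    curve: TimeActivityCurve,
    form: str,
    lambda_phys: float,
    n_starts: int,
    seed: int,
) -> FitResult | None:
    t, y = curve.t, curve.y
    sig = np.maximum(curve.sigma, SIGMA_FLOOR)
    k = n_free_params(form)
    n = len(t)
    lo, hi = _bounds(form, lambda_phys)
    resid = _residual_fn(form, t, y, sig, lambda_phys)

    x0 = _pack(form, initial_params(curve, form, lambda_phys))
    x0 = np.clip(x0, np.asarray(lo) + 1e-12, None)

    rng = np.random.default_rng(seed)
    # multi-start: log-uniform perturbations of the peeled start (first start exact)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        factor = 10.0 ** rng.uniform(-0.5, 0.5, size=k)
        starts.append(np.clip(x0 * factor, np.asarray(lo) + 1e-12, None))

    best = None
    for x in starts:
        try:
            sol = least_squares(
                resid, x, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        if sol.status <= 0:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None

    params = _canonicalize(form, _unpack(form, best.x))
    ssr = 2.0 * best.cost
    jac = best.jac
    if form == "bi" and not np.array_equal(params, _unpack(form, best.x)):
        # swap Jacobian columns to match the fast-first ordering
        jac = jac[:, [2, 3, 0, 1]]
    cov = _covariance(form, jac)
    model = model_from_params(form, params, lambda_phys)
    cv = None
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = sig / np.where(y > 0, y, np.nan)
    if np.all(np.isfinite(rel)) and np.allclose(rel, rel[0], rtol=1e-6):
        cv = float(rel[0])
    return FitResult(
        model=model,
        form=form,
        params=params,
        covariance=cov,
        aicc=aicc(ssr, n, k),
        n_points=n,
        weights_cv=cv,
        converged=True,
        species=curve.species,
        region=curve.region,
        unit=curve.unit,
        cost=ssr,
    )


def fit_candidates(
    curve: TimeActivityCurve,
    lambda_phys: float = LU177_LAMBDA_PHYS,
    candidates: Iterable[str] = CANDIDATE_FORMS,
    n_starts: int = 20,
    seed: int = 0,
) -> list[FitResult]:
    """Fit every candidate form to a curve by weighted least squares.

    Returns one FitResult per candidate that converged.  Candidates with
    fewer points than free parameters + 1 are skipped; if that removes all
    of them an InsufficientPointsError is raised, and if no remaining
    candidate converges a FitError with per-candidate diagnostics is
    raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate forms given")
    n = len(curve.samples)
    feasible = [f for f in candidates if n >= n_free_params(f) + 1]
    if not feasible:
        raise InsufficientPointsError(
            f"{curve.group}: {n} points cannot support any of {candidates} "
            f"(need >= free parameters + 1)"
        )
    results, diagnostics = [], {}
    for form in feasible:
        fit = _fit_one(curve, form, lambda_phys, n_starts, seed)
        if fit is None:
            diagnostics[form] = "did not converge"
        else:
            results.append(fit)
    if not results:
        raise FitError(f"{curve.group}: no candidate converged", diagnostics)
    return results


def select_model(fits: Sequence[FitResult], tie_tol: float = 0.01) -> FitResult:
    """Pick the fit with minimal AICc; near-ties go to the simpler model."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise FitError("select_model: no converged fits")
    best = min(fits, key=lambda f: f.aicc)
    contenders = [f for f in fits if abs(f.aicc - best.aicc) < tie_tol]
    return min(contenders, key=lambda f: (n_free_params(f.form), f.aicc))
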