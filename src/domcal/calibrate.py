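"""Minimum chi-square calibration of design weights to domain auxiliary
totals, and the four resulting weight systems.

Starting from design weights d_i, calibration seeks new weights t_i that
minimise the chi-square distance sum (t_i - d_i)^2 / (2 d_i q_i) subject to
the auxiliary constraint sum t_i x_i = X (the domain's known auxiliary
total), separately for the respondent stratum (target X1a) and the
subsampled non-respondent stratum (target X2a).  The Lagrangian solution is

    t_i = d_i (1 + l q_i x_i),     l = (X - sum d x) / sum d q x^2.

The q-weights select the estimator family:

* ``unit``        q_i = 1      -> GREG (generalized regression),
* ``inverse_x``   q_i = 1/x_i  -> ratio estimator t_i = d_i X / sum d x,
* ``exponential`` t_i = d_i exp(l x_i), l solved by Newton-Raphson so the
  constraint holds (an exponential-tilting / raking weight system),
* ``power``       t_i = d_i eta^{x_i}; writing eta = exp(l) this is the
  same one-parameter family, solved in log space.

Domain estimation is *indirect*: the calibration sums run over the full
respondent sample and full non-respondent subsample — not just the units
falling in the domain — borrowing strength from surrounding units when few
sampled units land in a small domain.  A direct (domain-restricted) mode is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleRealization, base_weights
from .popgen import DomainTotals, PopulationFrame

LINEAR_POLICIES = ("unit", "inverse_x")
NONLINEAR_POLICIES = ("exponential", "power")

#: Estimator names in presentation order.
ESTIMATORS = ("base", "ratio", "greg", "exponential", "power")

#: q-policy behind each calibrated estimator.
POLICY_OF_ESTIMATOR = {
    "ratio": "inverse_x",
    "greg": "unit",
    "exponential": "exponential",
    "power": "power",
}


class CalibrationError(RuntimeError):
    """Raised when a calibration solve is degenerate or fails to converge."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Settings of a single-domain calibration."""

    q_policy: str = "unit"
    tolerance: float = 1e-10
    max_iter: int = 100

    def __post_init__(self):
        if self.q_policy not in LINEAR_POLICIES + NONLINEAR_POLICIES:
            raise ValueError(f"unknown q_policy {self.q_policy!r}")
        if self.tolerance <= 0 or self.max_iter < 1:
            raise ValueError("tolerance must be > 0 and max_iter >= 1")


@dataclass
class StratumCalibration:
    """Calibrated weights of one stratum with solve diagnostics."""

    t: np.ndarray
    multiplier: float          # l (linear/exponential) or eta (power)
    iterations: int
    converged: bool
    residual: float            # relative constraint residual
    n_negative: int = 0


@dataclass
class CalibratedWeights:
    """Respondent and non-respondent calibrated weights for one domain."""

    resp: StratumCalibration | None
    nonresp: StratumCalibration | None
    policy: str

    @property
    def converged(self) -> bool:
        parts = [p for p in (self.resp, self.nonresp) if p is not None]
        return all(p.converged for p in parts)

    @property
    def n_negative(self) -> int:
        return sum(p.n_negative for p in (self.resp, self.nonresp)
                   if p is not None)


@dataclass(frozen=True)
class DomainEstimate:
    """Estimated total of one domain by one estimator."""

    domain: object
    estimator: str
    value: float
    converged: bool = True
    degenerate: bool = False
    n_negative: int = 0
    error: str | None = None


def q_weights(x: np.ndarray, policy: str) -> np.ndarray:
    """q-vector of a linear policy: all ones, or elementwise 1/x."""
    x = np.asarray(x, dtype=float)
    if policy == "unit":
        return np.ones_like(x)
    if policy == "inverse_x":
        if np.any(x <= 0):
            raise ValueError("inverse_x policy requires strictly positive x")
        return 1.0 / x
    if policy in NONLINEAR_POLICIES:
        raise ValueError(
            f"policy {policy!r} has no closed-form q vector; use the "
            "dedicated solver (calibrate_stratum)"
        )
    raise ValueError(f"unknown q policy {policy!r}")


def solve_linear_multiplier(d, q, x, target: float) -> float:
    """Closed-form Lagrange multiplier of the linear calibration.

    l = (target - sum d x) / sum d q x^2.
    """
    d, q, x = (np.asarray(v, dtype=float) for v in (d, q, x))
    denom = float(np.sum(d * q * x * x))
    # Negative denominators arise legitimately when chaining calibrations
    # (phase-2 base weights may be negative GREG weights); the closed form
    # only degenerates when the denominator vanishes.
    if denom == 0 or not np.isfinite(denom):
        raise CalibrationError("degenerate calibration: sum d q x^2 == 0")
    return (float(target) - float(np.sum(d * x))) / denom


def linear_calibrated_weights(d, q, x, l: float) -> np.ndarray:
    """Calibrated weights t_i = d_i (1 + l q_i x_i)."""
    d, q, x = (np.asarray(v, dtype=float) for v in (d, q, x))
    return d * (1.0 + l * q * x)


def solve_exponential_multiplier(d, x, target: float, tolerance: float = 1e-10,
                                 max_iter: int = 100) -> tuple[float, int]:
    """Solve sum d_i x_i exp(l x_i) = target for l by Newton-Raphson.

    The constraint function is strictly increasing and convex in l, so
    Newton from l = 0 converges globally; a bisection fallback on a
    sign-bracketing interval guards pathological cases.  x is rescaled by
    its maximum internally to avoid overflow on skewed auxiliaries.

    Returns ``(l, iterations)``.
    """
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    target = float(target)
    if np.any(d <= 0) or np.any(x <= 0):
        raise CalibrationError("exponential solve requires positive d and x")
    if target <= 0:
        raise CalibrationError("exponential solve requires a positive target")

    xmax = float(x.max())
    u = x / xmax  # in (0, 1]

    def f(m):
        with np.errstate(over="ignore"):
            return float(np.sum(d * x * np.exp(m * u))) - target

    def fprime(m):
        with np.errstate(over="ignore"):
            return float(np.sum(d * x * u * np.exp(m * u)))

    m = 0.0
    for it in range(1, max_iter + 1):
        fm = f(m)
        if abs(fm) <= tolerance * target:
            return m / xmax, it
        step = fm / fprime(m)
        m_new = m - step
        if not np.isfinite(m_new):
            break
        m = m_new
    # Bisection fallback on a wide bracket in the scaled variable.
    lo, hi = -745.0, 745.0  # exp under/overflow bounds for float64
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"no root in bracket: residuals ({flo:g}, {fhi:g}); "
            f"last l={m / xmax:g}"
        )
    for it2 in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tolerance * target:
            return mid / xmax, max_iter + it2 + 1
        if fm < 0:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"exponential solve did not converge; last residual {fm:g}"
    )


def solve_power_parameter(d, x, target: float, tolerance: float = 1e-10,
                          max_iter: int = 100) -> tuple[float, int]:
    """Solve sum d_i x_i eta^{x_i} = target for the base eta > 0.

    Solved in log space: eta = exp(l) with l from the exponential solve —
    the two one-parameter weight systems are a change of variables apart.

    Returns ``(eta, iterations)``.
    """
    l, it = solve_exponential_multiplier(d, x, target, tolerance, max_iter)
    return float(np.exp(l)), it


def calibrate_stratum(d, x, target: float, policy: str,
                      tolerance: float = 1e-10,
                      max_iter: int = 100) -> StratumCalibration:
    """Calibrate one stratum's weights to its auxiliary target.

    Dispatches on the q-policy: closed-form multiplier for ``unit`` and
    ``inverse_x``; Newton-Raphson solve for ``exponential`` and ``power``.
    """
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(d) == 0:
        raise CalibrationError("cannot calibrate an empty stratum")
    if policy in LINEAR_POLICIES:
        q = q_weights(x, policy)
        l = solve_linear_multiplier(d, q, x, target)
        t = linear_calibrated_weights(d, q, x, l)
        mult, iters = l, 1
    elif policy == "exponential":
        l, iters = solve_exponential_multiplier(d, x, target, tolerance, max_iter)
        t = d * np.exp(l * x)
        mult = l
    elif policy == "power":
        eta, iters = solve_power_parameter(d, x, target, tolerance, max_iter)
        with np.errstate(over="raise"):
            t = d * np.power(eta, x)
        mult = eta
    else:
        raise ValueError(f"unknown q policy {policy!r}")
    residual = abs(float(np.sum(t * x)) - target) / abs(target)
    return StratumCalibration(
        t=t, multiplier=float(mult), iterations=iters,
        converged=residual <= max(tolerance, 1e-8),
        residual=residual, n_negative=int(np.sum(t < 0)),
    )


def domain_estimate(y1, t1, y2, t2, domain, name: str,
                    converged: bool = True,
                    degenerate: bool = False,
                    n_negative: int = 0) -> DomainEstimate:
    """Weighted total sum t1*y1 + sum t2*y2 as a DomainEstimate."""
    y1, t1 = np.asarray(y1, dtype=float), np.asarray(t1, dtype=float)
    if y1.shape != t1.shape:
        raise ValueError("respondent y and weights misaligned")
    value = float(np.sum(t1 * y1))
    if y2 is not None and len(np.asarray(y2)) > 0:
        y2, t2 = np.asarray(y2, dtype=float), np.asarray(t2, dtype=float)
        if y2.shape != t2.shape:
            raise ValueError("non-respondent y and weights misaligned")
        value += float(np.sum(t2 * y2))
    return DomainEstimate(domain=domain, estimator=name, value=value,
                          converged=converged, degenerate=degenerate,
                          n_negative=n_negative)


def calibrate_domain(d1, x1, d2, x2, target1: float, target2: float,
                     policy: str, tolerance: float = 1e-10,
                     max_iter: int = 100) -> CalibratedWeights:
    """Calibrate both strata of one domain.

    ``d2``/``x2`` may be empty (no non-respondents in the replicate); the
    non-respondent constraint is then skipped and only the respondent side
    is calibrated.
    """
    resp = calibrate_stratum(d1, x1, target1, policy, tolerance, max_iter)
    nonresp = None
    if len(np.asarray(d2)) > 0:
        nonresp = calibrate_stratum(d2, x2, target2, policy, tolerance, max_iter)
    return CalibratedWeights(resp=resp, nonresp=nonresp, policy=policy)


def estimate_all(r: SampleRealization, frame: PopulationFrame,
                 totals: DomainTotals,
                 estimators=ESTIMATORS,
                 tolerance: float = 1e-10, max_iter: int = 100,
                 direct: bool = False) -> list[DomainEstimate]:
    """All requested estimators for every domain on one realization.

    For each domain the base weights of the full respondent sample and full
    non-respondent subsample are calibrated to that domain's (X1a, X2a)
    and the calibrated weighted total of y is returned (indirect
    estimation).  With ``direct=True`` the sums are restricted to units of
    the domain itself.  Solver failures are captured per (domain,
    estimator) cell; the batch continues.
    """
    w = base_weights(r, frame.n_units)
    degenerate = r.n2 == 0
    out: list[DomainEstimate] = []
    for dom in totals.domains:
        row = totals.row(dom)
        if direct:
            in1 = frame.domain[r.s1] == dom
            in2 = frame.domain[r.s2r] == dom
            s1, s2r = r.s1[in1], r.s2r[in2]
        else:
            s1, s2r = r.s1, r.s2r
        y1, x1 = frame.y[s1], frame.x[s1]
        y2, x2 = frame.y[s2r], frame.x[s2r]
        d1 = w.respondent_weights(len(s1))
        d2 = w.nonrespondent_weights(len(s2r))

        exp_cw: CalibratedWeights | None = None
        for est in estimators:
            if est == "base":
                # Direct Hansen-Hurwitz domain total: design weights over
                # the domain's own sampled units only.
                b1 = frame.domain[r.s1] == dom
                b2 = frame.domain[r.s2r] == dom
                out.append(domain_estimate(
                    frame.y[r.s1][b1], w.respondent_weights(int(b1.sum())),
                    frame.y[r.s2r][b2],
                    w.nonrespondent_weights(int(b2.sum())),
                    dom, "base", degenerate=degenerate))
                continue
            policy = POLICY_OF_ESTIMATOR[est]
            try:
                if est == "power" and exp_cw is not None:
                    # eta = exp(l): same weight system, so reuse the
                    # exponential solve instead of repeating Newton.
                    cw = _power_from_exponential(exp_cw)
                else:
                    cw = calibrate_domain(
                        d1, x1, d2, x2, row["X1a"], row["X2a"],
                        policy, tolerance, max_iter)
                    if est == "exponential":
                        exp_cw = cw
            except CalibrationError as exc:
                out.append(DomainEstimate(
                    domain=dom, estimator=est, value=float("nan"),
                    converged=False, degenerate=degenerate, error=str(exc)))
                continue
            t2 = cw.nonresp.t if cw.nonresp is not None else d2[:0]
            out.append(domain_estimate(
                y1, cw.resp.t, y2, t2, dom, est,
                converged=cw.converged, degenerate=degenerate,
                n_negative=cw.n_negative))
    return out


def _power_from_exponential(cw: CalibratedWeights) -> CalibratedWeights:
    """Re-express an exponential calibration as the power system."""
    def convert(p: StratumCalibration | None):
        if p is None:
            return None
        return StratumCalibration(
            t=p.t, multiplier=float(np.exp(p.multiplier)),
            iterations=p.iterations, converged=p.converged,
            residual=p.residual, n_negative=p.n_negative)
    return CalibratedWeights(resp=convert(cw.resp),
                             nonresp=convert(cw.nonresp), policy="power")


def estimates_to_frame(estimates: list[DomainEstimate]) -> pd.DataFrame:
    """Tabulate DomainEstimates in the estimates-CSV dialect."""
    return pd.DataFrame(
        [{"domain": e.domain, "estimator": e.estimator, "value": e.value,
          "converged": e.converged, "degenerate": e.degenerate}
         for e in estimates]
    )
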