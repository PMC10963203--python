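"""Two-phase (double) sampling calibration for unknown domain auxiliary
totals.

When the domain totals X1a/X2a of the auxiliary are not available, a large
first-phase sample (here: per-domain SRSWOR of a fixed fraction of each
domain) measures x; its Hansen-Hurwitz weighted domain totals x1a', x2a'
stand in for the unknown targets.  First-phase weights are calibrated to
those targets, a second-phase subsample is drawn from the first-phase
sample, and second-phase weights — first-phase calibrated weight times the
conditional design weight — are calibrated to the same targets.  The four
weight systems (ratio, GREG, exponential, power) apply at both phases.

First-phase calibration is treated as defining a weight *function* of x
(design weight times the solved multiplier term), so it can be evaluated at
any second-phase unit; for respondents this coincides with the realized
first-phase weight, since phase-2 respondents are a subset of phase-1
respondents under the fixed-stratum response model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import (
    CalibrationError,
    CalibratedWeights,
    DomainEstimate,
    StratumCalibration,
    calibrate_stratum,
    domain_estimate,
)
from .design import (
    DesignError,
    SampleRealization,
    _as_rng,
    draw_srswor,
    realize_response,
    subsample_nonrespondents,
)
from .popgen import PopulationFrame


def weight_factor(x, policy: str, multiplier: float) -> np.ndarray:
    """Multiplicative adjustment t/d of a calibrated weight system at x."""
    x = np.asarray(x, dtype=float)
    if policy == "unit":
        return 1.0 + multiplier * x
    if policy == "inverse_x":
        return np.full_like(x, 1.0 + multiplier)
    if policy == "exponential":
        return np.exp(multiplier * x)
    if policy == "power":
        return np.power(multiplier, x)
    raise ValueError(f"unknown q policy {policy!r}")


@dataclass(frozen=True)
class TwoPhaseSample:
    """Nested two-phase realization with design weights.

    ``phase1`` is drawn per-domain (SRSWOR of round(fraction*Na) in each
    domain); ``d11`` holds the exact first-phase design weight Na/n'a for
    every sampled unit (NaN elsewhere), and ``phase1.k`` the non-respondent
    subsampling factor.  ``phase2`` is an SRSWOR subsample of the whole
    phase-1 sample with conditional weight ``d11pp`` = n'/n''.
    """

    phase1: SampleRealization
    d11: np.ndarray
    phase2: SampleRealization
    d11pp: float
    phase1_fraction: float

    def validate(self) -> None:
        if not set(self.phase2.s) <= set(self.phase1.s):
            raise ValueError("phase-2 sample must nest inside phase 1")


@dataclass
class Phase1Calibration:
    """Per-domain result of first-phase calibration.

    ``x1a_hat``/``x2a_hat`` are the phase-1 Hansen-Hurwitz domain totals of
    the auxiliary (the estimated calibration targets); ``resp``/``nonresp``
    the calibrated stratum weights over the full phase-1 respondent sample
    and non-respondent subsample.
    """

    domain: object
    policy: str
    x1a_hat: float
    x2a_hat: float
    resp: StratumCalibration
    nonresp: StratumCalibration | None
    estimable: bool = True

    def resp_weight_at(self, tp: TwoPhaseSample, frame: PopulationFrame,
                       units: np.ndarray) -> np.ndarray:
        """First-phase respondent weight function evaluated at units."""
        base = tp.d11[units]
        return base * weight_factor(frame.x[units], self.policy,
                                    self.resp.multiplier)

    def nonresp_weight_at(self, tp: TwoPhaseSample, frame: PopulationFrame,
                          units: np.ndarray) -> np.ndarray:
        """First-phase non-respondent weight function evaluated at units."""
        if self.nonresp is None:
            raise CalibrationError(
                f"domain {self.domain}: no phase-1 non-respondent calibration"
            )
        base = tp.d11[units] * tp.phase1.k
        return base * weight_factor(frame.x[units], self.policy,
                                    self.nonresp.multiplier)


def draw_two_phase(frame: PopulationFrame, phase1_fraction: float,
                   n_phase2: int, n2r_targets: tuple[int, int],
                   seed) -> TwoPhaseSample:
    """Draw a nested two-phase realization.

    Phase 1 takes round(fraction*Na) units per domain; phase 2 is an SRSWOR
    subsample of size ``n_phase2`` from the whole phase-1 sample.  Response
    realization and non-respondent subsampling (targets ``n2r_targets``)
    apply at each phase using the unit's fixed stratum.
    """
    if not 0 < phase1_fraction <= 1:
        raise DesignError("phase1_fraction must lie in (0, 1]")
    rng = _as_rng(seed)

    d11 = np.full(frame.n_units, np.nan)
    parts = []
    for dom in frame.domains:
        members = np.flatnonzero(frame.domain == dom)
        na = len(members)
        n1a = int(round(phase1_fraction * na))
        if n1a < 1:
            raise DesignError(f"phase-1 draw empty in domain {dom}")
        chosen = members[draw_srswor(na, n1a, rng)]
        d11[chosen] = na / n1a
        parts.append(chosen)
    s_p1 = np.sort(np.concatenate(parts))
    s1_p1, s2_p1 = realize_response(s_p1, frame)
    s2r_p1, k1 = subsample_nonrespondents(s2_p1, n2r_targets[0], rng)
    phase1 = SampleRealization(s=s_p1, s1=s1_p1, s2=s2_p1, s2r=s2r_p1, k=k1)

    if not 1 <= n_phase2 <= len(s_p1):
        raise DesignError(
            f"phase-2 size {n_phase2} infeasible for phase-1 sample "
            f"of {len(s_p1)}"
        )
    s_p2 = np.sort(rng.choice(s_p1, size=n_phase2, replace=False))
    s1_p2, s2_p2 = realize_response(s_p2, frame)
    s2r_p2, k2 = subsample_nonrespondents(s2_p2, n2r_targets[1], rng)
    phase2 = SampleRealization(s=s_p2, s1=s1_p2, s2=s2_p2, s2r=s2r_p2, k=k2)

    return TwoPhaseSample(phase1=phase1, d11=d11, phase2=phase2,
                          d11pp=len(s_p1) / n_phase2,
                          phase1_fraction=phase1_fraction)


def phase1_targets(tp: TwoPhaseSample, frame: PopulationFrame,
                   domain) -> tuple[float, float]:
    """Phase-1 Hansen-Hurwitz domain totals (x1a', x2a') of the auxiliary."""
    p1 = tp.phase1
    in1 = frame.domain[p1.s1] == domain
    x1a = float(np.sum(tp.d11[p1.s1][in1] * frame.x[p1.s1][in1]))
    x2a = 0.0
    if p1.n2r > 0:
        in2 = frame.domain[p1.s2r] == domain
        x2a = float(np.sum(tp.d11[p1.s2r][in2] * p1.k * frame.x[p1.s2r][in2]))
    return x1a, x2a


def phase1_calibrate(tp: TwoPhaseSample, frame: PopulationFrame,
                     policy: str, tolerance: float = 1e-10,
                     max_iter: int = 100) -> dict:
    """Calibrate phase-1 weights to the estimated domain targets.

    Returns a dict domain -> Phase1Calibration.  A domain whose phase-1
    respondent stratum is empty (target zero) is flagged non-estimable for
    this replicate.
    """
    p1 = tp.phase1
    d1 = tp.d11[p1.s1]
    x1 = frame.x[p1.s1]
    d2 = tp.d11[p1.s2r] * (p1.k if p1.n2r > 0 else 1.0)
    x2 = frame.x[p1.s2r]

    out = {}
    for dom in frame.domains:
        x1a_hat, x2a_hat = phase1_targets(tp, frame, dom)
        if x1a_hat <= 0 or len(d1) == 0:
            out[dom] = Phase1Calibration(
                domain=dom, policy=policy, x1a_hat=x1a_hat, x2a_hat=x2a_hat,
                resp=None, nonresp=None, estimable=False)
            continue
        resp = calibrate_stratum(d1, x1, x1a_hat, policy, tolerance, max_iter)
        nonresp = None
        if len(d2) > 0 and x2a_hat > 0:
            nonresp = calibrate_stratum(d2, x2, x2a_hat, policy,
                                        tolerance, max_iter)
        out[dom] = Phase1Calibration(
            domain=dom, policy=policy, x1a_hat=x1a_hat, x2a_hat=x2a_hat,
            resp=resp, nonresp=nonresp)
    return out


def phase2_calibrate(tp: TwoPhaseSample, frame: PopulationFrame,
                     p1cal: dict, policy: str | None = None,
                     tolerance: float = 1e-10,
                     max_iter: int = 100) -> dict:
    """Calibrate second-phase weights to the phase-1 targets.

    The phase-2 base weight of a unit is its first-phase calibrated weight
    (evaluated through the phase-1 weight function) times the conditional
    design weight n'/n'' (and the phase-2 subsampling factor for
    non-respondents).  Returns a dict domain -> CalibratedWeights over
    (phase2.s1, phase2.s2r).
    """
    p2 = tp.phase2
    out = {}
    for dom, p1c in p1cal.items():
        pol = policy or p1c.policy
        if not p1c.estimable:
            out[dom] = None
            continue
        b1 = p1c.resp_weight_at(tp, frame, p2.s1) * tp.d11pp
        x1 = frame.x[p2.s1]
        try:
            resp = calibrate_stratum(b1, x1, p1c.x1a_hat, pol,
                                     tolerance, max_iter)
            nonresp = None
            if p2.n2r > 0 and p1c.nonresp is not None and p1c.x2a_hat > 0:
                b2 = (p1c.nonresp_weight_at(tp, frame, p2.s2r)
                      * tp.d11pp * p2.k)
                nonresp = calibrate_stratum(b2, frame.x[p2.s2r],
                                            p1c.x2a_hat, pol,
                                            tolerance, max_iter)
            out[dom] = CalibratedWeights(resp=resp, nonresp=nonresp,
                                         policy=pol)
        except CalibrationError:
            out[dom] = None
    return out


def two_phase_estimates(tp: TwoPhaseSample, frame: PopulationFrame,
                        p2cal: dict, estimator: str) -> list[DomainEstimate]:
    """Weighted y-totals of the second-phase calibrated weights."""
    p2 = tp.phase2
    y1 = frame.y[p2.s1]
    y2 = frame.y[p2.s2r]
    out = []
    for dom, cw in p2cal.items():
        if cw is None:
            out.append(DomainEstimate(
                domain=dom, estimator=estimator, value=float("nan"),
                converged=False, degenerate=True,
                error="domain not estimable in this replicate"))
            continue
        t2 = cw.nonresp.t if cw.nonresp is not None else y2[:0]
        yy2 = y2 if cw.nonresp is not None else y2[:0]
        out.append(domain_estimate(
            y1, cw.resp.t, yy2, t2, dom, estimator,
            converged=cw.converged,
            degenerate=(p2.n2 == 0 or cw.nonresp is None),
            n_negative=cw.n_negative))
    return out


def two_phase_base_estimates(tp: TwoPhaseSample,
                             frame: PopulationFrame) -> list[DomainEstimate]:
    """Uncalibrated two-phase Hansen-Hurwitz domain totals (direct)."""
    p2 = tp.phase2
    out = []
    for dom in frame.domains:
        in1 = frame.domain[p2.s1] == dom
        s1 = p2.s1[in1]
        value = float(np.sum(tp.d11[s1] * tp.d11pp * frame.y[s1]))
        if p2.n2r > 0:
            # phase-2 subsample inclusion: phase-1 draw x phase-2 draw x
            # phase-2 subsampling; phase-1 subsampling is not involved
            in2 = frame.domain[p2.s2r] == dom
            s2r = p2.s2r[in2]
            value += float(np.sum(tp.d11[s2r] * tp.d11pp
                                  * p2.k * frame.y[s2r]))
        out.append(DomainEstimate(domain=dom, estimator="base", value=value,
                                  degenerate=p2.n2 == 0))
    return out
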