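"""Sampling mechanics: SRSWOR draws, response realization, and
Hansen-Hurwitz subsampling of non-respondents.

A sample s of size n is drawn by simple random sampling without
replacement.  The sample splits by the units' fixed response stratum into
respondents s1 (size n1) and non-respondents s2 (size n2).  An SRSWOR
subsample s2r of size n2r = n2/k is re-contacted; its responses are
up-weighted by k, giving the Hansen-Hurwitz estimator

    T_HH = sum_{s1} (N/n) y_i + sum_{s2r} (N/n) (n2/n2r) y_i,

which is design-unbiased for the population total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import PopulationFrame, RESPONDENT


class DesignError(ValueError):
    """Raised for infeasible sampling designs."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SampleRealization:
    """One drawn sample with its response split and subsample.

    All index arrays hold positions into the frame (0..N-1).  ``k`` is the
    subsampling factor n2/n2r, NaN when n2 = 0 (nothing to subsample).
    """

    s: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    s2r: np.ndarray
    k: float

    @property
    def n(self) -> int:
        return len(self.s)

    @property
    def n1(self) -> int:
        return len(self.s1)

    @property
    def n2(self) -> int:
        return len(self.s2)

    @property
    def n2r(self) -> int:
        return len(self.s2r)

    @property
    def n_star(self) -> int:
        """Observed units: respondents plus subsampled non-respondents."""
        return self.n1 + self.n2r

    def validate(self) -> None:
        if sorted(np.concatenate([self.s1, self.s2])) != sorted(self.s):
            raise ValueError("s1 and s2 must partition s")
        if not set(self.s2r) <= set(self.s2):
            raise ValueError("s2r must be a subset of s2")

    def to_dict(self) -> dict:
        return {
            "s": self.s.tolist(), "s1": self.s1.tolist(),
            "s2": self.s2.tolist(), "s2r": self.s2r.tolist(),
            "n": self.n, "n1": self.n1, "n2": self.n2, "n2r": self.n2r,
            "k": None if np.isnan(self.k) else self.k,
        }


@dataclass(frozen=True)
class DesignWeights:
    """Base design weights of a realization.

    ``d1 = N/n`` applies to every sampled unit; subsampled non-respondents
    carry the extra factor ``d2prime = n2/n2r``, so their total weight is
    ``d1 * d2prime``.
    """

    d1: float
    d2prime: float

    def respondent_weights(self, n1: int) -> np.ndarray:
        return np.full(n1, self.d1)

    def nonrespondent_weights(self, n2r: int) -> np.ndarray:
        return np.full(n2r, self.d1 * self.d2prime)


def draw_srswor(N: int, n: int, seed) -> np.ndarray:
    """Draw n distinct unit positions from 0..N-1, uniformly over subsets."""
    if n < 1 or n > N:
        raise DesignError(f"sample size {n} infeasible for population {N}")
    rng = _as_rng(seed)
    return np.sort(rng.choice(N, size=n, replace=False))


def realize_response(s: np.ndarray, frame: PopulationFrame):
    """Partition the sample by the units' fixed response stratum."""
    s = np.asarray(s)
    if np.any(s < 0) or np.any(s >= frame.n_units):
        raise ValueError("sample indices outside the frame")
    resp = frame.stratum[s] == RESPONDENT
    return s[resp], s[~resp]


def subsample_nonrespondents(s2: np.ndarray, n2r_target: int, seed):
    """SRSWOR subsample of the non-respondents, capped at n2.

    Returns ``(s2r, k)`` with ``k = n2/n2r``.  An empty s2 yields an empty
    subsample with ``k = NaN`` (flagged, not an error): the realization has
    no non-respondent term.
    """
    if n2r_target < 1:
        raise DesignError("n2r_target must be >= 1")
    s2 = np.asarray(s2)
    n2 = len(s2)
    if n2 == 0:
        return s2[:0], float("nan")
    n2r = min(int(n2r_target), n2)
    rng = _as_rng(seed)
    s2r = np.sort(rng.choice(s2, size=n2r, replace=False))
    return s2r, n2 / n2r


def base_weights(r: SampleRealization, N: int) -> DesignWeights:
    """Design weights d1 = N/n and d2' = n2/n2r for a realization."""
    if N < r.n:
        raise DesignError("population smaller than the sample")
    if r.n2 > 0 and r.n2r == 0:
        raise DesignError(
            "realization has non-respondents but no subsample; the "
            "non-respondent term is not estimable"
        )
    d2 = r.n2 / r.n2r if r.n2r > 0 else 1.0
    return DesignWeights(d1=N / r.n, d2prime=d2)


def draw_realization(frame: PopulationFrame, n: int, n2r_target: int,
                     rng) -> SampleRealization:
    """Draw a full single-phase realization: sample, response split,
    non-respondent subsample."""
    rng = _as_rng(rng)
    s = draw_srswor(frame.n_units, n, rng)
    s1, s2 = realize_response(s, frame)
    s2r, k = subsample_nonrespondents(s2, n2r_target, rng)
    return SampleRealization(s=s, s1=s1, s2=s2, s2r=s2r, k=k)


def hansen_hurwitz_total(r: SampleRealization, frame: PopulationFrame,
                         N: int | None = None) -> float:
    """Base (uncalibrated) Hansen-Hurwitz estimate of the population total."""
    N = frame.n_units if N is None else N
    w = base_weights(r, N)
    total = w.d1 * frame.y[r.s1].sum()
    if r.n2r > 0:
        total += w.d1 * w.d2prime * frame.y[r.s2r].sum()
    return float(total)
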