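"""Finite-population data model and synthetic population generator.

A population of ``N`` units is partitioned into ``L`` non-overlapping
domains (small areas).  Each unit carries a study value ``y``, a positive
auxiliary value ``x``, and a fixed response stratum: respondent (``R``) or
non-respondent (``NR``).  Domain-level totals of ``x`` split by stratum are
the calibration targets; domain totals of ``y`` are the estimation truth.

The synthetic generator emulates the structure of the Swedish-municipality
study population: six domains of sizes 48/32/38/41/15/29 (203 units),
right-skewed ``x``, ``y`` roughly proportional to ``x``, and about 30 % of
units in the non-respondent stratum of every domain.  The packaged
``table1.csv`` fixture holds the printed domain totals of that population.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

RESPONDENT = "R"
NONRESPONDENT = "NR"

TOTALS_COLUMNS = ["Na", "N1a", "N2a", "Ya", "Y1a", "Y2a", "Xa", "X1a", "X2a"]

#: Domain sizes of the study population (203 units in 6 domains).
DEFAULT_DOMAIN_SIZES = (48, 32, 38, 41, 15, 29)


class ConfigurationError(ValueError):
    """Raised when a population or design specification is infeasible."""


@dataclass(frozen=True)
class DomainTotals:
    """Per-domain unit counts and y/x totals, split by response stratum.

    Wraps a DataFrame indexed by domain label with columns
    ``Na, N1a, N2a, Ya, Y1a, Y2a, Xa, X1a, X2a`` (counts; study-variable
    totals; auxiliary totals; suffix 1 = respondent stratum, 2 =
    non-respondent stratum).
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TOTALS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DomainTotals missing columns: {missing}")

    @property
    def domains(self) -> list:
        return list(self.table.index)

    def row(self, domain) -> pd.Series:
        return self.table.loc[domain]

    def __add__(self, other: "DomainTotals") -> "DomainTotals":
        return DomainTotals(self.table.add(other.table, fill_value=0.0))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DomainTotals):
            return NotImplemented
        return self.table.equals(other.table)

    @classmethod
    def from_csv(cls, path) -> "DomainTotals":
        df = pd.read_csv(path).set_index("domain")
        return cls(df[TOTALS_COLUMNS].astype(float))

    def to_csv(self, path) -> None:
        self.table.rename_axis("domain").to_csv(path)


@dataclass(frozen=True)
class PopulationFrame:
    """Unit-level finite population: the sampling frame.

    Arrays are aligned by position (0..N-1); ``unit_id`` is a label.
    """

    unit_id: np.ndarray
    domain: np.ndarray
    y: np.ndarray
    x: np.ndarray
    stratum: np.ndarray  # "R" / "NR"

    def __post_init__(self):
        n = len(self.unit_id)
        for name in ("domain", "y", "x", "stratum"):
            if len(getattr(self, name)) != n:
                raise ValueError("PopulationFrame arrays must be aligned")
        if len(np.unique(self.unit_id)) != n:
            raise ValueError("unit_id values must be unique")
        if np.any(self.x <= 0):
            raise ValueError("auxiliary variable x must be positive")
        bad = set(np.unique(self.stratum)) - {RESPONDENT, NONRESPONDENT}
        if bad:
            raise ValueError(f"unknown strata: {sorted(bad)}")

    @property
    def n_units(self) -> int:
        return len(self.unit_id)

    @property
    def domains(self) -> list:
        return sorted(pd.unique(self.domain))

    def is_respondent(self) -> np.ndarray:
        return self.stratum == RESPONDENT

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_id, "domain": self.domain,
             "y": self.y, "x": self.x, "stratum": self.stratum}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationFrame":
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PopulationFrame":
        return cls(
            unit_id=df["unit_id"].to_numpy(),
            domain=df["domain"].to_numpy(),
            y=df["y"].to_numpy(dtype=float),
            x=df["x"].to_numpy(dtype=float),
            stratum=df["stratum"].to_numpy(dtype=object),
        )

    def concat(self, other: "PopulationFrame") -> "PopulationFrame":
        if set(self.unit_id) & set(other.unit_id):
            raise ValueError("cannot concatenate frames with shared unit ids")
        return PopulationFrame(
            unit_id=np.concatenate([self.unit_id, other.unit_id]),
            domain=np.concatenate([self.domain, other.domain]),
            y=np.concatenate([self.y, other.y]),
            x=np.concatenate([self.x, other.x]),
            stratum=np.concatenate([self.stratum, other.stratum]),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a synthetic finite population.

    Parameters
    ----------
    domain_sizes
        Unit count per domain.
    nonresponse_rate
        Fraction of each domain placed in the non-respondent stratum
        (scalar, or one value per domain).  The study population has ~30 %.
    x_skew_shape
        Log-scale standard deviation of the lognormal auxiliary variable;
        any positive value gives a right-skewed x.
    link_slope
        Slope beta of the ratio link y ~ beta * x.
    noise_scale
        Relative dispersion of y about beta*x, applied as mean-one
        multiplicative lognormal noise so y stays positive.  Zero gives the
        exactly proportional population y = beta * x.
    target_totals
        Optional DomainTotals; generated x and y are rescaled per domain
        and stratum so realized totals match X1a/X2a and Y1a/Y2a exactly.
    seed
        Integer seed; identical specs generate identical frames.
    """

    domain_sizes: tuple = DEFAULT_DOMAIN_SIZES
    nonresponse_rate: float | Sequence[float] = 0.3
    x_skew_shape: float = 1.0
    link_slope: float = 1.8
    noise_scale: float = 0.15
    target_totals: DomainTotals | None = None
    seed: int = 0
    x_scale: float = field(default=1000.0)

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(
            np.asarray(self.nonresponse_rate, dtype=float),
            (len(self.domain_sizes),),
        )
        return np.array(r)

    def validate(self) -> None:
        if len(self.domain_sizes) == 0:
            raise ConfigurationError("at least one domain is required")
        if any(int(na) < 1 for na in self.domain_sizes):
            raise ConfigurationError("all domain sizes must be >= 1")
        rates = self.rates()
        if np.any(rates <= 0) or np.any(rates >= 1):
            raise ConfigurationError("nonresponse_rate must lie in (0, 1)")
        if self.x_skew_shape <= 0:
            raise ConfigurationError("x_skew_shape must be positive")
        if self.link_slope <= 0:
            raise ConfigurationError("link_slope must be positive")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be non-negative")
        for na, rate in zip(self.domain_sizes, rates):
            m = int(round(rate * na))
            if m == 0 or m == na:
                raise ConfigurationError(
                    f"domain of size {na} with rate {rate} would have an "
                    "empty response stratum"
                )


def load_table1_fixture() -> DomainTotals:
    """Domain totals of the six-domain study population, as printed."""
    ref = importlib.resources.files("domcal") / "fixtures" / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return DomainTotals.from_csv(path)


def generate_population(spec: PopulationSpec) -> PopulationFrame:
    """Generate a synthetic finite population from a spec.

    Within each domain, ``round(rate * Na)`` units are assigned to the
    non-respondent stratum via a seeded permutation; ``x`` is lognormal with
    shape ``x_skew_shape``; ``y = link_slope * x * eps`` with mean-one
    multiplicative lognormal noise of relative scale ``noise_scale``.  When
    ``target_totals`` is given, x and y are rescaled multiplicatively per
    (domain, stratum) so stratum totals match the targets exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rates = spec.rates()

    domains = spec.target_totals.domains if spec.target_totals is not None else None
    if domains is not None and len(domains) != len(spec.domain_sizes):
        raise ConfigurationError(
            "target_totals must cover exactly the requested domains"
        )

    ids, doms, ys, xs, strata = [], [], [], [], []
    next_id = 1
    for a, (na, rate) in enumerate(zip(spec.domain_sizes, rates)):
        na = int(na)
        label = domains[a] if domains is not None else a + 1
        m = int(round(rate * na))
        perm = rng.permutation(na)
        strat = np.where(perm < m, NONRESPONDENT, RESPONDENT)

        x = spec.x_scale * rng.lognormal(mean=0.0, sigma=spec.x_skew_shape, size=na)
        if spec.noise_scale > 0:
            sigma = np.sqrt(np.log1p(spec.noise_scale ** 2))
            eps = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=na)
        else:
            eps = np.ones(na)
        y = spec.link_slope * x * eps

        if spec.target_totals is not None:
            t = spec.target_totals.row(label)
            for code, xt, yt in ((RESPONDENT, t["X1a"], t["Y1a"]),
                                 (NONRESPONDENT, t["X2a"], t["Y2a"])):
                mask = strat == code
                x[mask] *= xt / x[mask].sum()
                y[mask] *= yt / y[mask].sum()

        ids.append(np.arange(next_id, next_id + na))
        next_id += na
        doms.append(np.full(na, label))
        ys.append(y)
        xs.append(x)
        strata.append(strat)

    return PopulationFrame(
        unit_id=np.concatenate(ids),
        domain=np.concatenate(doms),
        y=np.concatenate(ys),
        x=np.concatenate(xs),
        stratum=np.concatenate(strata).astype(object),
    )


def summarize_domains(frame: PopulationFrame) -> DomainTotals:
    """Exact per-domain, per-stratum counts and totals of the frame."""
    if frame.n_units == 0:
        raise ValueError("cannot summarize an empty frame")
    df = frame.to_dataframe()
    resp = df["stratum"] == RESPONDENT
    rows = {}
    for label, grp in df.groupby("domain", sort=True):
        r = grp[resp.loc[grp.index]]
        nr = grp[~resp.loc[grp.index]]
        rows[label] = [
            len(grp), len(r), len(nr),
            grp["y"].sum(), r["y"].sum(), nr["y"].sum(),
            grp["x"].sum(), r["x"].sum(), nr["x"].sum(),
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=TOTALS_COLUMNS)
    table.index.name = "domain"
    return DomainTotals(table.astype(float))


def validate_totals(t: DomainTotals, rounding_tol: float = 0.5) -> list[str]:
    """Check DomainTotals invariants; return a list of violation messages.

    Count identities must hold exactly; total identities up to
    ``rounding_tol`` (printed tables are rounded).  An empty list means the
    totals are internally consistent.
    """
    problems = []
    for domain in t.domains:
        r = t.row(domain)
        if r["Na"] != r["N1a"] + r["N2a"]:
            problems.append(
                f"domain {domain}: Na={r['Na']:g} != N1a+N2a={r['N1a'] + r['N2a']:g}"
            )
        for tot, parts in (("Ya", ("Y1a", "Y2a")), ("Xa", ("X1a", "X2a"))):
            gap = abs(r[tot] - (r[parts[0]] + r[parts[1]]))
            if gap > rounding_tol:
                problems.append(
                    f"domain {domain}: |{tot} - ({parts[0]}+{parts[1]})| = "
                    f"{gap:g} exceeds {rounding_tol:g}"
                )
        if np.any(r[list(TOTALS_COLUMNS)].to_numpy() < 0):
            problems.append(f"domain {domain}: negative entry")
    return problems
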