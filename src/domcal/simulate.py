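"""Design-based Monte Carlo engine.

Repeatedly draws samples from a fixed finite population, applies the
calibrated domain estimators, and summarises each (estimator, domain) cell
by

* ARB  — absolute relative bias, 100 * |mean(T_s) - Ya| / Ya,
* SMSE — simulated mean squared error, mean((T_s - Ya)^2),
* SRSE — simulated relative standard error, 100 * sqrt(SMSE) / Ya,

where T_s is the replicate-s estimate and Ya the true domain total.  The
engine is deterministic given the master seed: replicate randomness comes
from per-replicate substreams spawned from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import twophase as tp_mod
from .calibrate import ESTIMATORS, estimate_all
from .design import draw_realization
from .popgen import (
    DomainTotals,
    PopulationFrame,
    PopulationSpec,
    generate_population,
    load_table1_fixture,
    summarize_domains,
)


def arb(estimates, Ya: float) -> float:
    """Absolute relative bias in percent: 100*|mean(estimates) - Ya|/Ya."""
    estimates = np.asarray(estimates, dtype=float)
    if Ya <= 0:
        raise ValueError("true total Ya must be positive")
    if estimates.size == 0:
        raise ValueError("at least one estimate is required")
    return 100.0 * abs(float(np.mean(estimates)) - Ya) / Ya


def smse(estimates, Ya: float) -> float:
    """Simulated mean squared error: mean of squared deviations from Ya."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("at least one estimate is required")
    return float(np.mean((estimates - Ya) ** 2))


def srse(smse_value: float, Ya: float) -> float:
    """Simulated relative standard error in percent: 100*sqrt(SMSE)/Ya."""
    if Ya <= 0:
        raise ValueError("true total Ya must be positive")
    if smse_value < 0:
        raise ValueError("SMSE cannot be negative")
    return 100.0 * float(np.sqrt(smse_value)) / Ya


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one Monte Carlo study.

    The default population is a Table-1-scaled synthetic frame (203 units,
    6 domains, ~30 % non-respondents); the default single-phase design is
    n = 70 with a non-respondent subsample of 12, the study's smaller
    configuration.
    """

    population_spec: PopulationSpec | None = None
    population_csv: str | None = None
    n: int = 70
    n2r_target: int = 12
    reps: int = 2000
    estimators: tuple = ESTIMATORS
    mode: str = "single_phase"           # or "two_phase"
    phase1_fraction: float = 0.6
    n_phase2: int = 70
    n2r_phase2: int = 12
    seed: int = 0
    tolerance: float = 1e-10
    max_iter: int = 100

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n2r_target < 1:
            raise ValueError("n2r_target must be >= 1")
        if self.mode not in ("single_phase", "two_phase"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def resolve_population(self) -> PopulationFrame:
        if self.population_csv is not None:
            return PopulationFrame.from_csv(self.population_csv)
        spec = self.population_spec
        if spec is None:
            spec = PopulationSpec(target_totals=load_table1_fixture(),
                                  seed=self.seed)
        return generate_population(spec)

    def to_dict(self) -> dict:
        d = asdict(self)
        spec = d.pop("population_spec")
        if spec is not None:
            tt = spec.pop("target_totals", None)
            spec["target_totals"] = (None if tt is None
                                     else "resolved DomainTotals")
        d["population_spec"] = spec
        d["estimators"] = list(self.estimators)
        return d


@dataclass
class SimulationResult:
    """Aggregated Monte Carlo metrics per (estimator, domain)."""

    table: pd.DataFrame           # estimator,domain,arb,smse,srse,...
    metadata: dict = field(default_factory=dict)

    def cell(self, estimator: str, domain) -> pd.Series:
        t = self.table
        m = (t["estimator"] == estimator) & (t["domain"] == domain)
        return t[m].iloc[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (self.table.reset_index(drop=True)
                .equals(other.table.reset_index(drop=True))
                and self.metadata == other.metadata)


def _replicate_single(frame, totals, cfg, rng):
    r = draw_realization(frame, cfg.n, cfg.n2r_target, rng)
    return estimate_all(r, frame, totals, cfg.estimators,
                        cfg.tolerance, cfg.max_iter)


def _replicate_two_phase(frame, totals, cfg, rng):
    tps = tp_mod.draw_two_phase(frame, cfg.phase1_fraction, cfg.n_phase2,
                                (cfg.n2r_target, cfg.n2r_phase2), rng)
    out = []
    exp_p2 = None
    for est in cfg.estimators:
        if est == "base":
            out.extend(tp_mod.two_phase_base_estimates(tps, frame))
            continue
        policy = {"ratio": "inverse_x", "greg": "unit",
                  "exponential": "exponential", "power": "power"}[est]
        if est == "power" and exp_p2 is not None:
            # same weight system as exponential (eta = exp(l))
            ests = [e.__class__(domain=e.domain, estimator="power",
                                value=e.value, converged=e.converged,
                                degenerate=e.degenerate,
                                n_negative=e.n_negative, error=e.error)
                    for e in exp_p2]
            out.extend(ests)
            continue
        p1 = tp_mod.phase1_calibrate(tps, frame, policy,
                                     cfg.tolerance, cfg.max_iter)
        p2 = tp_mod.phase2_calibrate(tps, frame, p1, policy,
                                     cfg.tolerance, cfg.max_iter)
        ests = tp_mod.two_phase_estimates(tps, frame, p2, est)
        if est == "exponential":
            exp_p2 = ests
        out.extend(ests)
    return out


def run_study(config: SimulationConfig,
              frame: PopulationFrame | None = None) -> SimulationResult:
    """Run the Monte Carlo study and aggregate ARB/SMSE/SRSE.

    Replicates with solver failures contribute to every cell they did
    converge in; failed (estimator, domain, replicate) cells are dropped
    and counted.  Deterministic for a fixed master seed.
    """
    if frame is None:
        frame = config.resolve_population()
    if config.mode == "single_phase" and config.n > frame.n_units:
        raise ValueError("sample size exceeds population size")
    totals = summarize_domains(frame)

    replicate_fn = (_replicate_single if config.mode == "single_phase"
                    else _replicate_two_phase)

    domains = totals.domains
    values = {(e, d): [] for e in config.estimators for d in domains}
    degenerate = {(e, d): 0 for e in config.estimators for d in domains}
    failed = {(e, d): 0 for e in config.estimators for d in domains}
    negative = {(e, d): 0 for e in config.estimators for d in domains}

    streams = np.random.SeedSequence(config.seed).spawn(config.reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        for e in replicate_fn(frame, totals, config, rng):
            key = (e.estimator, e.domain)
            if np.isfinite(e.value) and e.converged:
                values[key].append(e.value)
            else:
                failed[key] += 1
            if e.degenerate:
                degenerate[key] += 1
            if e.n_negative > 0:
                negative[key] += 1

    rows = []
    for est in config.estimators:
        for dom in domains:
            Ya = float(totals.row(dom)["Ya"])
            v = np.asarray(values[(est, dom)], dtype=float)
            if v.size:
                m = smse(v, Ya)
                rows.append({
                    "estimator": est, "domain": dom,
                    "arb": arb(v, Ya), "smse": m, "srse": srse(m, Ya),
                    "reps": int(v.size),
                    "degenerate": degenerate[(est, dom)],
                    "failed": failed[(est, dom)],
                    "negative_weight_rate": negative[(est, dom)] / config.reps,
                })
            else:
                rows.append({
                    "estimator": est, "domain": dom,
                    "arb": float("nan"), "smse": float("nan"),
                    "srse": float("nan"), "reps": 0,
                    "degenerate": degenerate[(est, dom)],
                    "failed": failed[(est, dom)],
                    "negative_weight_rate": negative[(est, dom)] / config.reps,
                })
    table = pd.DataFrame(rows)
    meta = {"config": config.to_dict(), "seed": config.seed,
            "mode": config.mode, "version": 1}
    return SimulationResult(table=table, metadata=meta)


def write_results(result: SimulationResult, path) -> tuple[Path, Path]:
    """Write results CSV plus a JSON metadata sidecar; returns both paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_path = path / "results.csv"
    meta_path = path / "results_meta.json"
    # %.17g round-trips float64 exactly, so read_results is lossless
    result.table.to_csv(csv_path, index=False, float_format="%.17g")
    meta_path.write_text(json.dumps(result.metadata, indent=2, default=str))
    return csv_path, meta_path


def read_results(path) -> SimulationResult:
    """Read back a results directory written by ``write_results``."""
    path = Path(path)
    table = pd.read_csv(path / "results.csv", float_precision="round_trip")
    # all-zero rate columns parse as int; restore the float dtype
    table["negative_weight_rate"] = table["negative_weight_rate"].astype(float)
    metadata = json.loads((path / "results_meta.json").read_text())
    return SimulationResult(table=table, metadata=metadata)


def format_table(result: SimulationResult) -> str:
    """Human-readable table: estimator rows x domain columns, 'SRSE (ARB)'."""
    t = result.table
    domains = sorted(t["domain"].unique())
    rows = {}
    for est in t["estimator"].unique():
        cells = []
        for dom in domains:
            c = result.cell(est, dom)
            cells.append(f"{c['srse']:.2f} ({c['arb']:.2f})")
        rows[est] = cells
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"domain {d}" for d in domains])
    df.index.name = "estimator"
    return df.to_string()
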