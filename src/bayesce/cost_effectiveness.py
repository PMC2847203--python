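"""Cohort propagation and lifetime expected cost / QALY accumulation.

A patient's state-occupancy distribution is propagated day by day through
age-updated transition matrices; discounted costs and utilities are
accumulated over the horizon and summarized per posterior draw, so the
resulting distributions of expected cost and benefit carry the full joint
parameter uncertainty (one-stage probabilistic sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .inference import PosteriorSample
from .model_spec import (ModelConfig, ParameterIndex, build_parameter_index,
                         transition_probabilities)

__all__ = [
    "CostSchedule",
    "PatientProfile",
    "CEResult",
    "icd_cost_schedule",
    "typical_patient",
    "daily_discount_factor",
    "propagate_occupancy",
    "occupancy_trajectory",
    "expected_cost_benefit",
    "run_ce",
    "pce",
]

DAYS_PER_YEAR = 365


def daily_discount_factor(annual_rate: float) -> float:
    """Per-day discount factor from an annual rate (3.5%/yr -> ~0.9999058)."""
    if not 0 <= annual_rate < 1:
        raise ValueError("annual discount rate must be in [0, 1)")
    return (1.0 + annual_rate) ** (-1.0 / DAYS_PER_YEAR)


@dataclass(frozen=True)
class CostSchedule:
    """Initial and daily costs, utilities, discounting and horizon.

    ``initial_cost[u]`` and ``daily_cost[u, s-1]`` are indexed by treatment
    arm u (0 = comparator/AAD, 1 = intervention/ICD).  ``utility[s-1]`` is
    the QALY weight per year spent in state s; each day in state s accrues
    utility/365 QALYs.  ``discount_daily`` is the per-day discount factor
    rho, applied as rho**t with the initial cost undiscounted at day 0.
    """

    initial_cost: tuple[float, float]
    daily_cost: np.ndarray          # (2, R)
    utility: np.ndarray             # (R,)
    discount_daily: float
    horizon_days: int
    wtp_grid: tuple[float, ...] = tuple(float(v) for v in range(0, 100001, 5000))

    def __post_init__(self) -> None:
        object.__setattr__(self, "daily_cost", np.asarray(self.daily_cost, dtype=float))
        object.__setattr__(self, "utility", np.asarray(self.utility, dtype=float))
        if np.any(self.daily_cost < 0):
            raise ValueError("costs must be non-negative")
        if not 0 < self.discount_daily <= 1:
            raise ValueError("daily discount factor must be in (0, 1]")
        if self.horizon_days < 0:
            raise ValueError("horizon must be non-negative")

    def to_dict(self) -> dict:
        return {
            "initial_cost": list(self.initial_cost),
            "daily_cost": self.daily_cost.tolist(),
            "utility": self.utility.tolist(),
            "discount_daily": self.discount_daily,
            "horizon_days": self.horizon_days,
            "wtp_grid": list(self.wtp_grid),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostSchedule":
        return cls(tuple(d["initial_cost"]), np.asarray(d["daily_cost"]),
                   np.asarray(d["utility"]), d["discount_daily"],
                   d["horizon_days"], tuple(d.get("wtp_grid", (20000.0,))))


def icd_cost_schedule(horizon_years: float = 100.0,
                      annual_discount: float = 0.035,
                      utility_alive: float = 0.75) -> CostSchedule:
    """UK cost schedule for the eight-state ICD model.

    Initial costs 1566 (AAD) / 23841 (ICD); daily out-of-hospital cost
    2.43 / 2.30; hospital-state daily costs shared between arms; death
    costs and utility zero; 3.5%/yr discounting of both costs and QALYs.
    """
    shared = [526.0, 519.5, 296.5, 646.0, 5495.5, 122.0, 0.0]
    daily = np.array([[2.43] + shared, [2.30] + shared])
    utility = np.array([utility_alive] * 7 + [0.0])
    return CostSchedule(
        initial_cost=(1566.0, 23841.0),
        daily_cost=daily,
        utility=utility,
        discount_daily=daily_discount_factor(annual_discount),
        horizon_days=int(round(horizon_years * DAYS_PER_YEAR)),
    )


@dataclass(frozen=True)
class PatientProfile:
    """Covariate values (fractional allowed), starting age and treatment arm."""

    covariates: Mapping[str, float]
    age0: float
    treatment: int  # 0 = AAD, 1 = ICD

    def with_treatment(self, u: int) -> "PatientProfile":
        cov = dict(self.covariates)
        cov["aad"] = 1.0 - u  # model covariate codes the drug arm
        return PatientProfile(cov, self.age0, u)

    def raw(self) -> dict[str, float]:
        return dict(self.covariates)


def typical_patient(treatment: int = 1, country: float = 1.0) -> PatientProfile:
    """Average study patient: age 63, low LVEF, female fraction 0.13; the
    country covariate defaults to UK."""
    prof = PatientProfile(
        {"sex": 0.13, "lvef": 1.0, "country": country, "aad": 1.0 - treatment},
        age0=63.0, treatment=treatment)
    return prof


# ---------------------------------------------------------------------------
# daily design matrix and propagation kernels
# ---------------------------------------------------------------------------

def _daily_design(config: ModelConfig, profile: PatientProfile, T: int) -> np.ndarray:
    """(T, K+1) covariate design rows for days t = 1..T, with age advancing
    by 1/365 year per day."""
    raw = profile.raw()
    missing = [c for c in config.raw_covariate_names if c not in raw]
    if missing:
        raise ValueError(f"profile missing covariates: {missing}")
    X = np.empty((T, config.n_columns + 1))
    for t in range(1, T + 1):
        X[t - 1] = config.covariate_vector(raw, profile.age0 + t / DAYS_PER_YEAR)
    return X


@njit(cache=True)
def _ce_kernel(X, A, nd, dest, transient, ref, theta_ext,
               rho, cost_u, utility, R, T):
    """Propagate occupancy day by day and accumulate discounted cost/QALYs."""
    pi = np.zeros(R)
    pi[0] = 1.0
    new_pi = np.zeros(R)
    eta = np.zeros(A.shape[1])
    EC = 0.0
    EB = 0.0
    disc = 1.0
    for t in range(1, T + 1):
        x = X[t - 1]
        for s in range(R):  # absorbing rows keep their mass
            new_pi[s] = pi[s]
        for ri in range(transient.shape[0]):
            r = transient[ri]
            mass = pi[r - 1]
            new_pi[r - 1] -= mass
            if mass == 0.0:
                continue
            m = 0.0
            for d in range(nd[r]):
                e = 0.0
                for k in range(x.shape[0]):
                    e += theta_ext[A[r, d, k]] * x[k]
                eta[d] = e
                if e > m:
                    m = e
            ssum = np.exp(-m)
            for d in range(nd[r]):
                ssum += np.exp(eta[d] - m)
            new_pi[ref[r] - 1] += mass * np.exp(-m) / ssum
            for d in range(nd[r]):
                new_pi[dest[r, d] - 1] += mass * np.exp(eta[d] - m) / ssum
        for s in range(R):
            pi[s] = new_pi[s]
        disc *= rho
        cd = 0.0
        bd = 0.0
        for s in range(R):
            cd += pi[s] * cost_u[s]
            bd += pi[s] * utility[s]
        EC += disc * cd
        EB += disc * bd / DAYS_PER_YEAR
    return EC, EB


class _CEEngine:
    """Precomputed structures for repeated per-draw CE evaluation."""

    def __init__(self, config: ModelConfig, schedule: CostSchedule,
                 index: ParameterIndex | None = None):
        self.config = config
        self.schedule = schedule
        self.index = index or build_parameter_index(config)
        self.A, self.nd, self.dest = self.index.design_stack()
        sp = config.state_space
        self.R = sp.n_states
        self.transient = np.array(sp.transient, dtype=np.int64)
        self.ref = np.zeros(self.R + 1, dtype=np.int64)
        for r in sp.transient:
            self.ref[r] = sp.reference(r)

    def design_for(self, profile: PatientProfile, T: int | None = None) -> np.ndarray:
        return _daily_design(self.config, profile,
                             self.schedule.horizon_days if T is None else T)

    def evaluate(self, theta: np.ndarray, X: np.ndarray, u: int) -> tuple[float, float]:
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite theta")
        te = self.index.theta_extended(np.asarray(theta, dtype=float))
        EC, EB = _ce_kernel(X, self.A, self.nd, self.dest, self.transient,
                            self.ref, te, self.schedule.discount_daily,
                            self.schedule.daily_cost[u], self.schedule.utility,
                            self.R, X.shape[0])
        return self.schedule.initial_cost[u] + EC, EB


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def propagate_occupancy(theta: np.ndarray, config: ModelConfig,
                        profile: PatientProfile, t: int,
                        index: ParameterIndex | None = None) -> np.ndarray:
    """Occupancy vector pi_t after t daily transitions from state 1 at day 0,
    with age-derived covariates recomputed every day."""
    return occupancy_trajectory(theta, config, profile, t, index)[t]


def occupancy_trajectory(theta: np.ndarray, config: ModelConfig,
                         profile: PatientProfile, T: int,
                         index: ParameterIndex | None = None) -> np.ndarray:
    """(T+1, R) occupancy vectors pi_0..pi_T (plain numpy reference path)."""
    if T < 0:
        raise ValueError("t must be >= 0")
    idx = index or build_parameter_index(config)
    sp = config.state_space
    R = sp.n_states
    out = np.zeros((T + 1, R))
    out[0, 0] = 1.0
    raw = profile.raw()
    for t in range(1, T + 1):
        x = config.covariate_vector(raw, profile.age0 + t / DAYS_PER_YEAR)
        P = np.zeros((R, R))
        for r in range(1, R + 1):
            P[r - 1] = transition_probabilities(idx, theta, x, r)
        out[t] = out[t - 1] @ P
    return out


def expected_cost_benefit(theta: np.ndarray, config: ModelConfig,
                          profile: PatientProfile, schedule: CostSchedule,
                          engine: _CEEngine | None = None) -> tuple[float, float]:
    """Total discounted expected cost and QALYs over the horizon for the
    profile's treatment arm: E(C_u) = c_0u + sum_t rho^t pi_t . c_u and the
    analogous utility sum with utility/365 per day."""
    eng = engine or _CEEngine(config, schedule)
    X = eng.design_for(profile)
    return eng.evaluate(theta, X, profile.treatment)


@dataclass
class CEResult:
    """Per-draw expected costs/benefits for both arms and derived increments.

    The ICER is the ratio of posterior means of the increments, not the
    mean of per-draw ratios.
    """

    ec0: np.ndarray
    ec1: np.ndarray
    eb0: np.ndarray
    eb1: np.ndarray
    model_label: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ec0)
        if not (len(self.ec1) == len(self.eb0) == len(self.eb1) == n) or n == 0:
            raise ValueError("per-draw vectors must share a positive length")

    @property
    def n_draws(self) -> int:
        return len(self.ec0)

    @property
    def delta_c(self) -> np.ndarray:
        return self.ec1 - self.ec0

    @property
    def delta_b(self) -> np.ndarray:
        return self.eb1 - self.eb0

    def inb(self, lam: float) -> np.ndarray:
        return lam * self.delta_b - self.delta_c

    @property
    def icer(self) -> float:
        return float(self.delta_c.mean() / self.delta_b.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ec0": self.ec0, "ec1": self.ec1,
                             "eb0": self.eb0, "eb1": self.eb1,
                             "delta_c": self.delta_c, "delta_b": self.delta_b})

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "model", self.model_label)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CEResult":
        df = pd.read_csv(path)
        label = str(df["model"].iloc[0]) if "model" in df.columns else ""
        return cls(df["ec0"].to_numpy(), df["ec1"].to_numpy(),
                   df["eb0"].to_numpy(), df["eb1"].to_numpy(), label)

    def summary(self, lam: float = 20000.0) -> dict:
        dc, db = self.delta_c, self.delta_b
        q = lambda v: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
        return {
            "delta_c_mean": float(dc.mean()), "delta_c_ci": q(dc),
            "delta_b_mean": float(db.mean()), "delta_b_ci": q(db),
            "icer": self.icer, "pce": pce(self, lam), "lambda": lam,
        }


def run_ce(sample: PosteriorSample, config: ModelConfig,
           profile: PatientProfile, schedule: CostSchedule,
           max_draws: int | None = None, seed: int = 0) -> CEResult:
    """Evaluate lifetime expected cost/QALYs under both treatment arms for
    every posterior draw (optionally an evenly-spaced subset of size
    ``max_draws``)."""
    eng = _CEEngine(config, schedule)
    if max_draws is not None and max_draws < sample.n_draws:
        sel = np.linspace(0, sample.n_draws - 1, max_draws).round().astype(int)
    else:
        sel = np.arange(sample.n_draws)
    X0 = eng.design_for(profile.with_treatment(0))
    X1 = eng.design_for(profile.with_treatment(1))
    n = len(sel)
    ec0 = np.empty(n); ec1 = np.empty(n)
    eb0 = np.empty(n); eb1 = np.empty(n)
    for j, i in enumerate(sel):
        theta = sample.draws[i]
        ec0[j], eb0[j] = eng.evaluate(theta, X0, 0)
        ec1[j], eb1[j] = eng.evaluate(theta, X1, 1)
    return CEResult(ec0, ec1, eb0, eb1, model_label=sample.config_label or config.label)


def pce(ce: CEResult, lam: float | Sequence[float]):
    """Probability of cost-effectiveness: fraction of draws with positive
    incremental net benefit at willingness-to-pay lambda.  A grid of
    lambdas yields the cost-effectiveness acceptability curve."""
    if ce.n_draws == 0:
        raise ValueError("empty CE result")
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be non-negative")
    out = np.array([(l * ce.delta_b - ce.delta_c > 0).mean() for l in lam_arr])
    return float(out[0]) if np.isscalar(lam) or np.ndim(lam) == 0 else out
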