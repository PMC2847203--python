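"""Synthetic cohorts with known ground truth for end-to-end testing.

Cohorts emulate the structure of the ICD study data: eight states, binary
treatment/sex/LVEF/country covariates, time-dependent age, administrative
right-censoring with a target mean follow-up, yearly aggregation of daily
transitions into multinomial rows, and an absorbing death state.  The
generator evaluates transition probabilities through the same design/index
code path as the fitter, so parameter-recovery failures isolate the
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import TransitionData
from .model_spec import (ModelConfig, ParameterIndex, build_model_config,
                         build_parameter_index, two_state_config)

__all__ = [
    "CohortConfig",
    "default_theta_star",
    "simulate_cohort",
    "make_fixture_suite",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, covariate distribution, follow-up and ground truth.

    Follow-up is administrative: censoring times are uniform on
    (min_followup_years, max_followup_years), giving a mean follow-up of
    their midpoint for patients who survive.  The study-like default
    targets a 3.68-year mean with a 7.04-year maximum.
    """

    n_patients: int
    theta_star: np.ndarray
    aad_fraction: float = 0.5
    female_prevalence: float = 0.13
    lvef_prevalence: float = 0.8
    uk_prevalence: float = 0.55
    age_mean: float = 63.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (30.0, 85.0)
    min_followup_years: float = 0.32
    max_followup_years: float = 7.04
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_star",
                           np.asarray(self.theta_star, dtype=float))
        for p in (self.aad_fraction, self.female_prevalence,
                  self.lvef_prevalence, self.uk_prevalence):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must be in [0, 1]")
        if not 0 < self.min_followup_years <= self.max_followup_years:
            raise ValueError("follow-up window must be positive and ordered")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


def default_theta_star(index: ParameterIndex, seed: int = 12345) -> np.ndarray:
    """Documented true-parameter constants in the study's sparsity regime.

    Admission intercepts around -7 (a couple of admissions per patient-year
    across the six causes), death intercept around -8.5 (roughly 5%/year
    mortality), hospital stays of about a week (stay-vs-return log-odds
    ~1.8), and modest covariate effects drawn once from N(0, 0.3^2) with a
    +0.4 drug effect on death.  Values are generator constants, not
    estimates of anything.
    """
    rng = np.random.default_rng(seed)
    theta = np.zeros(index.n_free)
    for j, name in enumerate(index.names):
        if name == "mu_D":
            theta[j] = -8.5
        elif name.startswith("mu_1"):
            theta[j] = -7.0 + rng.normal(0, 0.3)
        elif name.startswith("mu_") and name[3] == name[4]:
            theta[j] = 1.8 + rng.normal(0, 0.2)
        elif name == "beta_D_aad":
            theta[j] = 0.4
        elif "age_pow" in name:
            # decaying polynomial coefficients keep probabilities sane at
            # the edges of the age range
            power = int(name.rsplit("pow", 1)[1])
            theta[j] = rng.normal(0, 0.4 / 2 ** (power - 1))
        else:
            theta[j] = rng.normal(0, 0.3)
    return theta


def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    n = cfg.n_patients
    age0 = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), *cfg.age_range)
    return pd.DataFrame({
        "patient": np.arange(1, n + 1),
        "aad": (rng.random(n) < cfg.aad_fraction).astype(float),
        "sex": (rng.random(n) < cfg.female_prevalence).astype(float),
        "lvef": (rng.random(n) < cfg.lvef_prevalence).astype(float),
        "country": (rng.random(n) < cfg.uk_prevalence).astype(float),
        "age0": age0,
    })


def simulate_cohort(cfg: CohortConfig, model: ModelConfig,
                    return_trajectories: bool = False):
    """Simulate daily multi-state histories and aggregate them to yearly
    multinomial transition rows.

    Covariates (including age) are held constant within each follow-up
    year, matching the fitted model's yearly aggregation.  Patients start
    in state 1 and are followed until death or administrative censoring.
    Returns a :class:`TransitionData`; with ``return_trajectories=True``
    also the per-patient daily state sequences.
    """
    index = build_parameter_index(model)
    if cfg.theta_star.shape[0] != index.n_free:
        raise ValueError(
            f"theta_star has length {cfg.theta_star.shape[0]}, "
            f"model {model.label} needs {index.n_free}")
    sp = model.state_space
    R = sp.n_states
    rng = np.random.default_rng(cfg.seed)
    pats = _draw_covariates(cfg, rng)
    n = cfg.n_patients
    censor_days = np.ceil(rng.uniform(cfg.min_followup_years,
                                      cfg.max_followup_years, n)
                          * DAYS_PER_YEAR).astype(np.int64)
    max_years = int(np.ceil(censor_days.max() / DAYS_PER_YEAR))
    te = index.theta_extended(cfg.theta_star)

    raw_names = model.raw_covariate_names
    trans_states = list(sp.transient)
    state = np.ones(n, dtype=np.int64)  # everyone starts out of hospital
    alive_mask = np.ones(n, dtype=bool)
    counts: dict[tuple[int, int, int], np.ndarray] = {}
    trajectories = [[1] for _ in range(n)] if return_trajectories else None

    # year-constant transition matrices per patient, recomputed annually
    for year in range(max_years):
        in_obs = alive_mask & (censor_days > year * DAYS_PER_YEAR)
        idx_pat = np.nonzero(in_obs)[0]
        if idx_pat.size == 0:
            break
        ages = pats["age0"].to_numpy()[idx_pat] + year
        X = np.empty((idx_pat.size, model.n_columns + 1))
        for ii, (pi, age) in enumerate(zip(idx_pat, ages)):
            raw = {c: float(pats[c].iloc[pi]) for c in raw_names}
            X[ii] = model.covariate_vector(raw, float(age))
        # per-patient cumulative transition distributions, by from-state
        Pcum = np.zeros((idx_pat.size, R + 1, R))
        for r in trans_states:
            coef = te[index.design[r]]                 # (nd, K+1)
            eta = X @ coef.T                           # (m, nd)
            logits = np.concatenate([np.zeros((idx_pat.size, 1)), eta], axis=1)
            logits -= logits.max(axis=1, keepdims=True)
            w = np.exp(logits)
            w /= w.sum(axis=1, keepdims=True)
            probs = np.zeros((idx_pat.size, R))
            probs[:, sp.reference(r) - 1] = w[:, 0]
            for d, s in enumerate(sp.destinations(r)):
                probs[:, s - 1] = w[:, 1 + d]
            Pcum[:, r] = np.cumsum(probs, axis=1)
        for a in sp.absorbing:
            Pcum[:, a, a - 1:] = 1.0

        year_counts = np.zeros((idx_pat.size, R + 1, R), dtype=np.int64)
        cur = state[idx_pat].copy()
        days_left = np.minimum(censor_days[idx_pat] - year * DAYS_PER_YEAR,
                               DAYS_PER_YEAR)
        active = np.ones(idx_pat.size, dtype=bool)
        for day in range(DAYS_PER_YEAR):
            live = active & (days_left > day)
            live &= ~np.isin(cur, list(sp.absorbing))
            if not live.any():
                break
            li = np.nonzero(live)[0]
            u = rng.random(li.size)
            cum = Pcum[li, cur[li]]                     # (m, R)
            nxt = (u[:, None] > cum).sum(axis=1) + 1
            year_counts[li, cur[li], nxt - 1] += 1
            if return_trajectories:
                for jj, pi in enumerate(idx_pat[li]):
                    trajectories[pi].append(int(nxt[jj]))
            cur[li] = nxt
        for ii, pi in enumerate(idx_pat):
            for r in trans_states:
                row = year_counts[ii, r]
                if row.sum() > 0:
                    counts[(int(pats['patient'].iloc[pi]), year, r)] = row
        state[idx_pat] = cur
        died = np.isin(cur, list(sp.absorbing))
        alive_mask[idx_pat[died]] = False

    keys = sorted(counts)
    rows = []
    cmat = np.zeros((len(keys), R))
    pat_lookup = pats.set_index("patient")
    for i, (pid, year, r) in enumerate(keys):
        rec = {"patient": pid, "year": year, "from_state": r,
               "age": float(pat_lookup.loc[pid, "age0"]) + year}
        for c in raw_names:
            rec[c] = float(pat_lookup.loc[pid, c])
        rows.append(rec)
        cmat[i] = counts[(pid, year, r)]
    cols = ["patient", "year", "from_state", "age"] + raw_names
    data = TransitionData(pd.DataFrame(rows, columns=cols), cmat)
    if return_trajectories:
        return data, trajectories
    return data


def make_fixture_suite(seed: int = 0) -> dict:
    """Small deterministic datasets for test harnesses.

    (a) tiny two-state dataset (single free intercept, conjugate-like
        posterior amenable to dense-grid integration);
    (b) medium eight-state dataset generated under base-case truth, for
        parameter recovery;
    (c) paired datasets generated under base-case truth and quartic-age
        truth, for model-selection power checks.
    """
    out: dict = {}

    ts_model = two_state_config()
    ts_index = build_parameter_index(ts_model)
    theta_a = np.array([-6.0])
    cfg_a = CohortConfig(n_patients=40, theta_star=theta_a,
                         min_followup_years=1.0, max_followup_years=3.0,
                         seed=seed)
    out["two_state"] = {
        "model": ts_model,
        "theta_star": theta_a,
        "data": simulate_cohort(cfg_a, ts_model),
    }

    m1 = build_model_config("M1")
    m1_index = build_parameter_index(m1)
    theta_b = default_theta_star(m1_index)
    cfg_b = CohortConfig(n_patients=250, theta_star=theta_b, seed=seed + 1)
    out["m1_medium"] = {
        "model": m1,
        "theta_star": theta_b,
        "data": simulate_cohort(cfg_b, m1),
    }

    m7 = build_model_config("M7")
    m7_index = build_parameter_index(m7)
    theta_c = default_theta_star(m7_index)
    # pronounced curvature in the age effect on death so that the quartic
    # model is genuinely better than the piecewise base case
    for j, name in enumerate(m7_index.names):
        if name == "beta_D_age_pow2":
            theta_c[j] = 0.8
        elif name == "beta_D_age_pow4":
            theta_c[j] = 0.35
    cfg_c1 = CohortConfig(n_patients=250, theta_star=theta_b, seed=seed + 2)
    cfg_c7 = CohortConfig(n_patients=250, theta_star=theta_c, seed=seed + 3)
    out["paired"] = {
        "m1": {"model": m1, "theta_star": theta_b,
               "data": simulate_cohort(cfg_c1, m1)},
        "m7": {"model": m7, "theta_star": theta_c,
               "data": simulate_cohort(cfg_c7, m7)},
    }
    return out
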