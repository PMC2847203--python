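"""Multinomial transition likelihood, priors and MCMC posterior sampling.

Observations are multinomial rows: for each (patient, year, from-state) the
counts of one-day transitions to every destination state during that year,
with covariates held constant within the year.  The sampler is an adaptive
univariate random-walk Metropolis-within-Gibbs with per-parameter step
sizes tuned towards a 0.44 acceptance rate during burn-in and frozen
afterwards; the model-structure code path is shared with
:mod:`bayesce.model_spec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln, logsumexp

from .model_spec import ModelConfig, ParameterIndex, build_parameter_index

__all__ = [
    "TransitionData",
    "PriorSpec",
    "PosteriorSample",
    "default_priors",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "posterior_mean_linear_predictors",
    "row_log_likelihoods",
]


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

@dataclass
class TransitionData:
    """Yearly-aggregated multinomial transition counts with covariates.

    ``rows`` has one record per (patient, year, from_state) with columns
    ``patient``, ``year``, ``from_state``, ``age`` and the raw covariates;
    ``counts[i, s-1]`` is the number of observed one-day transitions from
    ``from_state[i]`` to state ``s`` for that record.
    """

    rows: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.rows) != self.counts.shape[0]:
            raise ValueError("rows/counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative transition counts")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def validate(self, config: ModelConfig) -> None:
        """Raise with offending row numbers if counts sit on non-permitted
        transitions or required covariates are missing."""
        sp = config.state_space
        R = sp.n_states
        if self.counts.shape[1] != R:
            raise ValueError(
                f"counts have {self.counts.shape[1]} destination columns, expected {R}")
        missing = [c for c in config.raw_covariate_names if c not in self.rows.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        if "age" not in self.rows.columns:
            raise ValueError("missing 'age' column")
        bad: list[int] = []
        from_states = self.rows["from_state"].to_numpy()
        for r in range(1, R + 1):
            mask = from_states == r
            if not mask.any():
                continue
            allowed = np.zeros(R, dtype=bool)
            for (rr, s) in sp.permitted:
                if rr == r:
                    allowed[s - 1] = True
            offending = (self.counts[mask][:, ~allowed] > 0).any(axis=1)
            bad.extend(np.nonzero(mask)[0][offending].tolist())
        if bad:
            raise ValueError(
                f"counts on non-permitted transitions in rows {sorted(bad)}")

    # -- CSV round trip (long to-state format) ----------------------------
    def to_long_frame(self) -> pd.DataFrame:
        recs = []
        cov_cols = [c for c in self.rows.columns
                    if c not in ("patient", "year", "from_state")]
        for i, row in enumerate(self.rows.itertuples(index=False)):
            d = row._asdict()
            for s in range(1, self.counts.shape[1] + 1):
                c = self.counts[i, s - 1]
                if c > 0:
                    recs.append({"patient": d["patient"], "year": d["year"],
                                 "from_state": d["from_state"], "to_state": s,
                                 "count": int(c),
                                 **{k: d[k] for k in cov_cols}})
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, n_states: int) -> "TransitionData":
        required = {"patient", "year", "from_state", "to_state", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (df["to_state"] < 1).any() or (df["to_state"] > n_states).any():
            bad = df.index[(df["to_state"] < 1) | (df["to_state"] > n_states)]
            raise ValueError(f"to_state outside 1..{n_states} in rows {list(bad)}")
        cov_cols = [c for c in df.columns if c not in required]
        keys = ["patient", "year", "from_state"]
        grouped = df.groupby(keys, sort=True)
        rows = grouped[cov_cols].first().reset_index()
        counts = np.zeros((len(rows), n_states))
        for i, (_, g) in enumerate(grouped):
            np.add.at(counts[i], g["to_state"].to_numpy() - 1,
                      g["count"].to_numpy(dtype=float))
        return cls(rows, counts)

    @classmethod
    def from_csv(cls, path: str | Path, n_states: int) -> "TransitionData":
        return cls.from_long_frame(pd.read_csv(path), n_states)

    @classmethod
    def empty(cls, config: ModelConfig) -> "TransitionData":
        cols = ["patient", "year", "from_state", "age"] + config.raw_covariate_names
        return cls(pd.DataFrame(columns=cols),
                   np.zeros((0, config.state_space.n_states)))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the free parameters."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("prior mean/sd shape mismatch")
        if np.any(self.sd <= 0):
            raise ValueError("prior standard deviations must be positive")


def default_priors(index: ParameterIndex,
                   informative_death_treatment: bool = True) -> PriorSpec:
    """Dispersed N(0, 10^2) priors; the death-row treatment coefficient gets
    the meta-analysis prior N(0.414, 0.16^2) when present."""
    mean = np.zeros(index.n_free)
    sd = np.full(index.n_free, 10.0)
    if informative_death_treatment and "beta_D_aad" in index.names:
        p = index.names.index("beta_D_aad")
        mean[p] = 0.414
        sd[p] = 0.16
    return PriorSpec(mean, sd)


def log_prior(theta: np.ndarray, priors: PriorSpec) -> float:
    theta = np.asarray(theta, dtype=float)
    z = (theta - priors.mean) / priors.sd
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(priors.sd))
                 - 0.5 * theta.size * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class LikelihoodContext:
    """Preprocessed arrays for repeated likelihood evaluation.

    Destination counts are re-ordered per row as (reference, non-reference
    destinations in the index's order); ``logC`` is the multinomial
    normalizing constant, included so that per-row likelihood values are
    genuine predictive probabilities.
    """

    def __init__(self, data: TransitionData, config: ModelConfig,
                 index: ParameterIndex | None = None):
        data.validate(config)
        self.config = config
        self.index = index or build_parameter_index(config)
        sp = config.state_space
        n = data.n_rows
        K = config.n_columns
        A_stack, nd_states, dest_states = self.index.design_stack()
        self.A_stack, self.nd_states, self.dest_states = A_stack, nd_states, dest_states
        max_dest = A_stack.shape[1]

        self.row_state = data.rows["from_state"].to_numpy(dtype=np.int64) if n else \
            np.zeros(0, dtype=np.int64)
        self.X = np.zeros((n, K + 1))
        self.C = np.zeros((n, max_dest + 1))
        self.nd = np.zeros(n, dtype=np.int64)
        self.N = np.zeros(n)
        self.logC = np.zeros(n)
        ages = data.rows["age"].to_numpy(dtype=float) if n else np.zeros(0)
        raw_cols = {c: data.rows[c].to_numpy(dtype=float)
                    for c in config.raw_covariate_names} if n else {}
        for i in range(n):
            r = int(self.row_state[i])
            raw = {c: raw_cols[c][i] for c in raw_cols}
            self.X[i] = config.covariate_vector(raw, float(ages[i]))
            cnt = data.counts[i]
            if r in sp.absorbing:
                # absorbing rows carry no information; all mass on self
                self.nd[i] = 0
                self.C[i, 0] = cnt[r - 1]
            else:
                ref = sp.reference(r)
                dests = sp.destinations(r)
                self.nd[i] = len(dests)
                self.C[i, 0] = cnt[ref - 1]
                for d, s in enumerate(dests):
                    self.C[i, 1 + d] = cnt[s - 1]
            Ni = cnt.sum()
            self.N[i] = Ni
            self.logC[i] = gammaln(Ni + 1) - gammaln(cnt + 1).sum()

    # vectorized linear predictors for all rows at one or many thetas -----
    def eta_matrix(self, theta: np.ndarray) -> np.ndarray:
        """(n_rows, max_dest) linear predictors at a single theta."""
        te = self.index.theta_extended(theta)
        n, max_dest = self.C.shape[0], self.C.shape[1] - 1
        eta = np.zeros((n, max_dest))
        for r in self.config.state_space.transient:
            mask = self.row_state == r
            if not mask.any():
                continue
            coef = te[self.index.design[r]]          # (nd, K+1)
            eta[np.ix_(mask, range(coef.shape[0]))] = self.X[mask] @ coef.T
        return eta

    def row_log_lik(self, eta: np.ndarray) -> np.ndarray:
        """Per-row log-likelihood given the (n, max_dest) predictor matrix."""
        n, max_dest = self.C.shape[0], self.C.shape[1] - 1
        ll = np.array(self.logC)
        if n == 0:
            return ll
        mask = np.arange(max_dest)[None, :] < self.nd[:, None]
        logits = np.concatenate([np.zeros((n, 1)), np.where(mask, eta, -np.inf)], axis=1)
        lse = logsumexp(logits, axis=1)
        ll += -self.N * lse + np.sum(np.where(mask, self.C[:, 1:] * eta, 0.0), axis=1)
        return ll


def log_likelihood(theta: np.ndarray, data: TransitionData,
                   config: ModelConfig,
                   context: LikelihoodContext | None = None) -> float:
    """Total multinomial log-likelihood (including normalizing constants),
    with the 0*log(0) = 0 convention."""
    ctx = context or LikelihoodContext(data, config)
    if ctx.C.shape[0] == 0:
        return 0.0
    return float(ctx.row_log_lik(ctx.eta_matrix(theta)).sum())


# ---------------------------------------------------------------------------
# numba MCMC kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _softmax_state(eta, C, nd, i):
    """(max logit, scaled denominator, count-weighted logit sum) of row i;
    the reference destination contributes a fixed logit of 0."""
    m = 0.0
    for d in range(nd[i]):
        if eta[i, d] > m:
            m = eta[i, d]
    ssum = np.exp(-m)
    dot = 0.0
    for d in range(nd[i]):
        ssum += np.exp(eta[i, d] - m)
        dot += C[i, 1 + d] * eta[i, d]
    return m, ssum, dot


@njit(cache=True)
def _mwg_kernel(seed, n_iter, n_burnin, thin,
                theta, log_step,
                eta, C, nd, logC, N,
                tp_ptr, tp_row, tp_dest, tp_x,
                pr_ptr, pr_row,
                prior_mean, prior_sd,
                target, adapt_c):
    np.random.seed(seed)
    n_free = theta.shape[0]
    n_rows = C.shape[0]
    n_kept = (n_iter - n_burnin + thin - 1) // thin if n_iter > n_burnin else 0
    draws = np.empty((n_kept, n_free))
    dev = np.empty(n_kept)
    acc = np.zeros(n_free)
    n_prop = np.zeros(n_free)

    # per-row softmax state, updated incrementally: each proposal changes
    # one logit per touched row, so the denominator is adjusted in O(1)
    # (with an O(n_dest) rescan only when the row maximum moves down)
    row_m = np.empty(n_rows)
    row_ssum = np.empty(n_rows)
    row_dot = np.empty(n_rows)
    rowll = np.empty(n_rows)
    total_ll = 0.0
    for i in range(n_rows):
        m, ssum, dot = _softmax_state(eta, C, nd, i)
        row_m[i] = m
        row_ssum[i] = ssum
        row_dot[i] = dot
        rowll[i] = logC[i] - N[i] * (m + np.log(ssum)) + dot
        total_ll += rowll[i]

    max_touch = 1
    max_rows = 1
    for p in range(n_free):
        if tp_ptr[p + 1] - tp_ptr[p] > max_touch:
            max_touch = tp_ptr[p + 1] - tp_ptr[p]
        if pr_ptr[p + 1] - pr_ptr[p] > max_rows:
            max_rows = pr_ptr[p + 1] - pr_ptr[p]
    old_eta = np.empty(max_touch)
    old_state = np.empty((max_rows, 4))  # m, ssum, dot, ll per affected row

    kept = 0
    for it in range(n_iter):
        for p in range(n_free):
            delta = np.random.normal() * np.exp(log_step[p])
            lo, hi = pr_ptr[p], pr_ptr[p + 1]
            for j in range(lo, hi):
                i = pr_row[j]
                old_state[j - lo, 0] = row_m[i]
                old_state[j - lo, 1] = row_ssum[i]
                old_state[j - lo, 2] = row_dot[i]
                old_state[j - lo, 3] = rowll[i]
            for j in range(tp_ptr[p], tp_ptr[p + 1]):
                i = tp_row[j]
                d = tp_dest[j]
                old = eta[i, d]
                old_eta[j - tp_ptr[p]] = old
                new = old + delta * tp_x[j]
                eta[i, d] = new
                row_dot[i] += C[i, 1 + d] * (new - old)
                m = row_m[i]
                if new > m:
                    scale = np.exp(m - new)
                    row_ssum[i] = (row_ssum[i] * scale
                                   - np.exp(old - new) + 1.0)
                    row_m[i] = new
                elif old >= m:
                    # the old value may have been the maximum; rescan
                    m2, ssum2, dot2 = _softmax_state(eta, C, nd, i)
                    row_m[i] = m2
                    row_ssum[i] = ssum2
                else:
                    row_ssum[i] += np.exp(new - m) - np.exp(old - m)
            dll = 0.0
            for j in range(lo, hi):
                i = pr_row[j]
                v = (logC[i] - N[i] * (row_m[i] + np.log(row_ssum[i]))
                     + row_dot[i])
                rowll[i] = v
                dll += v - old_state[j - lo, 3]
            zo = (theta[p] - prior_mean[p]) / prior_sd[p]
            zn = (theta[p] + delta - prior_mean[p]) / prior_sd[p]
            logr = dll - 0.5 * (zn * zn - zo * zo)
            accepted = np.log(np.random.rand()) < logr
            if accepted:
                theta[p] += delta
                total_ll += dll
            else:
                # reverse order: a tie group may touch one logit twice
                for j in range(tp_ptr[p + 1] - 1, tp_ptr[p] - 1, -1):
                    eta[tp_row[j], tp_dest[j]] = old_eta[j - tp_ptr[p]]
                for j in range(lo, hi):
                    i = pr_row[j]
                    row_m[i] = old_state[j - lo, 0]
                    row_ssum[i] = old_state[j - lo, 1]
                    row_dot[i] = old_state[j - lo, 2]
                    rowll[i] = old_state[j - lo, 3]
            n_prop[p] += 1.0
            if it < n_burnin:
                alpha = np.exp(min(0.0, logr))
                gamma = adapt_c / (1.0 + n_prop[p]) ** 0.6
                log_step[p] += gamma * (alpha - target)
                if log_step[p] > 5.0:
                    log_step[p] = 5.0
                elif log_step[p] < -8.0:
                    log_step[p] = -8.0
            elif accepted:
                acc[p] += 1.0
        if it >= n_burnin:
            if (it - n_burnin) % thin == 0:
                draws[kept] = theta
                dev[kept] = -2.0 * total_ll
                kept += 1
        if (it + 1) % 500 == 0:  # kill float drift from incremental updates
            total_ll = 0.0
            for i in range(n_rows):
                m, ssum, dot = _softmax_state(eta, C, nd, i)
                row_m[i] = m
                row_ssum[i] = ssum
                row_dot[i] = dot
                rowll[i] = logC[i] - N[i] * (m + np.log(ssum)) + dot
                total_ll += rowll[i]
    denom = float(n_iter - n_burnin) if n_iter > n_burnin else 1.0
    return draws, dev, acc / denom, log_step


def _touch_structures(ctx: LikelihoodContext):
    """CSR structures: per free parameter, the (row, dest, x) entries its
    change perturbs, and the unique affected rows."""
    index = ctx.index
    n_free = index.n_free
    tp: list[list[tuple[int, int, float]]] = [[] for _ in range(n_free)]
    pr: list[set[int]] = [set() for _ in range(n_free)]
    for r in ctx.config.state_space.transient:
        rows = np.nonzero(ctx.row_state == r)[0]
        if rows.size == 0:
            continue
        A = index.design[r]
        for d in range(A.shape[0]):
            for k in range(A.shape[1]):
                p = A[d, k]
                if p >= n_free:
                    continue
                xv = ctx.X[rows, k]
                nz = rows[xv != 0.0]
                for i, x in zip(nz, ctx.X[nz, k]):
                    tp[p].append((int(i), d, float(x)))
                    pr[p].add(int(i))
    tp_ptr = np.zeros(n_free + 1, dtype=np.int64)
    pr_ptr = np.zeros(n_free + 1, dtype=np.int64)
    for p in range(n_free):
        tp_ptr[p + 1] = tp_ptr[p] + len(tp[p])
        pr_ptr[p + 1] = pr_ptr[p] + len(pr[p])
    tp_row = np.zeros(tp_ptr[-1], dtype=np.int64)
    tp_dest = np.zeros(tp_ptr[-1], dtype=np.int64)
    tp_x = np.zeros(tp_ptr[-1])
    pr_row = np.zeros(pr_ptr[-1], dtype=np.int64)
    for p in range(n_free):
        for j, (i, d, x) in enumerate(tp[p]):
            tp_row[tp_ptr[p] + j] = i
            tp_dest[tp_ptr[p] + j] = d
            tp_x[tp_ptr[p] + j] = x
        for j, i in enumerate(sorted(pr[p])):
            pr_row[pr_ptr[p] + j] = i
    return tp_ptr, tp_row, tp_dest, tp_x, pr_ptr, pr_row


# ---------------------------------------------------------------------------
# posterior sample container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """Kept MCMC draws of the free parameters plus per-draw deviance."""

    draws: np.ndarray                  # (n_kept, n_free)
    deviance: np.ndarray               # (n_kept,)
    names: tuple[str, ...]
    seed: int
    n_iter: int
    n_burnin: int
    thin: int = 1
    acceptance: np.ndarray | None = None
    config_label: str = ""
    config_digest: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.shape[0] == 0:
            raise ValueError("posterior sample must contain at least one draw")
        if not np.all(np.isfinite(self.deviance)):
            raise ValueError("non-finite deviance in posterior sample")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.names))
        df["deviance"] = self.deviance
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "seed": self.seed, "n_iter": self.n_iter, "n_burnin": self.n_burnin,
            "thin": self.thin, "config_label": self.config_label,
            "config_digest": self.config_digest,
            "acceptance": None if self.acceptance is None else list(self.acceptance),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PosteriorSample":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        names = tuple(c for c in df.columns if c != "deviance")
        acc = meta.get("acceptance")
        return cls(df[list(names)].to_numpy(), df["deviance"].to_numpy(), names,
                   meta["seed"], meta["n_iter"], meta["n_burnin"], meta["thin"],
                   None if acc is None else np.asarray(acc),
                   meta.get("config_label", ""), meta.get("config_digest", ""))


# ---------------------------------------------------------------------------
# sampler front end
# ---------------------------------------------------------------------------

def sample_posterior(data: TransitionData, config: ModelConfig,
                     priors: PriorSpec | None = None,
                     n_iter: int = 7000, n_burnin: int = 2000,
                     seed: int = 0, thin: int = 1,
                     initial: np.ndarray | None = None,
                     step_init: float = 0.5,
                     context: LikelihoodContext | None = None) -> PosteriorSample:
    """Adaptive random-walk Metropolis-within-Gibbs over the free parameters.

    Reproducible given ``seed``; adaptation of per-parameter step sizes is
    frozen after burn-in.  Initial values default to the prior means.
    """
    if not (n_iter > n_burnin >= 0):
        raise ValueError("need n_iter > n_burnin >= 0")
    ctx = context or LikelihoodContext(data, config)
    index = ctx.index
    if priors is None:
        priors = default_priors(index)
    if priors.mean.shape[0] != index.n_free:
        raise ValueError("prior length does not match free-parameter count")
    theta0 = np.array(priors.mean if initial is None else initial, dtype=float)
    if theta0.shape[0] != index.n_free:
        raise ValueError("initial value length mismatch")
    eta0 = ctx.eta_matrix(theta0)
    ll0 = ctx.row_log_lik(eta0).sum() if ctx.C.shape[0] else 0.0
    if not np.isfinite(ll0 + log_prior(theta0, priors)):
        raise ValueError("non-finite posterior density at initial values")

    tp_ptr, tp_row, tp_dest, tp_x, pr_ptr, pr_row = _touch_structures(ctx)
    log_step = np.full(index.n_free, np.log(step_init))
    draws, dev, acc, final_step = _mwg_kernel(
        np.uint32(seed & 0xFFFFFFFF), n_iter, n_burnin, thin,
        theta0.copy(), log_step,
        eta0.copy(), ctx.C, ctx.nd, ctx.logC, ctx.N,
        tp_ptr, tp_row, tp_dest, tp_x, pr_ptr, pr_row,
        priors.mean, priors.sd, 0.44, 1.0)
    return PosteriorSample(
        draws, dev, index.names, seed, n_iter, n_burnin, thin, acc,
        config.label, config.digest(),
        extras={"final_log_step": final_step},
    )


# ---------------------------------------------------------------------------
# posterior summaries used downstream
# ---------------------------------------------------------------------------

def posterior_mean_linear_predictors(sample: PosteriorSample,
                                     data: TransitionData,
                                     config: ModelConfig,
                                     context: LikelihoodContext | None = None,
                                     chunk: int = 256) -> np.ndarray:
    """Average over draws of each row's linear predictors (n_rows, max_dest).

    Computed by accumulating per-draw predictors; because predictors are
    linear in theta this equals the predictors at the posterior-mean theta.
    """
    ctx = context or LikelihoodContext(data, config)
    n, max_dest = ctx.C.shape[0], ctx.C.shape[1] - 1
    acc = np.zeros((n, max_dest))
    for lo in range(0, sample.n_draws, chunk):
        block = sample.draws[lo:lo + chunk]
        for theta in block:
            acc += ctx.eta_matrix(theta)
    return acc / sample.n_draws


def row_log_likelihoods(sample: PosteriorSample, data: TransitionData,
                        config: ModelConfig,
                        context: LikelihoodContext | None = None) -> np.ndarray:
    """(n_rows, n_draws) per-observation log-likelihoods over the posterior
    sample; the input to CPO and per-observation DIC computations."""
    ctx = context or LikelihoodContext(data, config)
    out = np.empty((ctx.C.shape[0], sample.n_draws))
    for j in range(sample.n_draws):
        out[:, j] = ctx.row_log_lik(ctx.eta_matrix(sample.draws[j]))
    return out
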