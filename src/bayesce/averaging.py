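"""Bayesian-bootstrap model selection probabilities and model averaging.

The sampling distribution of a sum-type fit statistic (log-PML or DIC) is
estimated by reweighting its per-observation contributions with flat
Dirichlet weights.  The same weight draw is applied to every model within a
replicate, so models are compared on common bootstrap replicates; the
selection probability of a model is the fraction of replicates in which it
attains the best criterion value.  These probabilities weight a mixture of
the model-specific posteriors (the model-averaged posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelWeights",
    "bayesian_bootstrap_weights",
    "bootstrap_statistic_replicates",
    "selection_probabilities",
    "model_weights",
    "model_average",
    "diagnostic_weights",
]

DEFAULT_B = 1000


def bayesian_bootstrap_weights(n: int, B: int, seed: int = 0) -> np.ndarray:
    """B draws of observation weights (q_1..q_n) from Dirichlet(1,...,1)."""
    if n < 1 or B < 1:
        raise ValueError("n and B must be >= 1")
    rng = np.random.default_rng(seed)
    e = rng.exponential(size=(B, n))
    return e / e.sum(axis=1, keepdims=True)


def bootstrap_statistic_replicates(per_obs_values: np.ndarray,
                                   weights: np.ndarray) -> np.ndarray:
    """Replicates of a sum statistic: sum_i n * q_i * v_i per weight draw."""
    v = np.asarray(per_obs_values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite per-observation values")
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[1] != v.shape[0]:
        raise ValueError("weights/values length mismatch")
    return v.shape[0] * (W @ v)


def _winner_shares(replicates: np.ndarray, maximize: bool) -> np.ndarray:
    """Per-model winning frequency over replicates; exact ties split equally."""
    B, M = replicates.shape
    best = replicates.max(axis=1) if maximize else replicates.min(axis=1)
    is_best = replicates == best[:, None]
    shares = is_best / is_best.sum(axis=1, keepdims=True)
    return shares.sum(axis=0) / B


@dataclass
class ModelWeights:
    """Bootstrap selection probabilities per model under PML and DIC."""

    labels: tuple[str, ...]
    prob_pml: np.ndarray
    prob_dic: np.ndarray
    replicates_log_pml: np.ndarray   # (B, M)
    replicates_dic: np.ndarray       # (B, M)
    B: int
    seed: int

    def __post_init__(self) -> None:
        for p in (self.prob_pml, self.prob_dic):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("selection probabilities must be a simplex vector")

    def prob(self, criterion: str) -> np.ndarray:
        if criterion.upper() == "PML":
            return self.prob_pml
        if criterion.upper() == "DIC":
            return self.prob_dic
        raise ValueError("criterion must be 'PML' or 'DIC'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model": self.labels,
                             "prob_pml": self.prob_pml,
                             "prob_dic": self.prob_dic})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def replicates_frame(self) -> pd.DataFrame:
        out = {}
        for m, lab in enumerate(self.labels):
            out[f"log_pml_{lab}"] = self.replicates_log_pml[:, m]
            out[f"dic_{lab}"] = self.replicates_dic[:, m]
        return pd.DataFrame(out)


def selection_probabilities(per_model_values: Mapping[str, np.ndarray],
                            criterion: str = "PML",
                            B: int = DEFAULT_B, seed: int = 0
                            ) -> tuple[dict[str, float], np.ndarray]:
    """Bootstrap probability that each model attains the best criterion.

    ``per_model_values`` maps model label to its per-observation
    contributions (log-CPO values for PML, DIC_i values for DIC) on the
    *same* observations.  Returns (probabilities, (B, M) replicate matrix).
    """
    labels = list(per_model_values)
    if not labels:
        raise ValueError("need at least one model")
    vals = [np.asarray(per_model_values[l], dtype=float) for l in labels]
    n = vals[0].shape[0]
    if any(v.shape[0] != n for v in vals):
        raise ValueError("models must share the same observation index")
    maximize = criterion.upper() == "PML"
    if criterion.upper() not in ("PML", "DIC"):
        raise ValueError("criterion must be 'PML' or 'DIC'")
    W = bayesian_bootstrap_weights(n, B, seed)
    reps = np.column_stack([bootstrap_statistic_replicates(v, W) for v in vals])
    shares = _winner_shares(reps, maximize)
    return dict(zip(labels, shares)), reps


def model_weights(log_cpo_by_model: Mapping[str, np.ndarray],
                  dic_i_by_model: Mapping[str, np.ndarray],
                  B: int = DEFAULT_B, seed: int = 0) -> ModelWeights:
    """Paired bootstrap over both criteria: one shared set of Dirichlet
    weight draws is applied to every model and both statistics."""
    labels = tuple(log_cpo_by_model)
    if tuple(dic_i_by_model) != labels:
        raise ValueError("PML and DIC inputs must list the same models")
    cpo = [np.asarray(log_cpo_by_model[l], dtype=float) for l in labels]
    dics = [np.asarray(dic_i_by_model[l], dtype=float) for l in labels]
    n = cpo[0].shape[0]
    if any(v.shape[0] != n for v in cpo + dics):
        raise ValueError("models must share the same observation index")
    W = bayesian_bootstrap_weights(n, B, seed)
    rep_pml = np.column_stack([bootstrap_statistic_replicates(v, W) for v in cpo])
    rep_dic = np.column_stack([bootstrap_statistic_replicates(v, W) for v in dics])
    return ModelWeights(
        labels,
        _winner_shares(rep_pml, maximize=True),
        _winner_shares(rep_dic, maximize=False),
        rep_pml, rep_dic, B, seed)


def model_average(samples_by_model: Mapping[str, np.ndarray],
                  weights: Mapping[str, float] | Sequence[float],
                  n_out: int = 10000, seed: int = 0,
                  method: str = "resample") -> np.ndarray:
    """Sample from the model-averaged posterior of a scalar functional.

    ``samples_by_model`` maps label to a 1-d (or (n, d)) array of posterior
    draws of the functional; weights must sum to 1.  ``method='resample'``
    draws a model per output sample from the weights then resamples a draw
    from that model; ``method='proportional'`` concatenates deterministic
    blocks of sizes round(w_k * n_out) (shuffled resamples within model).
    """
    labels = list(samples_by_model)
    if isinstance(weights, Mapping):
        w = np.array([float(weights[l]) for l in labels])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(labels):
            raise ValueError("weights length mismatch")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1")
    if np.all(w == 0):
        raise ValueError("all weights are zero")
    arrs = [np.atleast_1d(np.asarray(samples_by_model[l])) for l in labels]
    if any(a.shape[0] == 0 for a in arrs):
        raise ValueError("every model needs at least one draw")
    rng = np.random.default_rng(seed)
    if method == "resample":
        which = rng.choice(len(labels), size=n_out, p=w / w.sum())
        idx = [rng.integers(0, arrs[k].shape[0], size=n_out) for k in range(len(labels))]
        out = np.array([arrs[k][idx[k][j]] for j, k in enumerate(which)])
        return out
    if method == "proportional":
        counts = np.floor(w * n_out).astype(int)
        rem = n_out - counts.sum()
        if rem > 0:  # largest remainders get the leftover slots
            frac = w * n_out - counts
            for k in np.argsort(-frac)[:rem]:
                counts[k] += 1
        parts = [arrs[k][rng.integers(0, arrs[k].shape[0], size=c)]
                 for k, c in enumerate(counts) if c > 0]
        out = np.concatenate(parts)
        rng.shuffle(out)
        return out
    raise ValueError("method must be 'resample' or 'proportional'")


def diagnostic_weights(minus2_log_pml: Mapping[str, float],
                       dic: Mapping[str, float]) -> pd.DataFrame:
    """Weights proportional to PML and to exp(-0.5 DIC).

    Provided only as a labelled diagnostic; never used for averaging.
    """
    labels = list(minus2_log_pml)
    lp = np.array([-0.5 * minus2_log_pml[l] for l in labels])  # = log PML
    wp = np.exp(lp - lp.max())
    wp /= wp.sum()
    ld = np.array([-0.5 * dic[l] for l in labels])
    wd = np.exp(ld - ld.max())
    wd /= wd.sum()
    return pd.DataFrame({"model": labels,
                         "weight_prop_pml": wp,
                         "weight_prop_exp_half_dic": wd})
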