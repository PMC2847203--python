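"""Model structure for discrete-time multi-state transition models.

A model variant is defined by a state space (permitted one-day transitions),
a set of covariates entering multinomial-logistic transition regressions,
and a constraint system that ties coefficient slots together or fixes them
to zero.  Constrained slots are mapped onto a flat vector of free
parameters by :func:`build_parameter_index`.

Conventions
-----------
* States are labelled 1..R in all public I/O.
* A coefficient *slot* is a triple ``(r, s, k)``: the coefficient of
  covariate column ``k`` (``k=0`` is the intercept) on the log-odds of the
  one-day transition ``r -> s`` relative to the row's reference
  destination.  The reference destination of a transient row ``r`` is
  state 1 when ``(r, 1)`` is permitted, otherwise ``r`` itself.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AgeTransform",
    "CovariateSpec",
    "StateSpace",
    "ConstraintSet",
    "ModelConfig",
    "ParameterIndex",
    "icd_state_space",
    "two_state_space",
    "build_model_config",
    "two_state_config",
    "build_parameter_index",
    "linear_predictors",
    "transition_probabilities",
    "config_to_dict",
    "config_from_dict",
    "MODEL_LABELS",
]

Slot = tuple[int, int, int]

MODEL_LABELS = tuple(f"M{i}" for i in range(1, 11))

#: centering / scaling applied to age before raising to polynomial powers;
#: raw age**4 overflows the useful dynamic range of the coefficients.
AGE_CENTER = 63.0
AGE_SCALE = 10.0
AGE_CUTPOINTS = (60.0, 70.0)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeTransform:
    """How current age maps to one or more regression columns."""

    kind: str  # 'piecewise' | 'polynomial'
    cutpoints: tuple[float, ...] = AGE_CUTPOINTS
    degree: int = 2
    center: float = AGE_CENTER
    scale: float = AGE_SCALE

    def __post_init__(self) -> None:
        if self.kind not in ("piecewise", "polynomial"):
            raise ValueError(f"unknown age transform kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    @property
    def n_columns(self) -> int:
        if self.kind == "piecewise":
            return len(self.cutpoints)
        return self.degree

    def column_suffixes(self) -> list[str]:
        if self.kind == "piecewise":
            cuts = list(self.cutpoints) + [None]
            out = []
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                out.append(f"{lo:g}_{hi:g}" if hi is not None else f"ge{lo:g}")
            return out
        return [f"pow{p}" for p in range(1, self.degree + 1)]

    def values(self, age: float) -> np.ndarray:
        if self.kind == "piecewise":
            cuts = list(self.cutpoints) + [np.inf]
            return np.array(
                [1.0 if lo <= age < hi else 0.0
                 for lo, hi in zip(cuts[:-1], cuts[1:])]
            )
        z = (age - self.center) / self.scale
        return z ** np.arange(1, self.degree + 1)


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate (possibly expanding to several regression columns).

    ``kind`` is 'binary', 'fractional' or 'age-derived'.  Binary and
    fractional covariates take their value directly from the raw covariate
    mapping; age-derived covariates are recomputed from current age.  When
    ``interact_with`` names a raw covariate, every column is multiplied by
    that covariate's value (used for age-by-treatment interactions).
    """

    name: str
    kind: str = "binary"
    age_transform: AgeTransform | None = None
    interact_with: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "fractional", "age-derived"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if (self.kind == "age-derived") != (self.age_transform is not None):
            raise ValueError("age_transform required iff kind is 'age-derived'")

    def column_names(self) -> list[str]:
        if self.age_transform is None:
            return [self.name]
        return [f"{self.name}_{suf}" for suf in self.age_transform.column_suffixes()]

    @property
    def n_columns(self) -> int:
        return 1 if self.age_transform is None else self.age_transform.n_columns

    def values(self, raw: Mapping[str, float], age: float) -> np.ndarray:
        if self.age_transform is None:
            try:
                v = float(raw[self.name])
            except KeyError:
                raise KeyError(f"missing covariate {self.name!r}") from None
            out = np.array([v])
        else:
            out = self.age_transform.values(age)
        if self.interact_with is not None:
            try:
                out = out * float(raw[self.interact_with])
            except KeyError:
                raise KeyError(f"missing covariate {self.interact_with!r}") from None
        return out


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """Labelled states 1..R with a set of permitted one-day transitions."""

    states: tuple[str, ...]
    absorbing: frozenset[int]
    permitted: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        R = len(self.states)
        for r, s in self.permitted:
            if not (1 <= r <= R and 1 <= s <= R):
                raise ValueError(f"transition ({r},{s}) outside 1..{R}")
        for r in range(1, R + 1):
            dests = {s for (rr, s) in self.permitted if rr == r}
            if r in self.absorbing:
                if dests != {r}:
                    raise ValueError(f"absorbing state {r} must permit only ({r},{r})")
            else:
                if r not in dests or len(dests) < 2:
                    raise ValueError(
                        f"transient state {r} needs ({r},{r}) and at least one other destination"
                    )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(r for r in range(1, self.n_states + 1) if r not in self.absorbing)

    def reference(self, r: int) -> int:
        """Reference destination of row r (state 1 if reachable, else self)."""
        return 1 if (r, 1) in self.permitted else r

    def destinations(self, r: int) -> tuple[int, ...]:
        """Non-reference permitted destinations of row r, ascending."""
        ref = self.reference(r)
        return tuple(sorted(s for (rr, s) in self.permitted if rr == r and s != ref))


def icd_state_space() -> StateSpace:
    """Eight-state daily model: out of hospital, six admission causes, death.

    From state 1 every state is reachable; from an admission state the
    patient stays, returns home, or dies; death is absorbing.
    """
    states = (
        "out_of_hospital",
        "arrhythmic",
        "other_cardiac",
        "non_cardiac",
        "icd_maintenance",
        "icd_replacement",
        "aad_side_effects",
        "death",
    )
    permitted: set[tuple[int, int]] = {(1, s) for s in range(1, 9)}
    for r in range(2, 8):
        permitted |= {(r, r), (r, 1), (r, 8)}
    permitted.add((8, 8))
    return StateSpace(states, frozenset({8}), frozenset(permitted))


def two_state_space() -> StateSpace:
    return StateSpace(
        ("alive", "dead"),
        frozenset({2}),
        frozenset({(1, 1), (1, 2), (2, 2)}),
    )


# ---------------------------------------------------------------------------
# constraints and model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintSet:
    """Tie groups (named sets of slots sharing one free parameter) and
    slots fixed at zero."""

    tie_groups: tuple[tuple[str, frozenset[Slot]], ...] = ()
    zero_set: frozenset[Slot] = frozenset()

    def tie_map(self) -> dict[Slot, str]:
        out: dict[Slot, str] = {}
        for name, group in self.tie_groups:
            for slot in group:
                if slot in out:
                    raise ValueError(f"slot {slot} appears in more than one tie group")
                out[slot] = name
        return out


@dataclass(frozen=True)
class ModelConfig:
    """Complete structural definition of one model variant."""

    label: str
    state_space: StateSpace
    covariates: tuple[CovariateSpec, ...]
    constraints: ConstraintSet = field(default_factory=ConstraintSet)

    def __post_init__(self) -> None:
        slots = set(self.all_slots())
        tie_map = self.constraints.tie_map()
        for slot in self.constraints.zero_set:
            if slot not in slots:
                raise ValueError(f"zeroed slot {slot} is not a valid slot")
            if slot in tie_map:
                raise ValueError(f"slot {slot} is both zeroed and tied")
        for slot in tie_map:
            if slot not in slots:
                raise ValueError(f"tied slot {slot} is not a valid slot")

    # -- columns ---------------------------------------------------------
    @property
    def column_names(self) -> list[str]:
        out: list[str] = []
        for cov in self.covariates:
            out.extend(cov.column_names())
        return out

    @property
    def n_columns(self) -> int:
        return sum(cov.n_columns for cov in self.covariates)

    @property
    def raw_covariate_names(self) -> list[str]:
        """Raw inputs needed to evaluate the covariate columns (age aside)."""
        names: list[str] = []
        for cov in self.covariates:
            if cov.age_transform is None and cov.name not in names:
                names.append(cov.name)
            if cov.interact_with is not None and cov.interact_with not in names:
                names.append(cov.interact_with)
        return names

    def covariate_vector(self, raw: Mapping[str, float], age: float) -> np.ndarray:
        """Design vector (1, columns...) of length n_columns + 1."""
        parts = [np.array([1.0])]
        for cov in self.covariates:
            parts.append(cov.values(raw, age))
        return np.concatenate(parts)

    # -- slots -----------------------------------------------------------
    def all_slots(self) -> Iterable[Slot]:
        K = self.n_columns
        sp = self.state_space
        for r in sp.transient:
            for s in sp.destinations(r):
                for k in range(K + 1):
                    yield (r, s, k)

    def slot_status(self) -> dict[Slot, str]:
        """'free', 'zero' or tie-group name for every slot."""
        tie_map = self.constraints.tie_map()
        out: dict[Slot, str] = {}
        for slot in self.all_slots():
            if slot in self.constraints.zero_set:
                out[slot] = "zero"
            elif slot in tie_map:
                out[slot] = tie_map[slot]
            else:
                out[slot] = "free"
        return out

    def inclusion_map(self) -> dict[tuple[int, int], tuple[int, ...]]:
        """Column indices with a non-zero slot, per non-reference transition."""
        out: dict[tuple[int, int], tuple[int, ...]] = {}
        for (r, s, k) in self.all_slots():
            if (r, s, k) not in self.constraints.zero_set and k > 0:
                out.setdefault((r, s), ())
                out[(r, s)] = out[(r, s)] + (k,)
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(config_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterIndex:
    """Maps coefficient slots to positions in the flat free-parameter vector.

    ``design[r]`` is an integer array of shape ``(n_dest(r), K+1)`` whose
    entries are free-parameter positions, with ``n_free`` as the sentinel
    for zeroed slots (so indexing ``theta`` extended with a trailing 0
    yields the effective coefficients).
    """

    config: ModelConfig
    n_free: int
    names: tuple[str, ...]
    position: Mapping[Slot, int]
    design: Mapping[int, np.ndarray]

    def theta_extended(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.n_free:
            raise ValueError(f"theta has length {theta.shape[-1]}, expected {self.n_free}")
        pad = np.zeros(theta.shape[:-1] + (1,))
        return np.concatenate([theta, pad], axis=-1)

    def design_stack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Padded (R+1, max_dest, K+1) design tensor, n_dest per row and
        destination indices, for numerical kernels (1-based row index)."""
        sp = self.config.state_space
        R = sp.n_states
        K = self.config.n_columns
        max_dest = max((len(sp.destinations(r)) for r in sp.transient), default=0)
        A = np.full((R + 1, max_dest, K + 1), self.n_free, dtype=np.int64)
        nd = np.zeros(R + 1, dtype=np.int64)
        dest = np.zeros((R + 1, max_dest), dtype=np.int64)
        for r in sp.transient:
            dests = sp.destinations(r)
            nd[r] = len(dests)
            for d, s in enumerate(dests):
                dest[r, d] = s
                A[r, d] = self.design[r][d]
        return A, nd, dest


def build_parameter_index(config: ModelConfig) -> ParameterIndex:
    """Collapse tie groups, drop zeroed slots, and enumerate free parameters.

    Free slots are ordered row-major (from-state, destination, column); a tie
    group takes the position at which its first member is encountered.
    """
    status = config.slot_status()
    cols = ["mu"] + config.column_names
    position: dict[Slot, int] = {}
    names: list[str] = []
    group_pos: dict[str, int] = {}
    for slot in config.all_slots():
        st = status[slot]
        if st == "zero":
            continue
        if st == "free":
            r, s, k = slot
            name = f"mu_{r}{s}" if k == 0 else f"beta_{r}{s}_{cols[k]}"
            position[slot] = len(names)
            names.append(name)
        else:  # tie group
            if st not in group_pos:
                group_pos[st] = len(names)
                names.append(st)
            position[slot] = group_pos[st]
    n_free = len(names)

    sp = config.state_space
    K = config.n_columns
    design: dict[int, np.ndarray] = {}
    for r in sp.transient:
        dests = sp.destinations(r)
        mat = np.full((len(dests), K + 1), n_free, dtype=np.int64)
        for d, s in enumerate(dests):
            for k in range(K + 1):
                pos = position.get((r, s, k))
                if pos is not None:
                    mat[d, k] = pos
        design[r] = mat
    return ParameterIndex(config, n_free, tuple(names), position, design)


# ---------------------------------------------------------------------------
# linear predictors and transition probabilities
# ---------------------------------------------------------------------------

def linear_predictors(
    index: ParameterIndex, theta: np.ndarray, x: np.ndarray, r: int
) -> np.ndarray:
    """Log-odds of each non-reference permitted destination of row ``r``
    relative to the reference destination, at design vector ``x``."""
    sp = index.config.state_space
    if r in sp.absorbing:
        return np.zeros(0)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != index.config.n_columns + 1:
        raise ValueError(
            f"design vector has length {x.shape[0]}, expected {index.config.n_columns + 1}"
        )
    te = index.theta_extended(theta)
    return te[index.design[r]] @ x


def transition_probabilities(
    index: ParameterIndex, theta: np.ndarray, x: np.ndarray, r: int
) -> np.ndarray:
    """One-day transition probability vector over all R states from row ``r``.

    Inverse multinomial logit of the linear predictors with the reference
    destination's logit fixed at 0; exact zeros on non-permitted pairs.
    Stable for |log-odds| up to ~700 via max subtraction.
    """
    sp = index.config.state_space
    R = sp.n_states
    out = np.zeros(R)
    if r in sp.absorbing:
        out[r - 1] = 1.0
        return out
    eta = linear_predictors(index, theta, x, r)
    logits = np.concatenate([[0.0], eta])
    m = logits.max()
    w = np.exp(logits - m)
    w /= w.sum()
    out[sp.reference(r) - 1] = w[0]
    for d, s in enumerate(sp.destinations(r)):
        out[s - 1] = w[1 + d]
    return out


# ---------------------------------------------------------------------------
# factory: base-case and alternative variants
# ---------------------------------------------------------------------------

def _baseline_covariates(age_spec: CovariateSpec,
                         interactions: CovariateSpec | None = None,
                         ) -> tuple[CovariateSpec, ...]:
    covs = [
        CovariateSpec("aad"),      # 1 = anti-arrhythmic drug arm, 0 = ICD
        CovariateSpec("sex", kind="fractional"),  # 1 = female (fractional allowed)
        CovariateSpec("lvef"),     # 1 = LVEF < 35%
        CovariateSpec("country"),  # 1 = UK, 0 = Canada
        age_spec,
    ]
    if interactions is not None:
        covs.append(interactions)
    return tuple(covs)


def _column_range(covariates: Sequence[CovariateSpec], name: str) -> list[int]:
    """1-based column indices of a covariate's expansion."""
    k = 1
    for cov in covariates:
        if cov.name == name:
            return list(range(k, k + cov.n_columns))
        k += cov.n_columns
    raise KeyError(name)


def _icd_constraints(covariates: Sequence[CovariateSpec],
                     extra_zero: set[Slot] | None = None,
                     unzero_stay_age: bool = False) -> ConstraintSet:
    """Base-case constraint system over the eight-state space.

    * death-row slots tied across source states (one parameter per column),
    * hospital length-of-stay rows keep only the country effect,
    * no country effect on admission for, or stay in, the drug-side-effect
      state (7).
    """
    sp = icd_state_space()
    K = sum(c.n_columns for c in covariates)
    cols = ["mu"] + [n for c in covariates for n in c.column_names()]
    country = _column_range(covariates, "country")[0]

    tie_groups = []
    for k in range(K + 1):
        name = "mu_D" if k == 0 else f"beta_D_{cols[k]}"
        tie_groups.append((name, frozenset((r, 8, k) for r in range(1, 8))))

    zero: set[Slot] = set()
    for r in range(2, 8):  # stay rows: only country
        for k in range(1, K + 1):
            if k != country:
                zero.add((r, r, k))
    zero.add((1, 7, country))
    zero.add((7, 7, country))
    if unzero_stay_age:
        for r in range(2, 8):
            for k in _column_range(covariates, "age"):
                zero.discard((r, r, k))
    if extra_zero:
        zero |= extra_zero
    return ConstraintSet(tuple(tie_groups), frozenset(zero))


def _piecewise_age() -> CovariateSpec:
    return CovariateSpec("age", kind="age-derived",
                         age_transform=AgeTransform("piecewise"))


def _poly_age(degree: int) -> CovariateSpec:
    return CovariateSpec("age", kind="age-derived",
                         age_transform=AgeTransform("polynomial", degree=degree))


def _poly_age_x_aad(degree: int) -> CovariateSpec:
    return CovariateSpec("aad_x_age", kind="age-derived",
                         age_transform=AgeTransform("polynomial", degree=degree),
                         interact_with="aad")


def build_model_config(label: str) -> ModelConfig:
    """Factory for the base-case model variant M1 and alternatives M2-M10.

    M1   four binary baseline covariates + piecewise-constant age,
         death-row tying, stay rows restricted to a country effect;
    M2   M1 + piecewise age effect on hospital length of stay;
    M3   M1 with all effects except treatment removed from admission for
         drug side-effects;
    M4   M1 with sex effects removed except on death and arrhythmic
         admission;
    M5-M7   piecewise age replaced by a degree 2/3/4 age polynomial;
    M8-M10  M5-M7 plus treatment interactions with every age term.
    """
    sp = icd_state_space()
    if label == "M1":
        covs = _baseline_covariates(_piecewise_age())
        return ModelConfig(label, sp, covs, _icd_constraints(covs))
    if label == "M2":
        covs = _baseline_covariates(_piecewise_age())
        return ModelConfig(label, sp, covs,
                           _icd_constraints(covs, unzero_stay_age=True))
    if label == "M3":
        covs = _baseline_covariates(_piecewise_age())
        keep = set(_column_range(covs, "aad"))
        K = sum(c.n_columns for c in covs)
        extra = {(1, 7, k) for k in range(1, K + 1) if k not in keep}
        return ModelConfig(label, sp, covs, _icd_constraints(covs, extra_zero=extra))
    if label == "M4":
        covs = _baseline_covariates(_piecewise_age())
        sex = _column_range(covs, "sex")[0]
        extra = {(1, s, sex) for s in range(3, 8)}
        return ModelConfig(label, sp, covs, _icd_constraints(covs, extra_zero=extra))
    if label in ("M5", "M6", "M7"):
        degree = {"M5": 2, "M6": 3, "M7": 4}[label]
        covs = _baseline_covariates(_poly_age(degree))
        return ModelConfig(label, sp, covs, _icd_constraints(covs))
    if label in ("M8", "M9", "M10"):
        degree = {"M8": 2, "M9": 3, "M10": 4}[label]
        covs = _baseline_covariates(_poly_age(degree), _poly_age_x_aad(degree))
        return ModelConfig(label, sp, covs, _icd_constraints(covs))
    raise ValueError(f"unknown model label {label!r}; expected M1..M10")


def two_state_config(covariates: tuple[CovariateSpec, ...] = ()) -> ModelConfig:
    """Minimal alive/dead structure (single free intercept when no
    covariates are given); used for sampler validation."""
    return ModelConfig("two_state", two_state_space(), covariates)


# ---------------------------------------------------------------------------
# serialization (lossless structured-text round trip)
# ---------------------------------------------------------------------------

def config_to_dict(config: ModelConfig) -> dict:
    sp = config.state_space
    return {
        "label": config.label,
        "states": list(sp.states),
        "absorbing": sorted(sp.absorbing),
        "permitted": sorted([list(p) for p in sp.permitted]),
        "covariates": [
            {
                "name": c.name,
                "kind": c.kind,
                "interact_with": c.interact_with,
                "age_transform": None if c.age_transform is None else {
                    "kind": c.age_transform.kind,
                    "cutpoints": list(c.age_transform.cutpoints),
                    "degree": c.age_transform.degree,
                    "center": c.age_transform.center,
                    "scale": c.age_transform.scale,
                },
            }
            for c in config.covariates
        ],
        "tie_groups": [
            {"name": name, "slots": sorted([list(s) for s in group])}
            for name, group in config.constraints.tie_groups
        ],
        "zero_set": sorted([list(s) for s in config.constraints.zero_set]),
    }


def config_from_dict(d: Mapping) -> ModelConfig:
    sp = StateSpace(
        tuple(d["states"]),
        frozenset(d["absorbing"]),
        frozenset(tuple(p) for p in d["permitted"]),
    )
    covs = []
    for c in d["covariates"]:
        at = c.get("age_transform")
        covs.append(CovariateSpec(
            c["name"], c["kind"],
            None if at is None else AgeTransform(
                at["kind"], tuple(at["cutpoints"]), at["degree"],
                at["center"], at["scale"],
            ),
            c.get("interact_with"),
        ))
    ties = tuple(
        (g["name"], frozenset(tuple(s) for s in g["slots"]))
        for g in d["tie_groups"]
    )
    zeros = frozenset(tuple(s) for s in d["zero_set"])
    return ModelConfig(d["label"], sp, tuple(covs), ConstraintSet(ties, zeros))
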