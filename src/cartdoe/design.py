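"""Factor space, coded units and experimental-design construction.

The factor space mirrors the expansion study: number of activation steps
(1 or 2, treated as a two-level categorical), seed-train length (3/5/7 days),
seeding density (0.25/0.5/0.75 x 10^6 cells) and IL-2 dose (30/65/100 IU/mL).
Numeric factors are orthogonally scaled to coded units,
x -> (x - midrange) / halfrange, so every declared level lands in [-1, +1];
the two-level categorical maps to -1/+1. Model matrices carry an intercept,
main effects in declaration order and two-way interaction columns (products
of coded mains) in lexicographic order. Exact designs are picked from the
full factorial candidate set by greedy Fedorov exchange on det(X'X).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Term = tuple[str, ...]
INTERCEPT: Term = ()

FACTOR_KINDS = ("discrete-numeric", "continuous", "two-level-categorical")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Factor:
    name: str
    kind: str
    levels: tuple
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FACTOR_KINDS:
            raise DesignError(f"factor {self.name}: unknown kind {self.kind!r}")
        levels = tuple(float(v) for v in self.levels)
        if len(set(levels)) < 2:
            raise DesignError(f"factor {self.name}: needs >=2 distinct levels")
        if self.kind == "two-level-categorical" and len(levels) != 2:
            raise DesignError(f"factor {self.name}: categorical factors take exactly 2 levels")
        if list(levels) != sorted(levels):
            raise DesignError(f"factor {self.name}: levels must be sorted ascending")
        object.__setattr__(self, "levels", levels)

    @property
    def low(self) -> float:
        return self.levels[0]

    @property
    def high(self) -> float:
        return self.levels[-1]

    def code(self, value: float) -> float:
        """Natural level -> coded unit in [-1, +1]."""
        value = float(value)
        if not any(np.isclose(value, lv) for lv in self.levels):
            raise DesignError(
                f"factor {self.name}: {value} is not a declared level {self.levels}"
            )
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return (value - mid) / half

    def decode(self, coded: float) -> float:
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        value = coded * half + mid
        # snap to the nearest declared level when essentially on it
        for lv in self.levels:
            if np.isclose(value, lv):
                return lv
        return value


def table1_factors() -> list[Factor]:
    """The four process parameters of the expansion DOE."""
    return [
        Factor("activations", "two-level-categorical", (1, 2), ""),
        Factor("seed_train_days", "discrete-numeric", (3, 5, 7), "days"),
        Factor("seeding_density", "discrete-numeric", (0.25e6, 0.5e6, 0.75e6), "cells/cm^2"),
        Factor("il2_iu_per_ml", "discrete-numeric", (30, 65, 100), "IU/mL"),
    ]


@dataclass(frozen=True)
class DesignSpace:
    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignError("duplicate factor names")

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise DesignError(f"unknown factor {name!r}; declared: {self.factor_names}")

    def candidate_set(self) -> pd.DataFrame:
        """Full cross of declared levels, one row per candidate run."""
        combos = itertools.product(*(f.levels for f in self.factors))
        return pd.DataFrame(combos, columns=self.factor_names)

    def encode(self, runs: pd.DataFrame) -> pd.DataFrame:
        """Natural-unit settings -> coded-unit settings, column per factor."""
        coded = {}
        for f in self.factors:
            if f.name not in runs.columns:
                raise DesignError(f"runs table missing factor column {f.name!r}")
            coded[f.name] = [f.code(v) for v in runs[f.name]]
        return pd.DataFrame(coded, index=runs.index)


def default_space() -> DesignSpace:
    return DesignSpace(tuple(table1_factors()))


# ---------------------------------------------------------------------------
# model terms and matrices
# ---------------------------------------------------------------------------

def main_effect_terms(space: DesignSpace) -> list[Term]:
    return [(name,) for name in space.factor_names]


def two_way_terms(space: DesignSpace) -> list[Term]:
    names = space.factor_names
    return [tuple(pair) for pair in itertools.combinations(names, 2)]


def full_interaction_terms(space: DesignSpace) -> list[Term]:
    """Intercept + mains + all two-way interactions."""
    return [INTERCEPT] + main_effect_terms(space) + two_way_terms(space)


def canonical_term_order(space: DesignSpace, terms: list[Term]) -> list[Term]:
    """Intercept first, then mains in declaration order, then interactions
    lexicographically (factor order normalised within each term)."""
    order = {name: i for i, name in enumerate(space.factor_names)}
    normed = []
    for t in terms:
        for name in t:
            if name not in order:
                raise DesignError(f"term {t} references undeclared factor {name!r}")
        normed.append(tuple(sorted(t, key=order.__getitem__)))
    if len(set(normed)) != len(normed):
        raise DesignError(f"duplicate model terms in {terms}")

    def key(t: Term):
        return (len(t), tuple(order[name] for name in t))

    return sorted(normed, key=key)


def term_label(term: Term) -> str:
    return "intercept" if term == INTERCEPT else "*".join(term)


def model_matrix(space: DesignSpace, runs: pd.DataFrame,
                 terms: list[Term] | None = None) -> tuple[np.ndarray, list[Term]]:
    """Coded-unit model matrix (runs x terms) in canonical column order."""
    if terms is None:
        terms = full_interaction_terms(space)
    terms = canonical_term_order(space, terms)
    coded = space.encode(runs)
    cols = []
    for t in terms:
        if t == INTERCEPT:
            cols.append(np.ones(len(runs)))
        else:
            col = np.ones(len(runs))
            for name in t:
                col = col * coded[name].to_numpy()
            cols.append(col)
    return np.column_stack(cols), terms


# ---------------------------------------------------------------------------
# D-optimal selection (greedy Fedorov exchange)
# ---------------------------------------------------------------------------

def _logdet(X: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(X.T @ X)
    return val if sign > 0 else -np.inf


def select_d_optimal(space: DesignSpace, n_runs: int, terms: list[Term] | None = None,
                     seed: int = 0, n_restarts: int = 4) -> pd.DataFrame:
    """Choose ``n_runs`` rows of the candidate set maximising det(X'X).

    Greedy Fedorov exchange: starting from a random nonsingular subset, swap
    the (design point, candidate) pair with the best det improvement until no
    swap helps. Deterministic given ``seed``.
    """
    candidates = space.candidate_set()
    if terms is None:
        terms = full_interaction_terms(space)
    terms = canonical_term_order(space, terms)
    k = len(terms)
    if n_runs < k:
        raise DesignError(f"n_runs={n_runs} < {k} model terms: design infeasible")
    n_cand = len(candidates)
    if n_runs >= n_cand:
        return candidates.copy()

    Xall, _ = model_matrix(space, candidates, terms)
    rng = np.random.default_rng(seed)
    best_idx, best_val = None, -np.inf

    for _ in range(n_restarts):
        for _ in range(50):  # draw until nonsingular start
            idx = list(rng.choice(n_cand, size=n_runs, replace=False))
            if np.isfinite(_logdet(Xall[idx])):
                break
        current = _logdet(Xall[idx])
        improved = True
        while improved:
            improved = False
            in_set = set(idx)
            best_swap, best_gain = None, 1e-10
            for pos in range(n_runs):
                for j in range(n_cand):
                    if j in in_set:
                        continue
                    trial = idx.copy()
                    trial[pos] = j
                    gain = _logdet(Xall[trial]) - current
                    if gain > best_gain:
                        best_gain, best_swap = gain, (pos, j)
            if best_swap is not None:
                pos, j = best_swap
                idx[pos] = j
                current = _logdet(Xall[idx])
                improved = True
        if current > best_val:
            best_val, best_idx = current, sorted(idx)

    if not np.isfinite(best_val):
        raise DesignError("could not find a nonsingular design; increase n_runs")
    return candidates.iloc[best_idx].reset_index(drop=True)


def default_design(space: DesignSpace | None = None, seed: int = 0,
                   n_runs: int = 26, n_replicates: int = 3) -> pd.DataFrame:
    """Default study design: D-optimal subset for mains + all two-way
    interactions, plus replicates of the centre-most candidate point for a
    pure-error check (the categorical factor is held at its low level)."""
    space = space or default_space()
    selected = select_d_optimal(space, n_runs - n_replicates,
                                full_interaction_terms(space), seed=seed)
    candidates = space.candidate_set()
    coded = space.encode(candidates).to_numpy()
    centre = candidates.iloc[int(np.argmin(np.abs(coded).sum(axis=1)))]
    reps = pd.DataFrame([centre] * n_replicates)
    design = pd.concat([selected, reps], ignore_index=True)
    design.index.name = None
    return design
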