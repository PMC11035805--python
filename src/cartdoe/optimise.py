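"""Multi-response desirability optimisation over the factor lattice.

Each fitted response model is evaluated at every lattice point (by default
the full cross of tested levels). Predictions are rescaled to per-response
desirabilities d in [0, 1] — linear from worst to best over the lattice's
prediction range, direction set by the goal — and aggregated by a weighted
geometric mean, so a setting that zeroes any scored response scores zero
overall. The best and worst settings correspond to the process operating
points one would carry forward and avoid, respectively. Factors that appear
in no model leave the score flat; their levels tie, and the lowest level is
reported with an explicit inactive-factor annotation rather than as a
pseudo-optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpace
from .mlr import FittedModel

GOALS = ("maximize", "minimize", "ignore")


class OptimisationError(ValueError):
    pass


@dataclass
class OptimisationSpec:
    """Per-response goals, optional positive weights, optional search lattice."""

    goals: dict[str, str]
    weights: dict[str, float] | None = None
    lattice: pd.DataFrame | None = None
    aggregation: str = "geometric"  # or "arithmetic"

    def __post_init__(self) -> None:
        for resp, goal in self.goals.items():
            if goal not in GOALS:
                raise OptimisationError(f"{resp}: unknown goal {goal!r}")
        scored = [r for r, g in self.goals.items() if g != "ignore"]
        if not scored:
            raise OptimisationError("at least one response must not be ignored")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise OptimisationError("weights must be positive")
        if self.aggregation not in ("geometric", "arithmetic"):
            raise OptimisationError(f"unknown aggregation {self.aggregation!r}")

    def scored_responses(self) -> list[str]:
        return [r for r, g in self.goals.items() if g != "ignore"]

    def weight(self, response: str) -> float:
        if self.weights is None:
            return 1.0
        return float(self.weights.get(response, 1.0))


def desirability(predictions: dict[str, float], spec: OptimisationSpec,
                 ranges: dict[str, tuple[float, float]]) -> float:
    """Overall desirability of one candidate setting.

    ``ranges`` gives each scored response's (min, max) over the search space;
    a degenerate range drops that response from scoring with a warning.
    """
    ds, ws = [], []
    for resp in spec.scored_responses():
        lo, hi = ranges[resp]
        if hi <= lo:
            warnings.warn(
                f"response {resp!r} has a degenerate prediction range "
                f"[{lo}, {hi}]; ignored in the desirability score"
            )
            continue
        d = (predictions[resp] - lo) / (hi - lo)
        if spec.goals[resp] == "minimize":
            d = 1.0 - d
        ds.append(min(1.0, max(0.0, d)))
        ws.append(spec.weight(resp))
    if not ds:
        raise OptimisationError("no scorable responses (all ranges degenerate)")
    ds, ws = np.asarray(ds), np.asarray(ws)
    if spec.aggregation == "arithmetic":
        return float(np.average(ds, weights=ws))
    if np.any(ds == 0.0):
        return 0.0
    return float(np.exp(np.average(np.log(ds), weights=ws)))


@dataclass
class OptimisationResult:
    best: dict
    worst: dict
    table: pd.DataFrame                 # lattice + predictions + desirability, ranked
    inactive_factors: list[str] = field(default_factory=list)
    best_predictions: dict[str, float] = field(default_factory=dict)
    worst_predictions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "worst": self.worst,
            "inactive_factors": self.inactive_factors,
            "best_predictions": self.best_predictions,
            "worst_predictions": self.worst_predictions,
        }


def find_optimum(models: dict[str, FittedModel], space: DesignSpace,
                 spec: OptimisationSpec) -> OptimisationResult:
    """Exhaustively score the lattice and return best/worst settings.

    The lattice is evaluated in a deterministic order (sorted ascending by
    factor levels), so among tied settings the lowest levels are reported.
    """
    lattice = spec.lattice if spec.lattice is not None else space.candidate_set()
    if len(lattice) == 0:
        raise OptimisationError("empty search lattice")
    missing = [r for r in spec.scored_responses() if r not in models]
    if missing:
        raise OptimisationError(f"no fitted model for scored responses: {missing}")

    lattice = (
        lattice.sort_values(space.factor_names).reset_index(drop=True)
    )
    preds = {
        resp: models[resp].predict(space, lattice)
        for resp in spec.scored_responses()
    }
    ranges = {resp: (float(v.min()), float(v.max())) for resp, v in preds.items()}

    scores = np.array([
        desirability({r: preds[r][i] for r in preds}, spec, ranges)
        for i in range(len(lattice))
    ])
    # secondary key: the arithmetic aggregate, so points tied at zero by the
    # geometric mean's zeroing rule still rank by how bad they are overall
    arith = OptimisationSpec(goals=spec.goals, weights=spec.weights,
                             aggregation="arithmetic")
    secondary = np.array([
        desirability({r: preds[r][i] for r in preds}, arith, ranges)
        for i in range(len(lattice))
    ])

    active = set().union(*(models[r].factors_in_model() for r in preds)) if preds else set()
    inactive = [name for name in space.factor_names if name not in active]

    table = lattice.copy()
    for resp, v in preds.items():
        table[f"pred_{resp}"] = v
    table["desirability"] = scores
    table = table.sort_values("desirability", ascending=False, kind="stable")
    table = table.reset_index(drop=True)

    # stable lexicographic selection: primary score, then the arithmetic
    # aggregate; exact ties resolve to the lowest factor levels
    i_best = int(np.lexsort((-secondary, -scores))[0])
    i_worst = int(np.lexsort((secondary, scores))[0])
    best = lattice.iloc[i_best].to_dict()
    worst = lattice.iloc[i_worst].to_dict()
    return OptimisationResult(
        best=best,
        worst=worst,
        table=table,
        inactive_factors=inactive,
        best_predictions={r: float(preds[r][i_best]) for r in preds},
        worst_predictions={r: float(preds[r][i_worst]) for r in preds},
    )
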