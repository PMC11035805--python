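"""Response-surface regression: OLS fit, significance pruning with hierarchy,
and R2/Q2 model validation.

Each response is modelled in coded units as intercept + main effects +
two-way interactions. Terms are pruned by backward elimination at alpha
(default 0.05), never dropping a main effect while an interaction containing
it is retained. Model quality is judged by descriptive R2 and predictive Q2
(leave-one-out cross-validation, Q2 = 1 - PRESS/SStot); a gap R2 - Q2 above
0.2 flags an over-optimistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import (
    DesignSpace, INTERCEPT, Term, canonical_term_order, model_matrix, term_label,
)

DEFAULT_ALPHA = 0.05
DEFAULT_Q2_GAP = 0.2


class ModelError(ValueError):
    pass


class RankDeficiencyError(ModelError):
    pass


@dataclass
class FittedModel:
    """An OLS fit of one response with its diagnostics.

    ``hierarchy_terms`` are main effects kept only because a retained
    interaction contains them (their own p-value exceeds alpha).
    """

    response_name: str
    terms: list[Term]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r2: float
    q2: float
    press: float
    model_p: float
    residuals: np.ndarray
    n: int
    df_resid: int
    hierarchy_terms: set[Term] = field(default_factory=set)
    validity: dict[str, bool] = field(default_factory=dict)

    @property
    def term_labels(self) -> list[str]:
        return [term_label(t) for t in self.terms]

    def coefficient(self, term: Term) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def factors_in_model(self) -> set[str]:
        return {name for t in self.terms for name in t}

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients

    def predict(self, space: DesignSpace, runs: pd.DataFrame) -> np.ndarray:
        X, _ = model_matrix(space, runs, self.terms)
        return self.predict_matrix(X)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term_labels,
            "coefficient": self.coefficients,
            "se": self.standard_errors,
            "t": self.t_values,
            "p": self.p_values,
            "hierarchy_only": [t in self.hierarchy_terms for t in self.terms],
        })

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "terms": self.term_labels,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "r2": self.r2,
            "q2": self.q2,
            "press": self.press,
            "model_p": self.model_p,
            "hierarchy_terms": [term_label(t) for t in sorted(self.hierarchy_terms)],
            "validity": self.validity,
        }


def _check_rank(X: np.ndarray, terms: list[Term]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ModelError(
            f"{X.shape[0]} runs cannot identify {X.shape[1]} terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated via near-zero R diagonal of a pivoted QR
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [term_label(terms[i]) for i in np.nonzero(diag < 1e-10 * diag.max())[0]]
        raise RankDeficiencyError(
            f"model matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad or 'unresolved'}"
        )


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return np.sum(Q * Q, axis=1)


def q_squared(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Leave-one-out Q2 and PRESS via the hat-matrix identity.

    The LOO prediction error for observation i is e_i / (1 - h_ii); PRESS is
    the sum of their squares and Q2 = 1 - PRESS / SStot (SStot about the
    mean). Identical to refitting the model n times with one row held out.
    """
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    h = hat_diagonal(X)
    if np.any(h > 1 - 1e-12):
        raise ModelError(
            "leave-one-out undefined: a run has leverage 1 "
            f"(rows {np.nonzero(h > 1 - 1e-12)[0].tolist()})"
        )
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        # constant response: fit is legitimate, predictive power undefined
        return float("nan"), press
    return 1.0 - press / sstot, press


def fit_ols(X: np.ndarray, y: np.ndarray, terms: list[Term],
            response_name: str = "response") -> FittedModel:
    """Ordinary least squares on a coded model matrix with full diagnostics."""
    y = np.asarray(y, dtype=float)
    _check_rank(X, terms)
    res = sm.OLS(y, X).fit()
    q2, press = q_squared(X, y)
    has_intercept = INTERCEPT in terms
    non_intercept = [i for i, t in enumerate(terms) if t != INTERCEPT]
    if non_intercept and has_intercept:
        model_p = float(res.f_pvalue)
    else:
        model_p = float("nan")
    return FittedModel(
        response_name=response_name,
        terms=list(terms),
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        t_values=np.asarray(res.tvalues, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        r2=float(res.rsquared),
        q2=q2,
        press=press,
        model_p=model_p,
        residuals=np.asarray(res.resid, dtype=float),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def model_significance(model: FittedModel) -> float:
    """Overall F-test p-value of all non-intercept terms vs intercept-only."""
    if all(t == INTERCEPT for t in model.terms):
        raise ModelError("intercept-only model: overall F-test undefined")
    return model.model_p


def _protected_mains(terms: list[Term]) -> set[Term]:
    """Main effects contained in any retained interaction (hierarchy rule)."""
    out: set[Term] = set()
    for t in terms:
        if len(t) >= 2:
            out.update((name,) for name in t)
    return out


def backward_eliminate(
    space: DesignSpace,
    runs: pd.DataFrame,
    y: np.ndarray,
    terms: list[Term] | None = None,
    alpha: float = DEFAULT_ALPHA,
    q2_gap: float = DEFAULT_Q2_GAP,
    response_name: str = "response",
) -> FittedModel:
    """Prune a full model until every removable term is significant.

    At each step the single worst term with p > alpha is dropped and the
    model refit. The intercept is never dropped; a main effect is frozen
    while any retained interaction contains it (so interactions leave before
    their parents). Ties on p prefer the higher-order term, then the later
    column. Idempotent, and may legitimately end intercept-only.
    """
    if terms is None:
        from .design import full_interaction_terms
        terms = full_interaction_terms(space)
    current = canonical_term_order(space, terms)

    while True:
        X, current = model_matrix(space, runs, current)
        model = fit_ols(X, y, current, response_name)
        protected = _protected_mains(current)
        candidates = [
            (model.p_values[i], len(t), i, t)
            for i, t in enumerate(current)
            if t != INTERCEPT and t not in protected and model.p_values[i] > alpha
        ]
        if not candidates:
            break
        _, _, _, worst = max(candidates)
        current = [t for t in current if t != worst]

    protected = _protected_mains(model.terms)
    model.hierarchy_terms = {
        t for i, t in enumerate(model.terms)
        if t in protected and model.p_values[i] > alpha
    }
    own_p = [
        model.p_values[i] for i, t in enumerate(model.terms)
        if t != INTERCEPT and t not in model.hierarchy_terms
    ]
    model.validity = {
        "r2_q2_gap_ok": bool(model.r2 - model.q2 <= q2_gap),
        "all_terms_significant_or_hierarchy": bool(
            all(p <= alpha for p in own_p)
        ),
    }
    return model


# ---------------------------------------------------------------------------
# effect views (plot-ready tables)
# ---------------------------------------------------------------------------

def _reference_settings(space: DesignSpace, reference: dict | None) -> dict:
    """Default slice point: numeric factors at their midrange level, the
    two-level categorical at its low level."""
    ref = {}
    for f in space.factors:
        if reference and f.name in reference:
            ref[f.name] = reference[f.name]
        elif f.kind == "two-level-categorical":
            ref[f.name] = f.low
        else:
            ref[f.name] = f.levels[len(f.levels) // 2]
    return ref


def coefficient_table(model: FittedModel, ci_level: float = 0.95) -> pd.DataFrame:
    """Coefficients with t-based confidence intervals, for coefficient plots."""
    tcrit = stats.t.ppf(0.5 + ci_level / 2, model.df_resid)
    df = model.summary_frame()
    df["ci_lo"] = df["coefficient"] - tcrit * df["se"]
    df["ci_hi"] = df["coefficient"] + tcrit * df["se"]
    return df


def interaction_view(model: FittedModel, space: DesignSpace, factor_x: str,
                     factor_trace: str, reference: dict | None = None) -> pd.DataFrame:
    """Predicted response vs ``factor_x`` at each level of ``factor_trace``,
    remaining factors held at reference values; parallel lines mean no
    interaction."""
    in_model = model.factors_in_model()
    for name in (factor_x, factor_trace):
        if name not in in_model:
            raise ModelError(f"factor {name!r} does not appear in the model")
    ref = _reference_settings(space, reference)
    rows = []
    for trace_level in space.factor(factor_trace).levels:
        for x_level in space.factor(factor_x).levels:
            settings = dict(ref)
            settings[factor_x] = x_level
            settings[factor_trace] = trace_level
            rows.append(settings)
    grid = pd.DataFrame(rows)
    grid["predicted"] = model.predict(space, grid)
    return grid[[factor_x, factor_trace, "predicted"]]


def contour_grid(model: FittedModel, space: DesignSpace, factor_x: str,
                 factor_y: str, reference: dict | None = None,
                 n: int = 21) -> pd.DataFrame:
    """Predictions over an x-y lattice of two factors (coded-unit linspace
    between the declared extremes), the rest at reference values."""
    in_model = model.factors_in_model()
    for name in (factor_x, factor_y):
        if name not in in_model:
            raise ModelError(f"factor {name!r} does not appear in the model")
    ref = _reference_settings(space, reference)
    fx, fy = space.factor(factor_x), space.factor(factor_y)
    xs = np.linspace(fx.low, fx.high, n)
    ys = np.linspace(fy.low, fy.high, n)
    rows = []
    for yv in ys:
        for xv in xs:
            settings = dict(ref)
            settings[factor_x] = xv
            settings[factor_y] = yv
            rows.append(settings)
    grid = pd.DataFrame(rows)
    # grid points fall between declared levels: bypass level validation by
    # coding against the factor range directly
    coded = {}
    for f in space.factors:
        mid = 0.5 * (f.low + f.high)
        half = 0.5 * (f.high - f.low)
        coded[f.name] = (grid[f.name].to_numpy() - mid) / half
    X = np.column_stack([
        np.ones(len(grid)) if t == INTERCEPT
        else np.prod([coded[name] for name in t], axis=0)
        for t in model.terms
    ])
    grid["predicted"] = model.predict_matrix(X)
    return grid[[factor_x, factor_y, "predicted"]]


def effect_views(model: FittedModel, space: DesignSpace,
                 interaction: tuple[str, str] | None = None,
                 contour: tuple[str, str] | None = None,
                 reference: dict | None = None) -> dict[str, pd.DataFrame]:
    """Bundle of plot-ready tables: coefficient plot, optional interaction
    view and contour grid."""
    views = {"coefficients": coefficient_table(model)}
    if interaction is not None:
        views["interaction"] = interaction_view(model, space, *interaction,
                                                reference=reference)
    if contour is not None:
        views["contour"] = contour_grid(model, space, *contour,
                                        reference=reference)
    return views
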