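"""Synthetic DOE studies with known ground truth.

The raw donor data behind the expansion study are not deposited, so every
downstream stage is exercised on generated studies that emulate its factor
structure: a D-optimal run set over the four process parameters, response
values drawn from a sparse linear model in coded units (known intercepts,
main effects and two-way interactions) plus an additive per-donor shift and
Gaussian residual, and full culture/metabolite time series constructed by
inverting the kinetic rate equations so the kinetics stage recovers the
generating rates exactly in the noiseless limit.

Default effect signs follow the study's qualitative conclusions — a strong
adverse effect of a second activation on growth, a strong positive effect on
exhaustion-marker expression, moderate seed-train effects of the same signs
and an activations x seed-train interaction — with magnitudes anchored to
the reported group means (e.g. ~4.8 vs ~2.4 cumulative doublings for one vs
two activations). Residual scatter defaults to 5% of each response's
noiseless range over the candidate lattice, donor scatter to 2%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from .design import DesignSpace, Term, default_design, default_space, model_matrix
from .kinetics import CultureTimeSeries, MetabolitePanel

LN2 = np.log(2.0)

#: responses carried in a generated study's table
RESPONSE_COLUMNS = (
    "cpd", "fold", "cd69_pct", "pd1lag3_pct", "q_gluc", "p_lac", "dlac_dgluc",
)


class SyntheticConfigError(ValueError):
    pass


@dataclass
class GroundTruth:
    """True linear model (coded units) for one response."""

    response_name: str
    intercept: float
    coefficients: dict[Term, float]
    donor_sd: float = 0.0
    residual_sd: float = 0.0
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.donor_sd < 0 or self.residual_sd < 0:
            raise SyntheticConfigError(
                f"{self.response_name}: noise scales must be non-negative"
            )
        self.coefficients = {tuple(k): float(v) for k, v in self.coefficients.items()}

    def terms(self) -> list[Term]:
        return [(), *self.coefficients.keys()]

    def nonzero_terms(self) -> set[Term]:
        return {t for t, c in self.coefficients.items() if c != 0.0}

    def linear_predictor(self, space: DesignSpace, runs: pd.DataFrame) -> np.ndarray:
        for t in self.coefficients:
            for name in t:
                if name not in space.factor_names:
                    raise SyntheticConfigError(
                        f"{self.response_name}: term {t} references unknown "
                        f"factor {name!r}"
                    )
        X, terms = model_matrix(space, runs, self.terms())
        beta = np.array([
            self.intercept if t == () else self.coefficients[t] for t in terms
        ])
        return X @ beta


@dataclass
class StoichiometryProfile:
    """Coupling of glucose use to growth and lactate output.

    ``lactate_per_glucose`` is the molar yield (2 is the glycolytic ceiling);
    ``glucose_per_doubling`` is mmol consumed per 1e6 new cells produced.
    """

    lactate_per_glucose: float = 1.7
    glucose_per_doubling: float = 2e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.lactate_per_glucose <= 2.0:
            raise SyntheticConfigError(
                "lactate_per_glucose must lie in [0, 2] (glycolytic ceiling)"
            )
        if self.glucose_per_doubling <= 0:
            raise SyntheticConfigError("glucose_per_doubling must be positive")


@dataclass
class SyntheticStudy:
    design: pd.DataFrame            # factor settings + run_id + donor_id
    truths: list[GroundTruth]
    seed: int
    donors: int = 3
    space: DesignSpace = field(default_factory=default_space)

    def __post_init__(self) -> None:
        for f in self.space.factors:
            if self.design[f.name].nunique() < 2:
                raise SyntheticConfigError(
                    f"design does not vary factor {f.name!r}"
                )

    def truth(self, response: str) -> GroundTruth:
        for t in self.truths:
            if t.response_name == response:
                return t
        raise SyntheticConfigError(f"no ground truth for response {response!r}")


# ---------------------------------------------------------------------------
# default ground truths (study-condition effect structure)
# ---------------------------------------------------------------------------

def _range_scaled(space: DesignSpace, intercept: float,
                  coefficients: dict[Term, float]) -> float:
    """Noiseless predictor range over the full candidate lattice."""
    gt = GroundTruth("tmp", intercept, coefficients)
    pred = gt.linear_predictor(space, space.candidate_set())
    return float(pred.max() - pred.min())


def default_truths(space: DesignSpace | None = None,
                   residual_frac: float = 0.05,
                   donor_frac: float = 0.02) -> list[GroundTruth]:
    """Ground truths with the study's qualitative effect structure.

    Growth (cpd) is hurt most by a second activation, moderately by longer
    seed trains and higher seeding density, with an activations x seed-train
    interaction; exhaustion (PD1+LAG3+ %) mirrors those signs positively;
    per-cell glucose consumption, lactate production and the lactate yield
    rise with a second activation. IL-2 is truly inert everywhere. Noise
    scales are fractions of each response's noiseless lattice range.
    """
    space = space or default_space()
    act, st, dens = ("activations",), ("seed_train_days",), ("seeding_density",)
    specs = [
        # (name, intercept, coefficients, bounds)
        ("cpd", 3.6, {act: -1.2, st: -0.4, dens: -0.2, (act[0], st[0]): -0.3}, None),
        ("pd1lag3_pct", 63.0, {act: 14.5, st: 5.0, (act[0], st[0]): 4.0}, (0.0, 100.0)),
        ("cd69_pct", 45.0, {act: 14.0, st: 5.0, (act[0], st[0]): 5.0}, (0.0, 100.0)),
        ("q_gluc", 2.0, {act: 0.7, st: 0.2}, (0.0, np.inf)),
        ("p_lac", 3.5, {act: 1.4, st: 0.35}, (0.0, np.inf)),
        ("dlac_dgluc", 1.75, {act: 0.14}, (0.0, 2.0)),
    ]
    truths = []
    for name, intercept, coefs, bounds in specs:
        rng = _range_scaled(space, intercept, coefs)
        truths.append(GroundTruth(
            response_name=name, intercept=intercept, coefficients=coefs,
            donor_sd=donor_frac * rng, residual_sd=residual_frac * rng,
            bounds=bounds,
        ))
    return truths


def make_study(space: DesignSpace | None = None, seed: int = 0, n_runs: int = 26,
               donors: int = 3, truths: list[GroundTruth] | None = None) -> SyntheticStudy:
    """Assemble a study: default D-optimal design, cyclic donor assignment."""
    space = space or default_space()
    design = default_design(space, seed=seed, n_runs=n_runs)
    design = design.copy()
    design.insert(0, "run_id", [f"R{i + 1:02d}" for i in range(len(design))])
    design.insert(1, "donor_id", [f"HD{i % donors + 1}" for i in range(len(design))])
    return SyntheticStudy(
        design=design, truths=truths if truths is not None else default_truths(space),
        seed=seed, donors=donors, space=space,
    )


# ---------------------------------------------------------------------------
# response generation
# ---------------------------------------------------------------------------

def generate_responses(study: SyntheticStudy) -> pd.DataFrame:
    """Draw one response table from the study's ground truths.

    value = intercept + sum(coef x coded term) + donor shift + N(0, residual);
    bounded responses are clipped. ``fold`` is derived as 2**cpd rather than
    drawn independently. Deterministic given the study seed.
    """
    rng = np.random.default_rng(study.seed)
    table = study.design.copy()
    donor_ids = sorted(table["donor_id"].unique())
    for truth in study.truths:
        pred = truth.linear_predictor(study.space, table)
        shifts = dict(zip(donor_ids, rng.normal(0.0, truth.donor_sd or 0.0,
                                                len(donor_ids))))
        donor_effect = table["donor_id"].map(shifts).to_numpy()
        noise = rng.normal(0.0, truth.residual_sd or 0.0, len(table))
        values = pred + donor_effect + noise
        if truth.bounds is not None:
            values = np.clip(values, *truth.bounds)
        table[truth.response_name] = values
    if "cpd" in table.columns:
        idx = table.columns.get_loc("cpd") + 1
        table.insert(idx, "fold", 2.0 ** table["cpd"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# time-series generation (inverse kinetics)
# ---------------------------------------------------------------------------

@dataclass
class GeneratedRun:
    """A generated culture with its generating rates for round-trip tests."""

    series: CultureTimeSeries
    panels: dict[str, MetabolitePanel]
    true_mu: float
    true_q: dict[str, np.ndarray]       # pmol/cell/day per interval
    true_p: dict[str, np.ndarray]


#: fresh/basal medium composition, mmol/L
MEDIUM = {"glucose": 25.0, "lactate": 1.0, "glutamine": 4.0, "ammonia": 0.4}

#: per-cell glutamine consumption relative to glucose, and ammonia yield per
#: glutamine (phenomenological side panels)
GLUTAMINE_FRACTION = 0.15
AMMONIA_PER_GLUTAMINE = 0.7


def generate_time_series(
    target_cpd: float,
    days: int = 7,
    stoich: StoichiometryProfile | None = None,
    seed: int = 0,
    run_id: str = "R01",
    donor_id: str = "HD1",
    initial_density: float = 0.5e6,     # cells/mL
    volume_ml: float = 7.0,
    perfusion: float = 0.0,
    rate_decline: float = 0.05,         # fractional drop in per-cell rates per day
    q_gluc_pmol: float | None = None,   # pin the window-average glucose rate
    noise_sd: float = 0.0,              # fractional measurement noise
) -> GeneratedRun:
    """Forward-generate a culture by inverting the kinetic rate equations.

    Cells grow exponentially at constant mu = target_cpd * ln2 / days, so the
    final density is exactly 2**target_cpd times the seed. Per-cell metabolic
    rates decline geometrically with culture day (real cultures slow as
    nutrients deplete; a strictly constant rate would also make the lactate
    yield a 0/0). Glucose consumption follows the stoichiometry (or is scaled
    so its day 2-7 window average equals ``q_gluc_pmol``); lactate is
    produced at exactly ``lactate_per_glucose`` per glucose consumed within
    each interval, so the recovered dLac/dGluc equals that yield.
    Consumption is capped at the glucose available (with a warning), never
    driving concentrations negative. Measurement noise, when requested, is
    applied multiplicatively to the exact densities and concentrations.
    """
    if days < 2:
        raise SyntheticConfigError(f"need days >= 2 (got {days})")
    if initial_density <= 0:
        raise SyntheticConfigError("initial density must be positive")
    stoich = stoich or StoichiometryProfile()
    rng = np.random.default_rng(seed)

    times = np.arange(days + 1, dtype=float)
    mu = target_cpd * LN2 / days
    density = initial_density * 2.0 ** (target_cpd * times / days)  # cells/mL
    cells_per_l = density * 1000.0

    decline = (1.0 - rate_decline) ** np.arange(days)   # interval multipliers
    # baseline per-cell glucose rate, mmol/cell/day, from the stoichiometry
    q_base = mu * stoich.glucose_per_doubling / 1e6
    if q_gluc_pmol is not None:
        # pin the day 2-7 window average of the recovered rate instead
        idx = kin.window_intervals(times, kin.DEFAULT_WINDOW)
        q_base = q_gluc_pmol * 1e-9 / np.mean(decline[idx])
    q_sched = q_base * decline                          # mmol/cell/day per interval

    growth_factor = np.expm1(mu) / mu if mu != 0 else 1.0

    conc = {a: np.empty(days + 1) for a in kin.ANALYTES}
    for a in kin.ANALYTES:
        conc[a][0] = MEDIUM[a]
    true_q = {"glucose": np.empty(days), "glutamine": np.empty(days)}
    true_p = {"lactate": np.empty(days), "ammonia": np.empty(days)}

    d = perfusion
    for i in range(days):
        c_prev = cells_per_l[i]
        # glucose: invert the consumption equation, capping at availability
        mix = conc["glucose"][i] * (1 - d) + MEDIUM["glucose"] * d
        demand = q_sched[i] * c_prev * growth_factor
        if demand > mix:
            warnings.warn(
                f"run {run_id}: glucose demand exceeds availability on day "
                f"{i + 1}; consumption capped"
            )
            demand = mix
        conc["glucose"][i + 1] = mix - demand
        q_eff = demand / (c_prev * growth_factor)
        true_q["glucose"][i] = q_eff * 1e9

        # lactate: exact within-interval stoichiometry on consumed glucose
        lac_mix = conc["lactate"][i] * (1 - d)
        conc["lactate"][i + 1] = lac_mix + stoich.lactate_per_glucose * demand
        true_p["lactate"][i] = stoich.lactate_per_glucose * q_eff * 1e9

        # glutamine / ammonia: phenomenological satellites of the glucose flux
        gln_mix = conc["glutamine"][i] * (1 - d) + MEDIUM["glutamine"] * d
        gln_demand = min(GLUTAMINE_FRACTION * demand, gln_mix)
        conc["glutamine"][i + 1] = gln_mix - gln_demand
        true_q["glutamine"][i] = gln_demand / (c_prev * growth_factor) * 1e9
        amm_mix = conc["ammonia"][i] * (1 - d)
        conc["ammonia"][i + 1] = amm_mix + AMMONIA_PER_GLUTAMINE * gln_demand
        true_p["ammonia"][i] = AMMONIA_PER_GLUTAMINE * true_q["glutamine"][i]

    viability = np.clip(97.0 - 0.4 * times, 0.0, 100.0)
    obs_density = density.copy()
    obs_conc = {a: conc[a].copy() for a in kin.ANALYTES}
    if noise_sd > 0:
        obs_density *= np.exp(rng.normal(0.0, noise_sd, days + 1))
        for a in kin.ANALYTES:
            obs_conc[a] = np.maximum(
                obs_conc[a] * np.exp(rng.normal(0.0, noise_sd, days + 1)), 0.0
            )

    series = CultureTimeSeries(
        run_id=run_id, donor_id=donor_id, times=times,
        viable_density=obs_density, viability=viability,
        volume_ml=np.full(days + 1, float(volume_ml)),
        perfusion_rate=np.concatenate([[0.0], np.full(days, float(perfusion))]),
    )
    panels = {
        a: MetabolitePanel(run_id=run_id, analyte=a, concentrations=obs_conc[a],
                           feed_concentration=MEDIUM[a] if a in ("glucose", "glutamine")
                           else 0.0)
        for a in kin.ANALYTES
    }
    # convert true rates to the pmol/cell/day basis used by kinetic_summary:
    # the generator works per litre of culture, so the volume factor is 1 L
    # equivalent -- kinetic_summary multiplies by volume_L and uses total
    # cells, which cancels back to the per-litre-density basis used here
    return GeneratedRun(series=series, panels=panels, true_mu=mu,
                        true_q=true_q, true_p=true_p)


def generate_study_time_series(study: SyntheticStudy,
                               responses: pd.DataFrame,
                               days: int = 7,
                               initial_density: float = 0.1e6,
                               noise_sd: float = 0.0) -> dict[str, GeneratedRun]:
    """Per-run culture/metabolite series consistent with the response table.

    Each run's series is generated so the kinetics stage recovers (in the
    noiseless case, exactly) the run's tabulated cpd, window-average glucose
    consumption and lactate yield.
    """
    out = {}
    child_seeds = np.random.SeedSequence(study.seed).spawn(len(responses))
    for i, (_, row) in enumerate(responses.iterrows()):
        stoich = StoichiometryProfile(
            lactate_per_glucose=min(max(row["dlac_dgluc"], 0.0), 2.0),
        )
        run = generate_time_series(
            target_cpd=float(row["cpd"]), days=days, stoich=stoich,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            run_id=row["run_id"], donor_id=row["donor_id"],
            initial_density=initial_density,
            q_gluc_pmol=float(row["q_gluc"]), noise_sd=noise_sd,
        )
        out[row["run_id"]] = run
    return out
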