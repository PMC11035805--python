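"""File formats, run configuration and the end-to-end pipeline.

CSV schemas (comma-separated, UTF-8, header row required; lines starting
with ``#`` are provenance comments):

* counts:      run_id, donor_id, day, viable_density_cells_per_ml,
               viability_pct, volume_ml, perfusion_rate
* metabolites: run_id, day, analyte, concentration_mmol_per_l,
               feed_concentration_mmol_per_l
* responses:   run_id, donor_id, one column per factor (natural units),
               one column per measured response

Units are fixed by the schema (cells/mL, mL, mmol/L, days); day 0 is the
day of seeding after the seed train. Every file the pipeline writes carries
the config hash on a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .design import DesignSpace, default_space
from .groupstats import comparison_table
from .kinetics import ANALYTES, CultureTimeSeries, KineticSummary, MetabolitePanel, kinetic_summary
from .mlr import DEFAULT_ALPHA, DEFAULT_Q2_GAP, FittedModel, backward_eliminate
from .optimise import OptimisationSpec, find_optimum
from .synthetic import generate_responses, generate_study_time_series, make_study

log = logging.getLogger("cartdoe")

COUNTS_COLUMNS = [
    "run_id", "donor_id", "day", "viable_density_cells_per_ml",
    "viability_pct", "volume_ml", "perfusion_rate",
]
METABOLITE_COLUMNS = [
    "run_id", "day", "analyte", "concentration_mmol_per_l",
    "feed_concentration_mmol_per_l",
]

#: responses derived from time series by the kinetics stage
KINETIC_RESPONSES = ("cpd", "fold", "q_gluc", "p_lac", "dlac_dgluc")
#: end-of-culture marker responses read from the responses file
MARKER_RESPONSES = ("cd69_pct", "pd1lag3_pct")
DEFAULT_RESPONSES = ("cpd", "pd1lag3_pct")


class ParseError(ValueError):
    pass


class PipelineError(RuntimeError):
    """A stage failed; partial outputs were preserved."""


class RunConfig(BaseModel):
    """Everything a pipeline run depends on, in one hashable object."""

    data_dir: Path = Path(".")
    out_dir: Path = Path("results")
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    goals: dict[str, str] = Field(
        default_factory=lambda: {"cpd": "maximize", "pd1lag3_pct": "minimize"}
    )
    alpha: float = DEFAULT_ALPHA
    q2_gap: float = DEFAULT_Q2_GAP
    window: tuple[float, float] = (2.0, 7.0)
    seed: int = 0
    simulate: bool = False
    noise_sd: float = 0.02

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {v}")
        return v

    @field_validator("window")
    @classmethod
    def _window_ascending(cls, v):
        if v[1] <= v[0]:
            raise ValueError(f"window must be ascending, got {v}")
        return v

    def config_hash(self) -> str:
        # hash only analysis-relevant settings, not filesystem locations
        payload = self.model_dump_json(exclude={"out_dir", "data_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_counts_csv(path: Path | str) -> dict[str, CultureTimeSeries]:
    """Load and validate per-run culture time series."""
    df = _read_csv(Path(path), COUNTS_COLUMNS)
    out = {}
    for run_id, grp in df.groupby("run_id", sort=True):
        grp = grp.sort_values("day")
        dup = grp["day"][grp["day"].duplicated()]
        if not dup.empty:
            raise ParseError(
                f"{path}: run {run_id} repeats day(s) {sorted(dup.unique().tolist())}"
            )
        donors = grp["donor_id"].unique()
        if len(donors) != 1:
            raise ParseError(f"{path}: run {run_id} maps to several donors {donors}")
        out[str(run_id)] = CultureTimeSeries(
            run_id=str(run_id), donor_id=str(donors[0]),
            times=grp["day"].to_numpy(float),
            viable_density=grp["viable_density_cells_per_ml"].to_numpy(float),
            viability=grp["viability_pct"].to_numpy(float),
            volume_ml=grp["volume_ml"].to_numpy(float),
            perfusion_rate=grp["perfusion_rate"].to_numpy(float),
        )
    return out


def write_counts_csv(path: Path | str, series: dict[str, CultureTimeSeries],
                     header_comment: str | None = None) -> None:
    rows = []
    for run in series.values():
        for i in range(run.n_points):
            rows.append({
                "run_id": run.run_id, "donor_id": run.donor_id,
                "day": run.times[i],
                "viable_density_cells_per_ml": run.viable_density[i],
                "viability_pct": run.viability[i],
                "volume_ml": run.volume_ml[i],
                "perfusion_rate": run.perfusion_rate[i],
            })
    _write_csv(Path(path), pd.DataFrame(rows, columns=COUNTS_COLUMNS), header_comment)


def read_metabolites_csv(path: Path | str) -> dict[str, dict[str, MetabolitePanel]]:
    """Load per-run, per-analyte concentration panels."""
    df = _read_csv(Path(path), METABOLITE_COLUMNS)
    unknown = sorted(set(df["analyte"]) - set(ANALYTES))
    if unknown:
        raise ParseError(
            f"{path}: unknown analyte(s) {unknown}; accepted names: {', '.join(ANALYTES)}"
        )
    out: dict[str, dict[str, MetabolitePanel]] = {}
    for (run_id, analyte), grp in df.groupby(["run_id", "analyte"], sort=True):
        grp = grp.sort_values("day")
        feed = grp["feed_concentration_mmol_per_l"].to_numpy(float)
        out.setdefault(str(run_id), {})[str(analyte)] = MetabolitePanel(
            run_id=str(run_id), analyte=str(analyte),
            concentrations=grp["concentration_mmol_per_l"].to_numpy(float),
            feed_concentration=float(feed[0]) if feed.size else 0.0,
        )
    return out


def write_metabolites_csv(path: Path | str,
                          panels: dict[str, dict[str, MetabolitePanel]],
                          times: dict[str, np.ndarray],
                          header_comment: str | None = None) -> None:
    rows = []
    for run_id, by_analyte in panels.items():
        for analyte, panel in by_analyte.items():
            for day, conc in zip(times[run_id], panel.concentrations):
                rows.append({
                    "run_id": run_id, "day": day, "analyte": analyte,
                    "concentration_mmol_per_l": conc,
                    "feed_concentration_mmol_per_l": panel.feed_concentration,
                })
    _write_csv(Path(path), pd.DataFrame(rows, columns=METABOLITE_COLUMNS), header_comment)


def read_responses_csv(path: Path | str, space: DesignSpace) -> pd.DataFrame:
    df = _read_csv(Path(path), ["run_id", "donor_id", *space.factor_names])
    space.encode(df)  # validates declared levels
    return df


def _write_csv(path: Path, df: pd.DataFrame, header_comment: str | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def simulate_study_files(config: RunConfig) -> None:
    """Generate a synthetic study and write its input files to data_dir."""
    tag = f"config_hash={config.config_hash()} cartdoe={__version__} seed={config.seed}"
    study = make_study(seed=config.seed)
    responses = generate_responses(study)
    runs = generate_study_time_series(study, responses, noise_sd=config.noise_sd)

    data_dir = Path(config.data_dir)
    # the responses file carries factor settings and end-of-culture marker
    # percentages; growth/metabolite responses are derived from the series
    marker_cols = ["run_id", "donor_id", *study.space.factor_names,
                   *(c for c in MARKER_RESPONSES if c in responses.columns)]
    _write_csv(data_dir / "responses.csv", responses[marker_cols], tag)
    write_counts_csv(data_dir / "counts.csv",
                     {rid: r.series for rid, r in runs.items()}, tag)
    write_metabolites_csv(
        data_dir / "metabolites.csv",
        {rid: r.panels for rid, r in runs.items()},
        {rid: r.series.times for rid, r in runs.items()}, tag,
    )
    write_json(data_dir / "ground_truth.json", {
        "seed": study.seed,
        "truths": [
            {
                "response": t.response_name,
                "intercept": t.intercept,
                "coefficients": {"*".join(k): v for k, v in t.coefficients.items()},
                "donor_sd": t.donor_sd,
                "residual_sd": t.residual_sd,
            }
            for t in study.truths
        ],
    })
    log.info("simulated study written to %s (%s)", data_dir, tag)


def kinetics_stage(config: RunConfig) -> tuple[pd.DataFrame, dict[str, KineticSummary]]:
    """Derive kinetic responses for every run with a counts series."""
    data_dir = Path(config.data_dir)
    series = read_counts_csv(data_dir / "counts.csv")
    panels: dict[str, dict[str, MetabolitePanel]] = {}
    met_path = data_dir / "metabolites.csv"
    if met_path.exists():
        panels = read_metabolites_csv(met_path)
        unmatched = sorted(set(panels) - set(series))
        if unmatched:
            raise ParseError(f"{met_path}: run_id(s) {unmatched} have no counts series")
    summaries = {}
    rows = []
    for run_id, run in series.items():
        summary = kinetic_summary(run, panels.get(run_id, {}), window=config.window)
        summaries[run_id] = summary
        row = {"run_id": run_id, "cpd": summary.cpd[-1], "fold": summary.fold}
        if "glucose" in summary.q_avg:
            row["q_gluc"] = summary.q_avg["glucose"]
        if "lactate" in summary.p_avg:
            row["p_lac"] = summary.p_avg["lactate"]
        if summary.dlac_dgluc is not None:
            row["dlac_dgluc"] = summary.dlac_dgluc
        rows.append(row)
    return pd.DataFrame(rows), summaries


def assemble_response_table(config: RunConfig, space: DesignSpace) -> pd.DataFrame:
    """Join factor settings and marker responses with kinetics-derived ones."""
    table = read_responses_csv(Path(config.data_dir) / "responses.csv", space)
    kinetic_requested = [r for r in config.responses if r in KINETIC_RESPONSES]
    counts_path = Path(config.data_dir) / "counts.csv"
    if kinetic_requested and counts_path.exists():
        derived, _ = kinetics_stage(config)
        overlap = [c for c in derived.columns if c != "run_id"]
        table = table.drop(columns=[c for c in overlap if c in table.columns])
        table = table.merge(derived, on="run_id", how="left", validate="1:1")
    return table


def fit_stage(config: RunConfig, space: DesignSpace,
              table: pd.DataFrame) -> tuple[dict[str, FittedModel], list[str]]:
    """Fit and prune one model per requested response; collect failures."""
    models: dict[str, FittedModel] = {}
    failures: list[str] = []
    for resp in config.responses:
        if resp not in table.columns or table[resp].isna().any():
            failures.append(f"response {resp!r}: values missing from the assembled table")
            continue
        y = table[resp].to_numpy(float)
        if not np.all(np.isfinite(y)):
            failures.append(f"response {resp!r}: non-finite values")
            continue
        model = backward_eliminate(space, table, y, alpha=config.alpha,
                                   q2_gap=config.q2_gap, response_name=resp)
        if not model.validity["r2_q2_gap_ok"]:
            log.warning("response %s: R2 - Q2 gap %.3f exceeds %.2f (over-optimistic model)",
                        resp, model.r2 - model.q2, config.q2_gap)
        models[resp] = model
    return models, failures


def run_pipeline(config: RunConfig) -> dict:
    """Full pipeline: (simulate) -> kinetics -> fit -> optimise -> compare.

    Writes the report bundle under ``out_dir``; raises PipelineError after
    writing whatever stages succeeded if any requested response failed.
    """
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    tag = f"config_hash={config.config_hash()} cartdoe={__version__} seed={config.seed}"
    log.info("pipeline start (%s)", tag)
    space = default_space()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        simulate_study_files(config)

    failures: list[str] = []
    try:
        table = assemble_response_table(config, space)
    except (ParseError, FileNotFoundError) as exc:
        raise PipelineError(f"could not assemble the response table: {exc}") from exc

    missing_kinetic = [
        r for r in config.responses
        if r in KINETIC_RESPONSES and (r not in table.columns or table[r].isna().any())
    ]
    if missing_kinetic:
        failures.append(
            f"kinetic responses unavailable (no usable counts/metabolite data): "
            f"{missing_kinetic}"
        )

    models, fit_failures = fit_stage(config, space, table)
    failures.extend(fit_failures)
    _write_csv(out_dir / "response_table.csv", table, tag)
    write_json(out_dir / "models.json",
               {resp: m.to_dict() for resp, m in models.items()})

    bundle: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "models": {resp: m.to_dict() for resp, m in models.items()},
        "failures": failures,
    }

    scored = {r: g for r, g in config.goals.items()
              if g != "ignore" and r in models}
    if scored:
        spec = OptimisationSpec(goals=scored)
        result = find_optimum(models, space, spec)
        _write_csv(out_dir / "desirability_ranking.csv", result.table, tag)
        write_json(out_dir / "optimum.json", result.to_dict())
        bundle["optimum"] = result.to_dict()
    else:
        failures.append("no scored response had a fitted model; optimisation skipped")

    if "activations" in table.columns and table["activations"].nunique() == 2:
        comparable = [r for r in config.responses
                      if r in table.columns and not table[r].isna().any()]
        if comparable:
            comparisons = comparison_table(table, "activations", comparable)
            _write_csv(out_dir / "group_comparisons.csv", comparisons, tag)
            bundle["comparisons"] = comparisons.to_dict(orient="records")

    write_json(out_dir / "report.json", bundle)
    log.info("pipeline outputs written to %s", out_dir)
    if failures:
        raise PipelineError("; ".join(failures))
    return bundle
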