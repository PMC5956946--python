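"""Per-quintile MetS effects and end-to-end pipeline orchestration.

The quintile analysis asks where in the comparator risk-score distribution
the MetS severity score carries information: the outcome model is refitted
with separate MetS slopes inside each risk-score quintile (site-adjusted),
and the per-quintile hazard/odds ratio per SD of MetS severity is plotted on
a log scale with Wald CI whiskers.  A sidecar TSV always accompanies the
figure so the plotted numbers are testable without image comparison.

:func:`run_pipeline` wires the whole analysis together: simulate (or load) a
cohort, fit or load the MetS scoring equations, compute comparator scores,
apply exclusions, fit the nested Model A-D ladders, assemble performance
reports and quintile effects, and write a provenance manifest.  Everything
is deterministic given the seeds in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import mets_severity, perform_metrics, risk_engine
from .model_lab import ConvergenceError, fit_cox, fit_logistic, run_nested, site_dummies
from .synthetic_cohort import SUBGROUPS, TEN_YEARS_DAYS, CohortTable, SimulationConfig, simulate_cohort

__all__ = [
    "QuintileEffect",
    "quintile_bins",
    "per_quintile_mets_effect",
    "PipelineConfig",
    "run_pipeline",
    "bundled_spec_path",
]

#: report order for the comparator scores, CHD first then diabetes
DEFAULT_SCORE_ORDER = (
    ("framingham_synthetic", "chd"),
    ("ascvd_synthetic", "chd"),
    ("bang_synthetic", "t2dm"),
    ("schmidt_synthetic", "t2dm"),
)


def bundled_spec_path(name: str) -> pathlib.Path:
    """Path of a bundled (synthetic-coefficient) risk-score spec YAML."""
    ref = resources.files("metsrisk") / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return pathlib.Path(p)


# ---------------------------------------------------------------------------
# quintiles
# ---------------------------------------------------------------------------

def quintile_bins(score: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Empirical quintile assignment (1..5) with 20/40/60/80 percentile cuts.

    Values exactly on a boundary go to the lower quintile.  Returns
    ``(assignments, boundaries, degenerate)``; ``degenerate`` is set when
    duplicated boundaries collapse quintiles (fewer distinct values than
    bins).
    """
    score = np.asarray(score, dtype=float)
    if len(score) < 5:
        raise ValueError("need at least 5 observations for quintiles")
    boundaries = np.quantile(score, [0.2, 0.4, 0.6, 0.8])
    assignments = 1 + (score[:, None] > boundaries[None, :]).sum(axis=1)
    degenerate = len(np.unique(boundaries)) < 4 or len(np.unique(assignments)) < 5
    return assignments.astype(int), boundaries, bool(degenerate)


@dataclass
class QuintileEffect:
    """MetS severity HR/OR per SD within one comparator-score quintile."""

    quintile: int
    lower_bound: float
    upper_bound: float
    estimate: float          # HR or OR per SD of MetS severity
    ci_lower: float
    ci_upper: float
    n: int
    n_events: int
    flagged: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def per_quintile_mets_effect(
    df: pd.DataFrame,
    score_col: str,
    mets_col: str,
    outcome: str,
    duration_col: str = "time_to_chd",
    event_col: str = "chd_event",
    t2dm_col: str = "t2dm_10y",
    site_col: str = "site",
) -> list[QuintileEffect]:
    """Per-quintile MetS severity effect from one interacted model.

    Fits a single site-adjusted model with quintile indicators and
    MetS-by-quintile interaction slopes, so each quintile gets its own MetS
    HR/OR per SD.  Quintiles without events (or collapsed by duplicated
    boundaries) are flagged rather than silently estimated.
    """
    q, bounds, degenerate = quintile_bins(df[score_col].to_numpy())
    work = df.copy()
    work["_quintile"] = q
    sites = site_dummies(work, site_col)
    work = pd.concat([work, sites], axis=1)
    cols = []
    for k in range(2, 6):
        work[f"_q{k}"] = (q == k).astype(float)
        cols.append(f"_q{k}")
    slope_cols = []
    for k in range(1, 6):
        work[f"_mets_q{k}"] = work[mets_col] * (q == k)
        slope_cols.append(f"_mets_q{k}")
    if outcome == "chd":
        ev = work[event_col].astype(bool)
    else:
        ev = work[t2dm_col].astype(bool)
    events_per_q = {k: int(ev[q == k].sum()) for k in range(1, 6)}
    ns_per_q = {k: int((q == k).sum()) for k in range(1, 6)}

    if degenerate:
        out = []
        lows = np.r_[-np.inf, bounds]
        highs = np.r_[bounds, np.inf]
        for k in range(1, 6):
            out.append(
                QuintileEffect(
                    quintile=k,
                    lower_bound=float(lows[k - 1]),
                    upper_bound=float(highs[k - 1]),
                    estimate=np.nan,
                    ci_lower=np.nan,
                    ci_upper=np.nan,
                    n=ns_per_q[k],
                    n_events=events_per_q[k],
                    flagged=True,
                    note="degenerate quintile boundaries",
                )
            )
        return out

    terms = cols + slope_cols + list(sites.columns)
    if outcome == "chd":
        fit = fit_cox(work, duration_col, event_col, terms)
    elif outcome == "t2dm":
        fit = fit_logistic(work, t2dm_col, terms)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    table = fit.ratio_table()
    label = "HR" if outcome == "chd" else "OR"
    out = []
    lows = np.r_[-np.inf, bounds]
    highs = np.r_[bounds, np.inf]
    for k in range(1, 6):
        row = table.loc[f"_mets_q{k}"]
        flagged = events_per_q[k] == 0
        out.append(
            QuintileEffect(
                quintile=k,
                lower_bound=float(lows[k - 1]),
                upper_bound=float(highs[k - 1]),
                estimate=float(row[label]),
                ci_lower=float(row[f"{label}_lower"]),
                ci_upper=float(row[f"{label}_upper"]),
                n=ns_per_q[k],
                n_events=events_per_q[k],
                flagged=flagged,
                note="no events in quintile" if flagged else "",
            )
        )
    return out


def _plot_quintile_effects(effects: Sequence[QuintileEffect], title: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs = [e.quintile for e in effects if not e.flagged]
    ys = [e.estimate for e in effects if not e.flagged]
    lo = [e.estimate - e.ci_lower for e in effects if not e.flagged]
    hi = [e.ci_upper - e.estimate for e in effects if not e.flagged]
    ax.errorbar(xs, ys, yerr=[lo, hi], fmt="o-", capsize=3)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yscale("log")
    ax.set_xticks([1, 2, 3, 4, 5])
    ax.set_xlabel("risk-score quintile")
    ax.set_ylabel("MetS severity HR/OR per SD")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative description of one end-to-end run."""

    seed: int = 0
    n_participants: int | None = None  # override simulation default
    cohort_dir: str | None = None      # load instead of simulate when given
    simulation_overrides: dict = field(default_factory=dict)
    loadings_file: str | None = None   # published equations; default: CFA fit
    score_specs: dict[str, str] = field(default_factory=dict)  # name -> yaml path ("" = bundled)
    outcomes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SCORE_ORDER))
    horizon_days: int = TEN_YEARS_DAYS
    n_boot: int = 200
    km_method: str = "km"
    interaction_form: str = "continuous"
    write_cohort: bool = False
    make_plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute simulate -> score -> evaluate -> interact and write a bundle.

    Returns the manifest dictionary.  Any stage failure raises, annotated
    with the stage label.  Outputs: ``manifest.json``, per-score model and
    performance JSON, a combined TSV table per outcome, and (optionally)
    quintile-interaction SVG plots with sidecar TSVs.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config.to_dict()),
        "stages": [],
    }
    try:
        from . import __version__

        manifest["version"] = __version__
    except Exception:
        manifest["version"] = "unknown"

    try:
        stage = "simulate"
        if config.cohort_dir:
            cohort = CohortTable.from_csv(config.cohort_dir)
            sim_cfg = None
        else:
            overrides = dict(config.simulation_overrides)
            if config.n_participants is not None:
                overrides["n_participants"] = config.n_participants
            overrides["seed"] = config.seed
            sim_cfg = SimulationConfig.from_dict({**SimulationConfig().to_dict(), **overrides})
            cohort = simulate_cohort(sim_cfg)
        manifest["n_raw"] = cohort.n
        manifest["stages"].append(stage)

        stage = "exclusions"
        analytic, tally = risk_engine.apply_exclusions(cohort)
        manifest["exclusion_tally"] = tally
        manifest["n_analytic"] = analytic.n
        manifest["stages"].append(stage)
        if config.write_cohort:
            analytic.to_csv(out / "analytic_cohort")

        stage = "mets-score"
        if config.loadings_file:
            loadings = mets_severity.load_loadings(config.loadings_file)
        else:
            try:
                loadings = {g: mets_severity.fit_cfa_loadings(analytic, g) for g in SUBGROUPS}
            except mets_severity.CFAConvergenceError as exc:
                # small samples cannot support per-subgroup equations; fall
                # back to one pooled equation for every subgroup
                pooled_df = analytic.participants.copy()
                pooled_df["subgroup"] = "pooled"
                pooled = mets_severity.fit_cfa_loadings(pooled_df, "pooled")
                loadings = {}
                for g in SUBGROUPS:
                    eq = mets_severity.MetSLoadings.from_dict(pooled.to_dict())
                    eq.subgroup = g
                    eq.provenance = "cfa-fit-pooled"
                    loadings[g] = eq
                manifest.setdefault("notices", []).append(
                    f"per-subgroup CFA infeasible ({exc}); pooled equation used"
                )
        mets_severity.save_loadings(loadings, out / "mets_loadings.yaml")
        df = analytic.participants.copy().reset_index(drop=True)
        df["mets_z"] = mets_severity.score_cohort(df, loadings).to_numpy()
        df["homa_ir"] = mets_severity.homa_ir(df["insulin"].to_numpy(), df["glucose"].to_numpy())
        manifest["mets_provenance"] = next(iter(loadings.values())).provenance
        manifest["stages"].append(stage)

        stage = "outcomes"
        t2dm = risk_engine.t2dm_10yr_outcome(analytic, config.horizon_days)
        df["t2dm_10y"] = df["participant_id"].map(t2dm).astype(bool)
        manifest["chd_events_10y"] = int(
            (df["chd_event"] & (df["time_to_chd"] <= config.horizon_days)).sum()
        )
        manifest["t2dm_events_10y"] = int(df["t2dm_10y"].sum())
        manifest["stages"].append(stage)

        stage = "score"
        specs = {}
        for name, outcome in config.outcomes.items():
            path = config.score_specs.get(name, "")
            spec_path = pathlib.Path(path) if path else bundled_spec_path(name)
            specs[name] = risk_engine.RiskScoreSpec.from_yaml(spec_path)
        columns = {}
        for name, spec in specs.items():
            col = risk_engine.compute_score(df, spec)
            col = risk_engine.standardize(col, spec.standardize_flag)
            df[f"score_{name}"] = col.raw.to_numpy()
            if col.standardized is not None:
                df[f"score_{name}_z"] = col.standardized.to_numpy()
            columns[name] = col
        manifest["stages"].append(stage)

        stage = "evaluate"
        results = {}
        for name, outcome in config.outcomes.items():
            raw_col = f"score_{name}"
            std_col = f"score_{name}_z" if columns[name].standardized is not None else None
            if "mets_z" not in df.columns:
                manifest.setdefault("notices", []).append(
                    f"{name}: no MetS column; Models B-D skipped"
                )
                continue
            nested = run_nested(
                df,
                score_col=raw_col,
                mets_col="mets_z",
                outcome=outcome,
                score_std_col=std_col,
                interaction_form=config.interaction_form,
            )
            reports = {
                m: perform_metrics.performance_report(
                    nested,
                    new_model=m,
                    horizon_days=config.horizon_days,
                    km_method=config.km_method,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                for m in ("C", "D")
            }
            effects = per_quintile_mets_effect(df, raw_col, "mets_z", outcome)
            results[name] = {
                "outcome": outcome,
                "nested": nested,
                "reports": reports,
                "quintiles": effects,
            }
            payload = {
                "outcome": outcome,
                "interaction_form": config.interaction_form,
                "interaction_p": nested.interaction_p,
                "models": {
                    m: {
                        "aic": f.aic,
                        "loglik": f.loglik,
                        "n": f.n,
                        "n_events": f.n_events,
                        "ratios": nested.display_fits[m].ratio_table().to_dict(orient="index"),
                    }
                    for m, f in nested.fits.items()
                },
                "performance": {m: r.to_dict() for m, r in reports.items()},
                "quintile_effects": [e.to_dict() for e in effects],
            }
            with open(out / f"results_{name}.json", "w") as fh:
                json.dump(payload, fh, indent=1, default=float)
            sidecar = pd.DataFrame([e.to_dict() for e in effects])
            sidecar.to_csv(out / f"quintiles_{name}.tsv", sep="\t", index=False)
            if config.make_plots:
                label = "CHD" if outcome == "chd" else "T2DM"
                _plot_quintile_effects(
                    effects, f"MetS severity by {name} quintile ({label})", out / f"quintiles_{name}.svg"
                )
        manifest["stages"].append(stage)

        stage = "tables"
        for outcome in ("chd", "t2dm"):
            rows = []
            for name, res in results.items():
                if res["outcome"] != outcome:
                    continue
                nested = res["nested"]
                for m in ("A", "B", "C", "D"):
                    fit = nested.fits[m]
                    disp = nested.display_fits[m].ratio_table()
                    label = "HR" if outcome == "chd" else "OR"
                    row = {
                        "score": name,
                        "model": m,
                        "AIC": fit.aic,
                        "n": fit.n,
                        "events": fit.n_events,
                    }
                    std_col = f"score_{name}_z"
                    score_term = std_col if std_col in nested.display_fits[m].terms else f"score_{name}"
                    if m != "B":
                        row[f"score_{label}"] = disp.loc[score_term, label]
                        row[f"score_{label}_CI"] = (
                            f"({disp.loc[score_term, f'{label}_lower']:.2f}, "
                            f"{disp.loc[score_term, f'{label}_upper']:.2f})"
                        )
                    if m != "A" and "mets_z" in disp.index:
                        row[f"mets_{label}"] = disp.loc["mets_z", label]
                        row[f"mets_{label}_CI"] = (
                            f"({disp.loc['mets_z', f'{label}_lower']:.2f}, "
                            f"{disp.loc['mets_z', f'{label}_upper']:.2f})"
                        )
                    if m in ("C", "D"):
                        rep = res["reports"][m]
                        row["c"] = rep.c_new.value
                        row["IDI"] = rep.idi.value
                        row["NRI"] = rep.nri.overall.value
                        row["NRI_event"] = rep.nri.event.value
                        row["NRI_nonevent"] = rep.nri.nonevent.value
                    elif m == "A":
                        rep = res["reports"]["C"]
                        row["c"] = rep.c_old.value
                    if m == "D":
                        row["interaction_p"] = nested.interaction_p
                    rows.append(row)
            if rows:
                pd.DataFrame(rows).to_csv(out / f"table_{outcome}.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except ConvergenceError as exc:
        raise ConvergenceError(f"pipeline stage {stage!r} failed: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["_results"] = results
    return manifest
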