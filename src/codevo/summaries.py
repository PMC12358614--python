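"""Reported output surfaces computed from run logs.

All figures-style quantities — trait means, growth curves, maturation
ogives, age/length at maturation, absolute and relative population size,
mortality decomposition, age distribution and emergent heritability —
are recomputed here from the per-year logs the engine writes, never
carried as side state.  "End of runtime" statistics average over a
trailing window (200 years by default).

Replicate aggregation is mean-of-replicate-means, with the SD taken
across replicate-level values (between-replicate variability).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import life_history as lh
from .engine import RunLog

__all__ = [
    "END_WINDOW",
    "load_runs",
    "growth_curve",
    "proportion_mature_at_age",
    "age_distribution",
    "maturation_summary",
    "trait_summary",
    "population_summary",
    "relative_population",
    "mortality_decomposition",
    "heritability_report",
]

#: default trailing window for "end of runtime" statistics, years
END_WINDOW = 200


def load_runs(runs_dir: str | Path) -> list[dict[str, pd.DataFrame]]:
    """Load every ``rep_*`` output directory under ``runs_dir``."""
    rep_dirs = sorted(Path(runs_dir).glob("rep_*"))
    if not rep_dirs:
        raise FileNotFoundError(f"no rep_* run directories under {runs_dir}")
    return [RunLog.load(d) for d in rep_dirs]


def _tail(df: pd.DataFrame, window: int) -> pd.DataFrame:
    if window < 1:
        raise ValueError("window must be >= 1")
    last = df["year"].max()
    return df[df["year"] > last - window]


def _replicate_stats(values: list[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return np.nan, np.nan
    return float(v.mean()), float(v.std(ddof=0)) if v.size > 1 else 0.0


def growth_curve(age_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """Average length-at-age +/- SD over the end window, pooled across replicates.

    Per replicate, each age's mean length is the individual-weighted mean
    over the window; ages absent from a replicate's window are missing
    (not zero) and are excluded from pooling.
    """
    per_rep: dict[int, list[float]] = {}
    for df in age_frames:
        t = _tail(df, window)
        for age, grp in t.groupby("age"):
            w = grp["n"].to_numpy(float)
            if w.sum() <= 0:
                continue
            per_rep.setdefault(int(age), []).append(
                float(np.average(grp["mean_length"], weights=w))
            )
    rows = []
    for age in sorted(per_rep):
        mean, sd = _replicate_stats(per_rep[age])
        rows.append({"age": age, "mean_length": mean, "sd_length": sd,
                     "n_replicates": len(per_rep[age])})
    return pd.DataFrame(rows)


def proportion_mature_at_age(age_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """Average proportion mature at age over the end window (maturity ogive)."""
    per_rep: dict[int, list[float]] = {}
    for df in age_frames:
        t = _tail(df, window)
        for age, grp in t.groupby("age"):
            w = grp["n"].to_numpy(float)
            if w.sum() <= 0:
                continue
            per_rep.setdefault(int(age), []).append(
                float(np.average(grp["prop_mature"], weights=w))
            )
    rows = []
    for age in sorted(per_rep):
        mean, sd = _replicate_stats(per_rep[age])
        rows.append({"age": age, "prop_mature": mean, "sd": sd})
    return pd.DataFrame(rows)


def age_distribution(age_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """Share of individuals in each age class over the end window."""
    per_rep: list[pd.Series] = []
    for df in age_frames:
        t = _tail(df, window)
        counts = t.groupby("age")["n"].sum()
        if counts.sum() > 0:
            per_rep.append(counts / counts.sum())
    wide = pd.DataFrame(per_rep).fillna(0.0)
    return pd.DataFrame({
        "age": wide.columns.astype(int),
        "proportion": wide.mean(axis=0).to_numpy(),
        "sd": wide.std(axis=0, ddof=0).to_numpy(),
    }).sort_values("age", ignore_index=True)


def maturation_summary(summary_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """Mean age and length at maturation (+/- SD) among newly matured fish.

    Within a replicate, yearly means are weighted by the number of
    maturation events; SDs are between replicates.  Raises if the window
    contains no maturation events at all.
    """
    ages, lengths = [], []
    for df in summary_frames:
        t = _tail(df, window)
        t = t[t["n_newly_mature"] > 0]
        if len(t) == 0:
            continue
        w = t["n_newly_mature"].to_numpy(float)
        ages.append(float(np.average(t["mean_age_at_maturation"], weights=w)))
        lengths.append(float(np.average(t["mean_length_at_maturation"], weights=w)))
    if not ages:
        raise ValueError("no maturation events in the end window")
    a_mean, a_sd = _replicate_stats(ages)
    l_mean, l_sd = _replicate_stats(lengths)
    return pd.DataFrame([
        {"statistic": "age_at_maturation", "mean": a_mean, "sd": a_sd},
        {"statistic": "length_at_maturation", "mean": l_mean, "sd": l_sd},
    ])


def trait_summary(summary_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """End-window means +/- between-replicate SD of the genetic trait means."""
    rows = []
    for trait in ("mean_appetite_gv", "mean_pmrn_intercept_gv",
                  "mean_appetite_phen", "mean_pmrn_intercept_phen"):
        vals = [float(_tail(df, window)[trait].mean()) for df in summary_frames]
        mean, sd = _replicate_stats(vals)
        rows.append({"trait": trait.removeprefix("mean_"), "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def population_summary(summary_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """End-window abundance and biomass, mean +/- between-replicate SD."""
    rows = []
    for fieldname in ("n", "biomass", "recruits"):
        vals = [float(_tail(df, window)[fieldname].mean()) for df in summary_frames]
        mean, sd = _replicate_stats(vals)
        rows.append({"quantity": fieldname, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def relative_population(
    summary_frames: list[pd.DataFrame],
    initial_n: float,
    initial_biomass: float,
    window: int = END_WINDOW,
) -> tuple[float, float]:
    """End-window N and biomass relative to the initial population, in percent.

    A run that ends demographically identical to its starting snapshot
    returns (100.0, 100.0).
    """
    if initial_n <= 0 or initial_biomass <= 0:
        raise ValueError("initial snapshot must have positive N and biomass")
    pop = population_summary(summary_frames, window).set_index("quantity")["mean"]
    return (
        100.0 * float(pop["n"]) / initial_n,
        100.0 * float(pop["biomass"]) / initial_biomass,
    )


def mortality_decomposition(mortality_frames: list[pd.DataFrame], window: int = END_WINDOW) -> pd.DataFrame:
    """Mean component rate and attributed deaths by age over the end window."""
    parts = [_tail(df, window) for df in mortality_frames]
    allf = pd.concat(parts, ignore_index=True)
    out = (
        allf.groupby(["age", "component"])
        .agg(mean_rate=("mean_rate", "mean"), deaths=("deaths", "sum"))
        .reset_index()
    )
    return out


def heritability_report(parent_offspring: pd.DataFrame) -> dict[str, float]:
    """Emergent heritability per trait from the engine's recruitment log.

    Mid-parent/offspring regression of phenotypes, per trait, plus their
    mean as a single summary value.
    """
    h2_app = lh.estimate_heritability(
        parent_offspring["midparent_appetite"], parent_offspring["offspring_appetite"]
    )
    h2_pmrn = lh.estimate_heritability(
        parent_offspring["midparent_pmrn_intercept"],
        parent_offspring["offspring_pmrn_intercept"],
    )
    return {
        "appetite": h2_app,
        "pmrn_intercept": h2_pmrn,
        "mean": 0.5 * (h2_app + h2_pmrn),
    }


def write_summary_tables(runs_dir: str | Path, out_dir: str | Path,
                         window: int = END_WINDOW) -> None:
    """Compute every summary table for a run directory and write CSVs."""
    runs = load_runs(runs_dir)
    summaries = [r["summary"] for r in runs]
    ages = [r["age_structure"] for r in runs]
    morts = [r["mortality"] for r in runs]
    po = pd.concat([r["parent_offspring"] for r in runs], ignore_index=True)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    growth_curve(ages, window).to_csv(out / "growth_curves.csv", index=False)
    proportion_mature_at_age(ages, window).to_csv(out / "maturity_ogive.csv", index=False)
    age_distribution(ages, window).to_csv(out / "age_distribution.csv", index=False)
    maturation_summary(summaries, window).to_csv(out / "maturation.csv", index=False)
    trait_summary(summaries, window).to_csv(out / "traits.csv", index=False)
    population_summary(summaries, window).to_csv(out / "population.csv", index=False)
    mortality_decomposition(morts, window).to_csv(out / "mortality_decomposition.csv", index=False)
    pd.DataFrame([heritability_report(po)]).to_csv(out / "heritability.csv", index=False)
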