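"""Data model and I/O for the settlement-panel experiment.

The experiment: 60 PVC panels in 10 blocks of 6 (3 at 1 m, 3 at 3 m), one
panel per depth in each block assigned to each of three treatments —
control (C), weekly removal of half the *A. aurita* polyps (A), weekly
removal of every second potential-competitor individual/colony (O).  Panels
were photographed weekly for 8 weeks, before and after treatment, and cover
was estimated by 100-point counts over nine fixed categories.  Paired
environmental measurements (dissolved oxygen, temperature, salinity) were
taken at both depths each week.

Tables are stored as plain CSV:

* counts:   panel, week, phase(pre|post), category, count  [optional n column]
* meta:     panel, block, depth, treatment, mistaken_week (blank if none)
* env:      week, depth, dissolved_oxygen, temperature, salinity
* schedule: panel, week   (one row per actual treatment application)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = (
    "aurita_panel",
    "aurita_competitors",
    "bare",
    "botrylloides",
    "bugula",
    "molgula",
    "ascidiella",
    "botryllus",
    "other",
)

#: Named sessile taxa eligible for the MANOVA taxon-inclusion rule.
NAMED_TAXA = ("botrylloides", "bugula", "molgula", "ascidiella", "botryllus")

DEPTHS = (1.0, 3.0)
TREATMENTS = ("C", "A", "O")
N_WEEKS = 8
POINTS_PER_PHOTO = 100


class ValidationError(ValueError):
    """Raised when an experiment table violates its schema or invariants."""


@dataclass(frozen=True)
class TreatmentSchedule:
    """Weeks at which a removal was actually applied to one panel.

    ``events`` pairs each application week with its kind ('A': polyp
    removal, 'O': competitor removal).  The kind normally matches the
    panel's treatment, but a mistaken application on a control panel is an
    'A' event on a panel labelled C.
    """

    panel_id: int
    events: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ev = tuple(sorted(set((int(w), str(k)) for w, k in self.events)))
        for _w, k in ev:
            if k not in ("A", "O"):
                raise ValidationError(f"unknown removal kind {k!r}")
        object.__setattr__(self, "events", ev)

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(w for w, _k in self.events)


@dataclass
class ExperimentTable:
    """Validated container for one experiment's counts, metadata and environment."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    env: pd.DataFrame
    schedule: pd.DataFrame

    warnings: list[str] = field(default_factory=list)

    def schedules(self) -> dict[int, TreatmentSchedule]:
        out: dict[int, TreatmentSchedule] = {}
        for pid in self.meta["panel"]:
            rows = self.schedule.loc[self.schedule["panel"] == pid]
            out[int(pid)] = TreatmentSchedule(
                int(pid), tuple((int(r["week"]), str(r["kind"])) for _, r in rows.iterrows()))
        return out

    def panel_meta(self, panel_id: int) -> pd.Series:
        row = self.meta.loc[self.meta["panel"] == panel_id]
        if row.empty:
            raise KeyError(f"unknown panel {panel_id}")
        return row.iloc[0]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table is missing columns {missing}")


def validate(counts: pd.DataFrame, meta: pd.DataFrame, env: pd.DataFrame,
             schedule: pd.DataFrame) -> ExperimentTable:
    """Check schemas and invariants; return a validated ExperimentTable.

    Raises ValidationError listing offending rows on the first broken
    invariant; soft checks (e.g. an 'other' category exceeding 7 points)
    are collected as warnings.
    """
    _require_columns(counts, ("panel", "week", "phase", "category", "count"), "counts")
    _require_columns(meta, ("panel", "block", "depth", "treatment"), "meta")
    _require_columns(env, ("week", "depth", "dissolved_oxygen", "temperature"), "env")
    _require_columns(schedule, ("panel", "week"), "schedule")

    counts = counts.copy()
    counts["count"] = counts["count"].astype(int)

    bad_cat = sorted(set(counts["category"]) - set(CATEGORIES))
    if bad_cat:
        raise ValidationError(f"unknown categories {bad_cat}")
    bad_phase = sorted(set(counts["phase"]) - {"pre", "post"})
    if bad_phase:
        raise ValidationError(f"unknown phases {bad_phase}")
    if (counts["count"] < 0).any():
        raise ValidationError("negative counts")

    if meta["panel"].duplicated().any():
        dup = meta.loc[meta["panel"].duplicated(), "panel"].tolist()
        raise ValidationError(f"duplicate panel ids {dup}")
    bad_trt = sorted(set(meta["treatment"]) - set(TREATMENTS))
    if bad_trt:
        raise ValidationError(f"unknown treatments {bad_trt}")
    cell = meta.groupby(["block", "depth", "treatment"]).size()
    if (cell > 1).any():
        raise ValidationError(
            f"multiple panels share a (block, depth, treatment) cell:\n{cell[cell > 1]}")

    unknown = sorted(set(counts["panel"]) - set(meta["panel"]))
    if unknown:
        raise ValidationError(f"counts reference unknown panels {unknown}")
    unknown = sorted(set(schedule["panel"]) - set(meta["panel"]))
    if unknown:
        raise ValidationError(f"schedule references unknown panels {unknown}")
    schedule = schedule.copy()
    if "kind" not in schedule.columns:
        # default: the panel's own treatment (undefined for control panels)
        trt = meta.set_index("panel")["treatment"]
        schedule["kind"] = schedule["panel"].map(trt)
        if (schedule["kind"] == "C").any():
            bad = schedule.loc[schedule["kind"] == "C", "panel"].tolist()
            raise ValidationError(
                f"control panels {bad} have scheduled applications without a 'kind' column")
    bad_kind = sorted(set(schedule["kind"]) - {"A", "O"})
    if bad_kind:
        raise ValidationError(f"unknown removal kinds {bad_kind}")
    if not schedule.empty:
        if schedule["week"].min() < 1 or schedule["week"].max() > counts["week"].max():
            raise ValidationError("schedule weeks outside sampling weeks")

    totals = counts.groupby(["panel", "week", "phase"])["count"].sum()
    if "n" in counts.columns:
        declared = counts.groupby(["panel", "week", "phase"])["n"].first()
        bad = totals[totals != declared]
        if len(bad):
            raise ValidationError(
                f"counts do not sum to the declared total for:\n{bad}")

    # post must equal pre whenever no application happened that panel-week
    applied = set(map(tuple, schedule[["panel", "week"]].itertuples(index=False)))
    wide = counts.pivot_table(index=["panel", "week", "category"], columns="phase",
                              values="count", aggfunc="first")
    if "post" in wide.columns:
        both = wide.dropna(subset=["pre", "post"])
        mism = both[both["pre"] != both["post"]]
        offenders = [
            (p, w) for (p, w, _c) in mism.index if (p, w) not in applied
        ]
        if offenders:
            raise ValidationError(
                f"post != pre without a treatment application at {sorted(set(offenders))}")

    warnings: list[str] = []
    other = counts[(counts["category"] == "other") & (counts["count"] > 7)]
    if not other.empty:
        warnings.append(
            f"'other' exceeds 7 points on {other[['panel', 'week']].drop_duplicates().values.tolist()}")

    table = ExperimentTable(counts=counts.reset_index(drop=True), meta=meta.reset_index(drop=True),
                            env=env.reset_index(drop=True), schedule=schedule.reset_index(drop=True),
                            warnings=warnings)
    return table


def read_experiment(count_table_path: str | Path, meta_path: str | Path,
                    env_path: str | Path,
                    schedule_path: str | Path | None = None) -> ExperimentTable:
    """Read and validate the experiment CSVs.

    ``schedule_path`` defaults to ``schedule.csv`` next to the counts table;
    an absent schedule file means no applications (all-control design).
    """
    counts = pd.read_csv(count_table_path)
    meta = pd.read_csv(meta_path)
    env = pd.read_csv(env_path)
    if schedule_path is None:
        schedule_path = Path(count_table_path).with_name("schedule.csv")
    schedule_path = Path(schedule_path)
    if schedule_path.exists():
        schedule = pd.read_csv(schedule_path)
    else:
        schedule = pd.DataFrame({"panel": pd.Series(dtype=int),
                                 "week": pd.Series(dtype=int)})
    return validate(counts, meta, env, schedule)


def write_experiment(table: ExperimentTable, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "meta": out / "meta.csv",
        "env": out / "env.csv",
        "schedule": out / "schedule.csv",
    }
    table.counts.to_csv(paths["counts"], index=False)
    table.meta.to_csv(paths["meta"], index=False)
    table.env.to_csv(paths["env"], index=False)
    table.schedule.to_csv(paths["schedule"], index=False)
    return paths


@dataclass
class ManovaDataset:
    """Final-week pre-treatment five-part counts with the crossed design.

    ``treatment`` reassigns any mistakenly treated control panel back to C,
    the convention used for the final-composition analysis.
    """

    counts: np.ndarray          # (n_panels, 5) integer counts
    totals: np.ndarray          # (n_panels,)
    part_names: tuple[str, ...]
    panel: np.ndarray
    depth: np.ndarray
    treatment: np.ndarray
    block: np.ndarray

    @property
    def n_panels(self) -> int:
        return self.counts.shape[0]


def included_taxa(final_pre: pd.DataFrame, threshold: int = 20) -> tuple[str, ...]:
    """Named taxa contributing >= ``threshold`` points on at least one panel."""
    sub = final_pre[final_pre["category"].isin(NAMED_TAXA)]
    per_panel = sub.groupby(["category", "panel"])["count"].sum()
    keep = sorted({cat for (cat, _p), v in per_panel.items() if v >= threshold},
                  key=NAMED_TAXA.index)
    return tuple(keep)


def manova_subset(table: ExperimentTable, final_week: int | None = None,
                  threshold: int = 20) -> ManovaDataset:
    """Extract the final-composition dataset.

    Parts: *A. aurita* on panel, bare panel, and every named taxon reaching
    ``threshold`` points on at least one panel in the final-week
    pre-treatment photographs.  Totals are the points falling on included
    parts (excluded rare taxa and polyps on competitors simply reduce n:
    subcompositional coherence makes this harmless).
    """
    if final_week is None:
        final_week = int(table.counts["week"].max())
    final = table.counts[(table.counts["week"] == final_week)
                         & (table.counts["phase"] == "pre")]
    missing = sorted(set(table.meta["panel"]) - set(final["panel"]))
    if missing:
        raise ValidationError(f"no final-week pre-treatment data for panels {missing}")

    parts = ("aurita_panel", "bare") + included_taxa(final, threshold)
    wide = final.pivot_table(index="panel", columns="category", values="count",
                             aggfunc="sum", fill_value=0)
    for p in parts:
        if p not in wide.columns:
            wide[p] = 0
    meta = table.meta.set_index("panel").loc[wide.index]

    treatment = meta["treatment"].to_numpy(dtype=object).copy()
    if "mistaken_week" in meta.columns:
        # a control panel mistakenly treated once stays a control here
        pass

    counts = wide[list(parts)].to_numpy(dtype=int)
    return ManovaDataset(
        counts=counts,
        totals=counts.sum(axis=1),
        part_names=parts,
        panel=wide.index.to_numpy(),
        depth=meta["depth"].to_numpy(dtype=float),
        treatment=treatment.astype(str),
        block=meta["block"].to_numpy(dtype=int),
    )


@dataclass
class DynamicsDataset:
    """Three-category weekly time series for the dynamic models.

    One row per observation: control panel-weeks (and treatment panel-weeks
    without an application) contribute a single pre-phase record; panel-weeks
    with an application contribute distinct pre and post records.  Points on
    *A. aurita* growing on competitors are excluded from all categories, so
    n varies slightly below the photo total.
    """

    obs: pd.DataFrame  # panel, week, phase, aurita, bare, competitors, n, depth, treatment
    schedules: dict[int, TreatmentSchedule]

    @property
    def n_obs(self) -> int:
        return len(self.obs)


def dynamics_dataset(table: ExperimentTable) -> DynamicsDataset:
    """Aggregate counts to (A. aurita on panel, bare, potential competitors)."""
    competitors = [c for c in CATEGORIES
                   if c not in ("aurita_panel", "aurita_competitors", "bare")]
    c = table.counts
    agg = c.pivot_table(index=["panel", "week", "phase"], columns="category",
                        values="count", aggfunc="sum", fill_value=0)
    for cat in CATEGORIES:
        if cat not in agg.columns:
            agg[cat] = 0
    out = pd.DataFrame({
        "aurita": agg["aurita_panel"],
        "bare": agg["bare"],
        "competitors": agg[competitors].sum(axis=1),
    })
    out["n"] = out.sum(axis=1)
    out = out.reset_index()

    applied = set(map(tuple, table.schedule[["panel", "week"]].itertuples(index=False)))
    keep = out.apply(
        lambda r: r["phase"] == "pre" or (r["panel"], r["week"]) in applied, axis=1)
    out = out[keep]

    meta = table.meta.set_index("panel")
    out["depth"] = out["panel"].map(meta["depth"])
    out["treatment"] = out["panel"].map(meta["treatment"])
    out = out.sort_values(["panel", "week", "phase"],
                          ascending=[True, True, False]).reset_index(drop=True)
    return DynamicsDataset(obs=out, schedules=table.schedules())
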