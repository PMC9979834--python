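"""Experiment table validation and the MANOVA / dynamics extraction rules."""

import numpy as np
import pandas as pd
import pytest

from panelcomp.experiment_data import (CATEGORIES, ValidationError,
                                       dynamics_dataset, manova_subset,
                                       read_experiment, validate,
                                       write_experiment)
from panelcomp.synthetic_data import DesignSpec, generate_dynamics_experiment


def tiny_tables(counts_override=None):
    """2 panels x 2 weeks fixture, built in memory."""
    meta = pd.DataFrame({"panel": [1, 2], "block": [1, 1], "depth": [1.0, 1.0],
                         "treatment": ["C", "A"], "mistaken_week": ["", ""]})
    rows = []
    for panel in (1, 2):
        for week in (1, 2):
            for phase in ("pre", "post"):
                vals = {"aurita_panel": 5, "bare": 80, "bugula": 15}
                for cat in CATEGORIES:
                    rows.append({"panel": panel, "week": week, "phase": phase,
                                 "category": cat, "count": vals.get(cat, 0)})
    counts = pd.DataFrame(rows)
    if counts_override is not None:
        counts = counts_override(counts)
    env = pd.DataFrame({"week": [1, 1, 2, 2], "depth": [1.0, 3.0, 1.0, 3.0],
                        "dissolved_oxygen": [8, 7.5, 8.1, 7.4],
                        "temperature": [18, 17.8, 18.2, 17.9],
                        "salinity": [15, 15, 15.1, 15.1]})
    schedule = pd.DataFrame({"panel": [], "week": [], "kind": []})
    return counts, meta, env, schedule


class TestValidation:
    def test_tiny_fixture_accepted(self):
        table = validate(*tiny_tables())
        assert len(table.meta) == 2
        assert (table.counts.groupby(["panel", "week", "phase"])["count"]
                .sum() == 100).all()

    def test_declared_total_mismatch_rejected(self):
        def breaker(c):
            c = c.copy()
            c["n"] = 100
            c.loc[0, "count"] -= 1
            return c
        with pytest.raises(ValidationError, match="declared total"):
            validate(*tiny_tables(breaker))

    def test_unknown_category_rejected(self):
        def breaker(c):
            c = c.copy()
            c.loc[0, "category"] = "kraken"
            return c
        with pytest.raises(ValidationError, match="kraken"):
            validate(*tiny_tables(breaker))

    def test_post_differs_without_application_rejected(self):
        def breaker(c):
            c = c.copy()
            sel = (c.panel == 1) & (c.week == 1) & (c.phase == "post")
            c.loc[sel & (c.category == "bare"), "count"] = 79
            c.loc[sel & (c.category == "bugula"), "count"] = 16
            return c
        with pytest.raises(ValidationError, match="post != pre"):
            validate(*tiny_tables(breaker))

    def test_control_application_needs_kind(self):
        counts, meta, env, _ = tiny_tables()
        schedule = pd.DataFrame({"panel": [1], "week": [2]})
        with pytest.raises(ValidationError, match="kind"):
            validate(counts, meta, env, schedule)

    def test_other_above_seven_points_warns(self):
        def breaker(c):
            c = c.copy()
            c.loc[c.category == "bare", "count"] = 72
            c.loc[c.category == "other", "count"] = 8
            return c
        table = validate(*tiny_tables(breaker))
        assert any("other" in w for w in table.warnings)


class TestRoundTrip:
    def test_write_read_identity(self, dyn_table, tmp_path):
        table, _ = dyn_table
        paths = write_experiment(table, tmp_path)
        again = read_experiment(paths["counts"], paths["meta"], paths["env"],
                                paths["schedule"])
        pd.testing.assert_frame_equal(
            again.counts[["panel", "week", "phase", "category", "count"]],
            table.counts[["panel", "week", "phase", "category", "count"]])
        assert again.schedules() == table.schedules()


class TestManovaSubset:
    def test_selection_and_totals(self, dyn_table):
        table, _ = dyn_table
        data = manova_subset(table)
        assert data.part_names[:2] == ("aurita_panel", "bare")
        assert data.n_panels == len(table.meta)
        assert (data.totals <= 100).all() and (data.totals > 0).all()
        assert (data.counts.sum(axis=1) == data.totals).all()

    def test_taxon_rule_includes_on_single_panel(self):
        counts, meta, env, schedule = tiny_tables()
        # give ascidiella 20 points on panel 1 in the final week only
        sel = (counts.panel == 1) & (counts.week == 2)
        counts.loc[sel & (counts.category == "bare"), "count"] = 60
        counts.loc[sel & (counts.category == "ascidiella"), "count"] = 20
        table = validate(counts, meta, env, schedule)
        data = manova_subset(table)
        assert "ascidiella" in data.part_names
        # included for every panel, even those where it scored 0
        assert data.counts.shape[1] == len(data.part_names)

    def test_mistaken_panel_stays_control(self, preset):
        design = DesignSpec(n_blocks=2, mistaken=(1, 2))
        table, _ = generate_dynamics_experiment("overgrowth", preset, design, seed=3)
        data = manova_subset(table)
        assert data.treatment[list(data.panel).index(1)] == "C"
        # but its schedule carries the A-kind event for the dynamics track
        assert (2, "A") in table.schedules()[1].events

    def test_missing_final_week_errors(self):
        counts, meta, env, schedule = tiny_tables()
        counts = counts[~((counts.panel == 2) & (counts.week == 2))]
        table = validate(counts, meta, env, schedule)
        with pytest.raises(ValidationError, match="panels \\[2\\]"):
            manova_subset(table, final_week=2)

    def test_category_order_irrelevant(self, dyn_table):
        table, _ = dyn_table
        shuffled = table.counts.sample(frac=1.0, random_state=0)
        table2 = validate(shuffled, table.meta, table.env, table.schedule)
        d1, d2 = manova_subset(table), manova_subset(table2)
        order = np.argsort(d1.panel)
        order2 = np.argsort(d2.panel)
        np.testing.assert_array_equal(d1.counts[order], d2.counts[order2])


class TestDynamicsDataset:
    def test_aggregation_conserves_counts(self, dyn_table):
        table, _ = dyn_table
        ds = dynamics_dataset(table)
        totals = table.counts.groupby(["panel", "week", "phase"])["count"].sum()
        excl = (table.counts[table.counts.category == "aurita_competitors"]
                .groupby(["panel", "week", "phase"])["count"].sum())
        for _, r in ds.obs.iterrows():
            key = (r.panel, r.week, r.phase)
            assert r.n + excl.get(key, 0) == totals[key]

    def test_control_panels_once_per_week(self, dyn_table):
        table, _ = dyn_table
        ds = dynamics_dataset(table)
        controls = table.meta.loc[table.meta.treatment == "C", "panel"]
        sub = ds.obs[ds.obs.panel.isin(controls)]
        assert (sub.phase == "pre").all()
        assert sub.groupby(["panel", "week"]).size().max() == 1

    def test_post_rows_only_at_applications(self, dyn_table):
        table, _ = dyn_table
        ds = dynamics_dataset(table)
        applied = set(map(tuple, table.schedule[["panel", "week"]]
                          .itertuples(index=False)))
        post = ds.obs[ds.obs.phase == "post"]
        assert set(map(tuple, post[["panel", "week"]].itertuples(index=False))) == applied

    def test_polyps_on_competitors_excluded(self):
        counts, meta, env, schedule = tiny_tables()
        sel = (counts.panel == 1) & (counts.week == 1)
        counts.loc[sel & (counts.category == "bare"), "count"] = 78
        counts.loc[sel & (counts.category == "aurita_competitors"), "count"] = 2
        table = validate(counts, meta, env, schedule)
        ds = dynamics_dataset(table)
        row = ds.obs[(ds.obs.panel == 1) & (ds.obs.week == 1)].iloc[0]
        assert row.n == 98
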