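"""Event filtering, history building, naive occupancy and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occudyn import (
    CovariateSet,
    build_detection_history,
    filter_independent_events,
    naive_occupancy,
    standardize_covariates,
    subset_seasons,
)
from conftest import history_from_y, toy_design


def events_at_minutes(minutes, site=0, species="fox", base="2020-01-01 12:00"):
    t0 = pd.Timestamp(base)
    return pd.DataFrame(
        {
            "site_id": site,
            "species": species,
            "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minutes],
        }
    )


class TestIndependenceFilter:
    def test_single_event_retained(self):
        out = filter_independent_events(events_at_minutes([0]))
        assert len(out) == 1

    @pytest.mark.parametrize(
        "minutes, expected",
        [
            ([0, 20, 45], [0, 45]),
            ([0, 29, 58], [0, 58]),  # 29 dropped (<30 from 0); 58 kept (58-0 >= 30)
            ([0, 30], [0, 30]),  # boundary: exactly 30 min apart is independent
            ([0, 29.999], [0]),
        ],
    )
    def test_sliding_anchor(self, minutes, expected):
        out = filter_independent_events(events_at_minutes(minutes))
        got = [
            (ts - pd.Timestamp("2020-01-01 12:00")) / pd.Timedelta(minutes=1)
            for ts in out["timestamp"]
        ]
        assert got == expected

    def test_groups_independent(self):
        ev = pd.concat(
            [
                events_at_minutes([0, 10], site=0, species="fox"),
                events_at_minutes([0, 10], site=1, species="fox"),
                events_at_minutes([5, 12], site=0, species="badger"),
            ]
        )
        out = filter_independent_events(ev)
        assert len(out) == 3  # one per (site, species) group

    def test_unparseable_timestamp_names_row(self):
        ev = events_at_minutes([0, 10]).astype({"timestamp": str})
        ev.loc[1, "timestamp"] = "not-a-date"
        with pytest.raises(ValueError, match="not-a-date"):
            filter_independent_events(ev)

    def test_empty_input(self):
        ev = events_at_minutes([])
        out = filter_independent_events(ev)
        assert out.empty

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 10_000, allow_nan=False), min_size=0, max_size=40),
        st.integers(0, 2),
    )
    def test_idempotent_and_pairwise_spaced(self, minutes, n_sites):
        """filter(filter(E)) == filter(E); retained events >= 30 min apart."""
        rng = np.random.default_rng(0)
        frames = [
            events_at_minutes(sorted(minutes), site=s) for s in range(n_sites + 1)
        ]
        ev = pd.concat(frames, ignore_index=True)
        once = filter_independent_events(ev)
        twice = filter_independent_events(once)
        pd.testing.assert_frame_equal(once, twice)
        for _, grp in once.groupby(["site_id", "species"]):
            ts = grp["timestamp"].sort_values()
            gaps = ts.diff().dropna() / pd.Timedelta(minutes=1)
            assert (gaps >= 30).all()


def full_deployments(design, site_ids=None):
    from occudyn import deployments_from_design

    return deployments_from_design(design, site_ids)


class TestHistoryBuilder:
    def test_no_events_full_effort(self):
        design = toy_design(3, 2, 4)
        hist = build_detection_history(
            events_at_minutes([]), full_deployments(design), design, "fox"
        )
        assert np.all(hist.y == 0)
        assert np.all(hist.effort == 5)

    def test_event_day7_lands_in_occasion2(self):
        """Half-open binning: day 7 falls in [5, 10), the second occasion."""
        design = toy_design(1, 1, 4)
        ev = pd.DataFrame(
            {
                "site_id": [0],
                "species": ["fox"],
                "timestamp": [design.seasons[0].start + pd.Timedelta(days=7)],
            }
        )
        hist = build_detection_history(ev, full_deployments(design), design, "fox")
        assert hist.y[0, 0, 1] == 1
        assert hist.y[0, 0, [0, 2, 3]].sum() == 0

    def test_partial_deployment_effort_and_na(self):
        """0 covered days -> NA/effort 0; exactly 1 day -> active, effort 1."""
        design = toy_design(2, 1, 2)
        s0 = design.seasons[0].start
        deployments = pd.DataFrame(
            [
                # site 0: covers only day 5 (occasion 2's first day)
                {"site_id": 0, "start": s0 + pd.Timedelta(days=5), "end": s0 + pd.Timedelta(days=6)},
                # site 1: full coverage
                {"site_id": 1, "start": s0, "end": s0 + pd.Timedelta(days=10)},
            ]
        )
        hist = build_detection_history(
            events_at_minutes([]), deployments, design, "fox", site_ids=[0, 1]
        )
        assert np.isnan(hist.y[0, 0, 0]) and hist.effort[0, 0, 0] == 0
        assert hist.y[0, 0, 1] == 0 and hist.effort[0, 0, 1] == 1
        assert np.all(hist.effort[1, 0] == 5)

    def test_half_day_rule(self):
        """A day counts as covered only with >= 12 h of deployment."""
        design = toy_design(1, 1, 1)
        s0 = design.seasons[0].start
        dep = pd.DataFrame(
            [{"site_id": 0, "start": s0, "end": s0 + pd.Timedelta(hours=11)}]
        )
        hist = build_detection_history(events_at_minutes([]), dep, design, "fox", site_ids=[0])
        assert hist.effort[0, 0, 0] == 0
        dep2 = pd.DataFrame(
            [{"site_id": 0, "start": s0, "end": s0 + pd.Timedelta(hours=13)}]
        )
        hist2 = build_detection_history(events_at_minutes([]), dep2, design, "fox", site_ids=[0])
        assert hist2.effort[0, 0, 0] == 1

    def test_event_outside_deployment_dropped_with_warning(self):
        design = toy_design(1, 1, 2)
        s0 = design.seasons[0].start
        dep = pd.DataFrame(
            [{"site_id": 0, "start": s0, "end": s0 + pd.Timedelta(days=5)}]
        )
        ev = pd.DataFrame(
            {
                "site_id": [0],
                "species": ["fox"],
                "timestamp": [s0 + pd.Timedelta(days=6)],
            }
        )
        with pytest.warns(UserWarning, match="outside deployment"):
            hist = build_detection_history(ev, dep, design, "fox", site_ids=[0])
        assert hist.report["events_outside_deployment"] == 1
        assert np.nansum(hist.y) == 0

    def test_event_outside_seasons_counted(self):
        design = toy_design(1, 2, 2)
        dep = full_deployments(design)
        between = design.seasons[0].end + pd.Timedelta(days=2)
        dep = pd.concat(
            [dep, pd.DataFrame([{"site_id": 0, "start": design.seasons[0].start, "end": design.seasons[1].end}])],
            ignore_index=True,
        )
        ev = pd.DataFrame({"site_id": [0], "species": ["fox"], "timestamp": [between]})
        hist = build_detection_history(ev, dep, design, "fox", site_ids=[0])
        assert hist.report["events_outside_seasons"] == 1

    def test_occasion_binning_partition(self):
        """Every in-season event maps to exactly one occasion."""
        design = toy_design(1, 1, 5)
        rng = np.random.default_rng(3)
        days = rng.uniform(0, 25, size=80)
        ev = pd.DataFrame(
            {
                "site_id": 0,
                "species": "fox",
                "timestamp": [
                    design.seasons[0].start + pd.Timedelta(days=float(d)) for d in days
                ],
            }
        )
        occ_idx = (days // 5).astype(int)
        hist = build_detection_history(ev, full_deployments(design), design, "fox", site_ids=[0])
        expected = np.zeros(5)
        expected[np.unique(occ_idx)] = 1
        np.testing.assert_array_equal(hist.y[0, 0], expected)


class TestNaiveOccupancy:
    def test_all_zero(self):
        hist = history_from_y(np.zeros((5, 2, 3)))
        assert (naive_occupancy(hist) == 0).all()

    def test_direct_count(self):
        y = np.zeros((10, 1, 3))
        y[:3, 0, 0] = 1
        assert naive_occupancy(history_from_y(y)).iloc[0] == pytest.approx(0.3)

    def test_na_only_sites_excluded_from_denominator(self):
        """4-site toy: one NA-only site leaves 3 surveyed, 1 detected -> 1/3."""
        y = np.zeros((4, 1, 2))
        y[0, 0, :] = np.nan
        y[1, 0, 0] = 1
        assert naive_occupancy(history_from_y(y)).iloc[0] == pytest.approx(1 / 3)

    def test_unsurveyed_season_warns_nan(self):
        y = np.zeros((2, 2, 2))
        y[:, 1, :] = np.nan
        with pytest.warns(UserWarning, match="no surveyed sites"):
            out = naive_occupancy(history_from_y(y))
        assert np.isnan(out.iloc[1])

    def test_invariant_to_duplicate_events_within_occasion(self):
        """Naive occupancy only sees the 0/1 summary, not event counts."""
        design = toy_design(2, 1, 2)
        ev1 = events_at_minutes([0], base=str(design.seasons[0].start + pd.Timedelta(hours=1)))
        ev2 = events_at_minutes([0, 1, 2], base=str(design.seasons[0].start + pd.Timedelta(hours=1)))
        h1 = build_detection_history(ev1, full_deployments(design), design, "fox")
        h2 = build_detection_history(ev2, full_deployments(design), design, "fox")
        pd.testing.assert_series_equal(naive_occupancy(h1), naive_occupancy(h2))


class TestSubsetSeasons:
    def _hist_covs(self):
        rng = np.random.default_rng(0)
        y = (rng.random((6, 4, 3)) < 0.3).astype(float)
        hist = history_from_y(y)
        labels = hist.design.season_labels
        covs = CovariateSet(
            site=pd.DataFrame({"x": rng.normal(size=6)}),
            season_site={
                "g": pd.DataFrame(rng.normal(size=(6, 4)), columns=labels)
            },
            observation={"Effort": rng.uniform(1, 5, size=(6, 4, 3))},
        )
        return hist, covs

    def test_keep_all_is_identity(self):
        hist, covs = self._hist_covs()
        sub, covs2 = subset_seasons(hist, covs, hist.design.season_labels)
        np.testing.assert_array_equal(sub.y, hist.y)

    def test_two_wet_seasons_one_transition(self):
        hist, covs = self._hist_covs()
        labels = hist.design.season_labels
        sub, covs2 = subset_seasons(hist, covs, [labels[0], labels[2]])
        assert sub.design.n_seasons == 2
        assert sub.design.n_seasons - 1 == 1
        assert list(covs2.season_site["g"].columns) == [labels[0], labels[2]]
        assert covs2.observation["Effort"].shape == (6, 2, 3)

    def test_single_season_boundary(self):
        hist, covs = self._hist_covs()
        sub, _ = subset_seasons(hist, covs, [hist.design.season_labels[2]])
        assert sub.design.n_seasons == 1

    def test_unknown_label_errors(self):
        hist, covs = self._hist_covs()
        with pytest.raises(KeyError):
            subset_seasons(hist, covs, ["nope"])


class TestStandardize:
    def test_sample_sd_convention(self):
        """(1,2,3) -> (-1,0,1): centering by 2, scaling by sample SD 1."""
        covs = CovariateSet(site=pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        out = standardize_covariates(covs)
        np.testing.assert_allclose(out.site["x"], [-1, 0, 1])
        assert out.standardization["x"] == (2.0, 1.0)

    def test_idempotent(self):
        covs = CovariateSet(site=pd.DataFrame({"x": [1.0, 5.0, 2.0, 7.0]}))
        once = standardize_covariates(covs)
        twice = standardize_covariates(once)
        pd.testing.assert_frame_equal(once.site, twice.site)

    def test_constant_column_errors_with_name(self):
        covs = CovariateSet(site=pd.DataFrame({"flat": [3.0, 3.0, 3.0]}))
        with pytest.raises(ValueError, match="flat"):
            standardize_covariates(covs)

    def test_categoricals_untouched(self):
        covs = CovariateSet(
            site=pd.DataFrame({"x": [1.0, 2.0, 4.0], "Feat": ["a", "b", "a"]}),
            categorical_levels={"Feat": ["a", "b"]},
        )
        out = standardize_covariates(covs)
        assert list(out.site["Feat"]) == ["a", "b", "a"]

    def test_observation_covariate_moments(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(1, 5, size=(10, 2, 4))
        arr[0, 0, 0] = np.nan
        covs = CovariateSet(site=pd.DataFrame(index=range(10)), observation={"Effort": arr})
        out = standardize_covariates(covs)
        vals = out.observation["Effort"]
        finite = vals[np.isfinite(vals)]
        assert abs(finite.mean()) < 1e-12
        assert abs(finite.std(ddof=1) - 1) < 1e-12
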