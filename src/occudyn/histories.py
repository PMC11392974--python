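"""Detection histories from camera-trap event streams.

This module turns raw timestamped detection events plus camera deployment
records into the site x season x occasion detection/effort arrays that the
occupancy likelihood consumes:

1. :func:`filter_independent_events` keeps only events at least 30 minutes
   apart (per site and species) so that bursts of triggers from one animal
   visit count once;
2. :func:`build_detection_history` discretises retained events into 5-day
   occasions and computes per-occasion effort (active camera days), marking
   occasions with less than one active day as missing (NA);
3. :func:`naive_occupancy` gives the uncorrected proportion of surveyed
   sites with at least one detection per season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateSet
from .design import SurveyDesign

__all__ = [
    "DetectionHistory",
    "filter_independent_events",
    "build_detection_history",
    "naive_occupancy",
    "subset_seasons",
]

EVENT_COLUMNS = ["site_id", "species", "timestamp"]


@dataclass
class DetectionHistory:
    """Per-species detection and effort arrays for one survey.

    ``y`` has shape (n_sites, n_seasons, n_occasions) with values 0, 1 or
    NaN; ``effort`` holds active camera days per occasion.  The two are
    linked by construction: ``y`` is NaN exactly where effort < 1 day.
    """

    y: np.ndarray
    effort: np.ndarray
    species: str
    design: SurveyDesign
    site_ids: list = field(default_factory=list)
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        expected = (self.design.n_sites, self.design.n_seasons, self.design.n_occasions)
        if self.y.shape != expected or self.effort.shape != expected:
            raise ValueError(
                f"y/effort must have shape {expected}, got {self.y.shape}/{self.effort.shape}"
            )
        if not self.site_ids:
            self.site_ids = list(range(self.design.n_sites))
        na = np.isnan(self.y)
        low = self.effort < 1.0
        if not np.array_equal(na, low):
            raise ValueError("y must be NA exactly where effort < 1 day")
        vals = self.y[~na]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("non-missing y entries must be 0 or 1")
        if (self.effort < 0).any() or (self.effort > self.design.occasion_days).any():
            raise ValueError("effort must lie in [0, occasion_days]")

    @property
    def n_sites(self) -> int:
        return self.design.n_sites

    @property
    def mask(self) -> np.ndarray:
        """Boolean array: True where an occasion was actively surveyed."""
        return ~np.isnan(self.y)

    def to_long_frame(self) -> pd.DataFrame:
        n, t, k = self.y.shape
        idx = pd.MultiIndex.from_product(
            [self.site_ids, self.design.season_labels, range(1, k + 1)],
            names=["site", "season", "occasion"],
        )
        return pd.DataFrame(
            {"y": self.y.reshape(-1), "effort": self.effort.reshape(-1)}, index=idx
        ).reset_index()

    def to_wide_frame(self) -> pd.DataFrame:
        """One row per site-season with one column per occasion."""
        n, t, k = self.y.shape
        rows = []
        for i, sid in enumerate(self.site_ids):
            for jt, lab in enumerate(self.design.season_labels):
                row = {"site": sid, "season": lab}
                for jk in range(k):
                    row[f"o{jk + 1}"] = self.y[i, jt, jk]
                rows.append(row)
        return pd.DataFrame(rows)


def _parse_timestamps(events: pd.DataFrame) -> pd.Series:
    ts = pd.to_datetime(events["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() & events["timestamp"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {events['timestamp'].iloc[row]!r} at row {events.index[row]}"
        )
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValueError(f"missing timestamp at row {events.index[row]}")
    return ts


def filter_independent_events(events: pd.DataFrame, window: float = 30.0) -> pd.DataFrame:
    """Keep only independent events: >= ``window`` minutes apart.

    Within each (site, species) group, events are scanned chronologically
    and an event is retained iff at least ``window`` minutes have elapsed
    since the last *retained* event of that group (sliding anchor).  Events
    exactly at the window boundary are retained.  The operation is
    idempotent and returns a chronologically sorted table.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    events = events.copy()
    if events.empty:
        return events.reset_index(drop=True)
    events["timestamp"] = _parse_timestamps(events)
    events = events.sort_values(["timestamp", "site_id", "species"], kind="stable")

    delta = pd.Timedelta(minutes=window)
    keep = np.zeros(len(events), dtype=bool)
    grouped = events.reset_index(drop=True).groupby(["site_id", "species"], sort=False)
    for _, grp in grouped:
        last = None
        for pos, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= delta:
                keep[pos] = True
                last = ts
    out = events.reset_index(drop=True)[keep]
    return out.sort_values(["timestamp", "site_id", "species"], kind="stable").reset_index(
        drop=True
    )


def _deployment_day_coverage(
    deployments: pd.DataFrame, site_id, day_starts: np.ndarray
) -> np.ndarray:
    """Hours of deployment coverage for each calendar day in ``day_starts``."""
    cover = np.zeros(len(day_starts), dtype=float)
    rows = deployments[deployments["site_id"] == site_id]
    day_end = day_starts + np.timedelta64(24, "h")
    for _, r in rows.iterrows():
        lo = np.maximum(day_starts, np.datetime64(pd.Timestamp(r["start"])))
        hi = np.minimum(day_end, np.datetime64(pd.Timestamp(r["end"])))
        overlap = (hi - lo) / np.timedelta64(1, "h")
        cover += np.clip(overlap, 0.0, None)
    return np.minimum(cover, 24.0)


def build_detection_history(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    design: SurveyDesign,
    species: str,
    site_ids=None,
    min_day_hours: float = 12.0,
) -> DetectionHistory:
    """Discretise events into a detection/effort history for one species.

    Occasion ``k`` of a season spans days ``[start + (k-1)*d, start + k*d)``
    (half-open, ``d = occasion_days``).  ``y[i,t,k] = 1`` iff at least one
    event of the species fell in that site-occasion; effort counts
    deployment-covered days in the occasion (a day counts as covered when
    at least ``min_day_hours`` hours of it are under deployment).  Occasions
    with effort < 1 day are missing (NA).

    Events outside every deployment interval of their site are dropped with
    a warning; events outside every season are excluded and counted in
    ``history.report``.
    """
    if site_ids is None:
        site_ids = sorted(
            set(deployments["site_id"]).union(events["site_id"] if len(events) else [])
        )
        if len(site_ids) < design.n_sites:
            site_ids = list(range(design.n_sites))
    site_pos = {s: i for i, s in enumerate(site_ids)}

    n, t, k = design.n_sites, design.n_seasons, design.n_occasions
    effort = np.zeros((n, t, k), dtype=float)
    y = np.zeros((n, t, k), dtype=float)

    # --- effort from deployments -------------------------------------------------
    for jt, season in enumerate(design.seasons):
        n_days = design.occasion_days * k
        day_starts = (
            np.datetime64(season.start) + np.arange(n_days) * np.timedelta64(24, "h")
        )
        for sid in site_ids:
            i = site_pos[sid]
            hours = _deployment_day_coverage(deployments, sid, day_starts)
            active_days = (hours >= min_day_hours).astype(float)
            effort[i, jt, :] = active_days.reshape(k, design.occasion_days).sum(axis=1)

    # --- detections from events --------------------------------------------------
    n_dropped_outside_deployment = 0
    n_outside_seasons = 0
    ev = events[events["species"] == species].copy()
    if len(ev):
        ev["timestamp"] = _parse_timestamps(ev)
        for _, row in ev.iterrows():
            sid = row["site_id"]
            if sid not in site_pos:
                n_dropped_outside_deployment += 1
                continue
            i = site_pos[sid]
            ts = row["timestamp"]
            jt = None
            for s_idx, season in enumerate(design.seasons):
                end_used = season.start + pd.Timedelta(
                    days=design.occasion_days * design.n_occasions
                )
                if season.start <= ts < end_used:
                    jt = s_idx
                    break
            if jt is None:
                n_outside_seasons += 1
                continue
            dep = deployments[deployments["site_id"] == sid]
            covered = any(
                pd.Timestamp(r["start"]) <= ts < pd.Timestamp(r["end"])
                for _, r in dep.iterrows()
            )
            if not covered:
                n_dropped_outside_deployment += 1
                continue
            day = int((ts - design.seasons[jt].start) / pd.Timedelta(days=1))
            jk = day // design.occasion_days
            y[i, jt, jk] = 1.0

    if n_dropped_outside_deployment:
        warnings.warn(
            f"{n_dropped_outside_deployment} event(s) outside deployment intervals "
            "were dropped",
            stacklevel=2,
        )

    y = np.where(effort < 1.0, np.nan, y)
    return DetectionHistory(
        y=y,
        effort=effort,
        species=species,
        design=design,
        site_ids=list(site_ids),
        report={
            "events_outside_deployment": n_dropped_outside_deployment,
            "events_outside_seasons": n_outside_seasons,
        },
    )


def naive_occupancy(history: DetectionHistory) -> pd.Series:
    """Proportion of surveyed sites with >= 1 detection, per season.

    The denominator for a season counts only sites with at least one
    non-missing occasion in that season; a season with no surveyed sites
    yields NaN with a warning.
    """
    y = history.y
    detected = np.nansum(y, axis=2) > 0  # (N, T)
    surveyed = (~np.isnan(y)).any(axis=2)
    out = {}
    for jt, lab in enumerate(history.design.season_labels):
        n_surv = int(surveyed[:, jt].sum())
        if n_surv == 0:
            warnings.warn(f"season {lab!r}: no surveyed sites", stacklevel=2)
            out[lab] = np.nan
        else:
            out[lab] = float((detected[:, jt] & surveyed[:, jt]).sum()) / n_surv
    return pd.Series(out, name="naive_occupancy")


def subset_seasons(
    history: DetectionHistory, covs: CovariateSet | None, keep
) -> tuple[DetectionHistory, CovariateSet | None]:
    """Restrict a history (and covariates) to an ordered subset of seasons.

    Used e.g. to analyse only the wet seasons for species that are rarely
    detected in the dry season.  Transition-indexed covariates are
    re-aligned automatically because model matrices are built from the new
    season ordering.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must name at least one season")
    idx = [history.design.season_index(l) for l in keep]
    new_design = history.design.subset(keep)
    new_hist = DetectionHistory(
        y=history.y[:, idx, :].copy(),
        effort=history.effort[:, idx, :].copy(),
        species=history.species,
        design=new_design,
        site_ids=list(history.site_ids),
        report=dict(history.report),
    )
    if covs is None:
        return new_hist, None
    new_covs = covs.subset_seasons(keep)
    new_covs.observation = {
        k: v[:, idx, :].copy() for k, v in covs.observation.items()
    }
    return new_hist, new_covs
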