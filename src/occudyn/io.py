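"""CSV readers and writers for events, deployments, covariates and histories.

All files are plain comma-separated text with a header row; timestamps are
ISO-8601.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .covariates import CovariateSet
from .histories import DetectionHistory

__all__ = [
    "read_events",
    "write_events",
    "read_deployments",
    "write_deployments",
    "write_covariates",
    "read_covariates",
    "write_history",
]


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site_id", "species", "timestamp"} - set(df.columns)
    if missing:
        raise ValueError(f"events file {path}: missing columns {sorted(missing)}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site_id", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"deployments file {path}: missing columns {sorted(missing)}")
    return df


def write_deployments(deployments: pd.DataFrame, path) -> None:
    out = deployments.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_covariates(covs: CovariateSet, directory) -> None:
    """One file per covariate class: site and season-site (long format)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    covs.site.rename_axis("site").to_csv(directory / "site_covariates.csv")
    if covs.season_site:
        frames = []
        for name, df in covs.season_site.items():
            long = df.rename_axis("site").reset_index().melt(
                id_vars="site", var_name="season", value_name=name
            )
            frames.append(long.set_index(["site", "season"]))
        pd.concat(frames, axis=1).reset_index().to_csv(
            directory / "season_site_covariates.csv", index=False
        )


def read_covariates(directory, categorical_levels=None) -> CovariateSet:
    directory = Path(directory)
    site = pd.read_csv(directory / "site_covariates.csv", index_col="site")
    season_site = {}
    ss_path = directory / "season_site_covariates.csv"
    if ss_path.exists():
        long = pd.read_csv(ss_path)
        for name in [c for c in long.columns if c not in ("site", "season")]:
            wide = long.pivot(index="site", columns="season", values=name)
            season_site[name] = wide
    return CovariateSet(
        site=site,
        season_site=season_site,
        categorical_levels=dict(categorical_levels or {}),
    )


def write_history(history: DetectionHistory, path_long, path_wide=None) -> None:
    """Long format (site, season, occasion, y, effort) and optional wide."""
    history.to_long_frame().to_csv(path_long, index=False)
    if path_wide is not None:
        history.to_wide_frame().to_csv(path_wide, index=False)
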