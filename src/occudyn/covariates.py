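"""Covariate containers and standardization.

Covariates come in three flavours:

* **site** covariates — one value per station, constant across seasons
  (e.g. distance to riparian vegetation, shrub cover, the categorical
  camera-view feature type);
* **season-site** covariates — one value per station and season
  (e.g. grazing pressure, NDVI);
* **observation** covariates — one value per station, season and occasion
  (here, survey effort in active days).

Continuous covariates are standardized (mean 0, SD 1, sample SD with
``ddof=1``) before entering a model; the original (mean, SD) pairs are kept
so that effects can be plotted back on the natural scale.  Categorical
covariates are stored as levels and expanded to reference-coded indicator
columns only when a model matrix is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CovariateSet", "standardize_covariates"]


@dataclass
class CovariateSet:
    """Site-, season-site- and observation-level covariates for one survey.

    Attributes
    ----------
    site : pandas.DataFrame
        One row per site.  Numeric columns are continuous covariates unless
        listed in ``categorical_levels``.
    season_site : dict of str -> pandas.DataFrame
        Each value has one row per site and one column per season label.
    observation : dict of str -> numpy.ndarray
        Arrays of shape (n_sites, n_seasons, n_occasions); NaN marks
        occasions with no usable deployment.
    standardization : dict of str -> (mean, sd)
        Original-scale moments of each standardized continuous covariate.
    categorical_levels : dict of str -> list
        Level ordering for categorical site covariates; the first level is
        the reference cell.
    """

    site: pd.DataFrame
    season_site: dict = field(default_factory=dict)
    observation: dict = field(default_factory=dict)
    standardization: dict = field(default_factory=dict)
    categorical_levels: dict = field(default_factory=dict)
    is_standardized: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.site)

    def continuous_site_columns(self) -> list[str]:
        return [
            c
            for c in self.site.columns
            if c not in self.categorical_levels
            and pd.api.types.is_numeric_dtype(self.site[c])
        ]

    def has(self, name: str) -> bool:
        return (
            name in self.site.columns
            or name in self.season_site
            or name in self.observation
        )

    def kind(self, name: str) -> str:
        if name in self.categorical_levels:
            return "categorical"
        if name in self.site.columns:
            return "site"
        if name in self.season_site:
            return "season_site"
        if name in self.observation:
            return "observation"
        raise KeyError(f"unknown covariate {name!r}")

    def subset_seasons(self, labels: list[str]) -> "CovariateSet":
        """Slice season-indexed covariates down to ``labels`` (in order)."""
        season_site = {k: v[list(labels)].copy() for k, v in self.season_site.items()}
        # observation arrays are indexed positionally; caller supplies indices
        return replace(self, season_site=season_site)


def _standardize_array(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    vals = np.asarray(values, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        raise ValueError(f"covariate {name!r}: not enough values to standardize")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"covariate {name!r} has zero standard deviation")
    return (vals - mean) / sd, mean, sd


def standardize_covariates(covs: CovariateSet) -> CovariateSet:
    """Center and scale every continuous covariate to mean 0, SD 1.

    Uses the sample SD (``ddof=1``) over all values that enter the model:
    sites for site covariates, site x season values for season-site
    covariates, and non-missing occasions for observation covariates.
    Categorical covariates are untouched.  Applying this to an
    already-standardized set returns it unchanged.

    Raises
    ------
    ValueError
        If a continuous covariate is constant (zero SD), naming it.
    """
    if covs.is_standardized:
        return covs

    site = covs.site.copy()
    standardization = dict(covs.standardization)
    for col in covs.continuous_site_columns():
        std, mean, sd = _standardize_array(site[col].to_numpy(), col)
        site[col] = std
        standardization[col] = (mean, sd)

    season_site = {}
    for name, df in covs.season_site.items():
        std, mean, sd = _standardize_array(df.to_numpy(), name)
        season_site[name] = pd.DataFrame(std, index=df.index, columns=df.columns)
        standardization[name] = (mean, sd)

    observation = {}
    for name, arr in covs.observation.items():
        std, mean, sd = _standardize_array(arr, name)
        observation[name] = std
        standardization[name] = (mean, sd)

    return CovariateSet(
        site=site,
        season_site=season_site,
        observation=observation,
        standardization=standardization,
        categorical_levels=dict(covs.categorical_levels),
        is_standardized=True,
    )
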