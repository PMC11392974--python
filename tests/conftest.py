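"""Shared fixtures and independent oracles for the test suite.

The enumeration oracle computes the multi-season likelihood by brute-force
summation over every latent state sequence; it is deliberately independent
of the package's forward recursion.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from occudyn import (
    CovariateSet,
    DetectionHistory,
    SurveyDesign,
    Season,
    standardize_covariates,
)


def enum_site_loglik(y, phi1, gamma, eps, p):
    """Brute-force marginal likelihood: sum over all 2^T latent sequences.

    ``y`` is (T, K) with NaN for missing; ``gamma``/``eps`` are length T-1
    sequences (or scalars) and ``p`` broadcasts to (T, K).
    """
    y = np.asarray(y, dtype=float)
    n_seasons, n_occ = y.shape
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(n_seasons - 1, 1),))
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (max(n_seasons - 1, 1),))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n_seasons, n_occ))
    total = 0.0
    for zseq in itertools.product([0, 1], repeat=n_seasons):
        prob = phi1 if zseq[0] == 1 else 1.0 - phi1
        for t in range(n_seasons - 1):
            if zseq[t] == 1:
                prob *= eps[t] if zseq[t + 1] == 0 else 1.0 - eps[t]
            else:
                prob *= gamma[t] if zseq[t + 1] == 1 else 1.0 - gamma[t]
        for t in range(n_seasons):
            for k in range(n_occ):
                if np.isnan(y[t, k]):
                    continue
                if zseq[t] == 1:
                    prob *= p[t, k] if y[t, k] == 1 else 1.0 - p[t, k]
                else:
                    if y[t, k] == 1:
                        prob = 0.0
        total += prob
    with np.errstate(divide="ignore"):
        return float(np.log(total))


def toy_design(n_sites, n_seasons, n_occasions, occasion_days=5):
    seasons = []
    t0 = pd.Timestamp("2020-01-01")
    for j in range(n_seasons):
        start = t0 + pd.Timedelta(days=j * (occasion_days * n_occasions + 10))
        seasons.append(
            Season(f"S{j}", start, start + pd.Timedelta(days=occasion_days * n_occasions))
        )
    return SurveyDesign(
        n_sites=n_sites,
        seasons=tuple(seasons),
        occasion_days=occasion_days,
        n_occasions=n_occasions,
    )


def history_from_y(y, occasion_days=5):
    """Wrap a raw (N, T, K) array (NaN = missing) into a DetectionHistory."""
    y = np.asarray(y, dtype=float)
    n, t, k = y.shape
    design = toy_design(n, t, k, occasion_days)
    effort = np.where(np.isnan(y), 0.0, float(occasion_days))
    return DetectionHistory(y=y, effort=effort, species="toy", design=design)


def constant_covariates(n_sites, season_labels):
    """An empty covariate set (intercept-only models)."""
    return CovariateSet(site=pd.DataFrame(index=range(n_sites)), is_standardized=True)


@pytest.fixture(scope="session")
def study_scenario():
    """Default synthetic scenario shared by read-only tests."""
    from occudyn import scenario_study_default

    return scenario_study_default(seed=1)


@pytest.fixture(scope="session")
def fitted_default():
    """A reduced-budget fit of the generating model on the default scenario."""
    from occudyn import (
        DynamicOccupancyModel,
        scenario_study_default,
        simulate_detections,
        simulate_dynamics,
    )

    design, covs, truth = scenario_study_default(seed=7)
    z = simulate_dynamics(design, truth, covs, seed=8)
    hist, covs2 = simulate_detections(z, truth, covs, design, seed=9)
    model = DynamicOccupancyModel(hist, covs2, truth.model_spec())
    res = model.fit(n_chains=3, n_iter=1500, n_burn=500, seed=10)
    return truth, model, res
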