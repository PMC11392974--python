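"""Model ranking, stacking weights and model-averaged posteriors.

Candidate models are ranked by total PSIS-LOO elpd after a reliability
screen: any model with a site whose Pareto k-hat exceeds 0.7 is discarded
(importance sampling cannot provide useful estimates there).  When the
surviving models' elpd values are within 4 of the best, their predictive
performance is considered similar and the models are averaged by
*stacking*: simplex weights are chosen to maximize the combined
leave-one-out log score

    sum_i log sum_m w_m exp(elpd_i,m).

Averaged posteriors are a weighted mixture of the candidate posteriors in
which a coefficient absent from the selected model contributes exactly 0.
This is why averaged credible intervals can have an endpoint at exactly
zero: when the models carrying a covariate hold less than 95% of the
weight, at least 2.5% of the mixture mass sits on the spike at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import logsumexp, softmax

from .inference import OccupancyResults, PosteriorSample, summarize
from .loo import LooResult

__all__ = [
    "StackingWeights",
    "rank_models",
    "stacking_weights",
    "average_posteriors",
    "average_seasonal_occupancy",
]

#: models with any site k-hat above this are discarded from ranking
K_DISCARD = 0.7
#: below this every site's elpd is considered estimated with high accuracy
K_GOOD = 0.5
#: elpd differences smaller than this trigger model averaging
ELPD_AVERAGE = 4.0


@dataclass
class StackingWeights:
    """Simplex weights over candidate models and the attained log score."""

    weights: np.ndarray
    objective: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < -1e-9).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to one")


def rank_models(loos: list[LooResult], model_ids=None) -> pd.DataFrame:
    """Screen and rank candidate models by elpd.

    Returns a DataFrame (one row per model, best first among survivors)
    with columns ``elpd_loo``, ``se``, ``max_k``, ``n_bad_k``,
    ``high_accuracy`` (all k-hat < 0.5), ``discarded``, ``elpd_diff`` (gap
    to the top surviving model) and ``average`` (True for every survivor
    when all surviving gaps are below 4).

    Raises
    ------
    ValueError
        When every model is discarded; more posterior draws (or simpler
        models) are needed.
    """
    if not loos:
        raise ValueError("rank_models requires at least one model")
    if model_ids is None:
        model_ids = [f"model_{i}" for i in range(len(loos))]
    rows = []
    for mid, loo in zip(model_ids, loos):
        rows.append(
            {
                "model": mid,
                "elpd_loo": loo.elpd_loo,
                "se": loo.se,
                "max_k": loo.max_k,
                "n_bad_k": loo.n_bad_k,
                "high_accuracy": loo.high_accuracy,
                "discarded": bool(
                    loo.n_bad_k > 0 or np.any(~np.isfinite(loo.pareto_k) & (loo.pareto_k > 0))
                ),
            }
        )
    tab = pd.DataFrame(rows)
    if tab["discarded"].all():
        raise ValueError(
            "all candidate models were discarded (Pareto k-hat > 0.7); "
            "increase the number of posterior draws"
        )
    survivors = tab[~tab["discarded"]].sort_values("elpd_loo", ascending=False)
    top = survivors["elpd_loo"].iloc[0]
    tab["elpd_diff"] = np.where(tab["discarded"], np.nan, top - tab["elpd_loo"])
    all_close = bool((survivors["elpd_loo"] >= top - ELPD_AVERAGE).all()) and len(survivors) > 1
    tab["average"] = ~tab["discarded"] & all_close
    order = np.argsort(np.where(tab["discarded"], np.inf, -tab["elpd_loo"]), kind="stable")
    return tab.iloc[order].reset_index(drop=True)


def _stack_objective(weights: np.ndarray, elpd: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        return float(np.sum(logsumexp(elpd + np.log(weights)[None, :], axis=1)))


def stacking_weights(
    pointwise_elpd: np.ndarray, n_starts: int = 5, seed: int = 0
) -> StackingWeights:
    """Stacking weights maximizing the combined LOO log score.

    ``pointwise_elpd`` is a (sites x models) matrix.  The simplex search
    uses a softmax reparameterization with ``n_starts`` deterministic
    multi-starts.  Models with identical pointwise scores are tied and
    share their weight equally.
    """
    elpd = np.asarray(pointwise_elpd, dtype=float)
    if elpd.ndim != 2:
        raise ValueError("pointwise_elpd must be (sites x models)")
    if not np.all(np.isfinite(elpd)):
        raise ValueError("pointwise elpd contains non-finite entries")
    n_sites, n_models = elpd.shape
    if n_models == 1:
        return StackingWeights(np.ones(1), _stack_objective(np.ones(1), elpd))

    # collapse duplicate columns so that ties resolve to equal weights
    groups: list[list[int]] = []
    for m in range(n_models):
        for g in groups:
            if np.allclose(elpd[:, m], elpd[:, g[0]], atol=1e-12):
                g.append(m)
                break
        else:
            groups.append([m])
    rep = np.array([g[0] for g in groups])
    e = elpd[:, rep]
    n_g = len(groups)

    if n_g == 1:
        weights = np.zeros(n_models)
        for m in groups[0]:
            weights[m] = 1.0 / len(groups[0])
        return StackingWeights(weights, _stack_objective(weights, elpd))

    def neg(a):
        w = softmax(np.concatenate([a, [0.0]]))
        return -_stack_objective(w, e)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        a0 = np.zeros(n_g - 1) if start == 0 else rng.standard_normal(n_g - 1)
        res = scipy.optimize.minimize(neg, a0, method="BFGS", options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    w_g = softmax(np.concatenate([best.x, [0.0]]))
    weights = np.zeros(n_models)
    for wg, g in zip(w_g, groups):
        for m in g:
            weights[m] = wg / len(g)
    weights = np.clip(weights, 0.0, None)
    weights /= weights.sum()
    return StackingWeights(weights, _stack_objective(weights, elpd))


def _mixture_draws(
    fits: list[OccupancyResults], weights: StackingWeights, n_out: int, seed
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a mixture posterior; returns (draws, per-draw model index)."""
    w = np.asarray(weights.weights, dtype=float)
    if len(w) != len(fits):
        raise ValueError("weights must align with fits")
    for wm, fit in zip(w, fits):
        if wm > 0 and (fit is None or fit.posterior.n_draws == 0):
            raise ValueError("positive weight on a fit without stored draws")
    names: list[str] = []
    for fit in fits:
        for nm in fit.model.param_names:
            if nm not in names:
                names.append(nm)
    rng = np.random.default_rng(seed)
    model_idx = rng.choice(len(fits), size=n_out, p=w)
    out = np.zeros((n_out, len(names)))
    cols = {nm: j for j, nm in enumerate(names)}
    for m, fit in enumerate(fits):
        rows = np.flatnonzero(model_idx == m)
        if rows.size == 0:
            continue
        take = rng.integers(0, fit.posterior.n_draws, size=rows.size)
        sub = fit.draws.to_numpy()[take]
        for jj, nm in enumerate(fit.model.param_names):
            out[rows, cols[nm]] = sub[:, jj]
    return pd.DataFrame(out, columns=names), model_idx


def average_posteriors(
    fits: list[OccupancyResults],
    weights: StackingWeights,
    n_out: int = 4000,
    seed: int | None = None,
) -> tuple[PosteriorSample, pd.DataFrame]:
    """Stacked mixture of candidate posteriors with zero-fill of absent terms.

    Each of the ``n_out`` mixture draws selects model m with probability
    w_m and then a uniform retained draw from that model's posterior;
    coefficients the selected model does not contain contribute exactly 0.
    Returns the mixed sample and its summary table (mean, SD, 95% BCI,
    significance flag).
    """
    draws, _ = _mixture_draws(fits, weights, n_out, seed)
    sample = PosteriorSample(
        draws=draws,
        chain_id=np.zeros(n_out, dtype=int),
        n_chains=1,
        n_iter=n_out,
        n_burn=0,
        seed=seed,
    )
    return sample, summarize(draws)


def average_seasonal_occupancy(
    fits: list[OccupancyResults],
    weights: StackingWeights,
    n_out: int = 4000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Model-averaged mean seasonal occupancy with 95% BCI.

    Every mixture draw is pushed through the occupancy recursion of its
    own model and averaged over sites; the resulting draws of per-season
    mean occupancy are summarized.
    """
    w = np.asarray(weights.weights, dtype=float)
    rng = np.random.default_rng(seed)
    model_idx = rng.choice(len(fits), size=n_out, p=w)
    season_labels = fits[0].model.design.season_labels
    occ_draws = np.empty((n_out, len(season_labels)))
    cache: dict[int, np.ndarray] = {}
    for m in np.unique(model_idx):
        cache[m] = fits[m].seasonal_occupancy_draws()
        if fits[m].model.design.season_labels != season_labels:
            raise ValueError("all fits must share the same season layout")
    for m in np.unique(model_idx):
        rows = np.flatnonzero(model_idx == m)
        take = rng.integers(0, len(cache[m]), size=rows.size)
        occ_draws[rows] = cache[m][take]
    lo, hi = np.percentile(occ_draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": occ_draws.mean(axis=0), "q2.5": lo, "q97.5": hi},
        index=pd.Index(season_labels, name="season"),
    )
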