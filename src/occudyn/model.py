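"""Multi-season (dynamic) occupancy model: likelihood core and Model class.

The model follows the original dynamic-occupancy parameterization: a site's
latent state z[i,t] in {0,1} starts at z[i,1] ~ Bernoulli(phi1_i), then
transitions with colonization gamma (0 -> 1) and extinction eps (1 -> 0)
between primary periods; detections within a season are conditionally
independent Bernoulli(p) given z = 1, with no false positives.  Occupancy
for later seasons is derived recursively:

    phi[t+1] = phi[t] * (1 - eps[t]) + (1 - phi[t]) * gamma[t]

All four parameters carry logit-linear covariate effects.  The marginal
likelihood of a site's detection history integrates the latent states
exactly by a two-state forward recursion; missing (NA) occasions contribute
a factor of one, i.e. they are marginalized out.

:class:`DynamicOccupancyModel` wraps a detection history, covariates and a
:class:`ModelSpec` into a fittable model in the statsmodels mould: its
``fit_map`` / ``fit`` methods return point estimates or an
:class:`~occudyn.inference.OccupancyResults` posterior object.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .covariates import CovariateSet, standardize_covariates
from .histories import DetectionHistory

__all__ = [
    "ModelSpec",
    "DynamicOccupancyModel",
    "site_log_likelihood",
    "derived_occupancy",
    "log_logistic_prior",
]

_STATE_BLOCKS = ("phi1", "gamma", "eps")


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates act on each occupancy-model parameter.

    State parameters (first-season occupancy ``phi1``, colonization
    ``gamma``, extinction ``eps``) each carry at most one covariate, and
    gamma and eps are never covaried simultaneously in a single model —
    a guard against overparameterization at small site counts.  Detection
    ``p`` may combine several terms (typically Season plus one of Shrubs,
    Feat, Alt, Effort).
    """

    phi1_terms: tuple = ()
    gamma_terms: tuple = ()
    eps_terms: tuple = ()
    p_terms: tuple = ()
    species: str = ""
    seasons_used: tuple = ()
    #: candidate models never covary gamma and eps together (too many
    #: parameters at typical site counts); recovery studies fitting the
    #: full generating structure may relax this.
    allow_joint_dynamics: bool = False

    def __post_init__(self):
        for name in ("phi1_terms", "gamma_terms", "eps_terms", "p_terms", "seasons_used"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("phi1_terms", "gamma_terms", "eps_terms"):
            if len(getattr(self, name)) > 1:
                raise ValueError(
                    f"{name}: state parameters carry at most one covariate (univariate rule)"
                )
        if self.gamma_terms and self.eps_terms and not self.allow_joint_dynamics:
            raise ValueError(
                "gamma and eps must not carry covariates simultaneously in one model"
            )

    @property
    def name(self) -> str:
        def _fmt(terms):
            return "+".join(terms) if terms else "1"

        return (
            f"phi1~{_fmt(self.phi1_terms)}|gamma~{_fmt(self.gamma_terms)}"
            f"|eps~{_fmt(self.eps_terms)}|p~{_fmt(self.p_terms)}"
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


def log_logistic_prior(theta: np.ndarray) -> float:
    """Sum of independent standard-Logistic(0,1) log-densities.

    The weakly informative default prior for all intercepts and slopes on
    the logit scale; its density at zero is 1/4.
    """
    th = np.abs(np.asarray(theta, dtype=float))
    return float(np.sum(-th - 2.0 * np.log1p(np.exp(-th))))


def derived_occupancy(phi1: np.ndarray, gamma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Seasonal occupancy from first-season occupancy and the dynamics.

    Parameters
    ----------
    phi1 : array (..., N)
        First-season occupancy per site.
    gamma, eps : array (..., N, T-1)
        Colonization and extinction per site and transition.

    Returns
    -------
    array (..., N, T) of per-site occupancy for every season.
    """
    phi1 = np.asarray(phi1, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    n_trans = gamma.shape[-1]
    out = [phi1]
    for t in range(n_trans):
        prev = out[-1]
        out.append(prev * (1.0 - eps[..., t]) + (1.0 - prev) * gamma[..., t])
    return np.stack(out, axis=-1)


def _expit(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward_loglik(phi1, gamma, eps, p, y0, mask, any_det):
    """Exact marginal log-likelihood per site via a scaled forward pass.

    ``y0`` is the history with NA replaced by 0, ``mask`` flags non-missing
    occasions and ``any_det`` flags site-seasons with >= 1 detection.  The
    per-season emission under z=1 is the product of Bernoulli(p) factors
    over non-missing occasions; under z=0 it is 1 unless a detection was
    recorded (no false positives).  Probabilities of exactly 0 or 1 are
    handled by the natural limits, not by clipping; an impossible history
    returns -inf.
    """
    n, n_seasons, _ = y0.shape
    det = np.where(mask, np.where(y0 > 0.5, p, 1.0 - p), 1.0)
    e1 = det.prod(axis=2)  # (N, T)
    e0 = np.where(any_det, 0.0, 1.0)

    a0 = 1.0 - phi1
    a1 = phi1.copy()
    logscale = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(n_seasons):
            w0 = a0 * e0[:, t]
            w1 = a1 * e1[:, t]
            s = w0 + w1
            if t == n_seasons - 1:
                return logscale + np.log(s)
            ok = s > 0.0
            safe = np.where(ok, s, 1.0)
            logscale = np.where(ok, logscale + np.log(safe), -np.inf)
            w0 = np.where(ok, w0 / safe, 0.0)
            w1 = np.where(ok, w1 / safe, 0.0)
            g = gamma[:, t]
            e = eps[:, t]
            a0 = w0 * (1.0 - g) + w1 * e
            a1 = w0 * g + w1 * (1.0 - e)


def site_log_likelihood(y_i: np.ndarray, phi1: float, gamma, eps, p) -> float:
    """Marginal log-likelihood of a single site's detection history.

    Parameters
    ----------
    y_i : array (T, K)
        Detection history with NaN for missing occasions.
    phi1 : float
        First-season occupancy probability.
    gamma, eps : scalar or array (T-1,)
        Transition probabilities.
    p : scalar or array (T, K)
        Detection probabilities.
    """
    y_i = np.asarray(y_i, dtype=float)
    n_seasons, n_occ = y_i.shape
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(n_seasons - 1, 1),))
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (max(n_seasons - 1, 1),))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n_seasons, n_occ))
    mask = ~np.isnan(y_i)
    y0 = np.nan_to_num(y_i)
    any_det = (np.where(mask, y0, 0.0) > 0.5).any(axis=1)
    return float(
        _forward_loglik(
            np.array([phi1]),
            gamma[None, : n_seasons - 1],
            eps[None, : n_seasons - 1],
            p[None],
            y0[None],
            mask[None],
            any_det[None],
        )[0]
    )


class DynamicOccupancyModel:
    """Dynamic occupancy model for one species' detection history.

    Parameters
    ----------
    history : DetectionHistory
        Detection/effort arrays (sites x seasons x occasions).
    covariates : CovariateSet
        Covariates; standardized automatically if not already.
    spec : ModelSpec, optional
        Covariate structure (defaults to the constant model).
    transition_season : {"next", "current"}
        Which season's value of a season-site covariate drives the
        transition t -> t+1.  The default "next" attaches the value
        measured for the interval preceding season t+1 (e.g. forestry work
        carried out before a survey season, or the previous season's
        grazing pressure).

    Examples
    --------
    >>> model = DynamicOccupancyModel(history, covs, spec)
    >>> res = model.fit(n_chains=3, n_iter=3000, n_burn=1000, seed=1)
    >>> res.summary()
    """

    def __init__(
        self,
        history: DetectionHistory,
        covariates: CovariateSet,
        spec: ModelSpec | None = None,
        transition_season: str = "next",
    ):
        if transition_season not in ("next", "current"):
            raise ValueError("transition_season must be 'next' or 'current'")
        self.history = history
        self.spec = spec if spec is not None else ModelSpec()
        self.transition_season = transition_season
        self.covariates = (
            covariates if covariates.is_standardized else standardize_covariates(covariates)
        )
        self.design = history.design
        self._build_matrices()
        # likelihood precomputations
        self._mask = history.mask
        self._y0 = np.nan_to_num(history.y)
        self._any_det = (np.where(self._mask, self._y0, 0.0) > 0.5).any(axis=2)

    # ------------------------------------------------------------------ matrices
    def _season_site_values(self, name: str) -> np.ndarray:
        """(N, T-1) covariate values aligned to transitions."""
        df = self.covariates.season_site[name]
        vals = df[self.design.season_labels].to_numpy(dtype=float)
        if self.transition_season == "next":
            return vals[:, 1:]
        return vals[:, :-1]

    def _site_column(self, name: str) -> np.ndarray:
        return self.covariates.site[name].to_numpy(dtype=float)

    def _state_matrix(self, terms, transition: bool):
        n = self.design.n_sites
        n_trans = max(self.design.n_seasons - 1, 0)
        cols = [("Intercept", None)]
        for term in terms:
            kind = self.covariates.kind(term)
            if kind == "categorical":
                raise ValueError(f"categorical covariate {term!r} not supported on state parameters")
            cols.append((term, kind))
        if transition:
            x = np.ones((n, n_trans, len(cols)))
        else:
            x = np.ones((n, len(cols)))
        for j, (term, kind) in enumerate(cols[1:], start=1):
            if kind == "site":
                v = self._site_column(term)
                if transition:
                    x[:, :, j] = v[:, None]
                else:
                    x[:, j] = v
            elif kind == "season_site":
                if transition:
                    x[:, :, j] = self._season_site_values(term)
                else:
                    df = self.covariates.season_site[term]
                    x[:, j] = df[self.design.season_labels[0]].to_numpy(dtype=float)
            else:
                raise ValueError(f"covariate {term!r} cannot model a state parameter")
        names = [c[0] for c in cols]
        return x, names

    def _p_matrix(self):
        n, t, k = self.design.n_sites, self.design.n_seasons, self.design.n_occasions
        blocks = [np.ones((n, t, k, 1))]
        names = ["Intercept"]
        for term in self.spec.p_terms:
            if term == "Season":
                labels = self.design.season_labels
                for jt, lab in enumerate(labels[1:], start=1):
                    col = np.zeros((n, t, k, 1))
                    col[:, jt, :, 0] = 1.0
                    blocks.append(col)
                    names.append(f"Season:{lab}")
                continue
            kind = self.covariates.kind(term)
            if kind == "categorical":
                levels = self.covariates.categorical_levels[term]
                vals = self.covariates.site[term].to_numpy()
                for lev in levels[1:]:
                    col = np.zeros((n, t, k, 1))
                    col[:, :, :, 0] = (vals == lev)[:, None, None]
                    blocks.append(col)
                    names.append(f"{term}:{lev}")
            elif kind == "site":
                col = np.zeros((n, t, k, 1))
                col[:, :, :, 0] = self._site_column(term)[:, None, None]
                blocks.append(col)
                names.append(term)
            elif kind == "season_site":
                df = self.covariates.season_site[term]
                col = np.zeros((n, t, k, 1))
                col[:, :, :, 0] = df[self.design.season_labels].to_numpy(dtype=float)[
                    :, :, None
                ]
                blocks.append(col)
                names.append(term)
            else:  # observation
                arr = np.nan_to_num(self.covariates.observation[term])
                blocks.append(arr[:, :, :, None])
                names.append(term)
        return np.concatenate(blocks, axis=3), names

    def _build_matrices(self):
        for block, terms in (
            ("phi1", self.spec.phi1_terms),
            ("gamma", self.spec.gamma_terms),
            ("eps", self.spec.eps_terms),
        ):
            for term in terms:
                if not self.covariates.has(term):
                    raise KeyError(f"unknown covariate {term!r} on {block}")
        for term in self.spec.p_terms:
            if term != "Season" and not self.covariates.has(term):
                raise KeyError(f"unknown covariate {term!r} on p")

        self._x_phi1, phi1_names = self._state_matrix(self.spec.phi1_terms, transition=False)
        self._x_gamma, gamma_names = self._state_matrix(self.spec.gamma_terms, transition=True)
        self._x_eps, eps_names = self._state_matrix(self.spec.eps_terms, transition=True)
        self._x_p, p_names = self._p_matrix()
        self._block_names = {
            "phi1": phi1_names,
            "gamma": gamma_names,
            "eps": eps_names,
            "p": p_names,
        }
        sizes = [len(phi1_names), len(gamma_names), len(eps_names), len(p_names)]
        self._splits = np.cumsum(sizes)[:-1]
        self.param_names = (
            [f"phi1[{c}]" for c in phi1_names]
            + [f"gamma[{c}]" for c in gamma_names]
            + [f"eps[{c}]" for c in eps_names]
            + [f"p[{c}]" for c in p_names]
        )
        self.k_params = len(self.param_names)

    # --------------------------------------------------------------- evaluation
    def split_params(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k_params,):
            raise ValueError(f"expected {self.k_params} parameters, got {theta.shape}")
        return np.split(theta, self._splits)

    def linear_predictors(self, theta: np.ndarray) -> dict:
        """Probability arrays phi1 (N,), gamma/eps (N,T-1), p (N,T,K)."""
        b_phi1, b_gamma, b_eps, b_p = self.split_params(theta)
        return {
            "phi1": _expit(self._x_phi1 @ b_phi1),
            "gamma": _expit(self._x_gamma @ b_gamma),
            "eps": _expit(self._x_eps @ b_eps),
            "p": _expit(self._x_p @ b_p),
        }

    def loglikeobs(self, theta: np.ndarray) -> np.ndarray:
        """Per-site marginal log-likelihood (the pointwise vector)."""
        pr = self.linear_predictors(theta)
        return _forward_loglik(
            pr["phi1"], pr["gamma"], pr["eps"], pr["p"], self._y0, self._mask, self._any_det
        )

    def loglike(self, theta: np.ndarray) -> float:
        return float(self.loglikeobs(theta).sum())

    def log_prior(self, theta: np.ndarray) -> float:
        return log_logistic_prior(theta)

    def log_posterior(self, theta: np.ndarray) -> float:
        return self.loglike(theta) + self.log_prior(theta)

    def seasonal_occupancy(self, theta: np.ndarray) -> np.ndarray:
        """Derived per-site occupancy (N, T) at a parameter point."""
        pr = self.linear_predictors(theta)
        return derived_occupancy(pr["phi1"], pr["gamma"], pr["eps"])

    # ---------------------------------------------------------------- fitting
    def fit_map(self, start=None, tol: float = 1e-8, maxiter: int = 500):
        from .inference import fit_map

        return fit_map(self, start=start, tol=tol, maxiter=maxiter)

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 15000,
        n_burn: int = 5000,
        seed: int | None = None,
        **kwargs,
    ):
        from .inference import sample_posterior

        return sample_posterior(
            self, n_chains=n_chains, n_iter=n_iter, n_burn=n_burn, seed=seed, **kwargs
        )

    def params_series(self, theta: np.ndarray) -> pd.Series:
        return pd.Series(np.asarray(theta, dtype=float), index=self.param_names)
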