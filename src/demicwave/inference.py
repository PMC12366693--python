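"""Two-step ABC: rejection, GLM-adjusted posteriors, RF model choice.

The first ABC step is the demographic filter (see
:func:`demicwave.forward.demographic_filter`); this module implements the
second, molecular step:

* plain rejection on Euclidean distance between (PLS-reduced) statistic
  vectors, retaining a fraction ``delta`` of the simulations;
* a GLM regression adjustment of the retained parameter draws: a linear
  model of parameters on statistics is fitted over the retained cloud, every
  draw is shifted to the observed statistics along the fitted plane, and the
  adjusted sample is smoothed onto a 1000-point grid per parameter truncated
  to the prior support, from which mode, mean and the 95% highest density
  interval (shortest interval holding 0.95 mass) are read off;
* a marginal-density goodness-of-fit p-value: the fraction of retained
  simulations whose density under the fitted statistic model is lower than
  the observed vector's;
* random-forest scenario choice in the style of abcrf: a classification
  forest votes on the observed statistics, and the posterior probability of
  the selected scenario is one minus an out-of-bag misclassification rate
  predicted at the observed point by a regression forest;
* leave-one-out relative bias of posterior point estimates, and
* two-dimensional GLM posteriors sampled by random-walk MCMC for joint
  queries such as P(gamma_S > gamma_N) or P(a <= K_FA/K_HG <= b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "reject",
    "PosteriorGLM",
    "PosteriorEstimate",
    "glm_adjust",
    "marginal_density_pvalue",
    "ScenarioChoiceForest",
    "ModelChoiceResult",
    "rf_model_choice",
    "relative_bias",
    "joint_posterior_2d",
    "prob_query",
    "Posterior2D",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """MCMC failed its convergence diagnostic; carries the chain draws."""

    def __init__(self, message: str, chains: np.ndarray):
        super().__init__(message)
        self.chains = chains


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def reject(
    stats: np.ndarray, observed: np.ndarray, delta: float
) -> np.ndarray:
    """Indices of the round(delta*N) simulations closest to the observation.

    Euclidean distance on (reduced) statistic vectors; ties broken by row
    index (stable sort).
    """
    stats = np.asarray(stats, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = stats.shape[0]
    k = _round_half_up(delta * n)
    if k < 2:
        raise ValueError(f"delta*N = {delta * n:.2f} retains fewer than 2 rows")
    dist = np.sqrt(((stats - observed) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    return np.sort(order[:k])


@dataclass
class PosteriorEstimate:
    """Marginal GLM-adjusted posterior summaries per parameter."""

    names: list[str]
    grid: np.ndarray  # (p, grid_size)
    density: np.ndarray  # (p, grid_size), integrates to 1 on the grid
    mode: np.ndarray
    mean: np.ndarray
    hdi_low: np.ndarray
    hdi_high: np.ndarray
    delta: Optional[float] = None
    retained: Optional[np.ndarray] = None
    pvalue: Optional[float] = None
    adjusted: Optional[np.ndarray] = None

    def summary(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.names,
                "posterior_mode": self.mode,
                "posterior_mean": self.mean,
                "hdi_2.5%": self.hdi_low,
                "hdi_97.5%": self.hdi_high,
            }
        )


def _hdi_from_grid(
    grid: np.ndarray, density: np.ndarray, mass: float = 0.95
) -> tuple[float, float]:
    """Shortest contiguous grid interval holding >= ``mass``; ties -> central."""
    dx = grid[1] - grid[0]
    p = density * dx
    cum = np.concatenate([[0.0], np.cumsum(p)])
    n = len(grid)
    best = (np.inf, np.inf, 0, n - 1)
    center = 0.5 * (grid[0] + grid[-1])
    j = 0
    for i in range(n):
        j = max(j, i)
        while j < n and cum[j + 1] - cum[i] < mass:
            j += 1
        if j >= n:
            break
        width = grid[j] - grid[i]
        centrality = abs(0.5 * (grid[i] + grid[j]) - center)
        if (width, centrality) < (best[0], best[1]):
            best = (width, centrality, i, j)
    return float(grid[best[2]]), float(grid[best[3]])


class PosteriorGLM(BaseEstimator):
    """GLM regression-adjusted ABC posterior (sklearn-style estimator).

    ``fit(X, y)`` takes retained statistic vectors X (n, k) and parameter
    draws y (n, p); ``estimate(observed)`` returns a
    :class:`PosteriorEstimate` on 1000-point grids truncated to
    ``prior_bounds``.
    """

    def __init__(
        self,
        prior_bounds: Sequence[tuple[float, float]] | None = None,
        names: Sequence[str] | None = None,
        grid_size: int = 1000,
        min_rows: int = 100,
    ):
        self.prior_bounds = prior_bounds
        self.names = names
        self.grid_size = grid_size
        self.min_rows = min_rows

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PosteriorGLM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] < self.min_rows:
            raise ValueError(
                f"need >= {self.min_rows} retained rows for the GLM adjustment"
            )
        design = np.column_stack([np.ones(len(X)), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef  # (k+1, p)
        self.X_, self.y_ = X, y
        self.n_params_ = y.shape[1]
        return self

    def adjusted_draws(self, observed: np.ndarray) -> np.ndarray:
        """Retained draws shifted to the observed statistics along the GLM."""
        observed = np.asarray(observed, dtype=float).ravel()
        B = self.coef_[1:]  # (k, p)
        return self.y_ - (self.X_ - observed) @ B

    def estimate(self, observed: np.ndarray, **meta) -> PosteriorEstimate:
        adj = self.adjusted_draws(observed)
        p = self.n_params_
        bounds = self.prior_bounds
        if bounds is None:
            span = np.ptp(self.y_, axis=0)
            bounds = [
                (self.y_[:, j].min() - 0.05 * span[j], self.y_[:, j].max() + 0.05 * span[j])
                for j in range(p)
            ]
        names = list(self.names) if self.names else [f"param_{j}" for j in range(p)]
        grid = np.empty((p, self.grid_size))
        dens = np.empty((p, self.grid_size))
        mode = np.empty(p)
        mean = np.empty(p)
        lo = np.empty(p)
        hi = np.empty(p)
        for j in range(p):
            g = np.linspace(bounds[j][0], bounds[j][1], self.grid_size)
            vals = adj[:, j]
            if np.std(vals) < 1e-12 * max(1.0, abs(np.mean(vals))):
                d = np.zeros_like(g)
                d[np.argmin(np.abs(g - vals.mean()))] = 1.0
            else:
                d = sps.gaussian_kde(vals)(g)
            dx = g[1] - g[0]
            total = d.sum() * dx
            if total <= 0:
                raise ValueError("posterior has no mass inside the prior support")
            d /= total
            grid[j], dens[j] = g, d
            mode[j] = g[np.argmax(d)]
            mean[j] = (g * d).sum() * dx
            lo[j], hi[j] = _hdi_from_grid(g, d)
        return PosteriorEstimate(
            names=names,
            grid=grid,
            density=dens,
            mode=mode,
            mean=mean,
            hdi_low=lo,
            hdi_high=hi,
            adjusted=adj,
            **meta,
        )


def glm_adjust(
    retained_stats: np.ndarray,
    retained_params: np.ndarray,
    observed: np.ndarray,
    prior_bounds: Sequence[tuple[float, float]] | None = None,
    names: Sequence[str] | None = None,
    grid_size: int = 1000,
    min_rows: int = 100,
    **meta,
) -> PosteriorEstimate:
    """One-shot GLM-adjusted posterior from retained simulations."""
    est = PosteriorGLM(
        prior_bounds=prior_bounds, names=names, grid_size=grid_size,
        min_rows=min_rows,
    )
    est.fit(retained_stats, retained_params)
    return est.estimate(observed, **meta)


def marginal_density_pvalue(
    retained_stats: np.ndarray, observed: np.ndarray
) -> float:
    """Fraction of retained simulations with lower model density than observed.

    The statistic model is a multivariate normal fitted to the retained
    cloud; small p means the observation sits in the tails, i.e. the
    scenario cannot reproduce the observed diversity.
    """
    X = np.asarray(retained_stats, dtype=float)
    observed = np.asarray(observed, dtype=float).ravel()
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-9 * np.trace(np.atleast_2d(cov)) / max(
        X.shape[1], 1
    ) * np.eye(X.shape[1])
    mvn = sps.multivariate_normal(mean=mean, cov=cov, allow_singular=True)
    log_ret = mvn.logpdf(X)
    log_obs = mvn.logpdf(observed)
    return float(np.mean(log_ret < log_obs))


@dataclass
class ModelChoiceResult:
    votes: dict[str, int]
    selected: str
    posterior_probability: float
    confusion_matrix: np.ndarray  # rows: true scenario, normalized
    scenario_order: list[str]
    n_trees: int
    oob_error: float


class ScenarioChoiceForest(BaseEstimator):
    """ABC random-forest model choice (abcrf-style).

    ``fit(X, y)`` grows a classification forest on raw statistic vectors and
    scenario labels, stores the out-of-bag confusion matrix, and trains a
    regression forest on the out-of-bag misclassification indicator;
    ``choose(observed)`` returns per-scenario votes, the majority scenario
    and its posterior probability (1 - predicted local error rate).
    """

    def __init__(self, n_trees: int = 2000, random_state: int | None = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "ScenarioChoiceForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("model choice needs at least two scenarios")
        self.classes_ = np.unique(y)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        oob = self.forest_.oob_decision_function_
        valid = ~np.isnan(oob).any(axis=1)
        oob_pred = self.forest_.classes_[np.argmax(oob, axis=1)]
        cm = np.zeros((len(self.classes_), len(self.classes_)))
        for i, true in enumerate(self.classes_):
            sel = valid & (y == true)
            for j, pred in enumerate(self.classes_):
                cm[i, j] = np.mean(oob_pred[sel] == pred) if sel.any() else np.nan
        self.confusion_matrix_ = cm
        miscls = (oob_pred != y)[valid].astype(float)
        self.oob_error_ = float(miscls.mean())
        self.error_forest_ = RandomForestRegressor(
            n_estimators=min(self.n_trees, 1000),
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X[valid], miscls)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest_.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def choose(self, observed: np.ndarray) -> ModelChoiceResult:
        obs = np.atleast_2d(np.asarray(observed, dtype=float))
        tree_votes = np.array(
            [t.predict(obs)[0] for t in self.forest_.estimators_]
        )
        class_idx = self.forest_.classes_
        votes = {
            str(c): int((tree_votes == i).sum()) for i, c in enumerate(class_idx)
        }
        selected = str(class_idx[np.argmax([votes[str(c)] for c in class_idx])])
        local_err = float(np.clip(self.error_forest_.predict(obs)[0], 0.0, 1.0))
        return ModelChoiceResult(
            votes=votes,
            selected=selected,
            posterior_probability=1.0 - local_err,
            confusion_matrix=self.confusion_matrix_,
            scenario_order=[str(c) for c in self.classes_],
            n_trees=self.n_trees,
            oob_error=self.oob_error_,
        )


def rf_model_choice(
    tables: dict[str, np.ndarray],
    observed: np.ndarray,
    n_trees: int = 2000,
    random_state: int | None = 0,
) -> ModelChoiceResult:
    """Scenario choice from per-scenario statistic tables.

    Scenarios are subsampled (deterministically, by row order after seeding)
    to the smallest per-scenario count so each contributes equally.
    """
    if len(tables) < 2:
        raise ValueError("model choice needs at least two scenarios")
    n_min = min(len(v) for v in tables.values())
    rng = np.random.default_rng(random_state)
    X_parts, y_parts = [], []
    for name in sorted(tables):
        arr = np.asarray(tables[name], dtype=float)
        sel = rng.choice(len(arr), size=n_min, replace=False) if len(arr) > n_min else np.arange(n_min)
        X_parts.append(arr[np.sort(sel)])
        y_parts.append(np.full(n_min, name))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    forest = ScenarioChoiceForest(n_trees=n_trees, random_state=random_state).fit(X, y)
    return forest.choose(observed)


def relative_bias(
    stats: np.ndarray,
    params: np.ndarray,
    estimator: str = "mode",
    prior_bounds: Sequence[tuple[float, float]] | None = None,
    max_pseudo: Optional[int] = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Leave-one-out relative bias of posterior point estimates.

    Each retained simulation in turn becomes pseudo-observed; the posterior
    is estimated from all others and the point estimate mu compared to the
    known truth chi: bias_j = mean_i |mu_ij - chi_ij| / chi_ij.  Rows with a
    zero true value are excluded (with a warning) for that parameter.
    """
    stats = np.asarray(stats, dtype=float)
    params = np.asarray(params, dtype=float)
    if params.ndim == 1:
        params = params[:, None]
    n = len(stats)
    if n < 2:
        raise ValueError("need at least 2 simulations")
    idx = np.arange(n)
    if max_pseudo is not None and max_pseudo < n:
        rng = rng or np.random.default_rng(0)
        idx = np.sort(rng.choice(n, size=max_pseudo, replace=False))
    sums = np.zeros(params.shape[1])
    counts = np.zeros(params.shape[1])
    zero_skipped = 0
    for i in idx:
        others = np.ones(n, dtype=bool)
        others[i] = False
        post = glm_adjust(
            stats[others], params[others], stats[i], prior_bounds=prior_bounds
        )
        mu = post.mode if estimator == "mode" else post.mean
        chi = params[i]
        nz = chi != 0
        zero_skipped += int((~nz).sum())
        sums[nz] += np.abs(mu[nz] - chi[nz]) / np.abs(chi[nz])
        counts[nz] += 1
    if zero_skipped:
        warnings.warn(f"excluded {zero_skipped} zero-valued truths from relative bias")
    if (counts == 0).any():
        raise ValueError("no usable pseudo-observations for some parameter")
    return sums / counts


# -- two-dimensional posteriors -------------------------------------------

def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin diagnostic; chains shape (n_chains, n_draws)."""
    m, n = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    mseg, nseg = segs.shape
    means = segs.mean(axis=1)
    B = nseg * means.var(ddof=1)
    W = segs.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    var_plus = (nseg - 1) / nseg * W + B / nseg
    return float(np.sqrt(var_plus / W))


@dataclass
class Posterior2D:
    """Random-walk MCMC sample from a 2-D GLM-adjusted posterior."""

    names: list[str]
    draws: np.ndarray  # (n_total, 2)
    chains: np.ndarray  # (n_chains, n_draws, 2)
    rhat: np.ndarray  # (2,)
    acceptance_rate: float


def joint_posterior_2d(
    retained_stats: np.ndarray,
    retained_params2: np.ndarray,
    observed: np.ndarray,
    prior_bounds: Sequence[tuple[float, float]],
    rng: np.random.Generator | int = 0,
    names: Sequence[str] = ("param_0", "param_1"),
    n_draws: int = 4000,
    n_chains: int = 4,
    burn_in: int = 1000,
    rhat_threshold: float = 1.1,
) -> Posterior2D:
    """Sample the joint 2-D posterior of two parameters by random-walk MCMC.

    The target is a Gaussian kernel density over the GLM-adjusted retained
    draws truncated to the prior rectangle.  Chains are tuned toward a
    20-40% acceptance rate during burn-in and checked with a split-chain
    R-hat; non-convergence raises :class:`ConvergenceError` carrying the
    chains.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    params2 = np.asarray(retained_params2, dtype=float)
    if params2.shape[1] != 2:
        raise ValueError("exactly two parameters required")
    est = PosteriorGLM().fit(np.asarray(retained_stats, dtype=float), params2)
    adj = est.adjusted_draws(observed)
    lo = np.array([b[0] for b in prior_bounds])
    hi = np.array([b[1] for b in prior_bounds])
    inside = np.all((adj >= lo) & (adj <= hi), axis=1)
    support = adj[inside] if inside.sum() >= 10 else np.clip(adj, lo, hi)
    try:
        kde = sps.gaussian_kde(support.T)
    except np.linalg.LinAlgError:
        # degenerate (e.g. perfectly collinear) support: minute jitter
        scale0 = np.maximum(np.abs(support).max(axis=0), 1.0)
        jitter = rng.normal(0.0, 1e-9 * scale0, support.shape)
        kde = sps.gaussian_kde((support + jitter).T)

    def logpost(pt: np.ndarray) -> float:
        if np.any(pt < lo) or np.any(pt > hi):
            return -np.inf
        v = kde(pt[:, None])[0]
        return np.log(v) if v > 0 else -np.inf

    # propose along the principal axes of the adjusted cloud so that ridge-
    # shaped (nearly collinear) posteriors remain traversable
    cov = np.cov(support.T) + 1e-24 * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    axis_scale = np.sqrt(np.clip(evals, 0.0, None))
    chains = np.empty((n_chains, n_draws, 2))
    accepted_total = 0
    for c in range(n_chains):
        factor = 0.5
        x = support[rng.integers(len(support))].copy()
        lp = logpost(x)
        # burn-in with acceptance tuning of the global step factor
        acc = 0
        for it in range(burn_in):
            prop = x + evecs @ (factor * axis_scale * rng.normal(0.0, 1.0, 2))
            lpp = logpost(prop)
            if np.log(rng.random()) < lpp - lp:
                x, lp = prop, lpp
                acc += 1
            if (it + 1) % 100 == 0:
                rate = acc / 100
                if rate < 0.2:
                    factor *= 0.7
                elif rate > 0.4:
                    factor *= 1.4
                acc = 0
        for it in range(n_draws):
            prop = x + evecs @ (factor * axis_scale * rng.normal(0.0, 1.0, 2))
            lpp = logpost(prop)
            if np.log(rng.random()) < lpp - lp:
                x, lp = prop, lpp
                accepted_total += 1
            chains[c, it] = x
    rhat = np.array([_split_rhat(chains[:, :, j]) for j in range(2)])
    if np.any(rhat > rhat_threshold):
        raise ConvergenceError(
            f"split R-hat {rhat} exceeds {rhat_threshold}", chains
        )
    return Posterior2D(
        names=list(names),
        draws=chains.reshape(-1, 2),
        chains=chains,
        rhat=rhat,
        acceptance_rate=accepted_total / (n_chains * n_draws),
    )


def prob_query(
    posterior: Posterior2D | np.ndarray,
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> float:
    """Posterior probability of ``predicate(x, y)`` over the MCMC draws."""
    draws = posterior.draws if isinstance(posterior, Posterior2D) else posterior
    return float(np.mean(predicate(draws[:, 0], draws[:, 1])))
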