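"""Per-test response distributions: capable vs non-capable groups.

Scores on each test are categorized into four groups demarcated by the
sample quartiles (after orienting so that higher = better).  For every
test, two multinomial distributions over the four categories are then
estimated by Gibbs sampling: one for subjects whose latent state holds
every function the test requires at a high level ("capable", ideal
response 1), one for the rest ("non-capable").  Latent states are
unknown, so the sampler alternates between drawing each subject's state
from its conditional posterior given the current distributions and a
uniform prior over states, and drawing each test's two Dirichlet
posteriors given the current state assignments.

A finite Gaussian mixture with BIC component selection is available as
an alternative continuous density model for timed scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .poset import PosetModel

N_CATEGORIES = 4

__all__ = [
    "CategorizedScores",
    "TestResponseDistributions",
    "ContinuousDensity",
    "quartile_categorize",
    "categorize_cohort",
    "estimate_multinomials",
    "fit_mixture_density",
]


@dataclass(frozen=True)
class CategorizedScores:
    """Quartile categories for one test: float array with NaN for missing."""

    test: str
    categories: np.ndarray
    cutpoints: tuple[float, float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class TestResponseDistributions:
    """Posterior-mean category distributions for one test.

    ``dominance_ok`` is False when the capable distribution fails to
    stochastically dominate the non-capable one — the model-fit flag for
    a test that does not reflect the specified order structure.
    """

    test: str
    theta_capable: np.ndarray
    theta_noncapable: np.ndarray
    dominance_ok: bool
    n_capable: float
    n_noncapable: float

    def __post_init__(self) -> None:
        for v in (self.theta_capable, self.theta_noncapable):
            if abs(float(np.sum(v)) - 1.0) > 1e-9 or np.any(np.asarray(v) < 0):
                raise ValueError(f"{self.test}: invalid probability vector")


def quartile_categorize(
    scores, orientation: str = "higher-is-better", test: str = ""
) -> CategorizedScores:
    """Assign each score to one of four quartile categories.

    Cutpoints are the 25/50/75 sample percentiles of the non-missing,
    orientation-aligned scores (linear-interpolation percentile
    definition).  A value's category is the number of cutpoints strictly
    below it, so tied values always share a category and category 3 is
    the best quartile regardless of the raw orientation.
    """
    x = np.asarray(scores, dtype=float)
    if orientation == "lower-is-better":
        x = -x
    obs = x[~np.isnan(x)]
    if obs.size < 4:
        raise ValueError(f"{test or 'test'}: need >= 4 non-missing scores, got {obs.size}")
    degenerate = bool(np.min(obs) == np.max(obs))
    if degenerate:
        warnings.warn(
            f"{test or 'test'}: all scores identical; degenerate single-category "
            "distribution",
            stacklevel=2,
        )
    cuts = np.percentile(obs, [25, 50, 75], method="linear")
    cats = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    cats[mask] = (x[mask, None] > cuts[None, :]).sum(axis=1)
    return CategorizedScores(
        test=test,
        categories=cats,
        cutpoints=(float(cuts[0]), float(cuts[1]), float(cuts[2])),
        degenerate=degenerate,
    )


def categorize_cohort(scores: pd.DataFrame, battery) -> tuple[pd.DataFrame, dict]:
    """Quartile-categorize every battery test column of a cohort table.

    Returns (categories DataFrame aligned to ``scores``, dict of
    per-test cutpoints).  Missing scores stay missing.
    """
    cats = {}
    cuts = {}
    for t in battery:
        cs = quartile_categorize(scores[t.name].to_numpy(), t.orientation, test=t.name)
        cats[t.name] = cs.categories
        cuts[t.name] = cs.cutpoints
    return pd.DataFrame(cats, index=scores.index), cuts


def _loglik_matrix(C: np.ndarray, miss: np.ndarray, ideal: np.ndarray,
                   log_cap: np.ndarray, log_non: np.ndarray) -> np.ndarray:
    """n_subjects x n_states log-likelihood of observed categories."""
    n, T = C.shape
    ll_cap = np.zeros((n, T))
    ll_non = np.zeros((n, T))
    for t in range(T):
        m = ~miss[:, t]
        ll_cap[m, t] = log_cap[t, C[m, t]]
        ll_non[m, t] = log_non[t, C[m, t]]
    # subject x state: sum of capable loglik where ideal=1 plus non-capable where 0
    return ll_cap @ ideal.T + ll_non @ (1 - ideal.T)


def estimate_multinomials(
    categories: pd.DataFrame,
    model: PosetModel,
    dirichlet_alpha: float = 1.0,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int | None = None,
) -> dict[str, TestResponseDistributions]:
    """Gibbs-sample the capable/non-capable multinomials for every test.

    ``categories`` holds quartile categories (0-3, NaN missing), one
    column per battery test in battery order.  Each sweep draws every
    subject's state from its conditional posterior under a uniform
    state prior, then each test's two theta vectors from
    Dirichlet(alpha + category counts), a subject counting toward the
    capable group of a test iff the ideal response of its current state
    is 1 there.  Returns post-burn-in posterior means.

    Initialization tilts the capable distribution toward high
    categories (and assigns each subject its MAP state under that
    tilt), which pins the capable/non-capable role labels and avoids
    label switching.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in (zero post-burn-in draws)")
    test_names = [t.name for t in model.battery]
    C_raw = categories[test_names].to_numpy(dtype=float)
    miss = np.isnan(C_raw)
    if np.all(miss, axis=1).any():
        raise ValueError("every subject needs at least one categorized score")
    C = np.where(miss, 0, C_raw).astype(int)
    if C_raw[~miss].min() < 0 or C_raw[~miss].max() > 3:
        raise ValueError("categories must lie in 0..3")

    rng = np.random.default_rng(seed)
    n, T = C.shape
    ideal = model.ideal_matrix()
    S = ideal.shape[0]

    # dominance-seeded start: capable mass tilted to high categories
    theta_cap = np.tile(np.array([0.1, 0.2, 0.3, 0.4]), (T, 1))
    theta_non = np.tile(np.array([0.4, 0.3, 0.2, 0.1]), (T, 1))
    ll = _loglik_matrix(C, miss, ideal, np.log(theta_cap), np.log(theta_non))
    states = np.argmax(ll, axis=1)

    keep = n_iter - burn_in
    sum_cap = np.zeros((T, N_CATEGORIES))
    sum_non = np.zeros((T, N_CATEGORIES))
    sum_ncap = np.zeros(T)
    ever_capable = np.zeros(T, dtype=bool)

    obs_w = (~miss).astype(float)
    for it in range(n_iter):
        # (b) thetas | state assignments
        cap_mask = ideal[states, :].astype(float) * obs_w  # n x T
        counts_cap = np.zeros((T, N_CATEGORIES))
        counts_non = np.zeros((T, N_CATEGORIES))
        for k in range(N_CATEGORIES):
            sel = (C == k) & ~miss
            counts_cap[:, k] = (sel * cap_mask).sum(axis=0)
            counts_non[:, k] = (sel * (1 - cap_mask) * obs_w).sum(axis=0)
        theta_cap = rng.gamma(dirichlet_alpha + counts_cap)
        theta_cap /= theta_cap.sum(axis=1, keepdims=True)
        theta_non = rng.gamma(dirichlet_alpha + counts_non)
        theta_non /= theta_non.sum(axis=1, keepdims=True)

        # (a) states | thetas (uniform prior cancels)
        ll = _loglik_matrix(C, miss, ideal,
                            np.log(theta_cap), np.log(theta_non))
        logp = ll - logsumexp(ll, axis=1, keepdims=True)
        u = rng.random((n, 1))
        states = (np.exp(logp).cumsum(axis=1) < u).sum(axis=1)
        states = np.minimum(states, S - 1)

        if it >= burn_in:
            sum_cap += theta_cap
            sum_non += theta_non
            sum_ncap += counts_cap.sum(axis=1)
            ever_capable |= counts_cap.sum(axis=1) > 0

    mean_cap = sum_cap / keep
    mean_non = sum_non / keep
    prior_mean = np.full(N_CATEGORIES, 1.0 / N_CATEGORIES)

    out = {}
    for t, name in enumerate(test_names):
        cap = mean_cap[t]
        if not ever_capable[t]:
            warnings.warn(
                f"{name}: never capable under any sampled state; "
                "returning the prior mean for the capable distribution",
                stacklevel=2,
            )
            cap = prior_mean.copy()
        dominance_ok = bool(
            np.all(np.cumsum(cap)[:-1] <= np.cumsum(mean_non[t])[:-1] + 1e-12)
        )
        out[name] = TestResponseDistributions(
            test=name,
            theta_capable=cap,
            theta_noncapable=mean_non[t],
            dominance_ok=dominance_ok,
            n_capable=float(sum_ncap[t] / keep),
            n_noncapable=float(obs_w[:, t].sum() - sum_ncap[t] / keep),
        )
    return out


@dataclass(frozen=True)
class ContinuousDensity:
    """Finite Gaussian mixture density for a continuous (timed) score."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("mixture sds must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def pdf(self, x) -> np.ndarray:
        from scipy.stats import norm

        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights[:, None]
            * norm.pdf(x[None, :], self.means[:, None], self.sds[:, None]),
            axis=0,
        )


def fit_mixture_density(
    scores, max_components: int = 5, seed: int | None = None
) -> ContinuousDensity:
    """Fit Gaussian mixtures with 1..max_components and keep the best BIC."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 scores, got {x.size}")
    if np.min(x) == np.max(x):
        raise ValueError("degenerate zero-variance input")
    X = x[:, None]
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return ContinuousDensity(
        weights=best.weights_.copy(),
        means=best.means_.ravel().copy(),
        sds=np.sqrt(best.covariances_.ravel()),
    )
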