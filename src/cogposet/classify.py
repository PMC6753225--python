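"""Bayesian classification of subjects over POSET states.

Each state carries a prior probability (uniform by default: 1/29 for
the ADNI2 model, 1/33 for AIBL).  Given a subject's categorized
responses, the posterior over states follows by Bayes rule with the
conditional-independence likelihood: for each observed test, the
capable multinomial if the state's ideal response is 1 there, the
non-capable multinomial otherwise.  Function-level probabilities of
high functioning are sums of posterior state probabilities over the
states that determine the function high; confounded (undetermined)
functions contribute nothing — "not demonstrably high".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .battery import FUNCTIONS
from .poset import PosetModel
from .response import TestResponseDistributions

__all__ = [
    "SubjectPosterior",
    "uniform_prior",
    "posterior_over_states",
    "function_high_probabilities",
    "map_state",
    "classify_cohort",
]


@dataclass(frozen=True)
class SubjectPosterior:
    """Posterior over states plus derived function-high probabilities."""

    subject_id: object
    state_probs: np.ndarray
    function_high: np.ndarray  # over FUNCTIONS order
    map_state: int  # 1-based state index

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.state_probs)) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")
        if np.any(self.function_high < -1e-12) or np.any(self.function_high > 1 + 1e-12):
            raise ValueError("function_high probabilities must lie in [0, 1]")


def uniform_prior(model: PosetModel) -> np.ndarray:
    """The non-informative prior: 1/n_states on every state."""
    return np.full(model.n_states, 1.0 / model.n_states)


def _log_state_likelihood(
    responses,
    model: PosetModel,
    dists: dict[str, TestResponseDistributions],
) -> np.ndarray:
    ideal = model.ideal_matrix()
    test_index = {t.name: j for j, t in enumerate(model.battery)}
    items = responses.items() if isinstance(responses, dict) else responses
    ll = np.zeros(model.n_states)
    with np.errstate(divide="ignore"):
        for name, cat in items:
            if cat is None or (isinstance(cat, float) and np.isnan(cat)):
                continue
            if name not in test_index:
                raise KeyError(f"unknown test {name!r}")
            if name not in dists:
                raise KeyError(f"no response distributions for test {name!r}")
            k = int(cat)
            d = dists[name]
            if d.theta_capable[k] == 0 and d.theta_noncapable[k] == 0:
                raise ValueError(
                    f"impossible category {k} on test {name!r}: zero likelihood "
                    "under both response distributions"
                )
            col = ideal[:, test_index[name]]
            ll += np.where(
                col == 1, np.log(d.theta_capable[k]), np.log(d.theta_noncapable[k])
            )
    return ll


def posterior_over_states(
    responses,
    model: PosetModel,
    dists: dict[str, TestResponseDistributions],
    prior: np.ndarray | None = None,
    subject_id: object = None,
) -> SubjectPosterior:
    """Bayes-rule posterior over states from a subject's observed categories.

    ``responses`` maps test name -> quartile category (0-3), or is an
    iterable of (test name, category) pairs — the pair form admits
    replicated administrations of the same test.  Missing tests may be
    omitted or passed as NaN and contribute nothing.
    Computation is in log space; an observed category with zero
    probability under both distributions of some test raises an error
    naming the test.
    """
    if prior is None:
        prior = uniform_prior(model)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (model.n_states,):
        raise ValueError("prior length must equal the number of states")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must sum to 1")

    with np.errstate(divide="ignore"):
        logpost = np.log(prior) + _log_state_likelihood(responses, model, dists)
    norm = logsumexp(logpost)
    if not np.isfinite(norm):
        raise ValueError("all-zero posterior: responses impossible under the model")
    probs = np.exp(logpost - norm)
    probs /= probs.sum()
    return SubjectPosterior(
        subject_id=subject_id,
        state_probs=probs,
        function_high=function_high_probabilities(probs, model),
        map_state=map_state(probs),
    )


def function_high_probabilities(
    state_probs: np.ndarray, model: PosetModel
) -> np.ndarray:
    """P(function high) over (ATT, EM1, EM2, EM3, VF, CF, PS).

    Sums posterior mass over states whose *determined* level for the
    function is high.  States where the function is undetermined
    (confounded, e.g. CF* states and the bottom class) contribute zero:
    a function is only credited when the battery demonstrates it.
    """
    probs = np.asarray(state_probs, dtype=float)
    H = model.high_indicator_matrix()  # undetermined rows are 0 by construction
    return H.T @ probs


def map_state(state_probs: np.ndarray) -> int:
    """1-based index of the maximum-posterior state; ties -> lowest index."""
    return int(np.argmax(state_probs)) + 1


def classify_cohort(
    categories: pd.DataFrame,
    model: PosetModel,
    dists: dict[str, TestResponseDistributions],
    prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Posteriors for every subject row of a categorized cohort table.

    Returns a DataFrame indexed like ``categories`` with one column per
    state (``state_1`` ...), the seven function-high probabilities and
    the MAP state index.
    """
    test_names = [t.name for t in model.battery if t.name in categories.columns]
    rows = []
    for sid, row in categories[test_names].iterrows():
        post = posterior_over_states(row.to_dict(), model, dists, prior, subject_id=sid)
        rec = {f"state_{k}": p for k, p in enumerate(post.state_probs, start=1)}
        rec.update({f"P_{fn}": v for fn, v in zip(FUNCTIONS, post.function_high)})
        rec["map_state"] = post.map_state
        rows.append(rec)
    return pd.DataFrame(rows, index=categories.index)
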