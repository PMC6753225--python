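"""Bootstrap classification forest with explicit out-of-bag accounting.

Each tree is grown on a bootstrap resample (n draws with replacement)
with ``mtry`` candidate variables per split.  Out-of-bag (OOB) error is
the misclassification rate of the majority vote over the trees for
which a subject was *not* drawn — about one third of the sample per
tree — giving an honest error estimate without cross-validation.
Variable importance is the mean decrease in accuracy (MDA): for every
tree, the drop in OOB accuracy when one predictor is permuted within
the tree's OOB rows, averaged over trees and reported in percentage
points (negative values possible for uninformative predictors).

Tree induction itself delegates to scikit-learn's CART trees;
bootstrap sampling, OOB vote tallying and permutation importance are
computed here so the OOB/MDA semantics match the classical
randomForest formulation regardless of backend defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ForestConfig", "ForestResult", "RandomForestOOB", "fit_forest", "oob_mda"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; defaults follow the screening analysis
    (1000 trees, four candidate variables per split)."""

    ntree: int = 1000
    mtry: int = 4
    seed: int | None = None
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class ForestResult:
    """Fitted forest: trees, bootstrap/OOB bookkeeping and OOB error."""

    config: ForestConfig
    feature_names: list[str]
    classes: np.ndarray
    trees: list = field(repr=False)
    bootstrap_idx: list = field(repr=False)
    oob_idx: list = field(repr=False)
    oob_error_rate: float = np.nan  # percent
    oob_votes: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_oob_fraction(self) -> float:
        n = self.oob_votes.shape[0]
        return float(np.mean([len(o) / n for o in self.oob_idx]))

    def summary(self) -> str:
        lines = [
            "Bootstrap classification forest (OOB)",
            "=" * 38,
            f"trees:            {self.config.ntree}",
            f"mtry:             {self.config.mtry}",
            f"classes:          {list(self.classes)}",
            f"OOB error rate:   {self.oob_error_rate:.2f}%",
            f"mean OOB share:   {self.mean_oob_fraction:.3f}",
        ]
        return "\n".join(lines)


class RandomForestOOB:
    """Model object: predictor table + labels, fitted by :meth:`fit`.

    ``X`` is a numeric DataFrame (categorical predictors already
    integer-encoded: APOE4 allele count 0/1/2 ordinal, gender and
    education flags binary); rows with missing values must be dropped
    beforehand.
    """

    def __init__(self, X: pd.DataFrame, y, config: ForestConfig | None = None):
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("X contains missing values; use complete records only")
        self.X = X
        self.y = np.asarray(y)
        if len(self.y) != len(X):
            raise ValueError("X and y lengths differ")
        self.config = config or ForestConfig()
        if self.config.mtry > X.shape[1]:
            raise ValueError(
                f"mtry={self.config.mtry} exceeds the {X.shape[1]} predictors"
            )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        label_col: str,
        feature_cols: list[str] | None = None,
        config: ForestConfig | None = None,
    ) -> "RandomForestOOB":
        feats = feature_cols or [c for c in data.columns if c != label_col]
        complete = data[feats + [label_col]].dropna()
        return cls(complete[feats], complete[label_col].to_numpy(), config)

    def fit(self) -> ForestResult:
        cfg = self.config
        Xv = self.X.to_numpy(dtype=float)
        n = Xv.shape[0]
        classes, y_enc = np.unique(self.y, return_inverse=True)
        rng = np.random.default_rng(cfg.seed)

        single_class = classes.size == 1
        if single_class:
            warnings.warn("single-class labels: OOB error is trivially 0", stacklevel=2)

        trees, boots, oobs = [], [], []
        votes = np.zeros((n, classes.size))
        for _ in range(cfg.ntree):
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            tree = DecisionTreeClassifier(
                max_features=min(cfg.mtry, Xv.shape[1]),
                min_samples_leaf=cfg.min_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xv[idx], y_enc[idx])
            if oob.size:
                pred = tree.predict(Xv[oob])
                votes[oob, pred] += 1
            trees.append(tree)
            boots.append(idx)
            oobs.append(oob)

        voted = votes.sum(axis=1) > 0
        if not voted.all():
            warnings.warn(
                f"{int((~voted).sum())} subject(s) never out-of-bag; "
                "increase ntree for stable OOB estimates",
                stacklevel=2,
            )
        pred = votes.argmax(axis=1)
        err = float(np.mean(pred[voted] != y_enc[voted]) * 100) if voted.any() else np.nan
        if single_class:
            err = 0.0
        return ForestResult(
            config=cfg,
            feature_names=list(self.X.columns),
            classes=classes,
            trees=trees,
            bootstrap_idx=boots,
            oob_idx=oobs,
            oob_error_rate=err,
            oob_votes=votes,
        )


def fit_forest(X: pd.DataFrame, y, config: ForestConfig | None = None) -> ForestResult:
    """Functional wrapper: ``RandomForestOOB(X, y, config).fit()``."""
    return RandomForestOOB(X, y, config).fit()


def oob_mda(
    result: ForestResult, X: pd.DataFrame, y, seed: int | None = None
) -> pd.Series:
    """Permutation mean decrease in accuracy per variable (percentage points).

    For each tree and variable, OOB accuracy is computed before and
    after permuting that variable within the tree's OOB rows; the MDA
    is the mean accuracy drop over trees, scaled to percentage points.
    Sorted descending, as in importance tables.
    """
    X = pd.DataFrame(X)
    missing = [f for f in result.feature_names if f not in X.columns]
    if missing:
        raise KeyError(f"variables absent from X: {missing}")
    Xv = X[result.feature_names].to_numpy(dtype=float)
    classes, y_enc = np.unique(y, return_inverse=True)
    if not np.array_equal(classes, result.classes):
        raise ValueError("labels do not match the fitted forest's classes")
    rng = np.random.default_rng(seed)
    p = Xv.shape[1]
    drops = np.zeros(p)
    n_used = 0
    for tree, oob in zip(result.trees, result.oob_idx):
        if oob.size == 0:
            continue
        n_used += 1
        base = np.mean(tree.predict(Xv[oob]) == y_enc[oob])
        for j in range(p):
            Xp = Xv[oob].copy()
            perm = rng.permutation(oob.size)
            Xp[:, j] = Xp[perm, j]
            if np.array_equal(Xp[:, j], Xv[oob, j]):
                # permutation left the column unchanged (e.g. constant)
                continue
            acc = np.mean(tree.predict(Xp) == y_enc[oob])
            drops[j] += base - acc
    mda = pd.Series(drops / max(n_used, 1) * 100.0, index=result.feature_names)
    return mda.sort_values(ascending=False)
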