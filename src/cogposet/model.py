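"""Model/Results facade tying the pipeline stages together.

``PosetClassificationModel`` holds a cohort table and a battery
specification; ``fit`` builds the POSET state model, quartile-
categorizes the raw scores, Gibbs-estimates the capable/non-capable
response distributions and computes every subject's posterior.  The
returned ``PosetClassificationResults`` carries the estimates and the
downstream analyses (amyloid comparison table, APOE4-by-age accuracy
table, recovery metrics against a synthetic truth table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import BatterySpec, FUNCTIONS
from .classify import classify_cohort, uniform_prior
from .cohort import apoe_age_accuracy, compare_by_amyloid
from .poset import PosetModel, build_model
from .response import TestResponseDistributions, categorize_cohort, estimate_multinomials

__all__ = ["PosetClassificationModel", "PosetClassificationResults"]


class PosetClassificationModel:
    """Cognitive-profile classification model for one cohort.

    Parameters
    ----------
    cohort : DataFrame indexed by subject id, with one raw-score column
        per battery test (missing allowed) plus any covariate columns.
    battery : the test-to-function mapping.
    prior : optional prior over states; uniform (1/n_states) if omitted.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        battery: BatterySpec,
        prior: np.ndarray | None = None,
    ):
        missing_cols = [t.name for t in battery if t.name not in cohort.columns]
        if missing_cols:
            raise ValueError(f"cohort lacks test columns: {missing_cols}")
        self.cohort = cohort
        self.battery = battery
        self.poset: PosetModel = build_model(battery)
        self.prior = uniform_prior(self.poset) if prior is None else np.asarray(prior)

    @classmethod
    def from_csv(cls, path, battery: BatterySpec, **kwargs):
        from .io import read_cohort

        return cls(read_cohort(path), battery, **kwargs)

    def fit(
        self,
        seed: int | None = None,
        n_iter: int = 2000,
        burn_in: int = 500,
        dirichlet_alpha: float = 1.0,
    ) -> "PosetClassificationResults":
        categories, cutpoints = categorize_cohort(self.cohort, self.battery)
        dists = estimate_multinomials(
            categories,
            self.poset,
            dirichlet_alpha=dirichlet_alpha,
            n_iter=n_iter,
            burn_in=burn_in,
            seed=seed,
        )
        posteriors = classify_cohort(categories, self.poset, dists, self.prior)
        return PosetClassificationResults(
            model=self,
            categories=categories,
            cutpoints=cutpoints,
            response_distributions=dists,
            posteriors=posteriors,
            settings={
                "seed": seed,
                "n_iter": n_iter,
                "burn_in": burn_in,
                "dirichlet_alpha": dirichlet_alpha,
            },
        )


@dataclass
class PosetClassificationResults:
    """Fitted estimates, subject posteriors and derived analyses."""

    model: PosetClassificationModel
    categories: pd.DataFrame
    cutpoints: dict
    response_distributions: dict[str, TestResponseDistributions]
    posteriors: pd.DataFrame
    settings: dict = field(default_factory=dict)

    @property
    def poset(self) -> PosetModel:
        return self.model.poset

    @property
    def function_probs(self) -> pd.DataFrame:
        """Per-subject P(function high) columns (P_ATT ... P_PS)."""
        return self.posteriors[[f"P_{fn}" for fn in FUNCTIONS]]

    @property
    def map_states(self) -> pd.Series:
        return self.posteriors["map_state"]

    def theta_table(self) -> pd.DataFrame:
        """Long-format posterior-mean response distributions."""
        rows = []
        for name, d in self.response_distributions.items():
            for grp, theta in (("capable", d.theta_capable),
                               ("non-capable", d.theta_noncapable)):
                rows.append(
                    {"test": name, "group": grp, "dominance_ok": d.dominance_ok,
                     **{f"cat{k}": theta[k] for k in range(4)}}
                )
        return pd.DataFrame(rows)

    def compare_by_amyloid(self, stratify_cognitive_status: bool = False,
                           alpha: float = 0.05) -> pd.DataFrame:
        """Stratified Mann-Whitney table of function probabilities by
        amyloid status (requires an ``amyloid`` column in the cohort)."""
        return compare_by_amyloid(
            self.function_probs, self.model.cohort,
            stratify_cognitive_status=stratify_cognitive_status, alpha=alpha,
        )

    def apoe_age_accuracy(self) -> pd.DataFrame:
        """Majority-class amyloid prediction per APOE4-by-age cell."""
        return apoe_age_accuracy(self.model.cohort)

    def evaluate_recovery(self, truth: pd.DataFrame) -> dict:
        from .simulate import evaluate_recovery

        return evaluate_recovery(truth, self.posteriors)

    def plot_function_probabilities(self, by: str = "amyloid", ax=None):
        """Box plot of the seven function-high probabilities, grouped by
        a cohort covariate (matplotlib required)."""
        import matplotlib.pyplot as plt

        df = self.model.cohort.join(self.function_probs)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        groups = sorted(df[by].dropna().unique())
        width = 0.8 / max(len(groups), 1)
        for g, grp_val in enumerate(groups):
            sub = df[df[by] == grp_val]
            data = [sub[f"P_{fn}"].dropna() for fn in FUNCTIONS]
            pos = np.arange(len(FUNCTIONS)) + g * width
            ax.boxplot(data, positions=pos, widths=width * 0.9,
                       label=f"{by}={grp_val}")
        ax.set_xticks(np.arange(len(FUNCTIONS)) + 0.4 - width / 2)
        ax.set_xticklabels(FUNCTIONS)
        ax.set_ylabel("P(function high)")
        ax.legend()
        return ax

    def summary(self) -> str:
        n = len(self.posteriors)
        mean_fp = self.function_probs.mean()
        flagged = [n_ for n_, d in self.response_distributions.items()
                   if not d.dominance_ok]
        mean_top = float(
            self.posteriors[[c for c in self.posteriors.columns
                             if c.startswith("state_")]].max(axis=1).mean()
        )
        lines = [
            "POSET cognitive-profile classification",
            "=" * 42,
            f"battery:              {self.model.battery.name} "
            f"({len(self.model.battery)} tests)",
            f"states:               {self.poset.n_states} "
            f"(uniform prior 1/{self.poset.n_states})",
            f"subjects classified:  {n}",
            f"MCMC:                 n_iter={self.settings.get('n_iter')}, "
            f"burn_in={self.settings.get('burn_in')}, "
            f"seed={self.settings.get('seed')}",
            f"mean max-state mass:  {mean_top:.3f}",
            "dominance flags:      "
            + (", ".join(flagged) if flagged else "none"),
            "",
            "Mean P(function high):",
        ]
        for fn in FUNCTIONS:
            lines.append(f"  {fn:<4} {mean_fp[f'P_{fn}']:.3f}")
        return "\n".join(lines)
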