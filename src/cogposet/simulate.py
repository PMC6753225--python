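"""Seeded synthetic cohorts with the covariate, latent-state and
response structure the analysis assumes.

The generator emulates an amyloid-screening study: subjects in three
age bands with a cognitive status (normal or MCI), an APOE4 allele
count, an amyloid status whose prevalence rises with APOE4 count and
age, a latent cognitive-profile state, and per-test scores drawn from
the capable multinomial when the state's ideal response for the test
is 1 and from the non-capable multinomial otherwise.  An episodic-
memory depression parameter ``delta`` shifts latent-state mass away
from EM2-high states in amyloid positives; ``delta = 0`` makes the two
arms exchangeable, which is the null used for calibration checks.

Quartile categories can be back-transformed to continuous scores by
drawing within the matching quartile band of a standard normal, so
that sample-quartile categorization recovers the generating category
in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .battery import BatterySpec, FUNCTIONS
from .poset import PosetModel

__all__ = ["SyntheticConfig", "generate_cohort", "evaluate_recovery"]

AGE_RANGES = {1: (55, 69), 2: (70, 80), 3: (81, 90)}

#: Amyloid-positive probability per APOE4 count, by age group (<70, 70-80,
#: 81-90). Patterned on the observed ADNI2 cell proportions: prevalence
#: rises steeply with allele count and age.
DEFAULT_AMYLOID_PROBS = {
    0: (0.18, 0.28, 0.46),
    1: (0.49, 0.66, 0.85),
    2: (0.64, 0.75, 0.90),
}

#: APOE4 allele count distribution by cognitive status (counts 0/1/2);
#: MCI carries more alleles.
DEFAULT_APOE4_PROBS = {
    "normal": (0.70, 0.26, 0.04),
    "MCI": (0.58, 0.36, 0.06),
}

#: Subjects per (age group, cognitive status) cell; roughly the strata
#: sizes of a mid-sized two-arm screening study.
DEFAULT_CELL_N = {
    (1, "normal"): 86, (2, "normal"): 119, (3, "normal"): 32,
    (1, "MCI"): 90, (2, "MCI"): 86, (3, "MCI"): 24,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic cohort."""

    cell_n: dict = field(default_factory=lambda: dict(DEFAULT_CELL_N))
    apoe4_probs: dict = field(default_factory=lambda: dict(DEFAULT_APOE4_PROBS))
    amyloid_probs: dict = field(default_factory=lambda: dict(DEFAULT_AMYLOID_PROBS))
    #: strength of latent-state concentration toward high states for
    #: normals / away from them for MCI
    state_sharpness: float = 0.5
    #: EM-depression effect: weight of EM2-high states in amyloid
    #: positives is multiplied by (1 - delta)
    delta: float = 0.5
    theta_capable: tuple = (0.1, 0.1, 0.1, 0.7)
    theta_noncapable: tuple = (0.7, 0.1, 0.1, 0.1)
    #: per-test overrides: name -> (theta_capable, theta_noncapable)
    theta_overrides: dict = field(default_factory=dict)
    #: optional explicit latent-state weights (length n_states), used for
    #: every arm in place of the sharpness parameterization; the delta
    #: EM2 depression still applies to amyloid positives
    state_weights: tuple | None = None
    missing_rate: float = 0.02
    continuous_scores: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        for name, probs in (("theta_capable", self.theta_capable),
                            ("theta_noncapable", self.theta_noncapable)):
            p = np.asarray(probs, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability 4-vector")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _state_weights(model: PosetModel, status: str, amyloid: str,
                   config: SyntheticConfig) -> np.ndarray:
    """Latent-state distribution for one (cognitive status, amyloid) arm."""
    H = model.high_indicator_matrix()
    if config.state_weights is not None:
        w = np.asarray(config.state_weights, dtype=float)
        if w.shape != (model.n_states,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("state_weights must be non-negative, length n_states")
    else:
        n_high = H.sum(axis=1).astype(float)
        sharp = config.state_sharpness
        w = (np.exp(sharp * n_high) if status == "normal"
             else np.exp(-0.2 * sharp * n_high))
    if amyloid == "positive" and config.delta > 0:
        # move a fraction delta of each EM2-high state's mass to the
        # state with the same non-memory signature but EM demoted to
        # level 1 (mass shifts toward lower-EM states)
        em2_col = FUNCTIONS.index("EM2")
        vec_to_idx = {tuple(H[i]): i for i in range(len(H))}
        w = w.astype(float).copy()
        for i in range(len(H)):
            if H[i, em2_col] != 1:
                continue
            demoted = list(H[i])
            demoted[FUNCTIONS.index("EM2")] = 0
            demoted[FUNCTIONS.index("EM3")] = 0
            j = vec_to_idx.get(tuple(demoted))
            if j is not None:
                shift = config.delta * w[i]
                w[i] -= shift
                w[j] += shift
    return w / w.sum()


def _category_to_continuous(cats: np.ndarray, orientation: str,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw a score within the category's quartile band of a standard
    normal; lower-is-better tests are negated so small raw values are good."""
    u = (cats + rng.uniform(0.0, 1.0, size=cats.shape)) / 4.0
    z = norm.ppf(np.clip(u, 1e-10, 1 - 1e-10))
    return -z if orientation == "lower-is-better" else z


def generate_cohort(
    battery: BatterySpec,
    model: PosetModel,
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (subject table, latent truth table).

    The subject table has the pipeline's cohort CSV schema: id, age,
    age_group, gender, education_ge13, apoe4_count, amyloid,
    cognitive_status and one column per battery test (continuous scores
    by default; raw 0-3 categories when ``continuous_scores=False``).
    The truth table records each subject's latent state index and the
    state's seven high-function indicators.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    ideal = model.ideal_matrix()
    H = model.high_indicator_matrix()

    weight_cache = {
        (st, am): _state_weights(model, st, am, config)
        for st in ("normal", "MCI")
        for am in ("negative", "positive")
    }
    thetas = {}
    for t in battery:
        cap, non = config.theta_overrides.get(
            t.name, (config.theta_capable, config.theta_noncapable)
        )
        thetas[t.name] = (np.asarray(cap, float), np.asarray(non, float))

    subj_rows, truth_rows = [], []
    sid = 0
    for (age_group, status), n_cell in sorted(config.cell_n.items(),
                                              key=lambda kv: (kv[0][0], kv[0][1])):
        if n_cell <= 0:
            continue
        if status not in config.apoe4_probs:
            raise ValueError(f"no APOE4 probabilities configured for {status!r}")
        lo, hi = AGE_RANGES[age_group]
        for _ in range(n_cell):
            sid += 1
            age = int(rng.integers(lo, hi + 1))
            apoe = int(rng.choice(3, p=config.apoe4_probs[status]))
            if apoe not in config.amyloid_probs:
                raise ValueError(f"no amyloid probability configured for APOE4={apoe}")
            p_pos = config.amyloid_probs[apoe][age_group - 1]
            amyloid = "positive" if rng.random() < p_pos else "negative"
            w = weight_cache[(status, amyloid)]
            state = int(rng.choice(model.n_states, p=w))  # 0-based

            row = {
                "id": f"S{sid:05d}",
                "age": age,
                "age_group": age_group,
                "gender": ("F", "M")[int(rng.random() < 0.5)],
                "education_ge13": int(rng.random() < 0.8),
                "apoe4_count": apoe,
                "amyloid": amyloid,
                "cognitive_status": status,
            }
            for j, t in enumerate(battery):
                if rng.random() < config.missing_rate:
                    row[t.name] = np.nan
                    continue
                cap, non = thetas[t.name]
                theta = cap if ideal[state, j] == 1 else non
                cat = int(rng.choice(4, p=theta))
                if config.continuous_scores:
                    row[t.name] = float(
                        _category_to_continuous(np.array([cat]), t.orientation, rng)[0]
                    )
                else:
                    row[t.name] = cat
            subj_rows.append(row)
            truth = {"id": row["id"], "state": state + 1}
            truth.update({fn: int(H[state, k]) for k, fn in enumerate(FUNCTIONS)})
            truth_rows.append(truth)

    subjects = pd.DataFrame(subj_rows).set_index("id")
    truth = pd.DataFrame(truth_rows).set_index("id")
    return subjects, truth


def evaluate_recovery(truth: pd.DataFrame, posteriors: pd.DataFrame) -> dict:
    """Latent-state recovery metrics for classified synthetic subjects.

    ``posteriors`` is the classify_cohort output (state_k columns, P_*
    columns, map_state), aligned to ``truth`` by id.  Returns MAP-state
    accuracy, mean posterior mass on the true state, and per-function
    AUC of the function-high probability against the true indicator
    (NaN when a function has only one truth class).
    """
    from sklearn.metrics import roc_auc_score

    df = truth.join(posteriors, how="inner", lsuffix="_true")
    if df.empty:
        raise ValueError("no overlapping subject ids between truth and posteriors")
    acc = float((df["map_state"] == df["state"]).mean())
    mass = float(
        np.mean([row[f"state_{int(row['state'])}"] for _, row in df.iterrows()])
    )
    auc = {}
    for fn in FUNCTIONS:
        y = df[fn].to_numpy()
        p = df[f"P_{fn}"].to_numpy()
        auc[fn] = (
            float(roc_auc_score(y, p)) if np.unique(y).size == 2 else float("nan")
        )
    return {
        "map_accuracy": acc,
        "mean_mass_on_true_state": mass,
        "function_auc": auc,
    }
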