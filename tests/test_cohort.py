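"""Age grouping, z-scoring, Mann-Whitney comparisons and APOE4 tables."""

import numpy as np
import pandas as pd
import pytest

from cogposet.battery import FUNCTIONS
from cogposet.classify import classify_cohort
from cogposet.cohort import (
    apoe_age_accuracy,
    assign_age_group,
    bonferroni_threshold,
    compare_by_amyloid,
    mann_whitney_u,
    zscore_by_age_group,
)
from cogposet.simulate import SyntheticConfig, generate_cohort

from conftest import strong_dists


class TestAgeGroups:
    @pytest.mark.parametrize("age, group", [
        (55, 1), (69, 1), (69.9, 1), (70, 2), (80, 2), (80.7, 2), (81, 3), (90, 3),
    ])
    def test_boundaries(self, age, group):
        assert assign_age_group(age) == group

    @pytest.mark.parametrize("age", [54, 91, 95, float("nan")])
    def test_out_of_range_rejected(self, age):
        with pytest.raises(ValueError):
            assign_age_group(age)


class TestZScores:
    def test_groupwise_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(10, 3, size=90)
        groups = np.repeat([1, 2, 3], 30)
        z = zscore_by_age_group(scores, groups)
        for g in (1, 2, 3):
            sub = z[groups == g]
            assert abs(sub.mean()) < 1e-9
            assert abs(sub.std(ddof=1) - 1) < 1e-9

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            zscore_by_age_group([1.0, 2.0, 3.0], [1, 1, 2])

    def test_zero_spread_group_rejected(self):
        with pytest.raises(ValueError, match="zero within-group"):
            zscore_by_age_group([5.0, 5.0, 1.0, 2.0], [1, 1, 2, 2])

    def test_lower_is_better_sign_flip(self):
        times = [12.0, 30.0, 45.0, 60.0, 90.0]
        z = zscore_by_age_group(times, [1] * 5, orientation="lower-is-better")
        assert z[0] == max(z)  # fastest time gets the largest z
        assert z[-1] == min(z)

    def test_missing_propagates(self):
        z = zscore_by_age_group([1.0, np.nan, 3.0, 5.0], [1, 1, 1, 1])
        assert np.isnan(z[1]) and np.isfinite(z[0])


def exact_u_distribution(n1, n2):
    """Enumeration oracle: counts of each U value over all C(n1+n2, n1)
    equally likely rank assignments, by the classic partition recurrence."""
    max_u = n1 * n2
    f = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    f[0, :, 0] = 1
    f[:, 0, 0] = 1
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            for u in range(max_u + 1):
                f[a, b, u] = f[a, b - 1, u]
                if u >= b:
                    f[a, b, u] += f[a - 1, b, u - b]
    return f[n1, n2, :]


class TestMannWhitney:
    def test_identical_samples_give_half_max_u(self):
        x = [1.0, 2.0, 3.0]
        U, p = mann_whitney_u(x, list(x))
        assert U == pytest.approx(len(x) ** 2 / 2)

    def test_tiny_exact_two_sided_p(self):
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])

    def test_agrees_with_enumeration_oracle_at_n15(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.4, 1, 15)
        y = rng.normal(0.0, 1, 15)
        U, p = mann_whitney_u(x, y)
        dist = exact_u_distribution(15, 15)
        dist = dist / dist.sum()
        mid = 15 * 15 / 2
        dev = abs(U - mid)
        p_oracle = dist[np.abs(np.arange(dist.size) - mid) >= dev - 1e-9].sum()
        assert abs(p - min(1.0, p_oracle)) <= 1e-3

    def test_monte_carlo_permutation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.5, 1, 15)
        y = rng.normal(0.0, 1, 15)
        U, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        ranks = pd.Series(pooled).rank().to_numpy()
        draws = 1_000_000
        stats = np.empty(draws)
        chunk = 100_000
        for start in range(0, draws, chunk):
            keys = rng.random((chunk, ranks.size))
            order = np.argsort(keys, axis=1)[:, :n1]
            stats[start:start + chunk] = (
                ranks[order].sum(axis=1) - n1 * (n1 + 1) / 2
            )
        mid = n1 * len(y) / 2
        p_mc = np.mean(np.abs(stats - mid) >= abs(U - mid) - 1e-9)
        assert abs(p - p_mc) <= 3e-3

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(0.5, 1, size=30)
        U1, p1 = mann_whitney_u(x, y)
        U2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert U1 == U2 and p1 == pytest.approx(p2)


class TestCompareByAmyloid:
    def test_bonferroni_threshold_for_seven_functions(self):
        assert bonferroni_threshold() == pytest.approx(0.05 / 7)
        assert round(bonferroni_threshold(), 3) == 0.007

    def test_injected_em2_effect_detected(self, adni2, adni2_model):
        cfg = SyntheticConfig(
            seed=2003, delta=0.8, missing_rate=0.0, continuous_scores=False,
            amyloid_probs={k: (0.5, 0.5, 0.5) for k in range(3)},
            cell_n={(1, "normal"): 200},
        )
        cohort, _ = generate_cohort(adni2, adni2_model, cfg)
        posts = classify_cohort(
            cohort[[t.name for t in adni2]], adni2_model, strong_dists(adni2)
        )
        tab = compare_by_amyloid(posts[[f"P_{f}" for f in FUNCTIONS]], cohort)
        em2 = tab[tab["function"] == "EM2"]
        assert em2["significant_bonferroni"].any()

    def test_all_negative_cohort_not_computable(self, adni2, adni2_model):
        cfg = SyntheticConfig(
            seed=4, missing_rate=0.0, continuous_scores=False,
            amyloid_probs={k: (0.0, 0.0, 0.0) for k in range(3)},
            cell_n={(1, "normal"): 40},
        )
        cohort, _ = generate_cohort(adni2, adni2_model, cfg)
        posts = classify_cohort(
            cohort[[t.name for t in adni2]], adni2_model, strong_dists(adni2)
        )
        tab = compare_by_amyloid(posts[[f"P_{f}" for f in FUNCTIONS]], cohort)
        assert not tab["computable"].any()
        assert len(tab) == 7  # rows kept, flagged

    def test_row_shape_one_per_stratum_and_function(self, adni2, adni2_model):
        cfg = SyntheticConfig(seed=6, missing_rate=0.0, continuous_scores=False,
                              cell_n={(1, "normal"): 60, (2, "MCI"): 60})
        cohort, _ = generate_cohort(adni2, adni2_model, cfg)
        posts = classify_cohort(
            cohort[[t.name for t in adni2]], adni2_model, strong_dists(adni2)
        )
        tab = compare_by_amyloid(posts[[f"P_{f}" for f in FUNCTIONS]], cohort)
        assert len(tab) == 2 * 7
        tab2 = compare_by_amyloid(
            posts[[f"P_{f}" for f in FUNCTIONS]], cohort,
            stratify_cognitive_status=True,
        )
        assert len(tab2) == 2 * 7  # one cognitive status per age group here


class TestApoeAgeAccuracy:
    def cohort_from_counts(self, counts):
        rows = []
        for (apoe, grp), (n_neg, n_pos) in counts.items():
            for amy, n in (("negative", n_neg), ("positive", n_pos)):
                for _ in range(n):
                    rows.append({"apoe4_count": apoe, "age_group": grp,
                                 "amyloid": amy})
        return pd.DataFrame(rows)

    def test_published_cell_accuracies(self):
        counts = {(0, 1): (81, 18), (1, 3): (2, 11), (0, 2): (102, 40)}
        tab = apoe_age_accuracy(self.cohort_from_counts(counts)).set_index(
            ["apoe4_count", "age_group"]
        )
        assert tab.loc[(0, "<70"), "accuracy_pct"] == 81.8
        assert tab.loc[(0, "<70"), "majority_class"] == "negative"
        assert tab.loc[(1, "81-90"), "accuracy_pct"] == 84.6
        assert tab.loc[(1, "81-90"), "majority_class"] == "positive"
        assert tab.loc[(0, "70-80"), "accuracy_pct"] == 71.8

    def test_empty_cell_reports_na(self):
        tab = apoe_age_accuracy(self.cohort_from_counts({(0, 1): (3, 1)}))
        empty = tab[(tab["apoe4_count"] == 2) & (tab["age_group"] == "81-90")]
        assert np.isnan(empty["accuracy_pct"].iloc[0])
        assert empty["majority_class"].iloc[0] is None

    def test_accuracy_identity_and_count_reconciliation(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "apoe4_count": rng.integers(0, 3, 300),
            "age_group": rng.integers(1, 4, 300),
            "amyloid": rng.choice(["negative", "positive"], 300),
        })
        tab = apoe_age_accuracy(df)
        assert tab[["n_negative", "n_positive"]].to_numpy().sum() == 300
        filled = tab.dropna(subset=["accuracy_pct"])
        expect = (
            filled[["n_negative", "n_positive"]].max(axis=1)
            / filled[["n_negative", "n_positive"]].sum(axis=1)
            * 100
        ).round(1)
        assert np.allclose(filled["accuracy_pct"], expect)


def test_null_calibration_of_stratified_comparison(adni2, adni2_model):
    """With no amyloid effect (delta = 0) the nominal 0.05-level flag
    fires at about its nominal rate across 50 seeded replicate cohorts."""
    dists = strong_dists(adni2)
    names = [t.name for t in adni2]
    fracs = []
    for rep in range(50):
        cfg = SyntheticConfig(
            seed=1000 + rep, delta=0.0, missing_rate=0.0, continuous_scores=False,
            cell_n={(1, "normal"): 60, (2, "normal"): 60, (3, "normal"): 40,
                    (1, "MCI"): 60, (2, "MCI"): 60, (3, "MCI"): 40},
        )
        cohort, _ = generate_cohort(adni2, adni2_model, cfg)
        posts = classify_cohort(cohort[names], adni2_model, dists)
        tab = compare_by_amyloid(posts[[f"P_{f}" for f in FUNCTIONS]], cohort)
        ok = tab[tab["computable"]]
        fracs.append(ok["significant_nominal"].mean())
    frac = float(np.mean(fracs))
    assert 0.02 <= frac <= 0.08
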