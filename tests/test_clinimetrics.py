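"""AUC, ICC(A,k), SRD, learning slope and the step-2 filter."""

import numpy as np
import pytest

from metricselect.clinimetrics import (
    ClinimetricScores,
    SelectionThresholds,
    compute_auc,
    compute_eta,
    compute_icc_agreement,
    compute_srd,
    percentile,
    percentile_cutoffs,
    step2_filter,
)


def brute_force_auc(intact, affected):
    """Independent oracle: count concordant (affected worse) pairs."""
    wins = sum(
        1.0 if a > i else (0.5 if a == i else 0.0)
        for a in affected for i in intact
    )
    return wins / (len(intact) * len(affected))


def anova_icc_oracle(m):
    """Independent two-way ANOVA mean-squares oracle for ICC(A,k)."""
    import itertools

    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((r.mean() - grand) ** 2 for r in m) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i, j in itertools.product(range(n), range(k))
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestAUC:
    def test_enumerated_example(self):
        # pairs: (2.5 vs 1,2) win, (2.5 vs 3) lose, (4,5 vs all) win -> 8/9
        assert compute_auc([1, 2, 3], [2.5, 4, 5]) == pytest.approx(8 / 9)

    def test_complete_separation(self):
        assert compute_auc([1, 2], [3, 4]) == 1.0

    def test_identical_samples(self):
        assert compute_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_orientation_flip(self):
        a = compute_auc([1, 2, 3], [4, 5, 6], "higher_is_worse")
        b = compute_auc([1, 2, 3], [4, 5, 6], "lower_is_worse")
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [1.0])

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 20, size=2)
            intact = np.round(rng.normal(size=n1), 1)  # rounding makes ties
            affected = np.round(rng.normal(0.5, 1, size=n2), 1)
            assert compute_auc(intact, affected) == pytest.approx(
                brute_force_auc(intact, affected), abs=1e-12)


class TestICC:
    def test_identical_sessions(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert compute_icc_agreement(m) == pytest.approx(1.0)

    def test_hand_computed_anova_example(self):
        # MS_rows = 2, MS_cols = 1.5, MS_err = 0 -> 2 / (2 + 1.5/3) = 0.8
        assert compute_icc_agreement([[1, 2], [2, 3], [3, 4]]) == pytest.approx(0.8)

    def test_matches_mean_squares_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            m = rng.normal(size=(5, 2))
            assert compute_icc_agreement(m) == pytest.approx(
                anova_icc_oracle(m), abs=1e-9)

    def test_matches_pingouin_icc2k(self, rng):
        import pandas as pd
        import pingouin as pg

        m = rng.normal(size=(25, 2)) + rng.normal(size=(25, 1))
        df = pd.DataFrame(
            {"subject": np.repeat(np.arange(25), 2),
             "rater": np.tile(["a", "b"], 25),
             "score": m.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        sel = ref["Type"].isin(["ICC2k", "ICC(A,k)"])
        icc2k = float(ref.loc[sel, "ICC"].iloc[0])
        assert compute_icc_agreement(m) == pytest.approx(icc2k, abs=1e-9)

    def test_independent_columns_near_zero(self, rng):
        m = rng.normal(size=(200, 2))
        assert -0.25 <= compute_icc_agreement(m) <= 0.25

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_icc_agreement([[1, 2], [2, 3]])


class TestSRD:
    def test_perfect_reliability_gives_zero(self, rng):
        m = rng.normal(size=(10, 2))
        srd, _ = compute_srd(m, icc=1.0, normalized_range=10.0)
        assert srd == 0.0

    def test_closed_form_sigma_one(self, rng):
        # Sigma = 1, ICC = 0.5 -> 1.96 * sqrt(2) * sqrt(0.5) = 1.96
        m = rng.normal(size=(2000, 2))
        m = (m - m.mean()) / m.std(ddof=1)
        srd, _ = compute_srd(m, icc=0.5, normalized_range=10.0)
        assert srd == pytest.approx(1.96, abs=1e-6)

    def test_closed_form_sigma_two(self, rng):
        m = rng.normal(size=(500, 2))
        m = (m - m.mean()) / m.std(ddof=1) * 2.0
        srd, srd_pct = compute_srd(m, icc=0.75, normalized_range=100.0)
        assert srd == pytest.approx(1.96 * np.sqrt(2) * 2 * 0.5, abs=1e-6)
        assert srd_pct == pytest.approx(srd)

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            compute_srd(np.ones((5, 2)), icc=1.1, normalized_range=1.0)


class TestEta:
    def test_no_change(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        eta, p = compute_eta(m, normalized_range=10.0)
        assert eta == 0.0 and p == 1.0

    def test_arithmetic(self):
        test = np.array([10.0, 12.0, 14.0])
        m = np.column_stack([test, test - 2.0])
        eta, _ = compute_eta(m, normalized_range=20.0)
        assert eta == pytest.approx(-10.0)

    def test_planted_shift_recovered_on_average(self, rng):
        etas = []
        for _ in range(100):
            test = rng.normal(size=60)
            retest = test - 0.05 * 20.0 + rng.normal(scale=0.3, size=60)
            etas.append(compute_eta(np.column_stack([test, retest]), 20.0)[0])
        assert np.mean(etas) == pytest.approx(-5.0, abs=0.5)


class TestPercentiles:
    def test_nearest_rank_definition(self):
        assert percentile(np.arange(1.0, 101.0), 80) == 80.0
        assert percentile([5.0], 20) == 5.0

    def test_constant_vector(self):
        srd_cut, eta_cut = percentile_cutoffs(np.full(10, 3.0), np.full(10, 3.0))
        assert srd_cut == 3.0 and eta_cut == 3.0

    def test_linear_convention_available(self):
        v = np.arange(1.0, 101.0)
        assert percentile(v, 80, "linear") == pytest.approx(np.percentile(v, 80))


def _score(name, auc=0.9, icc=0.9, srd_pct=10.0, eta=-1.0):
    return ClinimetricScores(name, auc, icc, 1.0, srd_pct, eta, 0.5)


class TestStep2Filter:
    def test_keep_requires_all_criteria(self):
        scores = [
            _score("good"),
            _score("low_auc", auc=0.5, srd_pct=15.0),
            _score("low_icc", icc=0.3, srd_pct=20.0),
            _score("high_srd", srd_pct=90.0),
            _score("learner", eta=-50.0, srd_pct=25.0),
        ]
        passers, both, info = step2_filter(scores)
        assert passers == ["good"]
        assert "auc>=0.7" in info["reasons"]["low_auc"][0]

    def test_intersection_with_step1(self):
        scores = [_score("a"), _score("b"), _score("bad", auc=0.1, srd_pct=99,
                                                   eta=-99)]
        _, both, _ = step2_filter(scores, step1_survivors={"b"})
        assert both == ["b"]

    def test_adding_criterion_never_enlarges_survivors(self):
        scores = [_score(f"m{i}", auc=0.6 + 0.04 * i, srd_pct=5.0 * i,
                         eta=-float(i)) for i in range(10)]
        passers, _, _ = step2_filter(scores)
        relaxed = step2_filter(
            scores, SelectionThresholds(auc_min=0.0, icc_min=-10.0))[0]
        assert set(passers) <= set(relaxed)

    def test_all_zero_auc_gives_empty_survivors(self):
        scores = [_score(f"m{i}", auc=0.0) for i in range(5)]
        passers, both, _ = step2_filter(scores)
        assert passers == [] and both == []
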