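import itertools

import numpy as np
import pandas as pd
import pytest

from stimchar import (
    RatingMatrix,
    SyntheticRatingSpec,
    chance_level,
    confusion_matrix,
    fleiss_kappa,
    frames_to_seconds,
    make_ratings,
    one_sample_t,
    score_ratings,
)


class TestScoreRatings:
    def test_counts_and_percentages(self, small_truth_ratings):
        scores = score_ratings(small_truth_ratings)
        assert scores.loc["r1", "n_correct"] == 3
        assert scores.loc["r2", "n_correct"] == 2
        assert scores.loc["r2", "pct_correct"] == pytest.approx(100 * 2 / 3)

    def test_perfect_rater_scores_one_hundred_percent(self):
        spec = SyntheticRatingSpec(n_items=135, n_raters=3, kernel=tuple(
            tuple(1.0 if i == j else 0.0 for j in range(3)) for i in range(3)
        ), seed=0)
        scores = score_ratings(make_ratings(spec))
        assert (scores["n_correct"] == 135).all()
        assert (scores["pct_correct"] == 100.0).all()

    def test_mean_count_to_percentage_conversion(self):
        # a mean of 119.63 correct out of 135 items is 88.61 %
        assert 100 * 119.63 / 135 == pytest.approx(88.61, abs=0.005)

    def test_percentage_count_consistency(self):
        scores = score_ratings(make_ratings(SyntheticRatingSpec(seed=3)))
        back = scores["pct_correct"] * 135 / 100
        assert np.allclose(back, scores["n_correct"])

    def test_missing_truth_rejected(self, hand_ratings):
        with pytest.raises(ValueError):
            score_ratings(hand_ratings)


class TestConfusionMatrix:
    def test_hand_counted_two_raters(self):
        ratings = RatingMatrix(
            ratings=pd.DataFrame({"r1": ["Normal"], "r2": ["How"]}, index=["v1"]),
            truth=pd.Series(["Normal"], index=["v1"]),
        )
        mat = confusion_matrix(ratings)
        assert list(mat.loc["Normal"]) == [1, 1, 0]
        assert mat.to_numpy().sum() == 2

    def test_perfect_raters_give_diagonal_matrix(self):
        spec = SyntheticRatingSpec(n_items=9, n_raters=4, kernel=tuple(
            tuple(1.0 if i == j else 0.0 for j in range(3)) for i in range(3)
        ), seed=1)
        mat = confusion_matrix(make_ratings(spec))
        off = mat.to_numpy() - np.diag(np.diag(mat.to_numpy()))
        assert (off == 0).all()

    def test_conservation_and_per_item_sum(self):
        rm = make_ratings(SyntheticRatingSpec(n_items=12, n_raters=5, seed=2))
        overall = confusion_matrix(rm)
        per_item = confusion_matrix(rm, per_item=True)
        assert overall.to_numpy().sum() == 12 * 5
        summed = sum(m.to_numpy() for m in per_item.values())
        assert np.array_equal(summed, overall.to_numpy())
        # row sums = raters x items of that true category
        counts = rm.truth.value_counts()
        for lab in rm.labels:
            assert overall.loc[lab].sum() == 5 * counts.get(lab, 0)


class TestFleissKappa:
    def test_perfect_agreement_gives_one(self):
        ratings = RatingMatrix(
            ratings=pd.DataFrame(
                {"r1": ["A", "B", "A"], "r2": ["A", "B", "A"], "r3": ["A", "B", "A"]},
                index=["i1", "i2", "i3"],
            ),
            labels=("A", "B"),
        )
        assert fleiss_kappa(ratings).kappa == pytest.approx(1.0)

    def test_hand_computed_two_item_example(self, hand_ratings):
        """Votes (A,A,B) and (B,B,B): P-bar = 2/3, P-bar_e = 5/9, kappa = 0.25."""
        res = fleiss_kappa(hand_ratings)
        assert res.mean_agreement == pytest.approx(2 / 3)
        assert res.expected_agreement == pytest.approx(5 / 9)
        assert res.kappa == pytest.approx(0.25)
        assert res.per_item_agreement == pytest.approx([1 / 3, 1.0])
        assert res.category_proportions.sum() == pytest.approx(1.0)

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        rng = np.random.default_rng(0)
        for _ in range(10):
            rm = make_ratings(
                SyntheticRatingSpec(
                    n_items=20, n_raters=6, diagonal=rng.uniform(0.4, 0.95),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            ours = fleiss_kappa(rm)
            theirs = sm_kappa(rm.counts().to_numpy())
            assert ours.kappa == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_category_relabeling(self):
        rm = make_ratings(SyntheticRatingSpec(n_items=15, n_raters=5, seed=9))
        base = fleiss_kappa(rm).kappa
        for perm in itertools.permutations(rm.labels):
            mapping = dict(zip(rm.labels, perm))
            permuted = RatingMatrix(
                ratings=rm.ratings.replace(mapping), truth=None, labels=rm.labels
            )
            assert fleiss_kappa(permuted).kappa == pytest.approx(base)

    def test_single_category_mass_is_flagged_undefined(self):
        ratings = RatingMatrix(
            ratings=pd.DataFrame({"r1": ["A", "A"], "r2": ["A", "A"]}, index=["i1", "i2"]),
            labels=("A", "B"),
        )
        res = fleiss_kappa(ratings)
        assert res.undefined
        assert np.isnan(res.kappa)

    def test_unequal_rating_counts_rejected(self):
        ratings = RatingMatrix(
            ratings=pd.DataFrame(
                {"r1": ["A", "A"], "r2": ["A", None]}, index=["i1", "i2"]
            ),
            labels=("A", "B"),
        )
        with pytest.raises(ValueError):
            fleiss_kappa(ratings)


class TestChanceLevel:
    def test_three_way_choice_over_135_items(self):
        assert chance_level(135, 3) == 45.0

    def test_direct_division(self):
        assert chance_level(10, 4) == 2.5

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(ValueError):
            chance_level(10, 1)


class TestOneSampleT:
    def test_summary_mode_reproduces_reported_statistics(self):
        """Mean 119.63, SD 10.41, n 51 against chance 45: t ~= 51.18, d ~= 7.17."""
        res = one_sample_t(mu0=45.0, mean=119.63, sd=10.41, n=51)
        assert res.cohens_d == pytest.approx(7.17, abs=0.005)
        assert res.t == pytest.approx(51.18, abs=0.02)
        assert res.df == 50
        assert res.p < 1e-4
        assert res.ci_low == pytest.approx(116.70, abs=0.02)
        assert res.ci_high == pytest.approx(122.56, abs=0.02)

    def test_mu_equal_to_mean_gives_zero_effect(self):
        res = one_sample_t([4.0, 5.0, 6.0], mu0=5.0)
        assert res.t == 0.0
        assert res.cohens_d == 0.0

    def test_hand_computed_three_values(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=0.0)
        assert res.t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-10)

    def test_raw_and_summary_modes_agree_to_ten_digits(self):
        rng = np.random.default_rng(11)
        values = rng.normal(80, 12, size=51)
        raw = one_sample_t(values, mu0=45.0)
        summ = one_sample_t(
            mu0=45.0, mean=float(values.mean()), sd=float(values.std(ddof=1)), n=51
        )
        for attr in ("t", "p", "ci_low", "ci_high", "cohens_d"):
            a, b = getattr(raw, attr), getattr(summ, attr)
            assert a == pytest.approx(b, rel=1e-10)

    def test_ci_contains_sample_mean(self):
        res = one_sample_t([3.0, 9.0, 4.0, 7.0], mu0=0.0)
        assert res.ci_low < np.mean([3.0, 9.0, 4.0, 7.0]) < res.ci_high

    def test_zero_variance_flagged_degenerate(self):
        res = one_sample_t([5.0, 5.0, 5.0], mu0=3.0)
        assert res.degenerate


class TestFramesToSeconds:
    @pytest.mark.parametrize(
        "frames, fps, seconds",
        [(3, 60, 0.05), (0, 60, 0.0), (81, 60, 1.35), (18, 60, 0.3)],
    )
    def test_conversions(self, frames, fps, seconds):
        assert frames_to_seconds(frames, fps) == pytest.approx(seconds)

    def test_invalid_fps_rejected(self):
        with pytest.raises(ValueError):
            frames_to_seconds(3, 0)


class TestRatingMatrixIO:
    def test_long_csv_roundtrip(self, tmp_path):
        rm = make_ratings(SyntheticRatingSpec(n_items=6, n_raters=4, seed=5))
        path = tmp_path / "ratings.csv"
        rm.to_long().to_csv(path, index=False)
        back = RatingMatrix.read_csv(path)
        assert back.ratings.sort_index().equals(rm.ratings.sort_index())
        assert back.truth.sort_index().equals(rm.truth.sort_index())

    def test_label_outside_set_rejected(self):
        with pytest.raises(ValueError):
            RatingMatrix(
                ratings=pd.DataFrame({"r1": ["Weird"]}, index=["v1"]),
            )
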