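import numpy as np
import pandas as pd
import pytest

from crowdvoc.errors import ConfigError
from crowdvoc.evaluate import (ModelConfig, attendance_filter,
                               enumerate_splits, evaluate_compound, prc_curve,
                               roc_auc, train_classifier)
from crowdvoc.features import feature_names
from crowdvoc.filmlist import ALWAYS_TOGETHER, campaign_screenings

from conftest import make_record


def brute_force_auc(scores, labels):
    """Mean pairwise ordering probability with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return total / (len(pos) * len(neg))


def records_for(counts_per_class, screenings_each=10):
    recs, i = [], 0
    for cls, n_films in zip((0, 6, 12, 16), counts_per_class):
        for f in range(n_films):
            for _ in range(screenings_each):
                recs.append(make_record(film=f"c{cls}f{f}", age_class=cls,
                                        sid=f"S{i:04d}"))
                i += 1
    return recs


class TestSplitEnumeration:
    def test_campaign_film_list_yields_24_combos(self):
        plan = enumerate_splits(campaign_screenings(), 8, ALWAYS_TOGETHER)
        assert plan.n_combos == 24
        # the joint FSK-16 option pools the two single-screening films
        fsk16_options = {c[16] for c in plan.combos}
        assert frozenset({"The Counselor", "Machete Kills"}) in fsk16_options
        assert frozenset({"Paranormal Activity: Ghost Dimension"}) in fsk16_options

    @pytest.mark.parametrize("counts, expected", [
        ((2, 3, 2, 2), 24),
        ((2, 2, 2, 2), 16),
        ((1, 1, 1, 1), 1),
    ])
    def test_product_rule(self, counts, expected):
        plan = enumerate_splits(records_for(counts), min_test_screenings=1)
        assert plan.n_combos == expected

    def test_single_eligible_film_in_every_combo(self):
        recs = records_for((2, 1, 2, 2))
        plan = enumerate_splits(recs, min_test_screenings=1)
        assert all(combo[6] == frozenset({"c6f0"}) for combo in plan.combos)

    def test_class_without_eligible_film_is_named(self):
        recs = records_for((2, 2, 2, 2), screenings_each=3)
        with pytest.raises(ConfigError, match="class 0"):
            enumerate_splits(recs, min_test_screenings=8)

    def test_test_and_train_disjoint(self):
        plan = enumerate_splits(campaign_screenings(), 8, ALWAYS_TOGETHER)
        films = {r.film_title for r in campaign_screenings()}
        for i in range(plan.n_combos):
            test = plan.test_films(i)
            assert test < films and films - test


class TestAttendanceFilter:
    def test_threshold_filtering(self):
        recs = [make_record(viewers=v, sid=f"S{v}") for v in (5, 15, 25)]
        assert len(attendance_filter(recs, 0)) == 3
        assert len(attendance_filter(recs, 10)) == 2
        assert len(attendance_filter(recs, 20)) == 1

    def test_zero_threshold_is_identity(self):
        recs = [make_record(viewers=v, sid=f"S{v}") for v in (5, 15)]
        assert attendance_filter(recs, 0) == recs


class TestClassifier:
    def test_default_mtry_is_one_third_of_features(self):
        assert ModelConfig().resolve_vars(18) == 6

    def test_memorizes_separable_toy_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 4)), rng.normal(5, 0.1, (20, 4))])
        y = np.array([0] * 20 + [12] * 20)
        model = train_classifier(X, y, ModelConfig(n_trees=100, seed=1))
        proba = model.predict_proba(X)
        truth_col = [list(model.classes_).index(c) for c in y]
        assert np.all(proba[np.arange(40), truth_col] >= 0.9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 5)), rng.choice([0, 6], 30)
        cfg = ModelConfig(n_trees=50, seed=7)
        p1 = train_classifier(X, y, cfg).predict_proba(X)
        p2 = train_classifier(X, y, cfg).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((5, 3)), np.zeros(5), ModelConfig(n_trees=5))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_computed_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs correctly ordered
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_missing_class_reported_as_nan(self):
        assert np.isnan(roc_auc([0.1, 0.2], [1, 1]))

    def test_matches_bruteforce_including_ties(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            scores = rng.normal(size=30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) \
                == pytest.approx(1.0)


class TestPrcCurve:
    def test_perfect_ranking_gives_unit_precision(self):
        curve = prc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        np.testing.assert_allclose(curve, 1.0)

    def test_zero_positives_undefined(self):
        assert np.all(np.isnan(prc_curve([0.3, 0.4], [0, 0])))

    def test_random_scores_average_precision_near_prevalence(self):
        # interpolated precision is upward-biased at small samples, so the
        # prevalence limit is checked at a size where the bias is small
        rng = np.random.default_rng(77)
        prevalence, n = 0.3, 500
        curves = []
        for _ in range(300):
            labels = rng.random(n) < prevalence
            if not labels.any():
                continue
            curves.append(prc_curve(rng.random(n), labels))
        mean_precision = np.mean(np.vstack(curves)[:, 1:])  # skip recall 0
        assert mean_precision == pytest.approx(prevalence, abs=0.05)


@pytest.fixture(scope="module")
def toy_eval():
    rng = np.random.default_rng(4)
    rows = []
    for cls, nf, mu in zip((0, 6, 12, 16), (2, 3, 2, 2), (0, 3, 6, 9)):
        for f in range(nf):
            for s in range(10):
                feats = dict(zip(feature_names(),
                                 rng.normal(mu, 0.5, 18)))
                rows.append({"screening_id": f"c{cls}f{f}s{s}",
                             "film_title": f"c{cls}f{f}",
                             "age_class": cls, **feats})
    features = pd.DataFrame(rows)
    recs = records_for((2, 3, 2, 2))
    plan = enumerate_splits(recs, min_test_screenings=1)
    return evaluate_compound(features, plan, ModelConfig(n_trees=50, seed=0),
                             feature_names(), "toy")


class TestEvaluateCompound:

    def test_separated_classes_score_high(self, toy_eval):
        for cls in toy_eval.classes:
            assert toy_eval.auc_mean(cls) > 0.9

    def test_auc_values_bounded(self, toy_eval):
        for cls in toy_eval.classes:
            vals = toy_eval.auc[cls]
            assert np.all((vals[~np.isnan(vals)] >= 0)
                          & (vals[~np.isnan(vals)] <= 1))

    def test_per_film_subsets_partition_the_combos(self, toy_eval):
        plan = toy_eval.plan
        for cls in toy_eval.classes:
            films = {f for i in range(plan.n_combos)
                     for f in plan.combos[i][cls]}
            indices = sorted(i for f in films
                             for i in plan.combos_with_test_film(f)
                             if f in plan.combos[i][cls])
            assert indices == list(range(plan.n_combos))

    def test_summary_frame_shape(self, toy_eval):
        frame = toy_eval.summary_frame()
        assert list(frame["age_class"]) == [0, 6, 12, 16]
        assert (frame["n_combos"] == 24).all()
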