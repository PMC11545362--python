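"""Entropy, information gain, tree induction and continuous learning."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clinicflow as cf
from clinicflow.errors import FitError, SchemaError, UndefinedEntropyError, UpdateError
from clinicflow.tree import CLASSES_BINARY, LabeledDataset


def binary_dataset(feature_rows, labels):
    return LabeledDataset(
        features=pd.DataFrame(feature_rows),
        labels=np.array(labels, dtype=object),
        classes=CLASSES_BINARY,
    )


def brute_force_ig(data: LabeledDataset, feature: str) -> float:
    """Independent recomputation of IG from raw subset counts."""

    def h(labels):
        n = len(labels)
        out = 0.0
        for c in set(labels):
            p = sum(1 for x in labels if x == c) / n
            out -= p * math.log2(p)
        return out

    labels = list(data.labels)
    total = h(labels)
    n = len(labels)
    values = set(data.features[feature])
    sub = 0.0
    for v in values:
        part = [l for l, fv in zip(labels, data.features[feature]) if fv == v]
        sub += len(part) / n * h(part)
    return total - sub


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [([8, 0], 0.0), ([4, 4], 1.0), ([3, 1], 0.8112781244591328), ([1, 1, 1, 1], 2.0)],
    )
    def test_known_values(self, counts, expected):
        assert cf.entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(UndefinedEntropyError):
            cf.entropy([0, 0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=5).filter(lambda c: sum(c) > 0))
    def test_bounded_by_log_k(self, counts):
        h = cf.entropy(counts)
        assert -1e-12 <= h <= math.log2(len(counts)) + 1e-12


class TestInformationGain:
    def test_pure_halves_give_one_bit(self):
        data = binary_dataset(
            [{"f": "a"}, {"f": "a"}, {"f": "b"}, {"f": "b"}],
            ["show", "show", "not_show", "not_show"],
        )
        assert cf.information_gain(data, "f") == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_gains_nothing(self):
        data = binary_dataset(
            [{"f": "a"}] * 4, ["show", "show", "not_show", "not_show"]
        )
        assert cf.information_gain(data, "f") == 0.0

    def test_unknown_feature_raises(self):
        data = binary_dataset([{"f": "a"}], ["show"])
        with pytest.raises(SchemaError, match="nope"):
            cf.information_gain(data, "nope")

    def test_matches_bruteforce_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            rows = [
                {f"f{j}": str(rng.integers(0, 2)) for j in range(3)} for _ in range(n)
            ]
            labels = [("show", "not_show")[rng.integers(0, 2)] for _ in range(n)]
            data = binary_dataset(rows, labels)
            for feat in data.schema:
                assert cf.information_gain(data, feat) == pytest.approx(
                    max(0.0, brute_force_ig(data, feat)), abs=1e-12
                )

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 20))
            rows = [{"f": str(rng.integers(0, 3))} for _ in range(n)]
            labels = [("show", "not_show")[rng.integers(0, 2)] for _ in range(n)]
            data = binary_dataset(rows, labels)
            h = cf.entropy(data.class_counts())
            assert -1e-12 <= cf.information_gain(data, "f") <= h + 1e-12

    def test_duplicate_feature_same_gain(self):
        rng = np.random.default_rng(3)
        rows = [{"a": str(rng.integers(0, 2))} for _ in range(10)]
        for r in rows:
            r["b"] = r["a"]
        labels = [("show", "not_show")[rng.integers(0, 2)] for _ in range(10)]
        data = binary_dataset(rows, labels)
        assert cf.information_gain(data, "a") == pytest.approx(
            cf.information_gain(data, "b"), abs=1e-15
        )


class TestFitTree:
    def test_pure_data_yields_single_leaf(self):
        data = binary_dataset([{"f": "a"}, {"f": "b"}], ["show", "show"])
        model = cf.fit_tree(data, min_leaf=1)
        assert model.tree.is_leaf
        assert model.tree.counts["show"] == 2

    def test_root_splits_on_higher_gain_feature(self):
        # age separates labels perfectly, gender is independent noise
        rows, labels = [], []
        for age, gender, label in [
            ("young", "F", "show"), ("young", "M", "show"),
            ("old", "F", "not_show"), ("old", "M", "not_show"),
        ]:
            rows.append({"gender": gender, "age_bracket": age})
            labels.append(label)
        data = binary_dataset(rows, labels)
        model = cf.fit_tree(data, min_leaf=1, max_depth=3)
        assert model.tree.feature == "age_bracket"

    def test_empty_data_raises(self):
        with pytest.raises((FitError, SchemaError)):
            cf.fit_tree(binary_dataset([], []), min_leaf=1)

    def test_internal_counts_equal_sum_of_children(self, small_population):
        profiles = [p.profile for p in small_population]
        labels = [
            p.profile.history[-1] if p.profile.history else "realized"
            for p in small_population
        ]
        data, edges = cf.build_training_data(profiles, labels)
        model = cf.fit_tree(data, min_leaf=5, max_depth=4, travel_bin_edges=edges)

        def check(node):
            if node.is_leaf:
                return
            for c in node.counts:
                assert node.counts[c] == sum(ch.counts[c] for ch in node.children.values())
            for ch in node.children.values():
                check(ch)

        check(model.tree)
        assert model.tree.n == len(data)


class TestPredictRisk:
    def test_pure_leaf_high_attendance(self):
        data = binary_dataset(
            [{"age_bracket": "21-30", "gender": "F", "district": "D1",
              "travel_bin": "missing", "past_behavior": "none"}] * 20,
            ["show"] * 20,
        )
        model = cf.fit_tree(data, min_leaf=1)
        prof = cf.PatientProfile(patient_id="x", age_years=25, gender="F", district="D1")
        rp = model.predict_risk(prof)
        assert rp.p_attend > 0.9  # Laplace keeps it just below 1
        assert not rp.high_risk
        assert rp.p_attend + rp.p_cancel + rp.p_noshow == pytest.approx(1.0)

    def test_unseen_category_routed_with_warning(self, caplog, small_population):
        profiles = [p.profile for p in small_population[:500]]
        labels = [
            p.profile.history[0] if p.profile.history else "realized"
            for p in small_population[:500]
        ]
        data, edges = cf.build_training_data(profiles, labels)
        model = cf.fit_tree(data, min_leaf=5, travel_bin_edges=edges)
        stranger = cf.PatientProfile(
            patient_id="new", age_years=40, gender="F", district="UNSEEN-DISTRICT"
        )
        with caplog.at_level(logging.WARNING, logger="clinicflow.tree"):
            rp = model.predict_risk(stranger)
        assert 0.0 < rp.p_attend < 1.0

    def test_probabilities_sum_to_one(self, small_population):
        profiles = [p.profile for p in small_population]
        labels = [
            p.profile.history[-1] if p.profile.history else "realized"
            for p in small_population
        ]
        data, edges = cf.build_training_data(profiles, labels)
        model = cf.fit_tree(data, travel_bin_edges=edges)
        for p in small_population[:100]:
            rp = model.predict_risk(p.profile)
            assert rp.p_attend + rp.p_cancel + rp.p_noshow == pytest.approx(1.0, abs=1e-9)


def _profile(i, age, gender="F", district="D1"):
    return cf.PatientProfile(patient_id=f"p{i}", age_years=age, gender=gender, district=district)


class TestIncrementalUpdate:
    def _data(self, ages, labels):
        profiles = [_profile(i, a) for i, a in enumerate(ages)]
        data, _ = cf.build_training_data(profiles, labels, travel_bins=0)
        return data

    def test_empty_update_is_identity(self):
        data = self._data([20, 30, 65, 70], ["realized", "realized", "no_show", "no_show"])
        model = cf.fit_tree(data, min_leaf=1)
        updated = model.update(self._data([], []))
        assert updated is model
        assert updated.version == 1

    def test_sequential_updates_equal_concatenated(self):
        base = self._data([20, 25, 60, 65] * 3, ["realized", "realized", "no_show", "canceled"] * 3)
        a = self._data([30, 66], ["realized", "no_show"])
        b = self._data([35, 68], ["canceled", "no_show"])
        both = self._data([30, 66, 35, 68], ["realized", "no_show", "canceled", "no_show"])
        model = cf.fit_tree(base, min_leaf=1)
        seq = model.update(a).update(b)
        onego = model.update(both)
        assert seq.tree.to_dict() == onego.tree.to_dict()
        assert seq.version == 3 and onego.version == 2

    def test_window_drops_oldest_rows(self):
        old = self._data([20] * 6, ["no_show"] * 6)
        model = cf.fit_tree(old, min_leaf=1, window_length=6)
        new = self._data([20] * 6, ["realized"] * 6)
        updated = model.update(new)
        # window kept only the new rows; the refit forgets the old no-shows
        assert updated.trained_on == 6
        assert updated.tree.counts["realized"] == 6
        assert updated.tree.counts["no_show"] == 0

    def test_schema_mismatch_rejected(self):
        data = self._data([20, 30, 60, 70], ["realized", "realized", "no_show", "no_show"])
        model = cf.fit_tree(data, min_leaf=1)
        profiles = [_profile(9, 50)]
        other, _ = cf.build_training_data(profiles, ["realized"], binary=True, travel_bins=0)
        with pytest.raises(UpdateError):
            model.update(other)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, small_population):
        profiles = [p.profile for p in small_population[:800]]
        labels = [
            p.profile.history[0] if p.profile.history else "realized"
            for p in small_population[:800]
        ]
        data, edges = cf.build_training_data(profiles, labels)
        model = cf.fit_tree(data, travel_bin_edges=edges)
        clone = cf.NoShowModel.from_json(model.to_json())
        for p in small_population[:50]:
            a = model.predict_risk(p.profile)
            b = clone.predict_risk(p.profile)
            assert (a.p_attend, a.p_cancel, a.p_noshow) == (b.p_attend, b.p_cancel, b.p_noshow)


class TestLogisticScorer:
    def test_recovers_age_gradient(self):
        rng = np.random.default_rng(5)
        profiles, labels = [], []
        rates = {"21-30": 0.8, "41-50": 0.6, "61-70": 0.4}
        for i in range(3000):
            age = {0: 25, 1: 45, 2: 65}[int(rng.integers(0, 3))]
            p = _profile(i, age)
            profiles.append(p)
            labels.append("realized" if rng.random() < rates[p.age_bracket] else "no_show")
        data, _ = cf.build_training_data(profiles, labels, travel_bins=0)
        scorer = cf.fit_logistic(data)
        ps = {
            b: scorer.predict_risk(_profile(99, age)).p_attend
            for b, age in [("21-30", 25), ("41-50", 45), ("61-70", 65)]
        }
        assert ps["21-30"] > ps["41-50"] > ps["61-70"]
        for b, rate in rates.items():
            assert ps[b] == pytest.approx(rate, abs=0.05)

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(8)
        profiles, labels = [], []
        for i in range(2000):
            age = int(rng.choice([25, 45, 65]))
            g = "F" if rng.random() < 0.5 else "M"
            p = _profile(i, age, gender=g)
            base = {"21-30": 0.75, "41-50": 0.6, "61-70": 0.45}[p.age_bracket]
            base += 0.05 if g == "F" else 0.0
            profiles.append(p)
            labels.append("realized" if rng.random() < base else "canceled")
        data, _ = cf.build_training_data(profiles, labels, travel_bins=0)
        scorer = cf.fit_logistic(data, ridge=1e-9)

        from clinicflow.scoring import _one_hot

        X, _, _ = _one_hot(data.features)
        y = np.array([1.0 if s == "realized" else 0.0 for s in data.labels])
        ref = sklearn.LogisticRegression(C=1e9, fit_intercept=False, tol=1e-10).fit(X, y)
        assert np.allclose(scorer.coef, ref.coef_.ravel(), atol=1e-4)
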