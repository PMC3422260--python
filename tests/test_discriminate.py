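"""Cosine 1-NN, LOOCV and MCC behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trilevel import (
    ConfusionCounts,
    NearestNeighborCosineClassifier,
    OmicsMatrix,
    ValidationError,
    cosine_distance,
    loocv_confusion,
    mcc,
    nna_predict,
    score_all,
    score_set,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def make_matrix(values, labels, level="mRNA"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        level=level,
        feature_ids=[f"F{i}" for i in range(values.shape[0])],
        sample_ids=[f"S{j}" for j in range(values.shape[1])],
        values=values,
        labels=labels,
    )


class TestCosineDistance:
    def test_identical_vectors(self):
        assert cosine_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0, abs=1e-12)

    def test_orthogonal_vectors(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1)

    def test_oblique_pair(self):
        assert cosine_distance([1, 1], [1, 0]) == pytest.approx(1 - math.sqrt(2) / 2, abs=1e-7)

    def test_zero_norm_gives_one(self):
        assert cosine_distance([0, 0], [1, 2]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            cosine_distance([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(finite, min_size=1, max_size=8), st.data())
    def test_symmetry_and_self_distance(self, xs, data):
        ys = data.draw(st.lists(finite, min_size=len(xs), max_size=len(xs)))
        assert cosine_distance(xs, ys) == pytest.approx(cosine_distance(ys, xs), abs=1e-12)
        if np.linalg.norm(xs) == 0:  # zero-norm convention: distance 1
            assert cosine_distance(xs, xs) == 1.0
        else:
            assert cosine_distance(xs, xs) == pytest.approx(0, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(finite, min_size=2, max_size=8),
           st.floats(1e-3, 1e3), st.data())
    def test_invariant_to_positive_rescaling(self, xs, c, data):
        ys = data.draw(st.lists(finite, min_size=len(xs), max_size=len(xs)))
        d0 = cosine_distance(xs, ys)
        d1 = cosine_distance([c * x for x in xs], ys)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestNearestNeighbor:
    def test_identical_query_takes_that_label(self):
        m = make_matrix([[1, -1], [2, -2]], ["tumor", "normal"])
        assert nna_predict(m, [1, 2]) == "tumor"
        assert nna_predict(m, [-1, -2]) == "normal"

    def test_tie_broken_by_earlier_sample(self):
        # both training samples are equidistant from the query
        m = make_matrix([[1, 0], [0, 1]], ["normal", "tumor"])
        assert nna_predict(m, [1, 1]) == "normal"
        m2 = make_matrix([[0, 1], [1, 0]], ["tumor", "normal"])
        assert nna_predict(m2, [1, 1]) == "tumor"

    def test_single_training_sample_via_estimator(self):
        clf = NearestNeighborCosineClassifier().fit([[5.0, 1.0]], ["tumor"])
        assert clf.predict([[-5.0, -1.0]])[0] == "tumor"

    def test_query_length_mismatch(self):
        m = make_matrix([[1, -1], [2, -2]], ["tumor", "normal"])
        with pytest.raises(ValidationError):
            nna_predict(m, [1, 2, 3])

    def test_sklearn_cross_check(self):
        """Matches scikit-learn's 1-NN with cosine metric on tie-free data."""
        pytest.importorskip("sklearn")
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(0)
        Xtr = rng.normal(size=(25, 6)) + 4  # keep norms away from zero
        ytr = np.array(["tumor", "normal"] * 12 + ["tumor"])
        Xte = rng.normal(size=(40, 6)) + 4
        ours = NearestNeighborCosineClassifier().fit(Xtr, ytr).predict(Xte)
        ref = KNeighborsClassifier(n_neighbors=1, metric="cosine").fit(Xtr, ytr).predict(Xte)
        assert list(ours) == list(ref)


class TestLoocv:
    def test_two_separated_clusters_are_perfect(self):
        rng = np.random.default_rng(1)
        base = np.array([[1.0], [1.0], [1.0]])
        tumor = base + rng.normal(0, 0.01, size=(3, 10))
        normal = -base + rng.normal(0, 0.01, size=(3, 10))
        m = make_matrix(np.hstack([tumor, normal]), ["tumor"] * 10 + ["normal"] * 10)
        c = loocv_confusion(m, m.feature_ids)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)
        assert mcc(c) == 1.0

    def test_two_samples_cross_predict(self):
        # each sample's only neighbor has the other label
        m = make_matrix([[1, 2], [1, 2]], ["tumor", "normal"])
        c = loocv_confusion(m, m.feature_ids)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)
        assert mcc(c) == -1.0

    def test_total_equals_samples(self, study):
        m = study.matrices["mRNA"]
        c = loocv_confusion(m, m.feature_ids[:5])
        assert c.total == m.n_samples

    def test_disjoint_feature_set_errors(self, study):
        with pytest.raises(ValidationError, match="no features"):
            loocv_confusion(study.matrices["mRNA"], {"NOPE"})

    def test_permutation_null_mcc_centered_at_zero(self):
        """Randomly permuted labels give mean LOOCV MCC ~ 0 over 500 replicates."""
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(10, 40))
        labels = ["tumor"] * 20 + ["normal"] * 20
        m = make_matrix(values, labels)
        # neighbors are label-independent: compute them once
        from trilevel.discriminate import _cross_distances

        dist = _cross_distances(values, values)
        np.fill_diagonal(dist, np.inf)
        nn = np.argmin(dist, axis=1)
        mccs = []
        for _ in range(500):
            perm = rng.permutation(40)
            truth = np.zeros(40, dtype=bool)
            truth[perm[:20]] = True
            pred = truth[nn]
            c = ConfusionCounts(
                tp=int(np.sum(pred & truth)), tn=int(np.sum(~pred & ~truth)),
                fp=int(np.sum(pred & ~truth)), fn=int(np.sum(~pred & truth)),
            )
            mccs.append(mcc(c))
        assert abs(float(np.mean(mccs))) < 0.05


class TestMcc:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 10, 0, 0), 1.0),
            ((0, 0, 10, 10), -1.0),
            ((6, 4, 1, 2), 22 / math.sqrt(1680)),
            ((5, 0, 5, 0), 0.0),  # zero denominator factor
        ],
    )
    def test_values(self, counts, expected):
        tp, tn, fp, fn = counts
        assert mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)) == pytest.approx(expected, abs=1e-12)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValidationError):
            mcc(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))


class TestScoreAll:
    def test_identical_sets_get_identical_mccs(self, study):
        from trilevel.datatypes import TermLevelSets

        feats = frozenset(study.matrices["mRNA"].feature_ids[:6])
        matrices = {lv: study.matrices["mRNA"] for lv in ("methylation", "microRNA", "mRNA")}
        ts = TermLevelSets("T", feats, feats, feats)
        out = score_all(matrices, [ts])
        assert out.loc["T", "methylation"] == out.loc["T", "microRNA"] == out.loc["T", "mRNA"]

    def test_duplicate_term_ids_rejected(self, study, study_sets):
        with pytest.raises(ValidationError, match="duplicate term"):
            score_all(study.matrices, [study_sets[0], study_sets[0]])

    def test_invariant_to_sample_order(self, study):
        """Column permutation does not change the score on tie-free data."""
        m = study.matrices["mRNA"]
        feats = frozenset(m.feature_ids[:8])
        rng = np.random.default_rng(5)
        perm = rng.permutation(m.n_samples)
        m2 = make_matrix(m.values[:, perm], [m.labels[j] for j in perm])
        m2.feature_ids = m.feature_ids  # same features, reordered samples
        m2._feature_index = {f: i for i, f in enumerate(m.feature_ids)}
        assert score_set(m, feats) == pytest.approx(score_set(m2, feats), abs=1e-12)

    def test_planted_level_dominates(self, study, study_mcc):
        """A term planted only at mRNA (delta=3) scores highest there."""
        row = study_mcc.loc["T0000"]
        assert row["mRNA"] >= 0.9
        assert row["mRNA"] > row["methylation"]
        assert row["mRNA"] > row["microRNA"]
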