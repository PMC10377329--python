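"""Feature selection, stratified CV, confusion-matrix metrics, leakage."""

import numpy as np
import pytest

from fconn.cohort import default_contrast_spec, generate_cohort
from fconn.embedding import fc_flatten_features
from fconn.errors import ValidationError
from fconn.evaluation import (
    ConfusionMatrix,
    metrics,
    positive_label_for,
    run_cv,
    select_features,
    stratified_kfold,
)
from fconn.fc import fc_matrix
from fconn.melm import MELMConfig

MELM_SMALL = MELMConfig(n_layers=2, neurons_per_layer=(32, 32), seed=0)


class TestMetrics:
    def test_standard_definitions(self):
        cm = ConfusionMatrix(tp=9, fn=1, tn=8, fp=2, positive_label="AD")
        acc, sens, spec = metrics(cm)
        assert (acc, sens, spec) == (0.85, 0.90, 0.80)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=5, fn=0, tn=5, fp=0, positive_label="AD")
        assert metrics(cm) == (1.0, 1.0, 1.0)

    def test_as_printed_mode_shares_denominator(self):
        # literal printed forms: sens = TP/total, spec = TN/total
        cm = ConfusionMatrix(tp=9, fn=1, tn=8, fp=2, positive_label="AD")
        acc, sens, spec = metrics(cm, as_printed=True)
        assert (acc, sens, spec) == (0.85, 0.45, 0.40)
        assert sens + spec == pytest.approx(acc)

    def test_undefined_rate_is_error(self):
        cm = ConfusionMatrix(tp=0, fn=0, tn=8, fp=2, positive_label="AD")
        with pytest.raises(ValueError, match="sensitivity"):
            metrics(cm)

    def test_positive_label_is_more_impaired(self):
        assert positive_label_for(("CN", "MCI")) == "MCI"
        assert positive_label_for(("MCI", "AD")) == "AD"
        assert positive_label_for(("AD", "CN")) == "AD"


class TestSelectFeatures:
    def test_indicator_column_ranked_first(self, rng):
        x = rng.standard_normal((40, 20))
        labels = ["A"] * 20 + ["B"] * 20
        x[:, 7] = [0.0] * 20 + [1.0] * 20
        x[:, 7] += 0.01 * rng.standard_normal(40)
        sel = select_features(x, labels, 1)
        assert sel.tolist() == [7]

    def test_full_dimension_is_identity(self, rng):
        x = rng.standard_normal((20, 6))
        labels = ["A"] * 10 + ["B"] * 10
        assert select_features(x, labels, 6).tolist() == list(range(6))

    def test_k_zero_rejected(self, rng):
        x = rng.standard_normal((20, 6))
        with pytest.raises(ValidationError):
            select_features(x, ["A"] * 10 + ["B"] * 10, 0)

    def test_tiny_class_rejected(self, rng):
        x = rng.standard_normal((3, 4))
        with pytest.raises(ValidationError, match="2 training samples"):
            select_features(x, ["A", "A", "B"], 2)


class TestStratifiedKFold:
    def test_balanced_folds(self):
        labels = ["A"] * 20 + ["B"] * 20
        folds = stratified_kfold(labels, k=10, seed=0)
        labels = np.asarray(labels)
        for _, te in folds:
            assert (labels[te] == "A").sum() == 2
            assert (labels[te] == "B").sum() == 2

    def test_partition_property(self):
        labels = ["A"] * 15 + ["B"] * 25
        folds = stratified_kfold(labels, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(40))
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(40))
            assert not set(tr) & set(te)

    def test_determinism(self):
        labels = ["A"] * 12 + ["B"] * 12
        f1 = stratified_kfold(labels, k=4, seed=9)
        f2 = stratified_kfold(labels, k=4, seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_class_smaller_than_k(self):
        with pytest.raises(ValidationError, match="smaller k"):
            stratified_kfold(["A"] * 3 + ["B"] * 20, k=10)


class TestRunCV:
    def _separable(self, rng, n=40, d=30):
        x = rng.standard_normal((n, d))
        labels = ["CN"] * (n // 2) + ["AD"] * (n // 2)
        x[labels.index("AD"):, :5] += 3.0
        return x, labels

    def test_separable_features_high_accuracy(self, rng):
        x, labels = self._separable(rng)
        rep = run_cv(x, labels, ("CN", "AD"), "PCC", [10], MELM_SMALL, seed=0)[0]
        assert rep.accuracy >= 0.9

    def test_grid_yields_one_report_each(self, rng):
        x, labels = self._separable(rng)
        reps = run_cv(x, labels, ("CN", "AD"), "PCC", [10, 20], MELM_SMALL, seed=0)
        assert [r.n_features for r in reps] == [10, 20]

    def test_fold_totals_sum_to_cohort(self, rng):
        x, labels = self._separable(rng)
        rep = run_cv(x, labels, ("CN", "AD"), "PCC", [10], MELM_SMALL, seed=0)[0]
        assert sum(cm.total for cm in rep.per_fold) == len(labels)

    def test_macro_vs_pooled_accuracy_close_on_balanced_cohort(self, rng):
        x, labels = self._separable(rng)
        x += rng.standard_normal(x.shape) * 2.0  # make it imperfect
        rep = run_cv(x, labels, ("CN", "AD"), "PCC", [10], MELM_SMALL, seed=0)[0]
        pooled = sum(cm.tp + cm.tn for cm in rep.per_fold) / sum(
            cm.total for cm in rep.per_fold
        )
        assert abs(rep.accuracy - pooled) <= 0.02

    def test_permuted_labels_give_chance_level(self, rng):
        """Null cohort: label permutation destroys any class signal."""
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal((40, 50))
            labels = list(r.permutation(["CN"] * 20 + ["AD"] * 20))
            rep = run_cv(x, labels, ("CN", "AD"), "PCC", [20], MELM_SMALL,
                         seed=seed)[0]
            accs.append(rep.accuracy)
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_no_leakage_canary(self, rng):
        """A feature equal to the TEST-fold indicator is useless if selection
        and standardization are confined to training folds."""
        r = np.random.default_rng(0)
        x = r.standard_normal((40, 30))
        labels = ["CN"] * 20 + ["AD"] * 20
        folds = stratified_kfold(labels, k=10, seed=0)
        canary = np.zeros(40)
        # mark each subject with its own fold's test membership: within any
        # TRAINING subset this column carries no class signal
        te0 = folds[0][1]
        canary[te0] = 1.0
        x[:, 0] = canary
        rep = run_cv(x, labels, ("CN", "AD"), "PCC", [5], MELM_SMALL, seed=0)[0]
        assert rep.accuracy <= 0.75

    def test_unknown_task_group(self, rng):
        x = rng.standard_normal((20, 5))
        labels = ["CN"] * 10 + ["MCI"] * 10
        with pytest.raises(ValidationError, match="lacks"):
            run_cv(x, labels, ("CN", "AD"), "PCC", [2], MELM_SMALL)


def test_full_pipeline_accuracy_monotone_in_strength_gap():
    """Widening the between-group non-linear strength gap never hurts the
    eMIC pipeline's CV accuracy (three gaps, fixed seed, flattened-FC mode)."""
    accs = []
    for gap_hi in (0.0, 1.0, 2.4):
        spec = default_contrast_spec(
            n_per_group=15, labels=("CN", "AD"), n_rois=16, n_timepoints=140,
            n_linear_edges=2, n_nonlinear_edges=6, seed=5,
            nonlinear_strengths={"CN": 0.0, "AD": gap_hi},
        )
        cohort = generate_cohort(spec)
        feats = np.vstack([
            fc_flatten_features(fc_matrix(s, "eMIC")) for s in cohort.subjects
        ])
        labels = [cohort.labels[s.subject_id] for s in cohort.subjects]
        rep = run_cv(feats, labels, ("CN", "AD"), "eMIC", [20],
                     MELMConfig(n_layers=2, neurons_per_layer=(32, 32), seed=0),
                     seed=0, k_folds=5)[0]
        accs.append(rep.accuracy)
    assert accs[0] <= accs[1] <= accs[2]
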