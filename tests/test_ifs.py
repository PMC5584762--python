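import numpy as np
import pytest

from essnet import enrichment, ifs, mrmr, synthetic
from essnet.enrichment import FeatureMatrix
from essnet.ifs import (
    ClassifierSpec,
    FoldAssignment,
    cross_validate,
    predict_unlabeled,
    run_ifs,
    stratified_folds,
    train_final,
)
from essnet.metrics import compute_metrics

from conftest import SMALL_CONFIG


def _matrix(values):
    n, p = values.shape
    return FeatureMatrix(
        genes=tuple(f"g{i}" for i in range(n)),
        features=tuple((f"GO:{j}", "GO-BP") for j in range(p)),
        scores=values,
    )


# --- fold assignment ---------------------------------------------------------

def test_folds_are_stratified():
    labels = np.array([1] * 20 + [0] * 80)
    folds = stratified_folds(labels, n_folds=10, seed=3)
    for f in range(10):
        te = folds.test_indices(f)
        assert (labels[te] == 1).sum() == 2
        assert (labels[te] == 0).sum() == 8


def test_folds_deterministic_for_fixed_seed():
    labels = np.array([1] * 30 + [0] * 70)
    a = stratified_folds(labels, seed=11)
    b = stratified_folds(labels, seed=11)
    assert np.array_equal(a.fold_of, b.fold_of)
    c = stratified_folds(labels, seed=12)
    assert not np.array_equal(a.fold_of, c.fold_of)


def test_folds_at_study_class_sizes():
    labels = np.array([1] * 205 + [0] * 830)
    folds = stratified_folds(labels, n_folds=10, seed=0)
    pos_per_fold = [(labels[folds.test_indices(f)] == 1).sum() for f in range(10)]
    neg_per_fold = [(labels[folds.test_indices(f)] == 0).sum() for f in range(10)]
    assert set(pos_per_fold) == {20, 21} and sum(pos_per_fold) == 205
    assert set(neg_per_fold) == {83}


def test_folds_require_enough_members_per_class():
    labels = np.array([1] * 5 + [0] * 95)
    with pytest.raises(ValueError, match="fewer than 10 folds"):
        stratified_folds(labels, n_folds=10)


# --- cross-validation --------------------------------------------------------

def test_separable_data_scores_perfectly():
    rng = np.random.default_rng(0)
    labels = np.array([1] * 30 + [0] * 70)
    values = labels[:, None] * 10.0 + rng.random((100, 3))
    folds = stratified_folds(labels, seed=1)
    confusion, metrics = cross_validate(_matrix(values), labels, [0, 1, 2],
                                        ClassifierSpec(), folds)
    assert metrics.mcc == 1.0
    assert confusion.total == 100


def test_permuted_labels_score_near_zero():
    # null distribution: with the class signal destroyed, tenfold CV MCC on
    # 1000 samples stays within sampling noise of 0
    rng = np.random.default_rng(7)
    labels = np.array([1] * 200 + [0] * 800)
    values = rng.gamma(2.0, 1.0, size=(1000, 5))
    permuted = rng.permutation(labels)
    folds = stratified_folds(permuted, seed=1)
    _, metrics = cross_validate(_matrix(values), permuted, list(range(5)),
                                ClassifierSpec(), folds)
    assert abs(metrics.mcc) < 0.15


def test_confusion_counts_conserve_sample_count(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    folds = stratified_folds(labels, seed=2)
    confusion, _ = cross_validate(small_matrix, labels, list(range(10)),
                                  ClassifierSpec(), folds)
    assert confusion.total == len(labels)
    assert confusion.positives == int(labels.sum())


def test_single_class_training_fold_is_hard_error():
    labels = np.array([1] * 10 + [0] * 10)
    # adversarial assignment: every positive lands in fold 0, so folds 1..9
    # train without negatives... and fold 0's training split has no positives
    fold_of = np.array([0] * 10 + [i % 10 for i in range(10)])
    folds = FoldAssignment(fold_of=fold_of, n_folds=10, seed=0)
    values = np.abs(np.random.default_rng(1).normal(size=(20, 2)))
    with pytest.raises(ValueError, match="single class"):
        cross_validate(_matrix(values), labels, [0, 1], ClassifierSpec(), folds)


def test_empty_feature_subset_rejected(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    with pytest.raises(ValueError, match="non-empty"):
        cross_validate(small_matrix, labels, [], ClassifierSpec(),
                       stratified_folds(labels, seed=0))


# --- incremental feature selection -------------------------------------------

def test_single_point_sweep(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    res = run_ifs(small_matrix, labels, ranked, k_min=5, k_max=5, seed=0)
    assert len(res.records) == 1 and res.optimal_k == 5


def test_record_count_covers_the_sweep_range(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    res = run_ifs(small_matrix, labels, ranked, k_min=3, k_max=20, seed=0)
    assert len(res.records) == 18
    assert [r.k for r in res.records] == list(range(3, 21))


def test_ifs_is_deterministic(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    a = run_ifs(small_matrix, labels, ranked, k_min=5, k_max=15, seed=4)
    b = run_ifs(small_matrix, labels, ranked, k_min=5, k_max=15, seed=4)
    assert a == b


def test_all_prefixes_share_one_fold_assignment(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    folds = stratified_folds(labels, seed=9)
    res = run_ifs(small_matrix, labels, ranked, k_min=5, k_max=10, folds=folds)
    # re-evaluating any k on the same partition reproduces its record exactly
    for record in res.records:
        confusion, metrics = cross_validate(
            small_matrix, labels, list(ranked.mrmr_order[: record.k]),
            ClassifierSpec(), folds,
        )
        assert confusion == record.confusion and metrics == record.metrics


def test_empty_or_oversized_range_rejected(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    with pytest.raises(ValueError, match="empty IFS range"):
        run_ifs(small_matrix, labels, ranked, k_min=10, k_max=5)
    with pytest.raises(ValueError, match="exceeds"):
        run_ifs(small_matrix, labels, ranked, k_min=5, k_max=10_000)


def test_planted_signal_is_recovered_by_ifs(default_pipeline):
    """At the planted-signal study conditions the optimal model is nearly
    perfect and uses at least as many features as informative terms reach
    the ranking's head."""
    res = default_pipeline["ifs"]
    ds = default_pipeline["dataset"]
    ranked = default_pipeline["ranking"]
    matrix = default_pipeline["matrix"]
    assert res.optimal_record.metrics.mcc >= 0.9
    informative = set(ds.truth.informative_term_ids)
    in_head = sum(
        1 for j in ranked.mrmr_order[: res.optimal_k]
        if matrix.features[j][0] in informative
    )
    assert res.optimal_k >= in_head >= 1


def test_optimal_features_beat_random_features_paired():
    """Paired over 10 seeds: CV MCC of the mRMR-optimal feature set vs the
    same number of randomly drawn features."""
    wins, diffs = 0, []
    for seed in range(10):
        cfg = synthetic.SyntheticConfig(
            **{**SMALL_CONFIG.__dict__, "seed": 100 + seed}
        )
        ds = synthetic.generate(cfg)
        bg = enrichment.make_background(ds.network, ds.terms)
        mat = enrichment.build_feature_matrix(ds.network, ds.labeled.genes, ds.terms, bg)
        labels = ds.labeled.labels()
        ranked = mrmr.mrmr_rank(mat, labels)
        folds = stratified_folds(labels, seed=seed)
        res = run_ifs(mat, labels, ranked, k_min=2, k_max=20, step=2, folds=folds)
        k = res.optimal_k
        rng = np.random.default_rng(seed)
        random_subset = rng.choice(mat.n_features, size=k, replace=False)
        _, rand_metrics = cross_validate(mat, labels, list(random_subset),
                                         ClassifierSpec(), folds)
        diffs.append(res.optimal_record.metrics.mcc - rand_metrics.mcc)
        wins += diffs[-1] > 0
    assert wins >= 9
    assert np.mean(diffs) > 0


# --- final model and prediction ----------------------------------------------

def test_refit_on_training_data_is_at_least_as_good_as_cv(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    ranked = mrmr.mrmr_rank(small_matrix, labels)
    folds = stratified_folds(labels, seed=1)
    subset = list(ranked.mrmr_order[:10])
    _, cv_metrics = cross_validate(small_matrix, labels, subset, ClassifierSpec(), folds)
    model = train_final(small_matrix, labels, subset)
    pred = model.pipeline.predict(small_matrix.scores[:, subset])
    from essnet.metrics import ConfusionCounts
    train_metrics = compute_metrics(ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    ))
    assert train_metrics.mcc >= cv_metrics.mcc - 1e-9


def test_model_save_load_round_trip(tmp_path, small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    model = train_final(small_matrix, labels, list(range(8)))
    path = tmp_path / "model.joblib"
    model.save(path)
    back = model.load(path)
    assert back.feature_ids == model.feature_ids
    table_a = predict_unlabeled(model, small_matrix)
    table_b = predict_unlabeled(back, small_matrix)
    assert table_a.equals(table_b)


def test_kegg_only_ablation_uses_the_whole_pathway_block(small_matrix, small_dataset):
    """Training on the KEGG feature block alone mirrors the pathway-features
    ablation: the model sees every KEGG column and no GO column."""
    labels = small_dataset.labeled.labels()
    kegg_cols = [j for j, (_, ns) in enumerate(small_matrix.features) if ns == "KEGG"]
    assert len(kegg_cols) == SMALL_CONFIG.n_kegg_terms
    folds = stratified_folds(labels, seed=1)
    confusion, metrics = cross_validate(small_matrix, labels, kegg_cols,
                                        ClassifierSpec(), folds)
    assert confusion.total == len(labels)
    model = train_final(small_matrix, labels, kegg_cols)
    assert all(ns == "KEGG" for _, ns in model.feature_ids)
    assert len(model.feature_ids) == len(kegg_cols)


def test_predict_training_positive_row_as_positive(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    model = train_final(small_matrix, labels, list(range(small_matrix.n_features)))
    pos_gene = small_dataset.labeled.positives[0]
    clone = FeatureMatrix(
        genes=("query",),
        features=small_matrix.features,
        scores=small_matrix.row(pos_gene)[None, :].copy(),
    )
    table = predict_unlabeled(model, clone)
    training_pred = model.pipeline.predict(small_matrix.row(pos_gene)[None, :])
    assert table.label.tolist() == training_pred.tolist()


def test_predict_empty_set_is_empty(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    model = train_final(small_matrix, labels, [0, 1])
    empty = FeatureMatrix(genes=(), features=small_matrix.features,
                          scores=np.empty((0, small_matrix.n_features)))
    table = predict_unlabeled(model, empty)
    assert len(table) == 0
    assert list(table.columns) == ["gene", "label", "decision_value"]


def test_predict_rejects_missing_features(small_matrix, small_dataset):
    labels = small_dataset.labeled.labels()
    model = train_final(small_matrix, labels, [0, 1, 2])
    truncated = FeatureMatrix(
        genes=small_matrix.genes,
        features=small_matrix.features[3:],
        scores=small_matrix.scores[:, 3:],
    )
    with pytest.raises(ValueError, match="missing model feature"):
        predict_unlabeled(model, truncated)


def test_held_out_positive_mechanism_genes_predicted_positive(default_pipeline):
    """Train on most of the labeled genes, score held-out genes generated by
    the positive mechanism: at least 80% come back positive."""
    matrix = default_pipeline["matrix"]
    ds = default_pipeline["dataset"]
    res = default_pipeline["ifs"]
    ranked = default_pipeline["ranking"]
    held_out = list(ds.labeled.positives[-25:])
    train_genes = [g for g in matrix.genes if g not in set(held_out)]
    train_rows = matrix.subset_genes(train_genes)
    train_labels = np.array(
        [1 if g in set(ds.labeled.positives) else 0 for g in train_genes]
    )
    model = train_final(train_rows, train_labels,
                        list(ranked.mrmr_order[: res.optimal_k]))
    table = predict_unlabeled(model, matrix.subset_genes(held_out))
    assert table.label.mean() >= 0.8
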