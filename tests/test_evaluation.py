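"""Folds, aggregation, metrics, ROC/AUC; leakage and invariance properties."""

import numpy as np
import pytest

from nodulegan.evaluation import (
    CaseResult,
    FoldSplit,
    aggregate_case,
    classification_metrics,
    make_folds,
    roc_auc,
)
from nodulegan.volume_io import NoduleAnnotation


def anns(n_benign, n_malignant):
    out = []
    for i in range(n_benign + n_malignant):
        label = "benign" if i < n_benign else "malignant"
        out.append(NoduleAnnotation(f"case{i:03d}", (10, 10, 10), 8.0, label))
    return out


def results_from(scores_benign, scores_malignant):
    out = [CaseResult(f"b{i}", "benign", s) for i, s in enumerate(scores_benign)]
    out += [CaseResult(f"m{i}", "malignant", s) for i, s in enumerate(scores_malignant)]
    return out


def test_threefold_split_is_stratified_9_11():
    folds = make_folds(anns(27, 33), k=3, seed=0)
    labels = {a.case_id: a.label for a in anns(27, 33)}
    for f in range(3):
        cases = folds.fold_cases(f)
        assert sum(labels[c] == "benign" for c in cases) == 9
        assert sum(labels[c] == "malignant" for c in cases) == 11
    # partition: every case exactly once
    assert sorted(c for f in range(3) for c in folds.fold_cases(f)) == sorted(labels)


def test_single_fold_and_determinism():
    a = anns(5, 5)
    assert make_folds(a, k=1, seed=0).assignment == {x.case_id: 0 for x in a}
    assert make_folds(a, k=3, seed=4).assignment == make_folds(a, k=3, seed=4).assignment
    with pytest.raises(ValueError, match="fewer cases"):
        make_folds(anns(2, 5), k=3, seed=0)


def test_aggregate_case_rules():
    r = aggregate_case("c", "malignant", [0.9])
    assert r.probability == 0.9 and r.predicted_label == "malignant"
    r = aggregate_case("c", "benign", [0.2, 0.4])
    assert r.probability == pytest.approx(0.3) and r.predicted_label == "benign"
    r = aggregate_case("c", "benign", [0.7] * 256)
    assert r.probability == pytest.approx(0.7)
    assert aggregate_case("c", "benign", [0.5]).predicted_label == "malignant"  # tie -> malignant
    assert aggregate_case("c", "benign", [0.1, 0.2, 0.9], "median").probability == 0.2
    with pytest.raises(ValueError, match="no patch"):
        aggregate_case("c", "benign", [])


def test_per_class_accuracy_matches_printed_precision():
    # 18 of 27 benign correct, 31 of 33 malignant correct
    benign = [0.1] * 18 + [0.9] * 9  # 9 benign called malignant
    malignant = [0.9] * 31 + [0.1] * 2
    m = classification_metrics(results_from(benign, malignant))
    assert m["benign_accuracy_pct"] == 66.7
    assert m["malignant_accuracy_pct"] == 93.9
    assert m["overall_accuracy_pct"] == round(100 * 49 / 60, 1)


def test_all_correct_gives_100_each():
    m = classification_metrics(results_from([0.0] * 5, [1.0] * 7))
    assert m["benign_accuracy_pct"] == 100.0 and m["malignant_accuracy_pct"] == 100.0


def test_label_swap_symmetry():
    benign = [0.1] * 7 + [0.9] * 3
    malignant = [0.9] * 8 + [0.1] * 2
    m = classification_metrics(results_from(benign, malignant))
    swapped = [CaseResult(r.case_id, "benign" if r.true_label == "malignant" else "malignant", 1 - r.probability - 1e-9 if r.probability == 0.5 else 1 - r.probability) for r in results_from(benign, malignant)]
    ms = classification_metrics(swapped)
    assert ms["benign_accuracy_pct"] == m["malignant_accuracy_pct"]
    assert ms["malignant_accuracy_pct"] == m["benign_accuracy_pct"]


def test_auc_perfect_separation():
    roc = roc_auc(results_from([0.0, 0.1, 0.2], [0.8, 0.9, 1.0]))
    assert roc.auc == 1.0
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)


def test_auc_all_tied_scores_is_half():
    roc = roc_auc(results_from([0.5] * 4, [0.5] * 4))
    assert roc.auc == pytest.approx(0.5)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([CaseResult("a", "benign", 0.2)])


def test_permuted_labels_give_chance_auc():
    """With labels independent of scores, mean AUC over 100 permutations ~ 0.5."""
    rng = np.random.default_rng(0)
    scores = rng.uniform(0, 1, 200)
    aucs = []
    for _ in range(100):
        labels = rng.permutation([0] * 100 + [1] * 100)
        results = [
            CaseResult(f"c{i}", "malignant" if lab else "benign", float(s))
            for i, (s, lab) in enumerate(zip(scores, labels))
        ]
        aucs.append(roc_auc(results).auc)
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    b = rng.uniform(0, 1, 20)
    m = np.clip(rng.uniform(0, 1, 20) * 0.8 + 0.2, 0, 1)
    a1 = roc_auc(results_from(b, m)).auc
    squash = lambda p: p**3  # strictly monotone on [0,1]
    a2 = roc_auc(results_from(squash(b), squash(m))).auc
    assert a1 == pytest.approx(a2)


def test_compare_strategies_deterministic_rows():
    """The same strategy listed twice with shared seeds yields identical rows."""
    from nodulegan.augment import AugmentConfig
    from nodulegan.classifier import ClassifierArch, FinetuneConfig, PretrainConfig
    from nodulegan.evaluation import CVParams, Strategy, compare_strategies
    from nodulegan.phantom import PhantomConfig, generate_cohort
    from nodulegan.wgan import WGANConfig

    cohort = generate_cohort(4, 4, PhantomConfig(), seed=9)
    params = CVParams(
        k=1,
        seed=9,
        augment=AugmentConfig(angle_min=-20, angle_max=20, angle_step=20, symmetry_ops=("r0",)),
        wgan=WGANConfig.tiny(image_size=32, epochs=1, batch_size=8),
        pretrain=PretrainConfig(epochs=1, batch_size=8),
        finetune=FinetuneConfig(epochs=1, lr=0.001, batch_size=8),
        arch=ClassifierArch.tiny(),
        n_generated_per_class=16,
    )
    table, per = compare_strategies(cohort, [Strategy("wgan"), Strategy("wgan")], params)
    assert table.iloc[0].equals(table.iloc[1])
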