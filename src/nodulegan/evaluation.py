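"""Case-level cross-validated evaluation and the pretraining-strategy contrast.

Cases (not images) are the cross-validation unit: every augmented view of a
case inherits the case's fold, which prevents leakage between near-duplicate
views of the same nodule. Folds are stratified by class. Per fold, the
Wasserstein GANs are trained only on that fold's *training* cases flagged
isolated, the classifier is pretrained on GAN-generated images (or not, for
the scratch strategy), fine-tuned on the training patches, and evaluated on
the held-out cases. Per-patch malignant probabilities are aggregated to one
probability per case (mean by default); the headline decision threshold is
0.5 (ties -> malignant), and the ROC sweeps the full threshold range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc
from sklearn.model_selection import StratifiedKFold

from .augment import AXIAL, AugmentConfig, augment_nodule, oblique_slice
from .classifier import (
    ClassifierArch,
    FinetuneConfig,
    NoduleClassifier,
    PretrainConfig,
    finetune,
    predict,
    pretrain,
)
from .phantom import PhantomCase
from .voi import extract_voi
from .wgan import WGANConfig, generate_images, patches_to_wgan_images, sample_latent, train_wgan

LABEL_TO_INT = {"benign": 0, "malignant": 1}


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    k: int
    assignment: dict[str, int]  # case_id -> fold index

    def fold_cases(self, fold: int) -> set[str]:
        return {cid for cid, f in self.assignment.items() if f == fold}


def make_folds(annotations, k: int = 3, seed: int = 0) -> FoldSplit:
    """Stratified case-level partition, deterministic for a fixed seed."""
    ids = [a.case_id for a in annotations]
    labels = [a.label for a in annotations]
    if k == 1:
        return FoldSplit(1, {cid: 0 for cid in ids})
    for lab in set(labels):
        if labels.count(lab) < k:
            raise ValueError(f"class {lab!r} has fewer cases ({labels.count(lab)}) than folds ({k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, labels)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return FoldSplit(k, assignment)


# ---------------------------------------------------------------------------
# per-case aggregation and metrics
# ---------------------------------------------------------------------------


@dataclass
class CaseResult:
    case_id: str
    true_label: str
    probability: float  # aggregated malignant probability

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def predicted_label(self) -> str:
        # ties at the 0.5 threshold are called malignant
        return "malignant" if self.probability >= 0.5 else "benign"


def aggregate_case(case_id: str, true_label: str, patch_probs, method: str = "mean") -> CaseResult:
    """Combine per-patch malignant probabilities into one case-level probability."""
    probs = np.asarray(list(patch_probs), dtype=float)
    if probs.size == 0:
        raise ValueError(f"case {case_id}: no patch probabilities to aggregate")
    if method == "mean":
        p = probs.mean()
    elif method == "median":
        p = float(np.median(probs))
    elif method == "first":
        p = probs[0]
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return CaseResult(case_id, true_label, float(p))


def classification_metrics(results) -> dict:
    """Per-class and overall accuracy, as percentages rounded to one decimal."""
    results = list(results)
    out = {}
    correct_total = 0
    for label in ("benign", "malignant"):
        sub = [r for r in results if r.true_label == label]
        if not sub:
            raise ValueError(f"no {label} cases in results")
        correct = sum(r.predicted_label == r.true_label for r in sub)
        correct_total += correct
        out[f"{label}_accuracy_pct"] = round(100.0 * correct / len(sub), 1)
        out[f"{label}_n"] = len(sub)
    out["overall_accuracy_pct"] = round(100.0 * correct_total / len(results), 1)
    out["n"] = len(results)
    return out


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(results) -> ROCCurve:
    """ROC by sweeping the malignant-probability threshold; AUC by trapezoid."""
    results = list(results)
    y = np.array([LABEL_TO_INT[r.true_label] for r in results])
    scores = np.array([r.probability for r in results])
    if len(set(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return ROCCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# strategy comparison harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Strategy:
    pretraining: str = "wgan"  # "none" (scratch) or "wgan"
    augmented: bool = True

    def __post_init__(self):
        if self.pretraining not in ("none", "wgan"):
            raise ValueError(f"pretraining must be 'none' or 'wgan', got {self.pretraining!r}")

    @property
    def name(self) -> str:
        return ("wgan-pretrained" if self.pretraining == "wgan" else "scratch") + (
            "+aug" if self.augmented else ""
        )


@dataclass
class CVParams:
    """Everything one cross-validated strategy run needs."""

    k: int = 3
    seed: int = 0
    voi_resolution_mm: float = 1.0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    wgan: WGANConfig = field(default_factory=WGANConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    arch: ClassifierArch = field(default_factory=ClassifierArch.paper)
    n_generated_per_class: int = 1000
    aggregate: str = "mean"

    @classmethod
    def tiny(cls, seed: int = 0) -> "CVParams":
        """CPU-scale preset: 32 px images, narrow widths, short schedules.

        The WGAN uses a larger learning rate (5e-4) and a correspondingly
        wider clip box (0.02) than the full-scale defaults: at tiny scale the
        critic must stay informative within a few hundred updates, and with
        the full-scale box the clipped critic saturates before the generator
        receives a usable gradient.
        """
        return cls(
            seed=seed,
            augment=AugmentConfig(angle_step=10, symmetry_ops=("r0", "r90", "r180f", "r270f")),
            wgan=WGANConfig.tiny(image_size=32, epochs=10, lr=5e-4, n_critic=2, clip_value=0.02),
            pretrain=PretrainConfig(epochs=5, lr=0.001, batch_size=32),
            finetune=FinetuneConfig(epochs=3, lr=0.001, batch_size=32),
            arch=ClassifierArch.tiny(),
            n_generated_per_class=128,
        )


def _case_views(voi, config: AugmentConfig, augmented: bool):
    """Training/evaluation views of one VOI; the pure axial section is always first."""
    views = [oblique_slice(voi, AXIAL)]
    if augmented:
        views.extend(augment_nodule(voi, config))
    return views


def _audit_no_leakage(patches, allowed_cases: set[str]):
    bad = {p.source_case for p in patches} - allowed_cases
    if bad:
        raise RuntimeError(f"fold leakage: patches from cases {sorted(bad)} outside their fold")


def run_strategy_cv(cases: list[PhantomCase], strategy: Strategy, params: CVParams):
    """Full per-fold pipeline for one strategy; returns (case results, fold logs)."""
    folds = make_folds([c.annotation for c in cases], params.k, seed=params.seed)
    vois = {
        c.annotation.case_id: extract_voi(c.volume, c.annotation, params.voi_resolution_mm)
        for c in cases
    }
    results: list[CaseResult] = []
    logs = []
    for fold in range(params.k):
        test_ids = folds.fold_cases(fold)
        train_cases = [c for c in cases if c.annotation.case_id not in test_ids]
        test_cases = [c for c in cases if c.annotation.case_id in test_ids]
        if params.k == 1:  # single fold: train and test coincide (smoke/debug mode)
            train_cases = test_cases = cases

        train_patches, train_labels = [], []
        for c in train_cases:
            for v in _case_views(vois[c.annotation.case_id], params.augment, strategy.augmented):
                train_patches.append(v)
                train_labels.append(LABEL_TO_INT[c.annotation.label])
        if params.k > 1:
            _audit_no_leakage(train_patches, {c.annotation.case_id for c in train_cases})

        fold_seed = int(np.random.SeedSequence(params.seed, spawn_key=(fold,)).generate_state(1)[0]) % (2**31)
        if strategy.pretraining == "wgan":
            generated = {}
            for label in ("benign", "malignant"):
                # WGANs see only isolated training nodules of one class,
                # always via the augmented views (they need volume)
                class_patches = []
                for c in train_cases:
                    if c.annotation.label == label and c.annotation.isolated:
                        class_patches.extend(
                            _case_views(vois[c.annotation.case_id], params.augment, augmented=True)
                        )
                imgs = patches_to_wgan_images(class_patches, params.wgan)
                wcfg = replace(params.wgan, seed=fold_seed + (0 if label == "benign" else 1))
                gen, _, _ = train_wgan(imgs, wcfg)
                z = sample_latent(params.n_generated_per_class, wcfg, seed=fold_seed + 100)
                generated[label] = generate_images(gen, z)
            pre_cfg = replace(params.pretrain, seed=fold_seed)
            model, _ = pretrain(generated["benign"], generated["malignant"], pre_cfg, params.arch)
        else:
            model = NoduleClassifier(params.arch, seed=fold_seed)

        ft_cfg = replace(params.finetune, seed=fold_seed)
        tuned = finetune(model, train_patches, train_labels, ft_cfg)

        for c in test_cases:
            views = _case_views(vois[c.annotation.case_id], params.augment, strategy.augmented)
            probs = predict(tuned, views)
            if params.aggregate == "axial":
                result = aggregate_case(c.annotation.case_id, c.annotation.label, [probs[0]], "mean")
            else:
                result = aggregate_case(c.annotation.case_id, c.annotation.label, probs, params.aggregate)
            results.append(result)
        logs.append({"fold": fold, "strategy": strategy.name, "n_train": len(train_cases), "n_test": len(test_cases)})
    return results, logs


def compare_strategies(cases: list[PhantomCase], strategies, params: CVParams):
    """Run each strategy over shared folds/seeds; returns (table, per-strategy results).

    The table has one row per strategy with per-class accuracy, overall
    accuracy and AUC - the shape of a pretraining-method comparison.
    """
    rows = []
    per_strategy = {}
    for strategy in strategies:
        results, _ = run_strategy_cv(cases, strategy, params)
        metrics = classification_metrics(results)
        roc = roc_auc(results)
        per_strategy[strategy.name] = results
        rows.append(
            {
                "strategy": strategy.name,
                "pretraining": strategy.pretraining,
                "augmented": strategy.augmented,
                "benign_accuracy_pct": metrics["benign_accuracy_pct"],
                "malignant_accuracy_pct": metrics["malignant_accuracy_pct"],
                "overall_accuracy_pct": metrics["overall_accuracy_pct"],
                "auc": round(roc.auc, 3),
            }
        )
    return pd.DataFrame(rows), per_strategy
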