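"""Resampled patient-level evaluation protocol.

One evaluation run repeats, over ``n_resamples`` independent random
partitions, the full train/test protocol:

1. stratified patient-level 70/30 split (all nine spectra of a patient
   stay on one side);
2. EMSC reference and preprocessing fitted on the training partition only;
3. class balancing of the training rows (none / up / down / SMOTE);
4. hyperparameter tuning by patient-grouped 5-fold cross-validation,
   maximising spectrum-level Cohen's κ;
5. final fit, per-spectrum scoring of the test partition, per-patient
   majority vote over the nine replicate spectra;
6. patient-level sensitivity, specificity and balanced accuracy.

Summaries are means ± sample SDs (ddof 1) over iterations; per-patient
mean scores are pooled across iterations for the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .chemometrics import (
    ClassifierModel,
    FeatureMatrix,
    balance_classes,
    cohen_kappa,
    fit_classifier,
)
from .preprocess import apply_recipe, clf_recipe
from .spectra_io import SpectralDataset, Spectrum

__all__ = [
    "SplitPlan",
    "ROCCurve",
    "ResampleSummary",
    "DEFAULT_GRIDS",
    "split_patients",
    "tune_hyperparameters",
    "majority_vote",
    "confusion_metrics",
    "fit_split",
    "resample_evaluate",
    "roc_auc",
    "permute_patient_labels",
]

#: Default tuning grids: PLS-DA components 1..20, SVM cost decades, a fixed
#: 500-tree forest (tree count is not tuned).
DEFAULT_GRIDS: dict[str, list] = {
    "plsda": list(range(1, 21)),
    "svm_linear": [0.01, 0.1, 1.0, 10.0, 100.0],
    "rf": [500],
}


@dataclass
class SplitPlan:
    """Resampling design: split fraction, iteration count, CV folds, seed."""

    train_fraction: float = 0.7
    n_resamples: int = 100
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ResampleSummary:
    """Per-iteration metrics, aggregate mean ± SD, pooled ROC."""

    iterations: pd.DataFrame          # sensitivity, specificity, balanced_accuracy, hyper
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    balanced_accuracy_mean: float
    balanced_accuracy_sd: float
    patient_scores: pd.DataFrame      # iteration, patient_id, truth, score
    roc: ROCCurve | None
    model_kind: str
    sampler: str
    positive_class: str
    negative_class: str
    chosen_hyperparameters: list = field(default_factory=list)
    feature_importance: pd.DataFrame | None = None
    n_failed: int = 0


def split_patients(
    dataset: SpectralDataset,
    positive_class: str,
    negative_class: str,
    train_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[str]]:
    """Stratified random patient split; per-class train count = round(f·n)."""
    rng = np.random.default_rng(rng)
    labels = dataset.patient_labels()
    train: list[str] = []
    test: list[str] = []
    for cls in (positive_class, negative_class):
        ids = sorted(p for p, lab in labels.items() if lab == cls)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 patients")
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))  # round half up
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def _grouped_folds(
    patient_ids: Sequence[str], cv_folds: int, rng: np.random.Generator
) -> list[set[str]]:
    """Partition the unique patients into cv_folds random groups."""
    unique = sorted(set(patient_ids))
    if len(unique) < cv_folds:
        raise ValueError(f"fewer patients ({len(unique)}) than folds ({cv_folds})")
    perm = rng.permutation(len(unique))
    return [set(unique[i] for i in chunk) for chunk in np.array_split(perm, cv_folds)]


def tune_hyperparameters(
    fm: FeatureMatrix,
    kind: str,
    grid: Sequence,
    cv_folds: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[object, pd.DataFrame]:
    """Pick the grid point maximising mean spectrum-level κ over grouped CV folds.

    Folds partition *patients*, so the nine pseudo-replicate spectra of a
    patient never straddle a fold boundary. Ties go to the earliest
    (simplest) grid point. Returns (best value, per-grid-point κ table).
    """
    if not grid:
        raise ValueError("empty tuning grid")
    rng = np.random.default_rng(rng)
    if len(grid) == 1:
        return grid[0], pd.DataFrame({"hyper": list(grid), "kappa": [np.nan]})
    folds = _grouped_folds(fm.patient_ids, cv_folds, rng)
    pid = np.array(fm.patient_ids, dtype=object)
    fit_seed = int(rng.integers(2**31))
    mean_kappas = []
    for g in grid:
        kappas = []
        for fold in folds:
            val_mask = np.isin(pid, list(fold))
            train_fm = fm.take(np.where(~val_mask)[0])
            model = fit_classifier(train_fm, kind, g, rng=fit_seed)
            pred = model.predict(fm.X[val_mask])
            kappas.append(cohen_kappa(fm.y01[val_mask], pred))
        mean_kappas.append(float(np.mean(kappas)))
    best = grid[int(np.argmax(mean_kappas))]
    table = pd.DataFrame({"hyper": list(grid), "kappa": mean_kappas})
    return best, table


def majority_vote(
    predictions: Sequence[int], scores: Sequence[float] | None = None, threshold: float = 0.5
) -> int:
    """Modal class over one patient's spectra.

    A binary vote over an odd count (the usual nine spectra) cannot tie;
    an even-count tie is broken by the patient's mean score against the
    model threshold.
    """
    predictions = np.asarray(predictions, dtype=int)
    if predictions.size == 0:
        raise ValueError("majority_vote needs at least one prediction")
    n_pos = int(predictions.sum())
    n_neg = len(predictions) - n_pos
    if n_pos > n_neg:
        return 1
    if n_neg > n_pos:
        return 0
    if scores is None:
        raise ValueError("tied vote needs scores for the tie-break")
    return int(float(np.mean(scores)) >= threshold)


def confusion_metrics(
    truths: Sequence[int], predictions: Sequence[int]
) -> tuple[float, float, float]:
    """Patient-level (sensitivity %, specificity %, balanced accuracy %).

    Sensitivity refers to the positive class (encoded 1), specificity to
    the negative class (encoded 0).
    """
    t = np.asarray(truths, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if not (t == 1).any() or not (t == 0).any():
        raise ValueError("both classes must be present among the truths")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return sens, spec, (sens + spec) / 2.0


def _training_reference(
    train: SpectralDataset, reference_class: str | None
) -> Spectrum:
    """EMSC reference: mean training spectrum (optionally of one class)."""
    source = train if reference_class is None else train.subset_classes([reference_class])
    if not source.spectra:
        raise ValueError(f"no training spectra for reference class {reference_class!r}")
    return source.mean_spectrum(spectrum_id="emsc_reference")


def fit_split(
    dataset: SpectralDataset,
    train_patients: Sequence[str],
    test_patients: Sequence[str],
    positive_class: str,
    negative_class: str,
    model_kind: str,
    sampler: str = "none",
    grid: Sequence | None = None,
    cv_folds: int = 5,
    rng: np.random.Generator | int | None = None,
    reference_class: str | None = None,
    smote_k: int = 5,
) -> dict:
    """Run the protocol once on a fixed patient split.

    Everything estimated from data — the EMSC reference, the balancing
    draws, the tuned hyperparameter, the model — depends on the training
    patients only; test spectra are only ever scored.
    """
    rng = np.random.default_rng(rng)
    if grid is None:
        grid = DEFAULT_GRIDS[model_kind]
    train_ds = dataset.subset_patients(train_patients).subset_classes(
        [positive_class, negative_class]
    )
    test_ds = dataset.subset_patients(test_patients).subset_classes(
        [positive_class, negative_class]
    )
    reference = _training_reference(train_ds, reference_class)
    recipe = clf_recipe(reference)
    train_fm = FeatureMatrix.from_dataset(
        apply_recipe(train_ds, recipe), positive_class, negative_class
    )
    test_fm = FeatureMatrix.from_dataset(
        apply_recipe(test_ds, recipe), positive_class, negative_class
    )
    balanced = balance_classes(train_fm, sampler, k=smote_k, rng=rng)
    best, _ = tune_hyperparameters(balanced, model_kind, grid, cv_folds=cv_folds, rng=rng)
    model = fit_classifier(balanced, model_kind, best, rng=rng)

    scores = model.score(test_fm.X)
    preds = model.predict(test_fm.X)
    pid = np.array(test_fm.patient_ids, dtype=object)
    records = []
    for patient in sorted(set(test_fm.patient_ids)):
        mask = pid == patient
        vote = majority_vote(preds[mask], scores[mask], threshold=model.threshold)
        truth = int(test_fm.y01[mask][0])
        records.append(
            {
                "patient_id": patient,
                "truth": truth,
                "prediction": vote,
                "score": float(np.mean(scores[mask])),
            }
        )
    patients = pd.DataFrame(records)
    sens, spec, ba = confusion_metrics(patients["truth"], patients["prediction"])
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": ba,
        "patients": patients,
        "hyper": best,
        "model": model,
        "reference": reference,
    }


def resample_evaluate(
    dataset: SpectralDataset,
    model_kind: str,
    sampler: str,
    plan: SplitPlan,
    positive_class: str,
    negative_class: str,
    grid: Sequence | None = None,
    reference_class: str | None = None,
    max_failure_fraction: float = 0.1,
) -> ResampleSummary:
    """Repeat the split/tune/fit/vote protocol over ``plan.n_resamples`` partitions.

    Each iteration draws its own child seed (master seed with the
    iteration index mixed in) so any single iteration is independently
    reproducible. An iteration that raises is recorded and skipped; the
    run aborts if more than ``max_failure_fraction`` of iterations fail.
    """
    rows = []
    patient_frames = []
    chosen = []
    importances = []
    failures: list[tuple[int, str]] = []
    for it in range(plan.n_resamples):
        rng = np.random.default_rng(np.random.SeedSequence(plan.seed, spawn_key=(it,)))
        try:
            train_p, test_p = split_patients(
                dataset, positive_class, negative_class, plan.train_fraction, rng
            )
            result = fit_split(
                dataset,
                train_p,
                test_p,
                positive_class,
                negative_class,
                model_kind,
                sampler=sampler,
                grid=grid,
                cv_folds=plan.cv_folds,
                rng=rng,
                reference_class=reference_class,
            )
        except (ValueError, RuntimeError) as exc:
            failures.append((it, str(exc)))
            if len(failures) > max_failure_fraction * plan.n_resamples:
                raise RuntimeError(
                    f"{len(failures)}/{plan.n_resamples} iterations failed; "
                    f"first failure (iteration {failures[0][0]}): {failures[0][1]}"
                ) from exc
            continue
        rows.append(
            {
                "iteration": it,
                "sensitivity": result["sensitivity"],
                "specificity": result["specificity"],
                "balanced_accuracy": result["balanced_accuracy"],
                "hyper": result["hyper"],
            }
        )
        chosen.append(result["hyper"])
        pf = result["patients"].copy()
        pf.insert(0, "iteration", it)
        patient_frames.append(pf)
        model: ClassifierModel = result["model"]
        if model.feature_importance is not None:
            importances.append(model.feature_importance)
    if not rows:
        raise RuntimeError("all resample iterations failed")
    iterations = pd.DataFrame(rows)
    pooled = pd.concat(patient_frames, ignore_index=True)
    roc = None
    if pooled["truth"].nunique() == 2:
        roc = roc_auc(pooled["score"].to_numpy(), pooled["truth"].to_numpy())

    def _sd(col: str) -> float:
        return float(iterations[col].std(ddof=1)) if len(iterations) > 1 else 0.0

    importance_df = None
    if importances:
        fm_axis = None
        # wavenumbers of the binned features, recomputed from any iteration's model
        # via the pooled reference recipe would repeat work; reuse the dataset axis
        # bins instead (clf recipe: cut 1000-1800, bin 8).
        from .preprocess import Bin, Cut, apply_recipe_spectrum

        probe = apply_recipe_spectrum(dataset.spectra[0], [Cut(1000.0, 1800.0), Bin(8)])
        fm_axis = probe.wavenumbers
        imp = np.mean(np.stack(importances), axis=0)
        if len(imp) == len(fm_axis):
            importance_df = pd.DataFrame(
                {"wavenumber_cm-1": fm_axis, "importance": imp}
            ).sort_values("importance", ascending=False, ignore_index=True)

    return ResampleSummary(
        iterations=iterations,
        sensitivity_mean=float(iterations["sensitivity"].mean()),
        sensitivity_sd=_sd("sensitivity"),
        specificity_mean=float(iterations["specificity"].mean()),
        specificity_sd=_sd("specificity"),
        balanced_accuracy_mean=float(iterations["balanced_accuracy"].mean()),
        balanced_accuracy_sd=_sd("balanced_accuracy"),
        patient_scores=pooled,
        roc=roc,
        model_kind=model_kind,
        sampler=sampler,
        positive_class=positive_class,
        negative_class=negative_class,
        chosen_hyperparameters=chosen,
        feature_importance=importance_df,
        n_failed=len(failures),
    )


def roc_auc(scores: Sequence[float], truths: Sequence[int]) -> ROCCurve:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Tied scores step simultaneously; the curve runs from (0, 0) to (1, 1).
    The AUC equals the Mann-Whitney U statistic normalised by n₁·n₂.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    if len(np.unique(truths)) < 2:
        raise ValueError("ROC needs both classes among the truths")
    if np.ptp(scores) == 0:
        # degenerate sweep: one simultaneous step through all patients
        return ROCCurve(
            thresholds=np.array([np.inf, scores[0]]),
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            auc=0.5,
        )
    fpr, tpr, thresholds = roc_curve(truths, scores)
    return ROCCurve(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr))
    )


def permute_patient_labels(
    dataset: SpectralDataset, rng: np.random.Generator | int | None = None
) -> SpectralDataset:
    """Shuffle class labels across patients (all nine spectra move together).

    Null-calibration helper: any real class signal is destroyed while the
    patient/replicate structure and label marginals are preserved.
    """
    rng = np.random.default_rng(rng)
    labels = dataset.patient_labels()
    patients = sorted(labels)
    values = [labels[p] for p in patients]
    perm = rng.permutation(len(patients))
    new_label = {patients[i]: values[perm[i]] for i in range(len(patients))}
    return SpectralDataset(
        [s.replace(label=new_label[s.patient_id]) for s in dataset.spectra]
    )
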