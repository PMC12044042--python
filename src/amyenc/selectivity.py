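"""Selectivity of synthesized stimuli for their targeted regions.

Every retained stimulus is fed back through the fixed feature extractor
and scored by every encoding model, producing a cross-response table
(stimuli x (subject, region) predicted region-average activations).  Three
analyses quantify selectivity:

* an on/off-target regression per evaluated subject (on-target indicator,
  synthesis-subject block, and the five standardized low-level visual
  covariates), with a group t test on the on-target coefficient;
* a multiway PLS-DA classification of the targeted region from the
  cross-response vector, generalization estimated by leave-one-subject-out
  folds over the synthesizing subject, summarized by a row-normalized
  confusion matrix and an agglomerative confusion clustering that merges
  class pairs until all remaining cluster pairs are statistically
  discriminable (binomial test of pairwise accuracy against 0.5,
  Bonferroni-corrected);
* a randomization control in which amygdala voxels are randomly assigned
  to sets, set-mean coefficient targets synthesized and re-classified,
  yielding a percentile null interval for the classification accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import EncodingModel
from .image_features import FEATURE_COLUMNS, image_features
from .pls import plsda_decision_values, plsda_fit
from .synthesis import (
    SynthesisResult,
    SynthesisTarget,
    convergence_filter,
    make_target,
    synthesize_one,
)
from .synthetic import ToyNetworks

logger = logging.getLogger(__name__)


@dataclass
class CrossResponseTable:
    """Predicted activations of every stimulus in every encoding model.

    ``responses`` has one row per retained stimulus and a MultiIndex column
    per (subject, region) model; ``meta`` carries the stimulus metadata
    (target region/subject, seed) and the five low-level visual features.
    """

    responses: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_stimuli(self) -> int:
        return len(self.responses)

    def response_matrix(self, columns=None) -> np.ndarray:
        sub = self.responses if columns is None else self.responses[columns]
        return sub.to_numpy(dtype=float)


def build_cross_response_table(
    results: list[SynthesisResult],
    models: "dict[tuple[str, str], EncodingModel]",
    networks: ToyNetworks,
    compute_lowlevel: bool = True,
) -> CrossResponseTable:
    """Score every stimulus image under every encoding model.

    Features are re-extracted from the rendered images (the same path used
    for naturalistic stimuli); each cell is the mean predicted activation
    over the model's voxels.  Stimuli without a stored image are skipped
    with a log message.
    """
    from .affect import predict_image_response

    usable = []
    for res in results:
        if res.final_image is None:
            logger.warning("skipping stimulus without a rendered image")
            continue
        usable.append(res)
    if not usable:
        raise ValueError("no usable stimuli")
    feats = np.stack([networks.extract(r.final_image) for r in usable])
    cols = {}
    for (subject, region), model in models.items():
        _, avg = predict_image_response(model, feats)
        cols[(subject, region)] = avg
    responses = pd.DataFrame(cols)
    responses.columns = pd.MultiIndex.from_tuples(
        responses.columns, names=["subject", "region"]
    )
    meta = pd.DataFrame(
        {
            "stimulus_id": np.arange(len(usable)),
            "target_region": [r.target_region for r in usable],
            "target_subject": [r.target_subject for r in usable],
            "seed": [r.seed for r in usable],
            "final_objective": [r.final_objective for r in usable],
        }
    )
    if compute_lowlevel:
        ll = pd.DataFrame([image_features(r.final_image) for r in usable])
        meta = pd.concat([meta, ll], axis=1)
    return CrossResponseTable(responses=responses, meta=meta)


def _zscore_cols(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep, out = [], []
    for j, name in enumerate(names):
        sd = X[:, j].std(ddof=1)
        if sd < 1e-12:
            logger.warning("dropping zero-variance covariate %s", name)
            continue
        keep.append((X[:, j] - X[:, j].mean()) / sd)
        out.append(name)
    if not keep:
        return np.empty((X.shape[0], 0)), []
    return np.column_stack(keep), out


def on_off_target_regression(
    table: CrossResponseTable, evaluated_region: str
) -> dict:
    """Does each subject's model respond more to its on-target stimuli?

    For every evaluated subject, the subject's ``evaluated_region``
    response column is regressed on an on/off-target indicator, a
    synthesis-subject indicator block, and the five standardized low-level
    features; the on-target coefficients are then tested against zero
    across subjects (one-sample t, Cohen's d).
    """
    on = (table.meta["target_region"] == evaluated_region).to_numpy(dtype=float)
    if on.sum() == 0 or on.sum() == len(on):
        raise ValueError("need both on- and off-target stimuli")
    synth_subjects = pd.get_dummies(table.meta["target_subject"], drop_first=True)
    low = table.meta[FEATURE_COLUMNS].to_numpy(dtype=float)
    low_z, _ = _zscore_cols(low, FEATURE_COLUMNS)
    X = np.column_stack(
        [np.ones(len(on)), on, synth_subjects.to_numpy(dtype=float), low_z]
    )
    subjects = sorted({s for s, _ in table.responses.columns})
    betas = {}
    for subject in subjects:
        y = table.responses[(subject, evaluated_region)].to_numpy(dtype=float)
        if y.std() == 0:
            betas[subject] = 0.0
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        betas[subject] = float(coef[1])
    vals = np.array(list(betas.values()))
    n = vals.size
    sd = vals.std(ddof=1) if n > 1 else 0.0
    if sd > 0:
        t = vals.mean() / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        d = vals.mean() / sd
    else:
        t, p, d = 0.0, 1.0, 0.0
    return {
        "evaluated_region": evaluated_region,
        "subject_betas": betas,
        "mean_beta": float(vals.mean()),
        "t": float(t),
        "p": p,
        "d": float(d),
        "n_subjects": n,
    }


@dataclass
class ConfusionSummary:
    """LOSO classification outcome: confusion, accuracies, fold predictions."""

    class_labels: np.ndarray
    confusion: pd.DataFrame  # row-normalized, rows = true class
    accuracy_mean: float
    accuracy_se: float
    fold_accuracies: np.ndarray
    per_class_accuracy: pd.Series
    predictions: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    # predictions columns: fold, true, pred + one score column per class


def loso_classify(
    X: np.ndarray,
    labels,
    subjects,
    n_components: int = 7,
) -> ConfusionSummary:
    """Leave-one-subject-out PLS-DA classification.

    Folds are defined by ``subjects`` (the subject whose models generated
    each stimulus).  Test samples of a class absent from a fold's training
    data are skipped with a log message.  The confusion matrix is
    row-normalized over true classes; accuracy is reported as mean +/- SE
    over folds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    fold_ids = np.unique(subjects)
    if fold_ids.size < 2:
        raise ValueError("need at least two synthesis subjects for LOSO folds")
    counts = np.zeros((classes.size, classes.size))
    fold_acc = []
    pred_rows = []
    for fold in fold_ids:
        test = subjects == fold
        train = ~test
        train_classes = set(np.unique(labels[train]))
        usable = test & np.isin(labels, sorted(train_classes))
        n_skip = int(test.sum() - usable.sum())
        if n_skip:
            logger.warning(
                "fold %s: %d test stimuli of unseen classes skipped", fold, n_skip
            )
        if usable.sum() == 0:
            continue
        k = min(n_components, int(train.sum()) - 1, X.shape[1])
        model = plsda_fit(X[train], labels[train], n_components=k)
        scores = plsda_decision_values(model, X[usable])
        pred = model.class_labels[np.argmax(scores, axis=1)]
        true = labels[usable]
        fold_acc.append(float((pred == true).mean()))
        for t_lab, p_lab in zip(true, pred):
            counts[np.searchsorted(classes, t_lab), np.searchsorted(classes, p_lab)] += 1
        score_full = np.full((int(usable.sum()), classes.size), -np.inf)
        col_idx = np.searchsorted(classes, model.class_labels)
        score_full[:, col_idx] = scores
        for i in range(score_full.shape[0]):
            row = {"fold": fold, "true": true[i], "pred": pred[i]}
            row.update({f"score_{c}": score_full[i, j] for j, c in enumerate(classes)})
            pred_rows.append(row)
    fold_acc = np.asarray(fold_acc)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 0.0)
    per_class = pd.Series(np.diag(norm), index=classes)
    confusion = pd.DataFrame(norm, index=classes, columns=classes)
    se = fold_acc.std(ddof=1) / np.sqrt(fold_acc.size) if fold_acc.size > 1 else 0.0
    return ConfusionSummary(
        class_labels=classes,
        confusion=confusion,
        accuracy_mean=float(fold_acc.mean()),
        accuracy_se=float(se),
        fold_accuracies=fold_acc,
        per_class_accuracy=per_class,
        predictions=pd.DataFrame(pred_rows),
    )


def loso_classification(
    table: CrossResponseTable,
    n_components: int = 7,
    classes: "list | None" = None,
    response_columns=None,
) -> ConfusionSummary:
    """Classify the targeted region from the cross-response vector.

    ``classes`` restricts the analysis to stimuli targeting those regions;
    ``response_columns`` restricts the feature columns (default: all
    models).
    """
    meta = table.meta
    mask = np.ones(len(meta), dtype=bool)
    if classes is not None:
        mask = meta["target_region"].isin(classes).to_numpy()
    X = table.response_matrix(response_columns)[mask]
    return loso_classify(
        X,
        meta["target_region"].to_numpy()[mask],
        meta["target_subject"].to_numpy()[mask],
        n_components=n_components,
    )


def _pair_discriminability(
    predictions: pd.DataFrame,
    cluster_a: tuple,
    cluster_b: tuple,
    classes: np.ndarray,
) -> tuple[float, int, int]:
    """Held-out two-cluster accuracy and its binomial p-value vs 0.5."""
    members = set(cluster_a) | set(cluster_b)
    rows = predictions[predictions["true"].isin(members)]
    if len(rows) == 0:
        return 1.0, 0, 0
    score_a = rows[[f"score_{c}" for c in cluster_a]].max(axis=1)
    score_b = rows[[f"score_{c}" for c in cluster_b]].max(axis=1)
    pred_is_a = (score_a.to_numpy() >= score_b.to_numpy())
    true_is_a = rows["true"].isin(cluster_a).to_numpy()
    k = int((pred_is_a == true_is_a).sum())
    n = len(rows)
    p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return float(p), k, n


def confusion_cluster(
    summary: ConfusionSummary, alpha: float = 0.05
) -> dict:
    """Merge classes until all cluster pairs are statistically discriminable.

    Starting from singleton clusters, every cluster pair is tested for
    discriminability: held-out predictions restricted to the pair are
    rescored by the larger of each cluster's member class scores, and the
    resulting two-way accuracy is tested against 0.5 with a one-sided
    binomial test at ``alpha`` Bonferroni-corrected over the current
    number of pairs.  While any pair fails, the least-discriminable pair
    (largest p) is merged and all pairs retested.

    Returns a dict with ``clusters`` (tuple of class tuples), ``n_clusters``
    and ``assignments`` (class -> cluster index).
    """
    classes = summary.class_labels
    if classes.size == 1:
        return {"clusters": (tuple(classes),), "n_clusters": 1,
                "assignments": {classes[0]: 0}}
    if summary.predictions.empty:
        raise ValueError("fold-level predictions are required for clustering")
    clusters = [(c,) for c in classes]
    while len(clusters) > 1:
        pairs = list(combinations(range(len(clusters)), 2))
        m = len(pairs)
        pvals = []
        for i, j in pairs:
            p, _, _ = _pair_discriminability(
                summary.predictions, clusters[i], clusters[j], classes
            )
            pvals.append(p)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha / m:
            break
        i, j = pairs[worst]
        merged = tuple(clusters[i]) + tuple(clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: str(c[0]))
    assignments = {c: idx for idx, cl in enumerate(clusters) for c in cl}
    return {
        "clusters": tuple(tuple(c) for c in clusters),
        "n_clusters": len(clusters),
        "assignments": assignments,
    }


def randomization_control(
    amy_models: "dict[str, EncodingModel]",
    networks: ToyNetworks,
    n_sets: int = 4,
    n_iter: int = 40,
    seed: int = 0,
    n_seeds_per_target: int = 1,
    population: int = 16,
    generations: int = 25,
    init_sigma: float = 1.0,
    n_components: int | None = None,
) -> dict:
    """Null distribution of classification accuracy for random voxel sets.

    Each iteration assigns every amygdala voxel (independently per subject)
    to one of ``n_sets`` sets, averages each subject's encoding-model
    coefficients within each set to form synthesis targets, synthesizes
    stimuli, and classifies the targeted set with leave-one-subject-out
    PLS-DA on the stimuli's responses under every subject's set targets.
    The returned interval is the empirical 2.5/97.5 percentile band.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = sorted(amy_models)
    if n_components is None:
        n_components = n_sets
    accuracies = []
    for it in range(n_iter):
        try:
            acc = _randomization_iteration(
                amy_models,
                networks,
                subjects,
                n_sets,
                rng,
                n_seeds_per_target,
                population,
                generations,
                init_sigma,
                n_components,
            )
        except Exception:
            logger.exception("randomization iteration %d failed; dropped", it)
            continue
        accuracies.append(acc)
    accuracies = np.asarray(accuracies)
    lo, hi = np.percentile(accuracies, [2.5, 97.5])
    return {
        "accuracies": accuracies,
        "mean": float(accuracies.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_iter": int(accuracies.size),
        "chance": 1.0 / n_sets,
    }


def _randomization_iteration(
    amy_models,
    networks,
    subjects,
    n_sets,
    rng,
    n_seeds_per_target,
    population,
    generations,
    init_sigma,
    n_components,
):
    # per-subject random partition of amygdala voxels into sets
    targets: dict[tuple[str, int], SynthesisTarget] = {}
    for subject in subjects:
        model = amy_models[subject]
        v = model.n_voxels
        assign = rng.integers(0, n_sets, size=v)
        # guarantee every set is non-empty
        for s_idx in range(n_sets):
            if not np.any(assign == s_idx):
                assign[rng.integers(0, v)] = s_idx
        for s_idx in range(n_sets):
            tgt = make_target(model, np.flatnonzero(assign == s_idx))
            tgt = SynthesisTarget(
                beta=tgt.beta, subject_id=subject, region=f"set{s_idx}"
            )
            targets[(subject, s_idx)] = tgt
    results = []
    for (subject, s_idx), tgt in targets.items():
        for _ in range(n_seeds_per_target):
            run_seed = int(rng.integers(0, 2**31 - 1))
            results.append(
                synthesize_one(
                    networks,
                    tgt,
                    seed=run_seed,
                    population=population,
                    generations=generations,
                    init_sigma=init_sigma,
                )
            )
    retained = convergence_filter(results)
    if len(retained) < 2 * n_sets:
        raise RuntimeError("too few converged stimuli in this iteration")
    feats = np.stack([networks.extract(r.final_image) for r in retained])
    # responses of every stimulus under every subject's set-mean targets
    cols = [feats @ targets[(subject, s_idx)].beta
            for subject in subjects for s_idx in range(n_sets)]
    X = np.column_stack(cols)
    labels = np.array([r.target_region for r in retained])
    stim_subjects = np.array([r.target_subject for r in retained])
    out = loso_classify(X, labels, stim_subjects, n_components=n_components)
    return out.accuracy_mean
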