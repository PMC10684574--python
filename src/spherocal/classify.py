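"""Phenotype discrimination: PCA, balanced split, random forest, radar.

The retained peak parameters are standardized and reduced with PCA,
keeping the smallest number of components whose cumulative explained
variance exceeds 85%.  Samples are then split 80/20 (stratified), and
the split is redrawn until no per-feature t-test between train and test
and no per-class two-proportion z-test falls below alpha = 0.05 — the
balance checks that guard against an unlucky split.  A random-forest
classifier (500 trees) is trained on the component scores and reported
as a row-percentage confusion matrix on the held-out test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)


class ClassifyError(ValueError):
    """Raised for unusable classification inputs."""


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame              # samples x kept components
    loadings: pd.DataFrame            # features x kept components
    explained_variance_ratio: np.ndarray
    n_components: int
    dropped_features: list[str]
    dropped_rows: list
    variance_target: float


@dataclass(frozen=True)
class SplitReport:
    train_index: np.ndarray
    test_index: np.ndarray
    feature_pvalues: dict[str, float]
    class_pvalues: dict[str, float]
    attempts: int
    passed: bool


@dataclass(frozen=True)
class ClassificationReport:
    confusion_pct: pd.DataFrame       # rows: true class (percentages)
    confusion_counts: pd.DataFrame
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    seed: int
    n_estimators: int


def run_pca(
    features: pd.DataFrame, variance_target: float = 0.85
) -> PCAResult:
    """Standardize features and keep components explaining > the target.

    Rows with missing values are dropped (logged) and constant features
    removed with a warning before standardization.  Components are kept
    up to the smallest count whose cumulative explained variance
    exceeds ``variance_target``.
    """
    complete = features.dropna(axis=0)
    dropped_rows = [i for i in features.index if i not in complete.index]
    if dropped_rows:
        logger.info("PCA: dropped %d rows with missing values", len(dropped_rows))
    constant = [c for c in complete.columns if complete[c].nunique() <= 1]
    if constant:
        logger.warning("PCA: dropping constant features %s", constant)
    x = complete.drop(columns=constant)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ClassifyError("PCA needs >= 2 complete samples and >= 2 varying features")

    z = StandardScaler().fit_transform(x.to_numpy(dtype=float))
    pca = PCA()
    all_scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cum, variance_target) + 1)
    n_components = min(n_components, all_scores.shape[1])

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(all_scores[:, :n_components], index=x.index, columns=comp_names)
    loadings = pd.DataFrame(
        pca.components_[:n_components].T, index=x.columns, columns=comp_names
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_[:n_components],
        n_components=n_components,
        dropped_features=constant,
        dropped_rows=dropped_rows,
        variance_target=variance_target,
    )


def balanced_split(
    scores: pd.DataFrame,
    labels: pd.Series,
    train_frac: float = 0.80,
    alpha: float = 0.05,
    seed: int = 0,
    max_attempts: int = 200,
) -> SplitReport:
    """Stratified 80/20 split, redrawn until the balance checks pass.

    Per feature, a two-sample t-test compares train vs test values; per
    class, a two-proportion z-test compares the class frequency in the
    two partitions.  The split is accepted when every p-value is at
    least ``alpha``; sub-seeds are drawn deterministically from ``seed``
    so the procedure is reproducible.
    """
    labels = labels.loc[scores.index]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ClassifyError("need >= 2 classes to split")
    counts = labels.value_counts()
    if (counts < 5).any():
        raise ClassifyError(f"every class needs >= 5 samples; got {counts.to_dict()}")

    rng = np.random.default_rng(seed)
    best_min_p = -np.inf
    for attempt in range(1, max_attempts + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = train_test_split(
            np.asarray(scores.index, dtype=object),
            train_size=train_frac,
            stratify=labels.to_numpy(),
            random_state=sub_seed,
        )
        feature_p: dict[str, float] = {}
        for col in scores.columns:
            a = scores.loc[train_idx, col]
            b = scores.loc[test_idx, col]
            feature_p[col] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        class_p: dict[str, float] = {}
        for cls in classes:
            count = np.array([
                (labels.loc[train_idx] == cls).sum(),
                (labels.loc[test_idx] == cls).sum(),
            ])
            nobs = np.array([len(train_idx), len(test_idx)])
            _, p = proportions_ztest(count, nobs)
            class_p[str(cls)] = 1.0 if np.isnan(p) else float(p)
        min_p = min(list(feature_p.values()) + list(class_p.values()))
        if min_p >= alpha:
            return SplitReport(
                train_index=np.asarray(train_idx),
                test_index=np.asarray(test_idx),
                feature_pvalues=feature_p,
                class_pvalues=class_p,
                attempts=attempt,
                passed=True,
            )
        best_min_p = max(best_min_p, min_p)
    raise ClassifyError(
        f"no balanced split in {max_attempts} attempts "
        f"(best minimum p-value {best_min_p:.4f})"
    )


def train_and_classify(
    scores: pd.DataFrame,
    labels: pd.Series,
    split: SplitReport,
    n_estimators: int = 500,
    seed: int = 0,
) -> ClassificationReport:
    """Train a random forest on the train partition, score the test set.

    Defaults: 500 trees, unlimited depth, sqrt(k) features per split,
    fixed seed.  The confusion matrix is reported with rows (true
    classes) normalized to percentages; a class absent from the test
    partition gets a missing row and a flag in the log.
    """
    labels = labels.loc[scores.index]
    classes = sorted(labels.unique())
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        max_depth=None,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(scores.loc[split.train_index], labels.loc[split.train_index])
    y_true = labels.loc[split.test_index]
    y_pred = pd.Series(clf.predict(scores.loc[split.test_index]), index=split.test_index)

    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        counts.loc[t, p] += 1
    pct = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    per_class: dict[str, float] = {}
    for cls in classes:
        row_n = counts.loc[cls].sum()
        if row_n == 0:
            logger.warning("class %r missing from the test partition", cls)
            per_class[str(cls)] = float("nan")
            continue
        pct.loc[cls] = 100.0 * counts.loc[cls] / row_n
        per_class[str(cls)] = float(pct.loc[cls, cls])
    overall = float((y_true.to_numpy() == y_pred.to_numpy()).mean())
    return ClassificationReport(
        confusion_pct=pct,
        confusion_counts=counts,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        seed=seed,
        n_estimators=n_estimators,
    )


def radar_summary(
    normalized: pd.DataFrame, plate_map: pd.DataFrame
) -> pd.DataFrame:
    """Group-mean table behind radar plots (groups x parameters).

    Expects a percent-of-control table, so the vehicle-control group
    averages 100 per parameter.  Empty groups are omitted with a
    warning.
    """
    pm = plate_map.set_index("well")
    groups = pm.loc[[w for w in normalized.index if w in pm.index], "group"]
    rows = {}
    for group in dict.fromkeys(groups):
        wells = groups.index[groups == group]
        if len(wells) == 0:
            logger.warning("radar summary: empty group %r omitted", group)
            continue
        rows[group] = normalized.loc[wells].mean(skipna=True)
    return pd.DataFrame(rows).T
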