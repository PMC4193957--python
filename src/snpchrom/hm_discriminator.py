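"""Discriminating risk from neutral SNPs with histone-modification levels.

Per-SNP HM levels (normalised tag counts in a 200-bp window) feed per-mark
Welch t-tests, a random ten-portion 70/30 split, a least-squares linear
classifier whose intercept is fixed at 1, and ROC/AUC evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .genomic_io import GenomicSite, SnpRecord, TagSet

logger = logging.getLogger(__name__)

RISK_LABELS = frozenset({"risk_coding", "risk_noncoding", "risk"})


@dataclass
class FeatureMatrix:
    """Rows = SNPs, columns = HM types; labels are 'risk' or 'neutral'."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must match the number of rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, idx], self.labels, tuple(names))

    def take(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[rows], self.labels[rows], self.feature_names)


@dataclass
class ClassifierResult:
    """Fitted linear classifier with test scores and ROC/AUC.

    The reported parameter set is normalised so the constant term equals 1
    (:meth:`normalized_params`); ranking, and therefore the ROC curve and
    AUC, are unaffected by that rescaling.
    """

    slopes: np.ndarray
    intercept: float
    scores: np.ndarray
    test_labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    split_seed: int

    def normalized_params(self) -> tuple[float, np.ndarray]:
        """(constant, slopes) with the constant forced to 1 where possible."""
        if self.intercept == 0.0:
            logger.warning("zero intercept; parameters cannot be normalised to 1")
            return 0.0, self.slopes
        return 1.0, self.slopes / self.intercept


def _group_label(record: SnpRecord) -> str | None:
    if record.risk_label in RISK_LABELS:
        return "risk"
    if record.risk_label == "neutral":
        return "neutral"
    return None


def hm_levels(
    tagsets: Mapping[str, TagSet],
    snps: Sequence[SnpRecord],
    window: int = 200,
    genome_length: int | None = None,
    shifts: Mapping[str, int] | int = 0,
) -> FeatureMatrix:
    """HM level per SNP: shift-aligned 5'-end counts in the SNP window,
    divided by genome-average coverage.

    Only records labelled risk or neutral contribute rows.  ``shifts`` moves
    plus-strand 5' ends right and minus-strand 5' ends left by the per-mark
    shift before counting (one integer applies to every mark).
    """
    if genome_length is None or genome_length <= 0:
        raise ValueError("genome_length must be a positive integer")
    half = window // 2
    rows = [(rec, _group_label(rec)) for rec in snps]
    rows = [(rec, lab) for rec, lab in rows if lab is not None]
    if not rows:
        raise ValueError("no risk or neutral records among the SNPs")
    names = tuple(tagsets.keys())
    X = np.zeros((len(rows), len(names)))
    for j, name in enumerate(names):
        tags = tagsets[name]
        shift = shifts if isinstance(shifts, int) else shifts.get(name, 0)
        positions: dict[str, list[int]] = {}
        for iv in tags.intervals:
            eff = iv.five_prime + (-shift if iv.strand == "-" else shift)
            positions.setdefault(iv.chrom, []).append(eff)
        index = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in positions.items()}
        coverage = tags.total_tag_count / genome_length
        if coverage == 0:
            continue
        for i, (rec, _) in enumerate(rows):
            arr = index.get(rec.site.chrom)
            if arr is None:
                continue
            lo = np.searchsorted(arr, rec.site.pos - half)
            hi = np.searchsorted(arr, rec.site.pos + half)  # half-open window
            X[i, j] = (hi - lo) / coverage
    labels = np.array([lab for _, lab in rows])
    return FeatureMatrix(X, labels, names)


def differential_hm_test(matrix: FeatureMatrix) -> pd.DataFrame:
    """Welch t-test of each HM column between risk and neutral rows.

    Returns a DataFrame (hm, t, p, p_bonferroni) sorted by raw p-value.
    """
    risk = matrix.X[matrix.labels == "risk"]
    neutral = matrix.X[matrix.labels == "neutral"]
    if len(risk) < 2 or len(neutral) < 2:
        raise ValueError("need at least two rows per group")
    rows = []
    k = len(matrix.feature_names)
    for j, name in enumerate(matrix.feature_names):
        res = stats.ttest_ind(risk[:, j], neutral[:, j], equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # zero variance in both groups, equal means
            t, p = 0.0, 1.0
        rows.append({"hm": name, "t": t, "p": p, "p_bonferroni": min(1.0, p * k)})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)


def split_ten_portions(
    matrix: FeatureMatrix, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Shuffle rows, split into ten near-equal portions, 7 train / 3 test."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.n)
    portions = np.array_split(perm, 10)
    train_idx = np.concatenate(portions[:7])
    test_idx = np.concatenate(portions[7:])
    return matrix.take(train_idx), matrix.take(test_idx)


def fit_linear_classifier(train: FeatureMatrix) -> tuple[float, np.ndarray]:
    """Ordinary least-squares fit of 0/1 labels on the features.

    Returns ``(intercept, slopes)`` for ``score(x) = intercept + w.x``; the
    reported parameter set (:meth:`ClassifierResult.normalized_params`)
    rescales so the constant term is 1, which cannot change the ranking.  A
    singular design falls back to the minimum-norm solution with a warning.
    """
    y = (train.labels == "risk").astype(float)
    design = np.column_stack([np.ones(train.n), train.X])
    params, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "singular design matrix (rank %d < %d); using minimum-norm solution",
            rank, design.shape[1],
        )
    return float(params[0]), params[1:]


def classifier_scores(X: np.ndarray, slopes: np.ndarray, intercept: float = 0.0) -> np.ndarray:
    return intercept + np.asarray(X, dtype=float) @ slopes


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points (threshold sweep, ties shared) and trapezoid AUC.

    Equals the Mann-Whitney pairwise statistic: the probability that a
    random risk score exceeds a random neutral score, counting ties as 1/2.
    """
    y = np.asarray(labels) == "risk"
    if y.all() or not y.any():
        raise ValueError("need both risk and neutral labels for a ROC curve")
    fpr, tpr, thresholds = _roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr, thresholds, float(_trapezoid_auc(fpr, tpr))


def train_and_evaluate(
    matrix: FeatureMatrix,
    seed: int,
    features: Sequence[str] | None = None,
) -> ClassifierResult:
    """Split, fit and evaluate one classifier; one result per seed."""
    work = matrix if features is None else matrix.subset_features(features)
    train, test = split_ten_portions(work, seed)
    intercept, slopes = fit_linear_classifier(train)
    scores = classifier_scores(test.X, slopes, intercept)
    fpr, tpr, thresholds, auc_value = roc_auc(scores, test.labels)
    return ClassifierResult(
        slopes=slopes,
        intercept=intercept,
        scores=scores,
        test_labels=test.labels,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc_value,
        split_seed=seed,
    )
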