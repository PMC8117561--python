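"""Expression normalization, the TIL score, tertile grouping, LMS subgroup
rules and subtype-component association.

The tumor-infiltrating leukocyte (TIL) score of sample i is the median over
the immune-signature genes j of log2(count_ij / (median_j(count) + 0.01)),
the cohort median taken per gene. For counts well above 1, a score of 0
means the sample sits at the cohort-typical immune infiltration level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "TILScorer",
    "TILScores",
    "LMSGroups",
    "normalize_upper_quartile",
    "relative_expression",
    "til_score",
    "tertile_groups",
    "assign_lms_groups",
    "point_biserial",
]

ZERO_FLOOR = 0.01  # floor for zero counts before any log-ratio
TERTILE_LABELS = ("low", "medium", "high")


def normalize_upper_quartile(raw_counts: pd.DataFrame, target: float = 1000.0) -> pd.DataFrame:
    """Scale each sample so the 75th percentile of its nonzero counts equals
    ``target``. The target constant only shifts all per-sample relative-log
    values uniformly, so any positive value is equivalent downstream."""
    counts = raw_counts.astype(float)
    scaled = {}
    for col in counts.columns:
        vals = counts[col].to_numpy()
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {col!r} has no nonzero counts")
        q75 = float(np.percentile(nonzero, 75))
        scaled[col] = vals * (target / q75)
    return pd.DataFrame(scaled, index=counts.index)


def relative_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Per gene: log2(count / cohort median of that gene).

    Zero counts and zero medians are floored at 0.01 so the log stays
    finite; no other pseudocount enters.
    """
    if counts.shape[1] < 2:
        raise ValueError("relative expression needs a cohort of >= 2 samples")
    vals = np.maximum(counts.to_numpy(dtype=float), ZERO_FLOOR)
    med = np.maximum(np.median(vals, axis=1, keepdims=True), ZERO_FLOOR)
    return pd.DataFrame(np.log2(vals / med), index=counts.index, columns=counts.columns)


class TILScorer(TransformerMixin, BaseEstimator):
    """Median log-ratio immune score over a signature gene set.

    scikit-learn convention: ``X`` is (n_samples, n_genes) with the gene
    names given at construction (or a DataFrame whose columns are genes).
    ``fit`` learns the cohort medians of the signature genes; ``transform``
    returns the per-sample score median_j log2(x_ij / (median_j + 0.01)).
    Signature genes absent from the data are dropped with a warning.
    """

    def __init__(self, signature_genes=None):
        self.signature_genes = signature_genes

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        frame = self._frame(X)
        genes = list(self.signature_genes) if self.signature_genes is not None else list(frame.columns)
        present = [g for g in genes if g in frame.columns]
        absent = sorted(set(genes) - set(present))
        if absent:
            logger.warning("TIL score: %d signature genes absent from counts: %s",
                           len(absent), absent[:5])
        if not present:
            raise ValueError("no signature gene present in the count matrix")
        self.genes_ = present
        self.medians_ = frame[present].median(axis=0).to_numpy(dtype=float)
        return self

    def transform(self, X) -> np.ndarray:
        frame = self._frame(X)
        vals = np.maximum(frame[self.genes_].to_numpy(dtype=float), ZERO_FLOOR)
        ratios = np.log2(vals / (self.medians_[None, :] + ZERO_FLOOR))
        return np.median(ratios, axis=1)


@dataclass
class TILScores:
    score: pd.Series  # per sample
    tertile: pd.Series  # low / medium / high


def til_score(counts: pd.DataFrame, signature_genes) -> pd.Series:
    """Per-sample TIL score from a genes x samples count matrix."""
    scorer = TILScorer(signature_genes=signature_genes).fit(counts.T)
    return pd.Series(scorer.transform(counts.T), index=counts.columns, name="til_score")


def tertile_groups(scores: pd.Series) -> pd.Series:
    """Split samples into three contiguous score-ordered groups.

    Sizes differ by at most one; remainders go to low, then medium. Tied
    scores are broken by sample id (lexicographic), so the partition is
    deterministic.
    """
    n = len(scores)
    if n < 3:
        raise ValueError(f"tertile grouping needs >= 3 samples, got {n}")
    order = scores.to_frame("score").assign(sample=scores.index.astype(str))
    order = order.sort_values(["score", "sample"], kind="mergesort")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.repeat(TERTILE_LABELS, sizes)
    return pd.Series(labels, index=order.index, name="tertile").reindex(scores.index)


def score_tertiles(counts: pd.DataFrame, signature_genes) -> TILScores:
    """Convenience: TIL scores plus their tertile labels."""
    s = til_score(counts, signature_genes)
    return TILScores(score=s, tertile=tertile_groups(s))


@dataclass
class LMSGroups:
    group: pd.Series  # 1, 2 or 3 per sample
    stlms: pd.Series
    ulms: pd.Series


def assign_lms_groups(
    proportions: pd.DataFrame,
    stlms_component,
    ulms_component,
    threshold: float = 0.2,
) -> LMSGroups:
    """Rule-based LMS subgrouping from two component-proportion rows.

    Group 3: both proportions < threshold. Group 1: STLMS-associated
    proportion > ULMS-associated and > threshold. Group 2: the converse.
    The measure-zero residual (equal proportions >= threshold) goes to
    group 2 and is logged.
    """
    stlms = proportions.loc[stlms_component]
    ulms = proportions.loc[ulms_component]
    groups = pd.Series(index=proportions.columns, dtype=int, name="lms_group")
    for sample in proportions.columns:
        s, u = float(stlms[sample]), float(ulms[sample])
        if s < threshold and u < threshold:
            groups[sample] = 3
        elif s > u and s > threshold:
            groups[sample] = 1
        elif u > s and u > threshold:
            groups[sample] = 2
        else:  # s == u >= threshold
            logger.info("LMS groups: tie at %s (stlms=ulms=%.3f) -> group 2", sample, s)
            groups[sample] = 2
    return LMSGroups(group=groups, stlms=stlms, ulms=ulms)


def point_biserial(proportion_row, binary_labels) -> float:
    """Pearson correlation between a proportion vector and a 0/1 indicator."""
    x = np.asarray(proportion_row, dtype=float)
    y = np.asarray(binary_labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("proportions and labels must have the same length")
    if len(set(y.tolist())) < 2:
        raise ValueError("binary labels contain a single class")
    if x.std() == 0:
        raise ValueError("proportion vector has zero variance")
    return float(np.corrcoef(x, y)[0, 1])
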