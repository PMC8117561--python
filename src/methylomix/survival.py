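"""Tertile-stratified survival comparison: Kaplan-Meier curves, the
log-rank test, BH adjustment, and single-gene expression scans.

Estimation and testing delegate to lifelines (product-limit estimator and
Mantel-Haenszel log-rank); this module fixes the pipeline's conventions:
upper vs lower expression tertile, ties handled by the standard
hypergeometric variance with multiplicities, subjects censored exactly at
an event time counted as at risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .expression import tertile_groups

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "SurvivalTestResult",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "single_gene_survival_scan",
    "cox_univariable",
]


@dataclass
class SurvivalData:
    """Follow-up times, event flags (1 = death observed) and group labels."""

    time: pd.Series
    event: pd.Series
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.time < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event flags must be 0 (censored) or 1 (event)")


@dataclass
class SurvivalTestResult:
    statistic: float
    p: float
    groups_compared: tuple
    n_per_group: tuple


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival, n_at_risk) table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "n_at_risk": at_risk.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(data: SurvivalData, group_a, group_b) -> SurvivalTestResult:
    """Mantel-Haenszel log-rank comparison of two labelled groups."""
    if data.group is None:
        raise ValueError("SurvivalData carries no group labels")
    mask_a = data.group == group_a
    mask_b = data.group == group_b
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na == 0 or nb == 0:
        raise ValueError(f"both groups need >= 1 subject (got {na}, {nb})")
    total_events = int(data.event[mask_a].sum() + data.event[mask_b].sum())
    if total_events == 0:
        raise ValueError("log-rank undefined without any observed event")
    res = _ll_logrank(
        data.time[mask_a], data.time[mask_b],
        event_observed_A=data.event[mask_a], event_observed_B=data.event[mask_b],
    )
    return SurvivalTestResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        groups_compared=(group_a, group_b),
        n_per_group=(na, nb),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def single_gene_survival_scan(
    expression: pd.DataFrame, gene_list, survival: SurvivalData
) -> pd.DataFrame:
    """Upper-vs-lower expression-tertile log-rank per gene, BH across genes.

    ``expression`` is genes x samples; samples are matched to the survival
    index. Genes absent from the matrix are skipped with a warning.
    Returns a DataFrame (gene, p, p_adjusted) sorted by adjusted p.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene_list must be nonempty")
    samples = expression.columns.intersection(survival.time.index)
    rows = []
    for gene in gene_list:
        if gene not in expression.index:
            logger.warning("survival scan: gene %s absent from expression", gene)
            continue
        tert = tertile_groups(expression.loc[gene, samples])
        data = SurvivalData(
            time=survival.time[samples], event=survival.event[samples], group=tert
        )
        res = logrank_test(data, "high", "low")
        rows.append((gene, res.p))
    if not rows:
        raise ValueError("no gene from gene_list present in the expression matrix")
    out = pd.DataFrame(rows, columns=["gene", "p"])
    out["p_adjusted"] = bh_adjust(out["p"])
    return out.sort_values(["p_adjusted", "p", "gene"], ignore_index=True)


def cox_univariable(times, events, covariate) -> pd.DataFrame:
    """Thin wrapper: univariable Cox regression on one continuous predictor."""
    frame = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int),
         "x": np.asarray(covariate, float)}
    )
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    return cph.summary
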