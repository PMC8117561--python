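"""Component-specific VMRs, gene-level methylation, and expression-correlated
gene signatures.

A window is a variably methylated region (VMR) for a component when its
deconvolved beta differs from *every* other component by strictly more than
a threshold (default 0.2): hypomethylated if below all others, symmetric
for hypermethylated. VMR windows are mapped to genes through the probe
annotation; per-gene mean methylation of VMR-resident probes is then
correlated with relative expression across samples, yielding four
categories by (direction, sign of r). The core signature keeps the two
"upregulation" patterns: hypomethylated with r < -threshold (category a)
and hypermethylated with r > +threshold (category d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VMRSet",
    "LMCSignature",
    "extract_vmrs",
    "gene_level_methylation",
    "derive_signature",
    "promoter_fraction",
]

CATEGORY_BY_PATTERN = {
    ("hypo", -1): "a",
    ("hyper", -1): "b",
    ("hypo", 1): "c",
    ("hyper", 1): "d",
}
CORE_CATEGORIES = frozenset({"a", "d"})


@dataclass
class VMRSet:
    """Per-component hypo/hypermethylated windows.

    ``entries`` is a DataFrame with columns ``component``, ``window_id``,
    ``direction`` and ``delta_to_nearest_other`` (signed: negative for
    hypo, positive for hyper).
    """

    entries: pd.DataFrame
    threshold: float = 0.2

    def windows(self, component, direction: str | None = None) -> list:
        sel = self.entries["component"] == component
        if direction is not None:
            sel &= self.entries["direction"] == direction
        return list(self.entries.loc[sel, "window_id"])

    def directions(self, component) -> dict:
        sub = self.entries[self.entries["component"] == component]
        return dict(zip(sub["window_id"], sub["direction"]))


@dataclass
class LMCSignature:
    """Correlation-filtered gene signature of one component.

    ``genes``: DataFrame with columns gene, component, direction,
    pearson_r, category (a-d) and in_core; plus the skipped genes with a
    reason. Core signature = categories a and d (upregulation patterns).
    """

    genes: pd.DataFrame
    component: object
    r_threshold: float = 0.3
    skipped: pd.DataFrame | None = None

    @property
    def core_genes(self) -> list:
        return list(self.genes.loc[self.genes["in_core"], "gene"])


def extract_vmrs(t, threshold: float = 0.2) -> VMRSet:
    """Component-specific windows by the strict all-others separation rule.

    Window w is hypomethylated for component k iff
    ``t[w, k] < t[w, l] - threshold`` for every l != k (strict inequality;
    a difference of exactly ``threshold`` does not qualify); symmetric for
    hypermethylated. Only the argmin/argmax component of a row can qualify,
    so hypo and hyper sets are disjoint per component by construction.
    """
    frame = t if isinstance(t, pd.DataFrame) else pd.DataFrame(np.asarray(t, dtype=float))
    vals = frame.to_numpy(dtype=float)
    if vals.ndim != 2 or vals.shape[1] < 2:
        raise ValueError("need a windows x K matrix with K >= 2 (no 'other' components otherwise)")
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("component betas must lie in [0, 1]")
    order = np.sort(vals, axis=1)
    lo, lo2 = order[:, 0], order[:, 1]
    hi, hi2 = order[:, -1], order[:, -2]
    rows = []
    hypo_mask = lo < lo2 - threshold
    hyper_mask = hi > hi2 + threshold
    for w in np.flatnonzero(hypo_mask):
        k = int(np.argmin(vals[w]))
        rows.append((frame.columns[k], frame.index[w], "hypo", float(vals[w, k] - lo2[w])))
    for w in np.flatnonzero(hyper_mask):
        k = int(np.argmax(vals[w]))
        rows.append((frame.columns[k], frame.index[w], "hyper", float(vals[w, k] - hi2[w])))
    entries = pd.DataFrame(
        rows, columns=["component", "window_id", "direction", "delta_to_nearest_other"]
    )
    return VMRSet(entries=entries, threshold=threshold)


def _window_of(chrom: pd.Series, pos: pd.Series, window_size: int) -> pd.Series:
    start = (pos // window_size) * window_size
    return chrom.astype(str) + ":" + start.astype(int).astype(str) + "-" + (
        start + window_size
    ).astype(int).astype(str)


def gene_level_methylation(
    probes,
    vmr_set: VMRSet,
    probe_gene_map: pd.DataFrame,
    component,
    window_size: int = 5000,
) -> pd.DataFrame:
    """Mean beta per gene over probes inside the component's VMR windows.

    ``probe_gene_map`` has columns ``probe_id`` and ``gene``; probes
    annotated to several genes appear as several rows and contribute to
    every annotated gene. Genes with no qualifying probe are absent.
    """
    beta = probes.beta
    ann = probes.annotation.loc[beta.index]
    vmr_windows = set(vmr_set.windows(component))
    probe_window = _window_of(ann["chrom"], ann["pos"], window_size)
    in_vmr = probe_window.isin(vmr_windows)
    qualifying = beta.index[in_vmr.to_numpy()]
    pairs = probe_gene_map[
        probe_gene_map["probe_id"].isin(qualifying) & (probe_gene_map["gene"] != "")
    ]
    if pairs.empty:
        return pd.DataFrame(columns=beta.columns)
    expanded = beta.loc[pairs["probe_id"]]
    expanded.index = pairs["gene"].to_numpy()
    return expanded.groupby(level=0).mean()


def derive_signature(
    gene_betas: pd.DataFrame,
    relative_expression: pd.DataFrame,
    vmr_directions: dict,
    component=None,
    r_threshold: float = 0.3,
    min_samples: int = 3,
) -> LMCSignature:
    """Pearson-correlate per-gene VMR methylation with relative expression.

    ``vmr_directions`` maps gene -> 'hypo'/'hyper'. Samples are matched on
    the column intersection; each gene needs at least ``min_samples``
    paired samples with nonzero variance on both sides, otherwise it is
    skipped with a logged reason. Genes with |r| <= r_threshold are
    dropped; categories: a = hypo/negative, b = hyper/negative,
    c = hypo/positive, d = hyper/positive; core = {a, d}.
    """
    shared = gene_betas.columns.intersection(relative_expression.columns)
    rows, skipped = [], []
    for gene, direction in vmr_directions.items():
        if gene not in gene_betas.index or gene not in relative_expression.index:
            skipped.append((gene, "missing methylation or expression"))
            continue
        x = gene_betas.loc[gene, shared].to_numpy(dtype=float)
        y = relative_expression.loc[gene, shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_samples:
            skipped.append((gene, f"fewer than {min_samples} paired samples"))
            continue
        if x.std() == 0 or y.std() == 0:
            skipped.append((gene, "zero variance"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) <= r_threshold:
            continue
        category = CATEGORY_BY_PATTERN[(direction, 1 if r > 0 else -1)]
        rows.append((gene, component, direction, r, category, category in CORE_CATEGORIES))
    for gene, reason in skipped:
        logger.info("signature: skipped %s (%s)", gene, reason)
    genes = pd.DataFrame(
        rows, columns=["gene", "component", "direction", "pearson_r", "category", "in_core"]
    ).sort_values("gene", ignore_index=True)
    return LMCSignature(
        genes=genes,
        component=component,
        r_threshold=r_threshold,
        skipped=pd.DataFrame(skipped, columns=["gene", "reason"]),
    )


def promoter_fraction(
    vmr_probe_positions: pd.DataFrame, promoter_annotation: pd.DataFrame
) -> float:
    """Fraction of VMR probes falling inside any promoter interval.

    Promoters span 1000 bp upstream to 100 bp downstream of the TSS,
    strand-adjusted: ``[tss-1000, tss+100)`` on plus-strand genes,
    ``[tss-100, tss+1000)`` on minus-strand genes (upstream increases in
    coordinates). ``vmr_probe_positions`` needs columns chrom and pos;
    ``promoter_annotation`` needs gene, chrom, strand and tss.
    """
    if "strand" not in promoter_annotation.columns:
        raise ValueError("promoter annotation requires a strand column")
    if vmr_probe_positions.empty:
        return float("nan")
    strands = set(promoter_annotation["strand"])
    if not strands <= {"+", "-"}:
        raise ValueError(f"unknown strand values: {strands - {'+', '-'}}")
    plus = promoter_annotation["strand"] == "+"
    starts = np.where(
        plus, promoter_annotation["tss"] - 1000, promoter_annotation["tss"] - 100
    )
    ends = np.where(
        plus, promoter_annotation["tss"] + 100, promoter_annotation["tss"] + 1000
    )
    chroms = promoter_annotation["chrom"].to_numpy()
    in_promoter = np.zeros(len(vmr_probe_positions), dtype=bool)
    pos = vmr_probe_positions["pos"].to_numpy()
    pchrom = vmr_probe_positions["chrom"].to_numpy()
    for c in np.unique(chroms):
        sel = chroms == c
        psel = pchrom == c
        if not psel.any():
            continue
        hit = (
            (pos[psel, None] >= starts[None, sel]) & (pos[psel, None] < ends[None, sel])
        ).any(axis=1)
        in_promoter[psel] |= hit
    return float(in_promoter.mean())
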