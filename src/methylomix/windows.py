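"""Probe-level filtering and aggregation of beta values into genomic windows.

Coordinates are 0-based, half-open throughout; the genome is tiled into
``[k*w, (k+1)*w)`` bins anchored at position 0 of each chromosome. Windows
without any probe are absent from the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "WindowMatrix",
    "filter_probes",
    "aggregate_windows",
    "mean_sample_methylation",
]

DEFAULT_DROP_CHROMS = frozenset({"chrX", "chrY"})


@dataclass
class ProbeMatrix:
    """Beta values (probes x samples) plus per-probe annotation.

    ``annotation`` must be indexed by probe_id and carry at least
    ``chrom``, ``pos`` (0-based) and ``is_cpg`` columns; betas lie in
    [0, 1] where present (NaN marks missing measurements).
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.is_unique:
            raise ValueError("probe ids must be unique")
        missing = self.beta.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack annotation, e.g. {missing[0]!r}")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class WindowMatrix:
    """Window-averaged betas: the deconvolution input D.

    Row index is ``chrom:start-end``; ``probe_members`` maps each window id
    to the probe ids averaged into it.
    """

    beta: pd.DataFrame
    probe_members: dict = field(default_factory=dict)
    window_size: int = 5000

    @property
    def values(self) -> np.ndarray:
        return self.beta.to_numpy(dtype=float)


def filter_probes(probes: ProbeMatrix, drop_chroms=DEFAULT_DROP_CHROMS) -> ProbeMatrix:
    """Complete-case, autosomal, CpG-context probe filter.

    Retains probes that (i) have measurements in every sample, (ii) are not
    on ``drop_chroms`` (default sex chromosomes), and (iii) are CpG-context.
    """
    ann = probes.annotation.loc[probes.beta.index]
    keep = (
        probes.beta.notna().all(axis=1)
        & ~ann["chrom"].isin(set(drop_chroms))
        & ann["is_cpg"].astype(bool)
    )
    if not keep.any():
        raise ValueError(
            "no probes survive filtering (complete-case, autosomal, CpG); "
            "inputs are unusable for windowed deconvolution"
        )
    kept = probes.beta.index[keep]
    return ProbeMatrix(beta=probes.beta.loc[kept], annotation=ann.loc[kept])


def aggregate_windows(probes: ProbeMatrix, window_size: int = 5000) -> WindowMatrix:
    """Average probe betas over fixed genomic bins.

    Each probe falls in exactly one bin ``[k*w, (k+1)*w)`` of its
    chromosome; the window beta is the arithmetic mean of its member
    probes, per sample. Only windows with at least one probe are kept.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    ann = probes.annotation.loc[probes.beta.index]
    if (ann["pos"] < 0).any():
        raise ValueError("probe positions must be nonnegative")
    bin_start = (ann["pos"] // window_size) * window_size
    window_id = (
        ann["chrom"].astype(str)
        + ":"
        + bin_start.astype(int).astype(str)
        + "-"
        + (bin_start + window_size).astype(int).astype(str)
    )
    grouped = probes.beta.groupby(window_id.to_numpy()).mean()
    # sort genomically: by chromosome then start
    starts = grouped.index.str.split("[:-]").str[1].astype(int)
    chroms = grouped.index.str.split(":").str[0]
    order = pd.DataFrame({"chrom": chroms, "start": starts}, index=grouped.index)
    grouped = grouped.loc[order.sort_values(["chrom", "start"]).index]
    members = {
        wid: list(probes.beta.index[(window_id == wid).to_numpy()])
        for wid in grouped.index
    }
    return WindowMatrix(beta=grouped, probe_members=members, window_size=window_size)


def mean_sample_methylation(probes: ProbeMatrix) -> pd.Series:
    """Per-sample arithmetic mean beta over all retained probes.

    Group comparisons of these means (e.g. between LMS subgroups) are a
    plain two-sample Wilcoxon rank-sum test; use
    ``scipy.stats.mannwhitneyu`` on the returned values.
    """
    if probes.beta.shape[0] == 0:
        raise ValueError("need at least one probe")
    return probes.beta.mean(axis=0)
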