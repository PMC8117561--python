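"""Gene-level alteration calling, fusion filtering, and TIL-tertile
enrichment with Fisher's exact test and Fisher's method.

Per gene and alteration type, samples with at least one alteration in the
upper TIL tertile are compared against the lower tertile (the medium
tertile is excluded from testing, but displayed in oncoprints) with a
two-sided Fisher's exact test. Genes with any per-type p < 0.2 are kept;
p-values of genes altered in two or more types are combined with Fisher's
method (chi-square on -2*sum(log p), df = 2m), and the final p < 0.2 gate
is applied again. No correction across genes is performed — the screen is
exploratory by design and results carry an ``exploratory`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, log

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "AlterationTable",
    "EnrichmentResult",
    "filter_fusions",
    "gene_cna_calls",
    "fisher_exact_2x2",
    "fisher_method",
    "enrichment_scan",
    "oncoprint_order",
]

ALTERATION_TYPES = ("snv", "indel", "amplification", "deletion", "fusion")
P_GATE = 0.2

# MAF variant classes treated as silent / non-coding and excluded on ingest
SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)
INDEL_CLASSES = frozenset(
    {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}
)


@dataclass
class AlterationTable:
    """Deduplicated (sample, gene, type) events with provenance.

    A gene counts once per sample per alteration type regardless of how
    many raw events support it.
    """

    events: pd.DataFrame  # columns: sample, gene, type
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.events["type"]) - set(ALTERATION_TYPES)
        if bad:
            raise ValueError(f"unknown alteration types: {sorted(bad)}")
        self.events = self.events.drop_duplicates(
            subset=["sample", "gene", "type"], ignore_index=True
        )

    @classmethod
    def concat(cls, tables) -> "AlterationTable":
        provenance = {}
        for t in tables:
            provenance.update(t.provenance)
        return cls(
            events=pd.concat([t.events for t in tables], ignore_index=True),
            provenance=provenance,
        )


def maf_to_events(maf: pd.DataFrame, source: str = "maf") -> AlterationTable:
    """Non-silent SNV/indel events from a MAF-like table.

    Expects columns ``sample``, ``gene`` and ``variant_classification``;
    silent/non-coding classes are dropped, frameshift/in-frame classes map
    to type 'indel', everything else to 'snv'.
    """
    required = {"sample", "gene", "variant_classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF table lacks columns: {sorted(missing)}")
    kept = maf[~maf["variant_classification"].isin(SILENT_CLASSES)]
    kind = np.where(kept["variant_classification"].isin(INDEL_CLASSES), "indel", "snv")
    events = pd.DataFrame(
        {"sample": kept["sample"], "gene": kept["gene"], "type": kind}
    )
    return AlterationTable(
        events=events, provenance={source: "non-silent SNV/indel ingest"}
    )


def filter_fusions(
    fusions: pd.DataFrame, max_gene_recurrence: int = 20
) -> pd.DataFrame:
    """Arriba-output support filter plus recurrent-gene removal.

    Keeps rows with ``split_reads1 + split_reads2 > max(1,
    discordant_mates / 10)``, then removes every row of any gene that
    appears (in either partner position) in more than
    ``max_gene_recurrence`` distinct samples.
    """
    required = {"sample", "gene1", "gene2", "split_reads1", "split_reads2", "discordant_mates"}
    missing = required - set(fusions.columns)
    if missing:
        raise ValueError(f"fusion table lacks columns: {sorted(missing)}")
    support = fusions["split_reads1"] + fusions["split_reads2"]
    kept = fusions[support > np.maximum(1.0, fusions["discordant_mates"] / 10.0)]
    long = pd.concat(
        [
            kept[["sample", "gene1"]].rename(columns={"gene1": "gene"}),
            kept[["sample", "gene2"]].rename(columns={"gene2": "gene"}),
        ]
    ).drop_duplicates()
    recurrence = long.groupby("gene")["sample"].nunique()
    too_common = set(recurrence[recurrence > max_gene_recurrence].index)
    if too_common:
        kept = kept[~(kept["gene1"].isin(too_common) | kept["gene2"].isin(too_common))]
    return kept.reset_index(drop=True)


def fusions_to_events(fusions: pd.DataFrame, source: str = "fusions") -> AlterationTable:
    """One 'fusion' event per (sample, partner gene) of a filtered table."""
    long = pd.concat(
        [
            fusions[["sample", "gene1"]].rename(columns={"gene1": "gene"}),
            fusions[["sample", "gene2"]].rename(columns={"gene2": "gene"}),
        ]
    )
    events = long.assign(type="fusion")
    return AlterationTable(events=events, provenance={source: "filtered fusion ingest"})


def gene_cna_calls(
    segments: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    amp_threshold: float = 0.3,
    del_threshold: float = -0.3,
    source: str = "segments",
) -> AlterationTable:
    """Gene-level amplification/deletion calls from segmented copy number.

    A gene is amplified in a sample if any overlapping segment's log2
    ratio >= ``amp_threshold`` and deleted if any <= ``del_threshold``
    (0-based half-open intervals). Precomputed gene-level calls can bypass
    this by building an :class:`AlterationTable` directly.
    """
    for frame, cols in ((segments, {"sample", "chrom", "start", "end", "log2_ratio"}),
                        (gene_intervals, {"gene", "chrom", "start", "end"})):
        missing = cols - set(frame.columns)
        if missing:
            raise ValueError(f"table lacks columns: {sorted(missing)}")
    if (segments["end"] <= segments["start"]).any() or (
        gene_intervals["end"] <= gene_intervals["start"]
    ).any():
        raise ValueError("malformed intervals: end must exceed start")
    rows = []
    for chrom, genes_c in gene_intervals.groupby("chrom"):
        segs_c = segments[segments["chrom"] == chrom]
        if segs_c.empty:
            continue
        s_start = segs_c["start"].to_numpy()
        s_end = segs_c["end"].to_numpy()
        ratio = segs_c["log2_ratio"].to_numpy(dtype=float)
        samp = segs_c["sample"].to_numpy()
        for _, g in genes_c.iterrows():
            overlap = (s_start < g["end"]) & (s_end > g["start"])
            for s, r in zip(samp[overlap], ratio[overlap]):
                if r >= amp_threshold:
                    rows.append((s, g["gene"], "amplification"))
                elif r <= del_threshold:
                    rows.append((s, g["gene"], "deletion"))
    events = pd.DataFrame(rows, columns=["sample", "gene", "type"])
    return AlterationTable(
        events=events,
        provenance={source: f"CNA thresholds amp>={amp_threshold}, del<={del_threshold}"},
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test by exact hypergeometric summation.

    Sums, in exact rational arithmetic, the probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's; exact arithmetic makes the two-sided tie rule
    unambiguous. Returns a float in (0, 1].
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: Fraction(comb(c1, x) * comb(n - c1, r1 - x), denom) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(min(1, sum(p for p in probs.values() if p <= p_obs)))


def fisher_method(p_values) -> float:
    """Fisher's combined probability: chi-square on -2*sum(ln p), df = 2m."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * float(np.sum(np.log(p)))
    return float(chi2.sf(stat, 2 * p.size))


@dataclass
class EnrichmentResult:
    """Per-gene tertile-enrichment outcome across alteration types."""

    gene: str
    tables: dict  # type -> 2x2 [[alt_upper, alt_lower], [unalt_upper, unalt_lower]]
    p_by_type: dict  # type -> two-sided Fisher p
    combined_p: float
    n_types_tested: int
    retained: bool
    direction: str  # 'high' or 'low': tertile with the higher altered fraction
    exploratory: bool = True


def enrichment_scan(
    alterations: AlterationTable, tertiles: pd.Series
) -> list[EnrichmentResult]:
    """Upper-vs-lower tertile Fisher screen over every altered gene.

    ``tertiles`` maps sample -> 'low'/'medium'/'high' and must cover every
    sample carrying events. Returns one result per gene that passes the
    first p < 0.2 gate in any type; ``retained`` marks the final gate
    after Fisher's-method combination across types.
    """
    events = alterations.events
    unknown = set(events["sample"]) - set(tertiles.index)
    if unknown:
        raise ValueError(f"samples missing tertile labels: {sorted(unknown)[:5]}")
    upper = set(tertiles.index[tertiles == "high"])
    lower = set(tertiles.index[tertiles == "low"])
    if not upper or not lower:
        raise ValueError("both upper and lower tertiles must be nonempty")
    n_up, n_lo = len(upper), len(lower)

    results = []
    for gene, gdf in events.groupby("gene"):
        tables, p_by_type = {}, {}
        best_type, best_p = None, None
        for alt_type, tdf in gdf.groupby("type"):
            altered = set(tdf["sample"])
            au = len(altered & upper)
            al = len(altered & lower)
            table = [[au, al], [n_up - au, n_lo - al]]
            p = fisher_exact_2x2(table)
            tables[alt_type] = table
            p_by_type[alt_type] = p
            if best_p is None or p < best_p:
                best_p, best_type = p, alt_type
        if not any(p < P_GATE for p in p_by_type.values()):
            continue
        if len(p_by_type) >= 2:
            combined = fisher_method(list(p_by_type.values()))
        else:
            combined = next(iter(p_by_type.values()))
        au, al = tables[best_type][0]
        direction = "high" if au / n_up >= al / n_lo else "low"
        results.append(
            EnrichmentResult(
                gene=gene,
                tables=tables,
                p_by_type=p_by_type,
                combined_p=combined,
                n_types_tested=len(p_by_type),
                retained=combined < P_GATE,
                direction=direction,
            )
        )
    results.sort(key=lambda r: (r.combined_p, r.gene))
    return results


def oncoprint_order(
    results: list[EnrichmentResult],
    alterations: AlterationTable,
    tertiles: pd.Series,
    group_of_interest: str = "low",
    max_genes: int = 10,
) -> tuple[list[str], list[str]]:
    """Gene and sample orders for an oncoprint display.

    Genes: up to ``max_genes`` retained genes with the smallest combined p,
    then sorted by the number of altered samples within the TIL group of
    interest (descending). Samples: within each tertile (low, medium,
    high), memo-sorted for mutual exclusivity — the gene x sample
    alteration indicator is read as a binary number with the most-altered
    gene as the most significant digit, and columns sort descending.
    """
    retained = [r for r in results if r.retained]
    retained.sort(key=lambda r: (r.combined_p, r.gene))
    chosen = retained[:max_genes]
    events = alterations.events
    interest = set(tertiles.index[tertiles == group_of_interest])

    def altered_in_interest(gene: str) -> int:
        return events.loc[events["gene"] == gene, "sample"].pipe(
            lambda s: len(set(s) & interest)
        )

    genes = sorted(
        (r.gene for r in chosen),
        key=lambda g: (-altered_in_interest(g), g),
    )

    indicator = pd.DataFrame(
        0, index=genes, columns=list(tertiles.index), dtype=int
    )
    for _, row in events[events["gene"].isin(genes)].iterrows():
        indicator.loc[row["gene"], row["sample"]] = 1

    sample_order: list[str] = []
    for group in ("low", "medium", "high"):
        members = [s for s in tertiles.index if tertiles[s] == group]
        if genes:
            keys = [tuple(-indicator.loc[g, s] for g in genes) + (str(s),) for s in members]
            members = [s for _, s in sorted(zip(keys, members))]
        sample_order.extend(members)
    return genes, sample_order
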