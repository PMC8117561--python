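"""Synthetic cohort generator.

Emulates the statistical structure the deconvolution pipeline assumes:
beta-value matrices that are convex mixtures of K bimodal component
methylomes plus truncated Gaussian noise, planted component-specific
variably methylated regions (VMRs), expression counts coupled to component
proportions for designated signature genes, genomic alterations whose
probability depends on the proportion of a designated "immune" component,
and exponential survival times with an immune-proportion-dependent hazard.

Every output is a pure function of the configuration (including its seed):
one master seed spawns independent per-stage substreams so that stages can
be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_components",
    "simulate_mixture",
    "simulate_expression",
    "simulate_alterations_and_clinical",
    "simulate_cohort",
    "write_cohort",
]

_STAGES = ("components", "proportions", "mixture", "expression", "alterations", "survival", "fusions")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the conditions the pipeline's recovery properties are
    stated under: a desk-scale cohort (300 windows x 60 samples, 3
    components), planted VMR effect 0.4 with the downstream detection
    threshold at 0.2, methylation noise sd 0.02, expression coupling sized
    to give |Pearson r| ~ 0.6 between gene methylation and expression, a
    tertile hazard ratio of ~3 and ~20% administrative censoring.
    """

    n_windows: int = 300
    n_samples: int = 60
    k_true: int = 3
    dirichlet_alpha: float = 1.0
    noise_sd: float = 0.02
    n_vmr_per_component: int = 20
    vmr_effect: float = 0.4
    n_signature_genes: int = 15  # per component; coupled subset of its VMR genes
    expression_slope: float = 1.0  # log-scale coupling of counts to proportion
    expression_noise_sd: float = 0.3  # sd of log-normal multiplicative noise
    baseline_count: float = 1000.0
    hazard_rate: float = 1.0
    hazard_log_ratio: float = 2.1
    censor_time: float = 3.0
    alteration_logit_slope: float = 6.4
    alteration_logit_intercept: float = 1.0
    n_deletion_genes: int = 5
    n_amplification_genes: int = 5
    n_snv_genes: int = 10
    snv_rate: float = 0.15
    fusion_rate: float = 0.05
    n_fusion_pairs: int = 5
    n_background_genes: int = 50
    probes_per_window: int = 2
    window_size: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_windows": self.n_windows,
            "n_samples": self.n_samples,
            "probes_per_window": self.probes_per_window,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.k_true < 2:
            raise ValueError(f"k_true must be >= 2, got {self.k_true}")
        if not 0.2 < self.vmr_effect <= 1.0:
            raise ValueError(
                "vmr_effect must lie in (0.2, 1]: a planted effect at or below "
                "the 0.2 VMR threshold would be undetectable by design"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dirichlet_alpha <= 0 or self.baseline_count <= 0 or self.hazard_rate <= 0:
            raise ValueError("dirichlet_alpha, baseline_count and hazard_rate must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be >= 0")
        if self.n_vmr_per_component * self.k_true > self.n_windows:
            raise ValueError("not enough windows to host the requested VMRs")
        if self.n_signature_genes > self.n_vmr_per_component:
            raise ValueError("n_signature_genes (per component) cannot exceed n_vmr_per_component")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the master seed."""
        if stage not in _STAGES:
            raise KeyError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[_STAGES.index(stage)]
        return np.random.default_rng(child)


@dataclass
class GroundTruth:
    """Planted truth the recovery tests compare against."""

    t_true: np.ndarray  # windows x k, in [0, 1]
    a_true: np.ndarray  # k x samples, simplex columns
    vmr_map: list  # (component, window_index, direction)
    signature_gene_map: dict  # gene -> (component, direction)
    immune_component_index: int = 0


@dataclass
class SyntheticCohort:
    """All tables a full pipeline run consumes, plus the ground truth."""

    config: SimulationConfig
    truth: GroundTruth
    window_betas: pd.DataFrame  # windows x samples (the noiseless-to-noisy mixture D)
    probe_betas: pd.DataFrame  # probes x samples
    probe_annotation: pd.DataFrame  # probe_id, chrom, pos, is_cpg, gene, strand
    gene_annotation: pd.DataFrame  # gene, chrom, strand, tss
    counts: pd.DataFrame  # genes x samples
    snv: pd.DataFrame  # MAF-like
    segments: pd.DataFrame  # SEG-style
    gene_intervals: pd.DataFrame  # gene, chrom, start, end
    fusions: pd.DataFrame  # Arriba-style
    clinical: pd.DataFrame  # sample, time, event, subtype


def simulate_components(config: SimulationConfig) -> tuple[np.ndarray, list]:
    """Draw the component methylome matrix T with planted VMRs.

    Non-VMR windows share a single bimodal background beta across all
    components (equal mixture of Beta(2, 10) and Beta(10, 2), mimicking CpG
    bimodality). For each component, ``n_vmr_per_component`` windows are
    separated from every other component by at least ``vmr_effect``
    (hypomethylated below, or hypermethylated above, all others).

    Half of each component's VMR windows are *saturated* — the target
    component sits at beta exactly 0 (hypo) or 1 (hyper), as in
    component-specific fully unmethylated/methylated regions — and the
    non-target components carry small mutual jitter (< 0.15, below the 0.2
    VMR threshold) rather than being exactly equal. Together these make the
    true (T, A) an extreme point of the exact-factorization set, i.e. the
    zero-noise deconvolution problem is well posed; see the methods note.

    Returns ``(t_true, vmr_map)`` where ``vmr_map`` lists
    ``(component, window_index, direction)`` tuples.
    """
    rng = config.stage_rng("components")
    w, k = config.n_windows, config.k_true
    lowmode = rng.random(w) < 0.5
    background = np.where(lowmode, rng.beta(2, 10, size=w), rng.beta(10, 2, size=w))
    t = np.tile(background[:, None], (1, k))

    n_vmr = config.n_vmr_per_component
    vmr_map: list = []
    if n_vmr > 0:
        vmr_windows = rng.choice(w, size=n_vmr * k, replace=False)
        eff = config.vmr_effect
        for comp in range(k):
            for j, win in enumerate(vmr_windows[comp * n_vmr : (comp + 1) * n_vmr]):
                direction = "hypo" if j % 2 == 0 else "hyper"
                saturated = j % 4 < 2
                jitter = rng.uniform(0.0, 0.15, size=k)
                if direction == "hypo":
                    if saturated:
                        target, others = 0.0, np.minimum(eff + jitter, 1.0)
                    else:
                        base = rng.uniform(eff + 0.02, 0.96)
                        target, others = base - eff, np.minimum(base + jitter, 1.0)
                else:
                    if saturated:
                        target, others = 1.0, np.maximum(1.0 - eff - jitter, 0.0)
                    else:
                        base = rng.uniform(0.04, 1.0 - eff - 0.02)
                        target, others = base + eff, np.maximum(base - jitter, 0.0)
                t[win, :] = others
                t[win, comp] = target
                vmr_map.append((comp, int(win), direction))
    return np.clip(t, 0.0, 1.0), vmr_map


def simulate_proportions(config: SimulationConfig) -> np.ndarray:
    """Simplex-valid proportions: columns drawn from Dirichlet(alpha)."""
    rng = config.stage_rng("proportions")
    a = rng.dirichlet([config.dirichlet_alpha] * config.k_true, size=config.n_samples).T
    return a


def simulate_mixture(
    t_true: np.ndarray, a_true: np.ndarray, noise_sd: float, seed=None
) -> np.ndarray:
    """Mix components: D = clip(T·A + ε, 0, 1), ε iid Gaussian(0, noise_sd).

    ``seed`` may be an integer, a Generator, or None (no noise allowed only
    when noise_sd == 0 in that case the seed is irrelevant).
    """
    t_true = np.asarray(t_true, dtype=float)
    a_true = np.asarray(a_true, dtype=float)
    if t_true.ndim != 2 or a_true.ndim != 2 or t_true.shape[1] != a_true.shape[0]:
        raise ValueError(
            f"shape mismatch: T is {t_true.shape}, A is {a_true.shape}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    d = t_true @ a_true
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, size=d.shape)
    return np.clip(d, 0.0, 1.0)


def _gene_names(config: SimulationConfig, vmr_map: list) -> tuple[dict, dict]:
    """Assign one gene per VMR window; the first ``n_signature_genes`` VMR
    genes of each component (in map order) carry expression coupling."""
    per_comp_seen: dict[int, int] = {}
    window_gene: dict[int, str] = {}
    signature_gene_map: dict[str, tuple[int, str]] = {}
    for comp, win, direction in vmr_map:
        idx = per_comp_seen.get(comp, 0)
        gene = f"G{comp}_{idx:03d}"
        window_gene[win] = gene
        if idx < config.n_signature_genes:
            signature_gene_map[gene] = (comp, direction)
        per_comp_seen[comp] = idx + 1
    return window_gene, signature_gene_map


def simulate_expression(
    a_true: np.ndarray, signature_gene_map: dict, config: SimulationConfig
) -> pd.DataFrame:
    """RSEM-style integer counts coupled to component proportions.

    For a signature gene mapped to component c (either direction — both
    model transcriptional upregulation), the expected count is
    ``baseline_count * exp(expression_slope * a_true[c])`` with log-normal
    multiplicative noise; non-signature genes are independent of the
    proportions. Counts are rounded to integers and clipped at 0.
    """
    rng = config.stage_rng("expression")
    n = a_true.shape[1]
    samples = [f"S{i:03d}" for i in range(n)]
    rows, names = [], []
    for gene, (comp, _direction) in sorted(signature_gene_map.items()):
        mu = config.baseline_count * np.exp(config.expression_slope * a_true[comp])
        rows.append(mu * np.exp(rng.normal(0.0, config.expression_noise_sd, size=n)))
        names.append(gene)
    # uncoupled VMR genes and pure background genes: flat expectation
    for i in range(config.n_background_genes):
        mu = config.baseline_count
        rows.append(mu * np.exp(rng.normal(0.0, config.expression_noise_sd, size=n)))
        names.append(f"BG{i:03d}")
    counts = np.clip(np.rint(np.asarray(rows)), 0, None)
    return pd.DataFrame(counts, index=names, columns=samples)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_alterations_and_clinical(
    a_true: np.ndarray, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Alteration tables and clinical outcomes driven by the immune proportion.

    Deletion genes are altered with probability
    ``logistic(intercept − slope · p_immune)`` (enriched in low-immune
    samples); amplification genes with the mirrored argument
    ``logistic(intercept − slope · (1 − p_immune))``; SNV genes with a flat
    background rate. Survival times are exponential with log-hazard
    ``log(hazard_rate) − hazard_log_ratio · p_immune`` and administrative
    censoring at ``censor_time``.

    Returns ``(snv, segments, gene_intervals, fusions, clinical)``.
    """
    imm = a_true[0]  # immune component is index 0 by convention
    n = a_true.shape[1]
    samples = [f"S{i:03d}" for i in range(n)]
    rng = config.stage_rng("alterations")

    # --- SNVs (MAF-like, background rate only) ---
    snv_rows = []
    for g in range(config.n_snv_genes):
        hit = rng.random(n) < config.snv_rate
        for s in np.flatnonzero(hit):
            snv_rows.append((samples[s], f"SNV{g:03d}", "Missense_Mutation"))
    snv = pd.DataFrame(snv_rows, columns=["sample", "gene", "variant_classification"])

    # --- copy number: one segment per altered (sample, gene) on chr2 ---
    seg_rows, interval_rows = [], []
    gene_pos = 0
    c0, slope = config.alteration_logit_intercept, config.alteration_logit_slope
    for g in range(config.n_deletion_genes):
        gene = f"DEL{g:03d}"
        start, end = gene_pos, gene_pos + 10_000
        interval_rows.append((gene, "chr2", start, end))
        hit = rng.random(n) < _expit(c0 - slope * imm)
        for s in np.flatnonzero(hit):
            seg_rows.append((samples[s], "chr2", start, end, -1.0))
        gene_pos += 20_000
    for g in range(config.n_amplification_genes):
        gene = f"AMP{g:03d}"
        start, end = gene_pos, gene_pos + 10_000
        interval_rows.append((gene, "chr2", start, end))
        hit = rng.random(n) < _expit(c0 - slope * (1.0 - imm))
        for s in np.flatnonzero(hit):
            seg_rows.append((samples[s], "chr2", start, end, 1.0))
        gene_pos += 20_000
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "log2_ratio"]
    )
    gene_intervals = pd.DataFrame(
        interval_rows, columns=["gene", "chrom", "start", "end"]
    )

    # --- fusions (Arriba-style support columns; background rate) ---
    frng = config.stage_rng("fusions")
    fusion_rows = []
    for p in range(config.n_fusion_pairs):
        g1, g2 = f"FUSA{p:02d}", f"FUSB{p:02d}"
        hit = frng.random(n) < config.fusion_rate
        for s in np.flatnonzero(hit):
            fusion_rows.append(
                (
                    samples[s],
                    g1,
                    g2,
                    int(frng.poisson(3)),
                    int(frng.poisson(3)),
                    int(frng.poisson(4)),
                )
            )
    fusions = pd.DataFrame(
        fusion_rows,
        columns=["sample", "gene1", "gene2", "split_reads1", "split_reads2", "discordant_mates"],
    )

    # --- survival: exponential hazard decreasing with immune proportion ---
    srng = config.stage_rng("survival")
    hazard = config.hazard_rate * np.exp(-config.hazard_log_ratio * imm)
    t_event = srng.exponential(1.0 / hazard)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event < config.censor_time).astype(int)
    subtype = [f"ST{j}" for j in np.argmax(a_true, axis=0)]
    clinical = pd.DataFrame(
        {"sample": samples, "time": time, "event": event, "subtype": subtype}
    )
    return snv, segments, gene_intervals, fusions, clinical


def _probe_tables(
    config: SimulationConfig, d: np.ndarray, window_gene: dict, vmr_map: list
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expand the window mixture into a probe-level matrix plus annotation.

    Each window hosts ``probes_per_window`` CpG probes at evenly spaced
    offsets, all carrying the window's beta value, so window aggregation
    reproduces D exactly. VMR-window probes are annotated to the window's
    gene; gene TSSs alternate strand, placed on the first (plus) or second
    (minus) probe so promoter assignment is exercised in both orientations.
    """
    w = config.n_windows
    ws = config.window_size
    n_p = config.probes_per_window
    offsets = [int(ws * (i + 1) / (n_p + 1)) for i in range(n_p)]
    samples = [f"S{i:03d}" for i in range(d.shape[1])]

    probe_ids, ann_rows, beta_rows = [], [], []
    for win in range(w):
        start = win * ws
        gene = window_gene.get(win, "")
        for i, off in enumerate(offsets):
            pid = f"cg{win:05d}_{i}"
            probe_ids.append(pid)
            ann_rows.append((pid, "chr1", start + off, True, gene, "+"))
            beta_rows.append(d[win])
    probe_betas = pd.DataFrame(beta_rows, index=probe_ids, columns=samples)
    probe_annotation = pd.DataFrame(
        ann_rows, columns=["probe_id", "chrom", "pos", "is_cpg", "gene", "strand"]
    ).set_index("probe_id", drop=False)

    gene_rows = []
    for j, (comp, win, _dir) in enumerate(vmr_map):
        gene = window_gene[win]
        start = win * ws
        if j % 2 == 0:
            gene_rows.append((gene, "chr1", "+", start + offsets[0]))
        else:
            off = offsets[-1] if n_p > 1 else offsets[0]
            gene_rows.append((gene, "chr1", "-", start + off))
    gene_annotation = pd.DataFrame(gene_rows, columns=["gene", "chrom", "strand", "tss"])
    return probe_betas, probe_annotation, gene_annotation


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run every stage and assemble the full synthetic cohort."""
    t_true, vmr_map = simulate_components(config)
    a_true = simulate_proportions(config)
    assert np.allclose(a_true.sum(axis=0), 1.0, atol=1e-12)
    d = simulate_mixture(t_true, a_true, config.noise_sd, config.stage_rng("mixture"))
    window_gene, signature_gene_map = _gene_names(config, vmr_map)
    counts = simulate_expression(a_true, signature_gene_map, config)
    snv, segments, gene_intervals, fusions, clinical = simulate_alterations_and_clinical(
        a_true, config
    )
    probe_betas, probe_annotation, gene_annotation = _probe_tables(
        config, d, window_gene, vmr_map
    )
    samples = list(counts.columns)
    window_ids = [
        f"chr1:{w * config.window_size}-{(w + 1) * config.window_size}"
        for w in range(config.n_windows)
    ]
    truth = GroundTruth(
        t_true=t_true,
        a_true=a_true,
        vmr_map=vmr_map,
        signature_gene_map=signature_gene_map,
        immune_component_index=0,
    )
    return SyntheticCohort(
        config=config,
        truth=truth,
        window_betas=pd.DataFrame(d, index=window_ids, columns=samples),
        probe_betas=probe_betas,
        probe_annotation=probe_annotation,
        gene_annotation=gene_annotation,
        counts=counts,
        snv=snv,
        segments=segments,
        gene_intervals=gene_intervals,
        fusions=fusions,
        clinical=clinical,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every table as TSV in the dialects the pipeline readers consume,
    plus a ground-truth JSON for tests."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.probe_betas.rename_axis("probe_id").to_csv(out / "betas.tsv", sep="\t")
    cohort.probe_annotation.to_csv(out / "probe_annotation.tsv", sep="\t", index=False)
    cohort.gene_annotation.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
    cohort.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    cohort.snv.to_csv(out / "snv.tsv", sep="\t", index=False)
    cohort.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
    cohort.gene_intervals.to_csv(out / "gene_intervals.tsv", sep="\t", index=False)
    cohort.fusions.to_csv(out / "fusions.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    truth = cohort.truth
    payload = {
        "t_true": truth.t_true.tolist(),
        "a_true": truth.a_true.tolist(),
        "vmr_map": [[c, w, d] for c, w, d in truth.vmr_map],
        "signature_gene_map": {g: [c, d] for g, (c, d) in truth.signature_gene_map.items()},
        "immune_component_index": truth.immune_component_index,
        "config": dataclasses.asdict(cohort.config),
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
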