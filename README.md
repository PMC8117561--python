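# methylomix

Reference-free deconvolution of tumor methylomes into latent methylation
components, with downstream immune scoring, signature derivation, and
alteration/survival association — the analysis stack used to dissect
tumor-infiltrating leukocyte (TIL) content in soft-tissue sarcoma cohorts
from array methylation, RNA-seq and genomic-alteration data.

## What it does

Bulk tumor methylomes are mixtures: each CpG beta value is a convex
combination of the methylomes of the cell populations in the specimen.
Given a probe-level beta matrix, the pipeline

1. filters probes (complete-case, autosomal, CpG context) and averages
   betas over fixed 5-kb genomic windows, giving the input matrix
   **D** (windows × samples);
2. factorizes **D ≈ T·A** into K latent methylation components (LMCs):
   **T** ∈ [0,1]^(W×K) holds component methylomes, the columns of
   **A** ∈ Δ^(K−1) are per-sample mixture proportions, by minimizing

       ‖D − T·A‖²_F + λ·Σᵢⱼ Tᵢⱼ(1 − Tᵢⱼ)

   (the λ-penalty pushes component betas toward the biologically expected
   near-binary values), with cross-validated selection of K and λ and a
   restart-stability score;
3. extracts per-component **variably methylated regions** (VMRs): windows
   where one component's beta differs from *all* others by more than 0.2,
   hypo- or hypermethylated;
4. maps VMRs to genes, correlates gene-level VMR methylation with relative
   expression (log2 count over cohort median), and keeps the two
   "upregulation" patterns as the core signature: hypomethylated with
   Pearson r < −0.3, hypermethylated with r > 0.3;
5. scores immune infiltration per sample i as the signature-gene median

       TILᵢ = medianⱼ log2( countᵢⱼ / (medianⱼ(count) + 0.01) ),

   a score of 0 meaning cohort-typical infiltration, and stratifies the
   cohort into TIL tertiles;
6. tests gene-level alterations (non-silent SNVs/indels, copy-number
   calls, filtered fusions) for upper-vs-lower tertile enrichment with
   two-sided Fisher's exact tests, combined across alteration types by
   Fisher's method, and orders oncoprint output by mutual exclusivity;
7. compares overall survival between tertiles with Kaplan–Meier curves and
   the log-rank test (BH correction for single-gene scans), and assigns
   rule-based LMS subgroups from component proportions.

A first-class synthetic-data generator (`methylomix.simulate`) produces
cohorts with planted components, VMRs, expression coupling, alteration
enrichment and survival effects, so every stage is testable without any
data download.

## Worked example

```python
import methylomix as mx

cfg = mx.SimulationConfig(n_samples=60, seed=1)
cohort = mx.simulate_cohort(cfg)

probes = mx.filter_probes(mx.ProbeMatrix(beta=cohort.probe_betas,
                                         annotation=cohort.probe_annotation))
wm = mx.aggregate_windows(probes, window_size=5000)

model = mx.factorize(wm, k=3, lam=0.01, seed=7)
match = mx.match_components(model.t.to_numpy(), cohort.truth.t_true)

vmrs = mx.extract_vmrs(model.t, threshold=0.2)

sig = [g for g, (c, _) in cohort.truth.signature_gene_map.items() if c == 0]
scores = mx.til_score(cohort.counts, sig)
tert = mx.tertile_groups(scores)

clin = cohort.clinical.set_index("sample")
surv = mx.SurvivalData(time=clin["time"], event=clin["event"], group=tert)
res = mx.logrank_test(surv, "high", "low")
```

Output:

```
300 windows x 60 samples
final objective: 7.9852
component correlations: [0.9997, 0.9998, 0.9996]
60 component-specific VMR windows
TIL score range: -0.74 .. 1.02
log-rank upper vs lower tertile: chi2 = 9.29, p = 0.002302
```

The three fitted components correlate > 0.999 with the planted methylomes;
the VMR extractor recovers the 60 planted component-specific windows; and
because the generator couples survival hazard to the immune component's
proportion, the upper TIL tertile shows significantly better survival than
the lower one.

A CLI mirrors the library (`methylomix simulate`, `windows`, `deconvolve`,
`select-model`, `signatures`, `til-score`, `lms-groups`, `filter-fusions`, `enrich`,
`survive`, `gene-scan`); run `methylomix --help`.

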