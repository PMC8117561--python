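import numpy as np
import pandas as pd
import pytest

from methylomix import ProbeMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_windows=60,
        n_samples=24,
        k_true=3,
        n_vmr_per_component=8,
        n_signature_genes=6,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_probe_matrix(small_cohort):
    return ProbeMatrix(
        beta=small_cohort.probe_betas, annotation=small_cohort.probe_annotation
    )


@pytest.fixture()
def handmade_probes():
    """Five probes exercising every filter: one incomplete, one on chrX,
    one non-CpG, two clean ones in the same 5-kb window."""
    beta = pd.DataFrame(
        {
            "s1": [0.2, 0.5, 0.7, 0.1, 0.9],
            "s2": [0.4, np.nan, 0.6, 0.3, 0.8],
        },
        index=["cg_a", "cg_missing", "cg_x", "ch_noncpg", "cg_b"],
    )
    ann = pd.DataFrame(
        {
            "probe_id": ["cg_a", "cg_missing", "cg_x", "ch_noncpg", "cg_b"],
            "chrom": ["chr1", "chr1", "chrX", "chr1", "chr1"],
            "pos": [100, 200, 300, 400, 4900],
            "is_cpg": [True, True, True, False, True],
            "gene": ["G1", "", "", "", "G1"],
            "strand": ["+", "+", "+", "+", "+"],
        }
    ).set_index("probe_id", drop=False)
    return ProbeMatrix(beta=beta, annotation=ann)


def exact_pearson(x, y):
    """Brute-force Pearson correlation used as an independent oracle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm * xm).sum() * (ym * ym).sum()))
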