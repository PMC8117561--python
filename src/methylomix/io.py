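"""TSV readers and writers for the pipeline's tabular dialects.

All genomic coordinates are 0-based half-open internally; readers accept a
``one_based=True`` flag to convert annotation positions on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import DeconvolutionModel
from .windows import ProbeMatrix, WindowMatrix

__all__ = [
    "read_probe_matrix",
    "read_counts",
    "read_clinical",
    "read_fusions",
    "read_segments",
    "read_maf",
    "write_window_matrix",
    "read_window_matrix",
    "write_model",
    "read_model",
]


def read_probe_matrix(betas_path, annotation_path, one_based: bool = False) -> ProbeMatrix:
    """Probe beta TSV (probe_id + one column per sample) plus annotation TSV
    (probe_id, chrom, pos, is_cpg, gene, strand)."""
    beta = pd.read_csv(betas_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    ann = ann.set_index("probe_id", drop=False)
    if one_based:
        ann = ann.assign(pos=ann["pos"] - 1)
    return ProbeMatrix(beta=beta, annotation=ann)


def read_counts(path) -> pd.DataFrame:
    """Gene x sample expression TSV (counts or FPKM)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    return clinical.set_index("sample", drop=False)


def read_fusions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_segments(path, one_based: bool = False) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    if one_based:
        seg = seg.assign(start=seg["start"] - 1)
    return seg


def read_maf(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_window_matrix(wm: WindowMatrix, path) -> None:
    wm.beta.rename_axis("window").to_csv(path, sep="\t")


def read_window_matrix(path, window_size: int = 5000) -> WindowMatrix:
    beta = pd.read_csv(path, sep="\t", index_col=0)
    return WindowMatrix(beta=beta, probe_members={}, window_size=window_size)


def write_model(model: DeconvolutionModel, outdir) -> None:
    """Serialize a fitted factorization as a directory of T.tsv, A.tsv and
    meta.json (k, lambda, seed, objective trace)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model.t.rename_axis("window").to_csv(out / "T.tsv", sep="\t")
    model.a.rename_axis("component").to_csv(out / "A.tsv", sep="\t")
    meta = {
        "k": model.k,
        "lambda": model.lam,
        "n_init": model.n_init,
        "seed": model.seed,
        "best_init_index": model.best_init_index,
        "objective_trace": np.asarray(model.objective_trace).tolist(),
    }
    (out / "meta.json").write_text(json.dumps(meta))


def read_model(modeldir) -> DeconvolutionModel:
    d = Path(modeldir)
    t = pd.read_csv(d / "T.tsv", sep="\t", index_col=0)
    a = pd.read_csv(d / "A.tsv", sep="\t", index_col=0)
    meta = json.loads((d / "meta.json").read_text())
    return DeconvolutionModel(
        t=t,
        a=a,
        k=meta["k"],
        lam=meta["lambda"],
        objective_trace=np.asarray(meta["objective_trace"]),
        n_init=meta["n_init"],
        seed=meta["seed"],
        best_init_index=meta["best_init_index"],
    )
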