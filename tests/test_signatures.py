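import numpy as np
import pandas as pd
import pytest

from methylomix import (
    ProbeMatrix,
    derive_signature,
    extract_vmrs,
    gene_level_methylation,
    promoter_fraction,
)


def brute_force_vmrs(t, threshold=0.2):
    """Independent double-loop oracle for the all-others separation rule."""
    found = set()
    w, k = t.shape
    for win in range(w):
        for comp in range(k):
            others = [t[win, l] for l in range(k) if l != comp]
            if all(t[win, comp] < o - threshold for o in others):
                found.add((comp, win, "hypo"))
            if all(t[win, comp] > o + threshold for o in others):
                found.add((comp, win, "hyper"))
    return found


def vector_with_correlation(x, r, rng):
    """Construct y with exact sample Pearson correlation r against x."""
    z = rng.standard_normal(len(x))
    xc = (x - x.mean()) / x.std()
    zc = z - z.mean() - np.dot(z - z.mean(), xc) / np.dot(xc, xc) * xc
    zc /= zc.std()
    return r * xc + np.sqrt(1 - r**2) * zc


class TestExtractVmrs:
    def test_hypo_hyper_and_boundary_rows(self):
        t = pd.DataFrame(
            [
                [0.1, 0.5, 0.6],  # hypo for component 0
                [0.3, 0.5, 0.6],  # difference exactly 0.2: strict rule fails
                [0.9, 0.6, 0.5],  # hyper for component 0
            ]
        )
        vmrs = extract_vmrs(t, threshold=0.2)
        got = set(
            zip(vmrs.entries["component"], vmrs.entries["window_id"], vmrs.entries["direction"])
        )
        assert got == {(0, 0, "hypo"), (0, 2, "hyper")}
        deltas = dict(zip(vmrs.entries["window_id"], vmrs.entries["delta_to_nearest_other"]))
        assert deltas[0] == pytest.approx(-0.4)
        assert deltas[2] == pytest.approx(0.3)

    def test_single_component_rejected(self):
        with pytest.raises(ValueError, match="K >= 2"):
            extract_vmrs(np.full((5, 1), 0.5))

    def test_agrees_with_bruteforce_on_random_rows(self):
        rng = np.random.default_rng(0)
        t = rng.random((400, 4))
        vmrs = extract_vmrs(pd.DataFrame(t))
        got = set(
            zip(vmrs.entries["component"], vmrs.entries["window_id"], vmrs.entries["direction"])
        )
        assert got == brute_force_vmrs(t)

    def test_hypo_hyper_disjoint_per_component(self):
        rng = np.random.default_rng(1)
        vmrs = extract_vmrs(pd.DataFrame(rng.random((300, 3))), threshold=0.1)
        for comp in range(3):
            hypo = set(vmrs.windows(comp, "hypo"))
            hyper = set(vmrs.windows(comp, "hyper"))
            assert not hypo & hyper


class TestGeneLevelMethylation:
    @pytest.fixture()
    def probes_two_genes(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.9], "s2": [0.6, 0.8, 0.1]},
            index=["p1", "p2", "p3"],
        )
        ann = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [100, 4000, 20000],  # p1, p2 in window 0-5000
                "is_cpg": True,
            }
        ).set_index("probe_id", drop=False)
        return ProbeMatrix(beta=beta, annotation=ann)

    def _vmrs(self):
        entries = pd.DataFrame(
            {
                "component": [0],
                "window_id": ["chr1:0-5000"],
                "direction": ["hypo"],
                "delta_to_nearest_other": [-0.3],
            }
        )
        from methylomix.signatures import VMRSet

        return VMRSet(entries=entries)

    def test_mean_over_qualifying_probes(self, probes_two_genes):
        gene_map = pd.DataFrame({"probe_id": ["p1", "p2"], "gene": ["GA", "GA"]})
        gb = gene_level_methylation(probes_two_genes, self._vmrs(), gene_map, 0)
        assert gb.loc["GA", "s1"] == pytest.approx(0.3)

    def test_gene_outside_vmr_windows_absent(self, probes_two_genes):
        gene_map = pd.DataFrame({"probe_id": ["p3"], "gene": ["GB"]})
        gb = gene_level_methylation(probes_two_genes, self._vmrs(), gene_map, 0)
        assert gb.empty

    def test_multigene_probe_contributes_to_both(self, probes_two_genes):
        gene_map = pd.DataFrame(
            {"probe_id": ["p1", "p1", "p2"], "gene": ["GA", "GB", "GA"]}
        )
        gb = gene_level_methylation(probes_two_genes, self._vmrs(), gene_map, 0)
        assert gb.loc["GB", "s1"] == pytest.approx(0.2)
        assert gb.loc["GA", "s1"] == pytest.approx(0.3)


class TestDeriveSignature:
    def test_categories_and_core_membership(self):
        rng = np.random.default_rng(2)
        x = rng.random(40)
        samples = [f"s{i}" for i in range(40)]
        meth = pd.DataFrame(
            [x, x, x], index=["g_a", "g_excluded", "g_d"], columns=samples
        )
        expr = pd.DataFrame(
            [
                vector_with_correlation(x, -0.5, rng),
                vector_with_correlation(x, 0.2, rng),
                vector_with_correlation(x, 0.4, rng),
            ],
            index=["g_a", "g_excluded", "g_d"],
            columns=samples,
        )
        sig = derive_signature(
            meth, expr, {"g_a": "hypo", "g_excluded": "hyper", "g_d": "hyper"}
        )
        table = sig.genes.set_index("gene")
        assert table.loc["g_a", "category"] == "a" and table.loc["g_a", "in_core"]
        assert "g_excluded" not in table.index
        assert table.loc["g_d", "category"] == "d" and table.loc["g_d", "in_core"]
        assert table.loc["g_a", "pearson_r"] == pytest.approx(-0.5, abs=1e-10)

    def test_negative_pattern_categories_not_core(self):
        rng = np.random.default_rng(3)
        x = rng.random(30)
        samples = [f"s{i}" for i in range(30)]
        meth = pd.DataFrame([x, x], index=["g_b", "g_c"], columns=samples)
        expr = pd.DataFrame(
            [
                vector_with_correlation(x, -0.6, rng),
                vector_with_correlation(x, 0.6, rng),
            ],
            index=["g_b", "g_c"],
            columns=samples,
        )
        sig = derive_signature(meth, expr, {"g_b": "hyper", "g_c": "hypo"})
        table = sig.genes.set_index("gene")
        assert table.loc["g_b", "category"] == "b" and not table.loc["g_b", "in_core"]
        assert table.loc["g_c", "category"] == "c" and not table.loc["g_c", "in_core"]

    def test_zero_variance_and_short_genes_skipped(self):
        samples = list("abcd")
        meth = pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.5], [0.1, 0.2, 0.3, 0.4]],
            index=["flat", "short"],
            columns=samples,
        )
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, np.nan, 2.0]],
            index=["flat", "short"],
            columns=samples,
        )
        sig = derive_signature(meth, expr, {"flat": "hypo", "short": "hyper"})
        assert sig.genes.empty
        reasons = dict(zip(sig.skipped["gene"], sig.skipped["reason"]))
        assert "variance" in reasons["flat"]
        assert "paired samples" in reasons["short"]

    def test_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(25)]
        genes = [f"g{i}" for i in range(6)]
        meth = pd.DataFrame(rng.random((6, 25)), index=genes, columns=samples)
        expr = pd.DataFrame(rng.random((6, 25)), index=genes, columns=samples)
        dirs = {g: ("hypo" if i % 2 else "hyper") for i, g in enumerate(genes)}
        base = derive_signature(meth, expr, dirs, r_threshold=0.0)
        shuffled = derive_signature(
            meth.iloc[::-1, ::-1], expr.iloc[:, ::-1], dirs, r_threshold=0.0
        )
        pd.testing.assert_frame_equal(base.genes, shuffled.genes)


class TestPromoterFraction:
    def _ann(self):
        return pd.DataFrame(
            {
                "gene": ["plus", "minus"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "tss": [10000, 8000],
            }
        )

    def test_plus_strand_interval(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [9500]})
        assert promoter_fraction(probes, self._ann()) == 1.0

    def test_minus_strand_interval_reflected(self):
        # minus-strand promoter spans [tss-100, tss+1000) = [7900, 9000)
        inside = pd.DataFrame({"chrom": ["chr1"], "pos": [8500]})
        outside = pd.DataFrame({"chrom": ["chr1"], "pos": [7000]})
        assert promoter_fraction(inside, self._ann().iloc[[1]]) == 1.0
        assert promoter_fraction(outside, self._ann().iloc[[1]]) == 0.0

    def test_mixed_probes_fraction(self):
        probes = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2", "chr1"], "pos": [9500, 8500, 9500, 50]}
        )
        assert promoter_fraction(probes, self._ann()) == pytest.approx(0.5)

    def test_unknown_strand_rejected(self):
        ann = self._ann().assign(strand=["+", "."])
        with pytest.raises(ValueError, match="strand"):
            promoter_fraction(pd.DataFrame({"chrom": ["chr1"], "pos": [1]}), ann)
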