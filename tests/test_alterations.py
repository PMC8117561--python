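from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, fisher_exact

from methylomix import (
    AlterationTable,
    enrichment_scan,
    filter_fusions,
    fisher_exact_2x2,
    fisher_method,
    gene_cna_calls,
    oncoprint_order,
)
from methylomix.alterations import maf_to_events


def enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by integer-numerator enumeration (independent of
    the Fraction-based implementation)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {x: comb(c1, x) * comb(n - c1, r1 - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = sum(v for v in nums.values() if v <= obs)
    return total / comb(n, r1)


class TestFilterFusions:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample", "gene1", "gene2", "split_reads1", "split_reads2", "discordant_mates"],
        )

    def test_support_rule(self):
        t = self._table(
            [
                ("s1", "A", "B", 1, 1, 5),   # 2 > max(1, 0.5) -> kept
                ("s2", "C", "D", 1, 1, 30),  # 2 <= 3 -> removed
                ("s3", "E", "F", 0, 1, 0),   # 1 <= 1 -> removed
            ]
        )
        kept = filter_fusions(t)
        assert list(kept["sample"]) == ["s1"]

    def test_recurrent_gene_removed(self):
        rows = [(f"s{i}", "HOT", f"P{i}", 3, 3, 0) for i in range(21)]
        rows.append(("s99", "COLD", "Q", 3, 3, 0))
        kept = filter_fusions(self._table(rows))
        assert list(kept["gene1"]) == ["COLD"]
        # at the boundary (exactly 20 samples) the gene survives
        kept20 = filter_fusions(self._table(rows[:20] + rows[-1:]))
        assert set(kept20["gene1"]) == {"HOT", "COLD"}

    def test_missing_columns_named_in_error(self):
        with pytest.raises(ValueError, match="split_reads2"):
            filter_fusions(pd.DataFrame({"sample": [], "gene1": []}))


class TestGeneCnaCalls:
    def _fixtures(self):
        segments = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3"],
                "chrom": ["chr1"] * 3,
                "start": [0, 0, 0],
                "end": [10000] * 3,
                "log2_ratio": [1.2, -1.0, 0.1],
            }
        )
        genes = pd.DataFrame(
            {"gene": ["G"], "chrom": ["chr1"], "start": [2000], "end": [3000]}
        )
        return segments, genes

    def test_threshold_calls(self):
        segments, genes = self._fixtures()
        calls = gene_cna_calls(segments, genes).events
        got = set(zip(calls["sample"], calls["type"]))
        assert got == {("s1", "amplification"), ("s2", "deletion")}

    def test_non_overlapping_segment_ignored(self):
        segments, genes = self._fixtures()
        segments["end"] = 1000  # upstream of the gene
        assert gene_cna_calls(segments, genes).events.empty

    def test_malformed_interval_rejected(self):
        segments, genes = self._fixtures()
        genes["end"] = 1000  # end < start
        with pytest.raises(ValueError, match="malformed"):
            gene_cna_calls(segments, genes)


class TestFisherExact:
    def test_frozen_examples(self):
        assert fisher_exact_2x2([[5, 5], [0, 10]]) == pytest.approx(
            0.03250773993808, abs=1e-12
        )
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / comb(20, 10), abs=1e-15
        )

    def test_matches_enumeration_oracle_small_margins(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                            enumeration_oracle(a, b, c, d), abs=1e-12
                        )

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(0, 30, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_exact(t)[1], abs=1e-9
            )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError, match="nonnegative integers"):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError, match="nonnegative integers"):
            fisher_exact_2x2([[0.5, 1], [1, 1]])


class TestFisherMethod:
    def test_frozen_example(self):
        assert fisher_method([0.05, 0.10]) == pytest.approx(0.031491586, abs=1e-8)

    def test_identity_for_single_p(self):
        for p in [1e-6, 0.01, 0.37, 0.9, 1.0]:
            assert fisher_method([p]) == pytest.approx(p, abs=1e-12)

    def test_all_ones_combine_to_one(self):
        assert fisher_method([1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_chisquare_closed_form(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, size=5)
        stat = -2 * np.sum(np.log(p))
        assert fisher_method(p) == pytest.approx(float(chi2.sf(stat, 10)), abs=1e-14)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            fisher_method([0.5, 0.0])


def _tertiles(n_low=10, n_med=10, n_high=10):
    labels = ["low"] * n_low + ["medium"] * n_med + ["high"] * n_high
    return pd.Series(labels, index=[f"s{i:02d}" for i in range(len(labels))])


class TestEnrichmentScan:
    def test_low_tertile_deletion_retained(self):
        """5/10 deletions in the lower tertile vs 0/10 in the upper gives the
        frozen Fisher p 0.0325 < 0.2 and direction 'low'."""
        tert = _tertiles()
        events = pd.DataFrame(
            {"sample": [f"s{i:02d}" for i in range(5)], "gene": "RB1", "type": "deletion"}
        )
        res = enrichment_scan(AlterationTable(events=events), tert)
        assert len(res) == 1
        r = res[0]
        assert r.p_by_type["deletion"] == pytest.approx(0.03250773993808, abs=1e-10)
        assert r.combined_p == r.p_by_type["deletion"]
        assert r.retained and r.direction == "low" and r.exploratory

    def test_weak_single_type_gene_dropped_at_first_gate(self):
        tert = _tertiles()
        # 2 deletions in low vs 1 in high: p well above 0.2
        events = pd.DataFrame(
            {
                "sample": ["s00", "s01", "s20"],
                "gene": "G",
                "type": "deletion",
            }
        )
        assert enrichment_scan(AlterationTable(events=events), tert) == []

    def test_multitype_gene_combined_with_fishers_method(self):
        tert = _tertiles()
        snv = pd.DataFrame(
            {"sample": [f"s{i:02d}" for i in range(4)], "gene": "G", "type": "snv"}
        )
        dele = pd.DataFrame(
            {"sample": [f"s{i:02d}" for i in range(4)], "gene": "G", "type": "deletion"}
        )
        res = enrichment_scan(
            AlterationTable(events=pd.concat([snv, dele])), tert
        )
        r = res[0]
        assert r.n_types_tested == 2
        assert r.combined_p == pytest.approx(
            fisher_method([r.p_by_type["snv"], r.p_by_type["deletion"]]), abs=1e-14
        )

    def test_duplicate_events_do_not_inflate_counts(self):
        tert = _tertiles()
        once = pd.DataFrame({"sample": ["s00"], "gene": "G", "type": "snv"})
        thrice = pd.concat([once] * 3)
        r1 = enrichment_scan(AlterationTable(events=once.copy()), tert)
        r3 = enrichment_scan(AlterationTable(events=thrice), tert)
        assert [r.tables for r in r1] == [r.tables for r in r3]

    def test_missing_tertile_labels_rejected(self):
        events = pd.DataFrame({"sample": ["zz"], "gene": "G", "type": "snv"})
        with pytest.raises(ValueError, match="missing tertile"):
            enrichment_scan(AlterationTable(events=events), _tertiles())


class TestMafIngest:
    def test_silent_classes_dropped_and_indels_typed(self):
        maf = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s2", "s3"],
                "gene": ["A", "B", "C", "D"],
                "variant_classification": [
                    "Missense_Mutation",
                    "Silent",
                    "Frame_Shift_Del",
                    "3'UTR",
                ],
            }
        )
        events = maf_to_events(maf).events
        assert set(zip(events["gene"], events["type"])) == {("A", "snv"), ("C", "indel")}


class TestOncoprintOrder:
    def _results(self, genes, tert):
        events = pd.DataFrame(
            [(s, g, "deletion") for g, samples in genes.items() for s in samples],
            columns=["sample", "gene", "type"],
        )
        alts = AlterationTable(events=events)
        return enrichment_scan(alts, tert), alts

    def test_at_most_ten_genes_emitted(self):
        tert = _tertiles(15, 15, 15)
        genes = {
            f"G{i:02d}": [f"s{j:02d}" for j in range(6)] for i in range(12)
        }  # every gene: 6/15 low vs 0/15 high -> retained
        res, alts = self._results(genes, tert)
        assert len(res) == 12 and all(r.retained for r in res)
        ordered, _ = oncoprint_order(res, alts, tert, "low", max_genes=10)
        assert len(ordered) == 10

    def test_memo_sort_blocks_disjoint_genes(self):
        tert = _tertiles(8, 0, 8)
        genes = {
            "GA": ["s00", "s01", "s02", "s03"],
            "GB": ["s04", "s05", "s06", "s07"],
        }
        res, alts = self._results(genes, tert)
        ordered, samples = oncoprint_order(res, alts, tert, "low")
        low = [s for s in samples if tert[s] == "low"]
        assert ordered == ["GA", "GB"]  # equal counts: ties break by name
        # disjoint alteration sets come out as adjacent, non-interleaved blocks
        assert low == ["s00", "s01", "s02", "s03", "s04", "s05", "s06", "s07"]

    def test_single_gene_altered_samples_first(self):
        tert = _tertiles(4, 0, 4)
        res, alts = self._results({"G": ["s01", "s02", "s03"]}, tert)
        _, samples = oncoprint_order(res, alts, tert, "low")
        low = [s for s in samples if tert[s] == "low"]
        assert low == ["s01", "s02", "s03", "s00"]
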