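import numpy as np
import pandas as pd
import pytest

from pathdrp.dataset import (
    DatasetError,
    OmicsMatrix,
    PPINetwork,
    ResponseTable,
    assemble_uniform_dataset,
    deduplicate_drugs,
    filter_low_variance,
    filter_targets,
    normalize_expression,
)
from pathdrp.pathways import PathwayCollection


def om(modality, data, cells, genes):
    return OmicsMatrix(modality, pd.DataFrame(data, index=cells, columns=genes))


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_log2_fpkm_plus_one(self, raw, expected):
        mat = om("GEx", [[raw]], ["c1"], ["g1"])
        assert normalize_expression(mat).values.iloc[0, 0] == expected

    def test_negative_value_named(self):
        mat = om("GEx", [[-1.0]], ["c1"], ["g1"])
        with pytest.raises(DatasetError, match="c1.*g1"):
            normalize_expression(mat)


class TestVarianceFilter:
    def test_constant_gene_removed_high_sd_kept(self):
        mat = om("GEx", [[1.0, 0.0], [1.0, 10.0]], ["c1", "c2"], ["flat", "varied"])
        out = filter_low_variance(mat)
        assert out.gene_order == ["varied"]

    def test_zero_threshold_is_identity(self):
        mat = om("GEx", [[1.0, 0.0], [1.0, 10.0]], ["c1", "c2"], ["a", "b"])
        assert filter_low_variance(mat, 0.0).gene_order == ["a", "b"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        mat = om("GEx", rng.random((10, 20)), [f"c{i}" for i in range(10)],
                 [f"g{i}" for i in range(20)])
        counts = [
            len(filter_low_variance(mat, t).gene_order) for t in (0.0, 0.1, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTargetFilter:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["drug_id", "gene", "score", "channel"])

    def test_confidence_and_channel_rules(self):
        rows = [
            ("d1", "TP53", 850, "experimental"),   # kept
            ("d1", "KRAS", 800, "experimental"),   # strict inequality: dropped
            ("d1", "EGFR", 950, "text-mining"),    # wrong channel: dropped
            ("d2", "BRAF", 900, "database"),       # kept
        ]
        out = filter_targets(self.table(rows))
        assert out == {"d1": frozenset({"TP53"}), "d2": frozenset({"BRAF"})}

    def test_empty_drug_dropped(self):
        out = filter_targets(self.table([("d1", "TP53", 100, "experimental")]))
        assert out == {}

    def test_score_out_of_range_rejected(self):
        with pytest.raises(DatasetError):
            filter_targets(self.table([("d1", "TP53", 1200, "experimental")]))

    def test_monotone_in_min_score(self):
        rows = [("d1", f"g{i}", 700 + 50 * i, "experimental") for i in range(6)]
        counts = [
            sum(len(v) for v in filter_targets(self.table(rows), s).values())
            for s in (700, 800, 900)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDeduplicate:
    def resp(self, rows):
        return ResponseTable(
            pd.DataFrame(rows, columns=["cellline_id", "drug_id", "value"])
        )

    def test_larger_batch_wins(self):
        rows = [(f"c{i}", "X_b1", 1.0) for i in range(5)] + [
            (f"c{i}", "X_b2", 2.0) for i in range(3)
        ]
        out = deduplicate_drugs(self.resp(rows), {"X_b1": "X", "X_b2": "X"})
        assert set(out.records["drug_id"]) == {"X_b1"}

    def test_no_duplicates_identity(self):
        table = self.resp([("c1", "d1", 1.0), ("c1", "d2", 2.0)])
        out = deduplicate_drugs(table, {})
        assert len(out) == 2

    def test_tie_broken_lexicographically(self):
        rows = [("c1", "X_b2", 1.0), ("c2", "X_b2", 1.0),
                ("c1", "X_b1", 2.0), ("c2", "X_b1", 2.0)]
        out = deduplicate_drugs(self.resp(rows), {"X_b1": "X", "X_b2": "X"})
        assert set(out.records["drug_id"]) == {"X_b1"}


class TestAssembly:
    """Hand-traced cascade on a printed toy input."""

    def build_toy(self):
        cells = ["c1"]
        gex = om("GEx", [[1.0, 2.0, 3.0, 4.0]], cells, ["A", "B", "C", "D"])
        mut = om("Mut", [[0.0, 1.0, 0.0]], cells, ["A", "B", "C"])
        cnv = om("CNV", [[0.1, 0.2, 0.3]], cells, ["A", "B", "C"])
        coll = PathwayCollection("toy", (("P1", frozenset({"A", "B"})),), ("A", "B"))
        ppi = PPINetwork.from_edges([("A", "B", 900), ("B", "C", 900)])
        targets = {"d1": frozenset({"A"}), "d2": frozenset({"D"})}
        responses = ResponseTable(
            pd.DataFrame(
                [("c1", "d1", 1.0), ("c1", "d2", 2.0)],
                columns=["cellline_id", "drug_id", "value"],
            )
        )
        return gex, mut, cnv, targets, responses, coll, ppi

    def test_cascade_trace(self):
        gex, mut, cnv, targets, responses, coll, ppi = self.build_toy()
        ds = assemble_uniform_dataset(gex, mut, cnv, targets, {}, responses, coll, ppi)
        assert ds.gene_order == ["A", "B"]  # intersection ∩ pathway genes
        assert ds.drugs == ["d1"]  # d2's target D outside common set
        assert len(ds.responses) == 1
        assert ds.provenance["D_drugs"]["kept"] == 1

    def test_drug_without_targets_logged_at_stage_d(self):
        gex, mut, cnv, targets, responses, coll, ppi = self.build_toy()
        ds = assemble_uniform_dataset(gex, mut, cnv, targets, {}, responses, coll, ppi)
        assert "d2" in ds.provenance["C_targets"]["dropped"] or (
            "d2" in ds.provenance["D_drugs"]["dropped_no_target"]
        )

    def test_idempotent(self):
        gex, mut, cnv, targets, responses, coll, ppi = self.build_toy()
        ds = assemble_uniform_dataset(gex, mut, cnv, targets, {}, responses, coll, ppi)
        ds2 = assemble_uniform_dataset(
            ds.omics["GEx"], ds.omics["Mut"], ds.omics["CNV"],
            ds.drug_features.targets, ds.drug_features.fingerprints,
            ds.responses, ds.collection, ds.ppi,
        )
        assert ds2.gene_order == ds.gene_order
        assert ds2.drugs == ds.drugs
        assert ds2.responses.records.equals(ds.responses.records)

    def test_empty_common_set_rejected_with_stage(self):
        gex, mut, cnv, targets, responses, coll, ppi = self.build_toy()
        lone = PathwayCollection("x", (("P", frozenset({"Z"})),), ("Z",))
        with pytest.raises(DatasetError, match="stage B"):
            assemble_uniform_dataset(gex, mut, cnv, targets, {}, responses, lone, ppi)


def test_mut_matrix_must_be_binary():
    with pytest.raises(DatasetError):
        om("Mut", [[0.5]], ["c1"], ["g1"])


def test_ppi_rejects_self_loops():
    with pytest.raises(DatasetError):
        PPINetwork.from_edges([("A", "A", 500)])


def test_default_synthetic_passes_validator(default_dataset):
    ds, _ = default_dataset
    ds.validate()  # raises on violation
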