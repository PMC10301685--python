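"""Assembly of a uniform multi-omics drug-response dataset.

The raw ingredients — omics matrices (expression, mutation, copy number),
drug-target tables with confidence scores, drug fingerprints, long-form
response records and a protein-interaction edge list — come from
heterogeneous sources with different gene and sample coverage. Models can
only be compared fairly on one shared ("uniform") dataset, so assembly
applies a fixed cascade:

  A. keep cell lines present in every omics matrix and in the responses;
  B. intersect the gene sets of all omics matrices and drop genes that
     belong to no pathway;
  C. drop drug targets outside the common gene set or absent from the
     interaction network;
  D. keep only drugs with at least one surviving target and at least one
     response record.

A provenance report records entity counts at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pathways import PathwayCollection

__all__ = [
    "OmicsMatrix",
    "DrugFeatureSet",
    "ResponseTable",
    "PPINetwork",
    "UniformDataset",
    "normalize_expression",
    "filter_low_variance",
    "filter_targets",
    "deduplicate_drugs",
    "assemble_uniform_dataset",
]

log = logging.getLogger(__name__)

FINGERPRINT_BITS = 512

MODALITIES = ("GEx", "Mut", "CNV")


class DatasetError(ValueError):
    """Raised when inputs violate a dataset contract."""


@dataclass
class OmicsMatrix:
    """One omics modality: real matrix with cell-line rows and gene columns."""

    modality: str
    values: pd.DataFrame  # rows = cell lines, columns = genes

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise DatasetError(f"unknown modality {self.modality!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DatasetError(f"{self.modality}: duplicate row or column labels")
        if self.modality == "Mut":
            vals = self.values.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise DatasetError("Mut values must be 0/1")

    @property
    def gene_order(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cellline_order(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, celllines: Sequence[str], genes: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.modality, self.values.loc[list(celllines), list(genes)])


@dataclass
class DrugFeatureSet:
    """Gene-level targets and 512-bit structural fingerprints per drug."""

    targets: dict[str, frozenset[str]]
    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, fp in self.fingerprints.items():
            fp = np.asarray(fp, dtype=np.int8)
            if fp.shape != (FINGERPRINT_BITS,):
                raise DatasetError(
                    f"fingerprint for {drug!r} has length {fp.size}, "
                    f"expected {FINGERPRINT_BITS}"
                )
            if not np.isin(fp, (0, 1)).all():
                raise DatasetError(f"fingerprint for {drug!r} is not 0/1")
            self.fingerprints[drug] = fp

    @property
    def drugs(self) -> list[str]:
        return sorted(self.targets)


@dataclass
class ResponseTable:
    """Long-form (cell line, drug, value) sensitivity records.

    ``measure`` is ``logIC50`` or ``AUC``; at most one record per
    (cell line, drug) pair.
    """

    records: pd.DataFrame  # columns: cellline_id, drug_id, value
    measure: str = "logIC50"

    REQUIRED = ("cellline_id", "drug_id", "value")

    def __post_init__(self) -> None:
        if self.measure not in ("logIC50", "AUC"):
            raise DatasetError(f"unknown response measure {self.measure!r}")
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise DatasetError(f"response table missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        if not np.isfinite(self.records["value"].to_numpy(dtype=float)).all():
            raise DatasetError("non-finite response value")
        if self.records.duplicated(["cellline_id", "drug_id"]).any():
            raise DatasetError("duplicate (cell line, drug) response record")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def celllines(self) -> list[str]:
        return sorted(self.records["cellline_id"].unique())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())

    def pairs(self) -> list[tuple[str, str]]:
        return list(
            self.records[["cellline_id", "drug_id"]].itertuples(index=False, name=None)
        )

    def restrict(
        self, celllines: Sequence[str] | None = None, drugs: Sequence[str] | None = None
    ) -> "ResponseTable":
        df = self.records
        if celllines is not None:
            df = df[df["cellline_id"].isin(set(celllines))]
        if drugs is not None:
            df = df[df["drug_id"].isin(set(drugs))]
        return ResponseTable(df.copy(), self.measure)


@dataclass
class PPINetwork:
    """Undirected weighted protein-interaction graph over gene symbols."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Sequence[tuple[str, str, float]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b, score in edges:
            if a == b:
                raise DatasetError(f"self-loop on {a!r}")
            if not 0 <= score <= 1000:
                raise DatasetError(f"edge score {score} outside [0, 1000]")
            g.add_edge(a, b, weight=float(score))
        return cls(g)

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class UniformDataset:
    """Aligned omics, drug features, responses and pathways after assembly."""

    omics: dict[str, OmicsMatrix]
    drug_features: DrugFeatureSet
    responses: ResponseTable
    collection: PathwayCollection
    ppi: PPINetwork | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def gene_order(self) -> list[str]:
        return next(iter(self.omics.values())).gene_order

    @property
    def cellline_order(self) -> list[str]:
        return next(iter(self.omics.values())).cellline_order

    @property
    def drugs(self) -> list[str]:
        return self.drug_features.drugs

    def validate(self) -> None:
        """Check every structural invariant; raise DatasetError on violation."""
        genes = self.gene_order
        cells = self.cellline_order
        for mat in self.omics.values():
            if mat.gene_order != genes or mat.cellline_order != cells:
                raise DatasetError(f"{mat.modality}: gene/cell-line order mismatch")
        in_pathway = set().union(*(m for _, m in self.collection.pathways))
        if not set(genes) <= in_pathway:
            raise DatasetError("gene outside every pathway")
        gene_set = set(genes)
        ppi_genes = self.ppi.genes if self.ppi is not None else None
        resp_drugs = set(self.responses.records["drug_id"])
        for drug, targets in self.drug_features.targets.items():
            if not targets:
                raise DatasetError(f"drug {drug!r} has no targets")
            if not targets <= gene_set:
                raise DatasetError(f"drug {drug!r} target outside common gene set")
            if ppi_genes is not None and not targets <= ppi_genes:
                raise DatasetError(f"drug {drug!r} target outside PPI network")
            if drug not in resp_drugs:
                raise DatasetError(f"drug {drug!r} has no response record")
        kept_drugs = set(self.drug_features.targets)
        if not resp_drugs <= kept_drugs:
            raise DatasetError("response record references a dropped drug")
        if not set(self.responses.records["cellline_id"]) <= set(cells):
            raise DatasetError("response record references a dropped cell line")


def normalize_expression(raw: OmicsMatrix) -> OmicsMatrix:
    """log2(FPKM + 1) transform of an expression matrix."""
    vals = raw.values.to_numpy(dtype=float)
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise DatasetError(
            f"negative expression at ({raw.values.index[r]}, {raw.values.columns[c]})"
        )
    return OmicsMatrix(
        raw.modality,
        pd.DataFrame(np.log2(vals + 1.0), index=raw.values.index, columns=raw.values.columns),
    )


def filter_low_variance(gex: OmicsMatrix, sd_threshold: float = 0.1) -> OmicsMatrix:
    """Drop genes whose expression SD across cell lines is below threshold.

    The sample standard deviation (n-1 denominator) is used; column order of
    the survivors is preserved.
    """
    if gex.modality != "GEx":
        raise DatasetError("variance filter applies to GEx only")
    sd = gex.values.std(axis=0, ddof=1)
    keep = sd[sd >= sd_threshold].index
    if len(keep) == 0:
        raise DatasetError("variance filter removed every gene")
    return OmicsMatrix("GEx", gex.values[keep])


def filter_targets(
    targets: pd.DataFrame,
    min_score: int = 800,
    channels: frozenset[str] = frozenset({"experimental", "database"}),
) -> dict[str, frozenset[str]]:
    """Filter a raw drug-target table to high-confidence interactions.

    Keeps records with score strictly greater than ``min_score`` and channel
    in ``channels``; drugs with no surviving target are dropped.

    Parameters
    ----------
    targets
        Columns ``drug_id``, ``gene``, ``score`` (0-1000), ``channel``.
    """
    scores = targets["score"].to_numpy(dtype=float)
    if ((scores < 0) | (scores > 1000)).any():
        raise DatasetError("target confidence score outside [0, 1000]")
    kept = targets[(targets["score"] > min_score) & targets["channel"].isin(channels)]
    mapping = {
        drug: frozenset(group["gene"])
        for drug, group in kept.groupby("drug_id", sort=True)
    }
    if not mapping:
        log.warning("target filter left zero drugs")
    return mapping


def deduplicate_drugs(responses: ResponseTable, batch: Mapping[str, str]) -> ResponseTable:
    """Resolve drugs measured in multiple experimental batches.

    ``batch`` maps each batch-specific drug_id to a canonical drug key; for
    every canonical key the batch measured across the most cell lines is
    kept (ties broken by lexicographically smallest drug_id).
    """
    df = responses.records
    counts = df.groupby("drug_id")["cellline_id"].nunique()
    winners = []
    canon = pd.Series({d: batch.get(d, d) for d in counts.index})
    for _, group in counts.groupby(canon):
        # among max-count batches, smallest label wins (deterministic tie-break)
        winners.append(group[group == group.max()].index.min())
    return ResponseTable(df[df["drug_id"].isin(winners)].copy(), responses.measure)


def assemble_uniform_dataset(
    gex: OmicsMatrix,
    mut: OmicsMatrix,
    cnv: OmicsMatrix,
    targets: Mapping[str, frozenset[str]],
    fingerprints: Mapping[str, np.ndarray],
    responses: ResponseTable,
    collection: PathwayCollection,
    ppi: PPINetwork | None = None,
) -> UniformDataset:
    """Run the filtering cascade and return an aligned, validated dataset."""
    provenance: dict[str, dict] = {"input": {
        "celllines": {m.modality: len(m.cellline_order) for m in (gex, mut, cnv)},
        "genes": {m.modality: len(m.gene_order) for m in (gex, mut, cnv)},
        "drugs": len(targets),
        "responses": len(responses),
        "pathways": collection.m,
    }}

    # Stage A: cell lines present in all omics and in responses
    celllines = sorted(
        set(gex.cellline_order)
        & set(mut.cellline_order)
        & set(cnv.cellline_order)
        & set(responses.records["cellline_id"])
    )
    if not celllines:
        raise DatasetError("stage A: no shared cell lines")
    provenance["A_celllines"] = {"kept": len(celllines)}

    # Stage B: gene intersection across omics, restricted to annotated genes
    in_pathway = set().union(*(m for _, m in collection.pathways))
    common = [
        g
        for g in gex.gene_order
        if g in set(mut.gene_order) and g in set(cnv.gene_order) and g in in_pathway
    ]
    if not common:
        raise DatasetError("stage B: empty common gene set")
    provenance["B_genes"] = {"kept": len(common)}

    # Stage C: targets restricted to common genes (and PPI nodes if given)
    ppi_genes = ppi.genes if ppi is not None else None
    common_set = set(common)
    filtered_targets = {}
    for drug, tset in targets.items():
        kept = tset & common_set
        if ppi_genes is not None:
            kept &= ppi_genes
        if kept:
            filtered_targets[drug] = frozenset(kept)
    provenance["C_targets"] = {
        "drugs_with_targets": len(filtered_targets),
        "dropped": sorted(set(targets) - set(filtered_targets)),
    }

    # Stage D: drugs need both targets and responses
    measured = set(responses.restrict(celllines=celllines).records["drug_id"])
    drugs = sorted(set(filtered_targets) & measured)
    if not drugs:
        raise DatasetError("stage D: zero surviving drugs")
    provenance["D_drugs"] = {
        "kept": len(drugs),
        "dropped_no_response": sorted(set(filtered_targets) - measured),
        "dropped_no_target": sorted(measured - set(filtered_targets)),
    }

    final_responses = responses.restrict(celllines=celllines, drugs=drugs)
    celllines = sorted(set(final_responses.records["cellline_id"]))

    omics = {
        m.modality: m.restrict(celllines, common) for m in (gex, mut, cnv)
    }
    restricted = collection.restrict(common)
    provenance["final"] = {
        "celllines": len(celllines),
        "genes": len(common),
        "drugs": len(drugs),
        "responses": len(final_responses),
        "pathways": restricted.m,
    }

    ds = UniformDataset(
        omics=omics,
        drug_features=DrugFeatureSet(
            targets={d: filtered_targets[d] for d in drugs},
            fingerprints={d: fingerprints[d] for d in drugs if d in fingerprints},
        ),
        responses=final_responses,
        collection=restricted,
        ppi=ppi,
        provenance=provenance,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# File dialects


def read_omics_tsv(path: str | Path, modality: str) -> OmicsMatrix:
    """TSV matrix: header row of gene symbols, first column of cell-line IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(modality, df)


def write_omics_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_targets_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with columns drug_id, gene, score, channel."""
    return pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene": str})


def read_responses_tsv(path: str | Path, measure: str = "logIC50") -> ResponseTable:
    df = pd.read_csv(path, sep="\t", dtype={"cellline_id": str, "drug_id": str})
    return ResponseTable(df[["cellline_id", "drug_id", "value"]], measure)


def write_responses_tsv(table: ResponseTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_fingerprints_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """TSV: first column drug_id, remaining 512 columns the fingerprint bits."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(d): row.to_numpy(dtype=np.int8) for d, row in df.iterrows()}


def read_ppi_tsv(path: str | Path) -> PPINetwork:
    """Three-column edge TSV (gene, gene, score), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"])
    return PPINetwork.from_edges(list(df.itertuples(index=False, name=None)))


def write_provenance(dataset: UniformDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.provenance, indent=2, sort_keys=True))


def morgan_fingerprints(smiles: Mapping[str, str], radius: int = 2) -> dict[str, np.ndarray]:
    """Optional helper: Morgan fingerprints (512 bits) from SMILES via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=FINGERPRINT_BITS)
    out = {}
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DatasetError(f"unparseable SMILES for {drug!r}")
        out[drug] = np.array(gen.GetFingerprint(mol), dtype=np.int8)
    return out
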