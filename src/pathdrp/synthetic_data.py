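"""Synthetic multi-omics drug-sensitivity data with planted pathway signal.

The generator emulates the statistical structure that the benchmark's
analyses assume, with a linear-Gaussian model chosen for its closed-form
oracles:

* latent per-cell-line pathway activities a_{c,p} ~ N(0, 1);
* expression: x_{c,g} = sum_p M_gp w_{g,p} a_{c,p} + noise, shifted
  positive and inverse-transformed to an FPKM scale so the standard
  log2(FPKM+1) preprocessing reproduces it;
* mutations Bernoulli per gene; copy number mildly pathway-correlated;
* each drug gets one target pathway, target genes drawn from its members,
  and a 512-bit fingerprint derived from a per-pathway prototype with
  per-bit flips, so structural similarity tracks target similarity;
* responses: y_{c,d} = mu + b_d + gamma_c + beta * a_{c,p(d)} + eta with
  b_d ~ N(0, tau²), gamma_c ~ N(0, cell_sd²), eta ~ N(0, sigma²).

With tau much larger than beta, response variance is dominated by drug
identity — the regime in which naive per-drug means inflate per-cell-line
rank metrics. The ground truth provides the noise-free regression function
as a performance ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    FINGERPRINT_BITS,
    OmicsMatrix,
    PPINetwork,
    ResponseTable,
    UniformDataset,
    assemble_uniform_dataset,
    filter_low_variance,
    normalize_expression,
)
from .pathways import PathwayCollection, write_gmt
from .prediction import PredictionTable, make_prediction_table

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "oracle_predict", "write_inputs"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults define the package's study conditions.

    beta is the pathway effect in response units per activity unit, tau the
    drug-offset SD, sigma the observation-noise SD (all in label units,
    i.e. log IC50). tau >> beta by default so drug identity dominates.
    """

    n_celllines: int = 120
    n_drugs: int = 30
    n_genes: int = 300
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 30)
    beta: float = 1.5
    tau: float = 2.0
    cell_sd: float = 0.5
    sigma: float = 0.5
    loading_sd: float = 1.0
    gex_noise_sd: float = 0.3
    mutation_rate: float = 0.1
    fp_flip_rate: float = 0.05
    ppi_within_density: float = 0.3
    ppi_background_edges: int = 200
    targets_per_drug: tuple[int, int] = (1, 4)
    mu: float = -2.0
    seed: int = 7

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("pathway size range must fit within the gene count")
        for name in ("beta", "tau", "cell_sd", "sigma", "loading_sd", "gex_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("mutation_rate", "fp_flip_rate", "ppi_within_density"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated dataset."""

    activities: pd.DataFrame  # cell lines x pathways
    target_pathway: dict[str, str]  # drug -> pathway id
    drug_offsets: pd.Series
    cell_offsets: pd.Series
    config: SyntheticConfig
    noise_free: pd.DataFrame = field(default=None)  # cell lines x drugs regression surface

    def regression_value(self, cell: str, drug: str) -> float:
        return float(self.noise_free.loc[cell, drug])


@dataclass
class RawInputs:
    """The pre-assembly pieces, in exactly the dialects the pipeline reads."""

    gex_fpkm: OmicsMatrix
    mut: OmicsMatrix
    cnv: OmicsMatrix
    targets: dict[str, frozenset[str]]
    fingerprints: dict[str, np.ndarray]
    responses: ResponseTable
    collection: PathwayCollection
    ppi: PPINetwork


def _make_collection(cfg: SyntheticConfig, rng, genes) -> PathwayCollection:
    lo, hi = cfg.pathway_size_range
    pathways = []
    for p in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        pathways.append((f"PW{p:03d}", members))
    return PathwayCollection("synthetic", tuple(pathways), tuple(genes))


def _make_ppi(cfg: SyntheticConfig, rng, collection, genes) -> PPINetwork:
    edges: dict[tuple[str, str], float] = {}

    def add(a: str, b: str) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, float(rng.integers(700, 1001)))

    for _, members in collection.pathways:
        mem = sorted(members)
        # a path through the members guarantees every annotated gene a node
        for a, b in zip(mem[:-1], mem[1:]):
            add(a, b)
        n = len(mem)
        n_extra = int(cfg.ppi_within_density * n * (n - 1) / 2)
        for _ in range(n_extra):
            i, j = rng.integers(0, n, size=2)
            if i != j:
                add(mem[i], mem[j])
    for _ in range(cfg.ppi_background_edges):
        i, j = rng.integers(0, len(genes), size=2)
        if i != j:
            add(genes[i], genes[j])
    return PPINetwork.from_edges([(a, b, s) for (a, b), s in edges.items()])


def generate_raw(config: SyntheticConfig) -> tuple[RawInputs, GroundTruth]:
    """Draw the raw (pre-assembly) inputs and the latent ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    C, D, G, P = (
        config.n_celllines,
        config.n_drugs,
        config.n_genes,
        config.n_pathways,
    )
    cells = [f"CL{i:03d}" for i in range(C)]
    drugs = [f"DR{i:03d}" for i in range(D)]
    genes = [f"G{i:04d}" for i in range(G)]

    collection = _make_collection(config, rng, genes)
    mask = np.zeros((G, P))
    gidx = {g: i for i, g in enumerate(genes)}
    for j, (_, members) in enumerate(collection.pathways):
        mask[[gidx[g] for g in members], j] = 1.0

    # latent pathway activities per cell line
    A = rng.normal(size=(C, P))

    # expression: pathway-loaded signal plus noise, pushed onto FPKM scale
    W = rng.normal(scale=config.loading_sd, size=(G, P)) * mask.astype(bool)
    X = A @ W.T + rng.normal(scale=config.gex_noise_sd, size=(C, G))
    shift = -X.min() + 0.1
    fpkm = np.exp2(X + shift) - 1.0  # log2(FPKM+1) recovers X + shift
    gex = OmicsMatrix("GEx", pd.DataFrame(fpkm, index=cells, columns=genes))

    mut = OmicsMatrix(
        "Mut",
        pd.DataFrame(
            (rng.random((C, G)) < config.mutation_rate).astype(float),
            index=cells,
            columns=genes,
        ),
    )
    W_cnv = rng.normal(scale=0.3, size=(G, P)) * mask.astype(bool)
    cnv_vals = A @ W_cnv.T + rng.normal(scale=1.0, size=(C, G))
    cnv = OmicsMatrix("CNV", pd.DataFrame(cnv_vals, index=cells, columns=genes))

    # drugs: one target pathway each; targets from its members
    pw_ids = list(collection.pathway_ids)
    target_pathway: dict[str, str] = {}
    targets: dict[str, frozenset[str]] = {}
    lo_t, hi_t = config.targets_per_drug
    prototypes = (rng.random((P, FINGERPRINT_BITS)) < 0.5).astype(np.int8)
    fingerprints: dict[str, np.ndarray] = {}
    for d in drugs:
        j = int(rng.integers(P))
        target_pathway[d] = pw_ids[j]
        members = sorted(collection.pathways[j][1])
        k = int(rng.integers(lo_t, min(hi_t, len(members)) + 1))
        targets[d] = frozenset(rng.choice(members, size=k, replace=False))
        flips = rng.random(FINGERPRINT_BITS) < config.fp_flip_rate
        fingerprints[d] = np.where(flips, 1 - prototypes[j], prototypes[j]).astype(np.int8)

    # responses over the full grid
    b = rng.normal(scale=config.tau, size=D)
    gamma = rng.normal(scale=config.cell_sd, size=C)
    pw_index = {pid: j for j, pid in enumerate(pw_ids)}
    signal = np.stack([A[:, pw_index[target_pathway[d]]] for d in drugs], axis=1)
    surface = config.mu + b[None, :] + gamma[:, None] + config.beta * signal
    y = surface + rng.normal(scale=config.sigma, size=(C, D))
    records = pd.DataFrame(
        [(c, d, y[i, j]) for i, c in enumerate(cells) for j, d in enumerate(drugs)],
        columns=["cellline_id", "drug_id", "value"],
    )

    ppi = _make_ppi(config, rng, collection, genes)
    truth = GroundTruth(
        activities=pd.DataFrame(A, index=cells, columns=pw_ids),
        target_pathway=target_pathway,
        drug_offsets=pd.Series(b, index=drugs),
        cell_offsets=pd.Series(gamma, index=cells),
        config=config,
        noise_free=pd.DataFrame(surface, index=cells, columns=drugs),
    )
    raw = RawInputs(
        gex_fpkm=gex,
        mut=mut,
        cnv=cnv,
        targets=targets,
        fingerprints=fingerprints,
        responses=ResponseTable(records),
        collection=collection,
        ppi=ppi,
    )
    return raw, truth


def generate(config: SyntheticConfig | None = None) -> tuple[UniformDataset, GroundTruth]:
    """Generate raw inputs and push them through the real assembly cascade.

    The emitted dataset is indistinguishable from a file-based run: raw
    expression is FPKM, gets log-normalized and variance-filtered, genes
    outside every pathway are dropped, and drug/cell-line filters apply.
    """
    config = config or SyntheticConfig()
    raw, truth = generate_raw(config)
    gex = filter_low_variance(normalize_expression(raw.gex_fpkm))
    dataset = assemble_uniform_dataset(
        gex,
        raw.mut,
        raw.cnv,
        raw.targets,
        raw.fingerprints,
        raw.responses,
        raw.collection,
        raw.ppi,
    )
    return dataset, truth


def oracle_predict(truth: GroundTruth, responses: ResponseTable) -> PredictionTable:
    """Score pairs with the noise-free regression function (the ceiling)."""
    pairs = responses.pairs()
    y_true = responses.records["value"].to_numpy(dtype=float)
    y_pred = np.array([truth.regression_value(c, d) for c, d in pairs])
    return make_prediction_table(pairs, y_true, y_pred)


def write_inputs(raw: RawInputs, outdir: str | Path) -> dict[str, Path]:
    """Write raw inputs in the pipeline's file dialects; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gex": outdir / "gex_fpkm.tsv",
        "mut": outdir / "mut.tsv",
        "cnv": outdir / "cnv.tsv",
        "targets": outdir / "targets.tsv",
        "fingerprints": outdir / "fingerprints.tsv",
        "responses": outdir / "responses.tsv",
        "pathways": outdir / "pathways.gmt",
        "ppi": outdir / "ppi.tsv",
    }
    raw.gex_fpkm.values.to_csv(paths["gex"], sep="\t")
    raw.mut.values.to_csv(paths["mut"], sep="\t")
    raw.cnv.values.to_csv(paths["cnv"], sep="\t")
    rows = [
        (d, g, 900, "experimental")
        for d, tset in sorted(raw.targets.items())
        for g in sorted(tset)
    ]
    pd.DataFrame(rows, columns=["drug_id", "gene", "score", "channel"]).to_csv(
        paths["targets"], sep="\t", index=False
    )
    fp = pd.DataFrame(
        {d: v for d, v in sorted(raw.fingerprints.items())}
    ).T
    fp.index.name = "drug_id"
    fp.to_csv(paths["fingerprints"], sep="\t")
    raw.responses.records.to_csv(paths["responses"], sep="\t", index=False)
    write_gmt(raw.collection, paths["pathways"])
    with paths["ppi"].open("w") as fh:
        for a, b, data in sorted(raw.ppi.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.0f}\n")
    return paths
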