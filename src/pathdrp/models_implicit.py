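"""Implicit pathway models: attention over member genes, and enrichment features.

Two families. The hierarchical-attention network ("hidra" style) dedicates
a small subnetwork to each pathway: it reads only the member genes'
expression plus a learned drug embedding, weights the member genes by a
softmax attention, and emits one activation score per pathway; scores are
re-weighted by a pathway-level attention, concatenated with the drug
embedding and fed to a dense head. The enrichment-feature pipeline
("pathdsp" style) converts molecular profiles into per-pathway permutation
z-scores — for continuous profiles the observed statistic is the mean value
over member genes, for set-valued profiles the overlap count, each compared
to its null distribution under random gene-label permutations — and feeds
the resulting (entity x pathway) blocks to a plain dense network. Drug
targets may first be diffused over a protein-interaction network with a
random walk with restart so that enrichment sees network neighbourhoods
rather than bare target sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .autodiff import Tensor, concat, relu, softmax, tanh
from .dataset import FINGERPRINT_BITS, UniformDataset
from .features import Featurizer, get_featurizer
from .nn import DenseHead, Linear, Network, TrainConfig, dropout, gather_cols
from .pathways import PathwayCollection

__all__ = [
    "build_hidra",
    "compute_enrichment",
    "propagate_targets",
    "enrichment_features",
    "build_pathdsp",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hierarchical attention network


class HiDRANet(Network):
    """Per-pathway attention subnetworks + drug encoder + dense head."""

    def __init__(
        self,
        collection: PathwayCollection,
        gene_order: Sequence[str],
        drug_rep: str,
        config: TrainConfig,
        embed_size: int = 32,
        att_hidden: int = 8,
        drug_encoder: tuple[int, ...] = (64,),
        temperature: float = 1.0,
    ):
        super().__init__(config)
        if drug_rep not in ("targets", "fingerprint"):
            raise ValueError(f"unknown drug_rep {drug_rep!r}")
        self.featurizer = get_featurizer(
            "gex_targets" if drug_rep == "targets" else "gex_fp"
        )
        self.G = len(gene_order)
        self.drug_dim = self.G if drug_rep == "targets" else FINGERPRINT_BITS
        self.temperature = temperature
        rng = np.random.default_rng(config.seed)
        index = {g: i for i, g in enumerate(gene_order)}

        # drug encoder: drug features -> embedding
        widths = [self.drug_dim, *drug_encoder, embed_size]
        self.encoder = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

        # one attention subnetwork per pathway (pathways emptied by the gene
        # restriction are dropped with a warning)
        self.member_idx: list[np.ndarray] = []
        self.pathway_ids: list[str] = []
        self.att_in: list[Linear] = []
        self.att_out: list[Linear] = []
        self.score: list[Linear] = []
        for pid, members in collection.pathways:
            idx = np.array(sorted(index[g] for g in members if g in index), dtype=np.intp)
            if idx.size == 0:
                log.warning("pathway %s empty after gene restriction; dropped", pid)
                continue
            self.pathway_ids.append(pid)
            self.member_idx.append(idx)
            self.att_in.append(Linear(idx.size + embed_size, att_hidden, rng))
            self.att_out.append(Linear(att_hidden, idx.size, rng))
            self.score.append(Linear(1 + embed_size, 1, rng))
        self.m = len(self.pathway_ids)

        # pathway-level attention over the score vector
        self.patt_in = Linear(self.m, att_hidden, rng)
        self.patt_out = Linear(att_hidden, self.m, rng)

        self.head = DenseHead(self.m + embed_size, config.hidden, rng)
        self._layers = [
            *self.encoder,
            *self.att_in,
            *self.att_out,
            *self.score,
            self.patt_in,
            self.patt_out,
            *self.head.hidden_layers,
            self.head.out,
        ]

    def attention_weights(self, X: np.ndarray) -> list[np.ndarray]:
        """Gene-level attention per pathway (rows sum to 1), for inspection."""
        _, atts, _ = self._forward(Tensor(np.asarray(X, dtype=np.float64)))
        return [a.data for a in atts]

    def pathway_activations(self, X: np.ndarray) -> np.ndarray:
        """Raw per-pathway activation scores (batch x m), before the
        pathway-level re-weighting: each depends only on its member genes'
        expression and the drug embedding."""
        _, _, s = self._forward(Tensor(np.asarray(X, dtype=np.float64)))
        return s.data

    def _forward(self, x: Tensor) -> tuple[Tensor, list[Tensor], Tensor]:
        gex = gather_cols(x, np.arange(self.G))
        drug = gather_cols(x, np.arange(self.G, self.G + self.drug_dim))
        e = drug
        for layer in self.encoder:
            e = relu(layer(e))
        scores = []
        atts = []
        inv_t = 1.0 / self.temperature
        for idx, a_in, a_out, sc in zip(
            self.member_idx, self.att_in, self.att_out, self.score
        ):
            xg = gather_cols(gex, idx)
            logits = a_out(tanh(a_in(concat([xg, e], axis=1)))) * inv_t
            att = softmax(logits, axis=1)
            atts.append(att)
            context = (att * xg).sum(axis=1, keepdims=True)
            scores.append(relu(sc(concat([context, e], axis=1))))
        s = concat(scores, axis=1)
        beta = softmax(self.patt_out(tanh(self.patt_in(s))) * inv_t, axis=1)
        return concat([beta * s, e], axis=1), atts, s

    def forward(self, X, training=False, rng=None):
        h, _, _ = self._forward(Tensor(np.asarray(X, dtype=np.float64)))
        if training and self.config.dropout > 0:
            h = dropout(h, self.config.dropout, rng)
        return self.head(h, self.config.dropout if training else 0.0, rng)


def build_hidra(
    collection: PathwayCollection,
    gene_order: Sequence[str],
    drug_rep: str,
    config: TrainConfig,
    **kwargs,
) -> HiDRANet:
    """Build the per-pathway attention network.

    ``drug_rep`` selects the drug encoder input: gene-level target vectors
    (length G) or 512-bit structural fingerprints.
    """
    return HiDRANet(collection, gene_order, drug_rep, config, **kwargs)


# ---------------------------------------------------------------------------
# Enrichment scores


def compute_enrichment(
    profile: Mapping[str, float] | set[str] | frozenset[str],
    collection: PathwayCollection,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation z-score of each pathway against a molecular profile.

    For a continuous profile (gene -> value) the observed statistic for
    pathway p is the mean value over its members; for a set profile it is
    the overlap count. The null permutes gene labels ``n_permutations``
    times; the score is (S_obs - mean(S_perm)) / sd(S_perm), with 0 when the
    null is degenerate (sd = 0) or the pathway has no member in the profile
    support.
    """
    universe = list(collection.gene_universe)
    uni_index = {g: i for i, g in enumerate(universe)}
    is_set = isinstance(profile, (set, frozenset))
    values = np.zeros(len(universe))
    if is_set:
        ignored = set(profile) - set(uni_index)
        support = set(profile) & set(uni_index)
        for g in support:
            values[uni_index[g]] = 1.0
    else:
        ignored = set(profile) - set(uni_index)
        support = set()
        for g, v in profile.items():
            if g in uni_index:
                values[uni_index[g]] = float(v)
                support.add(g)
    if ignored:
        log.warning("%d profile gene(s) outside the collection universe ignored", len(ignored))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, len(universe)))
    for i in range(n_permutations):
        perms[i] = values[rng.permutation(len(universe))]

    scores = {}
    for pid, members in collection.pathways:
        idx = np.array([uni_index[g] for g in members if g in uni_index], dtype=np.intp)
        if idx.size == 0 or not (members & support):
            scores[pid] = 0.0
            continue
        if is_set:
            s_obs = float(values[idx].sum())
            s_perm = perms[:, idx].sum(axis=1)
        else:
            s_obs = float(values[idx].mean())
            s_perm = perms[:, idx].mean(axis=1)
        sd = s_perm.std(ddof=0)
        scores[pid] = 0.0 if sd == 0 else (s_obs - s_perm.mean()) / sd
    return pd.Series(scores, name="enrichment")


def propagate_targets(
    targets: set[str] | frozenset[str],
    ppi,
    restart_prob: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> pd.Series:
    """Random walk with restart from a drug's target genes over the PPI graph.

    Iterates s <- a*r + (1-a)*W_norm s with W the edge-weight matrix
    column-normalized and r uniform over the targets; the stationary scores
    are non-negative and sum to 1.
    """
    nodes = sorted(ppi.graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    seeds = sorted(set(targets) & set(nodes))
    if not seeds:
        raise ValueError("no target gene present in the interaction network")
    W = nx.to_numpy_array(ppi.graph, nodelist=nodes, weight="weight")
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    r = np.zeros(len(nodes))
    r[[index[g] for g in seeds]] = 1.0 / len(seeds)
    s = r.copy()
    a = restart_prob
    for _ in range(max_iter):
        s_next = a * r + (1 - a) * (W @ s)
        if np.abs(s_next - s).sum() < tol:
            return pd.Series(s_next, index=nodes, name="rwr")
        s = s_next
    raise RuntimeError(f"random walk did not converge within {max_iter} iterations")


def enrichment_features(
    dataset: UniformDataset,
    collection: PathwayCollection | None = None,
    blocks: Sequence[str] = ("GEx", "T"),
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-entity pathway enrichment blocks for the dense enrichment model.

    Cell-line blocks (``GEx``/``CNV`` continuous, ``Mut`` set-valued) score
    each cell line's profile; the drug block ``T`` scores each drug's target
    set, diffused over the PPI network when one is attached. ``FP`` is
    passed through raw (fingerprint bits are not gene-indexed; the network
    projects them). Expensive by construction: one permutation null per
    profile.
    """
    collection = collection or dataset.collection
    out: dict[str, pd.DataFrame] = {}
    rng = np.random.default_rng(seed)
    for block in blocks:
        if block in ("GEx", "CNV"):
            mat = dataset.omics[block].values
            rows = {
                c: compute_enrichment(
                    dict(zip(mat.columns, mat.loc[c])), collection,
                    n_permutations, int(rng.integers(2**31)),
                )
                for c in mat.index
            }
        elif block == "Mut":
            mat = dataset.omics["Mut"].values
            rows = {
                c: compute_enrichment(
                    frozenset(mat.columns[mat.loc[c] == 1]), collection,
                    n_permutations, int(rng.integers(2**31)),
                )
                for c in mat.index
            }
        elif block == "T":
            rows = {}
            for d in dataset.drugs:
                tset = dataset.drug_features.targets[d]
                if dataset.ppi is not None:
                    prof = propagate_targets(tset, dataset.ppi)
                    rows[d] = compute_enrichment(
                        prof.to_dict(), collection, n_permutations,
                        int(rng.integers(2**31)),
                    )
                else:
                    rows[d] = compute_enrichment(
                        tset, collection, n_permutations, int(rng.integers(2**31))
                    )
        elif block == "FP":
            rows = {
                d: pd.Series(fp.astype(float))
                for d, fp in dataset.drug_features.fingerprints.items()
            }
        else:
            raise ValueError(f"unknown enrichment block {block!r}")
        out[block] = pd.DataFrame(rows).T
    return out


# ---------------------------------------------------------------------------
# Dense network over enrichment features

CELL_BLOCKS = ("GEx", "Mut", "CNV")
DRUG_BLOCKS = ("T", "FP")


class PathDSPNet(Network):
    """Dense regression network over pathway-enrichment feature blocks."""

    def __init__(self, features: dict[str, pd.DataFrame], config: TrainConfig):
        super().__init__(config)
        unknown = set(features) - set(CELL_BLOCKS) - set(DRUG_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature block(s) {sorted(unknown)}")
        self.blocks = dict(features)
        widths = {
            name: df.shape[1] for name, df in features.items() if name != "FP"
        }
        if len(set(widths.values())) > 1:
            raise ValueError(f"enrichment blocks disagree on pathway count: {widths}")
        self.m = next(iter(widths.values()))
        cell_idx = None
        for name in CELL_BLOCKS:
            if name in features:
                idx = features[name].index
                if cell_idx is not None and not idx.equals(cell_idx):
                    raise ValueError("cell-line blocks have mismatched indices")
                cell_idx = idx
        self.order = [n for n in (*CELL_BLOCKS, *DRUG_BLOCKS) if n in features]
        rng = np.random.default_rng(config.seed)
        self.fp_proj = (
            Linear(FINGERPRINT_BITS, self.m, rng) if "FP" in features else None
        )
        n_in = self.m * len(self.order)
        self.head = DenseHead(n_in, config.hidden, rng)
        self._layers = [*self.head.hidden_layers, self.head.out]
        if self.fp_proj is not None:
            self._layers.append(self.fp_proj)
        self.featurizer = self._make_featurizer()

    def _make_featurizer(self) -> Featurizer:
        blocks, order = self.blocks, self.order

        def build(ds: UniformDataset, pairs) -> np.ndarray:
            cells = [c for c, _ in pairs]
            drugs = [d for _, d in pairs]
            cols = []
            for name in order:
                frame = blocks[name]
                keys = cells if name in CELL_BLOCKS else drugs
                missing = set(keys) - set(frame.index)
                if missing:
                    raise ValueError(
                        f"block {name!r} missing entries {sorted(missing)[:5]}"
                    )
                cols.append(frame.loc[keys].to_numpy(dtype=np.float64))
            return np.hstack(cols)

        def continuous_cols(ds: UniformDataset) -> np.ndarray:
            # enrichment z-scores are continuous; fingerprint bits are not
            cols, start = [], 0
            for name in order:
                width = blocks[name].shape[1]
                if name != "FP":
                    cols.append(np.arange(start, start + width))
                start += width
            return np.concatenate(cols)

        return Featurizer("pathdsp", build, continuous_cols)

    def forward(self, X, training=False, rng=None):
        x = Tensor(np.asarray(X, dtype=np.float64))
        pieces, start = [], 0
        for name in self.order:
            width = self.blocks[name].shape[1]
            part = gather_cols(x, np.arange(start, start + width))
            if name == "FP":
                part = self.fp_proj(part)
            pieces.append(part)
            start += width
        h = concat(pieces, axis=1)
        if training and self.config.dropout > 0:
            h = dropout(h, self.config.dropout, rng)
        return self.head(h, self.config.dropout if training else 0.0, rng)


def build_pathdsp(features: dict[str, pd.DataFrame], config: TrainConfig) -> PathDSPNet:
    """Build the dense enrichment-feature network for a chosen block variant."""
    return PathDSPNet(features, config)
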