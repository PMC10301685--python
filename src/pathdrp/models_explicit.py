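"""Explicit pathway models: networks with a membership-wired sparse layer.

Two families are provided. The first ("pathdnn" style) connects a
concatenated drug-target / gene-expression input directly to one node per
pathway, with connections allowed only where the gene belongs to the
pathway; a dense head follows. The second ("cds" style) first collapses the
per-gene input features (target bit, expression, optionally copy number)
into one node per gene through a block-diagonal feature->gene matrix M_XG,
then applies the gene->pathway membership mask M_GP, then the dense head.

Because both read gene-level drug features, structural fingerprints are
rejected at construction time: explicit models can only use gene-level
drug representations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor
from .dataset import UniformDataset
from .features import Featurizer, Standardizer, get_featurizer
from .nn import DenseHead, Linear, Network, TrainConfig, dropout, fit
from .pathways import PathwayCollection, membership_mask
from .prediction import PredictionTable, make_prediction_table

__all__ = ["build_pathdnn", "build_cds", "train_regressor"]


class ConfigurationError(ValueError):
    pass


class PathDNNNet(Network):
    """Input (2G) -> masked pathway layer (m) -> dense head -> scalar.

    The membership-masked layer is linear: pathway activity is a signed
    quantity, and a rectifier at the bottleneck would discard half its
    range; all nonlinearity lives in the dense head.
    """

    def __init__(
        self,
        collection: PathwayCollection,
        gene_order: Sequence[str],
        config: TrainConfig,
    ):
        super().__init__(config)
        self.featurizer = get_featurizer("pathdnn")
        rng = np.random.default_rng(config.seed)
        mgp = membership_mask(collection, gene_order).to_numpy(dtype=np.float64)
        # both the drug-target block and the expression block reach a pathway
        # node through the same gene memberships
        stacked = np.vstack([mgp, mgp])
        self.pathway_layer = Linear(stacked.shape[0], stacked.shape[1], rng, mask=stacked)
        self.head = DenseHead(collection.m, config.hidden, rng)
        self._layers = [self.pathway_layer, *self.head.hidden_layers, self.head.out]

    def forward(self, X, training=False, rng=None):
        h = self.pathway_layer(Tensor(X))
        if training and self.config.dropout > 0:
            h = dropout(h, self.config.dropout, rng)
        return self.head(h, self.config.dropout if training else 0.0, rng)


class CDSNet(Network):
    """Per-gene features -> gene layer (M_XG) -> pathway layer (M_GP) -> head."""

    def __init__(
        self,
        collection: PathwayCollection,
        gene_order: Sequence[str],
        modalities: Sequence[str],
        config: TrainConfig,
    ):
        super().__init__(config)
        modalities = tuple(modalities)
        if not modalities or not set(modalities) <= {"GEx", "CNV"}:
            raise ConfigurationError("modalities must be a non-empty subset of {GEx, CNV}")
        self.modalities = modalities
        with_cnv = "CNV" in modalities
        self.featurizer = get_featurizer("cds_gex_cnv" if with_cnv else "cds_gex")
        rng = np.random.default_rng(config.seed)
        G = len(gene_order)
        k = 1 + len(modalities)  # target bit + one value per omics modality
        # block-diagonal M_XG: gene g's node sees exactly its own k features
        mxg = np.zeros((G * k, G))
        for g in range(G):
            mxg[g * k : (g + 1) * k, g] = 1.0
        self.gene_layer = Linear(G * k, G, rng, mask=mxg)
        mgp = membership_mask(collection, gene_order).to_numpy(dtype=np.float64)
        self.pathway_layer = Linear(G, collection.m, rng, mask=mgp)
        self.head = DenseHead(collection.m, config.hidden, rng)
        self._layers = [
            self.gene_layer,
            self.pathway_layer,
            *self.head.hidden_layers,
            self.head.out,
        ]

    def forward(self, X, training=False, rng=None):
        h = self.gene_layer(Tensor(X))
        h = self.pathway_layer(h)
        if training and self.config.dropout > 0:
            h = dropout(h, self.config.dropout, rng)
        return self.head(h, self.config.dropout if training else 0.0, rng)


def _reject_fingerprints(drug_rep: str) -> None:
    if drug_rep == "fingerprint":
        raise ConfigurationError(
            "explicit models wire drug features through gene-pathway membership "
            "and can only utilize gene-level drug representations (targets), "
            "not structural fingerprints"
        )


def build_pathdnn(
    collection: PathwayCollection,
    gene_order: Sequence[str],
    config: TrainConfig,
    drug_rep: str = "targets",
) -> PathDNNNet:
    """Build the membership-masked pathway network (expression + targets)."""
    _reject_fingerprints(drug_rep)
    return PathDNNNet(collection, gene_order, config)


def build_cds(
    collection: PathwayCollection,
    gene_order: Sequence[str],
    modalities: Sequence[str],
    config: TrainConfig,
    drug_rep: str = "targets",
) -> CDSNet:
    """Build the gene-layer network (M_XG then M_GP wiring)."""
    _reject_fingerprints(drug_rep)
    return CDSNet(collection, gene_order, modalities, config)


def train_regressor(
    network: Network,
    dataset: UniformDataset,
    fold: dict[str, list[tuple[str, str]]],
    featurizer: Featurizer | None = None,
) -> tuple[Network, PredictionTable]:
    """Train on a fold's train pairs, early-stop on val, predict test pairs.

    Continuous feature columns (expression, copy number) are z-scored with
    train-fold statistics only; binary columns pass through unchanged.
    Label values are used raw, so reported RMSE is in label units.
    """
    featurizer = featurizer or network.featurizer
    resp = dataset.responses.records.set_index(["cellline_id", "drug_id"])["value"]

    def xy(pairs):
        X = featurizer.build(dataset, pairs)
        y = resp.loc[list(pairs)].to_numpy(dtype=np.float64)
        return X, y

    X_tr, y_tr = xy(fold["train"])
    X_val, y_val = xy(fold["val"])
    X_te, y_te = xy(fold["test"])
    std = Standardizer(featurizer.continuous_cols(dataset)).fit(X_tr)
    fit(network, std.transform(X_tr), y_tr, std.transform(X_val), y_val)
    preds = network.predict(std.transform(X_te))
    return network, make_prediction_table(fold["test"], y_te, preds)
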