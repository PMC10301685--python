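"""Universal baselines: naive group-mean predictors, a five-layer MLP,
and a randomized-trees regressor.

The naive predictor is the reference point for every comparison: it uses no
molecular features at all, only the identity of the drug and/or cell line.
Under leave-cell-lines-out it predicts each drug's training-set mean
response, so all test cell lines receive the same value per drug; under
leave-drugs-out it predicts each cell line's mean; under leave-pairs-out it
averages the two component means (global mean standing in for a missing
component). Any model that fails to beat it has learned nothing beyond
entity identity — the inflation trap that per-cell-line rank metrics are
prone to when responses are dominated by drug identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .autodiff import Tensor
from .dataset import FINGERPRINT_BITS, ResponseTable, UniformDataset
from .features import Featurizer, get_featurizer
from .nn import DenseHead, Network, TrainConfig
from .prediction import PredictionTable, make_prediction_table

__all__ = ["NaiveModel", "naive_fit", "naive_predict", "build_mlp", "build_rf", "RFRegressor"]


@dataclass
class NaiveModel:
    scheme: str
    drug_means: dict[str, float]
    cell_means: dict[str, float]
    global_mean: float


def naive_fit(train: ResponseTable, scheme: str) -> NaiveModel:
    """Compute the scheme-specific group means on training pairs only."""
    if scheme not in ("LPO", "LCO", "LDO"):
        raise ValueError(f"unknown scheme {scheme!r}")
    df = train.records
    if df.empty:
        raise ValueError("empty training responses")
    # sequential sum/count in table order: the means are exactly reproducible
    # by any independent group-by accumulation over the same record order
    drug_sum: dict[str, list] = {}
    cell_sum: dict[str, list] = {}
    total, n = 0.0, 0
    for c, d, v in df[["cellline_id", "drug_id", "value"]].itertuples(index=False):
        v = float(v)
        drug_sum.setdefault(d, [0.0, 0])
        drug_sum[d][0] += v
        drug_sum[d][1] += 1
        cell_sum.setdefault(c, [0.0, 0])
        cell_sum[c][0] += v
        cell_sum[c][1] += 1
        total += v
        n += 1
    drug_means = (
        {d: s / k for d, (s, k) in drug_sum.items()} if scheme in ("LCO", "LPO") else {}
    )
    cell_means = (
        {c: s / k for c, (s, k) in cell_sum.items()} if scheme in ("LDO", "LPO") else {}
    )
    return NaiveModel(scheme, drug_means, cell_means, total / n)


def naive_predict(model: NaiveModel, pairs, y_true=None) -> PredictionTable:
    """Predict each test pair from the fitted group means.

    LCO requires every test drug to be seen in train; LDO every test cell
    line (both hold by construction of the corresponding splits). LPO
    averages the drug and cell-line means, substituting the global mean for
    a component whose entity was never seen in train.
    """
    preds = []
    for c, d in pairs:
        if model.scheme == "LCO":
            if d not in model.drug_means:
                raise KeyError(
                    f"LCO naive predictor assumes every test drug is in train; {d!r} is not"
                )
            preds.append(model.drug_means[d])
        elif model.scheme == "LDO":
            if c not in model.cell_means:
                raise KeyError(
                    f"LDO naive predictor assumes every test cell line is in train; {c!r} is not"
                )
            preds.append(model.cell_means[c])
        else:
            dm = model.drug_means.get(d, model.global_mean)
            cm = model.cell_means.get(c, model.global_mean)
            preds.append(0.5 * (dm + cm))
    y = np.full(len(preds), np.nan) if y_true is None else np.asarray(y_true, float)
    return make_prediction_table(list(pairs), y, np.array(preds))


def naive_fit_predict(
    dataset: UniformDataset, fold: dict, scheme: str
) -> PredictionTable:
    """Fit on a fold's train pairs and score its test pairs."""
    resp = dataset.responses.records.set_index(["cellline_id", "drug_id"])["value"]
    train = ResponseTable(
        resp.loc[fold["train"]].reset_index().rename(columns={"value": "value"}),
        dataset.responses.measure,
    )
    model = naive_fit(train, scheme)
    y_true = resp.loc[fold["test"]].to_numpy(dtype=float)
    return naive_predict(model, fold["test"], y_true)


class MLPNet(Network):
    """Five-layer dense network (four hidden + scalar output)."""

    DEFAULT_HIDDEN = (128, 64, 32, 16)

    def __init__(self, n_inputs: int, config: TrainConfig, featurizer: Featurizer):
        if len(config.hidden) != 4:
            config = replace(config, hidden=self.DEFAULT_HIDDEN)
        super().__init__(config)
        self.featurizer = featurizer
        rng = np.random.default_rng(config.seed)
        self.head = DenseHead(n_inputs, config.hidden, rng)
        self._layers = [*self.head.hidden_layers, self.head.out]

    def forward(self, X, training=False, rng=None):
        h = Tensor(np.asarray(X, dtype=np.float64))
        return self.head(h, self.config.dropout if training else 0.0, rng)


def build_mlp(dataset: UniformDataset, drug_rep: str, config: TrainConfig) -> MLPNet:
    """Dense baseline over [expression | targets] or [expression | fingerprint]."""
    G = len(dataset.gene_order)
    if drug_rep == "targets":
        return MLPNet(2 * G, config, get_featurizer("gex_targets"))
    if drug_rep == "fingerprint":
        return MLPNet(G + FINGERPRINT_BITS, config, get_featurizer("gex_fp"))
    raise ValueError(f"unknown drug_rep {drug_rep!r}")


class RFRegressor:
    """Randomized-trees baseline behind the shared fit/predict contract."""

    def __init__(self, drug_rep: str, n_trees: int = 500, max_depth=None, seed: int = 0):
        self.featurizer = get_featurizer(
            "gex_targets" if drug_rep == "targets" else "gex_fp"
        )
        self.model = RandomForestRegressor(
            n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
        )

    def fit_predict(
        self, dataset: UniformDataset, fold: dict
    ) -> PredictionTable:
        resp = dataset.responses.records.set_index(["cellline_id", "drug_id"])["value"]
        # trees are scale-invariant: no standardization; val pairs join train
        train_pairs = fold["train"] + fold["val"]
        X_tr = self.featurizer.build(dataset, train_pairs)
        y_tr = resp.loc[train_pairs].to_numpy(dtype=float)
        self.model.fit(X_tr, y_tr)
        X_te = self.featurizer.build(dataset, fold["test"])
        y_te = resp.loc[fold["test"]].to_numpy(dtype=float)
        return make_prediction_table(fold["test"], y_te, self.model.predict(X_te))


def build_rf(drug_rep: str, n_trees: int = 500, max_depth=None, seed: int = 0) -> RFRegressor:
    if drug_rep not in ("targets", "fingerprint"):
        raise ValueError(f"unknown drug_rep {drug_rep!r}")
    return RFRegressor(drug_rep, n_trees, max_depth, seed)
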