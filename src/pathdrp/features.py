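"""Pair-level design matrices for the model families.

Each featurizer maps (dataset, list of (cell line, drug) pairs) to a single
float matrix whose column layout the corresponding network expects, and
reports which columns are continuous so training can z-score them from
train-fold statistics only (binary target bits and fingerprint bits are
left untouched).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .dataset import UniformDataset

__all__ = ["Featurizer", "Standardizer", "FEATURIZERS", "get_featurizer"]

Pairs = Sequence[tuple[str, str]]


@dataclass(frozen=True)
class Featurizer:
    """Builds the design matrix for one model family / input variant."""

    name: str
    build: Callable[[UniformDataset, Pairs], np.ndarray]
    continuous_cols: Callable[[UniformDataset], np.ndarray]


class Standardizer:
    """Z-scores a fixed set of columns using statistics fitted on train data."""

    def __init__(self, continuous_cols: np.ndarray):
        self.cols = np.asarray(continuous_cols, dtype=np.intp)
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        sub = X[:, self.cols]
        self.mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer not fitted")
        X = X.astype(np.float64, copy=True)
        X[:, self.cols] = (X[:, self.cols] - self.mean) / self.sd
        return X


def _gex_rows(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    gex = ds.omics["GEx"].values
    return gex.loc[[c for c, _ in pairs]].to_numpy(dtype=np.float64)


def _cnv_rows(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    cnv = ds.omics["CNV"].values
    return cnv.loc[[c for c, _ in pairs]].to_numpy(dtype=np.float64)


def target_matrix(ds: UniformDataset, drugs: Sequence[str]) -> np.ndarray:
    """Binary drug x gene target matrix over the dataset gene order."""
    index = {g: i for i, g in enumerate(ds.gene_order)}
    out = np.zeros((len(drugs), len(index)))
    for r, d in enumerate(drugs):
        for g in ds.drug_features.targets[d]:
            out[r, index[g]] = 1.0
    return out


def _target_rows(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    return target_matrix(ds, [d for _, d in pairs])


def _fp_rows(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    fps = ds.drug_features.fingerprints
    missing = {d for _, d in pairs} - set(fps)
    if missing:
        raise ValueError(f"no fingerprint for drug(s) {sorted(missing)[:5]}")
    return np.stack([fps[d] for _, d in pairs]).astype(np.float64)


# --- layouts ---------------------------------------------------------------


def _pathdnn(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    # [targets over genes | GEx over genes]  ->  length 2G
    return np.hstack([_target_rows(ds, pairs), _gex_rows(ds, pairs)])


def _pathdnn_cont(ds: UniformDataset) -> np.ndarray:
    G = len(ds.gene_order)
    return np.arange(G, 2 * G)


def _cds(ds: UniformDataset, pairs: Pairs, with_cnv: bool) -> np.ndarray:
    # per-gene blocks [target_g, gex_g(, cnv_g)] so the gene layer's
    # block-diagonal wiring sees contiguous per-gene fan-in
    blocks = [_target_rows(ds, pairs), _gex_rows(ds, pairs)]
    if with_cnv:
        blocks.append(_cnv_rows(ds, pairs))
    k = len(blocks)
    n, G = blocks[0].shape
    out = np.empty((n, G * k))
    for j, block in enumerate(blocks):
        out[:, j::k] = block
    return out


def _cds_cont(ds: UniformDataset, with_cnv: bool) -> np.ndarray:
    G = len(ds.gene_order)
    k = 3 if with_cnv else 2
    cols = [np.arange(1, G * k, k)]  # gex positions
    if with_cnv:
        cols.append(np.arange(2, G * k, k))
    return np.sort(np.concatenate(cols))


def _gex_plus_targets(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    # [GEx | targets]: MLP/RF (GEx, T) and HiDRA (GEx, T) layout
    return np.hstack([_gex_rows(ds, pairs), _target_rows(ds, pairs)])


def _gex_plus_fp(ds: UniformDataset, pairs: Pairs) -> np.ndarray:
    return np.hstack([_gex_rows(ds, pairs), _fp_rows(ds, pairs)])


def _gex_cont(ds: UniformDataset) -> np.ndarray:
    return np.arange(len(ds.gene_order))


FEATURIZERS: dict[str, Featurizer] = {
    "pathdnn": Featurizer("pathdnn", _pathdnn, _pathdnn_cont),
    "cds_gex": Featurizer(
        "cds_gex", lambda ds, p: _cds(ds, p, False), lambda ds: _cds_cont(ds, False)
    ),
    "cds_gex_cnv": Featurizer(
        "cds_gex_cnv", lambda ds, p: _cds(ds, p, True), lambda ds: _cds_cont(ds, True)
    ),
    "gex_targets": Featurizer("gex_targets", _gex_plus_targets, _gex_cont),
    "gex_fp": Featurizer("gex_fp", _gex_plus_fp, _gex_cont),
}


def get_featurizer(name: str) -> Featurizer:
    try:
        return FEATURIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown featurizer {name!r}; available: {sorted(FEATURIZERS)}"
        ) from None
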