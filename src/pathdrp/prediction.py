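"""The prediction-table contract shared by every model."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PredictionTable", "make_prediction_table"]

#: Columns of a prediction table: one row per scored (cell line, drug) pair.
COLUMNS = ("cellline_id", "drug_id", "y_true", "y_pred")

PredictionTable = pd.DataFrame  # alias: a DataFrame with COLUMNS


def make_prediction_table(
    pairs: Sequence[tuple[str, str]],
    y_true: np.ndarray,
    y_pred: np.ndarray,
) -> PredictionTable:
    if not (len(pairs) == len(y_true) == len(y_pred)):
        raise ValueError("pairs, y_true and y_pred must have equal length")
    df = pd.DataFrame(pairs, columns=["cellline_id", "drug_id"])
    df["y_true"] = np.asarray(y_true, dtype=float)
    df["y_pred"] = np.asarray(y_pred, dtype=float)
    return df


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> PredictionTable:
    return pd.read_csv(path, sep="\t", dtype={"cellline_id": str, "drug_id": str})
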