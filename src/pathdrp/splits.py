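"""Five-fold train/validation/test partitions under three validation schemes.

The unit of splitting depends on the prediction task:

* LPO (leave-pairs-out): (cell line, drug) pairs are partitioned directly;
  a cell line or drug may appear in train and test with different partners.
* LCO (leave-cell-lines-out): cell lines are partitioned; every pair of a
  test cell line is a test pair, so test cell lines are entirely unseen.
* LDO (leave-drugs-out): drugs are partitioned analogously.

Units are shuffled once per seed and cut into five near-equal blocks
B_0..B_4; fold k uses test = B_k, val = B_{(k+1) mod 5} and the remaining
three blocks as train, giving the 3:1:1 ratio. Across the five folds every
unit is tested exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import UniformDataset

__all__ = ["FoldSpec", "make_folds", "validate_folds", "SCHEMES"]

SCHEMES = ("LPO", "LCO", "LDO")
ROLES = ("train", "val", "test")


class SplitError(ValueError):
    """Raised for invalid split requests or violated fold invariants."""


@dataclass(frozen=True)
class FoldSpec:
    """A five-fold partition of response pairs.

    ``folds[k]`` maps role -> list of (cellline_id, drug_id) pairs.
    """

    scheme: str
    folds: tuple[dict[str, list[tuple[str, str]]], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_frame(self) -> pd.DataFrame:
        """Long-form TSV-ready view: cellline_id, drug_id, fold_index, role."""
        rows = [
            (c, d, k, role)
            for k, fold in enumerate(self.folds)
            for role in ROLES
            for c, d in fold[role]
        ]
        return pd.DataFrame(rows, columns=["cellline_id", "drug_id", "fold_index", "role"])


def make_folds(dataset: UniformDataset, scheme: str, seed: int) -> FoldSpec:
    """Build the five-fold 3:1:1 partition for one validation scheme."""
    if scheme not in SCHEMES:
        raise SplitError(f"unknown scheme {scheme!r}")
    pairs = dataset.responses.pairs()
    if scheme == "LPO":
        units: list = sorted(pairs)
    elif scheme == "LCO":
        units = sorted({c for c, _ in pairs})
    else:
        units = sorted({d for _, d in pairs})
    if len(units) < 5:
        raise SplitError(f"{scheme}: fewer than 5 units ({len(units)})")

    rng = np.random.default_rng(seed)
    order = [units[i] for i in rng.permutation(len(units))]
    blocks = [list(b) for b in np.array_split(np.array(order, dtype=object), 5)]
    if scheme == "LPO":
        blocks = [[tuple(p) for p in b] for b in blocks]

    by_cell: dict[str, list] = {}
    by_drug: dict[str, list] = {}
    for c, d in pairs:
        by_cell.setdefault(c, []).append((c, d))
        by_drug.setdefault(d, []).append((c, d))

    def expand(block: list) -> list[tuple[str, str]]:
        if scheme == "LPO":
            return list(block)
        lookup = by_cell if scheme == "LCO" else by_drug
        return [p for unit in block for p in lookup.get(unit, [])]

    folds = []
    for k in range(5):
        test_b, val_b = blocks[k], blocks[(k + 1) % 5]
        train_b = [u for j in range(5) if j not in (k, (k + 1) % 5) for u in blocks[j]]
        folds.append(
            {"train": expand(train_b), "val": expand(val_b), "test": expand(test_b)}
        )
    return FoldSpec(scheme, tuple(folds), seed)


def validate_folds(spec: FoldSpec, dataset: UniformDataset) -> pd.DataFrame:
    """Assert every fold invariant; return per-fold role counts.

    Checks per fold: the three roles partition all response pairs; under LCO
    no cell line (under LDO no drug) spans two roles. Across folds: the five
    test sets are disjoint and cover every pair.
    """
    all_pairs = set(dataset.responses.pairs())
    rows = []
    seen_test: set = set()
    for k, fold in enumerate(spec.folds):
        sets = {role: set(fold[role]) for role in ROLES}
        union = sets["train"] | sets["val"] | sets["test"]
        if union != all_pairs:
            raise SplitError(f"fold {k}: roles do not cover all pairs")
        if sum(len(s) for s in sets.values()) != len(all_pairs):
            raise SplitError(f"fold {k}: roles overlap")
        if spec.scheme in ("LCO", "LDO"):
            idx = 0 if spec.scheme == "LCO" else 1
            kind = "cell line" if spec.scheme == "LCO" else "drug"
            units = {role: {p[idx] for p in sets[role]} for role in ROLES}
            for a in range(3):
                for b in range(a + 1, 3):
                    shared = units[ROLES[a]] & units[ROLES[b]]
                    if shared:
                        raise SplitError(
                            f"{spec.scheme} leakage: {kind} {sorted(shared)[0]!r} in "
                            f"both {ROLES[a]} and {ROLES[b]} of fold {k}"
                        )
        if seen_test & sets["test"]:
            raise SplitError(f"fold {k}: test pairs repeat an earlier fold")
        seen_test |= sets["test"]
        rows.append({"fold": k, **{r: len(sets[r]) for r in ROLES}})
    if seen_test != all_pairs:
        raise SplitError("union of test folds does not cover all pairs")
    return pd.DataFrame(rows)
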