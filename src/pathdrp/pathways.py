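"""Pathway collections: GMT I/O, membership masks, randomized and downsampled controls.

A pathway collection is a flat list of named gene sets over a gene universe.
The models in this package use membership only (no topology or hierarchy):
an explicit network wires its gene->pathway layer with the binary membership
mask, an implicit one scores each set against a molecular profile.

Randomized collections are the negative controls used throughout the
benchmark: each pathway is replaced by a uniformly drawn gene set of the
same size, so any performance gap between the biological and randomized
collections isolates the value of the annotation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "membership_mask",
    "randomize_collection",
    "downsample_collection",
]


class PathwayError(ValueError):
    """Raised for malformed or inconsistent pathway collections."""


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets over a gene universe.

    Parameters
    ----------
    name
        Text label (e.g. ``"KEGG"`` or ``"synthetic"``).
    pathways
        Ordered ``(pathway_id, frozenset-of-gene-symbols)`` tuples.
    gene_universe
        Ordered gene symbols; must contain every member of every pathway.
    """

    name: str
    pathways: tuple[tuple[str, frozenset[str]], ...]
    gene_universe: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.pathways:
            raise PathwayError("no pathways in collection")
        ids = [pid for pid, _ in self.pathways]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PathwayError(f"duplicate pathway_id(s): {dupes}")
        universe = tuple(self.gene_universe) or tuple(
            sorted(set().union(*(m for _, m in self.pathways)))
        )
        object.__setattr__(self, "gene_universe", universe)
        uni = set(universe)
        for pid, members in self.pathways:
            if not members:
                raise PathwayError(f"pathway {pid!r} is empty")
            if not members <= uni:
                raise PathwayError(
                    f"pathway {pid!r} has members outside the gene universe: "
                    f"{sorted(members - uni)[:5]}"
                )

    @property
    def m(self) -> int:
        """Number of pathways."""
        return len(self.pathways)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.pathways)

    @property
    def sizes(self) -> tuple[int, ...]:
        """Pathway sizes N_i, in collection order."""
        return tuple(len(members) for _, members in self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        for pid, members in self.pathways:
            if pid == pathway_id:
                return members
        raise KeyError(pathway_id)

    def restrict(self, genes: Sequence[str], name: str | None = None) -> "PathwayCollection":
        """Restrict memberships to ``genes``; drop pathways left empty."""
        keep = set(genes)
        kept = tuple(
            (pid, frozenset(m & keep)) for pid, m in self.pathways if m & keep
        )
        if not kept:
            raise PathwayError("restriction removed every pathway")
        universe = tuple(g for g in self.gene_universe if g in keep)
        return PathwayCollection(name or self.name, kept, universe)


def read_gmt(path: str | Path, gene_universe: Sequence[str] | None = None) -> PathwayCollection:
    """Read a GMT file (tab-separated: id, description, member genes...).

    Duplicate member symbols within a line are collapsed; the description
    field is ignored. The universe defaults to the union of all members.
    """
    path = Path(path)
    pathways: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayError(
                    f"{path}:{lineno}: malformed GMT line (fewer than 3 fields)"
                )
            pid = fields[0]
            if pid in seen:
                raise PathwayError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
            seen.add(pid)
            members = frozenset(g for g in fields[2:] if g)
            pathways.append((pid, members))
    if not pathways:
        raise PathwayError(f"{path}: no pathways")
    return PathwayCollection(
        path.stem, tuple(pathways), tuple(gene_universe) if gene_universe else ()
    )


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT; description field written as ``na``."""
    with Path(path).open("w") as fh:
        for pid, members in collection.pathways:
            fh.write("\t".join([pid, "na", *sorted(members)]) + "\n")


def membership_mask(
    collection: PathwayCollection, gene_order: Sequence[str]
) -> pd.DataFrame:
    """Binary gene x pathway membership matrix M_GP.

    Rows follow ``gene_order``, columns follow collection order; entry
    ``(g, p)`` is 1 iff gene g is a member of pathway p. Genes outside every
    pathway yield all-zero rows.
    """
    gene_order = list(gene_order)
    if not gene_order:
        raise PathwayError("empty gene_order")
    if len(set(gene_order)) != len(gene_order):
        raise PathwayError("gene_order contains duplicate symbols")
    mask = np.zeros((len(gene_order), collection.m), dtype=np.int8)
    index = {g: i for i, g in enumerate(gene_order)}
    for j, (_, members) in enumerate(collection.pathways):
        rows = [index[g] for g in members if g in index]
        mask[rows, j] = 1
    return pd.DataFrame(mask, index=gene_order, columns=list(collection.pathway_ids))


def randomize_collection(collection: PathwayCollection, seed: int) -> PathwayCollection:
    """Size-matched random control: pathway i gets N_i genes drawn uniformly
    without replacement from the universe, independently across pathways.
    """
    universe = np.asarray(collection.gene_universe, dtype=object)
    if universe.size < max(collection.sizes):
        raise PathwayError("a pathway is larger than the gene universe")
    rng = np.random.default_rng(seed)
    pathways = tuple(
        (pid, frozenset(rng.choice(universe, size=len(members), replace=False)))
        for pid, members in collection.pathways
    )
    return PathwayCollection(
        collection.name + "_rand", pathways, collection.gene_universe
    )


def downsample_collection(
    collection: PathwayCollection, n_remove: int, seed: int
) -> PathwayCollection:
    """Remove ``n_remove`` pathways chosen uniformly; memberships untouched."""
    if not 0 <= n_remove < collection.m:
        raise PathwayError(
            f"n_remove must be in [0, m); got {n_remove} with m={collection.m}"
        )
    if n_remove == 0:
        return collection
    rng = np.random.default_rng(seed)
    keep = np.sort(
        rng.choice(collection.m, size=collection.m - n_remove, replace=False)
    )
    return PathwayCollection(
        f"{collection.name}_down{n_remove}",
        tuple(collection.pathways[i] for i in keep),
        collection.gene_universe,
    )
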