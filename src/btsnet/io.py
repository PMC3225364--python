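"""Readers and writers for edge lists (TSV, SIF) and partition tables."""

from __future__ import annotations

import logging
import os
from typing import Literal

import pandas as pd

from .network import InteractionNetwork
from .partition import BISPARSE, COHESIVE, Module, Partition

logger = logging.getLogger(__name__)

PARTITION_COLUMNS = ["node_label", "module_id", "module_type", "module_EDM"]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input; carries the offending line number."""


def read_edge_list(
    path: str | os.PathLike, format: Literal["tsv", "sif", "auto"] = "auto"
) -> InteractionNetwork:
    """Read an interaction network from a two-column TSV or a SIF file.

    Duplicate edges are collapsed, self-loops dropped, and node labels
    sorted lexicographically for a deterministic node order.  TSV lines
    beginning with ``#`` are comments; a third TSV column (edge weight) is
    ignored with a warning, since networks are treated as unweighted.
    SIF lines are ``source relation target [target ...]``; the relation
    string is ignored and each target contributes one edge.
    """
    path = os.fspath(path)
    if format == "auto":
        format = "sif" if path.lower().endswith(".sif") else "tsv"
    edges: list[tuple[str, str]] = []
    warned_weights = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if format == "tsv":
                if len(fields) < 2:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: expected two columns, got {len(fields)}"
                    )
                if len(fields) > 2 and not warned_weights:
                    logger.warning(
                        "%s:%d: extra columns (edge weights?) ignored; "
                        "networks are treated as unweighted",
                        path,
                        lineno,
                    )
                    warned_weights = True
                edges.append((fields[0], fields[1]))
            else:  # sif
                if len(fields) == 1:
                    # isolated-node line: SIF allows it, but we only
                    # instantiate nodes that appear in edges
                    continue
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: SIF line needs source, relation "
                        f"and at least one target"
                    )
                source = fields[0]
                for target in fields[2:]:
                    edges.append((source, target))
    if not edges:
        raise EdgeListParseError(f"{path}: no edges")
    return InteractionNetwork.from_edges(edges)


def write_edge_list(network: InteractionNetwork, path: str | os.PathLike) -> None:
    """Write the network as a canonical two-column TSV (sorted label pairs)."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edge_set()):
            fh.write(f"{u}\t{v}\n")


def write_partition(
    partition: Partition,
    path: str | os.PathLike,
    network: InteractionNetwork | None = None,
) -> None:
    """Write a partition as a TSV with one row per node.

    Columns: node_label, module_id, module_type, module_EDM; one header
    line; rows sorted by module_id then label.  If ``network`` is given,
    every network node must be assigned; unassigned nodes raise an error.
    """
    assignment = partition.assignment()
    if network is not None:
        missing = sorted(set(network.node_labels) - set(assignment))
        if missing:
            raise ValueError(f"unassigned nodes: {', '.join(missing)}")
    rows = []
    for mod in sorted(partition.modules, key=lambda m: m.id):
        for lab in sorted(mod.members):
            rows.append((lab, mod.id, mod.mtype, mod.edm))
    df = pd.DataFrame(rows, columns=PARTITION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_partition(path: str | os.PathLike) -> Partition:
    """Read a partition TSV written by :func:`write_partition`.

    Ground-truth files may omit the ``module_EDM`` column; EDM then
    defaults to NaN.  The ``module_type`` column may also be absent, in
    which case modules default to bi-sparse.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_label": str})
    if "node_label" not in df or "module_id" not in df:
        raise ValueError(f"{path}: missing node_label/module_id columns")
    modules = []
    for mid, grp in df.groupby("module_id", sort=True):
        if "module_type" in grp:
            mtype = str(grp["module_type"].iloc[0])
            if mtype not in (COHESIVE, BISPARSE):
                raise ValueError(f"{path}: unknown module_type {mtype!r}")
        else:
            mtype = BISPARSE
        edm = float(grp["module_EDM"].iloc[0]) if "module_EDM" in grp else float("nan")
        modules.append(
            Module(
                id=int(mid),
                members=frozenset(grp["node_label"].astype(str)),
                mtype=mtype,
                edm=edm,
            )
        )
    return Partition(modules=modules)
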