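"""Readers and writers: edge-list TSV, ranking TSV, YAML parameter files."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import yaml

from .graph import DirectedGraph, Ranking, sorted_nodes
from .rsbm import RSBMParams

__all__ = ["read_edge_list", "write_edge_list", "read_ranking", "write_ranking",
           "read_params", "write_params"]

log = logging.getLogger("agony")

PathLike = Union[str, Path]


def read_edge_list(path: PathLike) -> DirectedGraph:
    """Read a two-column (source, target) TSV edge list.

    ``#`` starts a comment; blank lines are skipped; node names are
    arbitrary strings.  Duplicate edges are collapsed (warning) and
    self-loops dropped (warning with a count); a malformed line raises
    with its line number.
    """
    edges = []
    seen = set()
    duplicates = 0
    self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (source, target), "
                    f"got {len(parts)}: {raw.rstrip()!r}")
            u, v = parts
            if u == v:
                self_loops += 1
                continue
            if (u, v) in seen:
                duplicates += 1
                continue
            seen.add((u, v))
            edges.append((u, v))
    if duplicates:
        log.warning("%s: collapsed %d duplicate edge(s)", path, duplicates)
    if self_loops:
        log.warning("%s: dropped %d self-loop(s)", path, self_loops)
    return DirectedGraph(edges)


def write_edge_list(G: DirectedGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted_nodes(G.edges):
            fh.write(f"{u}\t{v}\n")


def read_ranking(path: PathLike) -> Ranking:
    """Read a two-column (node, integer rank) TSV."""
    rank = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (node, rank), "
                    f"got {len(parts)}: {raw.rstrip()!r}")
            node, r = parts
            try:
                rank[node] = int(r)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: rank {r!r} is not an integer") from err
    return Ranking(rank)


def write_ranking(r: Ranking, path: PathLike) -> None:
    with open(path, "w") as fh:
        for node in sorted_nodes(r.nodes):
            fh.write(f"{node}\t{r[node]}\n")


def read_params(path: PathLike) -> RSBMParams:
    """RSBM parameters from a YAML mapping mirroring the field names
    (p, q, s, R, and n or class_sizes)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping of RSBM parameters")
    known = {"p", "q", "s", "R", "n", "class_sizes"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return RSBMParams(**data)


def write_params(params: RSBMParams, path: PathLike) -> None:
    data = {"p": params.p, "q": params.q, "s": params.s, "R": params.R}
    if params.uniform:
        data["n"] = params.class_sizes[0]
    else:
        data["class_sizes"] = list(params.class_sizes)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
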