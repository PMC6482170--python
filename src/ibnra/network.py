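"""Bipartite lncRNA-protein networks and the tabular formats around them.

The central container is :class:`BipartiteNetwork`: a binary interaction
matrix ``I`` of shape ``(n_proteins, n_lncrnas)`` together with the ordered
identifier lists for both axes.  Axis order is first-appearance order in the
edge list, and every derived matrix in the package inherits it, so results
are reproducible bit-for-bit.

All files are tab-separated UTF-8; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ibnra")

__all__ = [
    "BipartiteNetwork",
    "ExpressionProfileTable",
    "EmptyNetworkError",
    "FormatError",
    "read_interactions",
    "write_interactions",
    "filter_min_degree",
    "read_ppi_scores",
    "write_ppi_scores",
    "read_expression",
    "write_expression",
    "write_rankings",
    "write_similarity",
]


class FormatError(ValueError):
    """A table could not be parsed or violates its contract."""


class EmptyNetworkError(ValueError):
    """An operation produced or received a network with no edges."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Known lncRNA-protein interactions as a binary bipartite adjacency.

    Attributes
    ----------
    protein_ids : list of str
        Unique protein identifiers; row order of ``I``.
    lncrna_ids : list of str
        Unique lncRNA identifiers; column order of ``I``.
    I : ndarray of shape (n_proteins, n_lncrnas)
        0/1 interaction indicator: ``I[i, j] = 1`` iff protein ``i`` is known
        to interact with lncRNA ``j``.
    """

    protein_ids: list[str]
    lncrna_ids: list[str]
    I: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        I = np.asarray(self.I)
        if I.shape != (len(self.protein_ids), len(self.lncrna_ids)):
            raise ValueError(
                f"interaction matrix shape {I.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.lncrna_ids)} lncRNAs"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA ids")
        if not np.isin(I, (0, 1)).all():
            raise ValueError("interaction matrix must be binary")
        object.__setattr__(self, "I", I.astype(float))

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_edges(self) -> int:
        return int(self.I.sum())

    def protein_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.protein_ids)}

    def lncrna_index(self) -> dict[str, int]:
        return {l: j for j, l in enumerate(self.lncrna_ids)}


@dataclass(frozen=True)
class ExpressionProfileTable:
    """Real-valued lncRNA expression over tissues/cell types.

    ``profiles`` has one row per lncRNA in ``lncrna_ids`` order and one
    column per tissue; no missing values.
    """

    lncrna_ids: list[str]
    tissues: list[str]
    profiles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        P = np.asarray(self.profiles, dtype=float)
        if P.shape != (len(self.lncrna_ids), len(self.tissues)):
            raise ValueError("profile matrix shape does not match id/tissue lists")
        if np.isnan(P).any():
            raise FormatError("expression profiles contain missing values")
        object.__setattr__(self, "profiles", P)


def _data_lines(path) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_interactions(path, header: bool = False) -> BipartiteNetwork:
    """Read a 2-column ``(lncrna_id, protein_id)`` edge list into a network.

    Duplicate edges collapse to a single interaction.  Axis order is the
    order in which each id first appears in the file.

    Parameters
    ----------
    path : path-like
        TSV file with at least two columns; extra columns are ignored.
    header : bool
        Skip the first data line if True.

    Raises
    ------
    EmptyNetworkError
        If the file holds no edges.
    FormatError
        On a malformed row, naming its line number.
    """
    lines = _data_lines(path)
    if header and lines:
        lines = lines[1:]
    if not lines:
        raise EmptyNetworkError(f"no edges found in {path}")

    proteins: dict[str, int] = {}
    lncrnas: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise FormatError(f"{path}: malformed edge row at line {lineno}: {line!r}")
        l_id, p_id = parts[0].strip(), parts[1].strip()
        j = lncrnas.setdefault(l_id, len(lncrnas))
        i = proteins.setdefault(p_id, len(proteins))
        edges.append((i, j))

    I = np.zeros((len(proteins), len(lncrnas)))
    rows, cols = zip(*edges)
    I[rows, cols] = 1.0
    return BipartiteNetwork(list(proteins), list(lncrnas), I)


def write_interactions(net: BipartiteNetwork, path) -> None:
    """Write the network back out as a ``(lncrna_id, protein_id)`` edge list.

    Edges are emitted lncRNA-major in axis order.  Reading the file back
    recovers the same network up to axis order (an edge list fixes ids and
    edges but not both appearance orders at once).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for j, l_id in enumerate(net.lncrna_ids):
            for i in np.flatnonzero(net.I[:, j]):
                fh.write(f"{l_id}\t{net.protein_ids[i]}\n")


def filter_min_degree(net: BipartiteNetwork, min_degree: int = 2) -> BipartiteNetwork:
    """Iteratively drop proteins/lncRNAs with fewer than ``min_degree`` edges.

    Removal is repeated until a fixed point: deleting a node can push a
    neighbour below the threshold, so a single pass is not self-consistent.
    The default of 2 keeps every node testable under leave-one-out masking
    (holding out its one edge would otherwise orphan it).

    Raises
    ------
    EmptyNetworkError
        If filtering removes every node.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    I = net.I
    p_keep = np.arange(net.n_proteins)
    l_keep = np.arange(net.n_lncrnas)
    while True:
        p_ok = I.sum(axis=1) >= min_degree
        l_ok = I.sum(axis=0) >= min_degree
        if p_ok.all() and l_ok.all():
            break
        I = I[np.ix_(p_ok, l_ok)]
        p_keep = p_keep[p_ok]
        l_keep = l_keep[l_ok]
        if I.size == 0:
            raise EmptyNetworkError(
                f"network emptied by degree-{min_degree} filtering"
            )
    if len(p_keep) < net.n_proteins or len(l_keep) < net.n_lncrnas:
        logger.info(
            "degree filter kept %d/%d proteins, %d/%d lncRNAs",
            len(p_keep), net.n_proteins, len(l_keep), net.n_lncrnas,
        )
    return BipartiteNetwork(
        [net.protein_ids[i] for i in p_keep],
        [net.lncrna_ids[j] for j in l_keep],
        I,
    )


def read_ppi_scores(path, net: BipartiteNetwork, header: bool = False) -> np.ndarray:
    """Read 3-column ``(protein_id, protein_id, score)`` PPI scores.

    Returns the symmetric score matrix ``AP`` over ``net.protein_ids``;
    unlisted pairs are 0.  Rows naming proteins absent from the network are
    skipped with a logged count.  A pair listed twice with conflicting
    scores is an error; a consistent duplicate is kept once.
    """
    idx = net.protein_index()
    AP = np.zeros((net.n_proteins, net.n_proteins))
    seen: dict[tuple[int, int], float] = {}
    skipped = 0
    lines = _data_lines(path)
    if header and lines:
        lines = lines[1:]
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: malformed PPI row at line {lineno}: {line!r}")
        a, b, raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
        try:
            score = float(raw)
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric PPI score at line {lineno}: {raw!r}"
            ) from exc
        if score <= 0:
            raise FormatError(f"{path}: non-positive PPI score at line {lineno}")
        if a not in idx or b not in idx:
            skipped += 1
            continue
        i, j = idx[a], idx[b]
        key = (min(i, j), max(i, j))
        if key in seen:
            if seen[key] != score:
                raise FormatError(
                    f"{path}: conflicting duplicate PPI scores for "
                    f"({a}, {b}) at line {lineno}: {seen[key]} vs {score}"
                )
            continue
        seen[key] = score
        AP[i, j] = score
        AP[j, i] = score
    if skipped:
        logger.warning("skipped %d PPI rows naming proteins outside the network", skipped)
    return AP


def write_ppi_scores(AP: np.ndarray, protein_ids: list[str], path) -> None:
    """Write the upper triangle of a symmetric PPI score matrix as 3-col TSV."""
    AP = np.asarray(AP, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(len(protein_ids)):
            for j in range(i + 1, len(protein_ids)):
                if AP[i, j] != 0:
                    fh.write(f"{protein_ids[i]}\t{protein_ids[j]}\t{AP[i, j]:.10g}\n")


def write_expression(table: "ExpressionProfileTable", path) -> None:
    """Write an expression table as a TSV matrix with an id column."""
    pd.DataFrame(
        table.profiles, index=table.lncrna_ids, columns=table.tissues
    ).to_csv(path, sep="\t", index_label="lncrna_id")


def read_expression(path, net: BipartiteNetwork) -> ExpressionProfileTable:
    """Read a TSV expression matrix (row ids, tissue-label header).

    Rows are reordered to ``net.lncrna_ids``; rows for lncRNAs outside the
    network are dropped with a logged count.

    Raises
    ------
    FormatError
        If any network lncRNA is missing from the table (missing ids are
        listed) or if the table contains missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    missing = [l for l in net.lncrna_ids if l not in df.index]
    if missing:
        raise FormatError(
            "expression table missing lncRNAs: " + ", ".join(sorted(missing))
        )
    extras = len(df.index.difference(net.lncrna_ids))
    if extras:
        logger.warning("dropped %d expression rows outside the network", extras)
    df = df.loc[net.lncrna_ids]
    return ExpressionProfileTable(
        list(net.lncrna_ids), [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def write_rankings(
    scores: np.ndarray,
    net: BipartiteNetwork,
    path,
    exclude_known: bool = False,
) -> None:
    """Write per-lncRNA protein rankings as a 4-column TSV.

    One row per (lncrna_id, protein_id, score, rank); rank is computed
    within each lncRNA by descending score, ties broken by protein id
    (lexicographic, stable).  With ``exclude_known`` proteins already
    interacting with the lncRNA are omitted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != net.I.shape:
        raise ValueError(
            f"score matrix shape {scores.shape} != network shape {net.I.shape}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncrna_id\tprotein_id\tscore\trank\n")
        for j, l_id in enumerate(net.lncrna_ids):
            order = sorted(
                range(net.n_proteins),
                key=lambda i: (-scores[i, j], net.protein_ids[i]),
            )
            rank = 0
            for i in order:
                if exclude_known and net.I[i, j] == 1:
                    continue
                rank += 1
                fh.write(f"{l_id}\t{net.protein_ids[i]}\t{scores[i, j]:.10g}\t{rank}\n")


def write_similarity(M: np.ndarray, ids: list[str], path) -> None:
    """Export a square similarity matrix with an id header, for inspection."""
    pd.DataFrame(np.asarray(M, dtype=float), index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="id"
    )
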