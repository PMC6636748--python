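"""Protein–protein interaction networks: loading, validation, normalization.

The diffusion operates on the degree-normalized adjacency
``S = D^{-1/2} W D^{-1/2}`` of an undirected, nonnegatively weighted
network.  Binary networks are the special case of all-unit weights.
Gene identifiers are opaque strings; the gene universe is kept in
lexicographic order so that every downstream artifact is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

log = logging.getLogger(__name__)

__all__ = ["Interactome", "load_network", "normalize", "NetworkFormatError"]


class NetworkFormatError(ValueError):
    """Raised when an edge-list file violates the expected dialect."""


@dataclass
class Interactome:
    """An undirected weighted gene–gene interaction network.

    Attributes
    ----------
    genes : list of str
        Gene identifiers in lexicographic order; defines the coordinate
        system of every vector and matrix below.
    W : scipy.sparse.csr_matrix
        Symmetric nonnegative adjacency with zero diagonal
        (self-interactions are dropped at load time).
    """

    genes: list[str]
    W: sparse.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)
    _S: sparse.csr_matrix | None = field(default=None, init=False, repr=False)
    _D: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.W = sparse.csr_matrix(self.W)
        n = len(self.genes)
        if self.W.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.W.shape} does not match {n} genes"
            )
        self._index = {g: i for i, g in enumerate(self.genes)}
        if len(self._index) != n:
            raise ValueError("duplicate gene identifiers")

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @property
    def D(self) -> np.ndarray:
        """Degree vector, ``D_i = sum_k W_ik``."""
        if self._D is None:
            self._D = np.asarray(self.W.sum(axis=1)).ravel()
        return self._D

    @property
    def S(self) -> sparse.csr_matrix:
        """Normalized adjacency ``S = D^{-1/2} W D^{-1/2}``.

        Rows and columns of isolated nodes (degree zero) are identically
        zero; such genes stay in the universe and simply retain a pure
        fraction of their seed weight under diffusion.
        """
        if self._S is None:
            d = self.D
            with np.errstate(divide="ignore"):
                inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
            Dinv = sparse.diags(inv_sqrt)
            self._S = (Dinv @ self.W @ Dinv).tocsr()
        return self._S

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_genes: Sequence[str] = (),
    ) -> "Interactome":
        """Build a network from ``(gene_a, gene_b, weight)`` triples.

        Orientation is ignored, self-loops are dropped with a warning, and
        duplicate edges keep the maximum weight.  ``extra_genes`` lets the
        caller keep isolated genes in the universe.
        """
        best: dict[tuple[str, str], float] = {}
        genes: set[str] = set(extra_genes)
        for a, b, w in edges:
            genes.update((a, b))
            if a == b:
                # zero-weight self-loop = explicit isolated-node declaration
                if w != 0:
                    log.warning("self-loop on %r dropped", a)
                continue
            key = (a, b) if a < b else (b, a)
            if key in best and best[key] != w:
                log.warning(
                    "duplicate edge %s-%s with conflicting weights "
                    "(%g vs %g); keeping the maximum",
                    key[0], key[1], best[key], w,
                )
            best[key] = max(best.get(key, w), w)
        ordered = sorted(genes)
        idx = {g: i for i, g in enumerate(ordered)}
        n = len(ordered)
        if best:
            rows, cols, vals = [], [], []
            for (a, b), w in best.items():
                i, j = idx[a], idx[b]
                rows.extend((i, j))
                cols.extend((j, i))
                vals.extend((w, w))
            W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        else:
            W = sparse.csr_matrix((n, n))
        return cls(ordered, W)

    def to_edge_list(self) -> list[tuple[str, str, float]]:
        """Upper-triangle edge list in deterministic (sorted) order."""
        coo = sparse.triu(self.W).tocoo()
        out = [
            (self.genes[i], self.genes[j], float(v))
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ]
        out.sort()
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Write the edge list; isolated genes are declared by a zero-weight
        self-loop line so the gene universe round-trips exactly."""
        rows = self.to_edge_list()
        rows.extend((g, g, 0.0) for g, d in zip(self.genes, self.D) if d == 0)
        rows.sort()
        with open(path, "w") as fh:
            for a, b, w in rows:
                fh.write(f"{a}\t{b}\t{w:.17g}\n")

    def write_mtx(self, path: str | Path) -> None:
        """Export the adjacency in MatrixMarket coordinate format."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.W.tocoo(), symmetry="symmetric")


def load_network(path: str | Path, weighted: bool | None = None) -> Interactome:
    """Load an interactome from a TSV edge list.

    The dialect is ``gene_a<TAB>gene_b[<TAB>weight]``; lines starting with
    ``#`` are comments.  With ``weighted=False`` any third column is
    ignored and all edges get weight 1; with ``weighted=True`` a third
    column is required; with ``weighted=None`` (default) the presence of a
    third column decides.

    Raises
    ------
    NetworkFormatError
        On an empty file, a missing/negative/non-numeric weight, or a
        malformed line; the message names the offending line.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-delimited input
                parts = line.split()
            if len(parts) < 2:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected at least 2 columns"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if weighted is False or len(parts) < 3:
                if weighted is True and len(parts) < 3:
                    raise NetworkFormatError(
                        f"{path}: line {lineno}: weighted network requires a "
                        "third (weight) column"
                    )
                w = 1.0
            else:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise NetworkFormatError(
                        f"{path}: line {lineno}: non-numeric weight "
                        f"{parts[2]!r}"
                    ) from None
                if not np.isfinite(w):
                    raise NetworkFormatError(
                        f"{path}: line {lineno}: non-finite weight {parts[2]!r}"
                    )
                if w < 0:
                    raise NetworkFormatError(
                        f"{path}: line {lineno}: negative weight {w}"
                    )
            edges.append((a, b, w))
    if not edges:
        raise NetworkFormatError(f"{path}: empty edge list")
    return Interactome.from_edges(edges)


def normalize(W: sparse.spmatrix | np.ndarray, D: np.ndarray | None = None) -> sparse.csr_matrix:
    """Degree-normalize an adjacency: ``S_ij = W_ij / sqrt(D_i D_j)``.

    Rows/columns of zero-degree nodes are left all-zero.  ``D`` defaults
    to the row sums of ``W``.
    """
    W = sparse.csr_matrix(W)
    if D is None:
        D = np.asarray(W.sum(axis=1)).ravel()
    D = np.asarray(D, dtype=float).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(D > 0, 1.0 / np.sqrt(np.where(D > 0, D, 1.0)), 0.0)
    Dinv = sparse.diags(inv_sqrt)
    return (Dinv @ W @ Dinv).tocsr()
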