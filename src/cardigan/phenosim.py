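"""Phenotype similarity between diseases.

Two diseases are compared through the ontology terms annotated to them
(in the published workflow, MeSH headings of the literature linked to
each disease).  Each term's specificity is measured by its information
content, IC(t) = −log p(t), where p(t) is the fraction of annotated
diseases whose (ancestor-closed) term set contains t.  The similarity of
two diseases is the IC of the most informative ontology term that is a
common ancestor of their term sets — rare shared phenotype categories
give high similarity, sharing only the root gives zero.

Similarity can also be served from a precomputed symmetric matrix; both
sources expose the same ``sim(d1, d2)`` contract.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationCorpus",
    "SimilaritySource",
    "MatrixSimilarity",
    "OntologySimilarity",
    "information_content",
    "caniza_similarity",
    "similarity_matrix",
]


class Ontology:
    """A directed acyclic term hierarchy (tree or poly-hierarchy).

    Parameters
    ----------
    parents : mapping term -> iterable of parent terms
        Terms without parents are roots; terms appearing only as parents
        are added automatically.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: dict[str, frozenset[str]] = {}
        terms: set[str] = set()
        for t, ps in parents.items():
            ps = frozenset(ps)
            self.parents[t] = ps
            terms.add(t)
            terms.update(ps)
        for t in terms:
            self.parents.setdefault(t, frozenset())
        self.terms: frozenset[str] = frozenset(terms)
        self._ancestors: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.terms, WHITE)
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.parents[start]))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                for nxt in it:
                    if color[nxt] == GRAY:
                        raise ValueError(f"ontology contains a cycle through {nxt!r}")
                    if color[nxt] == WHITE:
                        color[nxt] = GRAY
                        stack.append((nxt, iter(self.parents[nxt])))
                        break
                else:
                    color[node] = BLACK
                    stack.pop()

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents[t])

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive ancestors of ``term``, including the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        acc = {term}
        for p in self.parents[term]:
            acc |= self.ancestors(p)
        result = frozenset(acc)
        self._ancestors[term] = result
        return result

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Ontology":
        """Read ``term<TAB>parent`` pairs (multiple parents = multiple lines).

        A line with a single column declares a root term.
        """
        parents: dict[str, set[str]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                term = parts[0].strip()
                parents.setdefault(term, set())
                if len(parts) > 1 and parts[1].strip():
                    parents[term].add(parts[1].strip())
        if not parents:
            raise ValueError(f"{path}: empty ontology file")
        return cls(parents)

    @classmethod
    def from_obo(cls, path: str | Path) -> "Ontology":
        """Read an OBO file via :mod:`obonet` (is_a edges)."""
        import obonet

        graph = obonet.read_obo(str(path))
        # obonet edges point child -> parent for is_a
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return cls(parents)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.terms):
                ps = sorted(self.parents[t])
                if not ps:
                    fh.write(f"{t}\n")
                for p in ps:
                    fh.write(f"{t}\t{p}\n")


class AnnotationCorpus:
    """Disease → ontology-term annotations with up-propagated usage counts.

    The corpus unit is the disease: ``count(t)`` is the number of
    annotated diseases whose ancestor-closed term set contains ``t``.
    Counts are therefore anti-monotone in depth (every ancestor of an
    annotated term is counted at least as often), which makes the
    information content monotone along ontology edges.
    """

    def __init__(self, annotations: Mapping[str, Iterable[str]], ontology: Ontology):
        self.ontology = ontology
        self.annotations: dict[str, frozenset[str]] = {}
        for d, ts in annotations.items():
            ts = frozenset(ts)
            unknown = ts - ontology.terms
            if unknown:
                raise KeyError(
                    f"disease {d!r} annotated with unknown terms {sorted(unknown)}"
                )
            self.annotations[d] = ts
        self._closure: dict[str, frozenset[str]] = {}
        counts: dict[str, int] = {}
        for d, ts in self.annotations.items():
            closed: set[str] = set()
            for t in ts:
                closed |= ontology.ancestors(t)
            self._closure[d] = frozenset(closed)
            for t in closed:
                counts[t] = counts.get(t, 0) + 1
        self.counts = counts
        self.n_entities = sum(1 for ts in self.annotations.values() if ts)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.annotations)

    def terms_of(self, disease: str) -> frozenset[str]:
        return self.annotations[disease]

    def closure_of(self, disease: str) -> frozenset[str]:
        return self._closure[disease]

    def count(self, term: str) -> int:
        if term not in self.ontology.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        return self.counts.get(term, 0)

    @classmethod
    def from_tsv(cls, path: str | Path, ontology: Ontology) -> "AnnotationCorpus":
        """Read ``disease_id<TAB>term_id`` annotation pairs."""
        ann: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                ann.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        return cls(ann, ontology)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for d in sorted(self.annotations):
                for t in sorted(self.annotations[d]):
                    fh.write(f"{d}\t{t}\n")


def information_content(term: str, corpus: AnnotationCorpus) -> float:
    """IC(t) = −log( count(t) / count over all annotated diseases ), in nats.

    Raises ``KeyError`` for a term absent from the ontology and
    ``ValueError`` for a term never used (directly or via descendants).
    """
    c = corpus.count(term)
    if c == 0:
        raise ValueError(f"term {term!r} has zero annotation count")
    return -math.log(c / corpus.n_entities) + 0.0  # avoid -0.0 at the root


def _mica_ic(a: str, b: str, ontology: Ontology, corpus: AnnotationCorpus) -> float:
    """IC of the most informative common ancestor of two terms (0 if none)."""
    common = ontology.ancestors(a) & ontology.ancestors(b)
    best = 0.0
    for t in common:
        c = corpus.count(t)
        if c > 0:
            best = max(best, -math.log(c / corpus.n_entities))
    return best


def caniza_similarity(
    d1: str,
    d2: str,
    ontology: Ontology,
    corpus: AnnotationCorpus,
    mode: str = "pairwise",
) -> float:
    """Phenotype similarity of two diseases from their ontology term sets.

    mode="pairwise" (default): the maximum, over term pairs (a in
    terms(d1), b in terms(d2)), of the IC of the most informative common
    ancestor of a and b.  This is the Resnik-family set similarity and a
    term shared by both diseases contributes its own IC.

    mode="union": the IC of the most informative term that is a common
    ancestor of *every* term of both diseases.  This collapses toward the
    root for multi-topic diseases and is provided for comparison.
    """
    for d in (d1, d2):
        if d not in corpus.annotations or not corpus.annotations[d]:
            raise ValueError(f"disease {d!r} has no annotations")
    t1, t2 = corpus.terms_of(d1), corpus.terms_of(d2)
    if mode == "pairwise":
        return max(_mica_ic(a, b, ontology, corpus) for a in t1 for b in t2)
    if mode == "union":
        common: frozenset[str] | None = None
        for t in t1 | t2:
            anc = ontology.ancestors(t)
            common = anc if common is None else common & anc
        best = 0.0
        for t in common or ():
            c = corpus.count(t)
            if c > 0:
                best = max(best, -math.log(c / corpus.n_entities))
        return best
    raise ValueError(f"unknown similarity mode {mode!r}")


class SimilaritySource:
    """Contract: ``sim(d1, d2)`` symmetric, nonnegative, repeatable."""

    def sim(self, d1: str, d2: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def diseases(self) -> list[str]:  # pragma: no cover - interface
        raise NotImplementedError

    def __contains__(self, disease: str) -> bool:
        return disease in set(self.diseases)


class MatrixSimilarity(SimilaritySource):
    """Similarity served from a precomputed symmetric matrix."""

    def __init__(self, matrix: pd.DataFrame, atol: float = 1e-9):
        if list(matrix.index) != list(matrix.columns):
            matrix = matrix.loc[:, matrix.index]
        vals = matrix.to_numpy(dtype=float)
        if np.max(np.abs(vals - vals.T), initial=0.0) > atol:
            raise ValueError(
                f"similarity matrix asymmetric beyond tolerance {atol}"
            )
        if np.any(vals < 0):
            raise ValueError("similarity matrix contains negative values")
        self.matrix = matrix.astype(float)
        self._ids = set(matrix.index)

    def sim(self, d1: str, d2: str) -> float:
        return float(self.matrix.at[d1, d2])

    @property
    def diseases(self) -> list[str]:
        return list(self.matrix.index)

    def __contains__(self, disease: str) -> bool:
        return disease in self._ids

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MatrixSimilarity":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", float_format="%.17g")


class OntologySimilarity(SimilaritySource):
    """Similarity computed lazily from an ontology and annotation corpus.

    ``fallback_zero=True`` makes unannotated diseases similar to nothing
    (similarity 0) instead of raising.
    """

    def __init__(
        self,
        ontology: Ontology,
        corpus: AnnotationCorpus,
        mode: str = "pairwise",
        fallback_zero: bool = False,
    ):
        self.ontology = ontology
        self.corpus = corpus
        self.mode = mode
        self.fallback_zero = fallback_zero
        self._cache: dict[tuple[str, str], float] = {}

    def sim(self, d1: str, d2: str) -> float:
        key = (d1, d2) if d1 <= d2 else (d2, d1)
        if key not in self._cache:
            try:
                value = caniza_similarity(
                    d1, d2, self.ontology, self.corpus, mode=self.mode
                )
            except ValueError:
                if not self.fallback_zero:
                    raise
                value = 0.0
            self._cache[key] = value
        return self._cache[key]

    @property
    def diseases(self) -> list[str]:
        return self.corpus.diseases

    def __contains__(self, disease: str) -> bool:
        return (
            disease in self.corpus.annotations
            and bool(self.corpus.annotations[disease])
        )


def similarity_matrix(
    diseases: Iterable[str], source: SimilaritySource
) -> MatrixSimilarity:
    """Materialize pairwise similarities into a symmetric matrix."""
    ids = list(diseases)
    n = len(ids)
    vals = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i, n):
            vals[i, j] = vals[j, i] = source.sim(a, ids[j])
    return MatrixSimilarity(pd.DataFrame(vals, index=ids, columns=ids))
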