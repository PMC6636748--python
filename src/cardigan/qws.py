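"""Query Weight Set construction.

The seed vector Y for a query disease assigns weight 1 to the query's own
known genes, a sigmoid-rescaled, dampened phenotype similarity (strictly
below the dampening factor h < 1) to genes known for other diseases, and
0 elsewhere.  The strict hierarchy 1 > h >= similarity-derived weights is
what lets the diffusion treat the query's own evidence as stronger than
any transferred evidence.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .interactome import Interactome
from .phenosim import SimilaritySource

log = logging.getLogger(__name__)

__all__ = [
    "DiseaseGeneMap",
    "SigmoidParams",
    "QueryWeightSet",
    "sigmoid_weight",
    "build_qws",
    "fit_sigmoid_params",
    "SigmoidFitResult",
]


class DiseaseGeneMap:
    """Mapping disease_id → set of associated gene_ids (one snapshot)."""

    def __init__(
        self, mapping: Mapping[str, Iterable[str]], snapshot: str | None = None
    ):
        self.mapping: dict[str, frozenset[str]] = {
            d: frozenset(gs) for d, gs in mapping.items()
        }
        self.snapshot = snapshot

    def genes_of(self, disease: str) -> frozenset[str]:
        return self.mapping.get(disease, frozenset())

    @property
    def diseases(self) -> list[str]:
        return sorted(self.mapping)

    def __contains__(self, disease: str) -> bool:
        return disease in self.mapping

    def pairs(self) -> set[tuple[str, str]]:
        return {(d, g) for d, gs in self.mapping.items() for g in gs}

    def without(self, disease: str, gene: str) -> "DiseaseGeneMap":
        """A copy with one association removed (disease kept, possibly empty)."""
        new = {d: set(gs) for d, gs in self.mapping.items()}
        new.setdefault(disease, set()).discard(gene)
        return DiseaseGeneMap(new, snapshot=self.snapshot)

    def with_genes(self, disease: str, genes: Iterable[str]) -> "DiseaseGeneMap":
        new = {d: set(gs) for d, gs in self.mapping.items()}
        new[disease] = set(genes)
        return DiseaseGeneMap(new, snapshot=self.snapshot)

    @classmethod
    def from_tsv(cls, path: str | Path, snapshot: str | None = None) -> "DiseaseGeneMap":
        """Read ``disease_id<TAB>gene_id`` pairs."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                mapping.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        return cls(mapping, snapshot=snapshot)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for d in sorted(self.mapping):
                for g in sorted(self.mapping[d]):
                    fh.write(f"{d}\t{g}\n")


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the dampened logistic that rescales similarity.

    h : dampening factor, the supremum of transferred weights, 0 < h < 1.
    a : slope, > 0.
    b : midpoint in similarity units; ``None`` means "use the median of
        the query's nonzero similarities", resolved per query.
    """

    h: float = 0.5
    a: float = 1.0
    b: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.h < 1.0):
            raise ValueError(f"dampening factor h must be in (0,1), got {self.h}")
        if self.a <= 0:
            raise ValueError(f"sigmoid slope a must be > 0, got {self.a}")


def sigmoid_weight(s: float, p: SigmoidParams, b: float | None = None) -> float:
    """w(s) = h / (1 + exp(−a·(s − b))): strictly increasing, sup = h."""
    if b is None:
        b = p.b
    if b is None:
        raise ValueError("sigmoid midpoint b is unresolved")
    z = -p.a * (s - b)
    # guard overflow for very negative s
    if z > 700:
        return 0.0
    return p.h / (1.0 + math.exp(z))


PROV_OWN = "own-gene"
PROV_SIM = "similarity-derived"
PROV_ZERO = "zero"


@dataclass
class QueryWeightSet:
    """Seed vector Y aligned to an interactome's gene order."""

    query: str
    genes: list[str]
    Y: np.ndarray
    provenance: list[str]
    params: SigmoidParams | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.Y, index=self.genes, name=self.query)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tweight\tprovenance\n")
            for g, y, pv in zip(self.genes, self.Y, self.provenance):
                fh.write(f"{g}\t{y:.17g}\t{pv}\n")


def _resolve_midpoint(
    query: str, assoc: DiseaseGeneMap, sim: SimilaritySource, p: SigmoidParams
) -> float:
    if p.b is not None:
        return p.b
    sims = []
    if query in sim:
        for d in assoc.diseases:
            if d == query or d not in sim:
                continue
            s = sim.sim(query, d)
            if s > 0:
                sims.append(s)
    return float(np.median(sims)) if sims else 0.0


def build_qws(
    query: str,
    assoc: DiseaseGeneMap,
    sim: SimilaritySource | None,
    net: Interactome,
    p: SigmoidParams | None = None,
) -> QueryWeightSet:
    """Build the seed vector for one query disease.

    Own genes of the query get weight 1.  A gene associated with other
    diseases gets the sigmoid weight of the *highest* similarity between
    the query and any of those diseases.  Unassociated genes get 0.
    Associated genes missing from the network are dropped with a warning.

    Raises ``ValueError`` when the query has neither known genes nor a
    similarity row — there is nothing to seed from.
    """
    p = p or SigmoidParams()
    own = assoc.genes_of(query)
    has_sim = sim is not None and query in sim
    if not own and not has_sim:
        raise ValueError(
            f"cannot seed query {query!r}: no known genes and no similarity data"
        )
    b = _resolve_midpoint(query, assoc, sim, p) if has_sim else 0.0

    n = net.n
    Y = np.zeros(n)
    prov = [PROV_ZERO] * n

    # best similarity of each foreign-disease gene to the query
    best_sim: dict[str, float] = {}
    if has_sim:
        for d in assoc.diseases:
            if d == query or d not in sim:
                continue
            s = sim.sim(query, d)
            for g in assoc.genes_of(d):
                if s > best_sim.get(g, -1.0):
                    best_sim[g] = s

    dropped: list[str] = []
    for g, s in best_sim.items():
        if g in own:
            continue
        if g not in net:
            dropped.append(g)
            continue
        i = net.index(g)
        Y[i] = sigmoid_weight(s, p, b=b)
        prov[i] = PROV_SIM
    for g in own:
        if g not in net:
            dropped.append(g)
            continue
        i = net.index(g)
        Y[i] = 1.0
        prov[i] = PROV_OWN
    if dropped:
        log.warning(
            "query %s: %d associated gene(s) absent from the network dropped: %s",
            query, len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    return QueryWeightSet(query, list(net.genes), Y, prov, params=replace(p, b=b))


@dataclass
class SigmoidFitResult:
    params: SigmoidParams
    alpha: float
    score: float
    table: pd.DataFrame  # one row per grid point with its mean LOO recall@100


def fit_sigmoid_params(
    train: DiseaseGeneMap,
    sim: SimilaritySource,
    net: Interactome,
    h_grid: Iterable[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    a_grid: Iterable[float] = (0.5, 1.0, 2.0),
    b_grid: Iterable[float | None] = (None,),
    alpha_grid: Iterable[float] = (0.5, 0.9),
    k: int = 100,
) -> SigmoidFitResult:
    """Grid search maximizing mean leave-one-out recall@k on a training set.

    Deterministic given grid and data: grid points are evaluated in
    lexicographic (h, a, b, alpha) order and ties keep the first
    (lexicographically smallest) point.  ``b=None`` grid entries use the
    per-query median midpoint.
    """
    from .evaluation import evaluate_loo  # deferred: avoid import cycle
    from .propagation import DiffusionParams

    grid = [
        (h, a, b, al)
        for h, a, b, al in itertools.product(h_grid, a_grid, b_grid, alpha_grid)
    ]
    if not grid:
        raise ValueError("empty parameter grid")
    eligible = [d for d in train.diseases if len(train.genes_of(d)) >= 2]
    if len(eligible) < 2:
        raise ValueError("need >=2 charted diseases with >=2 genes to fit")
    # sort key treats b=None as -inf so it precedes numeric midpoints
    grid.sort(key=lambda t: (t[0], t[1], (t[2] is not None, t[2] or 0.0), t[3]))
    rows = []
    best: tuple[float, int] | None = None  # (score, grid position)
    for pos, (h, a, b, al) in enumerate(grid):
        p = SigmoidParams(h=h, a=a, b=b)
        dp = DiffusionParams(alpha=al)
        res = evaluate_loo(train, net, sim, p, mode="charted", diffusion=dp)
        score = res.recall_at(k)
        rows.append({"h": h, "a": a, "b": b, "alpha": al, "recall": score})
        if best is None or score > best[0]:
            best = (score, pos)
    score, pos = best
    h, a, b, al = grid[pos]
    return SigmoidFitResult(
        params=SigmoidParams(h=h, a=a, b=b),
        alpha=al,
        score=score,
        table=pd.DataFrame(rows),
    )
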