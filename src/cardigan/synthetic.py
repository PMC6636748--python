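"""Synthetic worlds with planted disease modules.

The generator emulates the statistical premise of phenotype-driven
network prioritization: disease modules are densely connected regions of
the interactome, and diseases with similar phenotypes have nearby (here:
identical) home modules.  Concretely it builds

* a planted-partition interactome — ``m`` modules of ``s`` genes,
  within-module edge probability ``p_in``, between-module ``p_out``
  (optionally weighted, with higher weights within modules);
* charted diseases, each assigned a home module and a random subset of
  its genes;
* a rooted ontology with one branch per module and leaf terms under each
  branch, and disease annotations drawn mostly from the home module's
  leaf pool — so ontology-derived similarity is high for same-module
  disease pairs and (near) zero across modules;
* two association snapshots, the earlier one obtained by hiding a random
  fraction of associations from the later one (t0 ⊆ t1 by construction).

Everything is reproducible from a single integer seed, and every piece
can be written in exactly the text dialects the other modules read.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interactome import Interactome
from .phenosim import AnnotationCorpus, Ontology, OntologySimilarity
from .qws import DiseaseGeneMap

__all__ = ["SyntheticWorld", "make_world", "make_uncharted_query"]

ROOT_TERM = "T:root"


@dataclass
class SyntheticWorld:
    interactome: Interactome
    modules: dict[str, list[str]]          # module id -> its genes
    module_of: dict[str, str]              # disease id -> home module
    assoc_t1: DiseaseGeneMap
    assoc_t0: DiseaseGeneMap
    ontology: Ontology
    annotations: dict[str, frozenset[str]]  # disease id -> direct terms
    term_pools: dict[str, list[str]]        # module id -> leaf term pool
    seed: int
    edge_counts: dict[str, int]
    _corpus: AnnotationCorpus | None = field(default=None, repr=False)
    _n_queries: int = 0

    @property
    def corpus(self) -> AnnotationCorpus:
        if self._corpus is None:
            self._corpus = AnnotationCorpus(self.annotations, self.ontology)
        return self._corpus

    def similarity(self, **kw) -> OntologySimilarity:
        return OntologySimilarity(self.ontology, self.corpus, **kw)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.module_of)

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact in the dialects the other modules consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "network.tsv",
            "associations_t0": outdir / "associations_t0.tsv",
            "associations_t1": outdir / "associations_t1.tsv",
            "ontology": outdir / "ontology.tsv",
            "annotations": outdir / "annotations.tsv",
            "modules": outdir / "modules.tsv",
        }
        self.interactome.write_tsv(paths["network"])
        self.assoc_t0.write_tsv(paths["associations_t0"])
        self.assoc_t1.write_tsv(paths["associations_t1"])
        self.ontology.write_tsv(paths["ontology"])
        with open(paths["annotations"], "w") as fh:
            for d in sorted(self.annotations):
                for t in sorted(self.annotations[d]):
                    fh.write(f"{d}\t{t}\n")
        with open(paths["modules"], "w") as fh:
            for mid in sorted(self.modules):
                for g in sorted(self.modules[mid]):
                    fh.write(f"{mid}\t{g}\n")
        return paths


def make_world(
    m: int = 8,
    s: int = 25,
    p_in: float = 0.3,
    p_out: float = 0.01,
    diseases_per_module: int = 3,
    genes_per_disease: int = 6,
    hide_fraction: float = 0.25,
    terms_per_module: int = 6,
    terms_per_disease: int = 3,
    noise_term_prob: float = 0.2,
    weighted: bool = False,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a fully reproducible synthetic world.

    Defaults give 8 modules of 25 genes (n = 200) with a strong planted
    signal: expected within-module degree ~= (s-1)*p_in = 7.2 against an
    expected background degree ~= (n-s)*p_out = 1.75.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if not (0.0 <= hide_fraction <= 1.0):
        raise ValueError("hide_fraction must lie in [0, 1]")
    if min(m, s, diseases_per_module, genes_per_disease, terms_per_module,
           terms_per_disease) < 1:
        raise ValueError("all counts must be >= 1")
    if genes_per_disease > s:
        raise ValueError("genes_per_disease cannot exceed module size")
    if terms_per_disease > terms_per_module:
        raise ValueError("terms_per_disease cannot exceed terms_per_module")

    rng = np.random.default_rng(seed)
    n = m * s
    genes = [f"G{i:04d}" for i in range(n)]
    module_ids = [f"M{j:02d}" for j in range(m)]
    modules = {module_ids[j]: genes[j * s:(j + 1) * s] for j in range(m)}
    block = np.repeat(np.arange(m), s)

    # --- planted-partition adjacency (upper triangle, then symmetrized)
    same = block[:, None] == block[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    if weighted:
        w_in = rng.uniform(0.6, 1.0, size=(n, n))
        w_out = rng.uniform(0.05, 0.3, size=(n, n))
        weights = np.where(same, w_in, w_out)
    else:
        weights = np.ones((n, n))
    within = int(np.sum(upper & same))
    between = int(np.sum(upper & ~same))
    edges = [
        (genes[i], genes[j], float(weights[i, j]))
        for i, j in zip(*np.nonzero(upper))
    ]
    net = Interactome.from_edges(edges, extra_genes=genes)

    # --- ontology: root -> module branches -> leaf terms
    parents: dict[str, set[str]] = {ROOT_TERM: set()}
    term_pools: dict[str, list[str]] = {}
    for mid in module_ids:
        branch = f"T:{mid}"
        parents[branch] = {ROOT_TERM}
        pool = [f"T:{mid}:{i}" for i in range(terms_per_module)]
        for t in pool:
            parents[t] = {branch}
        term_pools[mid] = pool
    ontology = Ontology(parents)

    # --- diseases: home module, genes, annotations
    module_of: dict[str, str] = {}
    assoc: dict[str, set[str]] = {}
    annotations: dict[str, frozenset[str]] = {}
    d_idx = 0
    for j, mid in enumerate(module_ids):
        for _ in range(diseases_per_module):
            did = f"D{d_idx:03d}"
            d_idx += 1
            module_of[did] = mid
            assoc[did] = set(
                rng.choice(modules[mid], size=genes_per_disease, replace=False)
            )
            terms = set(
                rng.choice(term_pools[mid], size=terms_per_disease, replace=False)
            )
            if m > 1 and rng.random() < noise_term_prob:
                other = module_ids[
                    (j + 1 + int(rng.integers(m - 1))) % m
                ]
                terms.add(term_pools[other][int(rng.integers(terms_per_module))])
            annotations[did] = frozenset(terms)
    assoc_t1 = DiseaseGeneMap(assoc, snapshot="t1")

    # --- earlier snapshot: hide a fraction of associations
    t0: dict[str, set[str]] = {d: set() for d in assoc}
    for d in sorted(assoc):
        for g in sorted(assoc[d]):
            if rng.random() >= hide_fraction:
                t0[d].add(g)
    assoc_t0 = DiseaseGeneMap(t0, snapshot="t0")

    return SyntheticWorld(
        interactome=net,
        modules=modules,
        module_of=module_of,
        assoc_t1=assoc_t1,
        assoc_t0=assoc_t0,
        ontology=ontology,
        annotations=annotations,
        term_pools=term_pools,
        seed=seed,
        edge_counts={"within": within, "between": between},
    )


def make_uncharted_query(
    world: SyntheticWorld, module: str, terms_per_disease: int = 3
) -> str:
    """Add a molecularly uncharacterized query disease for a module.

    The query gets annotation terms drawn from its home module's leaf
    pool — so its phenotype similarity to the module's charted diseases
    is high — but no gene association is emitted anywhere.
    """
    if module not in world.modules:
        raise KeyError(f"unknown module {module!r}")
    qid = f"Q{world._n_queries:03d}:{module}"
    stable = zlib.crc32(qid.encode()) & 0x7FFFFFFF
    world._n_queries += 1
    rng = np.random.default_rng(np.random.SeedSequence((world.seed, stable)))
    pool = world.term_pools[module]
    k = min(terms_per_disease, len(pool))
    world.annotations[qid] = frozenset(rng.choice(pool, size=k, replace=False))
    world.module_of[qid] = module
    world._corpus = None  # annotation corpus must be rebuilt
    return qid
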