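"""Evaluation protocols and metrics.

Three protocols mirror how network-based disease-gene predictors are
benchmarked:

* leave-one-out — remove one disease–gene association, predict it back;
  "uncharted" mode removes the only gene of single-gene diseases, which
  turns them into synthetic molecularly-uncharacterized queries;
* time-lapse — predict with a historical association snapshot, test on
  associations discovered later;
* module reconstruction — keep a fraction of a curated disease module as
  seeds and score recovery of the removed part.

Metrics: recall@k over per-case held-out ranks, and the truncated
normalized AUC (area under the TPR-vs-false-positive-count curve up to a
false-positive cap, divided by the cap).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .interactome import Interactome
from .phenosim import SimilaritySource
from .propagation import DiffusionParams, GeneRanking, propagate, rank_genes
from .qws import DiseaseGeneMap, SigmoidParams, build_qws

log = logging.getLogger(__name__)

__all__ = [
    "CaseRecord",
    "ModuleRecord",
    "EvaluationResult",
    "evaluate_loo",
    "evaluate_timelapse",
    "normalized_auc",
    "evaluate_module_reconstruction",
    "random_baseline",
]

DEFAULT_K = (1, 10, 100, 200)


@dataclass(frozen=True)
class CaseRecord:
    """One held-out prediction case."""

    disease: str
    test_gene: str
    rank: int
    n_candidates: int
    stratum: str = "all"
    seed_genes: frozenset[str] = frozenset()  # the query's own-genes used to seed


@dataclass(frozen=True)
class ModuleRecord:
    """One module-reconstruction repetition."""

    disease: str
    kept_fraction: float | None
    rep: int
    nauc: float
    kept_genes: frozenset[str] = frozenset()


@dataclass
class EvaluationResult:
    records: list[CaseRecord] = field(default_factory=list)
    module_records: list[ModuleRecord] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=dict)
    violations: list[tuple[str, str]] = field(default_factory=list)

    def recall_at(self, k: int, stratum: str | None = None, unit: str = "case") -> float:
        """Fraction of held-out genes recovered within the top ``k``.

        ``unit="case"`` averages over (disease, gene) cases;
        ``unit="disease"`` first averages within each disease, then over
        diseases (relevant when one disease contributes several cases).
        """
        recs = [r for r in self.records if stratum is None or r.stratum == stratum]
        if not recs:
            raise ValueError("no evaluation cases recorded")
        if unit == "case":
            return float(np.mean([r.rank <= k for r in recs]))
        if unit == "disease":
            per: dict[str, list[bool]] = {}
            for r in recs:
                per.setdefault(r.disease, []).append(r.rank <= k)
            return float(np.mean([np.mean(v) for v in per.values()]))
        raise ValueError(f"unknown unit {unit!r}")

    def recall_curve(
        self, ks: Sequence[int] = DEFAULT_K, stratum: str | None = None
    ) -> dict[int, float]:
        return {k: self.recall_at(k, stratum=stratum) for k in ks}

    def nauc_by_fraction(self) -> dict[float, tuple[float, float]]:
        """Per kept-fraction (mean, standard error) of normalized AUC."""
        by: dict[float, list[float]] = {}
        for r in self.module_records:
            by.setdefault(r.kept_fraction, []).append(r.nauc)
        out = {}
        for f, vals in sorted(by.items(), key=lambda kv: (kv[0] is None, kv[0])):
            arr = np.asarray(vals)
            se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
            out[f] = (float(arr.mean()), se)
        return out

    def write_cases_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("disease_id\ttest_gene\trank\tn_candidates\tstratum\n")
            for r in self.records:
                fh.write(
                    f"{r.disease}\t{r.test_gene}\t{r.rank}\t{r.n_candidates}\t{r.stratum}\n"
                )

    @classmethod
    def read_cases_tsv(cls, path: str | Path) -> "EvaluationResult":
        res = cls()
        with open(path) as fh:
            fh.readline()
            for raw in fh:
                d, g, rank, nc, st = raw.rstrip("\n").split("\t")
                res.records.append(CaseRecord(d, g, int(rank), int(nc), st))
        return res

    def write_summary_json(self, path: str | Path, ks: Sequence[int] = DEFAULT_K) -> None:
        summary: dict = {"n_cases": len(self.records), "skipped": self.skipped}
        if self.records:
            summary["recall"] = {str(k): self.recall_at(k) for k in ks}
            strata = sorted({r.stratum for r in self.records})
            if len(strata) > 1:
                summary["recall_by_stratum"] = {
                    s: {str(k): self.recall_at(k, stratum=s) for k in ks}
                    for s in strata
                }
        if self.module_records:
            summary["nauc_by_fraction"] = {
                str(f): {"mean": m, "stderr": se}
                for f, (m, se) in self.nauc_by_fraction().items()
            }
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rank_case(
    query: str,
    assoc: DiseaseGeneMap,
    sim: SimilaritySource | None,
    net: Interactome,
    p: SigmoidParams,
    diffusion: DiffusionParams,
    exclude: Iterable[str],
) -> tuple[GeneRanking, frozenset[str]]:
    qws = build_qws(query, assoc, sim, net, p)
    F = propagate(net, qws, diffusion)
    ranking = rank_genes(F, net, exclude=exclude, query=query)
    own = frozenset(
        g for g, pv in zip(qws.genes, qws.provenance) if pv == "own-gene"
    )
    return ranking, own


def evaluate_loo(
    assoc: DiseaseGeneMap,
    net: Interactome,
    sim: SimilaritySource | None,
    p: SigmoidParams | None = None,
    mode: str = "charted",
    diffusion: DiffusionParams | None = None,
    exclude_known: bool = True,
) -> EvaluationResult:
    """Leave-one-out evaluation.

    mode="charted": every disease with >=2 known genes; each gene is
    removed in turn and predicted back with the remaining genes as seeds
    (and, by default, excluded from the candidate list).

    mode="uncharted": every disease with exactly one known gene; removing
    it yields a synthetic uncharacterized disease seeded purely by
    phenotype similarity.
    """
    if mode not in ("charted", "uncharted"):
        raise ValueError(f"unknown mode {mode!r}")
    p = p or SigmoidParams()
    diffusion = diffusion or DiffusionParams()
    result = EvaluationResult()
    for d in assoc.diseases:
        genes = assoc.genes_of(d)
        if mode == "charted" and len(genes) < 2:
            continue
        if mode == "uncharted" and len(genes) != 1:
            continue
        for g in sorted(genes):
            if g not in net:
                result.skipped["gene_not_in_network"] = (
                    result.skipped.get("gene_not_in_network", 0) + 1
                )
                continue
            reduced = assoc.without(d, g)
            remaining = reduced.genes_of(d) & frozenset(net.genes)
            try:
                ranking, own = _rank_case(
                    d, reduced, sim, net, p, diffusion,
                    exclude=remaining if exclude_known else (),
                )
            except ValueError as exc:
                log.warning("case (%s, %s) skipped: %s", d, g, exc)
                result.skipped["cannot_seed"] = (
                    result.skipped.get("cannot_seed", 0) + 1
                )
                continue
            result.records.append(
                CaseRecord(
                    disease=d,
                    test_gene=g,
                    rank=ranking.rank_of(g),
                    n_candidates=len(ranking),
                    stratum=mode,
                    seed_genes=own,
                )
            )
    if not result.records:
        raise ValueError(
            f"no eligible leave-one-out cases in mode {mode!r} "
            f"(skipped: {result.skipped})"
        )
    return result


def evaluate_timelapse(
    assoc_t0: DiseaseGeneMap,
    assoc_t1: DiseaseGeneMap,
    net: Interactome,
    sim: SimilaritySource | None,
    p: SigmoidParams | None = None,
    diffusion: DiffusionParams | None = None,
    exclude_known: bool = True,
) -> EvaluationResult:
    """Predict the later snapshot's new associations from the earlier one.

    Prediction uses only t0 associations.  Test genes are the t1-minus-t0
    gains restricted to network genes; each excluded gain is counted by
    reason.  Cases are stratified by whether the disease was uncharted
    (no genes) or charted at t0.  Associations present at t0 but missing
    at t1 are reported in ``result.violations``, not silently dropped.
    """
    p = p or SigmoidParams()
    diffusion = diffusion or DiffusionParams()
    result = EvaluationResult()
    result.violations = sorted(assoc_t0.pairs() - assoc_t1.pairs())
    if result.violations:
        log.warning(
            "%d association(s) present at t0 but absent at t1", len(result.violations)
        )
    gained = sorted(assoc_t1.pairs() - assoc_t0.pairs())
    for d, g in gained:
        if g not in net:
            result.skipped["gene_not_in_network"] = (
                result.skipped.get("gene_not_in_network", 0) + 1
            )
            continue
        t0_genes = assoc_t0.genes_of(d)
        stratum = "uncharted_at_t0" if not t0_genes else "charted_at_t0"
        known_in_net = t0_genes & frozenset(net.genes)
        try:
            ranking, own = _rank_case(
                d, assoc_t0, sim, net, p, diffusion,
                exclude=known_in_net if exclude_known else (),
            )
        except ValueError as exc:
            log.warning("case (%s, %s) skipped: %s", d, g, exc)
            result.skipped["cannot_seed"] = result.skipped.get("cannot_seed", 0) + 1
            continue
        result.records.append(
            CaseRecord(
                disease=d,
                test_gene=g,
                rank=ranking.rank_of(g),
                n_candidates=len(ranking),
                stratum=stratum,
                seed_genes=own,
            )
        )
    if not result.records:
        raise ValueError(
            "empty time-lapse test set after restriction to network genes "
            f"(gained associations: {len(gained)}, exclusions: {result.skipped})"
        )
    return result


def _nauc_from_positions(positions: np.ndarray, n_pos: int, fp_cap: int) -> float:
    """Truncated normalized AUC from 0-based ranking positions of positives.

    Each positive preceded by f false positives is counted during the
    (fp_cap - f) remaining false-positive steps; if the ranking runs out
    of negatives before the cap, the curve continues flat, which this
    closed form reproduces.
    """
    positions = np.sort(np.asarray(positions))
    fp_before = positions - np.arange(len(positions))
    return float(np.sum(np.clip(fp_cap - fp_before, 0, fp_cap)) / (n_pos * fp_cap))


def normalized_auc(
    ranking: GeneRanking, positives: Iterable[str], fp_cap: int = 200
) -> float:
    """Area under the TPR-vs-false-positive-count curve up to ``fp_cap``
    false positives, normalized by the cap.

    A perfect ranking (all positives before any negative) scores 1.0; a
    ranking whose positives all fall after ``fp_cap`` negatives scores
    0.0.  A uniformly random ranking scores fp_cap/(n - P)/2 in
    expectation, which is small for genome-scale networks.
    """
    if fp_cap < 1:
        raise ValueError("fp_cap must be >= 1")
    pos = set(positives)
    if not pos:
        raise ValueError("no positives given")
    genes = np.asarray(ranking.genes)
    mask = np.isin(genes, np.asarray(sorted(pos)))
    n_found = int(mask.sum())
    if n_found == 0:
        raise ValueError("none of the positives occur in the ranking")
    if n_found < len(pos):
        log.warning(
            "%d positive(s) absent from the ranking ignored", len(pos) - n_found
        )
    return _nauc_from_positions(np.flatnonzero(mask), n_found, fp_cap)


def evaluate_module_reconstruction(
    modules: Mapping[str, Iterable[str]],
    net: Interactome,
    sim: SimilaritySource | None,
    p: SigmoidParams | None = None,
    assoc: DiseaseGeneMap | None = None,
    kept_fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75),
    reps: int = 10,
    seed: int = 0,
    fp_cap: int = 200,
    diffusion: DiffusionParams | None = None,
    query_map: Mapping[str, str] | None = None,
) -> EvaluationResult:
    """Reconstruct disease modules from partial knowledge.

    For every module, kept-fraction f, and repetition: a seeded RNG keeps
    ``ceil(f * |module|)`` genes (f = 0 keeps none) as the query's known
    genes, the rest must be recovered; recovery is scored by the
    truncated normalized AUC of the removed genes in the ranking (kept
    genes excluded from the candidates).  ``assoc`` supplies the other
    diseases' associations used for the similarity background; the query
    disease's own entry is replaced by the kept subset.  ``query_map``
    maps module ids onto disease ids known to the similarity source;
    unmapped modules run without similarity background and are skipped
    (with a warning) when there is nothing to seed from.
    """
    if any(not (0.0 <= f <= 1.0) for f in kept_fractions):
        raise ValueError("kept_fractions must lie in [0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p = p or SigmoidParams()
    diffusion = diffusion or DiffusionParams()
    assoc = assoc or DiseaseGeneMap({})
    query_map = dict(query_map or {})
    result = EvaluationResult()
    root = np.random.SeedSequence(seed)
    module_ids = sorted(modules)
    streams = dict(zip(module_ids, root.spawn(len(module_ids))))
    net_genes = frozenset(net.genes)
    for mid in module_ids:
        mod_genes = sorted(set(modules[mid]) & net_genes)
        if not mod_genes:
            log.warning("module %s entirely outside the network; skipped", mid)
            result.skipped["module_outside_network"] = (
                result.skipped.get("module_outside_network", 0) + 1
            )
            continue
        query = query_map.get(mid, mid)
        if sim is not None and query not in sim:
            log.warning(
                "module %s: query %s unknown to the similarity source; "
                "running without similarity background", mid, query,
            )
        rng = np.random.default_rng(streams[mid])
        for f in kept_fractions:
            n_keep = math.ceil(f * len(mod_genes)) if f > 0 else 0
            for rep in range(reps):
                if n_keep >= len(mod_genes):
                    continue  # nothing left to recover
                kept = sorted(
                    rng.choice(mod_genes, size=n_keep, replace=False).tolist()
                )
                removed = sorted(set(mod_genes) - set(kept))
                trial_assoc = assoc.with_genes(query, kept)
                try:
                    ranking, _own = _rank_case(
                        query, trial_assoc, sim, net, p, diffusion, exclude=kept
                    )
                except ValueError as exc:
                    log.warning(
                        "module %s f=%g rep=%d skipped: %s", mid, f, rep, exc
                    )
                    result.skipped["cannot_seed"] = (
                        result.skipped.get("cannot_seed", 0) + 1
                    )
                    continue
                result.module_records.append(
                    ModuleRecord(
                        disease=mid,
                        kept_fraction=f,
                        rep=rep,
                        nauc=normalized_auc(ranking, removed, fp_cap=fp_cap),
                        kept_genes=frozenset(kept),
                    )
                )
    return result


def random_baseline(
    net: Interactome,
    positives: Iterable[str],
    ks: Sequence[int] = DEFAULT_K,
    fp_cap: int = 200,
    reps: int = 100,
    seed: int = 0,
) -> EvaluationResult:
    """Uniformly random gene orderings scored with the same metrics.

    For each repetition a random permutation of the gene universe is
    scored: every positive contributes one recall case (its rank), and
    the permutation contributes one truncated-normalized-AUC value.
    Fully reproducible from ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pos = sorted(set(positives))
    if not pos:
        raise ValueError("no positives given")
    missing = [g for g in pos if g not in net]
    if missing:
        raise KeyError(f"positives not in network: {missing[:5]}")
    rng = np.random.default_rng(seed)
    n = net.n
    pos_idx = np.asarray([net.index(g) for g in pos])
    result = EvaluationResult()
    for rep in range(reps):
        perm = rng.permutation(n)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        positions = inv[pos_idx]
        for g, pos0 in zip(pos, positions):
            result.records.append(
                CaseRecord(
                    disease="random",
                    test_gene=g,
                    rank=int(pos0) + 1,
                    n_candidates=n,
                    stratum="random",
                )
            )
        result.module_records.append(
            ModuleRecord(
                disease="random",
                kept_fraction=None,
                rep=rep,
                nauc=_nauc_from_positions(positions, len(pos), fp_cap),
            )
        )
    return result
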