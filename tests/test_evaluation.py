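import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardigan import (
    DiseaseGeneMap,
    GeneRanking,
    Interactome,
    evaluate_loo,
    evaluate_module_reconstruction,
    evaluate_timelapse,
    make_world,
    normalized_auc,
    random_baseline,
)
from cardigan.evaluation import EvaluationResult


def ranking_of(genes):
    return GeneRanking(list(genes), np.linspace(1, 0, len(genes)))


class TestNormalizedAuc:
    def test_perfect_ranking_scores_one(self):
        genes = [f"g{i:04d}" for i in range(300)]
        assert normalized_auc(ranking_of(genes), set(genes[:10])) == 1.0

    def test_all_positives_after_cap_scores_zero(self):
        genes = [f"g{i:04d}" for i in range(300)]
        assert normalized_auc(ranking_of(genes), set(genes[-10:]), fp_cap=200) == 0.0

    def test_interleaved_hand_value(self):
        # ranking: P N P N N ... one positive at 0 and one after 1 negative
        r = ranking_of(["p1", "n1", "p2", "n2", "n3", "n4"])
        # fp_cap=2: positive p1 counted for 2 FP steps, p2 for 1 => (2+1)/(2*2)
        assert normalized_auc(r, {"p1", "p2"}, fp_cap=2) == pytest.approx(0.75)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positives"):
            normalized_auc(ranking_of(["a", "b"]), set())

    @settings(derandomize=True, max_examples=100)
    @given(
        n=st.integers(5, 300),
        data=st.data(),
        cap=st.integers(1, 250),
    )
    def test_bounded_in_unit_interval_for_any_positive_set(self, n, data, cap):
        genes = [f"g{i:04d}" for i in range(n)]
        k = data.draw(st.integers(1, n))
        positives = data.draw(
            st.sets(st.sampled_from(genes), min_size=1, max_size=k)
        )
        value = normalized_auc(ranking_of(genes), positives, fp_cap=cap)
        assert 0.0 <= value <= 1.0

    def test_random_ranking_matches_closed_form_expectation(self):
        """Monte-Carlo mean ~ (fp_cap/(n-P))/2 for uniformly random orderings."""
        n, P, cap, reps = 2000, 30, 200, 400
        net = Interactome.from_edges([], extra_genes=[f"g{i:05d}" for i in range(n)])
        res = random_baseline(net, [f"g{i:05d}" for i in range(P)],
                              fp_cap=cap, reps=reps, seed=42)
        vals = np.array([r.nauc for r in res.module_records])
        expected = (cap / (n - P)) / 2
        stderr = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - expected) <= 3 * stderr


@pytest.fixture(scope="module")
def loo_world():
    world = make_world(m=4, s=25, p_in=0.5, p_out=0.01,
                       diseases_per_module=2, genes_per_disease=5, seed=21)
    return world, world.similarity()


class TestLeaveOneOut:
    def test_clique_disease_genes_recovered_near_top(self):
        """Two genes of one disease inside a tight planted module must be
        predicted back within the top 10 of a 100-node network; ranks are
        cross-checked against an exhaustive recomputation."""
        from cardigan import DiffusionParams, build_qws, propagate

        world = make_world(m=10, s=10, p_in=0.9, p_out=0.0,
                           diseases_per_module=1, genes_per_disease=2, seed=2)
        res = evaluate_loo(world.assoc_t1, world.interactome, None,
                           mode="charted")
        d0 = [r for r in res.records if r.disease == "D000"]
        assert len(d0) == 2
        for r in d0:
            assert r.rank <= 10
            # exhaustive check: recompute scores and count genes ahead
            reduced = world.assoc_t1.without("D000", r.test_gene)
            F = propagate(
                world.interactome,
                build_qws("D000", reduced, None, world.interactome),
                DiffusionParams(),
            )
            net = world.interactome
            mine = F[net.index(r.test_gene)]
            ahead = sum(
                1
                for g in net.genes
                if g not in r.seed_genes
                and (F[net.index(g)] > mine
                     or (F[net.index(g)] == mine and g < r.test_gene))
            )
            assert r.rank == ahead + 1

    def test_recall_is_monotone_in_k(self, loo_world):
        world, sim = loo_world
        res = evaluate_loo(world.assoc_t1, world.interactome, sim, mode="charted")
        rs = [res.recall_at(k) for k in (1, 10, 100, 200)]
        assert rs == sorted(rs)

    def test_uncharted_mode_skips_multi_gene_diseases(self, loo_world):
        world, sim = loo_world
        # every disease has >=2 genes at t1, so uncharted mode finds nothing
        assert all(len(world.assoc_t1.genes_of(d)) >= 2
                   for d in world.assoc_t1.diseases)
        with pytest.raises(ValueError, match="no eligible"):
            evaluate_loo(world.assoc_t1, world.interactome, sim, mode="uncharted")

    def test_uncharted_mode_uses_single_gene_diseases(self, loo_world):
        world, sim = loo_world
        single = DiseaseGeneMap(
            {d: sorted(world.assoc_t1.genes_of(d))[:1]
             for d in world.assoc_t1.diseases}
        )
        res = evaluate_loo(single, world.interactome, sim, mode="uncharted")
        assert len(res.records) == len(single.diseases)
        for r in res.records:
            assert r.seed_genes == frozenset()  # truly uncharted cases

    def test_held_out_gene_never_in_seed_set(self, loo_world):
        world, sim = loo_world
        res = evaluate_loo(world.assoc_t1, world.interactome, sim, mode="charted")
        for r in res.records:
            assert r.test_gene not in r.seed_genes

    def test_metric_agreement_after_tsv_round_trip(self, loo_world, tmp_path):
        world, sim = loo_world
        res = evaluate_loo(world.assoc_t1, world.interactome, sim, mode="charted")
        path = tmp_path / "cases.tsv"
        res.write_cases_tsv(path)
        again = EvaluationResult.read_cases_tsv(path)
        for k in (1, 10, 100):
            assert again.recall_at(k) == res.recall_at(k)


class TestTimeLapse:
    def test_identical_snapshots_rejected(self, loo_world):
        world, sim = loo_world
        with pytest.raises(ValueError, match="empty time-lapse test set"):
            evaluate_timelapse(world.assoc_t1, world.assoc_t1,
                               world.interactome, sim)

    def test_uncharted_gain_bookkeeping(self, loo_world):
        world, sim = loo_world
        t1 = world.assoc_t1
        # strip one disease entirely at t0: it gains its genes back at t1
        target = t1.diseases[0]
        t0 = t1.with_genes(target, [])
        res = evaluate_timelapse(t0, t1, world.interactome, sim)
        uncharted = [r for r in res.records if r.stratum == "uncharted_at_t0"]
        assert {r.disease for r in uncharted} == {target}
        assert len(uncharted) == len(t1.genes_of(target))

    def test_gained_gene_outside_network_counted_not_tested(self, loo_world):
        world, sim = loo_world
        t0 = world.assoc_t1
        target = t0.diseases[0]
        in_net = sorted(set(world.interactome.genes) - t0.genes_of(target))[0]
        t1 = t0.with_genes(target, t0.genes_of(target) | {"GHOST", in_net})
        res = evaluate_timelapse(t0, t1, world.interactome, sim)
        assert res.skipped == {"gene_not_in_network": 1}
        assert {r.test_gene for r in res.records} == {in_net}

    def test_t0_only_associations_reported_as_violations(self, loo_world):
        world, sim = loo_world
        t0 = world.assoc_t1
        d0, d1 = t0.diseases[0], t0.diseases[1]
        g = sorted(t0.genes_of(d0))[0]
        # d1 gains one new in-network gene; d0 loses one (a snapshot violation)
        gained = sorted(set(world.interactome.genes) - t0.genes_of(d1))[0]
        t1 = t0.without(d0, g).with_genes(d1, t0.genes_of(d1) | {gained})
        res = evaluate_timelapse(t0, t1, world.interactome, sim)
        assert (d0, g) in res.violations
        assert {r.test_gene for r in res.records} == {gained}

    def test_prediction_never_sees_t1_only_associations(self, loo_world):
        world, sim = loo_world
        t0 = world.assoc_t0
        t1 = world.assoc_t1
        res = evaluate_timelapse(t0, t1, world.interactome, sim)
        t1_only = {g for d, g in (t1.pairs() - t0.pairs())}
        for r in res.records:
            assert r.seed_genes <= t0.genes_of(r.disease)
            assert r.test_gene not in r.seed_genes


@pytest.fixture(scope="module")
def module_setup():
    world = make_world(seed=31)
    qmap = {
        mid: min(d for d, m in world.module_of.items() if m == mid)
        for mid in world.modules
    }
    return world, world.similarity(), qmap


class TestModuleReconstruction:
    def test_full_module_kept_yields_no_cases(self, module_setup):
        world, sim, qmap = module_setup
        res = evaluate_module_reconstruction(
            {"M00": world.modules["M00"]}, world.interactome, sim,
            assoc=world.assoc_t1, kept_fractions=[1.0], reps=3, seed=0,
            query_map=qmap,
        )
        assert res.module_records == []

    def test_zero_fraction_predicts_from_similarity_alone(self, module_setup):
        world, sim, qmap = module_setup
        res = evaluate_module_reconstruction(
            {"M00": world.modules["M00"]}, world.interactome, sim,
            assoc=world.assoc_t1, kept_fractions=[0.0], reps=3, seed=0,
            fp_cap=100, query_map=qmap,
        )
        assert len(res.module_records) == 3
        for r in res.module_records:
            assert r.kept_genes == frozenset()
            assert 0.0 <= r.nauc <= 1.0

    def test_module_outside_network_skipped_with_warning(self, module_setup, caplog):
        world, sim, qmap = module_setup
        import logging

        with caplog.at_level(logging.WARNING):
            res = evaluate_module_reconstruction(
                {"MX": {"GHOST1", "GHOST2"}}, world.interactome, sim,
                assoc=world.assoc_t1, kept_fractions=[0.5], reps=2, seed=0,
            )
        assert res.skipped == {"module_outside_network": 1}

    def test_seeded_rerun_is_identical(self, module_setup):
        world, sim, qmap = module_setup
        kw = dict(
            modules={"M01": world.modules["M01"]}, net=world.interactome,
            sim=sim, assoc=world.assoc_t1, kept_fractions=[0.5], reps=4,
            seed=7, fp_cap=100, query_map=qmap,
        )
        a = evaluate_module_reconstruction(**kw)
        b = evaluate_module_reconstruction(**kw)
        assert [r.nauc for r in a.module_records] == [r.nauc for r in b.module_records]
        assert [r.kept_genes for r in a.module_records] == [
            r.kept_genes for r in b.module_records
        ]


class TestRandomBaseline:
    def test_fixed_seed_is_bit_identical(self, path3):
        a = random_baseline(path3, ["A"], reps=5, seed=3, fp_cap=2)
        b = random_baseline(path3, ["A"], reps=5, seed=3, fp_cap=2)
        assert [r.rank for r in a.records] == [r.rank for r in b.records]

    def test_recall_at_network_size_is_one(self, path3):
        res = random_baseline(path3, ["A", "B"], reps=10, seed=0, fp_cap=2)
        assert res.recall_at(3) == 1.0

    def test_expected_recall_matches_closed_form(self):
        n, k, reps = 500, 50, 200
        net = Interactome.from_edges([], extra_genes=[f"g{i:04d}" for i in range(n)])
        res = random_baseline(net, ["g0000"], reps=reps, seed=9)
        hits = np.array([r.rank <= k for r in res.records], dtype=float)
        expected = k / n
        stderr = hits.std(ddof=1) / np.sqrt(reps)
        assert abs(hits.mean() - expected) <= 3 * stderr
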