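"""Consensus pipeline tests: pre-screen, intersection, tiering, funnel report."""

import math

import numpy as np
import pytest

from phytoppi import consensus as cs
from phytoppi import learners as ln
from phytoppi import pipeline
from phytoppi.datasets import negatives_random
from phytoppi.go_semantics import funsim
from phytoppi.io import PairRecord, ProteinRecord


@pytest.fixture()
def cc_universe(toy_go):
    """Six proteins annotated in the toy CC DAG (terms C, D, A, B...)."""
    dag, _ = toy_go
    seq = "ACDEFGHIKL" * 8
    prots = {}
    from phytoppi.io import AnnotationRecord

    for pid, terms in {
        "p1": ["C"], "p2": ["C"], "p3": ["D"], "p4": ["B"],
        "p5": ["C", "D"], "p6": [],
    }.items():
        prots[pid] = ProteinRecord(
            pid, seq, annotations=[AnnotationRecord(t, "CC") for t in terms]
        )
    return dag, prots


class TestPrescreen:
    def test_identical_single_term_kept(self, cc_universe):
        dag, prots = cc_universe
        kept, counts = cs.prescreen_cc([("p1", "p2")], prots, dag)
        assert kept[0][0] == ("p1", "p2")
        assert kept[0][1] == pytest.approx(1.0)
        assert counts["kept"] == 1

    def test_boundary_exactly_threshold_dropped(self, cc_universe):
        dag, prots = cc_universe
        score = funsim({"C"}, {"D"}, dag)
        kept, counts = cs.prescreen_cc(
            [("p1", "p3")], prots, dag, threshold=score
        )
        assert kept == [] and counts["below_threshold"] == 1
        # strictly-below threshold keeps it
        kept2, _ = cs.prescreen_cc([("p1", "p3")], prots, dag, threshold=score - 1e-9)
        assert len(kept2) == 1

    def test_unannotated_protein_dropped_with_count(self, cc_universe):
        dag, prots = cc_universe
        kept, counts = cs.prescreen_cc([("p1", "p6")], prots, dag)
        assert kept == [] and counts["no_cc_annotation"] == 1

    def test_toy_universe_survivors_match_enumeration(self, cc_universe):
        dag, prots = cc_universe
        pairs = [("p1", "p2"), ("p1", "p3"), ("p2", "p5"), ("p3", "p4"),
                 ("p4", "p5"), ("p1", "p6")]
        threshold = 0.4
        expected = []
        for a, b in pairs:
            ta, tb = prots[a].terms("CC"), prots[b].terms("CC")
            if ta and tb and funsim(ta, tb, dag) > threshold:
                expected.append((a, b))
        kept, _ = cs.prescreen_cc(pairs, prots, dag, threshold=threshold)
        assert [k for k, _ in kept] == expected


def trained_toy_models(seed=0):
    """Tiny real bundles: separable AC space and functional space."""
    rng = np.random.default_rng(seed)
    X_svm = rng.standard_normal((40, 420))
    y = (np.arange(40) % 2).astype(int)
    X_svm[y == 1] += 2.0
    svm = ln.train_svm(X_svm, y, ln.SVMHyperparams(1.0, -9.0), kind="svm_loc")
    X_rf = rng.standard_normal((40, 8))
    X_rf[y == 1, 4] += 6.0
    rf = ln.train_rf(X_rf, y, ln.RF_FEATURES_8, n_trees=50, seed=seed)
    return svm, rf, X_svm, X_rf, y


class TestPredictConsensus:
    def features_from(self, X_svm, X_rf):
        feats = []
        for i in range(len(X_svm)):
            f = cs.PairFeatures(pair=(f"a{i:02d}", f"b{i:02d}"), ac=X_svm[i])
            from phytoppi.profiles import CoexpressionScore

            f.coexpression = CoexpressionScore(*X_rf[i, [1, 0, 3, 2]])
            f.ias, f.cas, f.pas = X_rf[i, 4], X_rf[i, 5], X_rf[i, 6]
            f.profile_sim = X_rf[i, 7]
            feats.append(f)
        return feats

    def test_consensus_is_conjunction(self):
        svm, rf, X_svm, X_rf, y = trained_toy_models()
        records = cs.predict_consensus(self.features_from(X_svm, X_rf), svm, rf)
        for rec in records:
            assert rec.consensus == (rec.svm_decision and rec.rf_decision)
            assert rec.rf_decision == (rec.rf_probability > 0.5)

    def test_rf_probability_below_half_blocks_consensus(self):
        svm, rf, X_svm, X_rf, _ = trained_toy_models()
        recs = cs.predict_consensus(self.features_from(X_svm, X_rf), svm, rf)
        blocked = [r for r in recs if r.svm_decision and not r.rf_decision]
        assert all(not r.consensus for r in blocked)

    def test_missing_functional_features_marked_unknown(self):
        svm, rf, X_svm, X_rf, _ = trained_toy_models()
        feats = self.features_from(X_svm[:2], X_rf[:2])
        feats[0].coexpression = None
        feats[0].profile_sim = math.nan
        records = cs.predict_consensus(feats, svm, rf)
        assert records[0].status == "unknown"
        assert records[0].reason
        assert records[1].status == "ok"

    def test_incomplete_coexpression_routes_to_four_feature_model(self):
        svm, rf, X_svm, X_rf, y = trained_toy_models()
        rf4 = ln.train_rf(
            X_rf[:, 4:], y, ln.RF_FEATURES_4, n_trees=50, kind="rf_rand_4"
        )
        feats = self.features_from(X_svm[:4], X_rf[:4])
        for f in feats:
            f.coexpression = None
        records = cs.predict_consensus(feats, svm, rf, rf4_model=rf4)
        assert all(r.status == "ok" for r in records)

    def test_consensus_fpr_not_above_either_branch(self, small_world):
        """On synthetic data the intersection's false-positive rate cannot
        exceed either branch's — the architecture's purpose."""
        world = small_world
        train_pos = world.positives[:36]
        test_pos = world.positives[36:]
        trained = pipeline.train_pipeline(
            world, train_pos, seed=3,
            svm_grid={"log2_C": [1, 5], "log2_gamma": [-9, -5]}, n_trees=100,
        )
        test_neg = negatives_random(world.positives, seed=5)[: len(test_pos) * 3]
        candidates = list(test_pos) + [
            n for n in test_neg if n.key not in {p.key for p in world.positives}
        ]
        truth = {p.key: p.label == "positive" for p in candidates}
        records, _ = pipeline.predict(trained, world, candidates)
        ok = [r for r in records if r.status == "ok"]
        y = np.array([truth[r.pair] for r in ok])
        if (~y).sum() == 0:
            pytest.skip("no negatives survived the pre-screen at this scale")
        fpr = lambda pred: ln.evaluate(pred, y).fpr
        svm = np.array([r.svm_decision for r in ok])
        rf = np.array([r.rf_decision for r in ok])
        cons = np.array([r.consensus for r in ok])
        assert fpr(cons) <= min(fpr(svm), fpr(rf)) + 1e-12


class TestTiering:
    def record(self, prob=1.0, ias=250.0, pas=25.0, phylo=0.95, consensus=True):
        feat = cs.PairFeatures(pair=("a", "b"), ias=ias, pas=pas, profile_sim=phylo)
        return cs.PredictionRecord(
            pair=("a", "b"), rf_probability=prob, consensus=consensus, features=feat
        )

    def test_tier1_high_string_plus_second_evidence(self):
        ev = cs.EvidenceRecord(string_score=950, shared_pathways=["path1"])
        assert cs.assign_tier(self.record(prob=1.0), ev) == 1

    def test_tier2_single_evidence_flag(self):
        ev = cs.EvidenceRecord(shared_pathways=["path1"])
        assert cs.assign_tier(self.record(prob=0.96), ev) == 2

    def test_tier3_internal_scores_only(self):
        rec = self.record(prob=1.0, ias=250, pas=25, phylo=0.95)
        assert cs.assign_tier(rec, None) == 3

    def test_tier3_requires_maximal_probability_and_all_scores(self):
        assert cs.assign_tier(self.record(prob=0.99), None) == "untiered"
        assert cs.assign_tier(self.record(ias=150), None) == "untiered"
        assert cs.assign_tier(self.record(pas=10), None) == "untiered"
        assert cs.assign_tier(self.record(phylo=0.5), None) == "untiered"

    def test_non_consensus_never_tiered(self):
        ev = cs.EvidenceRecord(string_score=990, shared_pathways=["p"])
        assert cs.assign_tier(self.record(consensus=False), ev) == "untiered"

    def test_removing_evidence_never_raises_tier(self):
        order = {1: 3, 2: 2, 3: 1, "untiered": 0}
        full = cs.EvidenceRecord(
            string_score=950, shared_pathways=["p"], literature_comention=True
        )
        reduced = [
            cs.EvidenceRecord(string_score=950),
            cs.EvidenceRecord(shared_pathways=["p"]),
            cs.EvidenceRecord(),
            None,
        ]
        base = cs.assign_tier(self.record(prob=0.97), full)
        for ev in reduced:
            t = cs.assign_tier(self.record(prob=0.97), ev)
            assert order[t] <= order[base] or t == 3  # dropping all evidence may
            # re-qualify a pair for the internal-evidence tier, which is lower
        assert order[cs.assign_tier(self.record(prob=0.97, ias=0), None)] <= order[base]

    def test_string_score_validation(self):
        with pytest.raises(ValueError, match="string_score"):
            cs.EvidenceRecord(string_score=1500)


class TestSummarizeRun:
    def make_records(self, spec):
        """spec: list of (svm, rf_prob) tuples; status ok."""
        out = []
        for i, (svm, prob) in enumerate(spec):
            rec = cs.PredictionRecord(
                pair=(f"x{i}", f"y{i}"), svm_decision=svm,
                rf_probability=prob, rf_decision=prob > 0.5,
                consensus=svm and prob > 0.5,
            )
            out.append(rec)
        return out

    def test_zero_consensus_all_zero(self):
        records = self.make_records([(False, 0.1), (False, 0.9)])
        rep = cs.summarize_run(records)
        assert rep["consensus"] == 0
        assert rep["consensus_pct_all"] == 0.0

    def test_percentages_hand_arithmetic(self):
        # 10 candidates, 5 screened, 4 svm+, 2 rf+, 2 common
        records = self.make_records(
            [(True, 0.9), (True, 0.8), (True, 0.2), (True, 0.3), (False, 0.4)]
        )
        rep = cs.summarize_run(records, n_candidates=10)
        assert rep["cc_screened_pct_all"] == pytest.approx(50.0)
        assert rep["svm_positive_pct_cc"] == pytest.approx(80.0)
        assert rep["rf_positive_pct_cc"] == pytest.approx(40.0)
        assert rep["consensus"] == 2
        assert rep["consensus_pct_cc"] == pytest.approx(40.0)
        assert rep["consensus_pct_all"] == pytest.approx(20.0)

    def test_funnel_monotone(self):
        records = self.make_records(
            [(True, 0.9), (True, 0.1), (False, 0.95), (False, 0.2)]
        )
        rep = cs.summarize_run(records)
        assert rep["consensus"] <= min(rep["svm_positive"], rep["rf_positive"])
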