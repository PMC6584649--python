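"""Dataset construction tests: filters, negative schemes, identity pruning, folds."""

import itertools

import numpy as np
import pytest

from phytoppi import datasets as db
from phytoppi.io import PairRecord, ProteinRecord


def make_proteins(spec):
    """spec: {id: (length, {compartments})}"""
    out = {}
    for pid, (length, comps) in spec.items():
        out[pid] = ProteinRecord(pid, "ACDEFGHIKL" * (length // 10 + 1), localizations=set(comps))
        out[pid].sequence = out[pid].sequence[:length]
    return out


class TestFilterPositives:
    def proteins(self):
        return make_proteins(
            {
                "A": (100, {"n"}), "B": (100, {"n"}), "C": (49, {"c"}),
                "D": (50, {"c"}), "E": (200, {"m"}), "F": (60, {"m"}),
            }
        )

    def test_short_protein_boundary(self):
        prots = self.proteins()
        kept, counts = db.filter_positives(
            [PairRecord("A", "C"), PairRecord("A", "D")], prots
        )
        # length 49 partner dropped; length 50 survives a "< 50" filter
        assert [p.key for p in kept] == [("A", "D")]
        assert counts["short"] == 1

    def test_genetic_evidence_dropped(self):
        prots = self.proteins()
        kept, counts = db.filter_positives(
            [PairRecord("A", "B", evidence_system="genetic"), PairRecord("E", "F")],
            prots,
        )
        assert [p.key for p in kept] == [("E", "F")]
        assert counts["genetic"] == 1

    def test_toy_enumeration_with_counts(self):
        prots = self.proteins()
        raw = [
            PairRecord("A", "B"),
            PairRecord("B", "A"),  # duplicate after canonicalization
            PairRecord("A", "C"),  # short partner
            PairRecord("D", "E", evidence_system="genetic"),
            PairRecord("E", "F"),
            PairRecord("A", "Z"),  # unknown protein
        ]
        kept, counts = db.filter_positives(raw, prots)
        assert {p.key for p in kept} == {("A", "B"), ("E", "F")}
        assert counts == {
            "unknown_protein": 1, "short": 1, "genetic": 1, "duplicate": 1,
        }
        assert all(p.label == "positive" for p in kept)


class TestNegativeSchemes:
    def test_localization_pool_enumeration(self):
        prots = make_proteins({"A": (60, {"N"}), "B": (60, {"N"}), "C": (60, {"C"})})
        negs = db.negatives_by_localization(prots, [], 2, seed=0)
        assert {n.key for n in negs} == {("A", "C"), ("B", "C")}

    def test_shared_compartment_pool_empty(self):
        prots = make_proteins({"A": (60, {"N"}), "B": (60, {"N"})})
        with pytest.raises(ValueError, match="0 pairs"):
            db.negatives_by_localization(prots, [], 1, seed=0)

    def test_localization_negatives_are_disjoint_and_exclude_positives(self):
        rng = np.random.default_rng(0)
        comps = ["n", "c", "m", "x"]
        prots = make_proteins(
            {f"P{i}": (60, {comps[rng.integers(4)]}) for i in range(20)}
        )
        positives = [PairRecord("P0", "P1"), PairRecord("P2", "P3")]
        negs = db.negatives_by_localization(prots, positives, 30, seed=1)
        assert len(negs) == 30
        pos_keys = {p.key for p in positives}
        for n in negs:
            assert n.key not in pos_keys
            assert prots[n.protein_a].localizations.isdisjoint(
                prots[n.protein_b].localizations
            )

    def test_random_negatives_exhausted_universe(self):
        positives = [PairRecord(a, b) for a, b in [("A", "B"), ("A", "C"), ("B", "C")]]
        with pytest.raises(ValueError):
            db.negatives_random(positives, seed=0)

    def test_random_negatives_deterministic_and_disjoint_from_positives(self):
        positives = [
            PairRecord(f"P{i}", f"P{j}", label="positive")
            for i, j in [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
        ]
        first = db.negatives_random(positives, seed=42)
        assert first == db.negatives_random(positives, seed=42)
        pos_keys = {p.key for p in positives}
        for seed in range(1000):
            negs = db.negatives_random(positives, seed=seed)
            assert len(negs) == len(positives)
            assert all(n.key not in pos_keys for n in negs)


def nw_oracle(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Exhaustive enumeration of all global alignments of two short strings.

    Returns (best score, set of identity percentages of optimal alignments).
    """
    best = {}

    def walk(i, j, cols):
        if i == len(a) and j == len(b):
            score = 0.0
            matches = 0
            for x, y in cols:
                if x == "-" or y == "-":
                    score += gap
                elif x == y:
                    score += match
                    matches += 1
                else:
                    score += mismatch
            ident = 100.0 * matches / len(cols)
            best.setdefault(score, set()).add(round(ident, 9))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            walk(i, j + 1, cols + [("-", b[j])])

    walk(0, 0, [])
    top = max(best)
    return top, best[top]


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert db.global_identity("ACDEFG", "ACDEFG") == 100.0

    def test_completely_different_sequences(self):
        # equal length, all mismatches; gaps cost -1 so the ungapped
        # alignment (score 0) is optimal and has zero identity
        assert db.global_identity("AAAA", "GGGG") == 0.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ("GATTACA", "GCATGCU".replace("U", "T")),
            ("ACDEF", "ADF"),
            ("WWKE", "WKE"),
            ("MKV", "MKVLY"),
        ],
    )
    def test_against_exhaustive_alignment_oracle(self, a, b):
        best_score, identities = nw_oracle(a, b)
        got = db.global_identity(a, b)
        assert any(got == pytest.approx(i, abs=1e-9) for i in identities), (
            f"identity {got} not among optimal-alignment identities {identities} "
            f"(optimal score {best_score})"
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            db.global_identity("", "ACD")


class TestPruneByIdentity:
    def proteins(self):
        seqs = {
            "A": "MKVLYAANGG" * 6,
            "A2": "MKVLYAANGG" * 6,          # identical to A
            "B": "WWPQRSTEEF" * 6,
            "C": "GGHHIIKKLL" * 6,
            "D": "NNPPQQRRSS" * 6,
        }
        return {pid: ProteinRecord(pid, s) for pid, s in seqs.items()}

    def test_cutoff_100_keeps_everything(self):
        prots = self.proteins()
        pairs = [PairRecord("A", "B"), PairRecord("A2", "C")]
        assert db.prune_by_identity(pairs, prots, cutoff=100) == pairs

    def test_shared_identical_protein_dropped_at_80(self):
        prots = self.proteins()
        pairs = [PairRecord("A", "B"), PairRecord("A2", "C")]
        kept = db.prune_by_identity(pairs, prots, cutoff=80)
        assert [p.key for p in kept] == [("A", "B")]

    def test_greedy_matches_exhaustive_simulation(self):
        prots = self.proteins()
        pairs = [
            PairRecord("A", "B"), PairRecord("A2", "C"),
            PairRecord("C", "D"), PairRecord("B", "D"), PairRecord("A", "D"),
        ]
        cutoff = 80.0

        # independent greedy simulation over a precomputed identity matrix
        ident = {}
        for x, y in itertools.combinations(prots, 2):
            ident[frozenset((x, y))] = db.global_identity(
                prots[x].sequence, prots[y].sequence
            )
        def sim_ident(p, q):
            return 100.0 if p == q else ident[frozenset((p, q))]

        kept_prot, expected = [], []
        for pair in pairs:
            clash = any(
                sim_ident(p, q) > cutoff for p in pair.key for q in kept_prot
            )
            if not clash:
                expected.append(pair)
                kept_prot.extend(pair.key)
        assert db.prune_by_identity(pairs, prots, cutoff=cutoff) == expected

    def test_monotone_in_cutoff(self):
        prots = self.proteins()
        pairs = [
            PairRecord("A", "B"), PairRecord("A2", "C"),
            PairRecord("C", "D"), PairRecord("B", "D"),
        ]
        sizes = [
            len(db.prune_by_identity(pairs, prots, cutoff=c)) for c in (100, 80, 50, 30)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestFolds:
    def balanced_pairs(self, n_per_class):
        pos = [
            PairRecord(f"P{i}", f"Q{i}", label="positive") for i in range(n_per_class)
        ]
        neg = [
            PairRecord(f"R{i}", f"S{i}", label="negative") for i in range(n_per_class)
        ]
        return pos + neg

    def test_twelve_pairs_six_folds_perfectly_stratified(self):
        pairs = self.balanced_pairs(6)
        fold_of = db.assign_folds(pairs, k=6, seed=0)
        for fold in range(1, 7):
            members = [p for p in pairs if fold_of[p.key] == fold]
            assert len(members) == 2
            assert sum(p.label == "positive" for p in members) == 1

    def test_deterministic_under_seed(self):
        pairs = self.balanced_pairs(9)
        assert db.assign_folds(pairs, seed=3) == db.assign_folds(pairs, seed=3)

    def test_class_balance_deviation_at_most_one(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(12, 40))
            pairs = self.balanced_pairs(n)
            fold_of = db.assign_folds(pairs, k=6, seed=int(rng.integers(1000)))
            for fold in range(1, 7):
                members = [p for p in pairs if fold_of[p.key] == fold]
                n_pos = sum(p.label == "positive" for p in members)
                assert abs(n_pos - (len(members) - n_pos)) <= 1

    def test_too_many_folds_raises(self):
        with pytest.raises(ValueError):
            db.assign_folds(self.balanced_pairs(2), k=6)


class TestBuildDataset:
    def test_balance_invariant_both_schemes(self, small_world):
        world = small_world
        positives = world.positives[:20]
        for scheme in ("loc", "rand"):
            ds = db.build_dataset(positives, world.proteins, scheme=scheme, seed=5)
            assert ds.n_positive == 20
            assert len(ds.pairs) == 40
            folds = ds.folds()
            assert set(folds.tolist()) == set(range(1, 7))

    def test_duplicate_pair_rejected(self):
        pos = [PairRecord("A", "B", label="positive")]
        neg = [PairRecord("A", "B", label="negative")]
        with pytest.raises(ValueError, match="duplicate"):
            db.LabeledPairDataset(pos + neg, "rand")

    def test_unbalanced_rejected(self):
        pos = [PairRecord("A", "B", label="positive")]
        with pytest.raises(ValueError, match="unbalanced"):
            db.LabeledPairDataset(pos, "rand")
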