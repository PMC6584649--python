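"""Genome-scale consensus prediction: CC pre-screen, parallel branches,
intersection, and confidence tiering.

Candidate pairs are first screened for subcellular co-localization
(Cellular Component FunSim strictly above 0.4 by default); surviving
pairs are scored independently by the sequence SVM and the functional
random forest, and only pairs predicted by *both* branches are called
interacting.  Intersecting two independent predictors trades recall for
a much lower false-positive rate, which is the priority at genome scale.

Consensus predictions are then tiered by external supporting evidence
(association-database score, shared pathway membership, literature
co-mention, correlated mass-spectrometry elution profiles) and, for
pairs with no external evidence, by very high internal scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .go_semantics import AssociationTable, GoDag, funsim, pair_association
from .io import PairRecord, ProteinRecord, canonical_pair
from .learners import RF_FEATURES_4, RF_FEATURES_8, TrainedModelBundle
from .profiles import CoexpressionScore, profile_similarity
from .seq_features import PhysicochemicalScales, encode_ac

logger = logging.getLogger("phytoppi")

CC_FUNSIM_THRESHOLD = 0.4
PREDICTED_CONFIDENCE_THRESHOLD = 10000.0

EVIDENCE_FLAGS = ("string_high", "shared_pathway", "co_literature", "elution_profile")


@dataclass
class EvidenceRecord:
    """Optional external evidence for one pair."""

    string_score: int | None = None  # 0..1000
    shared_pathways: list[str] = field(default_factory=list)
    literature_comention: bool = False
    elution_correlated: bool = False

    def __post_init__(self) -> None:
        if self.string_score is not None and not 0 <= self.string_score <= 1000:
            raise ValueError("string_score must lie in [0, 1000]")

    def flags(self, string_high: int = 900) -> set[str]:
        out = set()
        if self.string_score is not None and self.string_score > string_high:
            out.add("string_high")
        if self.shared_pathways:
            out.add("shared_pathway")
        if self.literature_comention:
            out.add("co_literature")
        if self.elution_correlated:
            out.add("elution_profile")
        return out


@dataclass
class TierThresholds:
    """Configurable confidence-tier cutoffs.

    The association-score cutoffs (IAS/PAS) are only meaningful relative
    to the table they were computed from, so tier 3 requires either
    precomputed tables or explicitly chosen thresholds.
    """

    rf_probability: float = 0.95
    string_high: int = 900
    ias: float = 200.0
    pas: float = 20.0
    phylo: float = 0.9


@dataclass
class PairFeatures:
    """Assembled features of one candidate pair."""

    pair: tuple[str, str]
    ac: np.ndarray | None = None  # 420-dim sequence pair vector
    coexpression: CoexpressionScore | None = None
    ias: float = 0.0
    cas: float = 0.0
    pas: float = 0.0
    profile_sim: float = math.nan
    error: str | None = None

    def functional_vector(self, names: Sequence[str]) -> np.ndarray:
        coexpr = self.coexpression or CoexpressionScore()
        table = {
            "mr_microarray": coexpr.mr_microarray,
            "pcc_microarray": coexpr.pcc_microarray,
            "mr_rnaseq": coexpr.mr_rnaseq,
            "pcc_rnaseq": coexpr.pcc_rnaseq,
            "ias": self.ias,
            "cas": self.cas,
            "pas": self.pas,
            "profile_similarity": self.profile_sim,
        }
        return np.array([table[n] for n in names])

    @property
    def coexpression_complete(self) -> bool:
        return self.coexpression is not None and self.coexpression.is_complete()


@dataclass
class PredictionRecord:
    pair: tuple[str, str]
    cc_funsim: float = math.nan
    svm_decision: bool = False
    rf_probability: float = math.nan
    rf_decision: bool = False
    consensus: bool = False
    tier: int | str = "untiered"
    evidence_flags: set[str] = field(default_factory=set)
    status: str = "ok"  # ok | unknown
    reason: str | None = None
    features: PairFeatures | None = None


def prescreen_cc(
    pairs: Iterable[PairRecord | tuple[str, str]],
    proteins: Mapping[str, ProteinRecord],
    dag: GoDag,
    threshold: float = CC_FUNSIM_THRESHOLD,
    min_predicted_confidence: float = PREDICTED_CONFIDENCE_THRESHOLD,
) -> tuple[list[tuple[tuple[str, str], float]], dict[str, int]]:
    """Keep pairs whose CC FunSim is strictly above ``threshold``.

    Pairs with a protein lacking usable CC annotation (experimental, or
    predicted above the confidence cutoff) are dropped and counted, as
    are pairs below the cutoff.  Returns ([(pair, funsim), ...], counts).
    """
    survivors = []
    counts = {"no_cc_annotation": 0, "below_threshold": 0, "kept": 0}
    for pair in pairs:
        key = pair.key if isinstance(pair, PairRecord) else canonical_pair(*pair)
        terms = []
        for pid in key:
            prot = proteins.get(pid)
            t = prot.terms("CC", min_predicted_confidence) if prot else set()
            terms.append(t)
        if not terms[0] or not terms[1]:
            counts["no_cc_annotation"] += 1
            continue
        score = funsim(terms[0], terms[1], dag)
        if score > threshold:
            survivors.append((key, score))
            counts["kept"] += 1
        else:
            counts["below_threshold"] += 1
    logger.info("prescreen_cc: %s", counts)
    return survivors, counts


def assemble_features(
    pairs: Iterable[tuple[str, str]],
    proteins: Mapping[str, ProteinRecord],
    scales: PhysicochemicalScales,
    association_tables: Mapping[str, AssociationTable],
    coexpression: Mapping[tuple[str, str], CoexpressionScore] | None = None,
    profile_table=None,
    aggregate: str = "sum",
    min_predicted_confidence: float = PREDICTED_CONFIDENCE_THRESHOLD,
    max_lag: int = 30,
) -> list[PairFeatures]:
    """Assemble sequence and functional features for candidate pairs.

    A pair whose features cannot be computed is returned with its
    ``error`` set rather than silently dropped.  Association scores use
    all usable GO terms of both proteins; absent profile or
    co-expression data yields NaN / None fields, which downstream
    routing handles.
    """
    ac_cache: dict[str, np.ndarray] = {}

    def ac_of(pid: str) -> np.ndarray:
        if pid not in ac_cache:
            ac_cache[pid] = encode_ac(proteins[pid].sequence, scales, max_lag)
        return ac_cache[pid]

    out = []
    for a, b in (canonical_pair(*p) for p in pairs):
        feat = PairFeatures(pair=(a, b))
        try:
            if a not in proteins or b not in proteins:
                raise KeyError(f"unknown protein in pair ({a}, {b})")
            feat.ac = np.concatenate([ac_of(a), ac_of(b)])
            terms_a = set().union(
                *(proteins[a].terms(asp, min_predicted_confidence) for asp in ("CC", "BP", "MF"))
            )
            terms_b = set().union(
                *(proteins[b].terms(asp, min_predicted_confidence) for asp in ("CC", "BP", "MF"))
            )
            for kind in ("IAS", "CAS", "PAS"):
                table = association_tables.get(kind)
                if table is not None and terms_a and terms_b:
                    score = pair_association(terms_a, terms_b, table, aggregate)
                else:
                    score = 0.0
                setattr(feat, kind.lower(), score)
            if coexpression is not None:
                feat.coexpression = coexpression.get((a, b))
            if profile_table is not None and a in profile_table.index and b in profile_table.index:
                feat.profile_sim = profile_similarity(
                    profile_table.loc[a].to_numpy(), profile_table.loc[b].to_numpy()
                )
        except (KeyError, ValueError) as exc:
            feat.error = str(exc)
        out.append(feat)
    return out


def predict_consensus(
    features: Sequence[PairFeatures],
    svm_model: TrainedModelBundle,
    rf_model: TrainedModelBundle,
    rf4_model: TrainedModelBundle | None = None,
    cc_funsim: Mapping[tuple[str, str], float] | None = None,
) -> list[PredictionRecord]:
    """Run both branches on assembled features and intersect their calls.

    The 8-feature forest is used when co-expression is complete;
    otherwise the pair routes to the 4-feature model (if provided).
    Pairs whose features failed to assemble are marked ``unknown``.
    """
    records = []
    for feat in features:
        rec = PredictionRecord(pair=feat.pair, features=feat)
        if cc_funsim is not None:
            rec.cc_funsim = cc_funsim.get(feat.pair, math.nan)
        if feat.error is not None or feat.ac is None:
            rec.status, rec.reason = "unknown", feat.error or "missing sequence features"
            records.append(rec)
            continue
        full = feat.coexpression_complete and not math.isnan(feat.profile_sim)
        if full:
            branch, names = rf_model, RF_FEATURES_8
        elif rf4_model is not None and not math.isnan(feat.profile_sim):
            branch, names = rf4_model, RF_FEATURES_4
        else:
            rec.status, rec.reason = "unknown", "missing functional features"
            records.append(rec)
            continue
        if tuple(branch.feature_names) != tuple(names):
            raise ValueError(
                f"model {branch.kind} expects features {branch.feature_names}, "
                f"routing selected {names}"
            )
        rec.svm_decision = bool(svm_model.decide(feat.ac.reshape(1, -1))[0])
        rec.rf_probability = float(
            branch.predict_probability(feat.functional_vector(names).reshape(1, -1))[0]
        )
        rec.rf_decision = rec.rf_probability > 0.5
        rec.consensus = rec.svm_decision and rec.rf_decision
        records.append(rec)
    return records


def assign_tier(
    record: PredictionRecord,
    evidence: EvidenceRecord | None,
    thresholds: TierThresholds | None = None,
) -> int | str:
    """Confidence tier of a consensus prediction.

    Tier 1: high RF probability, a very high association-database score
    plus at least one further evidence flag.  Tier 2: high RF
    probability and exactly one evidence flag.  Tier 3: no external
    evidence but maximal RF probability and high internal functional
    scores (IAS, PAS, profile similarity).  Anything else is untiered;
    non-consensus pairs are never tiered.
    """
    t = thresholds or TierThresholds()
    if not record.consensus:
        record.tier = "untiered"
        return record.tier
    flags = evidence.flags(t.string_high) if evidence is not None else set()
    record.evidence_flags = flags
    high_prob = record.rf_probability >= t.rf_probability
    if high_prob and "string_high" in flags and len(flags) >= 2:
        record.tier = 1
    elif high_prob and len(flags) == 1:
        record.tier = 2
    elif not flags and record.features is not None and (
        record.rf_probability >= 1.0
        and record.features.ias > t.ias
        and record.features.pas > t.pas
        and record.features.profile_sim > t.phylo
    ):
        record.tier = 3
    else:
        record.tier = "untiered"
    return record.tier


def summarize_run(
    records: Sequence[PredictionRecord], n_candidates: int | None = None
) -> dict:
    """Stage-by-stage funnel counts and percentages.

    ``pct_all`` is relative to all candidate pairs, ``pct_cc`` to the
    pairs that survived the CC pre-screen (the scored records).
    """
    n_cc = sum(r.status == "ok" for r in records)
    n_svm = sum(r.svm_decision for r in records if r.status == "ok")
    n_rf = sum(r.rf_decision for r in records if r.status == "ok")
    n_common = sum(r.consensus for r in records if r.status == "ok")
    n_all = n_candidates if n_candidates is not None else len(records)
    pct = lambda x, d: 100.0 * x / d if d else 0.0
    tiers = {
        str(t): sum(r.tier == t for r in records) for t in (1, 2, 3)
    }
    return {
        "candidates": n_all,
        "cc_screened": n_cc,
        "cc_screened_pct_all": pct(n_cc, n_all),
        "svm_positive": n_svm,
        "svm_positive_pct_cc": pct(n_svm, n_cc),
        "rf_positive": n_rf,
        "rf_positive_pct_cc": pct(n_rf, n_cc),
        "consensus": n_common,
        "consensus_pct_cc": pct(n_common, n_cc),
        "consensus_pct_all": pct(n_common, n_all),
        "tiers": tiers,
    }
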