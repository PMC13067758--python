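"""Disease-level herb prioritization over a symptom set.

A disease is represented by a set of symptoms (e.g., the 30 curated renal
fibrosis symptoms).  Each herb's total score is the *sum* of its predicted
association probabilities over the symptom set, so a disease with |S|
symptoms bounds the score by [0, |S|].  Per symptom, herbs are ranked by
descending probability (ties broken lexicographically by herb id); the
rank-1 herb is the "preferred" and the rank-2 herb the "secondary"
therapeutic candidate for that symptom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kb_io import KnowledgeBase
from .model import PairScore, TrainedModel, predict
from .network import FeatureConfig, build_all_pair_features

__all__ = ["SymptomSet", "RankingReport", "disease_score", "rank_herbs",
           "rank_herbs_from_scores"]


@dataclass
class SymptomSet:
    disease: str
    symptoms: list[str]

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise ValueError("symptom set must be non-empty")
        if len(self.symptoms) != len(set(self.symptoms)):
            raise ValueError("symptom set contains duplicates")

    def resolve(self, kb: KnowledgeBase) -> None:
        unknown = [s for s in self.symptoms if s not in set(kb.symptoms)]
        if unknown:
            raise KeyError(f"symptom ids not in knowledge base: {unknown}")


@dataclass
class RankingReport:
    disease: str
    total_score: dict[str, float]              # herb -> sum of probabilities
    rank: dict[tuple[str, str], int]           # (herb, symptom) -> rank, 1 best
    preferred_count: dict[str, int]            # herb -> #symptoms at rank 1
    secondary_count: dict[str, int]            # herb -> #symptoms at rank 2
    top: list[tuple[str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        herbs = sorted(self.total_score)
        ranking = pd.DataFrame({
            "herb_id": herbs,
            "total_score": [self.total_score[h] for h in herbs],
            "preferred_count": [self.preferred_count.get(h, 0) for h in herbs],
            "secondary_count": [self.secondary_count.get(h, 0) for h in herbs],
        }).sort_values(["total_score", "herb_id"],
                       ascending=[False, True], ignore_index=True)
        per_symptom = pd.DataFrame(
            [(h, s, r) for (h, s), r in sorted(self.rank.items())],
            columns=["herb_id", "symptom_id", "rank"])
        return ranking, per_symptom


def disease_score(scores: list[PairScore], herb: str,
                  symptom_set: SymptomSet) -> float:
    """Sum of predicted probabilities for one herb over the symptom set."""
    wanted = set(symptom_set.symptoms)
    relevant = {s.symptom: s.probability for s in scores
                if s.herb == herb and s.symptom in wanted}
    missing = wanted - set(relevant)
    if missing:
        raise ValueError(f"missing scores for herb {herb!r}: {sorted(missing)}")
    return float(sum(relevant.values()))


def rank_herbs_from_scores(scores: list[PairScore], symptom_set: SymptomSet,
                           top_n: int = 10) -> RankingReport:
    """Build the full ranking report from precomputed pair scores."""
    herbs = sorted({s.herb for s in scores})
    if not herbs:
        raise ValueError("no herbs to rank")
    prob = {(s.herb, s.symptom): s.probability for s in scores}
    warnings: list[str] = []
    if top_n > len(herbs):
        warnings.append(f"top_n={top_n} clipped to {len(herbs)} herbs")
        top_n = len(herbs)

    total = {h: 0.0 for h in herbs}
    rank: dict[tuple[str, str], int] = {}
    preferred = {h: 0 for h in herbs}
    secondary = {h: 0 for h in herbs}
    for sym in symptom_set.symptoms:
        col = []
        for h in herbs:
            if (h, sym) not in prob:
                raise ValueError(f"missing score for pair ({h}, {sym})")
            p = prob[(h, sym)]
            total[h] += p
            col.append((-p, h))
        col.sort()  # descending probability, lexicographic tie-break
        for r, (_, h) in enumerate(col, start=1):
            rank[(h, sym)] = r
        preferred[col[0][1]] += 1
        if len(col) > 1:
            secondary[col[1][1]] += 1

    top = sorted(total.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return RankingReport(
        disease=symptom_set.disease, total_score=total, rank=rank,
        preferred_count=preferred, secondary_count=secondary,
        top=[(h, float(v)) for h, v in top], warnings=warnings)


def rank_herbs(model: TrainedModel, kb: KnowledgeBase, embeddings,
               symptom_set: SymptomSet, top_n: int = 10,
               feature_config: FeatureConfig | None = None) -> RankingReport:
    """Score every (herb, symptom-set) pair with the model and rank."""
    symptom_set.resolve(kb)
    fc = feature_config or FeatureConfig()
    pairs = [(h, s) for h in kb.herbs for s in symptom_set.symptoms]
    features = build_all_pair_features(kb, embeddings, pairs, fc)
    scores = predict(model, features)
    return rank_herbs_from_scores(scores, symptom_set, top_n)


def write_ranking(report: RankingReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranking, per_symptom = report.to_frames()
    ranking.to_csv(out / "ranking.tsv", sep="\t", index=False,
                   float_format="%.6f")
    per_symptom.to_csv(out / "per_symptom_ranks.tsv", sep="\t", index=False)
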