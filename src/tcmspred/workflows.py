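"""High-level workflows: the synthetic recovery study in library form.

Bundles the pipeline stages (simulate -> embed -> featurize -> evaluate)
so that the parameter-recovery study — cross-validated AUC of the fusion
model and its ablations on the default synthetic profile — can be run
with one call from tests, scripts, or a notebook.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .embedding import Corpus, EmbeddingTable, SgnsParams, cosine, train_sgns
from .evaluation import CVResult, cross_validate
from .kb_io import AssociationTable, KnowledgeBase
from .model import MODALITIES, ModelConfig
from .network import FeatureConfig, PairFeatures, build_all_pair_features
from .synthetic import GroundTruth, SynthParams, generate_corpus, generate_kb

__all__ = ["Study", "RECOVERY_MODEL_CONFIG", "build_study", "recovery_cv",
           "semantic_separation"]

# Reduced network for the desk-scale recovery study: the synthetic KB has
# ~100 tokens and sets of ~10-15 genes, so short sequences and narrow
# layers suffice and keep a 5-fold CV in the minutes range on one CPU.
RECOVERY_MODEL_CONFIG = ModelConfig(
    gene_dim=16, hidden=24, proc_hidden=(64,), cls_hidden=(32,),
    dropout=0.1, lr=1e-3, batch_size=64, max_epochs=15, patience=3)

RECOVERY_FEATURE_CONFIG = FeatureConfig(seq_len=16, n_perm=100)


@dataclass
class Study:
    kb: KnowledgeBase
    associations: AssociationTable
    truth: GroundTruth
    embeddings: EmbeddingTable
    features: list[PairFeatures]
    labels: np.ndarray
    synth: SynthParams
    sgns: SgnsParams
    feature_config: FeatureConfig


def build_study(
    seed: int = 7,
    synth: SynthParams | None = None,
    sgns: SgnsParams | None = None,
    feature_config: FeatureConfig | None = None,
) -> Study:
    """Generate the synthetic study and compute embeddings + features."""
    synth = replace(synth or SynthParams(), seed=seed)
    sgns = replace(sgns or SgnsParams(), seed=seed + 101)
    fc = replace(feature_config or RECOVERY_FEATURE_CONFIG, seed=seed + 202)

    kb, assoc, truth = generate_kb(synth)
    corpus = Corpus(generate_corpus(kb, truth, synth))
    table = train_sgns(corpus, sgns)
    features = build_all_pair_features(kb, table, assoc.pairs(), fc)
    return Study(
        kb=kb, associations=assoc, truth=truth, embeddings=table,
        features=features, labels=np.array(assoc.labels(), dtype=int),
        synth=synth, sgns=sgns, feature_config=fc)


def recovery_cv(
    study: Study,
    k: int = 5,
    seed: int = 0,
    modalities: tuple[str, ...] = MODALITIES,
    shuffle_labels: bool = False,
    model_config: ModelConfig | None = None,
) -> CVResult:
    """Cross-validate the fusion model (or an ablation) on the study."""
    cfg = replace(model_config or RECOVERY_MODEL_CONFIG,
                  modalities=modalities, seed=seed)
    labels = study.labels.copy()
    if shuffle_labels:
        labels = labels[np.random.default_rng(seed + 17).permutation(len(labels))]
    return cross_validate(study.features, labels, cfg, k=k, seed=seed)


def semantic_separation(study: Study) -> tuple[float, float]:
    """Mean embedding cosine of truly associated vs non-associated pairs."""
    pos, neg = [], []
    for h in study.kb.herbs:
        vh = study.embeddings.vector(h)
        for s in study.kb.symptoms:
            c = cosine(vh, study.embeddings.vector(s))
            (pos if study.truth.true_label[(h, s)] else neg).append(c)
    return float(np.mean(pos)), float(np.mean(neg))
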