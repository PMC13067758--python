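"""Shared fixtures: hand-built knowledge bases and the synthetic study.

The expensive default-profile study (SGNS training + full-grid
featurization) is session-scoped so the recovery checks share one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcmspred.embedding import EmbeddingTable
from tcmspred.kb_io import KnowledgeBase, PPIGraph
from tcmspred.network import FeatureConfig, build_all_pair_features
from tcmspred.synthetic import SynthParams, generate_kb
from tcmspred.workflows import Study, build_study


@pytest.fixture
def path_kb() -> KnowledgeBase:
    """A-B-C path graph; H1 targets {A, C}, S1 genes {B}."""
    return KnowledgeBase(
        herb_targets={"H1": frozenset({"A", "C"})},
        symptom_genes={"S1": frozenset({"B"})},
        ppi=PPIGraph.from_edges([("A", "B"), ("B", "C")]),
    )


@pytest.fixture(scope="session")
def small_params() -> SynthParams:
    """A fast profile for unit tests that need a realistic KB."""
    return SynthParams(n_herbs=20, n_symptoms=12, n_genes=120, n_modules=4,
                       p_in=0.2, p_out=0.02, targets_per_herb=8,
                       genes_per_symptom=10, corpus_sentences=600,
                       sentence_length=6, seed=11)


@pytest.fixture(scope="session")
def small_kb(small_params):
    return generate_kb(small_params)


@pytest.fixture(scope="session")
def small_features(small_kb, small_params):
    """Features for the small KB under random (non-trained) embeddings."""
    kb, assoc, _ = small_kb
    rng = np.random.default_rng(0)
    vocab = kb.herbs + kb.symptoms
    emb = EmbeddingTable(vocab=vocab,
                         vectors_in=rng.normal(size=(len(vocab), 8)),
                         vectors_out=np.zeros((len(vocab), 8)))
    fc = FeatureConfig(seq_len=12, n_perm=20, seed=5)
    feats = build_all_pair_features(kb, emb, assoc.pairs(), fc)
    return feats, np.array(assoc.labels(), dtype=int)


@pytest.fixture(scope="session")
def default_study() -> Study:
    """The full default synthetic profile with trained SGNS embeddings."""
    return build_study(seed=7)
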