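"""Synthetic knowledge bases with planted herb-symptom structure.

The generator emulates a SymMap-style resource at desk scale: genes are
partitioned into modules, the PPI graph is a stochastic block model that is
dense within modules and sparse between them, and each herb/symptom draws
its gene set mostly from one "home" module.  A pair is truly associated
when the cosine between the herb's and the symptom's module-occupancy
profiles exceeds a threshold, so PPI proximity, shared gene tokens, and
corpus co-occurrence all carry the same planted signal — the statistical
structure the fusion model assumes.

The observed labels flip each true label independently with probability
``label_noise``, emulating curation error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .kb_io import (
    AssociationRow,
    AssociationTable,
    KnowledgeBase,
    PPIGraph,
    write_associations,
    write_knowledge_base,
)

__all__ = ["SynthParams", "GroundTruth", "GenerationError", "generate_kb",
           "generate_corpus", "write_dataset"]


class GenerationError(RuntimeError):
    """Parameter combination produced a degenerate label distribution."""


@dataclass
class SynthParams:
    """Generator controls.

    Defaults define the desk-scale study profile used throughout the test
    suite: 60 herbs x 40 symptoms over 300 genes in 6 modules, assortative
    PPI (p_in >> p_out), cosine threshold 0.8 for a true association, and
    5% label noise.
    """

    n_herbs: int = 60
    n_symptoms: int = 40
    n_genes: int = 300
    n_modules: int = 6
    p_in: float = 0.15
    p_out: float = 0.01
    targets_per_herb: int = 10
    genes_per_symptom: int = 15
    overlap_threshold: float = 0.8
    label_noise: float = 0.05
    home_frac: float = 0.9
    corpus_sentences: int = 5000
    sentence_length: int = 8
    seed: int = 7

    def validate(self) -> None:
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out (assortative modules)")
        for name in ("n_herbs", "n_symptoms", "n_genes", "n_modules",
                     "targets_per_herb", "genes_per_symptom",
                     "corpus_sentences", "sentence_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if not (0 < self.home_frac <= 1):
            raise ValueError("home_frac must be in (0, 1]")


@dataclass
class GroundTruth:
    """Module profiles and pre-noise labels; profiles sum to 1."""

    herb_module_profile: dict[str, list[float]]
    symptom_module_profile: dict[str, list[float]]
    true_label: dict[tuple[str, str], int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "herb_module_profile": self.herb_module_profile,
                "symptom_module_profile": self.symptom_module_profile,
                "true_label": {f"{h}|{s}": v for (h, s), v in self.true_label.items()},
            },
            indent=1,
            sort_keys=True,
        )

    def true_pairs(self) -> list[tuple[str, str]]:
        return [p for p, v in sorted(self.true_label.items()) if v == 1]


def _profile(genes: list[str], module_of: dict[str, int], n_modules: int) -> np.ndarray:
    counts = np.zeros(n_modules)
    for g in genes:
        counts[module_of[g]] += 1
    return counts / counts.sum()


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _draw_gene_set(
    rng: np.random.Generator,
    home: int,
    mean_size: int,
    modules: list[list[str]],
    all_genes: list[str],
    home_frac: float = 0.9,
) -> list[str]:
    # Poisson-dispersed set size around the mean, floor 1.
    size = max(1, int(rng.poisson(mean_size)))
    picked: set[str] = set()
    for _ in range(size):
        if rng.random() < home_frac:
            pool = modules[home]
        else:
            pool = all_genes
        picked.add(pool[rng.integers(len(pool))])
    return sorted(picked)


def generate_kb(
    params: SynthParams,
) -> tuple[KnowledgeBase, AssociationTable, GroundTruth]:
    """Generate a knowledge base, labeled pairs, and the ground truth.

    Fully deterministic given ``params.seed``.  Raises
    :class:`GenerationError` when the threshold leaves zero positives or
    zero negatives.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    module_of = {g: i % params.n_modules for i, g in enumerate(genes)}
    modules: list[list[str]] = [[] for _ in range(params.n_modules)]
    for g in genes:
        modules[module_of[g]].append(g)

    # Stochastic block model over the gene space.
    edges: set[tuple[str, str]] = set()
    n = params.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            p = params.p_in if module_of[genes[i]] == module_of[genes[j]] else params.p_out
            if rng.random() < p:
                edges.add((genes[i], genes[j]))
    ppi = PPIGraph(nodes=frozenset(genes), edges=frozenset(edges))

    herbs = [f"H{i:03d}" for i in range(params.n_herbs)]
    symptoms = [f"S{i:03d}" for i in range(params.n_symptoms)]

    herb_targets: dict[str, frozenset[str]] = {}
    herb_profiles: dict[str, np.ndarray] = {}
    for h in herbs:
        home = int(rng.integers(params.n_modules))
        tset = _draw_gene_set(rng, home, params.targets_per_herb, modules, genes,
                              params.home_frac)
        herb_targets[h] = frozenset(tset)
        herb_profiles[h] = _profile(tset, module_of, params.n_modules)

    symptom_genes: dict[str, frozenset[str]] = {}
    symptom_profiles: dict[str, np.ndarray] = {}
    for s in symptoms:
        home = int(rng.integers(params.n_modules))
        gset = _draw_gene_set(rng, home, params.genes_per_symptom, modules, genes,
                              params.home_frac)
        symptom_genes[s] = frozenset(gset)
        symptom_profiles[s] = _profile(gset, module_of, params.n_modules)

    true_label: dict[tuple[str, str], int] = {}
    rows: list[AssociationRow] = []
    for h in herbs:
        for s in symptoms:
            t = int(_cosine(herb_profiles[h], symptom_profiles[s])
                    >= params.overlap_threshold)
            true_label[(h, s)] = t
            observed = t ^ int(rng.random() < params.label_noise)
            # Category label groups pairs by the symptom's dominant module,
            # standing in for the disease categories of real curation.
            cat = f"C{int(np.argmax(symptom_profiles[s]))}"
            rows.append(AssociationRow(h, s, observed, cat))

    n_pos = sum(true_label.values())
    if n_pos == 0 or n_pos == len(true_label):
        raise GenerationError(
            f"degenerate truth ({n_pos} positives of {len(true_label)}); "
            "adjust overlap_threshold"
        )

    kb = KnowledgeBase(herb_targets=herb_targets, symptom_genes=symptom_genes, ppi=ppi)
    truth = GroundTruth(
        herb_module_profile={h: herb_profiles[h].tolist() for h in herbs},
        symptom_module_profile={s: symptom_profiles[s].tolist() for s in symptoms},
        true_label=true_label,
    )
    return kb, AssociationTable(rows), truth


def generate_corpus(
    kb: KnowledgeBase, truth: GroundTruth, params: SynthParams
) -> list[list[str]]:
    """Build a token corpus in which truly associated pairs co-occur.

    Each sentence seeds on a random true-positive (herb, symptom) pair and
    fills the remaining slots half with tokens whose dominant module
    matches the herb's (signal) and half with uniform tokens (noise).
    Every herb and symptom token is guaranteed at least one occurrence.
    """
    rng = np.random.default_rng(params.seed + 1)
    pos_pairs = truth.true_pairs()
    if not pos_pairs:
        raise GenerationError("no true positive pairs; cannot build corpus")

    herb_home = {h: int(np.argmax(p)) for h, p in truth.herb_module_profile.items()}
    sym_home = {s: int(np.argmax(p)) for s, p in truth.symptom_module_profile.items()}
    by_module: dict[int, list[str]] = {}
    for h, m in herb_home.items():
        by_module.setdefault(m, []).append(h)
    for s, m in sym_home.items():
        by_module.setdefault(m, []).append(s)
    all_tokens = kb.herbs + kb.symptoms

    sentences: list[list[str]] = []
    for _ in range(params.corpus_sentences):
        h, s = pos_pairs[rng.integers(len(pos_pairs))]
        sent = [h, s]
        same = by_module.get(herb_home[h], all_tokens)
        while len(sent) < params.sentence_length:
            pool = same if rng.random() < 0.5 else all_tokens
            sent.append(pool[rng.integers(len(pool))])
        order = rng.permutation(len(sent))
        sentences.append([sent[i] for i in order])

    # Coverage pass: give unseen tokens one sentence each.
    seen = {t for sent in sentences for t in sent}
    for tok in all_tokens:
        if tok not in seen:
            filler = [all_tokens[rng.integers(len(all_tokens))]
                      for _ in range(max(1, params.sentence_length - 1))]
            sentences.append([tok] + filler)
    return sentences


def write_dataset(out_dir: str | Path, params: SynthParams) -> dict[str, Path]:
    """Generate and write the full synthetic dataset in kb_io's formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb, assoc, truth = generate_kb(params)
    corpus = generate_corpus(kb, truth, params)

    paths = {
        "herb_targets": out / "herb_targets.tsv",
        "symptom_genes": out / "symptom_genes.tsv",
        "ppi_edges": out / "ppi_edges.tsv",
        "associations": out / "associations.tsv",
        "corpus": out / "corpus.txt",
        "truth": out / "truth.json",
        "params": out / "synth_params.json",
    }
    write_knowledge_base(kb, paths["herb_targets"], paths["symptom_genes"],
                         paths["ppi_edges"])
    write_associations(assoc, paths["associations"])
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        for sent in corpus:
            fh.write(" ".join(sent) + "\n")
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    paths["params"].write_text(json.dumps(asdict(params), indent=1), encoding="utf-8")
    return paths
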