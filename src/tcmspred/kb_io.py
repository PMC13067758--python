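"""Knowledge-base domain types, TSV readers/writers, and structural validation.

The knowledge base ties together three entity spaces — herbs, clinical
symptoms, and genes/proteins — through two bipartite maps (herb -> target
genes, symptom -> associated genes) and one protein-protein interaction
(PPI) graph over the gene space.  Labeled (herb, symptom) pairs form the
supervision signal for association prediction.

File dialect: TSV with a mandatory header row, UTF-8, no quoting, no
comment lines.  Canonical entity ordering is lexicographic, which makes
every downstream sequence construction deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PPIGraph",
    "KnowledgeBase",
    "AssociationTable",
    "AssociationRow",
    "ValidationReport",
    "KBParseError",
    "KBValidationError",
    "load_knowledge_base",
    "load_associations",
    "load_symptom_set",
    "write_knowledge_base",
    "write_associations",
    "validate",
]


class KBParseError(ValueError):
    """Malformed input file (wrong column count, bad label, empty id)."""


class KBValidationError(ValueError):
    """Structurally invalid knowledge base or association table."""


@dataclass(frozen=True)
class PPIGraph:
    """Undirected, unweighted PPI graph.

    Edges are stored as sorted 2-tuples so that (a, b) and (b, a) are the
    same edge; self-loops are disallowed by construction.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @staticmethod
    def canonical_edge(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "PPIGraph":
        nodes: set[str] = set(extra_nodes)
        canon: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                continue
            nodes.update((a, b))
            canon.add(cls.canonical_edge(a, b))
        return cls(nodes=frozenset(nodes), edges=frozenset(canon))

    def with_nodes(self, extra: Iterable[str]) -> "PPIGraph":
        return PPIGraph(nodes=frozenset(self.nodes | set(extra)), edges=self.edges)

    def degree(self, node: str) -> int:
        if node not in self.nodes:
            raise KeyError(f"unknown gene node {node!r}")
        return sum(1 for e in self.edges if node in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class KnowledgeBase:
    """Herb targets, symptom gene sets, and the PPI graph, with canonical ids.

    Invariants: every referenced gene appears in ``genes``; the id lists are
    duplicate-free and lexicographically sorted; every herb/symptom has at
    least one gene after validation.
    """

    herb_targets: dict[str, frozenset[str]]
    symptom_genes: dict[str, frozenset[str]]
    ppi: PPIGraph
    herbs: list[str] = field(default_factory=list)
    symptoms: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.herbs:
            self.herbs = sorted(self.herb_targets)
        if not self.symptoms:
            self.symptoms = sorted(self.symptom_genes)
        if not self.genes:
            referenced: set[str] = set(self.ppi.nodes)
            for s in self.herb_targets.values():
                referenced |= s
            for s in self.symptom_genes.values():
                referenced |= s
            self.genes = sorted(referenced)
        # Genes referenced only by target/gene maps are kept as isolated
        # PPI nodes so that set sizes used by overlap features survive.
        missing = set(self.genes) - self.ppi.nodes
        if missing:
            self.ppi = self.ppi.with_nodes(missing)


@dataclass(frozen=True)
class AssociationRow:
    herb: str
    symptom: str
    label: int
    category: str | None = None


@dataclass
class AssociationTable:
    """Labeled (herb, symptom) pairs; duplicate pairs are rejected."""

    rows: list[AssociationRow]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def labels(self) -> list[int]:
        return [r.label for r in self.rows]

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.herb, r.symptom) for r in self.rows]


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _read_tsv_pairs(path: Path, n_cols: int) -> list[list[str]]:
    """Read a header-carrying TSV and return data rows split on tabs."""
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise KBParseError(f"{path}: empty file (header row required)")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < n_cols or any(not p.strip() for p in parts[:n_cols]):
            raise KBParseError(
                f"{path}:{lineno}: expected {n_cols} tab-separated non-empty "
                f"columns, got {line!r}"
            )
        rows.append([p.strip() for p in parts])
    return rows


def load_knowledge_base(
    herb_targets_path: str | Path,
    symptom_genes_path: str | Path,
    ppi_path: str | Path,
    warnings_out: list[str] | None = None,
) -> KnowledgeBase:
    """Load the three TSV files into a validated :class:`KnowledgeBase`.

    Duplicate PPI edges and self-loops are dropped with a warning; genes
    referenced by the maps but absent from the PPI edge list are retained
    as isolated nodes.
    """
    warns = warnings_out if warnings_out is not None else []

    herb_targets: dict[str, set[str]] = {}
    for herb, gene, *_ in _read_tsv_pairs(Path(herb_targets_path), 2):
        herb_targets.setdefault(herb, set()).add(gene)

    symptom_genes: dict[str, set[str]] = {}
    for sym, gene, *_ in _read_tsv_pairs(Path(symptom_genes_path), 2):
        symptom_genes.setdefault(sym, set()).add(gene)

    edges: set[tuple[str, str]] = set()
    ppi_nodes: set[str] = set()
    for a, b, *_ in _read_tsv_pairs(Path(ppi_path), 2):
        if a == b:
            warns.append(f"self-loop on {a} dropped")
            continue
        e = PPIGraph.canonical_edge(a, b)
        if e in edges:
            warns.append(f"duplicate edge {e} dropped")
            continue
        edges.add(e)
        ppi_nodes.update(e)

    mapped_genes = set().union(*herb_targets.values(), *symptom_genes.values())
    for g in sorted(mapped_genes - ppi_nodes):
        warns.append(f"gene {g} absent from PPI edge list; kept as isolated node")

    kb = KnowledgeBase(
        herb_targets={h: frozenset(s) for h, s in herb_targets.items()},
        symptom_genes={s: frozenset(g) for s, g in symptom_genes.items()},
        ppi=PPIGraph(frozenset(ppi_nodes | mapped_genes), frozenset(edges)),
    )
    report = validate(kb)
    if not report.ok:
        raise KBValidationError(
            "knowledge base failed validation: "
            + "; ".join(f"[{c}] {m} ({i})" for c, m, i in report.errors)
        )
    return kb


def load_associations(path: str | Path, kb: KnowledgeBase) -> AssociationTable:
    """Load labeled herb-symptom pairs, resolving every id against ``kb``."""
    rows: list[AssociationRow] = []
    seen: set[tuple[str, str]] = set()
    herbs, symptoms = set(kb.herbs), set(kb.symptoms)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise KBParseError(f"{path}: empty file (header row required)")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3 or any(not p for p in parts[:3]):
            raise KBParseError(f"{path}:{lineno}: expected >=3 columns, got {line!r}")
        herb, symptom, label_s = parts[:3]
        category = parts[3] if len(parts) > 3 and parts[3] else None
        if label_s not in ("0", "1"):
            raise KBParseError(f"{path}:{lineno}: label must be 0 or 1, got {label_s!r}")
        if herb not in herbs:
            raise KBValidationError(f"{path}:{lineno}: unknown herb id {herb!r}")
        if symptom not in symptoms:
            raise KBValidationError(f"{path}:{lineno}: unknown symptom id {symptom!r}")
        if (herb, symptom) in seen:
            raise KBValidationError(
                f"{path}:{lineno}: duplicate pair ({herb}, {symptom})"
            )
        seen.add((herb, symptom))
        rows.append(AssociationRow(herb, symptom, int(label_s), category))
    return AssociationTable(rows)


def load_symptom_set(path: str | Path, kb: KnowledgeBase | None = None) -> list[str]:
    """Read one symptom id per line; optionally resolve against a KB."""
    with open(path, encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(ids) != len(set(ids)):
        raise KBValidationError(f"{path}: duplicate symptom ids in symptom set")
    if kb is not None:
        unknown = [s for s in ids if s not in set(kb.symptoms)]
        if unknown:
            raise KBValidationError(f"{path}: unknown symptom ids {unknown}")
    return ids


def validate(kb: KnowledgeBase) -> ValidationReport:
    """Structural validation: empty entity sets are fatal, isolation warns."""
    report = ValidationReport()
    for herb in kb.herbs:
        if not kb.herb_targets.get(herb):
            report.errors.append(("empty-target-set", "herb has no targets", herb))
    for sym in kb.symptoms:
        if not kb.symptom_genes.get(sym):
            report.errors.append(("empty-gene-set", "symptom has no genes", sym))
    if len(kb.herbs) != len(set(kb.herbs)):
        report.errors.append(("dup-herb", "duplicate herb ids", ""))
    if len(kb.symptoms) != len(set(kb.symptoms)):
        report.errors.append(("dup-symptom", "duplicate symptom ids", ""))
    linked = {n for e in kb.ppi.edges for n in e}
    for g in sorted(kb.ppi.nodes - linked):
        report.warnings.append(("isolated-gene", "gene has no PPI edges", g))
    return report


def write_knowledge_base(
    kb: KnowledgeBase,
    herb_targets_path: str | Path,
    symptom_genes_path: str | Path,
    ppi_path: str | Path,
) -> None:
    """Write the canonical TSV representation (sorted rows, header first)."""
    with open(herb_targets_path, "w", encoding="utf-8") as fh:
        fh.write("herb_id\tgene_id\n")
        for herb in sorted(kb.herb_targets):
            for gene in sorted(kb.herb_targets[herb]):
                fh.write(f"{herb}\t{gene}\n")
    with open(symptom_genes_path, "w", encoding="utf-8") as fh:
        fh.write("symptom_id\tgene_id\n")
        for sym in sorted(kb.symptom_genes):
            for gene in sorted(kb.symptom_genes[sym]):
                fh.write(f"{sym}\t{gene}\n")
    with open(ppi_path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(kb.ppi.edges):
            fh.write(f"{a}\t{b}\n")


def write_associations(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("herb_id\tsymptom_id\tlabel\tcategory\n")
        for r in table.rows:
            fh.write(f"{r.herb}\t{r.symptom}\t{r.label}\t{r.category or ''}\n")
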