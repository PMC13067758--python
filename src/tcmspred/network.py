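"""PPI-network proximity between herb target sets and symptom gene sets.

The proximity measure is the asymmetric closest distance familiar from
network medicine: for a target set T and a symptom gene set G,

    d(T, G) = (1/|T|) * sum_{t in T} min_{g in G} sp(t, g)

with shortest-path hops sp and an unreachable-pair sentinel of (diameter
of the largest connected component) + 1.  The raw distance is standardized
into a z-score against a degree-preserving null: random node sets of the
same sizes drawn from log2-degree bins matching the observed sets'
degree-bin profiles.

Scalar overlap statistics (Jaccard, overlap coefficient) and padded gene
token sequences complete the per-pair feature record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .embedding import EmbeddingTable
from .kb_io import KnowledgeBase, PPIGraph

__all__ = [
    "FeatureConfig",
    "ProximityResult",
    "PairFeatures",
    "GraphDistances",
    "shortest_path_from",
    "closest_proximity",
    "proximity_z",
    "overlap_stats",
    "build_pair_features",
    "build_all_pair_features",
    "save_pair_features",
    "load_pair_features",
]


@dataclass
class FeatureConfig:
    """Featurization settings: sequence length L, permutations, binning."""

    seq_len: int = 64
    n_perm: int = 100
    min_bin_occupancy: int = 5
    seed: int = 0

    def digest(self, embedding_dim: int) -> str:
        payload = json.dumps(
            {"L": self.seq_len, "n_perm": self.n_perm,
             "min_bin": self.min_bin_occupancy, "emb_dim": embedding_dim},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProximityResult:
    d_obs: float
    mu_rand: float
    sigma_rand: float
    z: float
    n_perm: int
    degenerate_null: bool = False


@dataclass
class PairFeatures:
    herb: str
    symptom: str
    semantic_herb: np.ndarray
    semantic_symptom: np.ndarray
    proximity: tuple[float, float, float, float]  # (d_obs, z, jaccard, overlap)
    herb_token_seq: np.ndarray     # (L,) int gene indices, -1 = pad
    herb_mask: np.ndarray          # (L,) bool
    symptom_token_seq: np.ndarray
    symptom_mask: np.ndarray
    config_digest: str = ""


class GraphDistances:
    """Shared shortest-path machinery over one PPI graph.

    Holds the sparse adjacency, node indexing, degree bins, and the
    unreachable sentinel so that per-pair queries stay cheap.
    """

    def __init__(self, graph: PPIGraph, min_bin_occupancy: int = 5):
        self.nodes = sorted(graph.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols = [], []
        for a, b in graph.edges:
            ia, ib = self.index[a], self.index[b]
            rows += [ia, ib]
            cols += [ib, ia]
        self.adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n))
        self.degrees = np.asarray(self.adj.sum(axis=1)).ravel().astype(int)
        self.sentinel = self._sentinel()
        self.bins, self.bin_of = self._degree_bins(min_bin_occupancy)
        self._null_cache: dict[tuple, tuple[float, float]] = {}

    def _sentinel(self) -> float:
        """Diameter of the largest connected component, plus one."""
        n_comp, labels = connected_components(self.adj, directed=False)
        largest = np.argmax(np.bincount(labels))
        members = np.flatnonzero(labels == largest)
        if len(members) < 2:
            return 1.0
        dist = dijkstra(self.adj, unweighted=True, indices=members)
        finite = dist[:, members]
        return float(finite[np.isfinite(finite)].max()) + 1.0

    def _degree_bins(self, min_occ: int) -> tuple[list[np.ndarray], np.ndarray]:
        """log2 degree bins, sparse bins merged upward to >= min_occ."""
        raw = np.floor(np.log2(self.degrees + 1)).astype(int)
        order = sorted(set(raw))
        merged: list[list[int]] = []
        current: list[int] = []
        count = 0
        for lvl in order:
            idx = np.flatnonzero(raw == lvl)
            current.extend(idx.tolist())
            count += len(idx)
            if count >= min_occ:
                merged.append(current)
                current, count = [], 0
        if current:
            if merged:
                merged[-1].extend(current)
            else:
                merged.append(current)
        bins = [np.array(sorted(m)) for m in merged]
        bin_of = np.empty(len(self.nodes), dtype=int)
        for b, members in enumerate(bins):
            bin_of[members] = b
        return bins, bin_of

    def min_dist_to_set(self, targets: np.ndarray) -> np.ndarray:
        """Per-node hop distance to the nearest member of ``targets``."""
        d = dijkstra(self.adj, unweighted=True, indices=targets, min_only=True)
        return d

    def set_distance(self, T: np.ndarray, G: np.ndarray,
                     dist_to_G: np.ndarray | None = None) -> float:
        """Closest distance d(T, G) with sentinel for unreachable targets."""
        if dist_to_G is None:
            dist_to_G = self.min_dist_to_set(G)
        d = dist_to_G[T]
        d = np.where(np.isfinite(d), d, self.sentinel)
        return float(d.mean())

    def bin_profile(self, members: np.ndarray) -> tuple[int, ...]:
        return tuple(np.bincount(self.bin_of[members], minlength=len(self.bins)))

    def sample_matched(self, profile: tuple[int, ...],
                       rng: np.random.Generator) -> np.ndarray:
        out = []
        for b, cnt in enumerate(profile):
            if cnt:
                out.append(rng.choice(self.bins[b], size=cnt, replace=False))
        return np.concatenate(out)


def shortest_path_from(graph: PPIGraph, source: str) -> dict[str, int]:
    """BFS hop distances from ``source``; unreachable nodes are absent."""
    if source not in graph.nodes:
        raise KeyError(f"unknown source node {source!r}")
    g = graph.to_networkx()
    return dict(nx.single_source_shortest_path_length(g, source))


def closest_proximity(graph: PPIGraph | GraphDistances, T: set[str], G: set[str],
                      sentinel: float | None = None) -> float:
    """d(T, G): mean over targets of the hop distance to the nearest G gene."""
    if not T or not G:
        raise ValueError("closest_proximity requires non-empty sets")
    gd = graph if isinstance(graph, GraphDistances) else GraphDistances(graph)
    if sentinel is not None:
        saved, gd.sentinel = gd.sentinel, sentinel
        try:
            return gd.set_distance(
                np.array(sorted(gd.index[t] for t in T)),
                np.array(sorted(gd.index[g] for g in G)))
        finally:
            gd.sentinel = saved
    return gd.set_distance(
        np.array(sorted(gd.index[t] for t in T)),
        np.array(sorted(gd.index[g] for g in G)))


def proximity_z(graph: PPIGraph | GraphDistances, T: set[str], G: set[str],
                n_perm: int = 100, seed: int = 0) -> ProximityResult:
    """Standardize d(T, G) against the degree-binned permutation null.

    Null sets match |T|, |G| and each set's log2-degree-bin profile.  The
    null mean/sd are cached per (T-profile, G-profile) signature, which is
    what makes featurizing a full herb x symptom grid affordable.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    gd = graph if isinstance(graph, GraphDistances) else GraphDistances(graph)
    T_idx = np.array(sorted(gd.index[t] for t in T))
    G_idx = np.array(sorted(gd.index[g] for g in G))
    d_obs = gd.set_distance(T_idx, G_idx)

    prof_T, prof_G = gd.bin_profile(T_idx), gd.bin_profile(G_idx)
    key = (prof_T, prof_G, n_perm, seed)
    if key in gd._null_cache:
        mu, sd = gd._null_cache[key]
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            rT = gd.sample_matched(prof_T, rng)
            rG = gd.sample_matched(prof_G, rng)
            null[i] = gd.set_distance(rT, rG)
        mu, sd = float(null.mean()), float(null.std(ddof=0))
        gd._null_cache[key] = (mu, sd)

    degenerate = sd == 0.0
    z = 0.0 if degenerate else (d_obs - mu) / sd
    return ProximityResult(d_obs=d_obs, mu_rand=mu, sigma_rand=sd, z=z,
                           n_perm=n_perm, degenerate_null=degenerate)


def overlap_stats(T: set[str], G: set[str]) -> tuple[float, float]:
    """(Jaccard, overlap coefficient) of two non-empty sets."""
    if not T or not G:
        raise ValueError("overlap_stats requires non-empty sets")
    inter = len(T & G)
    return inter / len(T | G), inter / min(len(T), len(G))


def _token_seq(genes: frozenset[str], gene_index: dict[str, int],
               L: int) -> tuple[np.ndarray, np.ndarray]:
    ordered = sorted(genes)[:L]
    seq = np.full(L, -1, dtype=int)
    mask = np.zeros(L, dtype=bool)
    for i, g in enumerate(ordered):
        seq[i] = gene_index[g]
        mask[i] = True
    return seq, mask


def build_pair_features(
    kb: KnowledgeBase,
    embeddings: EmbeddingTable,
    herb: str,
    symptom: str,
    config: FeatureConfig,
    gd: GraphDistances | None = None,
    warnings_out: list[str] | None = None,
) -> PairFeatures:
    """Assemble the full multimodal feature record for one (herb, symptom)."""
    if herb not in kb.herb_targets:
        raise KeyError(f"unknown herb {herb!r}")
    if symptom not in kb.symptom_genes:
        raise KeyError(f"unknown symptom {symptom!r}")
    gd = gd or GraphDistances(kb.ppi, config.min_bin_occupancy)
    T, G = set(kb.herb_targets[herb]), set(kb.symptom_genes[symptom])

    prox = proximity_z(gd, T, G, n_perm=config.n_perm, seed=config.seed)
    jac, ovl = overlap_stats(T, G)

    gene_index = {g: i for i, g in enumerate(kb.genes)}
    h_seq, h_mask = _token_seq(kb.herb_targets[herb], gene_index, config.seq_len)
    s_seq, s_mask = _token_seq(kb.symptom_genes[symptom], gene_index, config.seq_len)

    return PairFeatures(
        herb=herb,
        symptom=symptom,
        semantic_herb=embeddings.vector_or_zero(herb, warnings_out),
        semantic_symptom=embeddings.vector_or_zero(symptom, warnings_out),
        proximity=(prox.d_obs, prox.z, jac, ovl),
        herb_token_seq=h_seq,
        herb_mask=h_mask,
        symptom_token_seq=s_seq,
        symptom_mask=s_mask,
        config_digest=config.digest(embeddings.dim),
    )


def build_all_pair_features(
    kb: KnowledgeBase,
    embeddings: EmbeddingTable,
    pairs: list[tuple[str, str]],
    config: FeatureConfig,
    warnings_out: list[str] | None = None,
) -> list[PairFeatures]:
    """Featurize many pairs, sharing graph work across them.

    The per-symptom distance field (one multi-source BFS per distinct
    symptom) and the per-profile null cache make the full grid tractable.
    """
    gd = GraphDistances(kb.ppi, config.min_bin_occupancy)
    gene_index = {g: i for i, g in enumerate(kb.genes)}
    digest = config.digest(embeddings.dim)

    sym_dist: dict[str, np.ndarray] = {}
    herb_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sym_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    herb_vec: dict[str, np.ndarray] = {}
    sym_vec: dict[str, np.ndarray] = {}

    out: list[PairFeatures] = []
    for herb, symptom in pairs:
        if herb not in kb.herb_targets:
            raise KeyError(f"unknown herb {herb!r}")
        if symptom not in kb.symptom_genes:
            raise KeyError(f"unknown symptom {symptom!r}")
        T = set(kb.herb_targets[herb])
        G = set(kb.symptom_genes[symptom])
        if symptom not in sym_dist:
            G_idx = np.array(sorted(gd.index[g] for g in G))
            sym_dist[symptom] = gd.min_dist_to_set(G_idx)
            sym_seq[symptom] = _token_seq(kb.symptom_genes[symptom], gene_index,
                                          config.seq_len)
            sym_vec[symptom] = embeddings.vector_or_zero(symptom, warnings_out)
        if herb not in herb_seq:
            herb_seq[herb] = _token_seq(kb.herb_targets[herb], gene_index,
                                        config.seq_len)
            herb_vec[herb] = embeddings.vector_or_zero(herb, warnings_out)

        T_idx = np.array(sorted(gd.index[t] for t in T))
        d_obs = gd.set_distance(T_idx, None, sym_dist[symptom])
        prox = proximity_z(gd, T, G, n_perm=config.n_perm, seed=config.seed)
        jac, ovl = overlap_stats(T, G)
        h_seq, h_mask = herb_seq[herb]
        s_seq, s_mask = sym_seq[symptom]
        out.append(PairFeatures(
            herb=herb, symptom=symptom,
            semantic_herb=herb_vec[herb], semantic_symptom=sym_vec[symptom],
            proximity=(d_obs, prox.z, jac, ovl),
            herb_token_seq=h_seq.copy(), herb_mask=h_mask.copy(),
            symptom_token_seq=s_seq.copy(), symptom_mask=s_mask.copy(),
            config_digest=digest,
        ))
    return out


def save_pair_features(features: list[PairFeatures], out_dir) -> None:
    """Write scalar features as TSV plus a binary cache of the dense parts.

    ``pair_features.tsv`` holds the human-readable scalars; semantic
    vectors, token sequences, and masks go into ``feature_cache.bin``
    (raw little-endian arrays) described by ``feature_manifest.json``.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pair_features.tsv", "w", encoding="utf-8") as fh:
        fh.write("herb_id\tsymptom_id\td_obs\tz\tjaccard\toverlap\n")
        for f in features:
            d, z, j, o = f.proximity
            fh.write(f"{f.herb}\t{f.symptom}\t{d:.10g}\t{z:.10g}\t"
                     f"{j:.10g}\t{o:.10g}\n")
    blocks = [
        ("sem_h", np.stack([f.semantic_herb for f in features]), "<f8"),
        ("sem_s", np.stack([f.semantic_symptom for f in features]), "<f8"),
        ("h_seq", np.stack([f.herb_token_seq for f in features]), "<i8"),
        ("h_mask", np.stack([f.herb_mask for f in features]), "u1"),
        ("s_seq", np.stack([f.symptom_token_seq for f in features]), "<i8"),
        ("s_mask", np.stack([f.symptom_mask for f in features]), "u1"),
    ]
    manifest = {"n": len(features),
                "digest": features[0].config_digest if features else "",
                "blocks": []}
    with open(out / "feature_cache.bin", "wb") as fh:
        for name, arr, dtype in blocks:
            arr = arr.astype(dtype)
            manifest["blocks"].append(
                {"name": name, "dtype": dtype, "shape": list(arr.shape)})
            fh.write(arr.tobytes())
    (out / "feature_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")


def load_pair_features(in_dir) -> list[PairFeatures]:
    from pathlib import Path

    src = Path(in_dir)
    manifest = json.loads(
        (src / "feature_manifest.json").read_text(encoding="utf-8"))
    blob = (src / "feature_cache.bin").read_bytes()
    arrays: dict[str, np.ndarray] = {}
    off = 0
    for block in manifest["blocks"]:
        dt = np.dtype(block["dtype"])
        size = int(np.prod(block["shape"])) * dt.itemsize
        arrays[block["name"]] = np.frombuffer(
            blob[off:off + size], dtype=dt).reshape(block["shape"]).copy()
        off += size
    rows = []
    with open(src / "pair_features.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            herb, sym, d, z, j, o = line.rstrip("\n").split("\t")
            rows.append((herb, sym, float(d), float(z), float(j), float(o)))
    if len(rows) != manifest["n"]:
        raise ValueError("feature cache and TSV row counts disagree")
    out = []
    for i, (herb, sym, d, z, j, o) in enumerate(rows):
        out.append(PairFeatures(
            herb=herb, symptom=sym,
            semantic_herb=arrays["sem_h"][i].astype(float),
            semantic_symptom=arrays["sem_s"][i].astype(float),
            proximity=(d, z, j, o),
            herb_token_seq=arrays["h_seq"][i].astype(int),
            herb_mask=arrays["h_mask"][i].astype(bool),
            symptom_token_seq=arrays["s_seq"][i].astype(int),
            symptom_mask=arrays["s_mask"][i].astype(bool),
            config_digest=manifest["digest"],
        ))
    return out
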