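"""Skip-gram with negative sampling (SGNS) token embeddings.

Trains word2vec-style embeddings for the herb/symptom vocabulary from a
co-occurrence corpus.  For a (center w, context c) pair the objective is

    L = log sigma(u_c . v_w) + sum_{j=1..k} log sigma(-u_{n_j} . v_w)

with negatives n_j drawn from the unigram distribution raised to the 0.75
power.  Training is plain sequential SGD over all in-window pairs, single
worker, fully deterministic under the seed.  The context window is fixed
at its nominal width (no random shrinking) to keep the update sequence
reproducible and easy to reason about.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["Corpus", "SgnsParams", "EmbeddingTable", "train_sgns", "cosine",
           "sgns_pair_objective", "load_corpus", "write_embeddings",
           "read_embeddings"]


@dataclass
class Corpus:
    sentences: list[list[str]]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sentences):
            if not s:
                raise ValueError(f"sentence {i} is empty")
            if any(not isinstance(t, str) or not t for t in s):
                raise ValueError(f"sentence {i} contains an empty token")


@dataclass
class SgnsParams:
    dim: int = 128
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    lr0: float = 0.025
    lr_min: float = 1e-4
    min_count: int = 1
    unigram_exponent: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.dim < 2 or self.window < 1 or self.negatives < 1:
            raise ValueError("require dim >= 2, window >= 1, negatives >= 1")


@dataclass
class EmbeddingTable:
    """Ordered vocabulary with input (v_w) and output (u_c) vectors."""

    vocab: list[str]
    vectors_in: np.ndarray   # (|V|, d) — the embeddings handed downstream
    vectors_out: np.ndarray  # (|V|, d) — context-side vectors

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors_in.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        """Input vector v_w for a known token; KeyError otherwise."""
        if token not in self._index:
            raise KeyError(f"token {token!r} not in embedding vocabulary")
        return self.vectors_in[self._index[token]].copy()

    def vector_or_zero(self, token: str, warnings_out: list[str] | None = None) -> np.ndarray:
        if token in self._index:
            return self.vectors_in[self._index[token]].copy()
        if warnings_out is not None:
            warnings_out.append(f"out-of-vocabulary token {token!r}; using zero vector")
        return np.zeros(self.dim)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; raises on zero-norm input."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def sgns_pair_objective(
    v_w: np.ndarray, u_c: np.ndarray, u_neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Objective L and analytic gradients for one pair with fixed negatives.

    Returns (L, dL/dv_w, dL/du_c, dL/du_neg).  Exposed so the gradient can
    be checked against finite differences.
    """
    s_pos = _sigmoid(u_c @ v_w)
    s_neg = _sigmoid(-(u_neg @ v_w))  # (k,)
    loss = float(np.log(s_pos) + np.sum(np.log(s_neg)))
    g_pos = 1.0 - s_pos                     # d/dx log sigma(x)
    g_neg = -(1.0 - s_neg)                  # (k,)  d/dv of log sigma(-u.v) terms
    d_vw = g_pos * u_c + u_neg.T @ g_neg
    d_uc = g_pos * v_w
    d_uneg = np.outer(g_neg, v_w)
    return loss, d_vw, d_uc, d_uneg


def train_sgns(corpus: Corpus, params: SgnsParams) -> EmbeddingTable:
    """Train SGNS embeddings by sequential SGD.

    Deterministic given ``params.seed`` (single-worker contract).  Raises
    if the corpus yields no (center, context) pairs or the vocabulary is
    empty after the min_count filter.
    """
    params.validate()
    counts: dict[str, int] = {}
    for sent in corpus.sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filter")
    index = {w: i for i, w in enumerate(vocab)}

    sents = [[index[t] for t in sent if t in index] for sent in corpus.sentences]
    n_pairs = sum(
        len(range(max(0, i - params.window), min(len(s), i + params.window + 1))) - 1
        for s in sents for i in range(len(s))
    )
    if n_pairs == 0:
        raise ValueError("corpus yields no (center, context) pairs")

    rng = np.random.default_rng(params.seed)
    d = params.dim
    V = len(vocab)
    vec_in = (rng.random((V, d)) - 0.5) / d
    vec_out = np.zeros((V, d))

    freq = np.array([counts[w] for w in vocab], dtype=float)
    noise = freq ** params.unigram_exponent
    noise_cdf = np.cumsum(noise / noise.sum())

    total = n_pairs * params.epochs
    done = 0
    k = params.negatives
    for _ in range(params.epochs):
        for sent in sents:
            L = len(sent)
            for i in range(L):
                w = sent[i]
                lo, hi = max(0, i - params.window), min(L, i + params.window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    c = sent[j]
                    lr = params.lr0 + (params.lr_min - params.lr0) * (done / total)
                    done += 1
                    neg = np.searchsorted(noise_cdf, rng.random(k))
                    neg = neg[(neg != c) & (neg != w)]  # word2vec skip rule
                    v_w = vec_in[w]
                    rows = np.concatenate(([c], neg))
                    u = vec_out[rows]                       # (k+1, d)
                    act = u @ v_w
                    sgn = _sigmoid(act)
                    g = np.empty(len(rows))
                    g[0] = 1.0 - sgn[0]
                    g[1:] = -sgn[1:]
                    # ascent on L == descent on -L
                    vec_in[w] = v_w + lr * (g @ u)
                    np.add.at(vec_out, rows, lr * np.outer(g, v_w))
    return EmbeddingTable(vocab=vocab, vectors_in=vec_in, vectors_out=vec_out)


def load_corpus(path: str | Path) -> Corpus:
    with open(path, encoding="utf-8") as fh:
        sentences = [line.split() for line in fh if line.strip()]
    return Corpus(sentences)


def write_embeddings(table: EmbeddingTable, path: str | Path,
                     params: SgnsParams | None = None) -> None:
    """TSV of token + input vector, with a JSON sidecar of parameters."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token\t" + "\t".join(
            f"v_{i + 1}" for i in range(table.dim)) + "\n")
        for tok, vec in zip(table.vocab, table.vectors_in):
            fh.write(tok + "\t" + "\t".join(f"{x:.10g}" for x in vec) + "\n")
    if params is not None:
        path.with_suffix(".json").write_text(
            json.dumps(asdict(params), indent=1), encoding="utf-8")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return EmbeddingTable(
        vocab=list(df.index),
        vectors_in=df.to_numpy(dtype=float),
        vectors_out=np.zeros_like(df.to_numpy(dtype=float)),
    )
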