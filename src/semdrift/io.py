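"""Readers and writers for the pipeline's interchange formats.

Embeddings use the word2vec text format (header "N D", then one
"token v1 ... vD" line per word); context matrices live alongside with a
``.ctx`` suffix.  Diachronic embeddings are stored as a compressed ``.npz``
(positions, window labels, per-step alignment maps) with the vocabulary in
a plain-text sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .alignment import DiachronicEmbedding
from .corpus import Vocabulary
from .embedding import EmbeddingRun


def write_word2vec(path, matrix: np.ndarray, vocab: Vocabulary) -> None:
    matrix = np.asarray(matrix)
    if matrix.shape[0] != len(vocab):
        raise ValueError("matrix rows must match vocabulary size")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for token, row in zip(vocab.lemmas, matrix):
            fh.write(token + " " + " ".join(f"{v:.8g}" for v in row) + "\n")


def read_word2vec(path) -> tuple[np.ndarray, Vocabulary]:
    with open(path, encoding="utf-8") as fh:
        n, d = map(int, fh.readline().split())
        tokens, rows = [], np.empty((n, d))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows[i] = [float(v) for v in parts[1:]]
    return rows, Vocabulary(tuple(tokens))


def write_embedding_run(path, run: EmbeddingRun, vocab: Vocabulary) -> None:
    path = Path(path)
    write_word2vec(path, run.word_vectors, vocab)
    write_word2vec(path.with_suffix(path.suffix + ".ctx"),
                   run.context_vectors, vocab)


def save_diachronic(path, emb: DiachronicEmbedding) -> None:
    path = Path(path)
    arrays = {
        "positions": emb.positions,
        "window_labels": np.asarray(emb.window_labels),
    }
    if emb.maps is not None:
        arrays["maps"] = np.stack(emb.maps)
    np.savez_compressed(path, **arrays)
    if emb.vocabulary is not None:
        Path(str(path) + ".vocab.txt").write_text(
            "\n".join(emb.vocabulary.lemmas) + "\n", encoding="utf-8")


def load_diachronic(path) -> DiachronicEmbedding:
    path = Path(path)
    with np.load(path) as data:
        positions = data["positions"]
        labels = data["window_labels"]
        maps = list(data["maps"]) if "maps" in data else None
    vocab_path = Path(str(path) + ".vocab.txt")
    vocab = None
    if vocab_path.exists():
        vocab = Vocabulary(tuple(
            vocab_path.read_text(encoding="utf-8").split()))
    return DiachronicEmbedding(positions, labels, vocab, maps)
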