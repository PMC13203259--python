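"""Static word-embedding spaces and the ``Embed(.)`` contract.

Every scoring operation in this package works through a single lookup
convention: an in-vocabulary token returns its learned vector, any other
string returns the zero vector of the space's dimension together with an
out-of-vocabulary flag.  Zero vectors carry no direction, so OOV tokens
dilute a text's mean vector toward the neutral point rather than being
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EmbeddingSpace",
    "EmbeddingFormatError",
    "load_embedding_space",
    "save_embedding_space",
    "cosine",
]


class EmbeddingFormatError(ValueError):
    """Raised for malformed word2vec-text files (header, arity, duplicates)."""


@dataclass
class EmbeddingSpace:
    """A vocabulary with one fixed-dimension real vector per token.

    Parameters
    ----------
    tokens : list of str
        Unique token strings; order is meaningful (frequency order in
        corpora trained by the usual tooling) and is preserved.
    vectors : ndarray of shape (n_tokens, d)
        One row per token, d >= 2, all entries finite.
    source_tag : str
        Free-text label for the corpus or period the space came from.
    """

    tokens: list[str]
    vectors: np.ndarray
    source_tag: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.tokens) != self.vectors.shape[0]:
            raise ValueError(
                f"{len(self.tokens)} tokens but {self.vectors.shape[0]} vector rows"
            )
        if self.vectors.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain non-finite entries")
        self._index = {}
        for i, tok in enumerate(self.tokens):
            if tok in self._index:
                raise EmbeddingFormatError(f"duplicate token {tok!r}")
            self._index[tok] = i

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def embed(self, token: str) -> tuple[np.ndarray, bool]:
        """Look up ``token``; total function.

        Returns
        -------
        vector : ndarray of shape (d,)
            The stored row for in-vocabulary tokens, otherwise zeros.
        in_vocab : bool
        """
        i = self._index.get(token)
        if i is None:
            return np.zeros(self.dimension), False
        return self.vectors[i].copy(), True

    def embed_many(self, tokens: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup: (len(tokens), d) matrix and in-vocab mask."""
        out = np.zeros((len(tokens), self.dimension))
        mask = np.zeros(len(tokens), dtype=bool)
        for j, tok in enumerate(tokens):
            i = self._index.get(tok)
            if i is not None:
                out[j] = self.vectors[i]
                mask[j] = True
        return out, mask

    def index_of(self, token: str) -> int:
        return self._index[token]

    def nearest_neighbors(self, token: str, k: int) -> list[str]:
        """The ``k`` in-vocabulary tokens most cosine-similar to ``token``.

        The query itself is excluded; ties are broken by vocabulary order
        so results are deterministic.  Fewer than ``k`` tokens are returned
        when the vocabulary is small.
        """
        if token not in self._index:
            raise KeyError(f"query token {token!r} is out of vocabulary")
        if k < 1:
            raise ValueError("k must be positive")
        qi = self._index[token]
        q = self.vectors[qi]
        qn = np.linalg.norm(q)
        norms = np.linalg.norm(self.vectors, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sims = (self.vectors @ q) / (norms * qn)
        sims = np.where(np.isfinite(sims), sims, -np.inf)
        sims[qi] = -np.inf
        # stable sort on (-sim, vocab index): lexsort's last key is primary
        order = np.lexsort((np.arange(len(sims)), -sims))
        order = [i for i in order if np.isfinite(sims[i])]
        return [self.tokens[i] for i in order[:k]]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; rejects zero-norm input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def load_embedding_space(
    path: str | Path, fmt: str = "word2vec-text", source_tag: str = ""
) -> EmbeddingSpace:
    """Read a word2vec text-format file.

    Dialect: UTF-8; first line ``<count> <dim>``; each following line is a
    whitespace-free token followed by ``dim`` space-separated floats.
    Declared counts must match the parsed content exactly.
    """
    if fmt != "word2vec-text":
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    tokens: list[str] = []
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"malformed header line in {path}")
        try:
            n_decl, d_decl = int(header[0]), int(header[1])
        except ValueError as exc:
            raise EmbeddingFormatError(f"malformed header line in {path}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            tok, vals = parts[0], parts[1:]
            if len(vals) != d_decl:
                raise EmbeddingFormatError(
                    f"line {lineno}: expected {d_decl} values for {tok!r}, "
                    f"got {len(vals)}"
                )
            tokens.append(tok)
            rows.append([float(x) for x in vals])
    if len(tokens) != n_decl:
        raise EmbeddingFormatError(
            f"header declares {n_decl} tokens but file contains {len(tokens)}"
        )
    return EmbeddingSpace(tokens, np.array(rows, dtype=float), source_tag=source_tag)


def save_embedding_space(
    space: EmbeddingSpace, path: str | Path, precision: int = 8
) -> None:
    """Write ``space`` in the word2vec text dialect read by the loader."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(space)} {space.dimension}\n")
        for tok, row in zip(space.tokens, space.vectors):
            vals = " ".join(f"{x:.{precision}g}" for x in row)
            fh.write(f"{tok} {vals}\n")
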