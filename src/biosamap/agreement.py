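"""Inter-annotator agreement statistics.

Two annotators assign, per ontology, one identifier (or none) to each
label of a shared set.  Agreement is quantified two ways:

* **Cohen's kappa** on exact categorical matches,
  ``kappa = (p_o - p_e) / (1 - p_e)``, with ``p_o`` the observed
  agreement proportion and ``p_e`` the agreement expected by chance from
  the two raters' marginal distributions.  "No identifier" is an
  explicit category.
* **Soft agreement**: the fraction of pairs whose textual
  representations (class names of the chosen terms, or the raw labels)
  exceed a cosine-similarity threshold — default 0.9, strictly greater
  — under a pluggable text-embedding contract.

The embedder contract is any callable ``text -> vector``; an optional
``fit(texts)`` hook is called with all texts before embedding, and an
``embedder_id`` attribute is recorded for provenance.  The in-repo
embedders (character-trigram term frequency, exact-match indicator) are
deterministic and need no model download; a sentence-transformer model
can be plugged in through the same contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    p_o: float
    p_e: float
    n: int


@dataclass(frozen=True)
class SoftAgreementResult:
    ratio: float
    threshold: float
    embedder_id: str
    n: int


def cohens_kappa(
    pairs: Sequence[tuple[Hashable, Hashable]]
) -> KappaResult:
    """Chance-corrected agreement between two raters' categories.

    Absent annotations must be passed as an explicit category (e.g.
    ``None``), not dropped.  When both raters use a single identical
    category, chance agreement is 1 and kappa is undefined (``None``).
    """
    if len(pairs) == 0:
        raise ValueError("cohens_kappa requires at least one pair")
    n = len(pairs)
    p_o = sum(1 for a, b in pairs if a == b) / n
    marg_a = Counter(a for a, _ in pairs)
    marg_b = Counter(b for _, b in pairs)
    p_e = sum(
        (marg_a[k] / n) * (marg_b[k] / n) for k in marg_a.keys() & marg_b.keys()
    )
    kappa = None if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, n=n)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dot product over the product of Euclidean norms, in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


class TrigramEmbedder:
    """Character-trigram term-frequency vectors over a fitted vocabulary.

    Deterministic and training-free; texts shorter than three characters
    contribute themselves as a single gram.
    """

    embedder_id = "char-trigram-tf"

    def __init__(self) -> None:
        self._vocab: dict[str, int] = {}

    @staticmethod
    def _grams(text: str) -> list[str]:
        text = text.casefold()
        if len(text) < 3:
            return [text] if text else []
        return [text[i : i + 3] for i in range(len(text) - 2)]

    def fit(self, texts: Sequence[str]) -> "TrigramEmbedder":
        for t in texts:
            for g in self._grams(t):
                self._vocab.setdefault(g, len(self._vocab))
        return self

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(max(len(self._vocab), 1), dtype=float)
        for g in self._grams(text):
            idx = self._vocab.get(g)
            if idx is not None:
                vec[idx] += 1.0
        return vec


class ExactMatchEmbedder:
    """One-hot indicator per distinct string: similarity 1 iff equal."""

    embedder_id = "exact-match-indicator"

    def __init__(self) -> None:
        self._vocab: dict[str, int] = {}

    def fit(self, texts: Sequence[str]) -> "ExactMatchEmbedder":
        for t in texts:
            self._vocab.setdefault(t, len(self._vocab))
        return self

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(max(len(self._vocab), 1), dtype=float)
        idx = self._vocab.get(text)
        if idx is None:
            # unseen text gets its own implicit direction; grow lazily
            self._vocab[text] = len(self._vocab)
            vec = np.zeros(len(self._vocab), dtype=float)
            idx = self._vocab[text]
        vec[idx] = 1.0
        return vec


def soft_agreement(
    name_pairs: Sequence[tuple[Optional[str], Optional[str]]],
    embedder,
    threshold: float = 0.9,
) -> SoftAgreementResult:
    """Fraction of text pairs with cosine similarity strictly above *threshold*.

    Pairs where both texts are absent are skipped; one-sided absence
    counts as a non-match in the denominator.
    """
    scorable = [
        (a, b) for a, b in name_pairs if not (a is None and b is None)
    ]
    if not scorable:
        raise ValueError("soft_agreement requires at least one scorable pair")
    texts = [t for pair in scorable for t in pair if t is not None]
    if hasattr(embedder, "fit"):
        embedder.fit(texts)
    cache: dict[str, np.ndarray] = {}

    def embed(text: str) -> np.ndarray:
        if text not in cache:
            cache[text] = np.asarray(embedder(text), dtype=float)
        return cache[text]

    hits = 0
    for a, b in scorable:
        if a is None or b is None:
            continue
        va, vb = embed(a), embed(b)
        if va.shape != vb.shape:  # lazily grown vocab; re-embed
            cache.clear()
            va, vb = embed(a), embed(b)
        if np.linalg.norm(va) == 0.0 or np.linalg.norm(vb) == 0.0:
            continue
        if cosine_similarity(va, vb) > threshold:
            hits += 1
    return SoftAgreementResult(
        ratio=hits / len(scorable),
        threshold=threshold,
        embedder_id=getattr(embedder, "embedder_id", repr(embedder)),
        n=len(scorable),
    )
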