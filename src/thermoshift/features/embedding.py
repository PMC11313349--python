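"""Embedding context features around the mutation site.

A context window of configurable length (25, 50, 100, 200, 500 or the
full sequence) is cut around the mutation site; the wild-type and
mutant subsequences are run through a pluggable per-residue embedder
backend; the resulting position x embedding-dimension matrices are
pooled to fixed-length vectors and combined (concatenated or
differenced) into feature columns.

Backends implement a minimal contract — ``name``,
``embedding_length`` and ``embed(sequence) -> ndarray`` of shape
(positions, embedding_length) — so protein language models can plug in
without the library depending on their weights.  The bundled
:class:`MockEmbedder` is a deterministic per-residue lookup: each
residue maps to a fixed pseudo-random vector, so it is context-free by
construction and usable in any test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from ..core import (
    CANONICAL_AA,
    Mutation,
    MutationRecord,
    ProteinRecord,
    ThermoshiftError,
    apply_mutation,
    bind_and_validate,
)
from .table import FeatureTable

#: Supported context lengths; ``"full"`` embeds the whole sequence.
CONTEXT_LENGTHS = (25, 50, 100, 200, 500, "full")


class WindowTooShortError(ThermoshiftError):
    """Protein shorter than the requested context length (excluded)."""


@runtime_checkable
class EmbedderBackend(Protocol):
    """Contract for per-residue embedders (mock or real PLMs)."""

    name: str
    embedding_length: int

    def embed(self, sequence: str) -> np.ndarray:  # (positions, embedding_length)
        ...


class MockEmbedder:
    """Deterministic per-residue lookup embedder.

    Each canonical residue maps to a fixed vector drawn once from a
    seeded generator; ``embed`` stacks the per-residue rows.  Being a
    pure lookup it is context-free: row *i* depends only on
    ``sequence[i]``.
    """

    def __init__(self, seed: int = 0, embedding_length: int = 32) -> None:
        if embedding_length < 1:
            raise ValueError("embedding_length must be positive")
        self.name = f"mock-{seed}-{embedding_length}"
        self.embedding_length = embedding_length
        rng = np.random.default_rng(seed)
        table = rng.standard_normal((len(CANONICAL_AA), embedding_length))
        self._rows = {res: table[i] for i, res in enumerate(CANONICAL_AA)}

    def embed(self, sequence: str) -> np.ndarray:
        return np.stack([self._rows[res] for res in sequence])


@dataclass(frozen=True)
class ContextWindow:
    """1-based inclusive subsequence bounds containing the mutation site."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self, sequence: str) -> str:
        return sequence[self.start - 1 : self.end]

    def offset(self, position: int) -> int:
        """0-based offset of a 1-based sequence position in the window."""
        return position - self.start


def extract_context(
    protein: ProteinRecord, mutation: Mutation, context_length: int | str
) -> ContextWindow:
    """Window of ``context_length`` residues centered on the mutation.

    Near a terminus the window is shifted toward the interior (never
    padded) so it keeps its full length; proteins shorter than the
    requested length are excluded (``WindowTooShortError``).
    ``"full"`` returns the whole sequence.
    """
    bind_and_validate(protein, mutation)
    n = len(protein)
    if context_length == "full":
        return ContextWindow(1, n)
    length = int(context_length)
    if length < 1:
        raise ValueError(f"context length must be positive, got {length}")
    if n < length:
        raise WindowTooShortError(
            f"{protein.id}: length {n} < context length {length} (too_short)"
        )
    start = mutation.position - (length - 1) // 2
    start = min(max(start, 1), n - length + 1)
    return ContextWindow(start, start + length - 1)


def pool_embedding(matrix: np.ndarray, mode: str = "per_position") -> np.ndarray:
    """Pool a (positions, embedding_length) matrix to a vector.

    ``per_position`` averages over the embedding dimension, giving one
    value per window position (vector of length = context length);
    ``per_dimension`` averages over positions, giving one value per
    embedding dimension — the natural choice for full-length windows,
    whose position count varies between proteins.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError(f"expected nonempty 2-D matrix, got shape {matrix.shape}")
    if mode == "per_position":
        return matrix.mean(axis=1)
    if mode == "per_dimension":
        return matrix.mean(axis=0)
    raise ValueError(f"unknown pooling mode {mode!r}")


def embedding_features(
    protein: ProteinRecord,
    mutation: Mutation,
    backend: EmbedderBackend,
    context_length: int | str = 200,
    combine: str = "concat",
    pooling: str | None = None,
) -> dict[str, float]:
    """Pooled embedding columns for one record.

    The wild-type and mutant context subsequences (identical window
    coordinates) are embedded and pooled identically, then combined:
    ``concat`` emits both vectors (2k columns), ``diff`` the
    mutant-minus-wild difference (k columns).  Pooling defaults to
    ``per_position`` for fixed windows and ``per_dimension`` for
    ``"full"`` windows.
    """
    if combine not in ("concat", "diff"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if pooling is None:
        pooling = "per_dimension" if context_length == "full" else "per_position"
    window = extract_context(protein, mutation, context_length)
    wild_sub = window.slice(protein.sequence)
    mut_sub = window.slice(apply_mutation(protein, mutation))
    wild_vec = pool_embedding(backend.embed(wild_sub), pooling)
    mut_vec = pool_embedding(backend.embed(mut_sub), pooling)
    tag = f"emb_{context_length}"
    if combine == "diff":
        return {
            f"{tag}_diff_{i:04d}": float(v) for i, v in enumerate(mut_vec - wild_vec)
        }
    out = {f"{tag}_wt_{i:04d}": float(v) for i, v in enumerate(wild_vec)}
    out.update({f"{tag}_mut_{i:04d}": float(v) for i, v in enumerate(mut_vec)})
    return out


def extract_embedding(
    proteins: dict[str, ProteinRecord],
    records: Sequence[MutationRecord],
    backend: EmbedderBackend,
    context_length: int | str = 200,
    combine: str = "concat",
    pooling: str | None = None,
) -> tuple[FeatureTable, dict[str, int]]:
    """Embedding columns for a record list; short proteins drop with
    reason ``too_short``."""
    rows: dict[str, dict[str, float]] = {}
    drops: dict[str, int] = {}
    for record in records:
        protein = proteins.get(record.protein_id)
        if protein is None:
            drops["no_sequence"] = drops.get("no_sequence", 0) + 1
            continue
        try:
            cols = embedding_features(
                protein, record.mutation, backend, context_length, combine, pooling
            )
        except WindowTooShortError:
            drops["too_short"] = drops.get("too_short", 0) + 1
            continue
        except ThermoshiftError:
            drops["sequence_mismatch"] = drops.get("sequence_mismatch", 0) + 1
            continue
        if record.record_id not in rows:
            rows[record.record_id] = cols
    prov = {
        c: {
            "extractor": "embedding",
            "backend": backend.name,
            "context_length": context_length,
            "pooling": pooling
            or ("per_dimension" if context_length == "full" else "per_position"),
            "combine": combine,
        }
        for r in rows.values()
        for c in r
    }
    return FeatureTable.from_rows(rows, prov), drops
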