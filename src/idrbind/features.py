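"""Per-residue model inputs: embeddings, the disorder channel, and AAindex.

The classifier consumes one feature vector per residue.  For the
embedding-based models this is an ``L x m`` matrix from a protein language
model (m = 1024 for ProtT5, 1280 for ESM-2) expanded by one binary column
indicating whether the residue lies inside a disordered region; the
disorder indicator is always the LAST column (index m), which fixes its
ablation index.  A classical-feature baseline replaces the embedding by
the 566 AAindex1 amino-acid property scales, z-scored per index across
the 20 standard letters so that their magnitudes are comparable with
embedding activations.

Embedders are pluggable: anything with ``embed(sequence) -> L x m array``
works.  Running the actual pLMs is out of scope here — the
:class:`ExternalEmbedder` adapter raises a configuration error until it is
wired to an external service, and tests use the synthetic embedder from
:mod:`idrbind.synthetic`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EMBEDDING_DIMS",
    "AAINDEX1_COUNT",
    "EmbedderNotConfiguredError",
    "Embedder",
    "ExternalEmbedder",
    "assemble_features",
    "split_features",
    "AAIndexTable",
    "parse_aaindex",
    "aaindex_features",
]

#: Embedding widths of the supported protein language models.
EMBEDDING_DIMS = {"prott5": 1024, "esm2": 1280}

#: Number of property scales in the full AAindex1 release.
AAINDEX1_COUNT = 566

#: AAindex1 value order: first data line, then second data line.
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


class EmbedderNotConfiguredError(RuntimeError):
    """An external embedding backend was requested but is not wired up."""


@runtime_checkable
class Embedder(Protocol):
    def embed(self, sequence: str) -> np.ndarray: ...


class ExternalEmbedder:
    """Adapter stub for an external pLM embedding backend.

    The real models (ProtT5/ESM-2) are not bundled; calling ``embed``
    without configuring a backend raises a clear configuration error
    instead of crashing downstream.
    """

    def __init__(self, name: str = "prott5", backend=None):
        if name not in EMBEDDING_DIMS:
            raise ValueError(f"unknown embedder {name!r}")
        self.name = name
        self.dim = EMBEDDING_DIMS[name]
        self._backend = backend

    def embed(self, sequence: str) -> np.ndarray:
        if self._backend is None:
            raise EmbedderNotConfiguredError(
                f"external embedder {self.name!r} not configured; provide a "
                "backend callable or use the synthetic embedder"
            )
        out = np.asarray(self._backend(sequence), dtype=np.float32)
        if out.shape != (len(sequence), self.dim):
            raise ValueError(
                f"backend returned shape {out.shape}, "
                f"expected ({len(sequence)}, {self.dim})"
            )
        return out


def assemble_features(embedding, disorder_mask) -> np.ndarray:
    """Append the binary disorder channel to an ``L x m`` embedding.

    Output is ``L x (m+1)``; columns ``0..m-1`` are the embedding verbatim
    and column ``m`` is the disorder indicator.  The mask may come from
    curated annotation or from a (binarized) disorder predictor — the
    assembly is identical.
    """
    emb = np.asarray(embedding)
    mask = np.asarray(disorder_mask)
    if emb.ndim != 2:
        raise ValueError("embedding must be 2-D")
    if mask.ndim != 1 or len(mask) != emb.shape[0]:
        raise ValueError(
            f"disorder mask length {mask.shape} does not match "
            f"embedding rows {emb.shape[0]}"
        )
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("disorder mask must be binary")
    return np.concatenate([emb, mask[:, None].astype(emb.dtype)], axis=1)


def split_features(features) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`assemble_features`: recover (embedding, mask)."""
    feat = np.asarray(features)
    return feat[:, :-1], feat[:, -1].astype(np.uint8)


@dataclasses.dataclass
class AAIndexTable:
    """AAindex1 property scales with per-index z-score statistics.

    ``values[letter]`` is the raw property vector of one amino acid
    (``NA`` entries imputed with the per-index mean over present letters);
    ``mean``/``std`` are per-index statistics over the 20 standard letters
    used for z-scoring.
    """

    accessions: list[str]
    values: dict[str, np.ndarray]
    mean: np.ndarray
    std: np.ndarray

    @property
    def n_indices(self) -> int:
        return len(self.accessions)

    def row(self, letter: str) -> np.ndarray:
        """Z-scored property vector; unknown residues (X) map to zeros."""
        if letter not in self.values:
            return np.zeros(self.n_indices)
        std = np.where(self.std > 0, self.std, 1.0)
        return (self.values[letter] - self.mean) / std


def parse_aaindex(path, expected_count: int | None = None) -> AAIndexTable:
    """Parse the AAindex1 flat file.

    Entries start with an ``H <accession>`` line; the ``I`` line is
    followed by two rows of ten values (A R N D C Q E G H I, then
    L K M F P S T W Y V); ``//`` terminates an entry.  ``NA`` values are
    imputed with the per-index mean over the present letters.  Pass
    ``expected_count=566`` to enforce the full release; the default leaves
    the count unchecked so reduced fixture tables parse too.
    """
    accessions: list[str] = []
    columns: list[list[float]] = []  # one list of 20 values per index
    accession = None
    lines = iter(Path(path).read_text().splitlines())
    for line in lines:
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I "):
            if accession is None:
                raise ValueError("AAindex entry with I line before H line")
            try:
                row1 = next(lines).split()
                row2 = next(lines).split()
            except StopIteration:
                raise ValueError(f"{accession}: truncated value rows") from None
            vals = row1 + row2
            if len(vals) != 20:
                raise ValueError(
                    f"{accession}: expected 20 values, got {len(vals)}"
                )
            parsed = [float("nan") if v == "NA" else float(v) for v in vals]
            finite = [v for v in parsed if v == v]
            if not finite:
                raise ValueError(f"{accession}: all values NA")
            fill = sum(finite) / len(finite)
            parsed = [fill if v != v else v for v in parsed]
            accessions.append(accession)
            columns.append(parsed)
            accession = None
    if expected_count is not None and len(accessions) != expected_count:
        raise ValueError(
            f"expected {expected_count} AAindex entries, found {len(accessions)}"
        )
    if not accessions:
        raise ValueError("no AAindex entries found")
    matrix = np.asarray(columns, dtype=float).T  # 20 letters x n_indices
    values = {letter: matrix[i].copy() for i, letter in enumerate(_AAINDEX_ORDER)}
    return AAIndexTable(
        accessions=accessions,
        values=values,
        mean=matrix.mean(axis=0),
        std=matrix.std(axis=0),
    )


def aaindex_features(sequence: str, table: AAIndexTable) -> np.ndarray:
    """Per-residue z-scored AAindex property matrix (``L x n_indices``)."""
    return np.stack([table.row(letter) for letter in sequence.upper()])
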