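"""Protein records with per-residue disorder and binding annotations.

The unit of curation is a :class:`ProteinRecord`: a sequence over the 20
standard amino acids (plus ``X`` for unknowns) together with two aligned
binary masks — which residues fall inside an intrinsically disordered
region (IDPR), and which of those bind a ligand.  Curated data guarantees
that binding annotations exist only inside disordered regions; that
invariant is enforced at construction and therefore at read time.

On-disk formats handled here:

* an annotated-FASTA dialect (4 lines per protein: ``>id``, sequence,
  disorder mask, binding mask) used for datasets,
* the CAID per-residue prediction format (``pos\\tresidue\\tscore\\tlabel``,
  1-based positions) used to exchange predictions with benchmarks,
* an HDF5 embedding store keyed by protein id (one ``L x m`` float32
  dataset each).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "FormatError",
    "Region",
    "ProteinRecord",
    "read_annotated_fasta",
    "write_annotated_fasta",
    "filter_max_length",
    "protein_class",
    "store_embeddings",
    "load_embeddings",
    "list_embeddings",
    "write_caid_predictions",
    "read_caid_predictions",
]

#: Residue alphabet accepted after normalisation.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

#: Non-standard one-letter codes mapped to X (no embedder / AAindex entry).
_NONSTANDARD = str.maketrans({c: "X" for c in "BZUOJ"})

#: Length filter default — proteins with over 10k residues are dropped.
MAX_PROTEIN_LENGTH = 10_000


class FormatError(ValueError):
    """Raised for malformed or invariant-violating on-disk records."""


@dataclasses.dataclass(frozen=True, order=True)
class Region:
    """Half-open residue interval ``[start, end)`` in 0-based coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _as_mask(values, name: str, record_id: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.uint8)
    if arr.ndim != 1:
        raise FormatError(f"{record_id}: {name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise FormatError(f"{record_id}: {name} contains values other than 0/1")
    return arr


@dataclasses.dataclass
class ProteinRecord:
    """A protein sequence with aligned per-residue disorder/binding masks.

    Invariants (checked at construction):

    * sequence, disorder mask and binding mask have equal length ``L >= 1``;
    * binding implies disorder — ligand-binding labels exist only inside
      annotated IDPRs;
    * the sequence uses the 20 standard letters plus ``X``; the rare codes
      B, Z, U, O, J are mapped to ``X`` with a warning.
    """

    id: str
    sequence: str
    disorder_mask: np.ndarray
    binding_mask: np.ndarray

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if any(c in "BZUOJ" for c in seq):
            warnings.warn(
                f"{self.id}: non-standard residues mapped to X", stacklevel=3
            )
            seq = seq.translate(_NONSTANDARD)
        self.sequence = seq
        if len(seq) < 1:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise FormatError(f"{self.id}: illegal residue letters {sorted(bad)}")
        self.disorder_mask = _as_mask(self.disorder_mask, "disorder mask", self.id)
        self.binding_mask = _as_mask(self.binding_mask, "binding mask", self.id)
        if not (len(seq) == len(self.disorder_mask) == len(self.binding_mask)):
            raise FormatError(
                f"{self.id}: sequence ({len(seq)}), disorder mask "
                f"({len(self.disorder_mask)}) and binding mask "
                f"({len(self.binding_mask)}) lengths differ"
            )
        if np.any(self.binding_mask > self.disorder_mask):
            pos = int(np.argmax(self.binding_mask > self.disorder_mask))
            raise FormatError(
                f"{self.id}: binding annotation outside a disordered region "
                f"at residue {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and np.array_equal(self.disorder_mask, other.disorder_mask)
            and np.array_equal(self.binding_mask, other.binding_mask)
        )

    @property
    def n_disordered(self) -> int:
        return int(self.disorder_mask.sum())

    @property
    def n_binding(self) -> int:
        return int(self.binding_mask.sum())


# ---------------------------------------------------------------------------
# Annotated FASTA (4-line blocks)
# ---------------------------------------------------------------------------

def read_annotated_fasta(path) -> list[ProteinRecord]:
    """Read the 4-line-block annotated-FASTA dialect.

    Each protein occupies four lines: ``>id``, sequence, disorder mask
    string, binding mask string.  Order is preserved; every record is
    validated (equal lengths, masks over '0'/'1', binding inside disorder).
    """
    lines = Path(path).read_text().splitlines()
    lines = [ln.strip() for ln in lines if ln.strip()]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated block (got {len(lines)} lines)")
    records: list[ProteinRecord] = []
    for i in range(0, len(lines), 4):
        header, seq, dis, bind = lines[i : i + 4]
        lineno = i + 1
        if not header.startswith(">"):
            raise FormatError(f"{path}:{lineno}: expected '>' header, got {header!r}")
        rid = header[1:].split()[0]
        for name, mask in (("disorder", dis), ("binding", bind)):
            if set(mask) - {"0", "1"}:
                raise FormatError(
                    f"{path}:{lineno}: {rid}: {name} mask has characters "
                    f"other than 0/1"
                )
        try:
            records.append(
                ProteinRecord(
                    id=rid,
                    sequence=seq,
                    disorder_mask=np.frombuffer(dis.encode(), dtype=np.uint8) - ord("0"),
                    binding_mask=np.frombuffer(bind.encode(), dtype=np.uint8) - ord("0"),
                )
            )
        except FormatError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from None
    return records


def write_annotated_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records in the 4-line-block dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            fh.write("".join(map(str, rec.disorder_mask.tolist())) + "\n")
            fh.write("".join(map(str, rec.binding_mask.tolist())) + "\n")


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def filter_max_length(
    records: Sequence[ProteinRecord], max_len: int = MAX_PROTEIN_LENGTH
) -> list[ProteinRecord]:
    """Drop proteins longer than ``max_len`` residues (default 10,000).

    Mirrors the curation step that excludes extreme outliers such as titin
    (34,350 residues); a protein of exactly ``max_len`` residues is kept.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    return [r for r in records if len(r) <= max_len]


def protein_class(record: ProteinRecord) -> str:
    """Classify a protein: ``"positive"`` iff it has any binding residue."""
    return "positive" if record.n_binding > 0 else "negative"


# ---------------------------------------------------------------------------
# Embedding store (HDF5, one float32 dataset per protein id)
# ---------------------------------------------------------------------------

def store_embeddings(path, protein_id: str, matrix, *, force: bool = False) -> None:
    """Store one ``L x m`` float32 matrix under ``protein_id``.

    Refuses to overwrite an existing id unless ``force=True``.  Round-trips
    are bit-exact for float32 input.
    """
    arr = np.asarray(matrix, dtype=np.float32)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{protein_id}: embedding must be a non-empty 2-D matrix")
    if not np.isfinite(arr).all():
        raise ValueError(f"{protein_id}: embedding contains non-finite values")
    with h5py.File(path, "a") as fh:
        if protein_id in fh:
            if not force:
                raise ValueError(
                    f"{protein_id}: already present in store (use force=True)"
                )
            del fh[protein_id]
        # track_times=False keeps files byte-identical across reruns
        fh.create_dataset(protein_id, data=arr, track_times=False)


def load_embeddings(path, protein_id: str) -> np.ndarray:
    """Load the matrix stored under ``protein_id``; KeyError if absent."""
    with h5py.File(path, "r") as fh:
        if protein_id not in fh:
            raise KeyError(f"{protein_id}: not in embedding store {path}")
        return np.asarray(fh[protein_id], dtype=np.float32)


def list_embeddings(path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return sorted(fh.keys())


# ---------------------------------------------------------------------------
# CAID per-residue prediction format
# ---------------------------------------------------------------------------

def write_caid_predictions(
    records: Iterable[ProteinRecord],
    scores: Mapping[str, Sequence[float]],
    labels: Mapping[str, Sequence[int]],
    path,
) -> None:
    """Write per-residue predictions in the CAID dialect.

    One ``>id`` header per protein followed by one line per residue:
    ``position<TAB>residue<TAB>score<TAB>label`` with 1-based positions and
    scores rendered with 3 decimals.
    """
    with open(path, "w") as fh:
        for rec in records:
            sc = np.asarray(scores[rec.id], dtype=float)
            lb = np.asarray(labels[rec.id], dtype=int)
            if len(sc) != len(rec) or len(lb) != len(rec):
                raise FormatError(
                    f"{rec.id}: predictions ({len(sc)} scores, {len(lb)} labels)"
                    f" do not match sequence length {len(rec)}"
                )
            fh.write(f">{rec.id}\n")
            for i, (aa, s, l) in enumerate(zip(rec.sequence, sc, lb)):
                fh.write(f"{i + 1}\t{aa}\t{s:.3f}\t{int(l)}\n")


def read_caid_predictions(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a CAID per-residue file; returns ``id -> (scores, labels)``."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    current: str | None = None
    scores: list[float] = []
    labels: list[int] = []

    def _flush() -> None:
        if current is not None:
            out[current] = (
                np.asarray(scores, dtype=float),
                np.asarray(labels, dtype=np.uint8),
            )

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            current = line[1:].split()[0]
            scores, labels = [], []
            continue
        parts = line.split("\t")
        if current is None or len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: malformed prediction line")
        pos = int(parts[0])
        if pos != len(scores) + 1:
            raise FormatError(
                f"{path}:{lineno}: {current}: positions not consecutive 1-based"
            )
        scores.append(float(parts[2]))
        labels.append(int(parts[3]))
    _flush()
    return out
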