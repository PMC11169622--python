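"""Pairwise-alignment redundancy reduction with the HSSP-value (HVAL).

Dataset splits for sequence-based predictors leak information whenever a
training protein is a close homolog of a test protein.  The classic guard
is the HSSP distance: a pair aligned over ``L`` columns is considered
redundant when its percent pairwise sequence identity (PIDE) exceeds a
length-dependent threshold curve ``p(L)``; the HVAL of a pair is
``PIDE - p(L)`` and ``HVAL <= 0`` marks the pair non-redundant.  At
alignment length 250 the curve sits just above 20%, i.e. pairs under 20%
identity over 250 aligned residues pass.

Alignments come from an affine-gap local (Smith-Waterman) aligner with
BLOSUM62 scoring, gap open 11 / extend 1 (a gap of length g costs
``11 + (g-1)``), and a minimum alignment length of 11 columns below which
pairs are flagged and treated as non-redundant.

Set reduction uses greedy hub removal: repeatedly drop the sequence with
the most redundant partners until no violating pair remains.  Ties are
broken by retaining the longer sequence, then by lexicographic id, making
the procedure deterministic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Literal, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord

__all__ = [
    "AlignmentParams",
    "AlignmentStats",
    "align_pair",
    "hssp_threshold",
    "hval",
    "is_redundant_pair",
    "reduce_within",
    "reduce_against",
    "ReductionResult",
    "write_removal_report",
]


@dataclasses.dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the internal local aligner."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of the first residue of a gap
    gap_extend: float = 1.0  # cost of each further gap residue
    min_ali_length: int = 11  # shorter alignments are flagged below-minimum


DEFAULT_PARAMS = AlignmentParams()


@dataclasses.dataclass(frozen=True)
class AlignmentStats:
    """Summary of the optimal local alignment of one sequence pair.

    ``pide`` is the percentage of identical aligned pairs relative to the
    alignment length ``ali_length`` (columns including gaps).  Pairs whose
    alignment is shorter than the configured minimum, or that have no
    positively scoring local match at all, carry ``below_min=True`` and are
    treated as non-redundant downstream.
    """

    pide: float
    ali_length: int
    raw_score: float
    below_min: bool = False


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> AlignmentStats:
    """Optimal local alignment statistics for a sequence pair.

    Returns PIDE over the alignment length (gap columns included in the
    denominator), the alignment length, and the raw score.  A pair with no
    positively scoring local match, or whose alignment spans fewer than
    ``params.min_ali_length`` columns, is flagged ``below_min``.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return AlignmentStats(pide=0.0, ali_length=0, raw_score=float(score),
                              below_min=True)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    ali_length = counts.identities + counts.mismatches + counts.gaps
    pide = 100.0 * counts.identities / ali_length
    return AlignmentStats(
        pide=float(pide),
        ali_length=int(ali_length),
        raw_score=float(score),
        below_min=ali_length < params.min_ali_length,
    )


def hssp_threshold(ali_length: int) -> float:
    """HSSP twilight-zone identity threshold ``p(L)`` in percent.

    ``p(L) = 480 * L^(-0.32 * (1 + exp(-L/1000)))`` for ``L <= 450``;
    constant ``p(450)`` beyond; clamped to [0, 100].  Strictly decreasing
    on [1, 450]: short alignments demand far higher identity before a pair
    counts as homologous.
    """
    if ali_length < 1:
        raise ValueError("alignment length must be >= 1")
    L = min(ali_length, 450)
    p = 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))
    return min(max(p, 0.0), 100.0)


def hval(stats: AlignmentStats) -> float:
    """HSSP-value of a pair: ``PIDE - p(ali_length)``.

    ``hval <= 0`` marks the pair non-redundant at the standard cutoff.
    Below-minimum pairs have no defined HVAL; callers must consult the
    ``below_min`` flag (such pairs are non-redundant by construction).
    """
    if stats.below_min:
        raise ValueError("HVAL undefined for a below-minimum-length alignment")
    return stats.pide - hssp_threshold(stats.ali_length)


Criterion = Literal["hval", "pide"]


def is_redundant_pair(
    stats: AlignmentStats, criterion: Criterion = "hval", cutoff: float = 0.0
) -> bool:
    """Whether a pair violates the non-redundancy criterion.

    ``criterion="hval"``: redundant iff ``hval > cutoff`` (default 0).
    ``criterion="pide"``: redundant iff ``pide >= cutoff`` (CD-HIT-style
    "below x% identity" clustering, cutoff in percent).
    """
    if stats.below_min:
        return False
    if criterion == "hval":
        return hval(stats) > cutoff
    if criterion == "pide":
        return stats.pide >= cutoff
    raise ValueError(f"unknown criterion {criterion!r}")


class ReductionResult(NamedTuple):
    retained: list[ProteinRecord]
    removed: list[tuple[str, str]]  # (removed id, partner that triggered removal)


def _pair_cache(
    records: Sequence[ProteinRecord], params: AlignmentParams
) -> Callable[[str, str, str, str], AlignmentStats]:
    cache: dict[tuple[str, str], AlignmentStats] = {}

    def get(id_a: str, seq_a: str, id_b: str, seq_b: str) -> AlignmentStats:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        if key not in cache:
            cache[key] = align_pair(seq_a, seq_b, params)
        return cache[key]

    return get


def reduce_within(
    records: Sequence[ProteinRecord],
    criterion: Criterion = "hval",
    cutoff: float = 0.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ReductionResult:
    """Greedy hub-removal redundancy reduction within one record set.

    Builds the graph of redundant pairs and repeatedly removes the record
    with the most redundant partners (ties: shorter sequence removed, then
    lexicographically larger id) until no violating pair remains.  Output
    order follows input order; the procedure is deterministic and
    idempotent.
    """
    get = _pair_cache(records, params)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    by_id = {r.id: r for r in records}
    adj: dict[str, set[str]] = {r.id: set() for r in records}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            stats = get(a.id, a.sequence, b.id, b.sequence)
            if is_redundant_pair(stats, criterion, cutoff):
                adj[a.id].add(b.id)
                adj[b.id].add(a.id)

    removed: list[tuple[str, str]] = []
    while adj:
        worst = max(
            adj,
            key=lambda rid: (len(adj[rid]), -len(by_id[rid].sequence), rid),
        )
        if not adj[worst]:
            break
        partner = min(adj[worst])
        removed.append((worst, partner))
        for other in adj.pop(worst):
            adj[other].discard(worst)
    retained = [r for r in records if r.id in adj]
    return ReductionResult(retained, removed)


def reduce_against(
    records: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord],
    criterion: Criterion = "hval",
    cutoff: float = 0.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ReductionResult:
    """Remove every record redundant to any reference record.

    The reference set is left untouched; with an empty reference this is
    the identity.
    """
    retained: list[ProteinRecord] = []
    removed: list[tuple[str, str]] = []
    for rec in records:
        hit = None
        for ref in reference:
            stats = align_pair(rec.sequence, ref.sequence, params)
            if is_redundant_pair(stats, criterion, cutoff):
                hit = ref.id
                break
        if hit is None:
            retained.append(rec)
        else:
            removed.append((rec.id, hit))
    return ReductionResult(retained, removed)


def write_removal_report(removed: Sequence[tuple[str, str]], path) -> None:
    """TSV report of removed ids with the partner that triggered removal."""
    with open(path, "w") as fh:
        fh.write("removed_id\tredundant_partner\n")
        for rid, partner in removed:
            fh.write(f"{rid}\t{partner}\n")
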