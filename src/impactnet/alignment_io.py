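"""Reading, validating, filtering, truncating and joining protein alignments.

An :class:`Alignment` is the entry point of every analysis: an equal-length
set of aligned amino-acid sequences with a designated reference sequence.
All downstream position labels are 1-based coordinates in the ungapped
reference, fixed at truncation time, so that results can be read directly
against the reference protein's residue numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

from Bio import AlignIO, SeqIO

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: legal symbols after normalisation: the 20 amino acids, gap, and unknown
ALPHABET = frozenset(AMINO_ACIDS) | {GAP, "X"}


class AlignmentError(ValueError):
    """Base class for alignment-level input problems."""


class AlignmentShapeError(AlignmentError):
    """Sequences of unequal length, or incompatible matrix shapes."""


class AlphabetError(AlignmentError):
    """A residue outside the amino-acid alphabet."""


class EmptyAlignmentError(AlignmentError):
    """No sequences (or no columns) left to analyse."""


class JoinError(AlignmentError):
    """Two alignments share no sequence identifiers."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in file order.
    seqs
        Upper-case residue strings, one per identifier, all the same length,
        over the 20 amino-acid letters plus ``-`` (gap) and ``X`` (unknown).
    reference_id
        Identifier of the reference sequence; optional until truncation.
    column_labels
        1-based position labels. After :func:`truncate_to_reference` these
        are positions in the ungapped reference sequence.
    column_tags
        Optional per-column protein tag (``"A"``/``"B"``) set by
        :func:`join_alignments`; ``None`` for a single-protein alignment.
    boundary
        For joined alignments, the number of columns contributed by the
        first protein; ``None`` otherwise.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    reference_id: Optional[str] = None
    column_labels: tuple[int, ...] = ()
    column_tags: Optional[tuple[str, ...]] = None
    boundary: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentShapeError(
                        f"sequence {sid!r} has length {len(s)}, expected {L}"
                    )
        if self.column_labels and self.seqs and len(self.column_labels) != self.n_columns:
            raise AlignmentShapeError("column_labels length does not match columns")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def labels(self) -> list[str]:
        """Human-readable column labels (``"12"`` or ``"A12"``/``"B3"``)."""
        if self.column_tags is None:
            return [str(p) for p in self.column_labels]
        return [f"{t}{p}" for t, p in zip(self.column_tags, self.column_labels)]


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def _validate_alphabet(sid: str, seq: str) -> None:
    for col, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"illegal character {ch!r} in sequence {sid!r} at column {col}"
            )


def read_alignment(
    path: str | Path, format: str = "fasta", reference_id: Optional[str] = None
) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Residues are upper-cased and ``.`` gaps normalised to ``-``; column
    labels are initialised ``1..L``. Raises :class:`AlignmentShapeError`
    for ragged inputs, :class:`EmptyAlignmentError` for an empty file and
    :class:`AlphabetError` for symbols outside the amino-acid alphabet.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    # AlignIO insists on equal lengths up front; parse records ourselves for
    # FASTA so ragged input gives our shape error rather than a parser error.
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        records = list(AlignIO.read(str(path), "stockholm")) if path.stat().st_size else []
    if not records:
        raise EmptyAlignmentError(f"no sequences found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalize(str(r.seq)) for r in records)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"sequences have unequal lengths {sorted(lengths)} in {path}"
        )
    for sid, s in zip(ids, seqs):
        _validate_alphabet(sid, s)
    L = lengths.pop()
    return Alignment(
        ids=ids,
        seqs=seqs,
        reference_id=reference_id,
        column_labels=tuple(range(1, L + 1)),
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment back to aligned FASTA (provenance output)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def truncate_to_reference(aln: Alignment, reference_id: str) -> Alignment:
    """Keep exactly the columns where the reference has a non-gap residue.

    Column labels become 1..(ungapped reference length); the reference row
    contains no gaps afterwards. Idempotent.
    """
    ref = aln.sequence(reference_id)  # raises KeyError if absent
    keep = [c for c, ch in enumerate(ref) if ch != GAP]
    if not keep:
        raise EmptyAlignmentError(
            f"reference {reference_id!r} is all gaps; nothing to keep"
        )
    seqs = tuple("".join(s[c] for c in keep) for s in aln.seqs)
    return Alignment(
        ids=aln.ids,
        seqs=seqs,
        reference_id=reference_id,
        column_labels=tuple(range(1, len(keep) + 1)),
        column_tags=None,
        boundary=None,
    )


def gap_fraction(seq: str) -> float:
    return seq.count(GAP) / len(seq) if seq else 0.0


def filter_gappy_sequences(
    aln: Alignment, max_gap_fraction: float = 0.20
) -> tuple[Alignment, int]:
    """Drop sequences whose gap fraction strictly exceeds the threshold.

    The default removes sequences with more than 20% gaps. The reference
    sequence is never removed (a warning is emitted if it exceeds the
    threshold). Returns the filtered alignment and the number removed.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be within [0, 1]")
    keep_ids, keep_seqs = [], []
    removed = 0
    for sid, seq in zip(aln.ids, aln.seqs):
        gappy = gap_fraction(seq) > max_gap_fraction
        if gappy and sid == aln.reference_id:
            warnings.warn(
                f"reference {sid!r} exceeds the gap threshold but is retained"
            )
            gappy = False
        if gappy:
            removed += 1
        else:
            keep_ids.append(sid)
            keep_seqs.append(seq)
    if not keep_ids:
        raise EmptyAlignmentError("gap filter removed every sequence")
    return (
        replace(aln, ids=tuple(keep_ids), seqs=tuple(keep_seqs)),
        removed,
    )


def strip_coordinates(seq_id: str) -> str:
    """Key extractor dropping Pfam-style ``/start-end`` (and trailing ``.n``)
    suffixes, e.g. ``"Q9X0H1.1/5-160" -> "Q9X0H1"``."""
    base = seq_id.split("/", 1)[0]
    return base.split(".", 1)[0]


def join_alignments(
    alnA: Alignment,
    alnB: Alignment,
    id_matcher: Optional[Callable[[str], str]] = None,
) -> Alignment:
    """Concatenate two alignments sample-by-sample on matching identifiers.

    Used for inter-protein analysis: each joined record is
    ``residuesA + residuesB`` for every identifier present in both inputs
    (in ``alnA``'s order), so that positions from the two proteins can be
    coupled within the same sample. Columns are tagged ``"A"``/``"B"`` and
    keep their per-protein position labels; ``boundary`` records protein
    A's column count.

    ``id_matcher`` maps a raw sequence id to a join key (default: identity,
    i.e. exact id equality; see :func:`strip_coordinates` for Pfam ids).
    """
    key = id_matcher or (lambda s: s)
    keyB = {}
    for sid, seq in zip(alnB.ids, alnB.seqs):
        keyB.setdefault(key(sid), (sid, seq))
    ids, seqs = [], []
    for sid, seq in zip(alnA.ids, alnA.seqs):
        hit = keyB.get(key(sid))
        if hit is not None:
            ids.append(sid)
            seqs.append(seq + hit[1])
    if not ids:
        raise JoinError(
            "no sequence ids matched between the two alignments "
            f"(examples: A={list(alnA.ids[:3])}, B={list(alnB.ids[:3])})"
        )
    labelsA = alnA.column_labels or tuple(range(1, alnA.n_columns + 1))
    labelsB = alnB.column_labels or tuple(range(1, alnB.n_columns + 1))
    return Alignment(
        ids=tuple(ids),
        seqs=tuple(seqs),
        reference_id=alnA.reference_id,
        column_labels=labelsA + labelsB,
        column_tags=("A",) * alnA.n_columns + ("B",) * alnB.n_columns,
        boundary=alnA.n_columns,
    )
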