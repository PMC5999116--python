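"""Master sequence construction and integer encoding of alignments.

The analysis reduces each alignment column to a small number of states
relative to a *master sequence* — the most frequent amino acid per column.
Binary encoding codes a residue 1 when it equals the master residue and 0
otherwise (gaps count as a 21st symbol and always code 0). The three-state
extension additionally distinguishes the two residues whose column
frequency exceeds a threshold (default 35%), coded 1 and 2 by descending
frequency, everything else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alignment_io import GAP, Alignment, AlignmentShapeError, EmptyAlignmentError


class AllGapColumnError(ValueError):
    """A column contains nothing but gaps, so no master residue exists."""


@dataclass(frozen=True)
class MasterSequence:
    """Per-column modal residues of an alignment.

    ``residues[c]`` is the most frequent symbol in column c — except when
    the gap is modal, in which case the most frequent *non-gap* residue is
    taken and ``gap_was_modal[c]`` is set. ``modal_frequency[c]`` is the
    fraction of all sequences (gaps included in the denominator) carrying
    the master residue. 'X' (unknown) is counted like any other symbol but
    never chosen as a master residue.
    """

    residues: str
    modal_frequency: np.ndarray
    gap_was_modal: np.ndarray

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EncodedMatrix:
    """Integer codes for every sequence at every position.

    ``codes`` is an (n_sequences, n_positions) int8 matrix. In the binary
    scheme codes are {0,1}; in the three-state scheme {0,1,2}.
    ``states[c]`` names the residues behind the non-zero codes of column c
    (binary: the master residue; three-state: one or two residues in
    descending frequency). Three-state columns with no qualifying residue
    are marked in ``excluded`` and skipped by pair analysis.
    """

    codes: np.ndarray
    scheme: str  # "binary" | "three_state"
    states: tuple[tuple[str, ...], ...]
    position_labels: tuple[int, ...]
    sequence_ids: tuple[str, ...]
    position_tags: Optional[tuple[str, ...]] = None
    boundary: Optional[int] = None
    excluded: Optional[np.ndarray] = None  # bool per column; None = none excluded

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_positions(self) -> int:
        return self.codes.shape[1]

    def label(self, col: int) -> str:
        p = self.position_labels[col]
        return f"{self.position_tags[col]}{p}" if self.position_tags else str(p)

    def is_excluded(self, col: int) -> bool:
        return bool(self.excluded[col]) if self.excluded is not None else False

    def to_frame(self) -> pd.DataFrame:
        """Codes as a DataFrame (rows = sequences, columns = labels)."""
        return pd.DataFrame(
            self.codes,
            index=list(self.sequence_ids),
            columns=[self.label(c) for c in range(self.n_positions)],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sequence_id")


def _column_array(aln: Alignment) -> np.ndarray:
    """(n_sequences, n_columns) array of single characters."""
    if aln.n_sequences == 0:
        raise EmptyAlignmentError("cannot encode an empty alignment")
    return np.array([list(s) for s in aln.seqs], dtype="U1")


def _column_counts(col: np.ndarray) -> list[tuple[str, int]]:
    """(symbol, count) sorted by count desc, ties broken alphabetically."""
    symbols, counts = np.unique(col, return_counts=True)
    return sorted(zip(symbols.tolist(), counts.tolist()), key=lambda t: (-t[1], t[0]))


def build_master(aln: Alignment) -> MasterSequence:
    """Build the master (modal) sequence of an alignment.

    Gaps are counted as a 21st symbol; if a gap wins a column, the most
    frequent non-gap residue is taken instead. Ties break alphabetically
    (deterministic across runs). A column consisting only of gaps raises
    :class:`AllGapColumnError`.
    """
    chars = _column_array(aln)
    n = aln.n_sequences
    residues, freqs, gap_modal = [], [], []
    for c in range(chars.shape[1]):
        ranked = _column_counts(chars[:, c])
        top_symbol = ranked[0][0]
        candidates = [(s, k) for s, k in ranked if s not in (GAP, "X")]
        if not candidates:
            raise AllGapColumnError(
                f"column {aln.column_labels[c] if aln.column_labels else c + 1} "
                "has no amino-acid residues"
            )
        master, count = candidates[0]
        residues.append(master)
        freqs.append(count / n)
        gap_modal.append(top_symbol == GAP)
    return MasterSequence(
        residues="".join(residues),
        modal_frequency=np.asarray(freqs),
        gap_was_modal=np.asarray(gap_modal, dtype=bool),
    )


def encode_binary(aln: Alignment, master: MasterSequence) -> EncodedMatrix:
    """Code each residue 1 iff it equals the master residue of its column.

    Gaps and every non-master residue code 0.
    """
    chars = _column_array(aln)
    if len(master) != chars.shape[1]:
        raise AlignmentShapeError(
            f"master length {len(master)} != alignment columns {chars.shape[1]}"
        )
    master_row = np.array(list(master.residues), dtype="U1")
    codes = (chars == master_row[None, :]).astype(np.int8)
    return EncodedMatrix(
        codes=codes,
        scheme="binary",
        states=tuple((r,) for r in master.residues),
        position_labels=aln.column_labels or tuple(range(1, chars.shape[1] + 1)),
        sequence_ids=aln.ids,
        position_tags=aln.column_tags,
        boundary=aln.boundary,
    )


def encode_three_state(
    aln: Alignment, frequency_threshold: float = 0.35
) -> EncodedMatrix:
    """Three-state encoding: the one or two residues with column frequency
    strictly above ``frequency_threshold`` become states 1 and 2 (by
    descending frequency); all other symbols, gaps included, code 0.

    The threshold must exceed 1/3 so that at most two residues can qualify.
    Columns where no residue qualifies are flagged ``excluded`` and are
    skipped by the pair analysis. Gaps and 'X' never qualify as states,
    though they stay in the frequency denominator.
    """
    if not (1.0 / 3.0 < frequency_threshold <= 1.0):
        raise ValueError(
            "frequency_threshold must be in (1/3, 1] so at most two states qualify"
        )
    chars = _column_array(aln)
    n, L = chars.shape
    codes = np.zeros((n, L), dtype=np.int8)
    states: list[tuple[str, ...]] = []
    excluded = np.zeros(L, dtype=bool)
    for c in range(L):
        ranked = _column_counts(chars[:, c])
        qualifying = [
            s for s, k in ranked if s not in (GAP, "X") and k / n > frequency_threshold
        ]
        states.append(tuple(qualifying))
        if not qualifying:
            excluded[c] = True
            continue
        for code, residue in enumerate(qualifying, start=1):
            codes[chars[:, c] == residue, c] = code
    return EncodedMatrix(
        codes=codes,
        scheme="three_state",
        states=tuple(states),
        position_labels=aln.column_labels or tuple(range(1, L + 1)),
        sequence_ids=aln.ids,
        position_tags=aln.column_tags,
        boundary=aln.boundary,
        excluded=excluded,
    )


def conservation(aln: Alignment, master: MasterSequence) -> np.ndarray:
    """Fraction of sequences carrying the master residue, per column.

    The denominator is all sequences, gap-carrying ones included, so this
    equals the per-column mean of the binary codes exactly.
    """
    chars = _column_array(aln)
    if len(master) != chars.shape[1]:
        raise AlignmentShapeError(
            f"master length {len(master)} != alignment columns {chars.shape[1]}"
        )
    master_row = np.array(list(master.residues), dtype="U1")
    return (chars == master_row[None, :]).mean(axis=0)
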