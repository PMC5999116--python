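"""Synthetic alignments with known directed structure.

The generator emulates the statistical structure the impact analysis
assumes: sequences are i.i.d. draws from a column model around a master
sequence. Each column c deviates from the master with probability
``mutation_rate[c]``; a planted pair (i -> j, coupling c) makes column j
copy column i's conserved/mutated status with probability ``c`` and fall
back to its own independent draw otherwise. Because ground truth is known
exactly, every pipeline stage can be tested without any external data.

No phylogeny is simulated — sequences are exchangeable given the column
model, matching the independence assumption the conditional-probability
statistic itself makes.

Note that the status-copy coupling creates a *symmetric* association:
when marginals are comparable, the reciprocal relation j -> i is genuinely
supported by the data as well. :func:`score_edges` therefore counts
reciprocal counterparts of planted pairs as planted signal, not as false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .alignment_io import AMINO_ACIDS, GAP, Alignment
from .impact_core import EdgeRecord


class SyntheticSpecError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic alignment.

    Parameters
    ----------
    n_sequences, n_positions
        Alignment dimensions.
    master
        Master residue string of length ``n_positions``; auto-generated
        from the seed when None.
    mutation_rate
        Per-column probability of deviating from the master (scalar or one
        value per column). Default 0.3 — a moderately variable protein
        family, informative for the conditional probabilities without
        washing out conservation.
    planted_pairs
        (source, target, coupling) triples in 1-based positions; the target
        copies the source's conserved/mutated status with probability
        ``coupling``. A target may be planted only once so ground truth
        stays unambiguous.
    gap_rate
        Probability that a deviation at an unplanted column is rendered as
        a gap character rather than an alternative residue. Planted columns
        never carry gaps, so couplings survive binary encoding untouched.
    alternative_mode
        "fixed": deviations use one fixed alternative residue per column
        (default; keeps the second state concentrated so both binary and
        three-state encodings see it). "uniform": deviations draw uniformly
        from the 19 non-master residues.
    seed
        Generator seed; identical specs produce identical alignments.
    """

    n_sequences: int
    n_positions: int
    master: Optional[str] = None
    mutation_rate: Union[float, Sequence[float]] = 0.3
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    gap_rate: float = 0.0
    alternative_mode: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_positions < 1:
            raise SyntheticSpecError("n_sequences and n_positions must be >= 1")
        if self.master is not None and len(self.master) != self.n_positions:
            raise SyntheticSpecError("master length must equal n_positions")
        if not 0.0 <= self.gap_rate <= 1.0:
            raise SyntheticSpecError("gap_rate must be within [0, 1]")
        if self.alternative_mode not in ("fixed", "uniform"):
            raise SyntheticSpecError("alternative_mode must be 'fixed' or 'uniform'")
        rates = self.rates()
        if rates.min() < 0.0 or rates.max() > 1.0:
            raise SyntheticSpecError("mutation_rate values must be within [0, 1]")
        targets = set()
        object.__setattr__(self, "planted_pairs", tuple(tuple(p) for p in self.planted_pairs))
        for src, tgt, c in self.planted_pairs:
            if src == tgt:
                raise SyntheticSpecError(f"planted pair {src}->{tgt} is a self-loop")
            for p in (src, tgt):
                if not 1 <= p <= self.n_positions:
                    raise SyntheticSpecError(f"planted position {p} out of range")
            if not 0.0 <= c <= 1.0:
                raise SyntheticSpecError("coupling must be within [0, 1]")
            if tgt in targets:
                raise SyntheticSpecError(
                    f"position {tgt} is the target of two planted pairs"
                )
            targets.add(tgt)

    def rates(self) -> np.ndarray:
        if np.isscalar(self.mutation_rate):
            return np.full(self.n_positions, float(self.mutation_rate))
        arr = np.asarray(self.mutation_rate, dtype=float)
        if arr.shape != (self.n_positions,):
            raise SyntheticSpecError("mutation_rate must be scalar or length L")
        return arr

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_sequences": self.n_sequences,
            "n_positions": self.n_positions,
            "master": self.master,
            "mutation_rate": (
                float(self.mutation_rate)
                if np.isscalar(self.mutation_rate)
                else [float(r) for r in self.mutation_rate]
            ),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "gap_rate": self.gap_rate,
            "alternative_mode": self.alternative_mode,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        doc = yaml.safe_load(Path(path).read_text())
        doc["planted_pairs"] = tuple(tuple(p) for p in doc.get("planted_pairs") or ())
        return cls(**doc)


def _auto_master(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=L))


def generate_alignment(
    spec: SyntheticSpec,
) -> tuple[Alignment, list[tuple[int, int, float]]]:
    """Draw one alignment from the spec; returns it with its ground truth.

    The returned planted list (1-based source, target, coupling) is exactly
    what recovery tests should score against. Deterministic given the
    spec's seed, byte-for-byte.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.n_positions
    master = spec.master or _auto_master(rng, L)
    rates = spec.rates()

    # fixed alternative residue per column (used in "fixed" mode and at
    # planted columns in either mode)
    others = [[a for a in AMINO_ACIDS if a != master[c]] for c in range(L)]
    fixed_alt = [others[c][int(rng.integers(len(others[c])))] for c in range(L)]

    # deviation status: True where a sequence leaves the master state
    status = rng.random((n, L)) < rates[None, :]
    planted_cols: set[int] = set()
    for src, tgt, c in spec.planted_pairs:
        i, j = src - 1, tgt - 1
        copy = rng.random(n) < c
        status[:, j] = np.where(copy, status[:, i], status[:, j])
        planted_cols.update((i, j))

    gap_draw = rng.random((n, L)) < spec.gap_rate
    uniform_alt = rng.integers(0, len(AMINO_ACIDS) - 1, size=(n, L))

    chars = np.empty((n, L), dtype="U1")
    for c in range(L):
        col = np.full(n, master[c], dtype="U1")
        dev = status[:, c]
        if c in planted_cols:
            col[dev] = fixed_alt[c]
        else:
            if spec.alternative_mode == "fixed":
                col[dev] = fixed_alt[c]
            else:
                col[dev] = np.array(others[c], dtype="U1")[uniform_alt[dev, c]]
            col[dev & gap_draw[:, c]] = GAP
        chars[:, c] = col

    width = len(str(n))
    ids = tuple(f"seq{k + 1:0{width}d}" for k in range(n))
    aln = Alignment(
        ids=ids,
        seqs=tuple("".join(row) for row in chars),
        column_labels=tuple(range(1, L + 1)),
    )
    return aln, [tuple(p) for p in spec.planted_pairs]


def generate_cohort_pair(
    spec_resistant: SyntheticSpec, spec_sensitive: SyntheticSpec
) -> tuple[Alignment, Alignment, list[tuple[int, int, float]]]:
    """Draw a resistant/sensitive cohort pair with shared ground truth.

    Both specs must share the master (when both are None, one master is
    derived from the resistant spec's seed and used for both) and the same
    planted (source, target) pairs: the coupling plants joint mutations in
    the resistant cohort and joint conservation in the sensitive cohort,
    which is exactly the compensatory pattern the cohort criterion
    P_resistant(j=0|i=0) & P_sensitive(j=1|i=1) detects.
    """
    if spec_resistant.n_positions != spec_sensitive.n_positions:
        raise SyntheticSpecError("cohort specs disagree on n_positions")
    if spec_resistant.master != spec_sensitive.master:
        raise SyntheticSpecError("cohort specs must share one master sequence")
    if [p[:2] for p in spec_resistant.planted_pairs] != [
        p[:2] for p in spec_sensitive.planted_pairs
    ]:
        raise SyntheticSpecError("cohort specs must plant the same (source, target) pairs")
    if spec_resistant.master is None:
        master = _auto_master(
            np.random.default_rng(spec_resistant.seed), spec_resistant.n_positions
        )
        spec_resistant = replace(spec_resistant, master=master)
        spec_sensitive = replace(spec_sensitive, master=master)
    aln_res, truth = generate_alignment(spec_resistant)
    aln_sen, _ = generate_alignment(spec_sensitive)
    return aln_res, aln_sen, truth


def write_ground_truth_tsv(
    truth: Sequence[tuple[int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tcoupling\n")
        for src, tgt, c in truth:
            fh.write(f"{src}\t{tgt}\t{c}\n")


def score_edges(
    edges: Sequence[EdgeRecord], truth: Sequence[tuple[int, int, float]]
) -> dict:
    """Score detected edges against the planted ground truth.

    ``recovered`` counts planted ordered pairs present in the edge list.
    An edge whose unordered pair was planted but that runs opposite to the
    planted direction is a ``reciprocal`` — genuine signal under the
    symmetric status-copy coupling, not an error. Everything else is a
    ``false_positive``.
    """
    planted = {(src, tgt) for src, tgt, _ in truth}
    planted_unordered = {frozenset(p) for p in planted}
    found = {(e.source, e.target) for e in edges}
    recovered = sorted(planted & found)
    reciprocal = sorted(
        p for p in found if p not in planted and frozenset(p) in planted_unordered
    )
    false_pos = sorted(
        p for p in found if frozenset(p) not in planted_unordered
    )
    return {
        "recovered": recovered,
        "n_recovered": len(recovered),
        "n_planted": len(planted),
        "reciprocal": reciprocal,
        "false_positives": false_pos,
        "n_false_positives": len(false_pos),
    }
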