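"""Directed co-evolution statistics on encoded alignments.

For an ordered position pair (i, j) two conditional probabilities are
computed over the sequences of the alignment:

    P(j=1 | i=1)  — how conservation at i imposes conservation at j, and
    P(j=0 | i=0)  — how a mutation at i imposes a compensatory mutation at j.

Position i *impacts* j when both probabilities are simultaneously >= a
cut-off gamma in [0, 1]. The identity pair (i, i) always sits at (1, 1) and
is excluded. Candidate edges are then screened by a permutation test that
shuffles the target column across sequences; edges with permutation
p-value below the significance threshold form the directed network.

The impact factor of i is its out-degree (number of positions it impacts);
the dependency factor of j is its in-degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import EncodedMatrix

NodeKey = "int | str"  # plain reference position, or tag+position like "A12"

ALIGNED = "aligned"
SWAPPED = "swapped"


class SchemeError(ValueError):
    """Operation applied to an EncodedMatrix with the wrong scheme."""


@dataclass(frozen=True)
class ConditionalPair:
    """The two conditional probabilities of one ordered pair (i, j).

    ``p11``/``p00`` are NaN when the conditioning event has zero count
    (``defined`` reports which are usable). ``n_i1 + n_i0`` equals the
    number of sequences.
    """

    p11: float
    p00: float
    n_i1: int
    n_i0: int

    @property
    def p11_defined(self) -> bool:
        return self.n_i1 > 0

    @property
    def p00_defined(self) -> bool:
        return self.n_i0 > 0


@dataclass(frozen=True)
class EdgeRecord:
    """One directed relation i -> j that passed the gamma criterion.

    ``p11`` and ``p00`` are the conservation- and mutation-side
    probabilities of the criterion that passed; in the three-state scheme
    ``p22`` carries the middle (second-state) condition of the passing
    branch and ``branch`` says whether the state-aligned (1->1, 2->2) or
    state-swapped (1->2, 2->1) condition set held. Cohort-mode edges store
    the per-cohort probabilities in ``resistant_p00``/``sensitive_p11``
    (mirrored into ``p00``/``p11``). ``p_value`` is None when the
    permutation test was not run.
    """

    source: int
    target: int
    p11: float
    p00: float
    gamma: float
    p_value: Optional[float] = None
    scheme: str = "binary"
    branch: Optional[str] = None
    source_tag: Optional[str] = None
    target_tag: Optional[str] = None
    p22: Optional[float] = None
    resistant_p00: Optional[float] = None
    sensitive_p11: Optional[float] = None

    @property
    def source_key(self):
        return node_key(self.source_tag, self.source)

    @property
    def target_key(self):
        return node_key(self.target_tag, self.target)

    @property
    def category(self) -> Optional[str]:
        """'intra-A' / 'intra-B' / 'inter' for joined alignments, else None."""
        if self.source_tag is None or self.target_tag is None:
            return None
        if self.source_tag == self.target_tag:
            return f"intra-{self.source_tag}"
        return "inter"


def node_key(tag: Optional[str], label: int):
    return label if tag is None else f"{tag}{label}"


@dataclass
class DetectionResult:
    """Edges plus the bookkeeping of one detection run."""

    edges: list[EdgeRecord]
    gamma: float
    scheme: str
    n_pairs_tested: int  # ordered pairs examined against the criterion
    n_gamma_passed: int  # pairs meeting the probability criterion
    n_discarded_significance: int  # gamma survivors failing the p-value cut
    n_undefined_pairs: int  # pairs with an undefined conditional probability

    def __iter__(self):
        return iter(self.edges)

    def __len__(self):
        return len(self.edges)


# ---------------------------------------------------------------------------
# conditional probabilities and the gamma criterion
# ---------------------------------------------------------------------------


def conditional_probabilities(matrix: EncodedMatrix, i: int, j: int) -> ConditionalPair:
    """P(j=1|i=1) and P(j=0|i=0) for binary codes, by direct counting.

    A zero denominator (column i constant) yields NaN for that probability,
    flagged through the ``*_defined`` properties — never an exception.
    """
    if matrix.scheme != "binary":
        raise SchemeError("conditional_probabilities requires the binary scheme")
    L = matrix.n_positions
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"position out of range: i={i}, j={j}, L={L}")
    ci = matrix.codes[:, i]
    cj = matrix.codes[:, j]
    i1 = ci == 1
    n_i1 = int(i1.sum())
    n_i0 = len(ci) - n_i1
    p11 = float((cj[i1] == 1).sum() / n_i1) if n_i1 else math.nan
    p00 = float((cj[~i1] == 0).sum() / n_i0) if n_i0 else math.nan
    return ConditionalPair(p11=p11, p00=p00, n_i1=n_i1, n_i0=n_i0)


def edge_passes(pair: ConditionalPair, gamma: float) -> bool:
    """True iff both probabilities are defined and each >= gamma.

    An undefined probability (perfectly conserved or perfectly mutated
    source column) fails: perfectly conserved positions emit no edges.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be within [0, 1]")
    if not (pair.p11_defined and pair.p00_defined):
        return False
    return pair.p11 >= gamma and pair.p00 >= gamma


def _branch_conditions(
    matrix: EncodedMatrix, i: int, branch: str
) -> list[tuple[int, int]]:
    """Condition list [(target_state a, source_state b), ...] for a branch.

    Conditions conditioning on a source state that is not defined at column
    i (no second qualifying residue, hence no code-2 sequences) are vacuous
    and dropped, so a column with a single state reduces to the binary-style
    criterion on that branch.
    """
    has2 = len(matrix.states[i]) >= 2
    if branch == ALIGNED:
        conds = [(1, 1), (2, 2), (0, 0)]
        return [c for c in conds if c[1] != 2 or has2]
    if branch == SWAPPED:
        conds = [(2, 1), (1, 2), (0, 0)]
        return [c for c in conds if c[1] != 2 or has2]
    raise ValueError(f"unknown branch {branch!r}")


def _conditions_probs(
    ci: np.ndarray, cj: np.ndarray, conditions: list[tuple[int, int]]
) -> list[float]:
    """P(j=a|i=b) for each condition; NaN when #{i=b} is zero."""
    out = []
    for a, b in conditions:
        mask = ci == b
        nb = int(mask.sum())
        out.append(float((cj[mask] == a).sum() / nb) if nb else math.nan)
    return out


def edge_passes_three_state(
    matrix: EncodedMatrix, i: int, j: int, gamma: float
) -> tuple[bool, Optional[str]]:
    """Evaluate both three-state condition sets for the pair (i, j).

    The *aligned* branch requires P(j=1|i=1), P(j=2|i=2) and P(j=0|i=0) all
    >= gamma; the *swapped* branch requires P(j=2|i=1), P(j=1|i=2) and
    P(j=0|i=0) all >= gamma. An undefined condition (zero conditioning
    count) fails its branch. Returns (passed, branch) with the aligned
    branch preferred when both hold.
    """
    if matrix.scheme != "three_state":
        raise SchemeError("edge_passes_three_state requires the three_state scheme")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be within [0, 1]")
    if matrix.is_excluded(i) or matrix.is_excluded(j):
        return False, None
    ci = matrix.codes[:, i]
    cj = matrix.codes[:, j]
    for branch in (ALIGNED, SWAPPED):
        probs = _conditions_probs(ci, cj, _branch_conditions(matrix, i, branch))
        if all(not math.isnan(p) and p >= gamma for p in probs):
            return True, branch
    return False, None


# ---------------------------------------------------------------------------
# permutation significance test
# ---------------------------------------------------------------------------


def pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    """Deterministic per-pair generator derived from the master seed.

    Sub-seeding from (seed, i, j) makes results independent of pair
    evaluation order and safe to parallelise.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i, j)))


def _perm_statistics(
    ci: np.ndarray, perm_j: np.ndarray, conditions: list[tuple[int, int]]
) -> np.ndarray:
    """min over conditions of P(j=a|i=b), per permuted row of column j.

    Undefined conditions score -inf so they can never look as extreme as a
    defined observation.
    """
    T = np.full(perm_j.shape[0], np.inf)
    for a, b in conditions:
        mask = ci == b
        nb = int(mask.sum())
        if nb == 0:
            return np.full(perm_j.shape[0], -np.inf)
        T = np.minimum(T, (perm_j[:, mask] == a).sum(axis=1) / nb)
    return T


def permutation_test(
    matrix: EncodedMatrix,
    i: int,
    j: int,
    n_permutations: int = 2000,
    seed: int = 0,
    branch: Optional[str] = None,
) -> float:
    """Permutation p-value for the directed relation i -> j.

    The entries of column j are shuffled across sequences (column i fixed),
    which preserves both marginal compositions while destroying the i-j
    association. The statistic is the minimum of the criterion's
    conditional probabilities — min(P(j=1|i=1), P(j=0|i=0)) for binary, the
    minimum over the branch's conditions for three-state. The one-sided
    p-value uses the add-one correction
    ``(1 + #{T_perm >= T_obs}) / (n_permutations + 1)`` and is exactly
    reproducible for a given seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ci = matrix.codes[:, i]
    cj = matrix.codes[:, j]
    if matrix.scheme == "binary":
        conditions = [(1, 1), (0, 0)]
    else:
        conditions = _branch_conditions(matrix, i, branch or ALIGNED)
    t_obs = _perm_statistics(ci, cj[None, :], conditions)[0]
    rng = pair_rng(seed, i, j)
    perm = rng.permuted(np.tile(cj, (n_permutations, 1)), axis=1)
    t_perm = _perm_statistics(ci, perm, conditions)
    return float((1 + int((t_perm >= t_obs).sum())) / (n_permutations + 1))


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------


def _binary_candidates(matrix: EncodedMatrix, gamma: float):
    """All ordered pairs meeting the binary gamma criterion, vectorised.

    Returns (candidates, n_undefined_pairs) where candidates is a list of
    (i, j, p11, p00).
    """
    codes = matrix.codes
    n, L = codes.shape
    B1 = codes == 1
    n1 = B1.sum(axis=0)
    n0 = n - n1
    defined = (n1 > 0) & (n0 > 0)
    # contingency counts via matrix products over the sequence axis
    C11 = B1.T.astype(np.int64) @ B1.astype(np.int64)
    B0 = ~B1
    C00 = B0.T.astype(np.int64) @ B0.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p11 = C11 / n1[:, None]
        p00 = C00 / n0[:, None]
    offdiag = ~np.eye(L, dtype=bool)
    undefined = offdiag & ~defined[:, None]
    passing = offdiag & defined[:, None] & (p11 >= gamma) & (p00 >= gamma)
    cand = [
        (int(i), int(j), float(p11[i, j]), float(p00[i, j]))
        for i, j in zip(*np.nonzero(passing))
    ]
    return cand, int(undefined.sum())


def detect_edges(
    matrix: EncodedMatrix,
    gamma: float,
    p_threshold: float = 0.01,
    n_permutations: int = 2000,
    seed: int = 0,
    significance: bool = True,
) -> DetectionResult:
    """Scan all ordered position pairs and return the significant edges.

    Pairs first pass the gamma criterion (both conditional probabilities
    >= gamma, strictly applied); the permutation test is then run on each
    survivor and only edges with p-value strictly below ``p_threshold``
    are kept. Set ``significance=False`` to keep every gamma survivor
    (p_value left as None). The number of pairs discarded at each stage is
    reported in the :class:`DetectionResult`.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be within [0, 1]")
    L = matrix.n_positions
    n_undefined = 0
    candidates: list[tuple] = []  # (i, j, p11, p00, p22, branch)
    if matrix.scheme == "binary":
        cand, n_undefined = _binary_candidates(matrix, gamma)
        candidates = [(i, j, p11, p00, None, None) for i, j, p11, p00 in cand]
        n_pairs = L * (L - 1)
    else:
        active = [c for c in range(L) if not matrix.is_excluded(c)]
        n_pairs = len(active) * (len(active) - 1)
        for i in active:
            ci = matrix.codes[:, i]
            for j in active:
                if i == j:
                    continue
                cj = matrix.codes[:, j]
                passed = False
                for branch in (ALIGNED, SWAPPED):
                    conds = _branch_conditions(matrix, i, branch)
                    probs = _conditions_probs(ci, cj, conds)
                    if any(math.isnan(p) for p in probs):
                        continue
                    if all(p >= gamma for p in probs):
                        p11, p00 = probs[0], probs[-1]
                        p22 = probs[1] if len(probs) == 3 else None
                        candidates.append((i, j, p11, p00, p22, branch))
                        passed = True
                        break
                if not passed and any(
                    math.isnan(p)
                    for p in _conditions_probs(
                        ci, cj, _branch_conditions(matrix, i, ALIGNED)
                    )
                ):
                    n_undefined += 1

    edges: list[EdgeRecord] = []
    n_discarded = 0
    for i, j, p11, p00, p22, branch in candidates:
        p_value: Optional[float] = None
        if significance:
            p_value = permutation_test(
                matrix, i, j, n_permutations=n_permutations, seed=seed, branch=branch
            )
            if not p_value < p_threshold:
                n_discarded += 1
                continue
        edges.append(
            EdgeRecord(
                source=int(matrix.position_labels[i]),
                target=int(matrix.position_labels[j]),
                p11=p11,
                p00=p00,
                gamma=gamma,
                p_value=p_value,
                scheme=matrix.scheme,
                branch=branch,
                source_tag=matrix.position_tags[i] if matrix.position_tags else None,
                target_tag=matrix.position_tags[j] if matrix.position_tags else None,
                p22=p22,
            )
        )
    return DetectionResult(
        edges=edges,
        gamma=gamma,
        scheme=matrix.scheme,
        n_pairs_tested=n_pairs,
        n_gamma_passed=len(candidates),
        n_discarded_significance=n_discarded,
        n_undefined_pairs=n_undefined,
    )


# ---------------------------------------------------------------------------
# impact and dependency factors
# ---------------------------------------------------------------------------


def impact_factor(
    edges: Iterable[EdgeRecord], positions: Optional[Iterable] = None
) -> dict:
    """Out-degree per position: the number of distinct targets it impacts.

    With ``positions`` given, every listed position appears in the result
    (0 when it emits no edge); otherwise only edge endpoints appear.
    """
    targets: dict = {}
    keys: set = set()
    for e in edges:
        targets.setdefault(e.source_key, set()).add(e.target_key)
        keys.update((e.source_key, e.target_key))
    if positions is not None:
        keys.update(positions)
    return {k: len(targets.get(k, ())) for k in sorted(keys, key=str)}


def dependency_factor(
    edges: Iterable[EdgeRecord], positions: Optional[Iterable] = None
) -> dict:
    """In-degree per position: the number of distinct sources impacting it."""
    sources: dict = {}
    keys: set = set()
    for e in edges:
        sources.setdefault(e.target_key, set()).add(e.source_key)
        keys.update((e.source_key, e.target_key))
    if positions is not None:
        keys.update(positions)
    return {k: len(sources.get(k, ())) for k in sorted(keys, key=str)}


# ---------------------------------------------------------------------------
# edge list serialisation
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "source_label",
    "target_label",
    "source_protein",
    "target_protein",
    "p11",
    "p00",
    "gamma",
    "p_value",
    "scheme",
    "branch",
    "p22",
    "resistant_p00",
    "sensitive_p11",
]


def edges_to_frame(edges: Sequence[EdgeRecord]) -> pd.DataFrame:
    rows = [
        {
            "source_label": e.source,
            "target_label": e.target,
            "source_protein": e.source_tag,
            "target_protein": e.target_tag,
            "p11": e.p11,
            "p00": e.p00,
            "gamma": e.gamma,
            "p_value": e.p_value,
            "scheme": e.scheme,
            "branch": e.branch,
            "p22": e.p22,
            "resistant_p00": e.resistant_p00,
            "sensitive_p11": e.sensitive_p11,
        }
        for e in edges
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(float(v))  # shortest exact round-trip representation
    return str(v)


def write_edges_tsv(edges: Sequence[EdgeRecord], path: str | Path) -> None:
    """Write the edge list as TSV; floats keep full round-trip precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for e in edges:
            row = [
                e.source,
                e.target,
                e.source_tag,
                e.target_tag,
                e.p11,
                e.p00,
                e.gamma,
                e.p_value,
                e.scheme,
                e.branch,
                e.p22,
                e.resistant_p00,
                e.sensitive_p11,
            ]
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_edges_tsv(path: str | Path) -> list[EdgeRecord]:
    """Read an edge TSV back into EdgeRecords (exact round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        opt = lambda v: None if v == "" else v
        optf = lambda v: None if v == "" else float(v)
        out.append(
            EdgeRecord(
                source=int(row["source_label"]),
                target=int(row["target_label"]),
                source_tag=opt(row["source_protein"]),
                target_tag=opt(row["target_protein"]),
                p11=float(row["p11"]),
                p00=float(row["p00"]),
                gamma=float(row["gamma"]),
                p_value=optf(row["p_value"]),
                scheme=row["scheme"],
                branch=opt(row["branch"]),
                p22=optf(row["p22"]),
                resistant_p00=optf(row["resistant_p00"]),
                sensitive_p11=optf(row["sensitive_p11"]),
            )
        )
    return out
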