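"""Resistant-versus-sensitive cohort comparison.

For drug-resistance data the directed criterion is split across two
cohorts: position i impacts j when a mutation at i goes with a
compensatory mutation at j *within the resistant cohort*,
P_resistant(j=0 | i=0) >= gamma, while both stay conserved *within the
sensitive cohort*, P_sensitive(j=1 | i=1) >= gamma. Both cohorts are
encoded against one shared master sequence — by default built from the
sensitive cohort, taken as the wild-type-like background — so that "0"
means the same mutation event on both sides. The criterion applies
unchanged to joined two-protein alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment_io import Alignment, AlignmentShapeError
from .encoding import EncodedMatrix, MasterSequence, build_master, encode_binary
from .impact_core import DetectionResult, EdgeRecord, pair_rng


@dataclass(frozen=True)
class CohortPair:
    """Binary code matrices of the two cohorts, sharing one master.

    Both matrices cover identical position labels and were encoded against
    the same :class:`MasterSequence` (``master_source`` records whether it
    came from the sensitive cohort or the pooled alignments).
    """

    resistant: EncodedMatrix
    sensitive: EncodedMatrix
    master: MasterSequence
    master_source: str

    def __post_init__(self) -> None:
        if self.resistant.position_labels != self.sensitive.position_labels:
            raise AlignmentShapeError("cohort position labels differ")
        if self.resistant.scheme != self.sensitive.scheme:
            raise AlignmentShapeError("cohort encoding schemes differ")


def encode_cohorts(
    aln_resistant: Alignment,
    aln_sensitive: Alignment,
    master_source: str = "sensitive",
) -> CohortPair:
    """Encode both cohorts against one shared master sequence.

    ``master_source="sensitive"`` (default) derives the master from the
    sensitive cohort; ``"pooled"`` derives it from the two cohorts stacked,
    which changes the master only at positions where the cohorts disagree
    on the modal residue.
    """
    if aln_resistant.n_columns != aln_sensitive.n_columns:
        raise AlignmentShapeError(
            f"cohorts have {aln_resistant.n_columns} vs "
            f"{aln_sensitive.n_columns} columns; truncate both to the same "
            "reference first"
        )
    if master_source == "sensitive":
        master = build_master(aln_sensitive)
    elif master_source == "pooled":
        pooled = Alignment(
            ids=tuple(f"R|{i}" for i in aln_resistant.ids)
            + tuple(f"S|{i}" for i in aln_sensitive.ids),
            seqs=aln_resistant.seqs + aln_sensitive.seqs,
            column_labels=aln_sensitive.column_labels,
            column_tags=aln_sensitive.column_tags,
            boundary=aln_sensitive.boundary,
        )
        master = build_master(pooled)
    else:
        raise ValueError("master_source must be 'sensitive' or 'pooled'")
    return CohortPair(
        resistant=encode_binary(aln_resistant, master),
        sensitive=encode_binary(aln_sensitive, master),
        master=master,
        master_source=master_source,
    )


def _cond_prob(col_i: np.ndarray, col_j: np.ndarray, state: int) -> float:
    """P(j=state | i=state) within one cohort; NaN on zero denominator."""
    mask = col_i == state
    n = int(mask.sum())
    return float((col_j[mask] == state).sum() / n) if n else math.nan


def detect_resistance_edges(
    pair: CohortPair,
    gamma: float,
    p_threshold: float = 0.01,
    n_permutations: int = 2000,
    seed: int = 0,
    significance: bool = True,
) -> DetectionResult:
    """Scan ordered pairs for compensatory-mutation relations across cohorts.

    i -> j requires P_resistant(j=0|i=0) >= gamma and
    P_sensitive(j=1|i=1) >= gamma. Significance is assessed by permuting
    column j independently within each cohort; the statistic is the
    minimum of the two probabilities, with undefined values scoring -inf.
    Pairs with an undefined probability in either cohort fail and are
    counted.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be within [0, 1]")
    res, sen = pair.resistant.codes, pair.sensitive.codes
    n_res, L = res.shape
    n_sen = sen.shape[0]
    # vectorised criterion: counts via matrix products per cohort
    R0 = res == 0
    S1 = sen == 1
    nr0 = R0.sum(axis=0)
    ns1 = S1.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p00_res = (R0.T.astype(np.int64) @ R0.astype(np.int64)) / nr0[:, None]
        p11_sen = (S1.T.astype(np.int64) @ S1.astype(np.int64)) / ns1[:, None]
    offdiag = ~np.eye(L, dtype=bool)
    defined = (nr0 > 0)[:, None] & (ns1 > 0)[:, None]
    undefined = offdiag & ~defined
    passing = offdiag & defined & (p00_res >= gamma) & (p11_sen >= gamma)

    matrix = pair.resistant  # for labels/tags (identical across cohorts)
    edges: list[EdgeRecord] = []
    n_discarded = 0
    cand = list(zip(*np.nonzero(passing)))
    for i, j in cand:
        i, j = int(i), int(j)
        rp00 = float(p00_res[i, j])
        sp11 = float(p11_sen[i, j])
        p_value: Optional[float] = None
        if significance:
            p_value = _cohort_permutation_test(
                res[:, i], res[:, j], sen[:, i], sen[:, j],
                n_permutations=n_permutations, seed=seed, i=i, j=j,
            )
            if not p_value < p_threshold:
                n_discarded += 1
                continue
        edges.append(
            EdgeRecord(
                source=int(matrix.position_labels[i]),
                target=int(matrix.position_labels[j]),
                p11=sp11,
                p00=rp00,
                gamma=gamma,
                p_value=p_value,
                scheme="binary",
                branch=None,
                source_tag=matrix.position_tags[i] if matrix.position_tags else None,
                target_tag=matrix.position_tags[j] if matrix.position_tags else None,
                resistant_p00=rp00,
                sensitive_p11=sp11,
            )
        )
    return DetectionResult(
        edges=edges,
        gamma=gamma,
        scheme="binary",
        n_pairs_tested=L * (L - 1),
        n_gamma_passed=len(cand),
        n_discarded_significance=n_discarded,
        n_undefined_pairs=int(undefined.sum()),
    )


def _cohort_permutation_test(
    res_i: np.ndarray,
    res_j: np.ndarray,
    sen_i: np.ndarray,
    sen_j: np.ndarray,
    n_permutations: int,
    seed: int,
    i: int,
    j: int,
) -> float:
    """Permute column j within each cohort; statistic
    min(P_res(j=0|i=0), P_sen(j=1|i=1)); add-one one-sided p-value."""
    pr = _cond_prob(res_i, res_j, 0)
    ps = _cond_prob(sen_i, sen_j, 1)
    if math.isnan(pr) or math.isnan(ps):
        return 1.0
    t_obs = min(pr, ps)
    rng = pair_rng(seed, i, j)
    perm_r = rng.permuted(np.tile(res_j, (n_permutations, 1)), axis=1)
    perm_s = rng.permuted(np.tile(sen_j, (n_permutations, 1)), axis=1)
    mr = res_i == 0
    ms = sen_i == 1
    tr = (perm_r[:, mr] == 0).sum(axis=1) / mr.sum()
    ts = (perm_s[:, ms] == 1).sum(axis=1) / ms.sum()
    t_perm = np.minimum(tr, ts)
    return float((1 + int((t_perm >= t_obs).sum())) / (n_permutations + 1))
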