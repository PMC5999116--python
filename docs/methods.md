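# Methods

## Model and procedure

The package treats a multiple sequence alignment as n independent draws
from a per-column substitution process around a master sequence. For each
column the master residue is the modal amino acid (gaps counted as a 21st
symbol; when the gap is modal, the most frequent residue is taken and the
event recorded). Binary encoding maps each residue to 1 (equals master)
or 0 (anything else, including gaps and unknown 'X'). The directed
statistic for an ordered pair (i, j) is the pair of conditional
probabilities P(j=1|i=1) and P(j=0|i=0), computed by direct contingency
counting over sequences; an edge i → j requires both to reach the cut-off
γ simultaneously. The comparison is inclusive (≥ γ) and strict — no
tolerance band below the cut-off. The identity pair (i, i), which always
sits at (1, 1), is excluded.

The pipeline order is: read alignment → truncate columns to the reference
sequence (labels become 1-based ungapped reference coordinates) → remove
sequences with more than 20% gaps (computed over the truncated columns,
so the fraction refers to positions that exist in the reference protein)
→ build master on the filtered set → encode → detect edges → assemble the
network. The 20%-is-retained boundary is strict: exactly 20% gaps is
kept. The reference row itself is never removed by the filter.

## Significance test

Each γ survivor is screened by a permutation test: the entries of the
*target* column j are shuffled across sequences while column i stays
fixed, which preserves both marginal compositions and nullifies exactly
the association being thresholded. The statistic is the minimum of the
criterion's conditional probabilities (min(p11, p00) in binary mode; the
minimum over the passing branch's conditions in three-state mode; the
minimum of the two cohort probabilities in cohort mode, with the shuffle
done independently within each cohort). The one-sided p-value uses the
add-one correction (1 + #{T_perm ≥ T_obs}) / (n_perm + 1), so it can
never be exactly zero and is valid for any number of permutations.
Defaults: 2000 permutations, p < 0.01, no multiple-testing correction —
the number of pairs tested is reported so users can correct downstream.
Because all probabilities entering the comparison share the same
denominators, T_perm ≥ T_obs is an exact rational comparison; no floating
point epsilon is needed.

Randomness is controlled by one master seed; each pair (i, j) derives its
own generator via `SeedSequence(entropy=seed, spawn_key=(i, j))`, so
results do not depend on the order pairs are evaluated in and identical
configurations reproduce outputs byte for byte.

Undefined probabilities (a constant conditioning column) fail the
criterion silently and are counted in the run summary. A perfectly
conserved column therefore emits no edges at any γ; it also receives none
for any γ > 0, since its incoming P(j=0|i=0) is exactly zero. At the
degenerate cut-off γ = 0 every defined pair passes by construction, so
γ = 0 is useful only as a sanity case.

## Three-state extension

Residues whose column frequency strictly exceeds 35% become states 1 and
2 (by descending frequency); gaps and 'X' never qualify, though they stay
in the frequency denominator. The threshold must exceed 1/3 so at most
two states can qualify. Columns with no qualifying state are excluded
from pair analysis. Two condition sets are evaluated per pair — aligned
(1→1, 2→2, 0→0) and swapped (1→2, 2→1, 0→0) — and the aligned branch is
preferred when both pass. A condition conditioning on a state the source
column does not have (no second qualifying residue) is vacuous and
dropped, so single-state columns reduce to the binary criterion; a
defined condition with zero conditioning count fails its branch.

## Cohort mode

Both cohorts are encoded against one shared master, by default built from
the sensitive cohort (the wild-type-like background), optionally from the
pooled alignments — the two differ only at positions where the cohorts
disagree on the modal residue. The directed criterion becomes
P_resistant(j=0|i=0) ≥ γ and P_sensitive(j=1|i=1) ≥ γ: a joint mutation
pattern in the resistant group that is jointly conserved in the sensitive
group. The same permutation policy (p < 0.01) is applied.

## Synthetic data generator

The generator emulates exactly the structure the statistic assumes:
i.i.d. sequences from a per-column model. Each column deviates from the
master with probability m_c (default 0.3, a moderately variable family —
informative for both conditional probabilities without washing out the
master); a planted pair (i → j, coupling c) makes column j copy column
i's conserved/mutated status with probability c. Deviations use one fixed
alternative residue per column by default, so the binary and three-state
encodings both see the coupling; a uniform-alternatives mode exists for
binary-only scenarios. `gap_rate` (default 0) is the probability that a
deviation at an *unplanted* column is written as a gap; planted columns
never carry gaps, keeping ground truth exact. The per-column deviation
frequency is therefore m_c exactly, gaps included.

The generator does **not** emulate phylogenetic relatedness, sequence
weighting, indel structure beyond single-column gaps, or position-specific
substitution preferences. Passing recovery tests therefore show that the
method detects the dependence structure it models — not that real
alignments, whose sequences are phylogenetically correlated, meet that
model. The statistic inherits this independence assumption by design.

The status-copy coupling is statistically symmetric: when the two
columns' mutation rates are comparable, the reciprocal relation j → i is
genuinely present in the generated data. Recovery scoring
(`score_edges`) consequently classifies reciprocals of planted pairs as
signal rather than false positives. Genuine asymmetry arises when the
source's mutations are rare and nested inside the target's (covered by a
dedicated test).

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ (`gamma`) | 0.8 | cut-off both conditional probabilities must reach; 0.7–0.9 is the informative range, lower values drift toward random (Poisson-like) degree profiles |
| `p_threshold` | 0.01 | permutation p-value cut (strictly below) |
| `n_permutations` | 2000 | shuffles per candidate edge; smallest resolvable p is 1/2001 |
| `max_gap_fraction` | 0.20 | sequences with strictly more gaps are removed |
| `three_state_threshold` | 0.35 | column frequency a residue must strictly exceed to be a state |
| `mutation_rate` | 0.3 | generator: per-column deviation probability |
| `gap_rate` | 0.0 (0.02 in recovery studies) | generator: fraction of unplanted deviations written as gaps |

## Numerical and design choices

- Modal ties break alphabetically — any deterministic rule works; this
  one is reproducible across platforms.
- Conservation is the plain modal fraction with all sequences (gaps
  included) in the denominator, which makes it exactly the column mean of
  the binary codes.
- Duplicate edge records collapse to the smallest p-value when a network
  is assembled; self-loops are an integrity error.
- The degree-distribution scan reports raw histograms per γ; no power-law
  fitting is attempted, the transition to Poisson-like profiles is left
  to inspection.
- Edge TSVs store floats with `repr`, so export → import round-trips
  records exactly.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
recovery studies use n = 1000–2000 sequences × 50 positions with 10
planted pairs at coupling 0.95; null calibration uses 2000 independent
column pairs at n = 500 with 2000 permutations each; the brute-force
cross-check enumerates all ordered pairs on 200 random matrices up to
30 × 12; cohort studies use 500 sequences per cohort and 5 planted pairs
at coupling 0.9. These sizes give binomial standard errors of ~0.01–0.02
on the estimated probabilities, small relative to the margins the
assertions test.

## Limitations

- No phylogenetic correction: related sequences count as independent
  evidence, inflating apparent couplings in clustered data.
- Raw per-pair p-values; at L positions ~L² pairs are screened, so users
  comparing across proteins should correct for multiple testing.
- The directed relation is a statistical summary, not a causal claim.
- Structure-based outputs (edge weighting by spatial distance, 3D
  rendering) are out of scope; the exporters leave generic attribute
  slots users can populate.
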