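# Methods

## Network construction

Scores enter the analysis as cohort z-scores: each of the 18 columns is
standardized by the analyzed cohort's own mean and sample SD (ddof = 1),
then multiplied by the measure's sign convention (−1 for every measure
except digit span forward/backward) so that positive z uniformly means a
better condition. The group statistics are a property of the analyzed
cohort, not an external norm: adding or removing participants changes every
z-score, and therefore every network.

Edges use the Gaussian proximity kernel `w = exp(−(zi − zj)²)`. It is
symmetric, translation-invariant, invariant under joint negation of the
profile, and maps a one-SD separation to w ≈ 0.368 and a two-SD separation
to w ≈ 0.018. Consequences worth knowing: (a) the kernel depends only on the
participant's own z row — it is strictly intra-individual given the group
statistics; (b) joint negation invariance means an unplanted multivariate-
normal cohort is *exactly* null for every symptom–centrality correlation
(the network is unchanged under z → −z while the symptom z flips sign),
which is what makes the type-I tests clean.

Proportional thresholding retains `round(K · n(n−1)/2)` edges
(half-away-from-zero; 31 edges at K = 0.20, 32 at K = 0.21 for n = 18).
Boundary ties in weight are broken by stable lexicographic (i, j) order and
logged; with continuous scores they have probability zero. Thresholding is
nested across K when weights are distinct.

## Graph metrics

* **Clustering** — Onnela geometric-mean triangle intensity,
  `C_i = Σ_{j,h} (w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1))`, defined for binary
  degree k ≥ 2 and 0 otherwise; requires weights in [0, 1] (enforced).
* **Paths** — shortest paths over connection lengths 1/w (Dijkstra via
  scipy); characteristic path length is the mean over *reachable*
  off-diagonal pairs. Unreachable pairs are excluded rather than penalized:
  in the selected K range networks are near-fully connected, and exclusion
  is the least-assumption rule. Exclusions are surfaced as warnings.
* **Null models** — degree-preserving double-edge swaps, 10 attempted
  passes per edge by default (the conventional mixing heuristic; recorded in
  run metadata), weights traveling with the swapped edges, self-loops and
  multi-edges rejected. Graphs with no valid swap (e.g. a triangle, or the
  complete graph) return unchanged — which is why the complete graph
  normalizes to exactly (γ, λ, σ) = (1, 1, 1).
* **Small-worldness** — γ and λ are the observed mean clustering and
  characteristic path length divided by the means of the same quantities
  over the rewired ensemble; σ = γ/λ.
* **Modularity** — weighted Newman Q, averaged over randomized-node-order
  Louvain runs (networkx). Averaging over runs follows from the heuristic's
  stochasticity; the best partition found is also reported. Louvain was
  chosen over deterministic spectral bisection because run-averaging is only
  meaningful for a stochastic heuristic; on every ≤8-node fixture tested the
  heuristic's mean Q stays at or below the exhaustive-partition maximum.
* **Betweenness** — Brandes accounting on connection lengths, multiplicities
  split fractionally across tied shortest paths, endpoints excluded for node
  betweenness, each unordered pair counted once (a 5-star's center scores
  (n−1)(n−2)/2 = 6). Edge betweenness credits every edge on a shortest path,
  so a direct edge earns at least its own endpoint pair. Both are validated
  against brute-force path-enumeration oracles in the test suite.

## Sparsity selection

For every participant × K cell the three criteria are evaluated with strict
inequalities: σ > 1, Q > 0.3, connected nodes > 15 (of 18). A sparsity K
enters the optimal range when all three hold simultaneously in strictly
more than the prevalence threshold (default 0.95, i.e. ≥ 86 of 90
participants). Selection is monotone in the threshold; a non-contiguous
selection is kept whole and logged. When no K qualifies, the pipeline
reports the empty selection and proceeds at the single best-satisfaction K
(with a warning in the run record) so downstream stages always have input;
an explicit `k_selected` in the config skips the scan entirely and is the
recommended way to replicate a previously chosen range such as 0.20–0.21.

Randomness is controlled by one master seed; each (participant, K) cell
draws its generator from a seed keyed by the participant id and K index, so
results are independent of row order.

## Rank-based centrality analysis

Betweenness values are rank-transformed per participant with tie averaging
and **rank 1 = highest betweenness** (most central); this direction is
printed in output headers because the opposite convention is also common.
Ranks are averaged over the selected K values. Node-level Spearman
correlations against raw BDI/BAI totals use α = 0.01 uncorrected (the
node-level analysis is exploratory); under the rank convention a positive
rho means higher severity ↔ less central node.

Edge ranks are computed over the full universe of 153 pairs, with pairs
absent from a thresholded network assigned betweenness 0 and hence the
worst tie-averaged ranks. This makes "top 20%" mean the best
round(0.20 · 153) = 31 pairs for every participant regardless of K. The
influential set keeps pairs marked in strictly more than 45% of
participants. Each influential edge's mean rank is correlated with
z(BDI) − z(BAI), where both z-scores are *plain* group-standardized totals
(no sign-convention flip — the flip would only negate both terms and change
the sign of the difference); per-edge α is Bonferroni 0.05/m with m the
observed influential-edge count. Degenerate inputs (constant rank columns,
identical BDI/BAI profiles, fewer than 4 participants) are skipped with
warnings collected in the run record, never silently dropped.

## Synthetic cohorts

The generator draws n = 90 participants (default) from a multivariate
normal with the published per-measure means/SDs and block
compound-symmetry correlation: r = 0.4 among the 11 clinical measures,
r = 0.2 among the 7 neurocognitive measures, r = 0.1 across blocks
(positive-definiteness validated at construction). Marginals are Gaussian
even for count-like measures and are not clamped at zero: the pipeline
consumes only z-scores, so only means, SDs and correlations matter.

`plant_bridge` installs ground truth for the centrality–severity analysis:
per participant, bridging propensity `b = logistic(−β · z_c)` (z_c the plain
z of the coupling symptom), and the target variable's signed z is placed at
`(1−b) · (max(others) + 1) + b · midpoint-of-widest-gap`, then
back-transformed to a raw score through the sign convention and the
cohort's pre-plant column statistics. The placement itself is
deterministic; all non-target columns are left bit-identical.

### What the generator does and does not emulate — known limitations

* Real psychometric batteries are more tightly intercorrelated than the
  default blocks (MMPI-2 clinical scales share items and correlate well
  above 0.4). The weaker synthetic correlations yield more dispersed
  z-profiles, so at K = 0.20–0.21 about 82% of synthetic participants keep
  more than 15 nodes connected and about 93% reach Q > 0.3 — below the
  ≥95% prevalence a real, more homogeneous cohort can show (σ > 1 holds for
  100%). For the same reason no edge pair recurs in the top 20% of edge
  ranks for more than 45% of synthetic participants, so the influential
  edge set is typically empty on default synthetic cohorts.
* The planted bridging ground truth is attenuated by the pipeline itself:
  re-standardizing the planted column maps the placement vector through an
  affine transform (standardize(d) for any affine back-transform of d), and
  a standardized column cannot hold half its values one unit beyond the
  profile maximum. The plant therefore survives only in the signed-z space
  in which it is defined; the suite checks the *directional* recovery there
  (higher severity → peripheral target → numerically larger rank, positive
  and significant at p < 0.01), while end-to-end recovery through the raw
  CSV is near-null and is documented as such rather than patched around.
  Passing tests on synthetic cohorts therefore demonstrate correctness of
  the machinery and directional recoverability of planted structure — not
  that real cohorts will reproduce any particular effect size.

## Problem sizes and defaults

Publication-scale settings are 10,000 rewired nulls and 500 modularity runs
per network; the package's test-scale settings (100/100), used throughout
the test suite and the acceptance script, estimate the same normalizations
with Monte-Carlo error small relative to the criterion margins. The
acceptance script evaluates K ∈ {0.20, 0.21} on the default 90-participant
cohort; the full K = 0.10–0.30 scan is available through `icovnet run`.
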