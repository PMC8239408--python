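# Methods

## The two-layer causal model

`causalnpa` operates on a *two-layer* representation of curated biological
knowledge. The **functional layer** is a signed directed multigraph compiled
from causal statements written in a BEL 1.0 subset: nodes are canonical
terms (chemical abundances, proteins, protein activities, RNAs, microRNAs,
complexes, biological processes, pathologies), and each edge carries a sign
— +1 for `increases`/`directlyIncreases`, −1 for
`decreases`/`directlyDecreases`, 0 for `association` — plus the merged
evidence (citations and annotations) behind it. Duplicate statements merge
into one edge with concatenated evidence; a node pair asserted with both
signs keeps two parallel edges (biology can be context-dependent; no merge
rule is defensible) and is flagged in the compile log.

The **transcript layer** attaches signed differential-expression gene
signatures to a subset of functional-layer nodes, the *inferable nodes*
(iNodes). A gene's sign s<sub>xg</sub> ∈ {+1, −1} states whether the gene
goes up or down when node x is active. Only signed edges participate in
scoring; association edges are kept for topology and visualisation.

## Scoring

Given an expression profile β (per-gene log2 fold-changes, optional
variances), scoring proceeds in three stages.

**Activities.** For each iNode x,
a(x) = mean over measured g ∈ T(x) of s<sub>xg</sub> · β<sub>g</sub>.
Unmeasured genes are skipped; iNodes with no measured gene are excluded and
listed. The signed mean is the simplest similarity between a profile and a
signature that is linear in β, which is what makes the scaling and
sign-flip invariances exact.

**Coefficient fit.** Node coefficients c minimise

    J(c) = Σ_{(x→y), σ≠0} w_xy (c(y) − σ_xy c(x))²  +  λ Σ_{anchored x} (c(x) − a(x))²

a harmonic fit on the signed backbone anchored at the inferred activities.
Direction is used as the sign-carrier only; the penalty is symmetric in
(x, y), as a harmonic fit requires, and edge direction is preserved in all
reporting. Parallel conflicting-sign edges contribute two penalty terms,
which jointly press the pair toward zero — contradictions shrink the fit.
The normal equations are one sparse symmetric positive-semidefinite system
(a signed graph Laplacian plus anchor and ridge diagonals), solved by a
sparse LU factorisation. Connected components containing no anchored iNode
are pinned at zero by the ridge term ε·I and reported. Because the matrix
depends only on the backbone and on *which* iNodes are anchored, one
factorisation is reused across all confidence-interval draws and all
transcript-layer permutations.

**Amplitude.** NPA = mean over scoring-subgraph nodes of c(x)², and each
node contributes c(x)² / Σ c(y)². The published description of this family
of scores is qualitative (activities → coefficients → amplitude, with
consistency rewarded); the specific quadratic form used here satisfies
those contracts, admits the exact per-node decomposition that leading-node
analysis needs, and is isolated behind `compute_npa` so an alternative
quadratic form is a drop-in replacement.

Two exact invariances follow from linearity and serve as analytic test
anchors: scaling every fold-change by α scales c by α and the NPA by α²,
and a global sign flip negates c while leaving the NPA unchanged. A second
anchor is the two-node conflict (one σ=−1 edge, both ends anchored at
a=1, λ=w=1), whose normal equations give c = (1/3, 1/3) and NPA = 1/9.

## Uncertainty and significance

**Confidence interval.** Parametric Monte Carlo: each draw resamples every
gene independently as normal(β_g, v_g) (missing variances are zero) and
rescores; the interval is the empirical (α/2, 1−α/2) quantile pair over
`ci_draws` (default 1000) draws. Resampling was preferred over a
delta-method closed form because the NPA is a quadratic form of β and the
normality assumption is the natural one for log-fold-changes; zero
variances degenerate to a point interval exactly.

**o statistic** (transcript-layer permutation): every signature gene
assignment is redrawn without replacement from the measured gene universe,
keeping per-iNode signature sizes and signs; the model is rescored end to
end. Tests whether the *specific* gene-to-iNode assignment matters.

**k statistic** (functional-layer permutation): the target endpoints of the
scoring-subgraph edges are shuffled (sources, signs and weights stay with
their edges; self-loops are redrawn up to 10 times, then accepted and
logged); the transcript layer is untouched. Tests whether the backbone
wiring matters. With a single scoring edge the permutation is the identity
and p_k = 1 by construction.

Both use add-one one-sided upper-tail p-values,
p = (1 + #{NPA_perm ≥ NPA_obs}) / (1 + N), so p ∈ [1/(N+1), 1] and an
unperturbed profile (all NPAs zero, ties counted) yields exactly p = 1.
Default N = 500; the packaged simulation studies use N = 200, which keeps
the whole calibration suite around ten seconds while leaving the smallest
attainable p (1/201 ≈ 0.005) an order of magnitude below α = 0.05.

All randomness flows from a single seed through named substreams
(`ci`, `o`, `k`), so the three procedures are individually reproducible and
mutually independent.

## Leading nodes

Leading nodes are the smallest contribution-ranked prefix whose cumulative
contribution reaches the threshold (default 80%, inclusive; ties broken
lexicographically so reports are deterministic). A tolerance of 1e−9
absorbs floating-point shortfall in sums like 8 × 0.1. Each leading node
carries a direction: the sign of its coefficient (activated / inactivated /
neutral). Subnetwork extraction induces the subgraph on the leading nodes
plus any caller-supplied extras (downstream outcomes are conventionally
added regardless of LN status); ordered pairs with no direct edge but a
directed path of length ≤ 4 in the full network get an edge flagged
`indirect`, signed by the product of signs along one shortest path, with
ambiguity across equal-length paths flagged and logged.

## Topology diagnostics

Hubs are ranked by total degree with parallel (including conflicting-sign)
edges counted separately — they are distinct evidence-bearing assertions.
Bottlenecks are ranked by normalised betweenness centrality on the simple
graph obtained by merging parallel edges. Published tables of this kind
rarely state their convention, so both the undirected (normalised by
(n−1)(n−2)/2) and directed ((n−1)(n−2)) conventions can be computed
side by side (`--both-conventions`) and the convention used is written into
every output header.

## Synthetic data: what it emulates and what it does not

The generators produce random signed backbones (node ids are valid causal
terms), disjoint signed signatures covering a chosen node fraction, and
profiles in two modes. *Consistent* profiles draw latent coefficients c*
by sign-coherent propagation (breadth-first from one random root per
component, child = parent × edge sign, first-visited parent wins) and set
β_g = s<sub>xg</sub>·c*(x) + normal(0, τ²); *null* profiles are pure
noise with c* = 0. Every profile adds 50% decoy genes outside the
transcript layer, so transcript-layer permutation has off-signature genes
to draw — mimicking the bulk of a genome-wide profile.

Sign-coherent propagation satisfies every edge exactly only on *balanced*
signed graphs; a frustrated cycle makes J(c*) = 0 unattainable no matter
how c* is chosen. `generate_network(acyclic=True)` therefore draws a
random recursive forest skeleton, and the reference study conditions use a
15-node spanning tree with balanced edge signs (p_negative = 0.5), 80%
iNode coverage and 5 genes per signature, noise τ = 0.1. These choices are
what make "consistent by construction" literally true: a balanced backbone
means noise-free data are exactly representable (the τ=0 identity test),
balanced signs give the sign-diverse activity pattern that backbone
rewiring must disrupt (the power of the k statistic), and dense signature
coverage mirrors scoring-oriented curated networks, where rewiring cannot
manufacture amplitude by recruiting unanchored nodes.

Under these conditions the packaged studies check: null calibration of the
o statistic (rejection rate at α=0.05 within [0.02, 0.10] over 200
replicates — permutation tests are exact under exchangeability, so ≈5% is
expected), power (p_o and p_k ≤ 0.05 in ≥19 of 20 generator seeds), and
latent recovery (median correlation between fitted and latent coefficients
≥ 0.9 over 20 seeds).

What the generator does **not** emulate: count-level noise models,
batch/platform effects, correlated genes within and across signatures,
overlapping signatures, unbalanced curated topologies, or realistic
zebrafish expression. Passing these studies therefore demonstrates the
statistical machinery is correct and calibrated on data satisfying the
model's assumptions — not that any particular real dataset will score
significantly.

## Numerical choices and degenerate inputs

- Ridge ε = 1e−9 on the fit diagonal: pins unanchored components at zero
  and guarantees a nonsingular system; it perturbs anchored solutions by
  O(ε), well inside the 1e−6 oracle tolerance.
- Anchor weight λ = 1 by default: activities and edges are equally
  credible absent contrary information; λ is exposed in `FitConfig`.
- Edge weights default to 1.0 (the source material states none); a sidecar
  weight can be set per edge.
- Empty statement list → empty network with a warning, not an error.
- All-zero coefficients → NPA 0, contributions undefined and flagged; the
  leading-node decomposition refuses to run.
- Gene identifiers are upper-cased for matching between layer and profile;
  original case is preserved on output.
- Unknown grammar tokens fail loudly (distinct error types naming the
  offending span) rather than being skipped.

## Known limitations

- The exact published NPA functional lives in an external companion
  package and is not printed in the source literature; this package's
  quadratic form matches the stated contracts but is not guaranteed to
  reproduce its numerical values.
- Backbone permutation (k) preserves sources, signs and weights but not
  the in-degree sequence; the scheme is documented and pluggable.
- Statement-per-edge BEL export cannot represent isolated nodes; use the
  JSON or GraphML exports when isolated nodes must round-trip.
- Scores are comparable across treatments within one network and dataset;
  comparison across networks is explicitly out of scope.
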