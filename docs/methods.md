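# Methods

## Model and assumptions

The package infers co-expression structure from a probesets × arrays matrix
of normalized, log-scale intensities (e.g. RMA output). It assumes
normalization and array-level QC happened upstream; the matrix is taken as
given. Pearson's *r* over the arrays of the (sub-)compendium is the only
similarity metric, so relationships are assumed approximately linear on the
log scale.

The HRR transform replaces raw correlations with reciprocal rank positions:
rank(A, B) is B's position in A's partner list ordered by decreasing *r*
(rank 1 = strongest), and HRR(A, B) = max(rank(A, B), rank(B, A)). Ranks are
only comparable between genes correlated over the same array set, which
drives two design rules: probesets with missing values are dropped from the
sub-compendium being built (rather than pairwise-complete correlation), and
any gene subsampling must happen before network construction, never after
ranking — HRR values scale with network size (the null 1% cutoff grows
roughly like 0.012 × n, so a cutoff estimated on a subsample applies only to
networks of that size).

A note on rank direction: partner lists are ranked by *decreasing* r, so
that rank 1 is the closest partner and small HRR means strong mutual
co-expression. This is the only direction consistent with the way HRR
networks are used (strong partners at small values, thresholds of the form
HRR ≤ cutoff).

Ties in *r* are broken by ascending probeset identifier. This makes every
result — ranks, HRR, guide clusters, edge lists — bit-identical across runs,
platforms and block sizes. Negative correlations participate in ranking and
simply land at large ranks.

## Blocked computation

`hrr_network` never materializes the dense float correlation matrix: rows
are processed in fixed-size blocks (correlation block → integer ranks,
discarding the floats), and the HRR symmetrization and guide-cluster
selection are likewise blocked. Block size is a memory knob only; results
are identical for every value (regression-tested). Rank/HRR matrices are
stored at the smallest integer width that holds n − 1 (int16 up to 32k
genes), so a 30,217-probeset compendium needs ~3.7 GiB for the two integer
matrices and runs in a few minutes on one CPU.

## Thresholded networks

Thresholding keeps all pairs with HRR ≤ cutoff and assigns every retained
edge a single uniform weight: the five published pairs (10 → 0.2, 20 →
0.067, 30 → 0.04, 40 → 0.028, 50 → 0.022) verbatim, and w = 1/(cutoff − 5)
for other cutoffs — the closed form those five pairs satisfy. The map has a
pole at 5; the valid-but-extreme cutoffs 2–5 get unit weight 1.0 (the
package's own total extension; MCL results are invariant to a global weight
rescaling, so the choice only matters for export consistency). Nodes that
lose all edges are reported separately rather than silently dropped.

## Permutation significance

The null model shuffles each gene's values independently across arrays —
destroying all inter-gene correlation while preserving every gene's marginal
distribution — and recomputes the full HRR matrix per permutation (default
100, seeded). All pairwise HRR values are pooled into one histogram; the
cutoff at level α is the largest h with empirical P(HRR ≤ h) < α (α ≥ 1
returns n − 1), and per-value p-values use the add-one correction
(count ≤ h + 1)/(total + 1) so no value gets p = 0. Pooling over all pairs
(rather than per-gene minima) matches the use of a single network-wide
cutoff. Column-label permutation was rejected: it preserves all correlations
and is useless as a null here.

Detectability bound: a module of size s has internal HRR up to s − 1, and
the null cutoff at 1% is ≈ 0.012 × n, so a 10-gene module is only entirely
below the 1% cutoff in compendia of roughly 750+ genes. The signal-detection
test therefore uses a 1000-gene compendium.

## MCL

The Markov Cluster Algorithm is implemented from scratch on scipy sparse
matrices: add self-loops, column-normalize, then iterate expansion (matrix
power, default 2), inflation (entrywise power I with renormalization) and
pruning (entries < 1e−5 removed, renormalized) until the maximum entry
change falls below 1e−8 or 100 iterations. Clusters are the weakly connected
components of the attractor structure of the converged matrix; a node
flowing to several attractor systems joins the lowest-numbered one, and
non-convergence yields a warning plus clusters from the last iterate.
Pruning/convergence defaults follow common MCL practice; on desk-scale
graphs results are insensitive to an order of magnitude either way
(covered by a sensitivity test). Cluster ids are assigned by descending
size, then lexicographically smallest member, so ids are stable.

Self-loops default to each node's maximum incident edge weight (1.0 for
loopless columns), not a fixed 1.0. The pipeline's edge lists carry small
uniform weights (0.04 at HRR30); a fixed unit loop would dominate every
column, freeze the flow at the identity and dissolve every cluster into
singletons. Scaling loops with the column keeps loop and edge flow on the
same footing whatever the weighting — this matches the loop heuristic of the
standard mcl implementation. A constant loop weight remains available as a
parameter.

Clusters with fewer than 3 members are moved to the unassigned set: pairs
and singletons carry no usable enrichment signal.

Inter-cluster connectivity is edge density between member sets:
score(A, B) = (#edges with one endpoint in each) / (|A| × |B|), with pairs
flagged connected when the score strictly exceeds the threshold (default
0.03). This is a documented choice of formula; it reproduces the magnitude
at which connected cluster pairs are typically reported.

## Enrichment and clustering performance

Per cluster and GO namespace, each term with ≥ 1 annotated member gets an
upper-tail hypergeometric p-value; BH adjustment is applied within the
cluster × namespace family (BP, MF and CC corrected separately, the default
behaviour of per-cluster GO tools); a term is significant at FDR < 0.05 with
≥ 2 annotated members. The background universe defaults to the compendium's
probesets carrying ≥ 1 annotation in the tested namespace — including
never-annotatable probesets would deflate p-values — with `universe="all"`
available to use the full probeset set.

Specificity = fraction of retained clusters with ≥ 1 significant term;
sensitivity = fraction of distinct (term, namespace) annotations on
background genes significant in ≥ 1 cluster; F = harmonic mean, defined as 0
when both components are 0 so sweep rankings stay total. Guide clusters are
scored the same way with the guide included as a member.

## Expression specificity (ESI / cESI)

ESI is a two-stage standardization: z-score each array column across genes
(removing per-array location/scale), then z-score each gene row of that
output across arrays. The thresholds > 1 (well expressed) and > 5
(specifically expressed) are then in SD units; a one-hot expression pattern
over n arrays attains the closed-form maximum √(n−1). Standard deviations
use the population (n) denominator, which makes that closed form exact;
`ddof=1` switches to sample SD. Rows with no variance after stage 1 get
ESI 0 everywhere. Stage 2 operates on the stage-1 output (the sequential
reading of "within, then between"); `between_on="raw"` applies it to the raw
values instead. cESI of a cluster in an array is the fraction of members
with ESI > 1; per condition group it is the mean of the per-array fractions
in the group, so the group-size-weighted mean over groups equals the
all-array fraction.

## Synthetic data

Modules follow a single-factor model: member expression = base + c·z + ε
with a shared latent z per active array and independent Gaussian noise ε
(sd `noise_sd`). The loading is solved from the requested within-module
correlation r via r = c²/(c² + σ²), giving a closed-form target that the
realized correlations are tested against. Condition-restricted modules
co-vary only in arrays matching their metadata selector and are additionally
raised by `active_offset` (default 4.0 log2 units ≈ 16-fold induction,
typical of strongly tissue-specific transcripts) in those arrays — induction
is what makes such modules visible to ESI/cESI, and the on/off contrast
itself contributes realistic co-expression over the full compendium.
Per-array additive offsets (sd 0.25) emulate residual scale effects.
Annotations attach each module's planted terms to a configurable fraction of
its genes plus uniformly scattered background terms.

Module size and the HRR cutoff interact: a module of size s fills only ranks
1..s−1 of each member, so at threshold HRR ≤ c with c ≥ s the members'
remaining top-c ranks necessarily recruit reciprocal edges into the noise
background, tethering the module to the global hairball (the null HRR ≤ 30
graph has mean degree ≈ 24 at any compendium size) — low-inflation MCL then
absorbs it. Recovery studies therefore plant modules wider than the cutoff
(35 genes at HRR30), which is also the regime of real co-expression modules,
whose reported sizes exceed typical cutoffs severalfold. With that design
the end-to-end pipeline (HRR30 → MCL at I = 1.3) recovers planted modules
with adjusted Rand index 1.0 and their planted terms at FDR < 0.05 in 10/10
seeds.

What the generator does not emulate: probe-level effects, correlated batch
structure beyond additive array offsets, heavy-tailed intensity
distributions, and partially overlapping or hierarchical modules. Passing
recovery tests on this generator demonstrates the machinery is correct and
calibrated, not that every real compendium is as separable.

## Numerical and degenerate-input choices

- Zero-variance probesets make Pearson r undefined and are a hard error
  listing the offending ids (callers drop them explicitly; nothing is
  silently imputed).
- Fewer than 3 arrays (globally or after metadata selection) is an error:
  correlation-based ranking is degenerate below that.
- Expression TSVs are written with %.17g and read with round-trip float
  parsing, so write → read is bit-exact.
- All randomness (generator, permutations, subsampling) flows through
  numpy's seeded `default_rng`; MCL and every transform are deterministic,
  so equal inputs give byte-identical outputs.

## Problem sizes used in the test suite

Test and acceptance workloads are sized for a single CPU: the guide-cluster
accounting check runs the full 30,217-probeset network (the array platform's
probeset count) over 12 arrays with blocked ranks; calibration uses 300
genes × 20 arrays × 100 permutations; recovery studies use 300 genes ×
40 arrays over 10 seeds. These sizes were chosen as the smallest that
exercise the claims they test.
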