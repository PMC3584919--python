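# Methods

## Problem and model

The package annotates enzyme function (four-field EC numbers) for protein
structures by transferring labels across matches of small functional-site
templates, optionally followed by global label diffusion on the network of
all matches. Its inputs are Cα traces (PDB), per-residue evolutionary
importance ranks (produced upstream by an evolutionary-trace-style analysis;
this package consumes them as plain tables), solvent-accessibility tables,
and an EC annotation table. The underlying assumptions are: (i) function is
carried by a few key residues whose geometry is conserved even when the fold
is not; (ii) those residues are evolutionarily important in *both* partners
of a genuine match; (iii) matches by chance lack the evolutionary signal and
can be filtered out.

## Pipeline conventions and parameters

**Residue identity.** Residues are addressed by author sequence number
within a chain, never by 0-based index. Insertion-coded residues are skipped
on input (with a warning); altlocs resolve to highest occupancy, then first
altloc id.

**Percentile ranks.** `pct(i) = #{j : rank(j) ≤ rank(i)} / N`, the
right-continuous rank coverage in (0, 1]; ties share the maximal value. It
is invariant under strictly monotone transforms of the raw ranks, which is
the property the downstream features rely on.

**Surface.** A residue is exposed when its accessible area is strictly
greater than 2 Å². When no accessibility table exists, a coarse Cα
neighbor-count proxy (radius 10 Å, lowest 60% of counts = exposed) is
available; it is clearly a fallback, and all shipped fixtures carry explicit
areas so nothing here depends on it.

**Clustering.** The cluster rule is single linkage on Cα–Cα distance with an
8 Å cutoff — a Cα-level proxy for heavy-atom contact, the only option when
side chains are out of scope. Coverage is swept in steps of 0.01; the
primary cluster is the first to hold ≥ 11 exposed residues. "Additional"
clusters (multiple-template modes) must share no residue with the primary,
hold at least `template size` exposed residues, and contain an exposed
residue ranking better than a configurable statistic of the primary's
exposed ranks — `best`, `median` (default), or `worst`. The comparator is a
genuine design freedom: the qualitative requirement is that secondary sites
be *important*, and the median is the middle reading. Cluster centers of
mass use all members, not only exposed ones.

**Template picking.** Deterministic greedy rule: first the best-ranked
member nearest the cluster center (ties → smallest residue number); then,
iteratively, among members in the best remaining exact-rank band, the one
nearest the midpoint between the selected residues' center of mass and the
cluster's. Rank is prioritized over distance, mirroring the "closest
best-ranked" choice of the first residue. A consequence worth noting: the
5-residue template of a cluster is always a prefix of its 6-residue
template. Template positions accept, besides the native residue type, any
type appearing at that position in an alignment row pattern that is
non-gapped across all template columns and occurs at least twice.

**Matching.** Depth-first paired-distance search with a 2.5 Å all-pairs
tolerance; a target residue may fill only one template position. The
enumeration counts expanded nodes and aborts with an explicit
`partial` flag above a cap (default 10⁵) — poly-alanine-like compositions
can otherwise explode combinatorially. RMSD is least-squares superposition
(Kabsch, no reflection); the rotation is applied explicitly rather than via
the `E₀ − 2Σσ` closed form, which loses ~1e-7 of precision to cancellation
on near-congruent sets. When several assignments connect the same
template/target pair, the lowest-RMSD one feeds voting and networks; all
assignments remain available in the raw search result.

**Filtering.** Self-matches and RMSD > 2 Å (strict) are removed first. The
significance classifier is an RBF SVM over standardized 7-vectors
`[rmsd, r₁..r₆]`; hyperparameters come from a small grid (C ∈ {1, 10, 100},
γ ∈ {scale, 0.1, 1}) with stratified 5-fold CV, deterministic under the
seed. Five-residue matches get a virtual sixth rank difference equal to the
mean of the other five. The SVM is trained on fixture-generated matches with
provenance recorded — there is no pretrained model — so every claim
involving it is a property of the pipeline, not a reproduction of an
external classifier. A transparent threshold rule (rmsd ≤ 2 Å and mean rank
difference ≤ 0.25) is provided as a fallback classifier. Reciprocity is
protein-level: any template of A matching B significantly and any of B
matching A suffices; a stricter site-level option requires the two directed
matches to involve overlapping residue sets.

**Voting.** One vote per unique reciprocal partner per full EC it carries
(multi-EC partners vote once per EC). Strict plurality wins; ties abstain
rather than guess. The iterative combination runs modes in decreasing
accuracy order (default 6R, 5R, M6R, M5R) and takes each query's first
non-abstaining answer.

**Sequence-identity baseline.** Global Needleman–Wunsch alignment
(BLOSUM62, gap open −11 / extend −1); identity = identical aligned pairs /
aligned non-gap-pair columns; the top target's annotations transfer (ties to
the smallest chain id).

## Network diffusion

Edges carry `s = ½[(rmsd − μ_r)/σ_r + (ET − μ_ET)/σ_ET]` with population
statistics over all network matches, so the mean `s` is zero by
construction. Diffusion needs nonnegative weights and `s` is signed, so a
monotone decreasing transform is applied; the default is `W = exp(−s)`
(order-preserving, positive, better-than-average matches get weight > 1),
with `max(0, −s)`, rank-based, and fixed-weight alternatives. Zero variance
in either component is refused with a pointer to the fixed-weight fallback.

The objective is

    H(f) = Σᵢ (fᵢ − yᵢ)² + α Σ_{i<j} w_ij (fᵢ − fⱼ)²,

with the smoothness sum counting each unordered pair once; its unique
minimizer solves `(I + αL) f = y`, which is symmetric positive definite for
any valid `W` and α > 0 (dense Cholesky below 500 nodes, sparse
factorization above). α defaults to 1.0 and trades label fidelity against
smoothness. Labels are closed-world: for a given function, `y = +1` on
nodes annotated with it, `−1` on nodes carrying only other annotations, `0`
on unannotated nodes. Confidence z-scores standardize `f` over the unknown
nodes (population SD; at least two unknowns required; constant `f` yields
all-zero z with a warning). Ties in z break by larger `f`, then
lexicographically smaller label.

## Evaluation

Accuracy = TP/(TP+FP), sensitivity = TP/(TP+FN) with FN = "no prediction",
exactly as printed in the annotation-transfer literature; note that false
positives then appear in neither the sensitivity numerator nor denominator,
so `coverage = (TP+FP)/N` is reported alongside. F-measure uses β = 0.5
(accuracy-weighted). The accuracy-vs-sensitivity sweep treats predictions
below each confidence threshold as abstentions and anchors the curve at
sensitivity 0 with the top prediction's accuracy; AUC is the trapezoid over
sensitivity. Cumulative accuracy can legitimately dip as the threshold
lowers, so no monotonicity is asserted.

## Synthetic benchmarks: what they emulate and what they do not

Each function gets a rigid "site motif" (connected Cα arrangement,
3.8–7 Å neighbor spacing, distinct residue types); every protein of that
function embeds a rotated/translated copy jittered by N(0, 0.2 Å) per
coordinate. Around each site, filler residues at 5.2–7.4 Å let the cluster
reach the 11-exposed-residue requirement; decoys (≥ 5 Å from site points,
variable count so chain lengths — and hence percentile ranks — differ across
proteins) supply background. Each protein also carries a *false site*: a
geometric copy of a different function's motif with unimportant ranks —
exactly the geometric-coincidence false positive the SVM must learn to
reject, and the main source of negative training examples (random decoy
geometry almost never passes a 6-point, 2.5 Å paired-distance search).
Coordinates are written at PDB precision (3 decimals), making outputs
bit-reproducible from the spec seed and putting a ~2×10⁻³ Å floor under
"zero" RMSD.

In two-site fixtures the sites receive interleaved top ranks (site 1:
1,3,5,…; site 2: 2,4,6,…) so both clusters are genuinely important and the
secondary cluster passes the default median comparator; scrambling the
primary site's geometry in a fraction of proteins (`corrupt_primary_fraction`)
creates the population on which single templates fail and secondary
templates rescue.

Default study conditions: 20 proteins, 4 functions, site size 6, jitter
0.2 Å, rank noise 0.25, ~18–23 decoys — small enough that the full
pipeline, including every pairwise search in both directions, runs in
seconds on one core, large enough that each function has five exemplars and
votes are 4-to-0 rather than 1-to-0.

What passing these benchmarks shows: the geometric search is exhaustive
within tolerance (verified against brute-force enumeration), the diffusion
solver reaches the true minimizer (verified against a generic numerical
minimizer), the selection/filter/vote logic implements the stated rules, and
the multiple-template and network mechanisms produce their qualitative
effects under controlled noise. What it does not show: performance on real
structures, where ranks are noisy in structured ways, sites deviate
non-isotropically, surface assignment is imperfect, and the annotation space
is vastly larger. No number computed on these fixtures is comparable to a
benchmark on curated structure sets.

## Known limitations

* Only Cα geometry; no side-chain or chemical-environment checks.
* Ranks are required input; the evolutionary analysis that produces them is
  out of scope, as is running DSSP (accessibility is consumed as input, with
  a coarse neighbor-count fallback).
* Ranks are restricted to resolved residues; unresolved positions simply do
  not participate.
* The matcher does not constrain matched target residues to the surface.
* Single-model PDB files only; no mmCIF, no NMR multi-model handling.
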