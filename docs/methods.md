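# Methods

This note records the model, its assumptions, the defaults and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and assumptions

Fragment left ends are modelled as a homogeneous Poisson process with rate λ
(fragments per base) on the *test* genome — the Lander–Waterman model. The
model assumes clean breaks (no novel sequence at junctions), independent
mapping errors with a constant per-fragment probability `p_err`, and a
fragment-length distribution summarized by `[L_min, L_max]` and its mean
`L_avg`. Three Poisson laws follow and drive all likelihoods:

| quantity | mean | role |
|---|---|---|
| point coverage `n(p)` | `λ_c = λ·L_avg` | breakend read-depth (beRD) terms |
| breakend-straddling fragments `k` | `λ_d = (L_avg − 2·rl)·λ` | discordant support |
| interval coverage `n(I)` | `λ_I = λ·(b_min − a_max + L_avg)` | deletion read depth |

`λ_d` counts fragments whose *inner gap* (the unsequenced middle of the
fragment) spans the junction: a fragment of length L contributes a window of
`L − 2·rl` start positions, whence the mean. Heterozygous variants halve the
rates (`λ_c/2`, `λ_d/2`, `λ_I/2`) because only one haplotype carries the
adjacency.

## Coordinates and the breakend trapezoid

Coordinates are 1-based and fully closed (SAM). For each read the
breakpoint-proximal coordinate is the rightmost aligned base on `+`, the
leftmost on `−`; `sign = +1` for a forward read. With proximal coordinates
`x < y`, the quantity `sign(x)(a−x) + sign(y)(b−y)` evaluated at the true
adjacency `(a, b)` is exactly the fragment's inner gap, so the trapezoid band
is `[L_min − 2·rl, L_max − 2·rl]`. This is algebraically identical to the
classical formulation in terms of the fragment's outer endpoints with band
`[L_min, L_max]`, but it makes the band and `λ_d = (L_avg − 2·rl)·λ` refer to
the same quantity and — decisive for testing — the simulator's true breakend
pair of an in-range fragment lies *exactly* inside the trapezoid. The
signature bounding box (`sign(x)(a−x) ≥ 0`, `sign(y)(b−y) ≥ 0`) places the
breakends on the breakpoint-proximal side of each read.

Classification: a pair is concordant iff it has convergent orientation for the
technology (Illumina: left read `+`, right read `−`; SOLiD: same strand with
the first-sequenced read in the strand-appropriate position) and outer span in
`[L_min, L_max]`. Discordant signatures: too-long convergent → deletion-type;
`+/+` and `−/−` → the two inversion types; different chromosomes →
translocation. Everted pairs *and too-short convergent pairs* are labelled
`divergent` (insertion/duplication-like evidence); the signature enumeration
has no insertion class and these are not clustered.

## Exact geometry

Polygon arithmetic uses `fractions.Fraction` vertices and integer half-plane
clipping (Sutherland–Hodgman); there is no floating-point tolerance, so
degenerate (zero-area) polygons and boundary contacts are decided exactly.
Within one (chromosome pair, signature, strand pattern) stratum every polygon
— including any intersection of polygons — is of the interval form
`{a ∈ A, b ∈ B, a + q·b ∈ S}` with `q = sign(x)·sign(y)`, which is closed
under intersection; pairwise and subset feasibility therefore reduce to exact
integer-interval checks, used for fast clustering and scoring.

Clustering: connected components of the pairwise trapezoid-overlap graph are
refined into *maximal* fragment subsets with a non-empty common intersection.
Convex sets in the plane do not satisfy "pairwise ⇒ common" (three translates
of the trapezoid can pairwise intersect with no common point), so an alignment
may genuinely belong to several maximal groups; the mapping-matrix sampler
resolves such ties. Components of ≤ 12 fragments are enumerated exactly by a
pruned subset tree; larger components use a deterministic grow-from-each-seed
heuristic (complete whenever the whole component shares a common point — the
generic case for a real variant) with duplicate and non-maximal results
removed. Output is sorted canonically, so clustering is invariant under input
permutation.

## Likelihoods

`poisson_log_pmf` uses the gamma-function extension of `log k!` so that
mapability-scaled non-integer counts `n̂(I) = n(I)/(α + β·R(I))` (α = 0.3,
β = 0.7) evaluate smoothly; rounding would introduce rank discontinuities in
Λ. Discordant counts are never mapability-scaled.

The generic breakend score maximizes each copy-number hypothesis over
`(a, b) ∈ B`. Coverage `n(a)` is piecewise constant between fragment-extent
change points, so the plane decomposes into rectangular cells of constant
`(n(a), n(b))`; each hypothesis is maximized over the cells that intersect `B`
(an exact interval test in the canonical form), which equals exhaustive
integer enumeration of `B` but runs in O(cells). Each hypothesis is maximized
independently and the ratio taken afterwards, which is conservative relative
to maximizing the per-pair ratio. Deletion-type candidates with a well-formed
interval (`a_max ≤ b_min`) use the interval read-depth model; an inverted
implied interval (typical for a single fragment supporting a short deletion)
falls back to the generic breakend model, logged at debug level.

Coverage cap: concordant coverage above the `0.9999` Poisson quantile forces
`c = 0`. The reference mean is the one relevant to each scorer — `λ_c` for
breakend terms (applied per candidate pair; the SV hypotheses maximize over
uncapped pairs only) and `λ_I` for the deletion interval (applied to the
scaled count). Inside the MCMC target, a capped column contributes its null
(`c = 0`) likelihood rather than −∞, so chains over components containing
capped candidates remain well defined; such calls are reported with `ĉ = 0`
and filtered by the `log Λ > 0` rule.

Defaults: `p_err = 0.01` (configurable, echoed in output headers); `η = 1e−3`
(the exponential prior on the number of variants; results are insensitive in
the tested range); λ supplied per run or estimated as
(#concordant fragments)/(genome length).

## The mapping-matrix sampler

Target: `P(M|A) ∝ η e^{−η V(M)} ∏_{j: S_j>0} max_{c>0} P(V_j|C_j=c)
∏_{unassigned} p_err`. Each iteration self-loops with probability 1/2, then
draws uniformly among the move classes *currently possible*; the proposal
probability `q(M, M′)` sums every class able to produce the transition under
that uniform class weight, and the acceptance ratio uses `q` in both
directions, computed only from the rows and columns that differ. Details that
the generic description leaves open, and the choices made:

* **N move on a single-column row**: dropping is forced (probability 1 given
  the row is selected); the alternative reading — dropping only with
  probability `p_err` — would leave the move able to propose no change.
* **Zbar / S conditioning**: the "retry until non-empty" loops are implemented
  by conditioning the per-row Bernoulli(1/2) pattern on being non-empty, so a
  specific pattern over r eligible rows has probability `(1/2)^r/(1−(1/2)^r)`;
  the same conditioned probability is used inside `q`, keeping proposal and
  density consistent (a uniform distribution over the *number* of moved rows
  would not match the sampling recipe and would break detailed balance).
* **S pair selection**: pairs `(j, k)` are weighted by `|R_jk(A)|` and
  normalized over pairs with at least one swappable entry in the current
  state.
* **Fixed rows**: rows with a unique possible column are fixed by default
  (`sample_unique=False`); their support enters each column as a constant
  offset and the chain runs on the remaining rows.

Independent connected components of the bipartite fragment–variant graph are
sampled separately; the target factorizes over components (verified as an
identity in the tests), so merged marginals equal full-matrix sampling.
Components whose edge count exceeds a ceiling (default 10⁶) fall back to
assigning unique rows only. Chain defaults are 10⁵ burn-in and 9×10⁵ sampling
iterations; summaries (per-cell marginals `m̄_ij`, per-column support-count
distributions, and the chain average of `Λ(V, M)` held as a log-sum-exp to
avoid overflow) are accumulated by sojourn counting and are bit-reproducible
given the seed.

For validation, the package can also assemble the chain's exact one-step
kernel `p(M, M′) = q·α` over an enumerated state space, check the detailed
balance identity `π(M)p(M,M′) = π(M′)p(M′,M)` directly, and simulate long
trajectories from that kernel through a compiled inner loop (numba when
available, pure Python otherwise). The acceptance suite enumerates every
binary alignment matrix with ≤ 4 fragments and ≤ 3 variants (2,924 patterns),
reduces them to 111 canonical classes under row/column permutation — exact
because all columns carry the same likelihood in that check — and compares the
9×10⁵-sample empirical distribution of each class's chain with the enumerated
posterior.

## Reporting

The default reporting path is the consensus matrix `M̄(τ)`: a fragment is
assigned where its marginal `m̄_ij ≥ τ` (τ = 0.5, inclusive, which guarantees
at most one qualifying column per fragment); every supported candidate is
rescored at its consensus support, filtered by `log Λ > 0` (and optionally a
minimum support of 2, the stricter reporting variant), ordered by score and
pruned. The chain-averaged likelihood ratio is carried as an auxiliary column.
Pruning is greedy best-first within each (chromosome pair, SV type): two calls
are redundant when their intervals overlap by ≥ 50% of their union or one
contains the other; the processing order (descending score, ties by
coordinates) makes it deterministic and idempotent. When every fragment is
unique the sampler is a point mass and the MCMC path reduces exactly to direct
scoring (the high-quality mode), which the tests assert as frame equality.

## Evaluation

Calls match known variants under the double-uncertainty metric: both closed
uncertainty intervals (`[x ± ε]` vs `[a ± δ]` and the right-hand counterparts)
must intersect; touching endpoints count. Defaults: ε = `L_max/2`; δ = 0 for
breakpoint-exact truth, δ ≈ 200 for paired-read-derived truth. When several
calls match one truth variant the variant counts once and the best-scoring
match provides the genotype. The *false-call rate on SV-free control regions*
is defined symmetrically: control intervals (one per planted variant, same
length, midway between consecutive variants) are treated as dummy variants and
the rate is the fraction "detected" under the same metric — i.e. the caller's
sensitivity to variants that do not exist.

## The simulator

The generator emulates exactly the statistical structure the model assumes: a
single reference chromosome; a diploid test genome with non-overlapping
deletions and inversions (homozygous on both haplotypes, heterozygous on one);
per-haplotype Poisson fragment sampling at rate λ/2 so heterozygous breakends
see `λ_c/2`; fragment lengths `Normal(L_avg, sd)` rounded and truncated below
at `2·rl`; reads projected through piecewise-linear coordinate maps. Reads
overlapping a junction are dropped together with their fragment (an aligner
would clip or fail them), producing the local coverage drop at breakends; a
fraction `p_err` of fragments have their placement replaced by a uniform
random (discordant) one; reads fully inside configured duplicated blocks gain
the homologous placement, creating ambiguous fragments, and the matching
mapability track is 0 inside repeat copies and 1 elsewhere. Defaults are the
benchmark conditions: 5 Mb reference, λ = 0.3 (≈ 60× fragment coverage),
`L_avg` = 200 bp, sd = 20 bp, 50 bp reads, `p_err` = 0.01; the default variant
panel holds 50 deletions (150–2,500 bp) and 10 inversions (500–5,000 bp), half
homozygous / half heterozygous within each type.

What the simulator does *not* emulate — hence what passing tests do not show
about real data: base-call errors and quality-dependent alignment, GC and
library-preparation coverage bias (real depth is over-dispersed relative to
Poisson), realistic repeat families and mapability structure, micro-homology
or novel insertions at junctions, and multi-library mixtures. The model's
per-library bounds and pluggable coverage scaling are the intended hooks for
those effects.

Mixed-library input (several read groups with different fragment-length laws)
is supported by keying `LibraryStats` on a `library` column: each alignment is
classified and its trapezoid built against its own library's bounds, while the
fragment rate λ and the pooled mean length drive the (global) likelihood, as a
single sequencing experiment implies.

Library bounds are estimated from the unique convergent-pair span
distribution by the 0.1%/99.9% quantile rule (a `mean ± k·sd` rule is
selectable). Because convergent pairs straddling deletions inflate the upper
tail, spans are first trimmed to a ±10·MAD band (≈ ±6.7σ for a normal law)
around the median — wide enough to leave the quantiles of the genuine length
law untouched.

## Problem sizes used in the checks

The acceptance suite runs the sampler-exactness sweep at the full stated scale
(9×10⁵ samples per canonical instance), the coverage-law check on a ~1 Mb
simulation with 40 homozygous junctions, and the end-to-end recovery on the
full 5 Mb benchmark; the end-to-end chain lengths are 5×10³ burn-in / 5×10⁴
samples, ample for the small components the benchmark produces (the
genome-scale defaults 10⁵/9×10⁵ remain the library defaults). The coverage-law check sets
`p_err = 0` to test the fragment process in isolation. Unit tests use smaller
chains and genomes chosen so each statistical assertion retains ≥ 3σ margins.

## Known limitations

Single-fragment candidates over low-coverage stretches can reach `log Λ > 0`
(the breakend maximization finds coverage dips); they are the dominant novel
calls in the benchmark and are removed by `min_support=2`. Duplication and
insertion hypotheses are out of scope (`divergent` evidence is classified but
not clustered); translocation clustering handles one chromosome pair at a
time. Read depth is strictly Poisson; over-dispersed models would slot in at
`poisson_log_pmf` but are not provided.
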