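# Methods

## The model

`accelscan` tests conserved genomic elements for lineage-specific
substitution-rate acceleration on terminal branches of a phylogeny. The
starting point is a neutral, time-reversible nucleotide model (tree with
branch lengths, equilibrium frequencies π over A,C,G,T, and a reversible
rate matrix Q), supplied in PHAST `.mod` format. On read, Q is always
renormalized so that −Σᵢ πᵢQᵢᵢ = 1; branch lengths are then expected
substitutions per site, and a single free tree-scale parameter ρ > 0
absorbs overall rate variation. The *null model* for an element has ρ as
its only free parameter.

Each candidate lineage *l* (a terminal branch; internal branches are out of
scope) carries two optional nonnegative parameters:

* **S_l** — unbiased acceleration (positive selection or loss of
  constraint),
* **B_l** — GC-biased acceleration (GC-biased gene conversion, gBGC).

Both act through the eventual fixation probability of a mutant with
population-scaled coefficient *x* in the weak-mutation limit,

    f(x) = x / (1 − e^(−x)),    f(0) = 1,

which is strictly increasing and smooth (a series expansion is used for
|x| < 1e−4). On an accelerated branch the off-diagonal rates become

    Q'_ij = Q_ij · f(S + B·δ_ij),

with δ_ij = +1 for weak→strong substitutions (A/T → G/C), −1 for
strong→weak, and 0 within a class. The combined argument S + B·δ follows
the composition of a selection coefficient with a conversion disparity in
the underlying population-genetic model. Q' is deliberately **not**
renormalized: acceleration must increase the expected substitution count,
not redistribute it. With B = 0 the matrix is exactly f(S)·Q, so unbiased
acceleration is a pure rate scaling — a fact the simulator's calibration
exploits. With B > 0 the modified chain is no longer reversible; since
modifications apply only to terminal branches, the likelihood remains
invariant to root placement among the unmodified internal nodes.

## Likelihood engine

Alignment log-likelihoods use the standard pruning recursion over unique
site patterns, with per-pattern rescaling of partial likelihoods to avoid
underflow. `N` and `-` both contribute all-ones partials (fully missing),
so an all-missing alignment has log-likelihood exactly 0 and a fully
masked row is equivalent to deleting the species. Neutral branch
transition matrices are computed from the symmetric eigendecomposition
D^{1/2} Q D^{−1/2} (valid for reversible Q); modified branches use a dense
matrix exponential. Tests verify the engine against exhaustive
enumeration over internal-node states on trees with up to five leaves at
1e−10.

Before fitting, the background frequencies are adapted to the element's
local GC content, measured over alignment rows *excluding* a configurable
species set (by default the tested lineages; in an ape scan one would
exclude all primates). Writing g for the local GC fraction, the adapted
π′ preserves the within-class ratios π_G:π_C and π_A:π_T with
π′_G + π′_C = g exactly; Q is rebuilt from the exchangeabilities
s_ij = Q_ij/π_j with the new frequencies and renormalized to unit rate.
The renormalization choice is ours (the alternative — keeping the raw
scale — merely shifts ρ̂, since ρ multiplies all branches); g is clamped
to [1e−6, 1−1e−6] so all frequencies stay positive.

## Model selection

For *n* lineages there are 2^(2n) models (1024 for five), one per subset
of freed parameters, organised as a DAG whose edges add exactly one
parameter. Traversal is breadth-first by complexity in a deterministic
order (lineage-alphabetical, S before B), so results are reproducible
bit-for-bit. An edge is tested only if its parent is the null model or was
itself recovered; each tested child is fit once (warm-started from its
best eligible parent, new parameter initialised at 1e−3) and annotated
with the **maximum** LRT p-value over its tested incoming edges. Traversal
stops at the first level that recovers nothing.

Because each added parameter is constrained to [0, ∞), the df=1 LRT null
is the boundary mixture ½δ₀ + ½χ²₁: p = 1 when Λ = 2ΔlogL ≤ 0, otherwise
half the χ²₁ tail. Nodes with annotation < P_cut (default 0.01) form the
recovered set. If the recovered set is totally ordered by inclusion (a
chain), the most complex model is selected; otherwise the recovered models
with no recovered children compete on AIC = 2(1+|K|+|M|) − 2 logL, with
ties broken toward fewer parameters and then the lexicographic canonical
spec string. (Tree scale is counted in the AIC; being common to all
models it never affects comparisons.) A final LRT of the selected model
against the null with k = |K|+|M| extra parameters uses the
chi-bar-squared null Σⱼ C(k,j) 2^(−k) P(χ²ⱼ ≥ Λ) — the natural extension
of the one-parameter boundary mixture; a conservative χ²_k alternative is
available via `SelectionConfig(chi_bar_final=False)`. An element is called
a linAR when a non-null model was selected and this final p-value is
below α (default 1e−4). No multiple-testing correction is applied across
elements; the stringent α plays that role.

Fitting maximises the pruning log-likelihood with L-BFGS-B over
ρ ∈ [1e−6, 100] and active parameters in [0, 50] (generous, numerically
safe envelopes), from a warm start plus a cold start; if a child's
maximised likelihood falls below its parent's by more than 1e−6 the fit is
restarted from the parent's optimum (where the child exactly reproduces
the parent's likelihood), and flagged non-converged only if the violation
persists. Tolerances: L-BFGS-B ftol 1e−11, gtol 1e−7.

## Simulator and power study

Alignments are simulated column-independently: root state from π, then
states propagated down the tree with each branch's transition matrix
(modified on accelerated branches). There are no indels or alignment
errors. Acceleration strength is specified in expected substitutions per
100 bp on the target branch: since unbiased acceleration scales the branch
rate by exactly f(S), the calibration solves f(S)·t·100 = target by Brent
root-finding; targets at or below the neutral expectation map to S = 0.
For GC-biased simulations the expected rate is evaluated against π as an
approximation to the parent-node state distribution. A separate routine
simulates the continuous-time jump process along one branch (exponential
waiting times), so calibration checks count true substitutions including
multiple hits, not just endpoint differences.

The power experiment simulates a grid of conditions, runs the full
selection procedure per alignment, and classifies each call by the active
lineage set of its selected model (ignoring whether the parameter is S or
B): empty → "no acceleration"; any active lineage outside the simulated
set → "other"; otherwise the joined lineage names. Per-alignment RNG
streams derive from (master seed, condition index, replicate index), so
each condition is independently reproducible. The final annotation (not
the α threshold) defines the categories, matching how false-positive and
detection rates are tabulated.

The repository bundles a **synthetic 12-taxon surrogate** neutral model
(`accelscan/data/surrogate_12taxa.mod`): five ape-named target leaves plus
seven outgroups, a REV matrix with realistic transition/transversion
exchangeabilities at 41% GC, and branch lengths chosen so that after the
0.1 conserved-element rescaling the neutral expectation is 0.6
substitutions per 100 bp on the human branch and 0.9 on gorilla. It
emulates the depth and shape of a genome-wide vertebrate model at a size
where offline simulation studies run in minutes; it does not reproduce
100-way taxon sampling, so power results on it are checked as properties
(monotone detection in strength, high null specificity) rather than as
exact percentages. Default study sizes — 25 replicates of 100 bp per
condition in the bundled study, 1000 null alignments for LRT calibration,
a 200-element null scan — were chosen to make sampling error explicit in
the assertions while keeping a single-CPU run fast.

What passing these simulations does **not** show about real data: the
simulator has no alignment error, no indels, no segmental duplications or
lineage-specific repeats — exactly the artifacts the element-filtering and
masking steps (and, upstream, conservative synteny filters) exist to
remove. Detection percentages on real elements also depend on element
length (the bundled study uses 100 bp; real conserved elements average
~150 bp, which can only help).

## Element bookkeeping

Elements are merged when separated by fewer than 10 bp (half-open
coordinates: merge when next.start − prev.end < 10, tracking the running
maximum end so nested intervals merge correctly), then dropped when
shorter than 50 bp, then dropped when any required species lacks a single
unambiguous base — applied after masking, since masking can remove a
species' last base. Masks are per-species interval lists applied by
N-substitution (gaps stay gaps), interpreted in reference coordinates when
the alignment carries a reference interval and as column offsets
otherwise. Merged alignments are concatenated over the union of species
with absent rows padded by N. Every step appends a provenance record.

## Clustering statistics

Nearest-neighbour test: for each linAR the distance to the nearest other
linAR is the inter-interval gap on the same chromosome (0 on overlap;
elements alone on a chromosome are excluded); the statistic is the median.
The null distribution comes from drawing equally many elements from the
background set without replacement. The default p-value is lower-tail
(clustered = smaller median); the empirical count/n_perm is reported, with
a "< 1/n_perm" display at zero and an add-one smoothed value stored
alongside.

Discrete clusters group consecutive background elements separated by at
most 100 kb (boundary inclusive by default; configurable). Each cluster
with k ≥ 1 linARs out of n elements gets an upper-tail binomial p-value at
the genome-wide linAR proportion, divided by 1 − (1−p)^n to condition on
containing at least one linAR (so a singleton cluster is exactly
uninformative, p = 1), then Benjamini–Hochberg q-values across tested
clusters.

## Known limitations

* Acceleration is restricted to terminal branches; clade or ancestral
  tests are not provided.
* The null model is not a neutral-evolution null: B > 0 (gBGC) and modest
  S > 0 (loss of constraint) are non-adaptive explanations that the scan
  does not separate from positive selection.
* The chi-bar-squared weights for the multi-parameter final call assume
  independent one-sided constraints; the exact weights depend on the
  Fisher information geometry, which is why the conservative χ²_k option
  exists.
* Only ORDER-0 reversible nucleotide models are supported.
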