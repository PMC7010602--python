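# Methods

## The probabilistic model

Every analysis in this package scores cells with the same likelihood,
built from the steady-state distribution of the two-state (telegraph)
model of gene transcription.  A promoter switches between an OFF state
(no transcription) and an ON state (transcription at rate θ_t); switching
rates are θ_on (activation) and θ_off (inactivation), and mRNA decays at
a first-order rate.  All three parameters are dimensionless — expressed
in units of the mRNA degradation rate constant, which is why no
degradation parameter appears anywhere in the API.  The stationary
probability of observing m transcripts is

    P2(m; θ_on, θ_off, θ_t) =
        [Γ(θ_on+m) Γ(θ_on+θ_off) θ_t^m] /
        [Γ(m+1) Γ(θ_on+θ_off+m) Γ(θ_on) ]
        · ₁F₁(θ_on+m, θ_on+θ_off+m, −θ_t)

with ₁F₁ the confluent hypergeometric function of the first kind.  Small
θ_on, θ_off with large θ_t gives bursty, bimodal count distributions;
θ_off → 0 recovers a Poisson(θ_t); θ_t = 0 is the degenerate all-zeros
limit (accepted as a valid boundary even though interior parameters must
be strictly positive).

**Numerics.**  ₁F₁(a, b, −z) with b > a > 0 and z up to 400 alternates
destructively when summed directly.  We evaluate it through the Kummer
transform ₁F₁(a, b, −z) = e^(−z) ₁F₁(b−a, b, z), whose series has only
positive terms; log-terms are accumulated with a log-sum-exp over
j = 0 … z + 10√(z+1) + 60 terms, a margin far past the term peak at
j ≈ z.  The remaining gamma factors use `gammaln`.  Any mass point that
still comes out non-finite falls back to 50-digit arbitrary-precision
evaluation (mpmath); in practice the fallback never fires on the default
grid.

**Dropout.**  Droplet protocols miss transcripts; the probability that a
gene with true count m reads as zero is modeled as e^(−λm).  λ = 0 means
every measurement drops out; λ = ∞ is the package's explicit no-dropout
sentinel.  Folding dropout into the telegraph PMF yields the observed-count
distribution: the zero bin accumulates Σ_m e^(−λm) P2(m), positive bins
are thinned by (1 − e^(−λm)).  λ is estimated from data by ordinary least
squares of ln(zero fraction) on mean expression through the origin, over
genes whose zero fraction lies strictly inside (0, 1), clipped at 0.

**The lookup table.**  All fitting is an exact argmax over a precomputed
grid: θ_on and θ_off log-spaced over 0.01–100 (12 values each) and θ_t
log-spaced over 1–400 (20 values), 2,880 points in total, each tabulated
for counts 0…200.  The grid spans strongly bursty to near-constitutive
regimes with PMF means covering the full scaled-count range; it is
user-replaceable.  Each table row is renormalized to sum to one over the
truncated support; rows whose untruncated tail mass exceeds 10⁻³ are
flagged (their truncation is material, their likelihoods still usable).
When a dropout model is supplied it is baked into the table once, so all
downstream fitting remains a pure lookup.  Because every row is a proper
PMF, gene fits reduce to one matrix product between the table and
per-count histograms.

## Preprocessing

Raw inputs (2^−ΔCt qPCR values, log RPKM/TPM, or UMI counts) pass
through, in order: median-of-totals UMI normalization (UMI data only);
removal of genes then cells whose zero fraction reaches the thresholds
(defaults 100%/100%, i.e. only all-zero rows/columns); selection of
Y = min(200, G, ⌊pct·N⌋) informative genes by within-bin standardized
dispersion (20 equal-count mean-expression bins, Fano-factor z-scores);
and the scaling transform.  The scaling stretches each gene onto the
integer range the table covers:

    m̂ = 2^( log2(m+1) · log2(201) / log2(m_max+1) ) − 1, rounded.

This form is monotone and maps 0 ↦ 0 and the gene maximum ↦ 200 exactly.
(The +1 offsets matter: without them zero maps to one, which would
destroy the dropout model's zero bin, and the maximum overshoots 200.)
Scaling is deliberately not idempotent — a scaled matrix refuses to be
scaled again.

A final optional filter ranks genes by their gene-wise maximum
log-likelihood under a single all-cells fit; low likelihood means a
broad, informative distribution.  Genes past the elbow of the
likelihood-vs-rank curve (maximum perpendicular distance to the endpoint
chord — parameter-free and reproducible) are flagged for removal.

## Clustering

The greedy algorithm starts from a seeded uniform-random partition into K
clusters and alternates (a) exact per-(cluster, gene) table fits and
(b) reassignment of every cell to its argmax-likelihood cluster, ties to
the lowest cluster index, until labels stabilize (default cap 100
iterations).  Both steps can only increase the total log-likelihood, so
the recorded objective trace is non-decreasing.  A cluster emptied during
reassignment is repaired by moving in the globally worst-fitting cell;
this repair could in principle dent monotonicity, but on data of the kind
the generators produce it effectively never fires after the first
iteration.

Many greedy runs (default 50; run i always uses seed base+i, so any
worker count or scheduling gives identical output) are aggregated into an
N × N consensus matrix of co-assignment counts, which is clustered by PAM
k-medoids on the dissimilarity n_runs − counts.  Our PAM uses the
deterministic greedy BUILD initialization followed by best-improvement
SWAP (max 300 swaps) — BUILD is at least as good as a random seeded start
and removes one source of run-to-run variation, which is why the seed
argument is accepted but unused.

The number of clusters can be chosen by the eigengap of the normalized
Laplacian of the consensus similarity: K* = argmax (λ_{K+1} − λ_K) over
the candidate range.  One subtlety: even a perfectly homogeneous
population yields a consensus with weak correlated structure (greedy
partitions of the same data are far from independent), so some in-range
gap is always numerically largest.  We therefore require the winning gap
to reach at least 0.3× the leading (K = 1) spectral gap; otherwise the
smallest candidate K is returned with a warning.

For large datasets the consensus is bypassed: the clustering with the
highest total likelihood among the independent greedy runs is kept.

## Lineage inference

Cluster dissimilarity is likelihood transfer: s_kj is the mean
per-cell, per-gene log-likelihood of cluster k's cells under cluster j's
fitted parameters.  The same normalization is applied to the diagonal —
s_kk is the highest entry in row k by construction, so ŝ_kj = s_kk − s_kj
is nonnegative, and d_kj = max(ŝ_kj, ŝ_jk) is a symmetric distance with
zero diagonal.

The default graph construction adds edges in ascending distance (ties
broken by the smaller node pair) until every cluster has degree ≥ 1, and
by default continues until the graph is one component, since a lineage
with disconnected islands is rarely the intended object.

With per-cell capture times or stages, the directed construction is used
instead: candidate edges farther than median + 3 scaled MADs (consistency
constant 1.4826) of the distance distribution are discarded; clusters are
labeled by their modal member time (ties to the smallest value); the
lowest-label cluster(s) are roots; and every other cluster receives
exactly one incoming edge from the feasible parent at smallest distance,
where feasible parents carry the label nearest to but not exceeding the
5th percentile of the cluster's member times.  The percentile cutoff is
what makes the rule robust to a few stragglers; it also means the rule
needs genuinely asynchronous data — if every member of a cluster shares
one time value, the cutoff equals that value and a same-stage sibling
becomes formally feasible.  Graphs can be curated programmatically
(`edit_graph`), with every edit logged.

**Transition genes.**  For a lineage edge (j, k), each gene is scored by
v_g^{jk} = v_g^j + v_g^k − v_g^{j+k}: the log-likelihood lost when the
two clusters' cells are forced into a single pooled fit.  Separate
maximization can only help, so scores are nonnegative; genes are ranked
decreasing.  The selected set is the shortest prefix of the ranking whose
scores reach the threshold share (default 50%) of the total, extended
while the next gene's score stays within 0.8× of the last included one.
The extension is this package's tie rule: with several near-equal
dominant genes a bare cumulative cutoff would split genes that carry
statistically indistinguishable information, and which of them land
inside the prefix would be decided by sampling noise.

## Pseudotime

Cluster pseudotimes come from capture times (modal member time divided by
the global maximum) or, absent times, from cumulative graph distance to a
chosen start cluster normalized by the largest cumulative distance.

Each cell in cluster k is then allocated to one of the directed edges
incident to k by maximizing, over a discretized pseudotime grid spanning
the edge, the linear interpolation between its two cluster
log-likelihoods; the cell takes the best edge and the argmax position as
its pseudotime t(n).  Because a linear function attains its maximum at an
endpoint, t(n) collapses onto a cluster pseudotime whenever the two
likelihoods differ, and onto the interval midpoint when they tie.  This
endpoint degeneracy is inherent to the formulation, not an artifact: the
interpolant's only real information is the sign and size of
Λ_target − Λ_source.  We therefore keep that difference as the explicit
within-edge ordering key — cells on the same edge with equal t(n) are
ordered by increasing Λ_target − Λ_source, then by cell id — which is
exactly the order any strictly monotone reparameterization of the
interpolant would produce (verified in the tests by comparing orders
across grid resolutions).  Cells of isolated clusters keep t = t_k with
no edge, under a warning.

A developmental path is an ordered cluster sequence whose consecutive
pairs are directed edges; its ordering collects the cells assigned to
those edges sorted as above.  The likelihood landscape is the per-cell
negative log-likelihood under its own cluster — high values mark broad,
uncertain expression states.

## Trajectory analyses

Gene trajectories are sliding-window means over the path-ordered cells
(window = ⌈10% of path cells⌉ by default, stride 1; the window's
pseudotime is the mean of its members').  The co-expression network links
genes whose smoothed profiles have |Pearson r| ≥ 0.8 with two-sided
p ≤ 0.01 (no multiple-testing correction, matching the thresholds as
used; a caveat: smoothing autocorrelates the profiles, so the nominal
p-values are optimistic and the r threshold does the real work).
Negative correlations are kept as negatively signed edges.  Gene modules
are maximal cliques of at least 5 genes (Bron–Kerbosch with pivoting via
networkx), reported deterministically (size-descending, then
lexicographic).

## The synthetic generators

`sample_two_state` draws from the truncated renormalized PMF by inverse
CDF; `apply_dropout` zeroes entries with probability e^(−λ·count);
`simulate_clusters` builds block matrices with ground-truth labels.

`simulate_lineage` emulates a time-stamped bifurcating differentiation
experiment: a five-state tree (progenitors → neurons and glia at t = 2;
glia → astrocytes and oligodendrocytes at t = 8) over 12 genes, sampled
at nine capture times (0, 1, 2, 4, 6, 8, 12, 16, 20) with 200 cells each
(1,800 cells).  Each state has dedicated marker genes bursting high
(θ_t = 150 against a baseline of 15, θ_on = 2, θ_off = 1); the two
terminal siblings carry three markers each so that merging them is
expensive in likelihood.  Per-gene parameters are interpolated on log
scale along each tree edge over a short transition window (one time
unit), with PMFs precomputed at 25 interpolation knots per edge.

Two stochastic layers make the capture design informative.  Sampling
times are jittered by Normal(0, 0.2) around the nominal capture time.
Independently, each cell carries an exponential commitment delay (mean 4
time units) subtracted from its sampling time to give its developmental
time — differentiation is asynchronous, so later states accumulate cells
at later captures, giving every cluster a well-defined modal stage and a
straggler tail.  Without this asynchrony the modal stage of a long-lived
terminal state is decided by multinomial noise and the timed lineage rule
is unidentifiable by construction.  The truth table records both the
nominal capture time and the developmental time, plus each cell's chosen
leaf, current state, edge and fractional position; recovery properties
are measured against developmental time, which is what expression
actually encodes.

What the generator does **not** emulate: mechanistic gene-regulatory
dynamics (states are endpoints with interpolated parameters, not
solutions of a network model), sequencing depth variation, batch effects,
doublets, or gene–gene correlation within a state (genes are conditionally
independent given the state).  Passing the recovery tests therefore shows
the pipeline recovers structure that is present in the likelihood's own
terms; it does not certify performance against real-data artifacts the
model does not describe.

## Problem sizes and determinism

Defaults used by the test-suite recovery checks: 600 cells × 15 genes for
consensus clustering (50 runs), the full 1,800 × 12 lineage preset with
the best-of-20 greedy bypass for topology/pseudotime recovery, 2,000
draws per gene for parameter recovery, and 50,000 draws for
distributional fidelity.  Every stochastic routine takes an explicit seed
and is bit-reproducible given it; consensus aggregation is contractually
independent of the worker count because run i always derives its seed as
base + i.

## Known limitations

- Likelihoods are exact only on the 0–200 integer scale; continuous
  expression is rounded after scaling.
- Grid-based fitting quantizes parameter estimates to the grid; "within
  one grid step" is the resolution limit by design.
- The timed lineage rule requires stage labels that increase along the
  tree; it can fail loudly (with a named cluster and a suggestion to use
  `edit_graph`) on data where capture times carry no lineage signal.
- Pseudotimes take at most a handful of distinct values per path
  (endpoint degeneracy above); downstream smoothing relies on the
  within-edge ordering key, not on continuous pseudotime spacing.
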