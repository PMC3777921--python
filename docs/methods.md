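# Methods

This note documents the models and procedures implemented in
`nucgraph`, the parameter choices that matter, what the synthetic data
does and does not emulate, and the package's known limitations.

## Input model and coordinates

Input alignments follow the Hicup-style paired SAM dialect: one aligned
read per line, consecutive lines are mates, and only the QNAME, FLAG,
RNAME and POS fields are required. Pairs are unordered; storage is
canonical (ends sorted by chromosome, position, strand), so `(a, b)` and
`(b, a)` are the same contact. All internal coordinates are 0-based
half-open; SAM positions are converted on entry (−1) and BED intervals
pass through unchanged. Input pairs are assumed to be pre-filtered
upstream (mapping quality, distance-to-restriction-site checks are the
aligner pipeline's job). Exact duplicate pairs are retained by default
because multiplicity carries signal for edge weights; `--dedup` removes
them.

In-silico digestion cuts at the start of each recognition-site
occurrence on the forward strand (`cut_offset` shifts the cut within the
site, e.g. 1 for HindIII's A^AGCTT chemistry; the default 0 keeps the
site boundary convention simple and explicit). Fragment GC is computed
over A/C/G/T only — N bases are excluded from numerator and denominator —
and mappability defaults to 1.0 unless a track is supplied.

## Read-level bias normalization

Hi-C counts are biased by fragment length, GC content and mappability.
We model contact intensity between fixed non-overlapping genomic windows
(default 1 Mb; tests and examples use smaller windows on small synthetic
genomes) with a log-linear Poisson regression. Window covariates
aggregate member fragments (assigned by fragment midpoint): total
fragment length, length-weighted mean GC, mean mappability, each floored
at 1e−3 before taking logs to avoid −∞ on degenerate windows.

The regression observations are *unordered window pairs* (u, v),
including u = v and pairs with zero observed contacts:

    y_uv ~ Poisson(mu_uv)
    log mu_uv = beta0 + beta_len (log len_u + log len_v)
              + beta_gc (log gc_u + log gc_v) + beta_map (log map_u + log map_v)

Writing eta_w = beta0 + beta·logX_w, the fitted mean of a window pair is
exp(eta_u + eta_v − beta0). Fitting observations at window-pair level
(rather than regressing per-window marginal counts) is what makes this
expression an actual count expectation: with a per-window count
regression the same formula overshoots pair counts by a factor of the
number of windows, and the resulting scores degenerate towards 0.

The model is solved by iteratively reweighted least squares (Newton
steps on the Poisson log-likelihood), converging when max|Δβ| < 1e−8,
failing after 100 iterations. A covariate that is constant across
windows is dropped with a warning and reported with coefficient 0.
Coefficients are fitted per chromosome for intra-chromosomal pairs plus
one pooled genome-wide set used for inter-chromosomal pairs and as a
fallback for chromosomes with too few informative windows
(`scope="genome"` fits the pooled set only).

Each read pair joining windows (u, v) is scored once per pair (not per
end) with the Poisson enrichment quantile

    score = P(Y <= y_uv − 1),  Y ~ Poisson(exp(eta_u + eta_v − beta0)),

the probability that bias alone would produce fewer contacts than
observed. Scores are probabilities in [0, 1]; filtering retains pairs
with score ≥ threshold, so the retained set shrinks monotonically as the
threshold rises and 0.99 is stricter than 0.9. Under bias-only data the
scores are approximately uniform, with two caveats worth knowing: the
Poisson CDF is atomic at small means, and the mean score is taken over
*pairs*, which over-samples high-count window pairs — a size bias that
pushes the null mean slightly above 1/2 (≈0.57–0.60 on the synthetic
null fixtures). The classic contact-map normalization (each bin pair
divided by its bias expectation, pooled coefficients) is provided for
interoperability with matrix-based workflows.

## Neighbourhood graph construction

Fragments belong to a gene iff their intervals overlap by ≥1 bp; a
fragment spanning two genes belongs to both, and a read pair whose
partner fragment overlaps two genes creates one edge to each. At each
level, every frontier gene's fragments are cross-referenced against the
pair table; the partner end's fragment either overlaps a gene (edge), or
is intergenic. Intergenic partners are expanded — the fragment midpoint
is linked to the nearest gene upstream (gene end ≤ midpoint) and
downstream (gene start ≥ midpoint), keeping both genes on a side at an
exact distance tie, and adding only one edge at a chromosome end — or,
with expansion disabled, recorded as singularity points. Genes
discovered by expansion are ordinary vertices and join the next frontier
by default (a flag excludes them). Each gene enters the frontier once;
iteration does not re-process visited genes.

A physical read pair contributes at most one edge per unordered gene
pair, tracked by pair identity. This keeps planted multiplicities exact
and makes multi-seed builds equal the union of single-seed builds — the
order-independence that licenses concurrent per-seed execution. Output
is deterministic: vertices and frontiers are processed in (level,
symbol) order. Self-loops (both ends in one gene) are kept in the
multigraph; they are excluded, along with multiplicities, wherever the
simple projection is analysed.

## Annotation

Edge annotation counts track intervals overlapping either supporting
fragment interval of each contact; the exported edge table reports the
mean per supporting contact so that edge multiplicity does not inflate
feature values (sum and max aggregations are available). Vertex
covariates for ERGM `nodecov`/`absdiff` terms are densities — interval
count over the gene body divided by gene length in kb — decoupling the
covariate from gene length. This per-vertex aggregation is an
interpretation: edge-level feature values have no canonical ERGM term,
`nodecov` being vertex-level by definition.

The bundled CTCF matrix is a constructed position-probability matrix
around the canonical CTCF zinc-finger core consensus (consensus base
0.85, others 0.05, degenerate positions uniform; log-odds against a
uniform background; threshold 0.8 × maximum score, which admits one
mismatch at an informative position). It is a synthetic stand-in
suitable for method validation, not a database motif; any PWM can be
supplied as JSON. Scanning covers both strands and skips windows
containing N.

The RSS scanner requires a heptamer CACAGTG match within
`max_mismatch_hept` (default 1) mismatches followed, after a spacer of
12±1 or 23±1 bp, by a nonamer ACAAAAACC match within `max_mismatch_nona`
(default 2); the reported value is the total mismatch count. The
defaults keep the background hit rate on random sequence low while
tolerating near-consensus cryptic sites; this is a consensus-mismatch
scan, not an information-content model.

Isochore calling classifies non-overlapping GC windows (default 100 kb)
into the five canonical families by GC%: L1 < 37, L2 37–41, H1 41–46,
H2 46–53, H3 > 53; adjacent same-class windows are merged and segments
shorter than 300 kb discarded, following the definition of isochores as
>300 kb homogeneous regions. Boundaries are therefore resolved to one
window.

Expression mapping uses |logFC| as vertex weight and colours vertices
red (logFC > 0), green (logFC < 0) or grey (zero or absent). The
built-in differential expression is a deliberately plain two-group
log2 ratio with a Welch t-test (p = 1 when either group has fewer than
two samples); moderated statistics belong to dedicated DE packages and
precomputed tables can be loaded instead.

## Graph statistics, correlation, ERGMs

Summary indexes are computed on the simple undirected projection
(multiplicities collapsed, self-loops removed): density 2E/(V(V−1)),
connected components, diameter of the largest component, and per-vertex
degree, betweenness and closeness (closeness scaled by the reachable
fraction; 0 for isolated vertices).

Graph correlation aligns both graphs on the union of their vertex
symbol sets, forms binary adjacency matrices (≥1 edge → 1; a flag uses
multiplicities), and returns the Pearson correlation of the strict upper
triangles as a percentage. Binary-plus-union is the only convention that
keeps cross-run percentages well-defined when graphs differ in vertex
content; identical non-degenerate graphs score 100%. The correlation is
undefined (and raised as an error) when either aligned matrix is
constant — an edgeless or complete graph on the universe.

ERGMs operate on the simple projection, since the statistics are
defined for simple graphs; multiplicity can enter only through
covariates. Supported statistics: `edges`, `nodecov(x)` = Σ_edges
(x_i + x_j), `absdiff(x)` = Σ_edges |x_i − x_j|, `degree(k)`, and
`triangle`. The `mutual` term is rejected with an explanatory error:
reciprocity is meaningless on undirected graphs. When every term is
dyad-independent the likelihood factorizes over dyads and the exact MLE
is a logistic regression of the dyad indicator on per-dyad change
statistics, solved by Newton–Raphson with standard errors from the
observed information and Wald z p-values; perfect separation and
collinearity raise errors suggesting term removal. Otherwise
Geyer–Thompson MCMC-MLE is used: starting from the maximum
pseudo-likelihood estimate, graphs are sampled at the current
parameter, and the importance-sampled log-likelihood ratio
θ·s_obs − log mean exp((θ−θ0)·s_i) is maximized (BFGS, analytic
gradient), for 3 outer restarts by default; the Fisher information is
estimated as the importance-weighted covariance of the sampled
statistics. Sampler collapse to empty or complete graphs raises a
degeneracy error with diagnostics.

The sampler is a Metropolis single-dyad toggle chain: a uniformly
random dyad is proposed for toggling and accepted with probability
min(1, exp(θ·Δs)), with sufficient statistics maintained incrementally
(and verified against full recomputation in tests). This chain has the
ERGM as its stationary distribution; for dyad-independent models the
per-dyad edge frequency converges to the logistic closed form, which is
the key cross-validation of the sampler against the exact fit. Defaults:
burn-in 10⁴ proposals, thinning 10², 100 simulated networks. Reported
diagnostics include the acceptance rate and an autocorrelation-based
effective sample size of the first statistic.

Goodness of fit simulates networks from the fitted model and compares
the observed degree distribution, edgewise-shared-partner counts and
geodesic-distance distribution (unreachable dyads in a separate bin)
against per-bin simulation quantiles; the plot draws the observed curve
over min–max and interquartile envelopes. A well-fitting model keeps the
observed curves inside the envelopes for the large majority of bins.

## Synthetic data: what it emulates, what it does not

The generator produces study conditions, not dials: genomes with
piecewise-constant GC and restriction sites injected at geometric
spacing (accidental site occurrences are scrubbed so digest density is
controlled); non-overlapping uniformly placed genes; read pairs whose
ends fall within 300 bp of a fragment's restriction ends, mimicking
Hi-C ligation chemistry; planted gene–gene contact counts, planted
intergenic contact points, and uniform random-ligation noise; planted
motif/RSS/isochore features with truth tracks; and log-normal two-group
expression with planted fold changes (baseline log2 level N(5, 1),
noise σ = 0.2, 5 samples per group by default — typical microarray-like
scales). Planted reads prefer fragments overlapping only their target
gene so that planted contacts do not leak edges to bystander genes. All
randomness flows from a single integer seed through one named generator.

Deliberately not emulated: polymer-physics distance decay of contact
frequency, sequencing errors, mapping ambiguity, copy-number variation,
and realistic motif composition of background sequence. Passing tests
therefore demonstrate algorithmic correctness — exact recovery of
planted structure, calibration of the scoring model, agreement with
closed forms and brute-force oracles — not performance on real tissue
data, where bias structure and noise are richer.

Test and acceptance problem sizes (two 400 kb chromosomes, ~3 kb
fragments, 20–24 genes, hundreds of read pairs; ERGMs at 15–40
vertices with 200 recovery replicates) were chosen so the full suite
exercises every code path in seconds while keeping Monte Carlo checks
statistically meaningful (3-standard-error bands).

## Numerical choices and degenerate inputs

- GLM convergence: max|Δβ| < 1e−8, 100 iterations (Poisson IRLS);
  1e−10, 100 iterations (logistic Newton); linear-algebra failures
  surface as fit errors, never silent results.
- Covariate floors (1e−3) before logs; exponentials clipped at ±30 to
  avoid overflow during iteration.
- Empty sequence → no fragments; absent site → whole-chromosome
  fragment; empty track → all-zero annotations; empty pair list →
  all-zero contact map.
- Isochore classification uses half-open GC% intervals with upper
  bounds (37, 41, 46, 53); boundary values fall into the lower class's
  upper neighbour consistently via searchsorted semantics.
- Distance ties in intergenic expansion link all tied genes; vertex and
  frontier orderings are lexicographic, making every build reproducible.

## Limitations

- Curved ERGMs (GWESP/GWD), Bayesian ERGMs and directed models are out
  of scope; `degree(k)`/`triangle` models can be degenerate for some
  parameter values, which is reported, not worked around.
- The MCMC-MLE standard errors ignore the (small) Monte Carlo noise of
  the importance-sampling step beyond the weighted-covariance estimate.
- The correlation convention (binary, union of vertex sets) is a
  documented choice; other conventions give different percentages when
  comparing graphs with differing vertex content.
- BAM/CRAM and network retrieval (pathway databases, expression
  repositories) are not handled; gene lists and expression tables are
  read from local files.
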