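# nucgraph

Gene-centric neighbourhood graphs from Hi-C paired-read data, with
read-level bias normalization, multi-omics annotation, and statistical
graph analysis.

Hi-C reports pairs of genomic fragments that were spatially close in the
nucleus. Most pipelines immediately bin those pairs into a contact
matrix; `nucgraph` instead keeps the sequence-level information and asks
a gene-centric question: *what is in the 3D neighbourhood of a gene of
interest?* Starting from one or more seed genes, read pairs anchored in
the genes' restriction fragments are followed to their partner
fragments, producing an undirected multigraph whose vertices are genes
and whose edges are individual Hi-C contacts. Intergenic contact points
can be expanded to their nearest flanking genes, and the search can be
iterated so each round's discoveries seed the next. The package is aimed
at computational biologists studying chromatin architecture, gene
co-localization and its relation to regulation.

## What it computes

**Read-level normalization.** Contact intensity between genomic windows
is modelled by a log-linear Poisson regression on windowed fragment
covariates — total fragment length, length-weighted GC content, mean
mappability:

    y_uv ~ Poisson(mu_uv),   log mu_uv = eta_u + eta_v − beta0,
    eta_w = beta0 + beta_len·log len_w + beta_gc·log gc_w + beta_map·log map_w

Each read pair then receives a reliability score — the Poisson
enrichment quantile `P(Y < y_uv; mu_uv)` of its window pair — and a
user-chosen threshold tunes how aggressively biased contacts are
filtered (0.99 is stricter than 0.9). The classic binned contact-map
normalization (raw / expected bias) is also provided.

**Graph analysis.** Graphs are described by global indexes (density,
connectivity, diameter) and local ones (degree, betweenness, closeness);
two graphs are compared by the Pearson correlation of their binary
adjacency matrices on the union of their vertex sets, reported as a
percentage. Exponential-family random graph models

    P(G) ∝ exp(θ · s(G)),  s ∈ {edges, nodecov(x), absdiff(x), degree(k), triangle}

are fitted exactly (logistic MLE on dyad change statistics) when all
terms are dyad-independent, and by Geyer–Thompson MCMC maximum
likelihood with a Metropolis toggle sampler otherwise; fitted models are
checked by simulation-based goodness-of-fit diagnostics over the degree,
edgewise-shared-partner and geodesic-distance distributions.

**Annotation.** Edges and vertices can be annotated from any BED track
or from built-in sequence predictors: PWM scanning for CTCF-like binding
sites, consensus-mismatch scanning for cryptic recombination signal
sequences (heptamer CACAGTG + 12/23 bp spacer + nonamer ACAAAAACC), and
GC segmentation into the five isochore families (L1/L2/H1/H2/H3).
Expression tables colour vertices by fold-change sign (red up, green
down) and weight them by |logFC|.

**Synthetic data.** A first-class generator produces genomes with
controlled GC and restriction-site spacing, gene layouts, read pairs
with planted gene–gene contacts plus random-ligation noise, planted
sequence features with truth tracks, and two-group expression matrices —
everything the test suite and the acceptance script run on.

## Worked example

```python
import nucgraph as ng
from nucgraph.graph_stats import graph_statistics, graph_correlation, ergm_fit

genome = ng.make_genome(n_chroms=2, chrom_len=400_000, site_spacing_mean=3000, seed=11)
fragments = ng.digest_sequences(genome, "AAGCTT")          # HindIII site
genes = ng.make_gene_layout(genome, n_genes=20, seed=12)
spec = ng.ContactSpec(gene_pairs=[("G0001", "G0002", 6), ("G0001", "G0007", 4),
                                  ("G0002", "G0012", 5)], noise_pairs=300, seed=13)
pairs = ng.simulate_hic(genome, fragments, genes, spec)
ng.assign_fragments(pairs, fragments)

model = ng.fit_bias_model(pairs, fragments, window_bp=50_000)
scored = ng.score_reads(pairs, fragments, model)
kept = ng.filter_reads(scored, 0.9)                        # strict filtering
graph = ng.build_neighbourhood(["G0001"], kept, fragments, genes, levels=2)

s = graph_statistics(graph)
print(graph)
print(f"density: {s.density:.3f}  diameter: {s.diameter}")
print("self-correlation:", graph_correlation(graph, graph))
print(ergm_fit(graph, "edges").summary())
```

prints

```
NeighbourhoodGraph(13 genes, 34 contacts, 0 singularities)
density: 0.205  diameter: 4
self-correlation: 100.0
term                Estimate  Std. Error     p-value
edges               -1.35455     0.28041    1.36e-06
method: exact-logistic
```

The three planted contacts survive the 0.9 threshold with their planted
multiplicities on top (G0001–G0002 appears 7× — 6 planted plus one
chance noise pair), the level-2 iteration pulls in G0012 through G0002,
and the edges-only ERGM coefficient is the log-odds of the graph's
density, as it must be for a Bernoulli graph.

The same pipeline is available from the shell:

```sh
nucgraph run --config run.yaml        # simulate → digest → normalize → build → stats
nucgraph digest --fasta g.fa --site AAGCTT -o frags.tsv
nucgraph ergm --graph out/graph --terms edges,nodecov:ctcf --seed 42 -o fit.json
```

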