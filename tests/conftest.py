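"""Shared fixtures: a small deterministic synthetic world."""
import numpy as np
import pytest

import nucgraph as ng


@pytest.fixture(scope="session")
def world():
    """Genome, digest, gene layout — 2 chromosomes, 24 genes."""
    genome = ng.make_genome(n_chroms=2, chrom_len=400_000,
                            site_spacing_mean=3000, seed=101)
    fragments = ng.digest_sequences(genome, "AAGCTT")
    genes = ng.make_gene_layout(genome, n_genes=24,
                                gene_len_range=(3_000, 9_000), seed=102)
    return genome, fragments, genes


@pytest.fixture(scope="session")
def planted_world(world):
    """The world plus noiseless planted contacts and the built graph."""
    genome, fragments, genes = world
    spec = ng.ContactSpec(
        gene_pairs=[("G0001", "G0002", 5), ("G0001", "G0003", 3),
                    ("G0002", "G0004", 4)],
        noise_pairs=0, seed=7)
    pairs = ng.simulate_hic(genome, fragments, genes, spec)
    ng.assign_fragments(pairs, fragments)
    return genome, fragments, genes, spec, pairs


def brute_force_overlaps(intervals, chrom, start, end):
    """Quadratic interval-intersection oracle."""
    return sum(1 for c, s, e, _ in intervals
               if c == chrom and s < end and start < e)


def bfs_distances(adj, src):
    """Plain BFS over an adjacency dict; returns {node: distance}."""
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_betweenness(adj):
    """Betweenness by explicit shortest-path counting (BFS sigma/delta),
    written independently of networkx."""
    nodes = list(adj)
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest paths with path counts
        dist = {s: 0}
        sigma = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        order = []
        preds = {v: [] for v in nodes}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                order.append(u)
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
                    if dist.get(v) == dist[u] + 1:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
            frontier = nxt
        delta = {v: 0.0 for v in nodes}
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # undirected: each pair counted twice
    return {v: b / 2.0 for v, b in bc.items()}
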