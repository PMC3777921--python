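"""Gene-centric neighbourhood graph construction.

Starting from a set of seed genes, read pairs whose one end falls in a
fragment of a frontier gene are followed to the partner end's fragment.
A partner fragment inside a gene creates an edge; an intergenic partner
is either recorded as a singularity point or expanded to the nearest
upstream/downstream genes. Newly discovered genes form the frontier of
the next iteration, widening the neighbourhood level by level.
"""
from __future__ import annotations

import logging
import warnings

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .types import Gene, ReadPair, RestrictionFragment

logger = logging.getLogger(__name__)

__all__ = [
    "NeighbourhoodGraph",
    "fragments_for_genes",
    "assign_fragments",
    "build_neighbourhood",
    "build_for_coordinates",
    "build_for_gene_list",
]


class NeighbourhoodGraph:
    """Undirected multigraph of genes connected by Hi-C contacts.

    Backed by a :class:`networkx.MultiGraph`; every parallel edge is one
    supporting read pair, carrying the two fragment intervals, the
    discovery level and the discovery origin. Self-loops (both ends in
    one gene) are allowed. ``singularities`` collects intergenic contact
    points when expansion is disabled.
    """

    def __init__(self) -> None:
        self.g = nx.MultiGraph()
        self.singularities: List[Tuple[str, int]] = []
        self.skipped_pairs = 0

    # -- construction -----------------------------------------------------
    def add_vertex(self, gene: Gene, level: int, origin: str) -> None:
        if gene.symbol not in self.g:
            self.g.add_node(gene.symbol, gene=gene, level=level, origin=origin)

    def add_edge(self, g1: str, g2: str, pair: Optional[ReadPair],
                 frag1: Tuple[str, int, int], frag2: Tuple[str, int, int],
                 level: int, origin: str = "contact") -> None:
        self.g.add_edge(g1, g2, pair=pair, frag1=frag1, frag2=frag2,
                        level=level, origin=origin, features={})

    # -- views ------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def vertex_order(self) -> List[str]:
        """Deterministic vertex order: (level, symbol)."""
        return sorted(self.g.nodes, key=lambda s: (self.g.nodes[s]["level"], s))

    def edge_multiset(self) -> Dict[Tuple[str, str], int]:
        """Multiplicity of each unordered gene pair."""
        out: Dict[Tuple[str, str], int] = {}
        for u, v in self.g.edges():
            key = tuple(sorted((u, v)))
            out[key] = out.get(key, 0) + 1
        return out

    def simple_graph(self) -> nx.Graph:
        """Simple undirected projection: multiplicities collapsed,
        self-loops removed. Vertex/edge attributes are carried over."""
        s = nx.Graph()
        for node, data in self.g.nodes(data=True):
            s.add_node(node, **data)
        for u, v in self.g.edges():
            if u != v:
                s.add_edge(u, v)
        return s

    def vertex_covariate(self, name: str) -> Dict[str, float]:
        key = f"cov_{name}"
        return {n: float(self.g.nodes[n].get(key, 0.0)) for n in self.g.nodes}

    def __repr__(self) -> str:
        return (f"NeighbourhoodGraph({self.n_vertices} genes, "
                f"{self.n_edges} contacts, "
                f"{len(self.singularities)} singularities)")


# ---------------------------------------------------------------------------
# Fragment / gene cross-referencing


class _FragmentIndex:
    """Binary-search index of tiling fragments, per chromosome."""

    def __init__(self, fragments: Sequence[RestrictionFragment]) -> None:
        self.fragments = list(fragments)
        self.by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: Dict[str, List[RestrictionFragment]] = {}
        for f in fragments:
            per_chrom.setdefault(f.chrom, []).append(f)
        for chrom, frags in per_chrom.items():
            frags.sort(key=lambda f: f.start)
            self.by_chrom[chrom] = (
                np.array([f.start for f in frags]),
                np.array([f.end for f in frags]),
                np.array([f.id for f in frags]),
            )
        self.by_id = {f.id: f for f in fragments}

    def locate(self, chrom: str, pos: int) -> Optional[int]:
        """Fragment id containing pos, or None."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return None
        return int(ids[i])

    def overlapping(self, chrom: str, start: int, end: int) -> List[int]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, ids = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [int(i) for i in ids[lo:hi]]


def fragments_for_genes(genes: Sequence[Gene],
                        fragments: Sequence[RestrictionFragment],
                        ) -> Dict[str, Set[int]]:
    """Map each gene symbol to the ids of fragments overlapping it by >= 1 bp.

    A fragment may belong to several genes. A gene on a chromosome with no
    fragments yields an empty set with a warning.
    """
    index = _FragmentIndex(fragments)
    out: Dict[str, Set[int]] = {}
    for gene in genes:
        ids = set(index.overlapping(gene.chrom, gene.start, gene.end))
        if gene.chrom not in index.by_chrom:
            warnings.warn(f"gene {gene.symbol}: chromosome {gene.chrom!r} "
                          f"absent from fragment table")
        out[gene.symbol] = ids
    return out


def assign_fragments(pairs: Iterable[ReadPair],
                     fragments: Sequence[RestrictionFragment]) -> int:
    """Set frag1_id/frag2_id on each pair in place.

    Returns the number of pairs with at least one end outside every
    fragment (those keep ``None`` ids and are skipped downstream).
    """
    index = _FragmentIndex(fragments)
    unassigned = 0
    for p in pairs:
        p.frag1_id = index.locate(p.chrom1, p.pos1)
        p.frag2_id = index.locate(p.chrom2, p.pos2)
        if p.frag1_id is None or p.frag2_id is None:
            unassigned += 1
    return unassigned


# ---------------------------------------------------------------------------
# Graph building


class _GeneIndex:
    """Per-chromosome sorted gene lists for overlap and nearest queries."""

    def __init__(self, genes: Sequence[Gene]) -> None:
        self.by_symbol = {g.symbol: g for g in genes}
        if len(self.by_symbol) != len(genes):
            raise ValueError("duplicate gene symbols in annotation set")
        self.by_chrom: Dict[str, List[Gene]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort(key=lambda g: (g.start, g.end, g.symbol))
        self._starts = {c: [g.start for g in gs] for c, gs in self.by_chrom.items()}

    def overlapping(self, chrom: str, start: int, end: int) -> List[Gene]:
        out = []
        for g in self.by_chrom.get(chrom, []):
            if g.start >= end:
                break
            if g.end > start:
                out.append(g)
        return out

    def nearest_flanking(self, chrom: str, pos: int) -> Tuple[List[Gene], List[Gene]]:
        """Nearest genes strictly upstream (end <= pos) and downstream
        (start >= pos) of a point; distance ties keep every tied gene."""
        genes = self.by_chrom.get(chrom, [])
        up_best: List[Gene] = []
        up_dist = None
        down_best: List[Gene] = []
        down_dist = None
        for g in genes:
            if g.end <= pos:
                d = pos - g.end
                if up_dist is None or d < up_dist:
                    up_best, up_dist = [g], d
                elif d == up_dist:
                    up_best.append(g)
            elif g.start >= pos:
                d = g.start - pos
                if down_dist is None or d < down_dist:
                    down_best, down_dist = [g], d
                elif d == down_dist:
                    down_best.append(g)
        return up_best, down_best


def build_neighbourhood(seed_genes: Sequence[str],
                        pairs: Sequence[ReadPair],
                        fragments: Sequence[RestrictionFragment],
                        all_genes: Sequence[Gene],
                        levels: int = 1,
                        expand_intergenic: bool = True,
                        expanded_join_frontier: bool = True,
                        ) -> NeighbourhoodGraph:
    """Build the neighbourhood multigraph of ``seed_genes``.

    Iterates ``levels`` times; at each level every frontier gene's
    fragments are cross-referenced against the read pairs, partner
    fragments are resolved to genes (edge), expanded to nearest flanking
    genes (intergenic expansion) or recorded as singularity points.

    A physical read pair contributes at most one edge per unordered gene
    pair, so multi-seed builds equal the union of single-seed builds.
    Output ordering is deterministic: vertices and frontiers are
    processed in (level, symbol) order.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    gene_index = _GeneIndex(all_genes)
    unknown = [s for s in seed_genes if s not in gene_index.by_symbol]
    if unknown:
        raise ValueError(f"unknown seed gene symbols: {', '.join(sorted(unknown))}")

    frag_index = _FragmentIndex(fragments)
    gene_frag = fragments_for_genes(all_genes, fragments)
    if not any(gene_frag[s] for s in seed_genes):
        raise ValueError("no fragments found for any seed gene")

    # pair lookup: fragment id -> [(pair index, end number)]
    by_frag: Dict[int, List[Tuple[int, int]]] = {}
    skipped = 0
    for i, p in enumerate(pairs):
        if p.frag1_id is None:
            p.frag1_id = frag_index.locate(p.chrom1, p.pos1)
        if p.frag2_id is None:
            p.frag2_id = frag_index.locate(p.chrom2, p.pos2)
        if p.frag1_id is None or p.frag2_id is None:
            skipped += 1
            continue
        by_frag.setdefault(p.frag1_id, []).append((i, 1))
        by_frag.setdefault(p.frag2_id, []).append((i, 2))
    if skipped:
        logger.info("skipped %d pairs with ends outside all fragments", skipped)

    graph = NeighbourhoodGraph()
    graph.skipped_pairs = skipped
    for s in sorted(seed_genes):
        graph.add_vertex(gene_index.by_symbol[s], level=0, origin="seed")

    frag_genes_cache: Dict[int, List[Gene]] = {}

    def genes_of_fragment(fid: int) -> List[Gene]:
        if fid not in frag_genes_cache:
            f = frag_index.by_id[fid]
            frag_genes_cache[fid] = gene_index.overlapping(f.chrom, f.start, f.end)
        return frag_genes_cache[fid]

    used: Set[Tuple] = set()  # (pair idx, unordered gene pair) / expansion records
    frontier = sorted(set(seed_genes))
    visited = set(frontier)

    for level in range(1, levels + 1):
        discovered: Set[str] = set()
        for g_sym in frontier:
            for fid in sorted(gene_frag[g_sym]):
                for pair_idx, endno in by_frag.get(fid, []):
                    p = pairs[pair_idx]
                    partner_fid = p.frag2_id if endno == 1 else p.frag1_id
                    partner = frag_index.by_id[partner_fid]
                    own = frag_index.by_id[fid]
                    partner_genes = genes_of_fragment(partner_fid)
                    if partner_genes:
                        for h in partner_genes:
                            key = (pair_idx, tuple(sorted((g_sym, h.symbol))))
                            if key in used:
                                continue
                            used.add(key)
                            if h.symbol not in graph.g:
                                graph.add_vertex(h, level=level, origin="contact")
                                discovered.add(h.symbol)
                            graph.add_edge(
                                g_sym, h.symbol, p,
                                (own.chrom, own.start, own.end),
                                (partner.chrom, partner.start, partner.end),
                                level=level, origin="contact")
                    elif expand_intergenic:
                        up, down = gene_index.nearest_flanking(
                            partner.chrom, partner.midpoint)
                        for h in up + down:
                            key = (pair_idx, "x", tuple(sorted((g_sym, h.symbol))))
                            if key in used:
                                continue
                            used.add(key)
                            if h.symbol not in graph.g:
                                graph.add_vertex(h, level=level,
                                                 origin="intergenic-expansion")
                                if expanded_join_frontier:
                                    discovered.add(h.symbol)
                            graph.add_edge(
                                g_sym, h.symbol, p,
                                (own.chrom, own.start, own.end),
                                (partner.chrom, partner.start, partner.end),
                                level=level, origin="intergenic-expansion")
                    else:
                        graph.singularities.append(
                            (partner.chrom, partner.midpoint))
        frontier = sorted(discovered - visited)
        visited |= discovered
        if not frontier:
            break
    return graph


def build_for_coordinates(interval: str,
                          pairs: Sequence[ReadPair],
                          fragments: Sequence[RestrictionFragment],
                          all_genes: Sequence[Gene],
                          **kwargs) -> NeighbourhoodGraph:
    """Neighbourhood of every gene overlapping ``chrom:start-end``."""
    chrom, rest = interval.rsplit(":", 1)
    lo_s, hi_s = rest.replace(",", "").split("-")
    lo, hi = int(lo_s), int(hi_s)
    if not chrom or lo >= hi:
        raise ValueError(f"invalid genomic interval {interval!r}")
    seeds = [g.symbol for g in all_genes if g.overlaps(chrom, lo, hi)]
    if not seeds:
        raise ValueError(f"no genes overlap interval {interval}")
    return build_neighbourhood(seeds, pairs, fragments, all_genes, **kwargs)


def build_for_gene_list(path: str,
                        pairs: Sequence[ReadPair],
                        fragments: Sequence[RestrictionFragment],
                        all_genes: Sequence[Gene],
                        **kwargs) -> NeighbourhoodGraph:
    """Neighbourhood of the symbols listed one-per-line in a file."""
    with open(path) as fh:
        seeds = [line.strip() for line in fh if line.strip()]
    if not seeds:
        raise ValueError(f"gene list {path} is empty")
    return build_neighbourhood(seeds, pairs, fragments, all_genes, **kwargs)
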