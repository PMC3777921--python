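"""Input/output for every external format the toolkit touches.

Covers the Hicup-style paired SAM dialect (one aligned read per line,
consecutive lines are mates), in-silico restriction digestion of FASTA
genomes, BED gene/feature ingestion, and the vertex/edge table export of
neighbourhood graphs.
"""
from __future__ import annotations


from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import FeatureTrack, Gene, ReadPair, RestrictionFragment

__all__ = [
    "load_hic_sam",
    "write_hic_sam",
    "digest_genome",
    "digest_sequences",
    "load_genes",
    "load_features",
    "write_genes_bed",
    "write_features_bed",
    "write_fasta",
    "read_fasta",
    "write_fragments_tsv",
    "load_fragments_tsv",
    "write_graph_tables",
    "read_graph_tables",
    "write_scored_pairs",
    "load_scored_pairs",
]

SAM_REVERSE_FLAG = 0x10


class SamFormatError(ValueError):
    """Raised on unparseable or mis-paired Hicup SAM input."""


def _parse_sam_record(line: str, lineno: int) -> Tuple[str, str, int, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise SamFormatError(
            f"line {lineno}: expected >= 4 tab-separated SAM fields, got {len(fields)}"
        )
    qname, flag_s, rname, pos_s = fields[:4]
    try:
        flag = int(flag_s)
        pos = int(pos_s)
    except ValueError as exc:
        raise SamFormatError(f"line {lineno}: non-integer FLAG/POS: {exc}") from None
    if pos < 1:
        raise SamFormatError(f"line {lineno}: POS must be >= 1 (got {pos})")
    strand = "-" if flag & SAM_REVERSE_FLAG else "+"
    return qname, rname, pos - 1, strand  # SAM is 1-based; internal is 0-based


def load_hic_sam(path: str) -> List[ReadPair]:
    """Load Hicup-dialect paired reads: records 2k and 2k+1 form pair k.

    Header lines (leading ``@``) are permitted and skipped. Positions are
    converted from SAM 1-based to 0-based; strand comes from FLAG bit 0x10.
    Pairs are returned in canonical (chrom, pos)-sorted end order.
    """
    pairs: List[ReadPair] = []
    pending: Optional[Tuple[str, str, int, str]] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@") or not line.strip():
                continue
            rec = _parse_sam_record(line, lineno)
            if pending is None:
                pending = rec
            else:
                q1, c1, p1, s1 = pending
                q2, c2, p2, s2 = rec
                pairs.append(ReadPair(c1, p1, s1, c2, p2, s2).canonical())
                pending = None
    if pending is not None:
        raise SamFormatError(
            f"odd number of alignment records: trailing unpaired read "
            f"{pending[0]!r} ({pending[1]}:{pending[2] + 1})"
        )
    return pairs


def write_hic_sam(path: str, pairs: List[ReadPair],
                  chrom_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write pairs back out in the consecutive-mates SAM dialect."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, p in enumerate(pairs):
            for endno, (chrom, pos, strand) in enumerate(
                [(p.chrom1, p.pos1, p.strand1), (p.chrom2, p.pos2, p.strand2)], 1
            ):
                flag = SAM_REVERSE_FLAG if strand == "-" else 0
                fh.write(
                    f"pair{i}/{endno}\t{flag}\t{chrom}\t{pos + 1}\t42\t*\t*\t0\t0\t*\t*\n"
                )


# ---------------------------------------------------------------------------
# In-silico digestion


def _gc_fraction(seq: str) -> float:
    """GC over A/C/G/T only; N bases excluded from both counts."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    return gc / total if total else 0.0


def digest_sequences(sequences: Dict[str, str], site: str,
                     cut_offset: int = 0,
                     mappability: Optional[FeatureTrack] = None,
                     ) -> List[RestrictionFragment]:
    """Digest in-memory chromosome sequences at every forward-strand site.

    The cut is placed ``cut_offset`` bases into each recognition-site
    occurrence (default 0: at the site start). Fragments tile each
    chromosome; GC is computed per fragment; mappability defaults to 1.0
    unless a track is supplied (fragment value = mean of overlapping track
    values weighted by overlap length).
    """
    if not site or any(b not in "ACGT" for b in site.upper()):
        raise ValueError(f"site must be a non-empty unambiguous ACGT string, got {site!r}")
    site = site.upper()
    map_by_chrom = mappability.by_chrom() if mappability is not None else {}
    fragments: List[RestrictionFragment] = []
    next_id = 0
    for chrom in sequences:
        seq = sequences[chrom].upper()
        n = len(seq)
        if n == 0:
            continue
        cuts = [0]
        start = seq.find(site)
        while start != -1:
            cut = start + cut_offset
            if 0 < cut < n and cut != cuts[-1]:
                cuts.append(cut)
            start = seq.find(site, start + 1)
        cuts.append(n)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mapp = _interval_mean(map_by_chrom.get(chrom, []), lo, hi, default=1.0)
            fragments.append(
                RestrictionFragment(next_id, chrom, lo, hi,
                                    gc=_gc_fraction(seq[lo:hi]), mappability=mapp)
            )
            next_id += 1
    return fragments


def _interval_mean(intervals, lo: int, hi: int, default: float) -> float:
    """Coverage-weighted mean of track values over [lo, hi); uncovered
    bases contribute the default."""
    total = 0.0
    covered = 0
    for s, e, v in intervals:
        ov = min(e, hi) - max(s, lo)
        if ov > 0:
            total += v * ov
            covered += ov
    length = hi - lo
    return (total + default * (length - covered)) / length


def digest_genome(fasta_path: str, site: str, cut_offset: int = 0,
                  mappability: Optional[FeatureTrack] = None) -> List[RestrictionFragment]:
    """Digest a FASTA genome; see :func:`digest_sequences`."""
    return digest_sequences(read_fasta(fasta_path), site, cut_offset, mappability)


# ---------------------------------------------------------------------------
# FASTA / BED / TSV


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def load_genes(bed_path: str) -> List[Gene]:
    """Load genes from BED (>=3 columns; col 4 = symbol, col 6 = strand)."""
    genes: List[Gene] = []
    seen = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{bed_path} line {lineno}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"{bed_path} line {lineno}: start >= end")
            symbol = cols[3] if len(cols) > 3 and cols[3] else f"feat{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            if symbol in seen:
                raise ValueError(f"{bed_path} line {lineno}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(Gene(symbol, chrom, start, end, strand))
    return genes


def load_features(bed_path: str, name: str) -> FeatureTrack:
    """Load any BED annotation as a feature track (col 4 numeric = value)."""
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{bed_path} line {lineno}: fewer than 3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"{bed_path} line {lineno}: start >= end")
            value = 1.0
            if len(cols) > 3:
                try:
                    value = float(cols[3])
                except ValueError:
                    value = 1.0  # name column, not a score
            intervals.append((chrom, start, end, value))
    return FeatureTrack(name, intervals)


def write_genes_bed(path: str, genes: List[Gene]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")


def write_features_bed(path: str, track: FeatureTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_fragments_tsv(path: str, fragments: List[RestrictionFragment]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tgc\tmappability\n")
        for f in fragments:
            fh.write(f"{f.id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.gc:.6f}\t{f.mappability:.6f}\n")


def load_fragments_tsv(path: str) -> List[RestrictionFragment]:
    fragments = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            i, chrom, start, end, gc, mapp = line.rstrip("\n").split("\t")
            fragments.append(RestrictionFragment(int(i), chrom, int(start), int(end),
                                                 float(gc), float(mapp)))
    return fragments


def write_scored_pairs(path: str, pairs: List[ReadPair]) -> None:
    """TSV export of (possibly scored) read pairs."""
    with open(path, "w") as fh:
        fh.write("chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tfrag1\tfrag2\tscore\n")
        for p in pairs:
            f1 = "" if p.frag1_id is None else str(p.frag1_id)
            f2 = "" if p.frag2_id is None else str(p.frag2_id)
            sc = "" if p.score is None else f"{p.score:.8g}"
            fh.write(f"{p.chrom1}\t{p.pos1}\t{p.strand1}\t{p.chrom2}\t{p.pos2}"
                     f"\t{p.strand2}\t{f1}\t{f2}\t{sc}\n")


def load_scored_pairs(path: str) -> List[ReadPair]:
    pairs = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            c1, p1, s1, c2, p2, s2, f1, f2, sc = line.rstrip("\n").split("\t")
            pairs.append(ReadPair(c1, int(p1), s1, c2, int(p2), s2,
                                  int(f1) if f1 else None,
                                  int(f2) if f2 else None,
                                  float(sc) if sc else None))
    return pairs


# ---------------------------------------------------------------------------
# Graph tables


def write_graph_tables(graph, vertices_path: str, edges_path: str) -> None:
    """Export a neighbourhood graph as vertex and edge TSV tables.

    The vertex table lists one gene per row with its discovery level,
    origin and (when expression has been mapped) weight and colour. The
    edge table aggregates parallel edges between the same gene pair into
    one row carrying the multiplicity, the supporting fragment intervals
    of every contact, and the per-feature annotation means.
    """
    feature_names = sorted(
        {k for _, _, d in graph.g.edges(data=True) for k in d.get("features", {})}
    )
    with open(vertices_path, "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\tstrand\tlevel\torigin\tweight\tcolour\n")
        for symbol in graph.vertex_order():
            d = graph.g.nodes[symbol]
            gene = d["gene"]
            fh.write(f"{symbol}\t{gene.chrom}\t{gene.start}\t{gene.end}\t{gene.strand}"
                     f"\t{d['level']}\t{d['origin']}"
                     f"\t{d.get('weight', '')}\t{d.get('colour', '')}\n")
    groups: Dict[Tuple[str, str], list] = {}
    for u, v, d in graph.g.edges(data=True):
        key = tuple(sorted((u, v)))
        groups.setdefault(key, []).append(d)
    with open(edges_path, "w") as fh:
        cols = ["gene1", "gene2", "multiplicity", "level", "origin", "fragments"]
        cols += feature_names
        fh.write("\t".join(cols) + "\n")
        for (g1, g2), ds in sorted(groups.items()):
            level = min(d["level"] for d in ds)
            origin = ds[0]["origin"]
            frags = ";".join(
                "{0}:{1}-{2}|{3}:{4}-{5}".format(*d["frag1"], *d["frag2"]) for d in ds
            )
            row = [g1, g2, str(len(ds)), str(level), origin, frags]
            for name in feature_names:
                vals = [d.get("features", {}).get(name, 0.0) for d in ds]
                row.append(f"{float(np.mean(vals)):g}")
            fh.write("\t".join(row) + "\n")


def read_graph_tables(vertices_path: str, edges_path: str):
    """Rebuild a neighbourhood graph from its exported tables.

    Round-trips the vertex set and the edge multiset written by
    :func:`write_graph_tables` (feature annotations come back as the
    per-gene-pair mean, applied to every supporting contact).
    """
    from .neighbourhood import NeighbourhoodGraph

    graph = NeighbourhoodGraph()
    with open(vertices_path) as fh:
        fh.readline()
        for line in fh:
            sym, chrom, start, end, strand, level, origin, weight, colour = \
                line.rstrip("\n").split("\t")
            graph.add_vertex(Gene(sym, chrom, int(start), int(end), strand),
                             int(level), origin)
            if weight:
                graph.g.nodes[sym]["weight"] = float(weight)
                graph.g.nodes[sym]["colour"] = colour
    with open(edges_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        feature_names = header[6:]
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            g1, g2, mult, level, origin, frags = cols[:6]
            features = {name: float(v) for name, v in zip(feature_names, cols[6:])}
            for part in frags.split(";"):
                f1s, f2s = part.split("|")
                frag1 = _parse_region(f1s)
                frag2 = _parse_region(f2s)
                graph.g.add_edge(g1, g2, frag1=frag1, frag2=frag2,
                                 level=int(level), origin=origin,
                                 features=dict(features), pair=None)
    return graph


def _parse_region(s: str) -> Tuple[str, int, int]:
    chrom, rest = s.rsplit(":", 1)
    start, end = rest.split("-")
    return (chrom, int(start), int(end))
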