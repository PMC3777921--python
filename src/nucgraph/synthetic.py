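"""Self-contained synthetic fixtures with the statistical structure the
rest of the toolkit assumes.

Generates a small genome with a controllable GC profile and injected
restriction sites, a non-overlapping gene layout, Hicup-style read
pairs with planted gene-gene contacts plus uniform random-ligation
noise, planted sequence features (motifs, RSSs, isochores) with truth
tracks, and a two-group expression matrix with planted fold changes.
All randomness flows from a single integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .omics_map import RSS_HEPTAMER, RSS_NONAMER, default_ctcf_pwm
from .types import FeatureTrack, Gene, ReadPair, RestrictionFragment

__all__ = [
    "ContactSpec",
    "make_genome",
    "make_gene_layout",
    "simulate_hic",
    "plant_features",
    "make_expression",
]

_BASES = np.array(list("ACGT"))
READ_END_OFFSET = 300  # read ends fall within this many bp of a restriction end


@dataclass
class ContactSpec:
    """Planted contact structure for :func:`simulate_hic`."""

    gene_pairs: List[Tuple[str, str, int]] = field(default_factory=list)
    intergenic_points: List[Tuple[str, int, int, str]] = field(default_factory=list)
    noise_pairs: int = 0
    seed: int = 0

    def validate(self, gene_symbols) -> None:
        symbols = set(gene_symbols)
        for a, b, n in self.gene_pairs:
            if n < 0:
                raise ValueError("planted pair counts must be >= 0")
            for s in (a, b):
                if s not in symbols:
                    raise ValueError(f"planted contact names unknown gene {s!r}")
        for chrom, pos, n, src in self.intergenic_points:
            if n < 0:
                raise ValueError("planted pair counts must be >= 0")
            if src not in symbols:
                raise ValueError(f"intergenic point names unknown gene {src!r}")
        if self.noise_pairs < 0:
            raise ValueError("noise_pairs must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def make_genome(n_chroms: int = 1,
                chrom_len: int = 500_000,
                gc_segments: Optional[Sequence[Tuple[int, float]]] = None,
                enzyme_site: str = "AAGCTT",
                site_spacing_mean: int = 4000,
                seed: int = 0) -> Dict[str, str]:
    """Random genome with piecewise-constant GC and injected enzyme sites.

    ``gc_segments`` is a list of (length_bp, gc_fraction) blocks applied
    per chromosome (cycled/truncated to the chromosome length; default a
    single 0.5-GC block). Sites are spliced in at geometric spacing with
    the given mean so the digest is non-trivial. Deterministic per seed.
    """
    if chrom_len < 10 * site_spacing_mean:
        raise ValueError("chrom_len must be >= 10 * site_spacing_mean")
    segments = list(gc_segments) if gc_segments else [(chrom_len, 0.5)]
    for length, gc in segments:
        if not 0.0 < gc < 1.0:
            raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    genome: Dict[str, str] = {}
    for c in range(n_chroms):
        parts = []
        covered = 0
        i = 0
        while covered < chrom_len:
            length, gc = segments[i % len(segments)]
            length = min(length, chrom_len - covered)
            parts.append(_random_sequence(rng, length, gc))
            covered += length
            i += 1
        seq = list("".join(parts))
        _scrub_accidental_sites(seq, enzyme_site, rng)
        pos = 0
        while True:
            pos += int(rng.geometric(1.0 / site_spacing_mean))
            if pos + len(enzyme_site) >= chrom_len:
                break
            seq[pos:pos + len(enzyme_site)] = enzyme_site
        genome[f"chr{c + 1}"] = "".join(seq)
    return genome


def _scrub_accidental_sites(seq: list, site: str, rng: np.random.Generator) -> None:
    """Mutate one base of every chance occurrence of the enzyme site so
    the digest density is controlled by the injected sites alone."""
    mid = len(site) // 2
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    while True:
        text = "".join(seq)
        start = text.find(site)
        if start == -1:
            return
        while start != -1:
            pos = start + mid
            seq[pos] = others[seq[pos]][int(rng.integers(3))]
            start = text.find(site, start + len(site))


def make_gene_layout(genome: Dict[str, str],
                     n_genes: int = 20,
                     gene_len_range: Tuple[int, int] = (2_000, 10_000),
                     seed: int = 0) -> List[Gene]:
    """Place non-overlapping genes uniformly; symbols G0001... ."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    genes: List[Gene] = []
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise RuntimeError("could not place non-overlapping genes; "
                               "reduce n_genes or gene length")
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        limit = len(genome[chrom]) - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + length
        if any(s < end and start < e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"G{len(genes) + 1:04d}", chrom, start, end, strand))
    return genes


def _fragments_by_gene(fragments: Sequence[RestrictionFragment],
                       genes: Sequence[Gene]) -> Dict[str, List[RestrictionFragment]]:
    """Fragments usable for planting a gene's reads.

    Prefers fragments overlapping only that gene, so planted contacts do
    not leak edges to bystander genes; falls back to any overlapping
    fragment when a gene shares all its fragments."""
    exclusive: Dict[str, List[RestrictionFragment]] = {g.symbol: [] for g in genes}
    any_overlap: Dict[str, List[RestrictionFragment]] = {g.symbol: [] for g in genes}
    for f in fragments:
        owners = [g for g in genes if g.overlaps(f.chrom, f.start, f.end)]
        for g in owners:
            any_overlap[g.symbol].append(f)
            if len(owners) == 1:
                exclusive[g.symbol].append(f)
    out = {}
    for g in genes:
        frags = exclusive[g.symbol] or any_overlap[g.symbol]
        if not frags:
            raise ValueError(f"gene {g.symbol} overlaps no restriction fragment")
        out[g.symbol] = frags
    return out


def _end_in_fragment(rng: np.random.Generator, f: RestrictionFragment
                     ) -> Tuple[str, int, str]:
    """A read end near one of the fragment's restriction ends."""
    off = int(rng.integers(0, min(READ_END_OFFSET, f.length_bp)))
    if rng.random() < 0.5:
        pos = f.start + off
        strand = "+"
    else:
        pos = f.end - 1 - off
        strand = "-"
    return f.chrom, pos, strand


def simulate_hic(genome: Dict[str, str],
                 fragments: Sequence[RestrictionFragment],
                 genes: Sequence[Gene],
                 spec: ContactSpec,
                 sam_path: Optional[str] = None,
                 truth_path: Optional[str] = None) -> List[ReadPair]:
    """Generate Hicup-dialect read pairs realising a contact spec.

    Planted gene pairs get reads whose ends fall near the restriction
    ends of a random fragment of each gene; intergenic points pair the
    fragment containing the point with a fragment of the source gene;
    noise pairs join two uniformly random fragments. When paths are
    given, the SAM file (readable by load_hic_sam) and a ground-truth
    table are written alongside.
    """
    spec.validate([g.symbol for g in genes])
    rng = np.random.default_rng(spec.seed)
    gene_frags = _fragments_by_gene(fragments, genes) if genes else {}
    pairs: List[ReadPair] = []
    truth_rows: List[Tuple[str, str, str, int]] = []

    def pick(frags: Sequence[RestrictionFragment]) -> RestrictionFragment:
        return frags[int(rng.integers(len(frags)))]

    for a, b, n in spec.gene_pairs:
        for _ in range(n):
            c1, p1, s1 = _end_in_fragment(rng, pick(gene_frags[a]))
            c2, p2, s2 = _end_in_fragment(rng, pick(gene_frags[b]))
            pairs.append(ReadPair(c1, p1, s1, c2, p2, s2).canonical())
        truth_rows.append(("gene_pair", a, b, n))

    frag_list = list(fragments)
    for chrom, pos, n, src in spec.intergenic_points:
        containing = [f for f in frag_list
                      if f.chrom == chrom and f.start <= pos < f.end]
        if not containing:
            raise ValueError(f"intergenic point {chrom}:{pos} inside no fragment")
        target = containing[0]
        for _ in range(n):
            c1, p1, s1 = _end_in_fragment(rng, pick(gene_frags[src]))
            c2, p2, s2 = _end_in_fragment(rng, target)
            pairs.append(ReadPair(c1, p1, s1, c2, p2, s2).canonical())
        truth_rows.append(("intergenic", src, f"{chrom}:{pos}", n))

    for _ in range(spec.noise_pairs):
        f1 = pick(frag_list)
        f2 = pick(frag_list)
        c1, p1, s1 = _end_in_fragment(rng, f1)
        c2, p2, s2 = _end_in_fragment(rng, f2)
        pairs.append(ReadPair(c1, p1, s1, c2, p2, s2).canonical())
    if spec.noise_pairs:
        truth_rows.append(("noise", "", "", spec.noise_pairs))

    if sam_path is not None:
        from .hic_io import write_hic_sam
        write_hic_sam(sam_path, pairs,
                      chrom_lengths={c: len(s) for c, s in genome.items()})
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("kind\ta\tb\tn\n")
            for row in truth_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return pairs


def plant_features(genome: Dict[str, str],
                   motif_positions: Optional[Dict[str, List[int]]] = None,
                   rss_positions: Optional[Dict[str, List[Tuple[int, int]]]] = None,
                   isochore_layout: Optional[Dict[str, List[Tuple[int, int, float]]]] = None,
                   seed: int = 0) -> Tuple[Dict[str, str], Dict[str, FeatureTrack]]:
    """Splice truth features into a genome; returns (genome, truth tracks).

    ``motif_positions``: chrom -> CTCF-consensus start positions.
    ``rss_positions``: chrom -> (start, spacer) with spacer 12 or 23.
    ``isochore_layout``: chrom -> (start, end, gc) blocks regenerated at
    the stated GC so the segmenter has homogeneous segments to find.
    """
    rng = np.random.default_rng(seed)
    genome = {c: list(s) for c, s in genome.items()}
    truth: Dict[str, List[Tuple[str, int, int, float]]] = {
        "ctcf": [], "rss": [], "iso": []}

    for chrom, start, end, gc in _flat(isochore_layout):
        genome[chrom][start:end] = _random_sequence(rng, end - start, gc)

    consensus = default_ctcf_pwm().consensus
    for chrom, positions in (motif_positions or {}).items():
        for pos in positions:
            genome[chrom][pos:pos + len(consensus)] = consensus
            truth["ctcf"].append((chrom, pos, pos + len(consensus), 1.0))

    for chrom, sites in (rss_positions or {}).items():
        for pos, spacer in sites:
            if spacer not in (12, 23):
                raise ValueError("RSS spacer must be 12 or 23")
            spacer_seq = _random_sequence(rng, spacer, 0.5)
            site = RSS_HEPTAMER + spacer_seq + RSS_NONAMER
            genome[chrom][pos:pos + len(site)] = site
            truth["rss"].append((chrom, pos, pos + len(site), 0.0))

    for chrom, start, end, gc in _flat(isochore_layout):
        truth["iso"].append((chrom, start, end, _iso_class(gc)))

    tracks = {name: FeatureTrack(name, ivs) for name, ivs in truth.items()}
    return {c: "".join(s) for c, s in genome.items()}, tracks


def _flat(layout):
    for chrom, blocks in (layout or {}).items():
        for start, end, gc in blocks:
            yield chrom, start, end, gc


def _iso_class(gc: float) -> float:
    from .omics_map import ISOCHORE_BOUNDS
    return float(1 + int(np.searchsorted(ISOCHORE_BOUNDS, 100 * gc, side="left")))


def make_expression(genes: Sequence[Gene],
                    de_genes: Optional[Dict[str, float]] = None,
                    n_per_group: int = 5,
                    sigma: float = 0.2,
                    seed: int = 0) -> Tuple[pd.DataFrame, List[str]]:
    """Two-group log-normal expression matrix with planted fold changes.

    Baseline log2 expression per gene ~ N(5, 1); group B samples are
    shifted by the planted logFC for listed genes; per-sample noise is
    N(0, sigma) on the log2 scale. Returns (matrix genes x samples,
    group labels). Deterministic per seed.
    """
    de_genes = de_genes or {}
    unknown = set(de_genes) - {g.symbol for g in genes}
    if unknown:
        raise ValueError(f"de_genes names unknown symbols: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    symbols = [g.symbol for g in genes]
    base = rng.normal(5.0, 1.0, size=len(symbols))
    samples = ([f"A{i + 1}" for i in range(n_per_group)]
               + [f"B{i + 1}" for i in range(n_per_group)])
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    data = np.empty((len(symbols), len(samples)))
    for gi, sym in enumerate(symbols):
        shift = de_genes.get(sym, 0.0)
        for si, lab in enumerate(labels):
            log2 = base[gi] + (shift if lab == "B" else 0.0) \
                + rng.normal(0.0, sigma)
            data[gi, si] = 2.0 ** log2
    return pd.DataFrame(data, index=symbols, columns=samples), labels
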