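"""Multi-omics annotation of neighbourhood graphs.

Edges gain genomic-feature values (from any BED track or from the
on-the-fly predictors below); vertices gain per-kb feature densities
(for ERGM nodecov terms) and expression weights/colours. Predictors:
PWM scanning for CTCF-like binding sites, consensus-mismatch scanning
for cryptic recombination signal sequences (heptamer + 12/23 bp spacer
+ nonamer), and GC-homogeneity segmentation into the five isochore
families.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureTrack, Gene

__all__ = [
    "Pwm",
    "DeTable",
    "annotate_edges",
    "edge_annotation_summary",
    "predict_ctcf",
    "predict_rss",
    "call_isochores",
    "map_expression",
    "simple_de",
    "default_ctcf_pwm",
    "RSS_HEPTAMER",
    "RSS_NONAMER",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")

RSS_HEPTAMER = "CACAGTG"
RSS_NONAMER = "ACAAAAACC"

# GC% upper bounds of the five canonical isochore families (L1 L2 H1 H2 H3)
ISOCHORE_BOUNDS = (37.0, 41.0, 46.0, 53.0)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=np.int8)


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class Pwm:
    """Position weight matrix: 4 x L log-odds over A,C,G,T.

    ``threshold`` is the minimal log-odds score (natural log, uniform
    background) at which a site is called.
    """

    name: str
    matrix: np.ndarray  # shape (L, 4), log-odds
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM weights must be finite")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_probabilities(cls, name: str, probs: np.ndarray,
                           threshold_fraction: float = 0.8,
                           background: float = 0.25) -> "Pwm":
        probs = np.asarray(probs, dtype=float)
        logodds = np.log(np.maximum(probs, 1e-6) / background)
        pwm = cls(name, logodds, threshold=0.0)
        pwm.threshold = threshold_fraction * pwm.max_score
        return pwm


def default_ctcf_pwm() -> Pwm:
    """The bundled CTCF-like matrix (a constructed, synthetic PWM built
    around the canonical CTCF zinc-finger core consensus)."""
    text = resources.files("nucgraph.data").joinpath("ctcf_pwm.json").read_text()
    spec = json.loads(text)
    return Pwm.from_probabilities(spec["name"], np.array(spec["probabilities"]),
                                  threshold_fraction=spec["threshold_fraction"])


# ---------------------------------------------------------------------------
# Interval overlap machinery


class _OverlapCounter:
    """Counts track intervals overlapping a query, per chromosome.

    Uses the identity #overlaps = N - #(start >= query_end)
    - #(end <= query_start) on independently sorted bounds.
    """

    def __init__(self, track: FeatureTrack) -> None:
        self.starts: Dict[str, np.ndarray] = {}
        self.ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in track.by_chrom().items():
            self.starts[chrom] = np.sort(np.array([s for s, _, _ in ivs]))
            self.ends[chrom] = np.sort(np.array([e for _, e, _ in ivs]))

    def count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self.starts:
            return 0
        starts, ends = self.starts[chrom], self.ends[chrom]
        n = len(starts)
        ge = n - int(np.searchsorted(starts, end, side="left"))
        le = int(np.searchsorted(ends, start, side="right"))
        return n - ge - le


def annotate_edges(graph, track: FeatureTrack):
    """Annotate a neighbourhood graph with a feature track, in place.

    Every supporting contact (multi-edge) gets the number of track
    intervals overlapping either of its two fragment intervals; the
    exported edge table averages these per gene pair (mean per contact).
    Every vertex gets the per-kb density of track intervals over the
    gene body, stored as ``cov_<name>`` for ERGM nodecov use. Returns
    the graph.
    """
    counter = _OverlapCounter(track)
    for _, _, d in graph.g.edges(data=True):
        c1, s1, e1 = d["frag1"]
        c2, s2, e2 = d["frag2"]
        d.setdefault("features", {})[track.name] = float(
            counter.count(c1, s1, e1) + counter.count(c2, s2, e2))
    for sym, d in graph.g.nodes(data=True):
        gene: Gene = d["gene"]
        hits = counter.count(gene.chrom, gene.start, gene.end)
        d[f"cov_{track.name}"] = hits / ((gene.end - gene.start) / 1000.0)
    return graph


def edge_annotation_summary(graph, name: str, agg: str = "mean"
                            ) -> Dict[Tuple[str, str], float]:
    """Per-gene-pair aggregation of an edge annotation (mean/sum/max)."""
    funcs = {"mean": np.mean, "sum": np.sum, "max": np.max}
    if agg not in funcs:
        raise ValueError("agg must be one of mean, sum, max")
    groups: Dict[Tuple[str, str], List[float]] = {}
    for u, v, d in graph.g.edges(data=True):
        key = tuple(sorted((u, v)))
        groups.setdefault(key, []).append(d.get("features", {}).get(name, 0.0))
    return {k: float(funcs[agg](v)) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# On-the-fly predictors


def _as_sequences(sequence: Union[str, Dict[str, str]]) -> Dict[str, str]:
    if isinstance(sequence, str):
        return {"seq": sequence}
    return sequence


def _pwm_scan_strand(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; NaN where a window has N."""
    L = matrix.shape[0]
    n = len(codes)
    if n < L:
        return np.empty(0)
    scores = np.zeros(n - L + 1)
    bad = np.zeros(n - L + 1, dtype=bool)
    for j in range(L):
        window = codes[j:n - L + 1 + j]
        ok = window >= 0
        bad |= ~ok
        scores += np.where(ok, matrix[j, np.clip(window, 0, 3)], 0.0)
    scores[bad] = np.nan
    return scores


def predict_ctcf(sequence: Union[str, Dict[str, str]],
                 pwm: Optional[Pwm] = None) -> FeatureTrack:
    """Scan both strands for PWM hits scoring >= pwm.threshold.

    Windows containing N are skipped; hits are reported on forward
    coordinates with the log-odds score as value.
    """
    if pwm is None:
        pwm = default_ctcf_pwm()
    intervals = []
    for chrom, seq in _as_sequences(sequence).items():
        n = len(seq)
        L = pwm.length
        fwd = _pwm_scan_strand(_encode(seq), pwm.matrix)
        for pos in np.flatnonzero(np.nan_to_num(fwd, nan=-np.inf) >= pwm.threshold):
            intervals.append((chrom, int(pos), int(pos) + L, float(fwd[pos])))
        rev = _pwm_scan_strand(_encode(_revcomp(seq)), pwm.matrix)
        for pos in np.flatnonzero(np.nan_to_num(rev, nan=-np.inf) >= pwm.threshold):
            start = n - int(pos) - L
            intervals.append((chrom, start, start + L, float(rev[pos])))
    return FeatureTrack("ctcf", intervals)


def _mismatch_profile(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatches against the pattern at each start (N counts as mismatch)."""
    L = len(pattern)
    n = len(codes)
    if n < L:
        return np.empty(0, dtype=int)
    pat = _encode(pattern)
    mm = np.zeros(n - L + 1, dtype=int)
    for j in range(L):
        mm += (codes[j:n - L + 1 + j] != pat[j]).astype(int)
    return mm


_RSS_SPACERS = (11, 12, 13, 22, 23, 24)  # 12 +/- 1 and 23 +/- 1


def predict_rss(sequence: Union[str, Dict[str, str]],
                max_mismatch_hept: int = 1,
                max_mismatch_nona: int = 2) -> FeatureTrack:
    """Scan both strands for cryptic recombination signal sequences.

    A hit is a heptamer CACAGTG match (within ``max_mismatch_hept``
    mismatches) followed, after a spacer of 12+/-1 or 23+/-1 bp, by a
    nonamer ACAAAAACC match (within ``max_mismatch_nona``). The value is
    the total mismatch count (lower is better).
    """
    intervals = []
    for chrom, seq in _as_sequences(sequence).items():
        n = len(seq)
        for strand_seq, forward in ((seq, True), (_revcomp(seq), False)):
            codes = _encode(strand_seq)
            hept = _mismatch_profile(codes, RSS_HEPTAMER)
            nona = _mismatch_profile(codes, RSS_NONAMER)
            for start in np.flatnonzero(hept <= max_mismatch_hept):
                for spacer in _RSS_SPACERS:
                    npos = start + len(RSS_HEPTAMER) + spacer
                    if npos >= len(nona):
                        continue
                    if nona[npos] <= max_mismatch_nona:
                        end = npos + len(RSS_NONAMER)
                        value = float(hept[start] + nona[npos])
                        if forward:
                            intervals.append((chrom, int(start), int(end), value))
                        else:
                            intervals.append((chrom, n - int(end), n - int(start), value))
    return FeatureTrack("rss", intervals)


def call_isochores(sequence: Union[str, Dict[str, str]],
                   window_bp: int = 100_000,
                   min_len_bp: int = 300_000) -> FeatureTrack:
    """Segment sequences into the five isochore families by windowed GC%.

    Non-overlapping windows are classified (L1 < 37, L2 37-41, H1 41-46,
    H2 46-53, H3 > 53 GC%), adjacent same-class windows merged, and
    segments shorter than ``min_len_bp`` discarded. The value is the
    family index 1-5.
    """
    if window_bp > min_len_bp:
        raise ValueError("window_bp must be <= min_len_bp")
    intervals = []
    for chrom, seq in _as_sequences(sequence).items():
        n = len(seq)
        n_windows = n // window_bp
        if n_windows == 0:
            continue
        classes = []
        for w in range(n_windows):
            sub = seq[w * window_bp:(w + 1) * window_bp].upper()
            gc = sub.count("G") + sub.count("C")
            at = sub.count("A") + sub.count("T")
            pct = 100.0 * gc / (gc + at) if gc + at else 0.0
            classes.append(1 + int(np.searchsorted(ISOCHORE_BOUNDS, pct, side="left")))
        # merge runs of identical class
        run_start = 0
        for w in range(1, n_windows + 1):
            if w == n_windows or classes[w] != classes[run_start]:
                start = run_start * window_bp
                end = w * window_bp  # tail beyond the last full window ignored
                if end - start >= min_len_bp:
                    intervals.append((chrom, start, end, float(classes[run_start])))
                run_start = w
    return FeatureTrack("iso", intervals)


# ---------------------------------------------------------------------------
# Expression


@dataclass
class DeTable:
    """Differential-expression results: one row per gene (logFC, p)."""

    table: pd.DataFrame  # index gene symbol, columns logFC, p

    def __post_init__(self) -> None:
        if not {"logFC", "p"}.issubset(self.table.columns):
            raise ValueError("DeTable requires columns logFC and p")
        if not np.all(np.isfinite(self.table["logFC"])):
            raise ValueError("logFC must be finite")

    @classmethod
    def from_tsv(cls, path: str) -> "DeTable":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={df.columns[0]: "gene"}).set_index("gene")
        return cls(df[["logFC", "p"]])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def map_expression(graph, de: DeTable):
    """Map expression onto vertices: weight = |logFC|; colour red for
    up-regulation, green for down-regulation, grey when logFC = 0 or the
    gene is absent from the table. Returns the graph."""
    for sym, d in graph.g.nodes(data=True):
        if sym in de.table.index:
            lfc = float(de.table.loc[sym, "logFC"])
        else:
            lfc = 0.0
        d["weight"] = abs(lfc)
        d["colour"] = "red" if lfc > 0 else ("green" if lfc < 0 else "grey")
    return graph


def simple_de(expr_matrix: pd.DataFrame, group_labels: Sequence[str]) -> DeTable:
    """Plain two-group log-ratio differential expression.

    logFC = mean log2(group B) - mean log2(group A) per gene (groups in
    sorted label order); p is the Welch t-test p-value on log2 values
    when both groups have >= 2 samples, else 1. Expression must be
    strictly positive.
    """
    labels = pd.Series(list(group_labels), index=expr_matrix.columns)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two group labels, got {uniq}")
    if (expr_matrix <= 0).any().any():
        raise ValueError("expression values must be strictly positive")
    log2 = np.log2(expr_matrix)
    a = log2.loc[:, labels == uniq[0]]
    b = log2.loc[:, labels == uniq[1]]
    logfc = b.mean(axis=1) - a.mean(axis=1)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = pd.Series(p, index=expr_matrix.index).fillna(1.0)
    else:
        p = pd.Series(1.0, index=expr_matrix.index)
    return DeTable(pd.DataFrame({"logFC": logfc, "p": p}))
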