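"""Read-level Hi-C bias normalization under a Poisson covariate model.

Contact intensity is modelled log-linearly on windowed fragment
covariates — total fragment length, length-weighted GC content and mean
mappability — following the parametric Poisson approach of contact-map
correction, but applied at read level: each pair receives a reliability
score in [0, 1] (the Poisson enrichment quantile of its window-pair
count over the bias-only expectation), and filtering keeps pairs whose
score passes a user-chosen threshold. The classic binned contact-map
normalization is also provided.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import poisson

from .neighbourhood import assign_fragments
from .types import ReadPair, RestrictionFragment

__all__ = [
    "NormalizationModel",
    "ContactMap",
    "fit_bias_model",
    "score_reads",
    "filter_reads",
    "to_contact_map",
    "normalize_contact_map",
    "poisson_irls",
]

COVARIATE_FLOOR = 1e-3  # gc/mappability floored before log
COEF_NAMES = ("beta0", "beta_len", "beta_gc", "beta_map")


class FitError(RuntimeError):
    pass


def poisson_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 100) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson log-linear regression by iteratively reweighted least squares.

    Maximizes sum(y*eta - exp(eta)), eta = X @ beta. Converges when
    max|Δbeta| < tol; raises FitError after ``max_iter`` iterations.
    Returns (beta, standard errors) with SE from the observed information
    (X' W X)^-1.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-10))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        XtWX = X.T @ (X * W[:, None])
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from None
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            eta = X @ beta
            mu = np.exp(np.clip(eta, -30, 30))
            XtWX = X.T @ (X * mu[:, None])
            se = np.sqrt(np.diag(np.linalg.inv(XtWX)))
            return beta, se
    raise FitError(f"IRLS did not converge in {max_iter} iterations")


@dataclass
class _WindowTable:
    """Per-window aggregated covariates and read-end counts."""

    chrom: np.ndarray          # window chromosome
    start: np.ndarray          # window start (bp)
    log_len: np.ndarray        # log total fragment length
    log_gc: np.ndarray         # log length-weighted mean GC (floored)
    log_map: np.ndarray        # log mean mappability (floored)
    count: np.ndarray          # read ends in window


@dataclass
class NormalizationModel:
    """Fitted Poisson bias model over fixed genomic windows.

    Coefficients are kept per chromosome (used for intra-chromosomal
    pairs) plus one pooled genome-wide set (used for inter-chromosomal
    pairs and as fallback); ``scope='genome'`` fits the pooled model
    only. ``se`` mirrors ``coef``; dropped (constant) covariates carry
    coefficient 0 and SE nan.
    """

    window_bp: int
    scope: str
    windows: _WindowTable
    window_of_fragment: Dict[int, int]
    coef: Dict[Optional[str], np.ndarray]
    se: Dict[Optional[str], np.ndarray]
    pair_counts: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def _model_for(self, chrom1: str, chrom2: str) -> np.ndarray:
        if chrom1 == chrom2 and chrom1 in self.coef:
            return self.coef[chrom1]
        return self.coef[None]

    def eta(self, w: int, beta: np.ndarray) -> float:
        t = self.windows
        x = np.array([1.0, t.log_len[w], t.log_gc[w], t.log_map[w]])
        return float(x @ beta)


def _build_windows(pairs: Sequence[ReadPair],
                   fragments: Sequence[RestrictionFragment],
                   window_bp: int) -> Tuple[_WindowTable, Dict[int, int]]:
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    # fragment -> window of its midpoint
    keys: Dict[Tuple[str, int], int] = {}
    rows: List[Tuple[str, int]] = []
    window_of_fragment: Dict[int, int] = {}
    agg_len: List[float] = []
    agg_gc: List[float] = []
    agg_map: List[float] = []
    agg_n: List[int] = []
    for f in fragments:
        wkey = (f.chrom, (f.midpoint // window_bp) * window_bp)
        if wkey not in keys:
            keys[wkey] = len(rows)
            rows.append(wkey)
            agg_len.append(0.0)
            agg_gc.append(0.0)
            agg_map.append(0.0)
            agg_n.append(0)
        w = keys[wkey]
        window_of_fragment[f.id] = w
        agg_len[w] += f.length_bp
        agg_gc[w] += f.gc * f.length_bp
        agg_map[w] += f.mappability
        agg_n[w] += 1
    length = np.array(agg_len)
    gc = np.array(agg_gc) / length
    mapp = np.array(agg_map) / np.array(agg_n)
    count = np.zeros(len(rows))
    for p in pairs:
        for fid in (p.frag1_id, p.frag2_id):
            if fid is not None and fid in window_of_fragment:
                count[window_of_fragment[fid]] += 1
    table = _WindowTable(
        chrom=np.array([r[0] for r in rows]),
        start=np.array([r[1] for r in rows]),
        log_len=np.log(length),
        log_gc=np.log(np.maximum(gc, COVARIATE_FLOOR)),
        log_map=np.log(np.maximum(mapp, COVARIATE_FLOOR)),
        count=count,
    )
    return table, window_of_fragment


def _fit_one(table: _WindowTable, mask: np.ndarray,
             pair_counts: Dict[Tuple[int, int], int],
             intra_only: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the pairwise Poisson regression on one window subset.

    Observations are unordered window pairs (u, v), u <= v, with
    covariate rows [1, log len_u + log len_v, ...] and the observed
    pair count (zeros included); so the fitted mean of a pair is
    exp(eta_u + eta_v - beta0) with eta_w = beta0 + beta . logX_w.
    Constant covariates are dropped with a warning (coefficient 0).
    """
    if (table.count[mask] > 0).sum() < 2:
        raise FitError("need >= 2 windows with nonzero counts")
    widx = np.flatnonzero(mask)
    chrom = table.chrom[widx]
    iu, ju = np.triu_indices(len(widx), k=0)
    if intra_only:
        same = chrom[iu] == chrom[ju]
        iu, ju = iu[same], ju[same]
    u, v = widx[iu], widx[ju]
    y = np.array([pair_counts.get((min(a, b), max(a, b)), 0)
                  for a, b in zip(u, v)], dtype=float)
    cols = [np.ones(len(u)),
            table.log_len[u] + table.log_len[v],
            table.log_gc[u] + table.log_gc[v],
            table.log_map[u] + table.log_map[v]]
    keep = [0]
    for j in (1, 2, 3):
        if np.ptp(cols[j]) > 1e-12:
            keep.append(j)
        else:
            warnings.warn(f"covariate {COEF_NAMES[j]} is constant; dropped "
                          f"(coefficient reported 0)")
    X = np.column_stack([cols[j] for j in keep])
    b, s = poisson_irls(X, y)
    beta = np.zeros(4)
    se = np.full(4, np.nan)
    for bi, j in enumerate(keep):
        beta[j] = b[bi]
        se[j] = s[bi]
    return beta, se


def fit_bias_model(pairs: Sequence[ReadPair],
                   fragments: Sequence[RestrictionFragment],
                   window_bp: int = 1_000_000,
                   scope: str = "per-chromosome") -> NormalizationModel:
    """Fit the Poisson bias regression of window read-end counts on
    log(length), log(GC), log(mappability).

    ``scope='per-chromosome'`` (default) fits one coefficient set per
    chromosome for intra-chromosomal scoring plus a pooled genome-wide
    set for inter-chromosomal pairs; chromosomes with too few informative
    windows silently fall back to the pooled fit. ``scope='genome'``
    fits the pooled set only. Pairs must already carry fragment ids
    (:func:`nucgraph.neighbourhood.assign_fragments`).
    """
    if scope not in ("per-chromosome", "genome"):
        raise ValueError("scope must be 'per-chromosome' or 'genome'")
    if any(p.frag1_id is None or p.frag2_id is None for p in pairs):
        assign_fragments(list(pairs), fragments)
    table, window_of_fragment = _build_windows(pairs, fragments, window_bp)
    # unordered window-pair contact counts (fit observations + scoring)
    counts: Dict[Tuple[int, int], int] = {}
    for p in pairs:
        if p.frag1_id is None or p.frag2_id is None:
            continue
        u = window_of_fragment.get(p.frag1_id)
        v = window_of_fragment.get(p.frag2_id)
        if u is None or v is None:
            continue
        wp = (u, v) if u <= v else (v, u)
        counts[wp] = counts.get(wp, 0) + 1
    coef: Dict[Optional[str], np.ndarray] = {}
    se: Dict[Optional[str], np.ndarray] = {}
    all_mask = np.ones(len(table.count), dtype=bool)
    coef[None], se[None] = _fit_one(table, all_mask, counts, intra_only=False)
    if scope == "per-chromosome":
        for chrom in np.unique(table.chrom):
            mask = table.chrom == chrom
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    coef[chrom], se[chrom] = _fit_one(table, mask, counts,
                                                      intra_only=True)
            except FitError:
                pass  # pooled fallback
    return NormalizationModel(window_bp=window_bp, scope=scope, windows=table,
                              window_of_fragment=window_of_fragment,
                              coef=coef, se=se, pair_counts=counts)


def _window_pair(model: NormalizationModel, p: ReadPair) -> Optional[Tuple[int, int]]:
    if p.frag1_id is None or p.frag2_id is None:
        return None
    u = model.window_of_fragment.get(p.frag1_id)
    v = model.window_of_fragment.get(p.frag2_id)
    if u is None or v is None:
        return None
    return (u, v) if u <= v else (v, u)


def score_reads(pairs: Sequence[ReadPair],
                fragments: Sequence[RestrictionFragment],
                model: NormalizationModel) -> List[ReadPair]:
    """Score each pair with its Poisson enrichment quantile.

    For a pair joining windows (u, v), the bias-only expected intensity
    is mu = exp(eta_u + eta_v - beta0) and the observed window-pair
    count is y; the score is PoissonCDF(y - 1; mu) — the probability
    that bias alone would produce fewer contacts than observed. Pairs
    with an end outside all fragments keep score None.
    """
    scored = []
    for p in pairs:
        wp = _window_pair(model, p)
        if wp is None:
            p.score = None
            scored.append(p)
            continue
        u, v = wp
        beta = model._model_for(str(model.windows.chrom[u]),
                                str(model.windows.chrom[v]))
        mu = np.exp(model.eta(u, beta) + model.eta(v, beta) - beta[0])
        y = model.pair_counts.get(wp, 0)
        p.score = float(poisson.cdf(y - 1, mu))
        scored.append(p)
    return scored


def filter_reads(scored_pairs: Sequence[ReadPair],
                 threshold: float) -> List[ReadPair]:
    """Keep pairs whose score >= threshold (monotone in the threshold)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [p for p in scored_pairs if p.score is not None and p.score >= threshold]


# ---------------------------------------------------------------------------
# Contact maps


@dataclass
class ContactMap:
    """Symmetric binned contact-count matrix.

    ``bins`` orders (chrom, start) genomic bins; ``counts`` is symmetric
    with each read pair incrementing exactly one cell of the upper
    triangle (mirrored below the diagonal).
    """

    bin_size_bp: int
    bins: List[Tuple[str, int]]
    counts: np.ndarray

    @property
    def total_pairs(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())

    def to_dense_tsv(self, path: str) -> None:
        labels = [f"{c}:{s}" for c, s in self.bins]
        with open(path, "w") as fh:
            fh.write("bin\t" + "\t".join(labels) + "\n")
            for lab, row in zip(labels, self.counts):
                fh.write(lab + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")

    def to_triplet_tsv(self, path: str) -> None:
        """MTX-style sparse triplets over the upper triangle."""
        with open(path, "w") as fh:
            fh.write("bin1\tbin2\tcount\n")
            n = len(self.bins)
            for i in range(n):
                for j in range(i, n):
                    if self.counts[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{self.counts[i, j]:g}\n")


def _bin_index(fragments: Sequence[RestrictionFragment],
               bin_size: int) -> Tuple[List[Tuple[str, int]], Dict[Tuple[str, int], int]]:
    extent: Dict[str, int] = {}
    for f in fragments:
        extent[f.chrom] = max(extent.get(f.chrom, 0), f.end)
    bins: List[Tuple[str, int]] = []
    for chrom in sorted(extent):
        for start in range(0, extent[chrom], bin_size):
            bins.append((chrom, start))
    return bins, {b: i for i, b in enumerate(bins)}


def to_contact_map(pairs: Sequence[ReadPair],
                   fragments: Sequence[RestrictionFragment],
                   bin_size: int) -> ContactMap:
    """Bin read pairs into a symmetric raw contact-count matrix."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins, index = _bin_index(fragments, bin_size)
    counts = np.zeros((len(bins), len(bins)))
    for p in pairs:
        b1 = index.get((p.chrom1, (p.pos1 // bin_size) * bin_size))
        b2 = index.get((p.chrom2, (p.pos2 // bin_size) * bin_size))
        if b1 is None or b2 is None:
            continue
        i, j = min(b1, b2), max(b1, b2)
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ContactMap(bin_size, bins, counts)


def normalize_contact_map(cmap: ContactMap,
                          fragments: Sequence[RestrictionFragment],
                          model: NormalizationModel) -> ContactMap:
    """Divide each cell by its bias expectation exp(eta_i + eta_j - beta0).

    Bin covariates are aggregated from member fragments with the same
    recipe as the model windows; the pooled (genome-wide) coefficient
    set is used. Symmetry and non-negativity are preserved.
    """
    beta = model.coef[None]
    n = len(cmap.bins)
    index = {b: i for i, b in enumerate(cmap.bins)}
    length = np.zeros(n)
    gc = np.zeros(n)
    mapp = np.zeros(n)
    nfrag = np.zeros(n)
    for f in fragments:
        b = index.get((f.chrom, (f.midpoint // cmap.bin_size_bp) * cmap.bin_size_bp))
        if b is None:
            continue
        length[b] += f.length_bp
        gc[b] += f.gc * f.length_bp
        mapp[b] += f.mappability
        nfrag[b] += 1
    ok = nfrag > 0
    eta = np.zeros(n)
    eta[ok] = (beta[0]
               + beta[1] * np.log(length[ok])
               + beta[2] * np.log(np.maximum(gc[ok] / length[ok], COVARIATE_FLOOR))
               + beta[3] * np.log(np.maximum(mapp[ok] / nfrag[ok], COVARIATE_FLOOR)))
    eta[~ok] = beta[0]  # empty bins: unit bias
    expected = np.exp(eta[:, None] + eta[None, :] - beta[0])
    return ContactMap(cmap.bin_size_bp, list(cmap.bins), cmap.counts / expected)
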