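"""Exponential-family random graph models on simple undirected graphs.

P(G) proportional to exp(theta . s(G)) with supported statistics:
``edges``, ``nodecov(x)`` (sum over edges of x_i + x_j), ``absdiff(x)``
(sum over edges of |x_i - x_j|), ``degree(k)`` (number of vertices of
degree k) and ``triangle``. Dyad-independent models (edges / nodecov /
absdiff only) are fitted exactly by logistic regression of the dyad
indicator on per-dyad change statistics; models with degree or triangle
terms use Geyer-Thompson MCMC maximum likelihood with a Metropolis
single-toggle sampler, restarted from the maximum pseudo-likelihood
fit. Simulation and goodness-of-fit diagnostics (degree, edgewise
shared partners, geodesic distance) round out the workflow.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
from scipy import optimize, stats

__all__ = [
    "ErgmError",
    "DegeneracyError",
    "ErgmTerm",
    "parse_terms",
    "ErgmFit",
    "GofReport",
    "graph_statistics_vector",
    "change_statistics",
    "ergm_fit",
    "simulate_from_ergm",
    "ergm_gof",
]


class ErgmError(RuntimeError):
    pass


class DegeneracyError(ErgmError):
    """Sampler collapsed to the empty or complete graph."""


DYAD_INDEPENDENT = {"edges", "nodecov", "absdiff"}
KNOWN_TERMS = DYAD_INDEPENDENT | {"degree", "triangle"}


@dataclass(frozen=True)
class ErgmTerm:
    kind: str
    arg: Optional[Union[str, int]] = None

    def __post_init__(self):
        if self.kind == "mutual":
            raise ErgmError(
                "the 'mutual' term is meaningless on undirected graphs; "
                "a directed projection is not implemented")
        if self.kind not in KNOWN_TERMS:
            raise ErgmError(f"unknown ERGM term {self.kind!r}")
        if self.kind in ("nodecov", "absdiff") and not isinstance(self.arg, str):
            raise ErgmError(f"{self.kind} requires a covariate name")
        if self.kind == "degree" and not isinstance(self.arg, int):
            raise ErgmError("degree requires an integer k")

    @property
    def label(self) -> str:
        if self.arg is None:
            return self.kind
        return f"{self.kind}.{self.arg}"


def parse_terms(spec: Union[str, Sequence]) -> List[ErgmTerm]:
    """Parse 'edges,nodecov:ctcf,degree:1,triangle' or a list thereof."""
    if isinstance(spec, str):
        spec = [s.strip() for s in spec.split(",") if s.strip()]
    terms = []
    for item in spec:
        if isinstance(item, ErgmTerm):
            terms.append(item)
            continue
        if ":" in item:
            kind, arg = item.split(":", 1)
            terms.append(ErgmTerm(kind, int(arg) if kind == "degree" else arg))
        else:
            terms.append(ErgmTerm(item))
    if not terms:
        raise ErgmError("empty term list")
    return terms


# ---------------------------------------------------------------------------
# Model state: adjacency matrix + covariate arrays


class _Model:
    def __init__(self, n: int, terms: Sequence[ErgmTerm],
                 covariates: Dict[str, np.ndarray]):
        self.n = n
        self.terms = list(terms)
        self.cov = covariates
        for t in self.terms:
            if t.kind in ("nodecov", "absdiff") and t.arg not in covariates:
                raise ErgmError(f"covariate {t.arg!r} missing for term {t.label}")
        self.dyad_independent = all(t.kind in DYAD_INDEPENDENT for t in self.terms)

    def statistics(self, A: np.ndarray) -> np.ndarray:
        """Full recomputation of the sufficient statistics s(G)."""
        iu, ju = np.triu_indices(self.n, k=1)
        present = A[iu, ju].astype(bool)
        deg = A.sum(axis=1)
        out = np.zeros(len(self.terms))
        for k, t in enumerate(self.terms):
            if t.kind == "edges":
                out[k] = present.sum()
            elif t.kind == "nodecov":
                x = self.cov[t.arg]
                out[k] = (x[iu[present]] + x[ju[present]]).sum()
            elif t.kind == "absdiff":
                x = self.cov[t.arg]
                out[k] = np.abs(x[iu[present]] - x[ju[present]]).sum()
            elif t.kind == "degree":
                out[k] = int((deg == t.arg).sum())
            elif t.kind == "triangle":
                out[k] = np.trace(np.linalg.matrix_power(A, 3)) / 6.0
        return out

    def change(self, A: np.ndarray, i: int, j: int) -> np.ndarray:
        """Change statistics s(G + ij) - s(G - ij) for dyad (i, j)."""
        out = np.zeros(len(self.terms))
        deg = None
        for k, t in enumerate(self.terms):
            if t.kind == "edges":
                out[k] = 1.0
            elif t.kind == "nodecov":
                x = self.cov[t.arg]
                out[k] = x[i] + x[j]
            elif t.kind == "absdiff":
                x = self.cov[t.arg]
                out[k] = abs(x[i] - x[j])
            elif t.kind == "degree":
                if deg is None:
                    deg = A.sum(axis=1)
                # degrees of i and j without the (i, j) edge
                di = deg[i] - A[i, j]
                dj = deg[j] - A[i, j]
                delta = 0
                for d in (di, dj):
                    if d + 1 == t.arg:
                        delta += 1
                    if d == t.arg:
                        delta -= 1
                out[k] = delta
            elif t.kind == "triangle":
                common = int(np.dot(A[i], A[j]) - A[i, j] * (A[i, i] + A[j, j]))
                out[k] = common
        return out

    def all_dyad_change(self, A: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(change-statistic matrix, edge indicator) over all dyads i<j."""
        iu, ju = np.triu_indices(self.n, k=1)
        X = np.empty((len(iu), len(self.terms)))
        for r, (i, j) in enumerate(zip(iu, ju)):
            X[r] = self.change(A, int(i), int(j))
        y = A[iu, ju].astype(float)
        return X, y


def _prepare(graph, terms, covariates) -> Tuple[_Model, np.ndarray, List[str]]:
    """Normalize inputs: accepts a NeighbourhoodGraph, networkx Graph, or
    (n, adjacency) style matrix; resolves covariates to vertex order."""
    if hasattr(graph, "simple_graph"):
        nxg = graph.simple_graph()
        order = graph.vertex_order()
    elif isinstance(graph, nx.Graph):
        nxg = graph
        order = sorted(graph.nodes)
    else:
        A = np.asarray(graph)
        order = [str(i) for i in range(A.shape[0])]
        cov = {k: np.asarray(v, dtype=float)
               for k, v in (covariates or {}).items()}
        terms = parse_terms(terms)
        return _Model(A.shape[0], terms, cov), A.astype(int), order
    n = len(order)
    idx = {s: i for i, s in enumerate(order)}
    A = np.zeros((n, n), dtype=int)
    for u, v in nxg.edges():
        if u != v:
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1
    terms = parse_terms(terms)
    cov: Dict[str, np.ndarray] = {}
    for t in terms:
        if t.kind in ("nodecov", "absdiff"):
            name = t.arg
            if covariates and name in covariates:
                src = covariates[name]
                if isinstance(src, dict):
                    cov[name] = np.array([float(src[s]) for s in order])
                else:
                    cov[name] = np.asarray(src, dtype=float)
            elif all(f"cov_{name}" in nxg.nodes[s] for s in order):
                cov[name] = np.array([float(nxg.nodes[s][f"cov_{name}"])
                                      for s in order])
            else:
                missing = [s for s in order
                           if not (covariates and s in covariates.get(name, {}))
                           and f"cov_{name}" not in nxg.nodes[s]]
                raise ErgmError(
                    f"covariate {name!r} missing for vertices: {missing[:5]}")
    return _Model(n, terms, cov), A, order


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class ErgmFit:
    """Fitted ERGM: coefficient table plus sampler diagnostics."""

    terms: List[ErgmTerm]
    theta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    method: str
    n_vertices: int
    covariates: Dict[str, np.ndarray] = field(default_factory=dict)
    vertex_order: List[str] = field(default_factory=list)
    observed_stats: Optional[np.ndarray] = None
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{'term':<16}{'Estimate':>12}{'Std. Error':>12}{'p-value':>12}"]
        for t, th, s, pv in zip(self.terms, self.theta, self.se, self.p):
            lines.append(f"{t.label:<16}{th:>12.5f}{s:>12.5f}{pv:>12.3g}")
        lines.append(f"method: {self.method}")
        return "\n".join(lines)

    def to_json(self, path: str) -> None:
        obj = {
            "terms": [[t.kind, t.arg] for t in self.terms],
            "theta": self.theta.tolist(),
            "se": self.se.tolist(),
            "p": self.p.tolist(),
            "method": self.method,
            "n_vertices": self.n_vertices,
            "covariates": {k: v.tolist() for k, v in self.covariates.items()},
            "vertex_order": self.vertex_order,
            "observed_stats": (None if self.observed_stats is None
                               else self.observed_stats.tolist()),
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ErgmFit":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            terms=[ErgmTerm(k, a) for k, a in obj["terms"]],
            theta=np.array(obj["theta"]),
            se=np.array(obj["se"]),
            p=np.array(obj["p"]),
            method=obj["method"],
            n_vertices=obj["n_vertices"],
            covariates={k: np.array(v) for k, v in obj["covariates"].items()},
            vertex_order=obj["vertex_order"],
            observed_stats=(None if obj["observed_stats"] is None
                            else np.array(obj["observed_stats"])),
            diagnostics=obj["diagnostics"],
        )


def _logistic_mle(X: np.ndarray, y: np.ndarray,
                  tol: float = 1e-10, max_iter: int = 100
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson logistic regression; SE from observed information."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        if np.all(W < 1e-12):
            raise ErgmError(
                "perfect separation in the logistic fit; consider removing a term")
        XtWX = X.T @ (X * W[:, None])
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            raise ErgmError("singular information matrix in logistic fit; "
                            "consider removing a collinear term") from None
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    else:
        raise ErgmError("logistic fit did not converge")
    if np.max(np.abs(beta)) > 25:
        raise ErgmError(
            "perfect separation in the logistic fit; consider removing a term")
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    XtWX = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(XtWX)))
    return beta, se


def graph_statistics_vector(graph, terms, covariates=None) -> np.ndarray:
    """Sufficient statistics s(G) of a graph for the given terms."""
    model, A, _ = _prepare(graph, terms, covariates)
    return model.statistics(A)


def change_statistics(graph, terms, covariates=None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-dyad change statistics and edge indicators of a graph."""
    model, A, _ = _prepare(graph, terms, covariates)
    return model.all_dyad_change(A)


def ergm_fit(graph, terms, covariates=None, method: str = "auto",
             mcmc_params: Optional[dict] = None, seed: int = 0) -> ErgmFit:
    """Fit an ERGM to the simple projection of a graph.

    ``method='auto'`` uses the exact logistic MLE for dyad-independent
    models and MCMC-MLE otherwise; 'exact-logistic' and 'mcmc-mle'
    force a route. Wald z p-values are reported per term.
    """
    model, A, order = _prepare(graph, terms, covariates)
    s_obs = model.statistics(A)
    if method == "auto":
        method = "exact-logistic" if model.dyad_independent else "mcmc-mle"
    if method == "exact-logistic" and not model.dyad_independent:
        raise ErgmError("exact-logistic requires a dyad-independent model")

    X, y = model.all_dyad_change(A)
    theta0, se0 = _logistic_mle(X, y)  # exact MLE or MPLE start

    if method == "exact-logistic":
        z = theta0 / se0
        p = 2 * stats.norm.sf(np.abs(z))
        return ErgmFit(model.terms, theta0, se0, p, "exact-logistic",
                       model.n, dict(model.cov), order, s_obs)
    if method != "mcmc-mle":
        raise ErgmError(f"unknown method {method!r}")

    params = {"n_sims": 500, "burn_in": 10_000, "thin": 200,
              "outer_iters": 3, **(mcmc_params or {})}
    rng = np.random.default_rng(seed)
    theta = theta0.copy()
    info = np.eye(len(theta))
    acc_rate = 0.0
    for outer in range(params["outer_iters"]):
        draws, stats_mat, acc_rate = _sample(
            model, theta, params["n_sims"], params["burn_in"], params["thin"],
            rng, start=A, return_graphs=False)
        dens = stats_for_density(model, stats_mat)
        if dens is not None and (np.all(dens < 0.005) or np.all(dens > 0.995)):
            raise DegeneracyError(
                f"sampler degenerate at theta={theta}: simulated densities "
                f"collapse to {'empty' if np.all(dens < 0.005) else 'complete'} graphs")
        theta, info = _geyer_thompson_step(theta, s_obs, stats_mat)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = theta / se
    p = 2 * stats.norm.sf(np.abs(z))
    ess = _effective_sample_size(stats_mat[:, 0])
    fit = ErgmFit(model.terms, theta, se, p, "mcmc-mle", model.n,
                  dict(model.cov), order, s_obs,
                  diagnostics={"acceptance_rate": float(acc_rate),
                               "ess_first_stat": float(ess),
                               "n_sims": params["n_sims"]})
    return fit


def stats_for_density(model: _Model, stats_mat: np.ndarray) -> Optional[np.ndarray]:
    for k, t in enumerate(model.terms):
        if t.kind == "edges":
            return stats_mat[:, k] / (model.n * (model.n - 1) / 2)
    return None


def _geyer_thompson_step(theta0: np.ndarray, s_obs: np.ndarray,
                         stats_mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One importance-sampled log-likelihood-ratio maximization.

    Maximizes theta.s_obs - log mean exp((theta - theta0).s_i) over the
    sample drawn at theta0; returns (theta_hat, Fisher information
    estimated as the importance-weighted covariance of s)."""
    S = stats_mat

    def negll(th):
        d = S @ (th - theta0)
        m = d.max()
        return -(th @ s_obs) + m + np.log(np.mean(np.exp(d - m)))

    def grad(th):
        d = S @ (th - theta0)
        w = np.exp(d - d.max())
        w /= w.sum()
        return -(s_obs - w @ S)

    res = optimize.minimize(negll, theta0, jac=grad, method="BFGS",
                            options={"maxiter": 200})
    th = res.x
    d = S @ (th - theta0)
    w = np.exp(d - d.max())
    w /= w.sum()
    mean = w @ S
    centred = S - mean
    info = (centred * w[:, None]).T @ centred
    # guard against a near-singular weighted covariance
    info = info + 1e-10 * np.eye(len(th))
    return th, info


def _effective_sample_size(x: np.ndarray) -> float:
    n = len(x)
    if n < 3 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] < 0.05:
            break
        tau += 2 * acf[k]
    return n / tau


# ---------------------------------------------------------------------------
# Simulation


def _sample(model: _Model, theta: np.ndarray, n_sims: int, burn_in: int,
            thin: int, rng: np.random.Generator,
            start: Optional[np.ndarray] = None, return_graphs: bool = True):
    """Metropolis single-dyad toggle chain.

    Proposes a uniformly random dyad toggle and accepts with probability
    min(1, exp(theta . ds)); sufficient statistics are maintained
    incrementally. Returns (graphs or None, statistics matrix, acceptance
    rate)."""
    n = model.n
    A = (np.zeros((n, n), dtype=int) if start is None else start.copy())
    s = model.statistics(A)
    iu, ju = np.triu_indices(n, k=1)
    n_dyads = len(iu)
    total = burn_in + n_sims * thin
    picks = rng.integers(0, n_dyads, size=total)
    us = rng.random(total)
    accepted = 0
    draws = []
    stats_mat = np.empty((n_sims, len(theta)))
    next_record = burn_in + thin - 1
    rec = 0
    for step in range(total):
        i = int(iu[picks[step]])
        j = int(ju[picks[step]])
        delta = model.change(A, i, j)
        sign = -1.0 if A[i, j] else 1.0
        logr = sign * float(theta @ delta)
        if logr >= 0 or us[step] < np.exp(logr):
            A[i, j] = A[j, i] = 1 - A[i, j]
            s = s + sign * delta
            accepted += 1
        if step == next_record:
            stats_mat[rec] = s
            if return_graphs:
                draws.append(A.copy())
            rec += 1
            next_record += thin
    return (draws if return_graphs else None), stats_mat, accepted / total


def simulate_from_ergm(terms, theta, n_vertices: int,
                       covariates: Optional[Dict[str, np.ndarray]] = None,
                       n_sims: int = 100, burn_in: int = 10_000,
                       thin: int = 100, seed: int = 0,
                       return_stats: bool = False):
    """Draw graphs (adjacency matrices) from an ERGM by Metropolis toggling.

    The chain starts from the empty graph, discards ``burn_in`` toggle
    proposals, then records every ``thin``-th state. For dyad-independent
    models the per-dyad edge frequency converges to the logistic closed
    form. Deterministic per seed.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ErgmError("theta must be finite")
    cov = {k: np.asarray(v, dtype=float) for k, v in (covariates or {}).items()}
    model = _Model(n_vertices, parse_terms(terms), cov)
    rng = np.random.default_rng(seed)
    draws, stats_mat, acc = _sample(model, theta, n_sims, burn_in, thin, rng)
    if return_stats:
        return draws, stats_mat, acc
    return draws


# ---------------------------------------------------------------------------
# Goodness of fit


def _degree_dist(A: np.ndarray, max_deg: int) -> np.ndarray:
    deg = A.sum(axis=1)
    return np.bincount(deg.astype(int), minlength=max_deg + 1)[:max_deg + 1]


def _esp_dist(A: np.ndarray, max_esp: int) -> np.ndarray:
    """Edgewise shared partners: for each edge, the number of common
    neighbours of its endpoints."""
    out = np.zeros(max_esp + 1, dtype=int)
    n = A.shape[0]
    common = A @ A
    iu, ju = np.nonzero(np.triu(A, k=1))
    for i, j in zip(iu, ju):
        c = int(common[i, j])
        out[min(c, max_esp)] += 1
    return out


def _geodesic_dist(A: np.ndarray, max_d: int) -> np.ndarray:
    """Dyad counts at geodesic distance 1..max_d, plus an unreachable bin."""
    g = nx.from_numpy_array(A)
    out = np.zeros(max_d + 1, dtype=int)  # index d-1 for d, last = infinity
    n = A.shape[0]
    reached = 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if dst > src and d >= 1:
                out[min(d, max_d) - 1] += 1
                reached += 1
    out[-1] = n * (n - 1) // 2 - reached
    return out


@dataclass
class GofReport:
    """Observed vs simulated distributions for degree, edgewise shared
    partners and geodesic distance, with per-bin simulation quantiles."""

    observed: Dict[str, np.ndarray]
    simulated: Dict[str, np.ndarray]  # (n_sims, bins)
    bins: Dict[str, List[str]]

    STATS = ("degree", "esp", "geodesic")

    def quantiles(self, stat: str, qs=(0.0, 0.25, 0.5, 0.75, 1.0)) -> np.ndarray:
        return np.quantile(self.simulated[stat], qs, axis=0)

    def envelope_coverage(self, stat: str) -> float:
        """Share of bins where the observed count lies inside the
        simulated [min, max] envelope."""
        sims = self.simulated[stat]
        obs = self.observed[stat]
        lo = sims.min(axis=0)
        hi = sims.max(axis=0)
        ok = (obs >= lo) & (obs <= hi)
        return float(ok.mean())

    def plot(self, path: str) -> None:
        """Three-panel envelope chart (degree / ESP / geodesic)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 1, figsize=(7, 9))
        for ax, stat in zip(axes, self.STATS):
            q = self.quantiles(stat)
            x = np.arange(q.shape[1])
            ax.fill_between(x, q[0], q[4], alpha=0.2, label="sim min-max")
            ax.fill_between(x, q[1], q[3], alpha=0.35, label="sim IQR")
            ax.plot(x, self.observed[stat], "k-", lw=2, label="observed")
            ax.set_xticks(x)
            ax.set_xticklabels(self.bins[stat], fontsize=7)
            ax.set_title(stat)
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def ergm_gof(graph, fit: ErgmFit, n_sims: int = 100, seed: int = 0) -> GofReport:
    """Simulate from a fitted model and tabulate the three standard
    topology diagnostics against the observed graph."""
    model, A, _ = _prepare(graph, fit.terms, fit.covariates)
    n = model.n
    draws = simulate_from_ergm(fit.terms, fit.theta, n,
                               covariates=fit.covariates, n_sims=n_sims,
                               seed=seed)
    max_deg = n - 1
    max_esp = max(2, int(max(_esp_dist(A, n).nonzero()[0], default=0)) + 2)
    max_esp = min(max_esp, n - 2) if n > 2 else 1
    max_geo = n  # geodesic bins 1..n plus infinity
    observed = {
        "degree": _degree_dist(A, max_deg),
        "esp": _esp_dist(A, max_esp),
        "geodesic": _geodesic_dist(A, max_geo),
    }
    simulated = {k: np.zeros((len(draws), len(v))) for k, v in observed.items()}
    for r, B in enumerate(draws):
        simulated["degree"][r] = _degree_dist(B, max_deg)
        simulated["esp"][r] = _esp_dist(B, max_esp)
        simulated["geodesic"][r] = _geodesic_dist(B, max_geo)
    bins = {
        "degree": [str(d) for d in range(max_deg + 1)],
        "esp": [str(d) for d in range(max_esp + 1)],
        "geodesic": [str(d) for d in range(1, max_geo + 1)] + ["inf"],
    }
    return GofReport(observed, simulated, bins)
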