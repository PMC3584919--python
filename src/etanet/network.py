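"""Weighted match networks and competitive label diffusion.

Every protein is a node; every reciprocal template match is an undirected
edge. An edge's raw quality ``s`` is the mean of the z-scored RMSD and
z-scored ETScore of its best match over all matches in the network,

    s_ij = 1/2 [ (rmsd_ij - mu_rmsd)/sigma_rmsd + (ET_ij - mu_ET)/sigma_ET ],

so better-than-average matches have negative ``s``. Because diffusion needs
nonnegative weights, ``s`` is passed through a monotone decreasing transform
(default ``W = exp(-s)``).

For each function, nodes are labeled +1 (known to have it), -1 (known to have
some other function), or 0 (unknown), and the diffused scores ``f`` minimize

    H(f) = sum_i (f_i - y_i)^2 + alpha * sum_{i<j} w_ij (f_i - f_j)^2,

whose unique minimizer solves (I + alpha L) f = y with L = D - W the graph
Laplacian. Diffused scores are standardized over the unknown nodes into
confidence z-scores; each unknown node is predicted the function with the
largest z.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.stats import rankdata

from .model import AnnotationTable, ProteinRecord
from .pipeline import MatchEngine

SPARSE_THRESHOLD = 500


@dataclass(eq=False)
class NetworkEdge:
    a: str
    b: str
    rmsd: float
    et_score: float
    s: float = float("nan")
    weight: float = float("nan")


def edge_weight(s: float | np.ndarray, transform: str = "exp") -> np.ndarray:
    """Monotone decreasing map from combined z-score to nonnegative weight."""
    s = np.asarray(s, dtype=float)
    if transform == "exp":
        return np.exp(-s)
    if transform == "relu":
        return np.maximum(0.0, -s)
    if transform == "fixed":
        return np.ones_like(s)
    if transform == "rank":
        flat = np.atleast_1d(s)
        w = 1.0 - (rankdata(flat) - 1.0) / len(flat)
        return w.reshape(s.shape)
    raise ValueError(f"unknown weight transform {transform!r}")


@dataclass(eq=False)
class MatchNetwork:
    """Symmetric nonnegative weighted adjacency over proteins."""

    nodes: list[str]
    W: np.ndarray
    edges: dict[tuple[str, str], NetworkEdge]
    stats: dict[str, float]
    transform: str = "exp"

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    @classmethod
    def from_edges(
        cls,
        nodes: Iterable[str],
        edge_scores: Mapping[tuple[str, str], tuple[float, float]],
        transform: str = "exp",
    ) -> "MatchNetwork":
        nodes = sorted(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        W = np.zeros((n, n))
        edges: dict[tuple[str, str], NetworkEdge] = {}
        stats = {"mu_rmsd": float("nan"), "sigma_rmsd": float("nan"),
                 "mu_et": float("nan"), "sigma_et": float("nan")}
        if edge_scores:
            keys = sorted((min(a, b), max(a, b)) for a, b in edge_scores)
            raw = {
                (min(a, b), max(a, b)): v for (a, b), v in edge_scores.items()
            }
            rmsds = np.array([raw[k][0] for k in keys], dtype=float)
            ets = np.array([raw[k][1] for k in keys], dtype=float)
            mu_r, sd_r = float(rmsds.mean()), float(rmsds.std())  # population SD
            mu_e, sd_e = float(ets.mean()), float(ets.std())
            stats = {"mu_rmsd": mu_r, "sigma_rmsd": sd_r, "mu_et": mu_e, "sigma_et": sd_e}
            if transform != "fixed" and (sd_r == 0.0 or sd_e == 0.0):
                raise ValueError(
                    "zero variance in rmsd or ETScore across network matches; "
                    "use transform='fixed' for unit edge weights"
                )
            if transform == "fixed":
                s = np.zeros(len(keys))
            else:
                s = 0.5 * ((rmsds - mu_r) / sd_r + (ets - mu_e) / sd_e)
            w = edge_weight(s, transform)
            for k, (a, b) in enumerate(keys):
                edges[(a, b)] = NetworkEdge(
                    a, b, float(rmsds[k]), float(ets[k]), float(s[k]), float(w[k])
                )
                W[idx[a], idx[b]] = W[idx[b], idx[a]] = w[k]
        return cls(nodes=nodes, W=W, edges=edges, stats=stats, transform=transform)


def build_network(
    proteins: Mapping[str, ProteinRecord],
    mode: str,
    model,
    transform: str = "exp",
    engine: MatchEngine | None = None,
    **engine_kwargs,
) -> MatchNetwork:
    """Reciprocal-match network over a protein set (query-query, query-target
    and target-target parts all arise from running every unordered pair).

    Each reciprocal pair contributes one undirected edge carrying the
    (rmsd, ETScore) of its minimum-RMSD significant match.
    """
    if engine is None:
        engine = MatchEngine(proteins, model, mode, **engine_kwargs)
    ids = sorted(proteins)
    edge_scores: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pairs = engine.reciprocal_pairs(a, b)
            if pairs:
                best = min((p.best_match for p in pairs), key=lambda m: m.rmsd)
                edge_scores[(a, b)] = (best.rmsd, best.et_score)
    return MatchNetwork.from_edges(ids, edge_scores, transform)


def _validate_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    if np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("W must have a zero diagonal")
    return W


def diffuse(W: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Solve (I + alpha L) f = y, the unique minimizer of the diffusion objective.

    The system is symmetric positive definite for any valid W and alpha > 0;
    dense Cholesky below 500 nodes, sparse factorization above.
    """
    W = _validate_adjacency(W)
    y = np.asarray(y, dtype=float)
    if y.shape != (W.shape[0],):
        raise ValueError("y length must equal the node count")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    n = W.shape[0]
    if n >= SPARSE_THRESHOLD:
        Ws = scipy.sparse.csr_matrix(W)
        L = scipy.sparse.diags(np.asarray(Ws.sum(axis=1)).ravel()) - Ws
        A = scipy.sparse.identity(n, format="csc") + alpha * L.tocsc()
        return scipy.sparse.linalg.spsolve(A, y)
    L = np.diag(W.sum(axis=1)) - W
    A = np.eye(n) + alpha * L
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), y)


def confidence_z(f: np.ndarray, unknown_mask: np.ndarray) -> np.ndarray:
    """Standardize diffused scores over the unknown nodes (population SD).

    Returns one z per unknown node, in node order. Constant f over the
    unknowns is degenerate: all z are 0 with a warning.
    """
    f = np.asarray(f, dtype=float)
    mask = np.asarray(unknown_mask, dtype=bool)
    sub = f[mask]
    if sub.size < 2:
        raise ValueError("confidence z-scores need at least 2 unknown nodes")
    sd = sub.std()
    if sd < 1e-12:
        warnings.warn("diffused scores constant over unknown nodes; z set to 0")
        return np.zeros(sub.size)
    return (sub - sub.mean()) / sd


@dataclass(eq=False)
class DiffusionResult:
    nodes: list[str]
    functions: list[str]
    unknown: list[str]
    alpha: float
    y: dict[str, np.ndarray] = field(default_factory=dict)
    f: dict[str, np.ndarray] = field(default_factory=dict)
    z: dict[str, np.ndarray] = field(default_factory=dict)
    best: dict[str, tuple[str, float]] = field(default_factory=dict)

    def predictions(self) -> list[tuple[str, str, float]]:
        """(node, best label, confidence z) for every unknown node."""
        return [(node, lab, z) for node, (lab, z) in sorted(self.best.items())]


def competitive_diffusion(
    network: MatchNetwork,
    annotations: AnnotationTable | Mapping[str, Iterable[str]],
    alpha: float = 1.0,
) -> DiffusionResult:
    """Diffuse every function's labels and predict argmax-z per unknown node.

    For a given function, y is +1 on nodes annotated with it, -1 on nodes
    annotated only with other functions (closed-world reading of "known not
    to have it"), and 0 on unannotated nodes. Ties in z break by larger f,
    then lexicographically smaller label.
    """
    nodes = network.nodes
    labels = {
        n: (
            annotations.full_ec(n)
            if isinstance(annotations, AnnotationTable)
            else frozenset(annotations.get(n, ()))
        )
        for n in nodes
    }
    functions = sorted({ec for ecs in labels.values() for ec in ecs})
    if not functions:
        raise ValueError("no labeled function in the network")
    unknown = [n for n in nodes if not labels[n]]
    mask = np.array([not labels[n] for n in nodes], dtype=bool)
    result = DiffusionResult(
        nodes=list(nodes), functions=functions, unknown=unknown, alpha=alpha
    )
    for fn in functions:
        y = np.array(
            [1.0 if fn in labels[n] else (-1.0 if labels[n] else 0.0) for n in nodes]
        )
        f = diffuse(network.W, y, alpha)
        result.y[fn] = y
        result.f[fn] = f
        result.z[fn] = confidence_z(f, mask) if len(unknown) >= 2 else np.array([])
    for k, node in enumerate(unknown):
        best_fn, best_z, best_f = None, -np.inf, -np.inf
        for fn in functions:
            zk = float(result.z[fn][k]) if result.z[fn].size else 0.0
            fk = float(result.f[fn][nodes.index(node)])
            if zk > best_z or (zk == best_z and fk > best_f):
                best_fn, best_z, best_f = fn, zk, fk
        result.best[node] = (best_fn, best_z)
    return result


def confidence_bands(
    predictions: Sequence[tuple[str, str, float]],
    truth: Mapping[str, Iterable[str]],
    thresholds: Sequence[float] = (2.0, 0.5),
) -> list[dict]:
    """Cumulative accuracy of predictions at or above each confidence threshold."""
    rows = []
    for thr in sorted(thresholds, reverse=True):
        kept = [(n, lab) for n, lab, z in predictions if z >= thr]
        correct = sum(lab in frozenset(truth.get(n, ())) for n, lab in kept)
        rows.append(
            {
                "threshold": thr,
                "n": len(kept),
                "accuracy": correct / len(kept) if kept else 0.0,
            }
        )
    return rows
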