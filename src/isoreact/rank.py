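"""PageRank over reaction networks and Reverse PageRank inference.

PageRank ranks formulas by the stationary probability of a damped random
walk on the reaction network — depending only on topology (and edge-type
weights), not on peak intensities.  Reverse PageRank inverts this: given
observed node intensities, it searches for per-reaction-type edge weights
whose PageRank best reproduces the intensity distribution, yielding a
relative probability for each reaction type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = ["PageRankScores", "ReactionProbabilities", "PageRankNotConverged",
           "pagerank", "top_ranked", "reverse_pagerank"]


class PageRankNotConverged(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"power iteration did not converge in {max_iter} iterations "
            f"(L1 residual {residual:.3e})"
        )


@dataclass(frozen=True)
class PageRankScores:
    """Stationary distribution of the damped walk."""

    scores: Mapping[str, float]
    damping: float
    iterations: int
    residual: float

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def items(self):
        return self.scores.items()


@dataclass(frozen=True)
class ReactionProbabilities:
    """Per-reaction-type weights inferred by Reverse PageRank.

    Weights are normalized so the most probable reaction type has weight 1;
    all weights lie in (0, 1].
    """

    weights: Mapping[str, float]
    objective: str
    objective_value: float
    baseline_value: float  # objective at uniform weights
    n_evaluations: int

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0]))


def _edge_arrays(net: nx.MultiDiGraph):
    """Deterministic node ordering and flat (src, dst, type) edge arrays."""
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted(
        (u, v, str(d.get("transformation", k)))
        for u, v, k, d in net.edges(keys=True, data=True)
    )
    types = sorted({t for _, _, t in edges})
    t_index = {t: i for i, t in enumerate(types)}
    src = np.array([index[u] for u, _, _ in edges], dtype=np.int64)
    dst = np.array([index[v] for _, v, _ in edges], dtype=np.int64)
    typ = np.array([t_index[t] for _, _, t in edges], dtype=np.int64)
    return nodes, types, src, dst, typ


def _power_iteration(n: int, src, dst, edge_w, d: float,
                     tol: float, max_iter: int):
    """Damped random walk stationary distribution by power iteration.

    Out-edges of a node share its transition mass proportionally to their
    weights; dangling nodes teleport uniformly.
    """
    out_sum = np.bincount(src, weights=edge_w, minlength=n)
    has_out = out_sum > 0
    safe_out = np.where(has_out, out_sum, 1.0)
    pi = np.full(n, 1.0 / n)
    frac = edge_w / safe_out[src] if len(src) else edge_w
    for it in range(1, max_iter + 1):
        walk = np.bincount(dst, weights=pi[src] * frac, minlength=n) if len(src) \
            else np.zeros(n)
        dangling_mass = pi[~has_out].sum()
        new = d * walk + (d * dangling_mass + (1.0 - d)) / n
        residual = float(np.abs(new - pi).sum())
        pi = new
        if residual < tol:
            pi /= pi.sum()  # guard rounding drift
            return pi, it, residual
    raise PageRankNotConverged(residual, max_iter)


def pagerank(
    net: nx.MultiDiGraph,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    edge_weights: Mapping[str, float] | None = None,
) -> PageRankScores:
    """PageRank of a reaction network.

    *edge_weights* maps transformation name → weight (uniform when omitted);
    a node's out-edges share its transition mass proportionally to their
    type weights.  Raises :class:`PageRankNotConverged` when the L1
    residual does not fall below *tol* within *max_iter* iterations.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes, types, src, dst, typ = _edge_arrays(net)
    if edge_weights is None:
        w = np.ones(len(types))
    else:
        w = np.array([float(edge_weights.get(t, 1.0)) for t in types])
        if np.any(w < 0):
            raise ValueError("edge-type weights must be non-negative")
    pi, it, residual = _power_iteration(len(nodes), src, dst, w[typ] if len(typ)
                                        else np.zeros(0), d, tol, max_iter)
    return PageRankScores(
        scores=dict(zip(nodes, pi.tolist())),
        damping=d, iterations=it, residual=residual,
    )


def top_ranked(scores: PageRankScores, k: int) -> list[tuple[str, float]]:
    """Top *k* nodes by score, descending; ties break on the formula string."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


# ---------------------------------------------------------------------------
# Reverse PageRank
# ---------------------------------------------------------------------------

_OBJECTIVES = ("kl", "l2", "cosine")

#: Coordinate-search grid over a single type weight.
_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.55, 0.75, 1.0)


def reverse_pagerank(
    net: nx.MultiDiGraph,
    intensities: Mapping[str, float] | None = None,
    d: float = 0.85,
    objective: str = "kl",
    seed: int = 0,
    n_random_starts: int = 3,
    bounds: tuple[float, float] = (0.01, 1.0),
    pr_tol: float = 1e-10,
    pr_max_iter: int = 2000,
) -> ReactionProbabilities:
    """Infer reaction-type probabilities from node intensities.

    Finds per-transformation edge weights *w* whose PageRank π(w) best
    matches the normalized intensity distribution q.  Default objective:
    KL(q ‖ π(w)); "l2" and "cosine" (1 - cosine similarity) are available.
    The search is derivative-free: cyclic coordinate refinement over a fixed
    grid followed by a Nelder–Mead polish, from the uniform start plus
    *n_random_starts* seeded random starts.  Weights are box-constrained to
    *bounds* and normalized so the maximum is 1.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {_OBJECTIVES}")
    if net.number_of_edges() == 0:
        raise ValueError("degenerate network: no edges")
    nodes, types, src, dst, typ = _edge_arrays(net)
    n = len(nodes)

    if intensities is None:
        intensities = {u: net.nodes[u].get("intensity") for u in nodes}
    missing = [u for u in nodes if intensities.get(u) is None
               or not intensities[u] > 0]
    if missing:
        raise ValueError(
            f"{len(missing)} node(s) lack a positive intensity "
            f"(e.g. {missing[:3]}); intensities are required for every node"
        )
    q = np.array([float(intensities[u]) for u in nodes])
    q = q / q.sum()

    lo, hi = bounds
    n_types = len(types)
    evals = 0

    def loss(w: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        wc = np.clip(w, lo, hi)
        penalty = float(np.abs(w - wc).sum())
        pi, _, _ = _power_iteration(n, src, dst, wc[typ], d, pr_tol, pr_max_iter)
        if objective == "kl":
            val = float(np.sum(q * np.log(q / pi)))
        elif objective == "l2":
            val = float(np.sum((q - pi) ** 2))
        else:
            val = 1.0 - float(q @ pi / (np.linalg.norm(q) * np.linalg.norm(pi)))
        return val + penalty

    def coordinate_refine(w: np.ndarray, sweeps: int = 3) -> tuple[np.ndarray, float]:
        w = w.copy()
        best = loss(w)
        for _ in range(sweeps):
            improved = False
            for j in range(n_types):
                for g in _GRID:
                    if g == w[j]:
                        continue
                    trial = w.copy()
                    trial[j] = g
                    val = loss(trial)
                    if val < best - 1e-12:
                        best, w, improved = val, trial, True
            if not improved:
                break
        return w, best

    rng = np.random.default_rng(seed)
    starts = [np.ones(n_types)]
    for _ in range(n_random_starts):
        starts.append(rng.uniform(lo, hi, size=n_types))

    baseline = loss(np.ones(n_types))
    best_w, best_val = np.ones(n_types), baseline
    for w0 in starts:
        w1, v1 = coordinate_refine(w0)
        res = optimize.minimize(
            loss, w1, method="Nelder-Mead",
            options={"maxiter": 200 * n_types, "xatol": 1e-4, "fatol": 1e-10},
        )
        w2 = np.clip(res.x, lo, hi)
        v2 = loss(w2)
        for w, v in ((w1, v1), (w2, v2)):
            if v < best_val:
                best_w, best_val = w.copy(), v
    if not np.isfinite(best_val):
        raise RuntimeError("reverse PageRank optimization failed (non-finite loss)")

    best_w = np.clip(best_w, lo, hi)
    best_w = best_w / best_w.max()
    best_w = np.clip(best_w, lo, hi)
    logger.info("reverse pagerank: objective %s %.6g (uniform baseline %.6g, "
                "%d evaluations)", objective, best_val, baseline, evals)
    return ReactionProbabilities(
        weights=dict(zip(types, best_w.tolist())),
        objective=objective,
        objective_value=float(best_val),
        baseline_value=float(baseline),
        n_evaluations=evals,
    )
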