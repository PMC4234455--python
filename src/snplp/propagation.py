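"""Label propagation on the bipartite sample/SNP-state graph.

Starting from labels y in {-1, 0, +1} on the sample nodes, labels are
diffused across the degree-normalised operator B = D_V^{-1/2} W D_U^{-1/2}
by the simultaneous updates

    f_{t+1}(V) = (1 - alpha) y(V) + alpha B   f_t(U)
    f_{t+1}(U) = (1 - alpha) y(U) + alpha B^T f_t(V)

which converge (for alpha < 1, since the symmetric block operator
S = [[0, B], [B^T, 0]] has spectral norm <= 1) to the unique minimiser

    f* = (1 - alpha) (I - alpha S)^{-1} Y

of the smoothness-plus-fit objective Q(f) with trade-off mu = (1-alpha)/alpha.
Converged state-node scores near +1 indicate association with cases, near
-1 with controls, near 0 uninformative; sample-node scores are transductive
case/control predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import BipartiteGraph, LabelAssignment, normalized_operator
from .ranking import RankedList, make_ranked_list

DENSE_SOLVE_CAP = 5000

AGGREGATIONS = ("max_abs", "mean_abs", "signed_range")


@dataclass
class PropagationConfig:
    """Solver settings.

    alpha : diffusion/fit balance in [0, 1); alpha=0 returns the initial
        labels, larger alpha diffuses further.  0.25 is the default used
        for ranking runs.
    tol : L-infinity convergence threshold on successive labelings.
    max_iter : iteration cap; non-convergence is flagged, not raised.
    """

    alpha: float = 0.25
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def mu(self) -> float:
        """Objective trade-off mu = (1 - alpha) / alpha."""
        if self.alpha == 0.0:
            return np.inf
        return (1.0 - self.alpha) / self.alpha


@dataclass
class PropagationResult:
    f_samples: np.ndarray
    f_states: np.ndarray
    iterations: int
    converged: bool
    objective_value: float


def propagate_iterative(
    graph: BipartiteGraph, y: LabelAssignment, cfg: PropagationConfig | None = None
) -> PropagationResult:
    """Diffuse labels iteratively until the L-infinity change drops below tol."""
    cfg = cfg or PropagationConfig()
    _check_labels(graph, y)
    B = normalized_operator(graph)
    a = cfg.alpha
    fv, fu = y.y_samples.astype(float).copy(), y.y_states.astype(float).copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        fv_new = (1.0 - a) * y.y_samples + a * (B @ fu)
        fu_new = (1.0 - a) * y.y_states + a * (B.T @ fv)
        delta = max(
            np.abs(fv_new - fv).max(initial=0.0),
            np.abs(fu_new - fu).max(initial=0.0),
        )
        fv, fu = fv_new, fu_new
        if delta < cfg.tol:
            converged = True
            break
    if cfg.alpha > 0:
        q = objective(graph, fv, fu, y, cfg.mu)
    else:
        # mu -> inf limit pins f = y; report the finite smoothness part
        q = objective(graph, fv, fu, y, 1.0) - float(
            np.sum((fv - y.y_samples) ** 2) + np.sum((fu - y.y_states) ** 2)
        )
    return PropagationResult(
        f_samples=fv,
        f_states=fu,
        iterations=iterations,
        converged=converged,
        objective_value=q,
    )


def solve_closed_form(
    graph: BipartiteGraph,
    y: LabelAssignment,
    alpha: float,
    cap: int = DENSE_SOLVE_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution f* = (1 - alpha)(I - alpha S)^{-1} Y by dense solve.

    Intended as the small-graph oracle for the iterative solver; refuses
    graphs beyond ``cap`` total nodes.
    """
    _check_labels(graph, y)
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    n, m = graph.n_samples, graph.n_states
    if n + m > cap:
        raise ValueError(
            f"graph has {n + m} nodes, above the dense-solve cap {cap}; "
            "use propagate_iterative"
        )
    B = normalized_operator(graph).toarray()
    S = np.block([[np.zeros((n, n)), B], [B.T, np.zeros((m, m))]])
    Y = np.concatenate([y.y_samples, y.y_states]).astype(float)
    f = (1.0 - alpha) * np.linalg.solve(np.eye(n + m) - alpha * S, Y)
    return f[:n], f[n:]


def objective(
    graph: BipartiteGraph,
    f_samples: np.ndarray,
    f_states: np.ndarray,
    y: LabelAssignment,
    mu: float,
) -> float:
    """Smoothness + fit cost Q(f).

    Q = sum over edges of w(v,u) (f(v)/sqrt(d(v)) - f(u)/sqrt(d(u)))^2
        + mu * (sum_v (f(v)-y(v))^2 + sum_u (f(u)-y(u))^2)
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    gv = f_samples / np.sqrt(graph.sample_degrees)
    gu = f_states / np.sqrt(graph.state_degrees)
    coo = graph.incidence.tocoo()
    smooth = float(np.sum(coo.data * (gv[coo.row] - gu[coo.col]) ** 2))
    fit = float(np.sum((f_samples - y.y_samples) ** 2) + np.sum((f_states - y.y_states) ** 2))
    return smooth + mu * fit


def rank_snps(
    result: PropagationResult,
    graph: BipartiteGraph,
    aggregation: str = "max_abs",
    params: dict | None = None,
) -> RankedList:
    """Aggregate state-node scores into one score per SNP and rank.

    Aggregations over a SNP's surviving state scores (pruned states count
    as 0):

    - ``max_abs`` (default): largest absolute state score; rewards any
      strongly associated state.
    - ``mean_abs``: mean absolute score over the three states.
    - ``signed_range``: max score minus min score.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; options: {AGGREGATIONS}")
    per_snp: dict[str, dict[int, float]] = {}
    for (snp_id, state), score in zip(graph.state_nodes, result.f_states):
        per_snp.setdefault(snp_id, {})[state] = float(score)
    for snp_id, _state in graph.pruned_states:
        per_snp.setdefault(snp_id, {})
    scores: dict[str, float] = {}
    for snp_id, states in per_snp.items():
        full = [states.get(s, 0.0) for s in range(3)]
        if aggregation == "max_abs":
            scores[snp_id] = max(abs(x) for x in full)
        elif aggregation == "mean_abs":
            scores[snp_id] = sum(abs(x) for x in full) / 3.0
        else:
            scores[snp_id] = max(full) - min(full)
        per_snp[snp_id] = {s: states.get(s, 0.0) for s in range(3)}
    return make_ranked_list(
        scores, per_snp, method="lp",
        params={"aggregation": aggregation, **(params or {})},
    )


def predict_samples(
    result: PropagationResult,
    graph: BipartiteGraph,
    sample_ids: list[str] | None = None,
) -> dict[str, float]:
    """Transductive case/control scores f(v); higher = more case-like.

    ``sample_ids`` restricts the output (typically to held-out samples);
    training samples may be requested, but their scores are anchored to
    the labels by the fitting term.
    """
    wanted = sample_ids if sample_ids is not None else graph.sample_ids
    pos = {s: i for i, s in enumerate(graph.sample_ids)}
    out: dict[str, float] = {}
    for s in wanted:
        if s in pos:
            out[s] = float(result.f_samples[pos[s]])
        else:  # pruned sample: no edges, no diffusion path
            out[s] = 0.0
    return out


def lp_rank(
    dataset,
    cfg: PropagationConfig | None = None,
    aggregation: str = "max_abs",
    training_mask=None,
) -> RankedList:
    """Convenience: build graph, label, propagate, rank, in one call."""
    from .graph import build_graph, initial_labels

    dataset.require_cases_and_controls()
    cfg = cfg or PropagationConfig()
    graph = build_graph(dataset)
    y = initial_labels(dataset, graph, training_mask)
    result = propagate_iterative(graph, y, cfg)
    ranked = rank_snps(result, graph, aggregation)
    ranked.params.update(
        alpha=cfg.alpha, tol=cfg.tol, iterations=result.iterations,
        converged=result.converged, objective_value=result.objective_value,
    )
    return ranked


def _check_labels(graph: BipartiteGraph, y: LabelAssignment) -> None:
    if y.y_samples.shape != (graph.n_samples,) or y.y_states.shape != (graph.n_states,):
        raise ValueError("label assignment does not match graph node counts")
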