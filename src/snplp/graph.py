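"""Bipartite sample / SNP-state graph encoding of a genotype dataset.

Each SNP contributes up to three state nodes (genotype 0 = major
homozygote, 1 = heterozygote, 2 = minor homozygote).  A unit-weight edge
links sample v to state node u exactly when v's non-missing genotype at
that SNP equals the node's state, so missing calls simply contribute no
edge.  State nodes that no sample exhibits, and samples with every call
missing, have degree zero and are pruned (the symmetric degree
normalisation is undefined at degree zero, and an unobserved state
carries no evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dataset import CASE, CONTROL, MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

N_STATES = 3


@dataclass
class BipartiteGraph:
    """Sample nodes V, SNP-state nodes U, and the unit incidence matrix W."""

    sample_ids: list[str]                      # node set V, dataset order
    state_nodes: list[tuple[str, int]]         # node set U: (snp_id, state)
    incidence: sp.csr_matrix                   # W, |V| x |U|, entries in {0,1}
    sample_degrees: np.ndarray                 # d(v) = number of non-missing calls
    state_degrees: np.ndarray                  # d(u) = number of carriers of the state
    pruned_states: list[tuple[str, int]] = field(default_factory=list)
    pruned_samples: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_states(self) -> int:
        return len(self.state_nodes)

    @property
    def n_edges(self) -> int:
        return int(self.incidence.nnz)


@dataclass
class LabelAssignment:
    """Initial node labels: +1 training case, -1 training control, 0 unknown."""

    y_samples: np.ndarray
    y_states: np.ndarray


def build_graph(dataset: GenotypeDataset) -> BipartiteGraph:
    """Encode a dataset as the bipartite sample/SNP-state graph.

    State nodes are ordered by (SNP column index, state); zero-degree
    state nodes and all-missing samples are pruned and recorded.
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise ValueError("cannot build a graph from an empty dataset")
    G = dataset.genotypes
    observed = G != MISSING

    sample_keep = observed.any(axis=1)
    pruned_samples = [s for s, k in zip(dataset.sample_ids, sample_keep) if not k]
    if pruned_samples:
        logger.warning(
            "pruned %d samples with all genotypes missing: %s",
            len(pruned_samples), pruned_samples[:5],
        )
        G = G[sample_keep]
        observed = observed[sample_keep]
    sample_ids = [s for s, k in zip(dataset.sample_ids, sample_keep) if k]

    rows, cols = np.nonzero(observed)
    # full state-node index: snp j, state s -> j * 3 + s
    full_col = cols * N_STATES + G[rows, cols].astype(np.intp)
    W_full = sp.csr_matrix(
        (np.ones(len(rows)), (rows, full_col)),
        shape=(len(sample_ids), dataset.n_snps * N_STATES),
    )
    degrees_full = np.asarray(W_full.sum(axis=0)).ravel()
    keep = degrees_full > 0
    state_nodes = [
        (dataset.snp_ids[j], s)
        for j in range(dataset.n_snps)
        for s in range(N_STATES)
        if keep[j * N_STATES + s]
    ]
    pruned_states = [
        (dataset.snp_ids[j], s)
        for j in range(dataset.n_snps)
        for s in range(N_STATES)
        if not keep[j * N_STATES + s]
    ]
    W = W_full[:, keep].tocsr()
    return BipartiteGraph(
        sample_ids=sample_ids,
        state_nodes=state_nodes,
        incidence=W,
        sample_degrees=np.asarray(W.sum(axis=1)).ravel(),
        state_degrees=np.asarray(W.sum(axis=0)).ravel(),
        pruned_states=pruned_states,
        pruned_samples=pruned_samples,
    )


def initial_labels(
    dataset: GenotypeDataset,
    graph: BipartiteGraph,
    training_mask: np.ndarray | None = None,
) -> LabelAssignment:
    """Label training cases +1 and training controls -1; everything else 0.

    ``training_mask`` is a boolean mask over ``dataset`` samples (default:
    all samples).  State nodes always start unlabeled.
    """
    if training_mask is None:
        training_mask = np.ones(dataset.n_samples, dtype=bool)
    training_mask = np.asarray(training_mask, dtype=bool)
    if training_mask.shape != (dataset.n_samples,):
        raise ValueError("training_mask length does not match dataset")
    ph = dataset.phenotypes
    n_case = int(((ph == CASE) & training_mask).sum())
    n_ctrl = int(((ph == CONTROL) & training_mask).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError(
            f"training mask must select both classes; got {n_case} cases, "
            f"{n_ctrl} controls"
        )
    label_by_id = {}
    for sid, p, m in zip(dataset.sample_ids, ph, training_mask):
        if m and p == CASE:
            label_by_id[sid] = 1.0
        elif m and p == CONTROL:
            label_by_id[sid] = -1.0
    y_samples = np.array(
        [label_by_id.get(s, 0.0) for s in graph.sample_ids], dtype=float
    )
    return LabelAssignment(
        y_samples=y_samples,
        y_states=np.zeros(graph.n_states, dtype=float),
    )


def normalized_operator(graph: BipartiteGraph) -> sp.csr_matrix:
    """Degree-normalised diffusion operator B = D_V^{-1/2} W D_U^{-1/2}.

    B[v, u] = w(v, u) / sqrt(d(v) d(u)); every node must have degree >= 1
    (guaranteed by pruning in :func:`build_graph`).
    """
    if (graph.sample_degrees < 1).any() or (graph.state_degrees < 1).any():
        raise RuntimeError("zero-degree node in pruned graph (pruning contract violated)")
    dv = sp.diags(1.0 / np.sqrt(graph.sample_degrees))
    du = sp.diags(1.0 / np.sqrt(graph.state_degrees))
    return (dv @ graph.incidence @ du).tocsr()


def random_bipartite_graph(
    rng: np.random.Generator, max_nodes: int = 30
) -> BipartiteGraph:
    """Random unit-incidence bipartite graph with no isolated nodes.

    A validation utility: the generated graphs exercise the solver over
    arbitrary degree patterns, independent of any genotype dataset.
    """
    while True:
        n = int(rng.integers(2, max_nodes - 2))
        m = int(rng.integers(2, max_nodes - n))
        W = (rng.random((n, m)) < rng.uniform(0.15, 0.6)).astype(float)
        W = W[W.sum(axis=1) > 0][:, W.sum(axis=0) > 0]
        if W.shape[0] >= 2 and W.shape[1] >= 2:
            break
    Ws = sp.csr_matrix(W)
    return BipartiteGraph(
        sample_ids=[f"v{i}" for i in range(W.shape[0])],
        state_nodes=[(f"u{j}", 0) for j in range(W.shape[1])],
        incidence=Ws,
        sample_degrees=np.asarray(Ws.sum(axis=1)).ravel(),
        state_degrees=np.asarray(Ws.sum(axis=0)).ravel(),
    )


def export_edge_list(graph: BipartiteGraph, path) -> None:
    """Write the edge list as TSV (sample_id, snp_id, state, weight)."""
    coo = graph.incidence.tocoo()
    with open(path, "w") as fh:
        fh.write("sample_id\tsnp_id\tstate\tweight\n")
        for v, u, w in zip(coo.row, coo.col, coo.data):
            snp_id, state = graph.state_nodes[u]
            fh.write(f"{graph.sample_ids[v]}\t{snp_id}\t{state}\t{w:g}\n")
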