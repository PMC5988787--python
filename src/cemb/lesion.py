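"""Simulated node lesions and their predicted functional consequences.

A lesion zeroes every connection of one node in the structural network.
Because re-embedding the lesioned connectome lands in a different random
rotation each run, pre- and post-lesion predictions are compared through a
mapping trained to be *initialization-invariant*: a nested cross-validation
stacks training rows across many embedding runs (so the regressor must rely
on rotation-stable feature structure), always predicting on edges and runs
held out of training.  Per edge, the resulting sets of pre- and post-lesion
predictions are compared with a max-null permutation test; a node's *degree
difference* counts its incident significantly changed edges.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cemb.connectome_io import Connectome, FunctionalMatrix
from cemb.embedding import EmbeddingEnsemble
from cemb.reconstruction import fisher_z
from cemb.struct2func import (
    EdgeFeatureTable,
    MLPConfig,
    MappingModel,
    all_edges,
    edge_folds,
    fit_mlp,
)


@dataclasses.dataclass(frozen=True)
class LesionCVConfig:
    """Nested cross-validation and permutation-test parameters.

    Edges are split into ``n_edge_folds`` folds; the embedding ensemble is
    split ``n_embedding_splits`` times into train/test runs at
    ``embedding_train_fraction`` (0.9 keeps 450 of 500 runs for training).
    Every (fold, split) combination trains one regressor.
    """

    n_edge_folds: int = 3
    embedding_train_fraction: float = 0.9
    n_embedding_splits: int = 3
    n_permutations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edge_folds < 2:
            raise ValueError("need at least 2 edge folds")
        if not 0 < self.embedding_train_fraction < 1:
            raise ValueError("embedding_train_fraction must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclasses.dataclass
class EdgePredictionSets:
    """Held-out predicted FC per edge, pre- and post-lesion.

    Each edge collects one prediction per held-out run per embedding split,
    always from the fold where the edge itself was held out.
    """

    edges: np.ndarray  # (E, 2)
    pre: np.ndarray  # (E, n_splits * n_test_runs)
    post: np.ndarray  # same shape

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("pre/post prediction shapes differ")


@dataclasses.dataclass
class LesionContrast:
    """Per-edge significance flags and per-node degree differences."""

    edges: np.ndarray
    observed_delta: np.ndarray  # mean(pre) - mean(post) per edge
    sig_decrease: np.ndarray  # bool: pre > post beyond the permutation max
    sig_increase: np.ndarray  # bool: post > pre beyond the permutation max
    n_nodes: int

    def flag_matrix(self, direction: str) -> np.ndarray:
        flags = self.sig_decrease if direction == "decrease" else self.sig_increase
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        e = self.edges[flags]
        m[e[:, 0], e[:, 1]] = 1
        m[e[:, 1], e[:, 0]] = 1
        return m


def lesion_node(c: Connectome, node: int | str) -> Connectome:
    """Zero all connections of one node (row and column of the matrix)."""
    idx = c.index(node) if isinstance(node, str) else int(node)
    if not 0 <= idx < c.n_nodes:
        raise ValueError(f"node index {idx} out of range")
    w = c.weights.copy()
    w[idx, :] = 0.0
    w[:, idx] = 0.0
    return c.copy_with_weights(w)


def invariant_mapping_cv(
    pre: EmbeddingEnsemble,
    post: EmbeddingEnsemble,
    fc: FunctionalMatrix,
    cfg: LesionCVConfig | None = None,
    mlp: MLPConfig | None = None,
    fit=fit_mlp,
) -> EdgePredictionSets:
    """Initialization-invariant nested CV of the embedding -> FC mapping.

    For each edge fold and each embedding split, one regressor is trained on
    {training edges x training pre-lesion runs} stacked rows (Hadamard
    features, Fisher-z FC targets) and applied to the held-out edges using
    each held-out run's features — from the pre-lesion ensemble and, with
    the identical models, from the post-lesion ensemble.  Training never
    sees post-lesion embeddings, held-out edges, or held-out runs.
    """
    if cfg is None:
        cfg = LesionCVConfig()
    if len(pre) != len(post):
        raise ValueError("pre and post ensembles must have equal size")
    n_nodes = pre[0].n_nodes
    if fc.n_nodes != n_nodes:
        raise ValueError("functional matrix does not match ensembles")
    edges = all_edges(n_nodes)
    targets = fisher_z(fc)[edges[:, 0], edges[:, 1]]

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    folds = edge_folds(len(edges), cfg.n_edge_folds, seed=int(rng.integers(2**31)))
    n_runs = len(pre)
    n_test_runs = max(1, int(round((1 - cfg.embedding_train_fraction) * n_runs)))
    if n_test_runs >= n_runs:
        raise ValueError("embedding split leaves no training runs")
    splits = []
    for _ in range(cfg.n_embedding_splits):
        perm = rng.permutation(n_runs)
        splits.append((np.sort(perm[n_test_runs:]), np.sort(perm[:n_test_runs])))

    pre_stack = pre.stack()  # (R, N, D)
    post_stack = post.stack()

    def edge_feats(stack: np.ndarray, run_ids: np.ndarray, edge_ids: np.ndarray):
        # rows ordered run-major: for each run, all edges of the block
        e = edges[edge_ids]
        blocks = [stack[r, e[:, 0]] * stack[r, e[:, 1]] for r in run_ids]
        return np.vstack(blocks)

    n_cols = cfg.n_embedding_splits * n_test_runs
    preds_pre = np.full((len(edges), n_cols), np.nan)
    preds_post = np.full((len(edges), n_cols), np.nan)

    for s, (train_runs, test_runs) in enumerate(splits):
        for fold in folds:
            test_edges = fold
            train_edges = np.setdiff1d(np.arange(len(edges)), fold)
            x_train = edge_feats(pre_stack, train_runs, train_edges)
            y_train = np.tile(targets[train_edges], len(train_runs))
            model = fit(
                EdgeFeatureTable(
                    edges=np.tile(edges[train_edges], (len(train_runs), 1)),
                    features=x_train,
                    target=y_train,
                ),
                mlp,
            )
            for r_pos, r in enumerate(test_runs):
                col = s * n_test_runs + r_pos
                fpre = pre_stack[r, edges[test_edges, 0]] * pre_stack[r, edges[test_edges, 1]]
                fpost = post_stack[r, edges[test_edges, 0]] * post_stack[r, edges[test_edges, 1]]
                preds_pre[test_edges, col] = model.predict(fpre)
                preds_post[test_edges, col] = model.predict(fpost)

    assert not np.any(np.isnan(preds_pre)) and not np.any(np.isnan(preds_post))
    return EdgePredictionSets(edges=edges, pre=preds_pre, post=preds_post)


def permutation_edge_test(
    preds: EdgePredictionSets,
    n_permutations: int = 10000,
    seed: int = 0,
) -> LesionContrast:
    """Max-null permutation test of pre- vs post-lesion predictions.

    Per edge, the observed difference is mean(pre) - mean(post); pooled
    values are label-permuted ``n_permutations`` times (independently per
    edge, shared seed stream) and an edge is flagged only when its observed
    difference exceeds *every* permuted difference in that direction —
    an exceedance probability below 1/n_permutations, uncorrected.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    edges = preds.edges
    n = preds.pre.shape[1]
    delta = preds.pre.mean(axis=1) - preds.post.mean(axis=1)
    sig_dec = np.zeros(len(edges), dtype=bool)
    sig_inc = np.zeros(len(edges), dtype=bool)
    for k in range(len(edges)):
        pooled = np.concatenate([preds.pre[k], preds.post[k]])
        if np.ptp(pooled) == 0:  # degenerate: never significant
            continue
        idx = np.argsort(rng.random((n_permutations, 2 * n)), axis=1)
        g1 = pooled[idx[:, :n]].mean(axis=1)
        g2 = pooled[idx[:, n:]].mean(axis=1)
        null = g1 - g2
        if delta[k] > null.max():
            sig_dec[k] = True
        elif delta[k] < null.min():
            sig_inc[k] = True
    n_nodes = int(edges.max()) + 1 if len(edges) else 0
    return LesionContrast(
        edges=edges,
        observed_delta=delta,
        sig_decrease=sig_dec,
        sig_increase=sig_inc,
        n_nodes=n_nodes,
    )


def degree_difference(
    contrast: LesionContrast, labels: list[str] | None = None
) -> dict[str, np.ndarray | list]:
    """Per-node counts of incident significantly changed edges.

    Counts are row sums of the symmetric flag matrices, reported separately
    for the increase (post > pre) and decrease (pre > post) directions,
    with nodes ranked by each.
    """
    inc = contrast.flag_matrix("increase").sum(axis=1)
    dec = contrast.flag_matrix("decrease").sum(axis=1)
    out: dict[str, np.ndarray | list] = {
        "degree_increase": inc,
        "degree_decrease": dec,
        "rank_increase": list(np.argsort(-inc)),
        "rank_decrease": list(np.argsort(-dec)),
    }
    if labels is not None:
        out["labels"] = list(labels)
    return out
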