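"""Mapping structural embeddings to functional connectivity, edge-wise.

Each unordered node pair (an *edge* of the full functional matrix, whether
or not a structural fiber connects it) is represented by the Hadamard
product of its two node vectors; a regressor — a deep multi-layer
perceptron, with an ordinary-least-squares baseline — learns to predict the
Fisher-z functional correlation of the pair from that feature vector.
Performance is the Spearman correlation between predicted and empirical
values on held-out edges, reported overall and split into direct
(structurally connected) and indirect pairs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.stats
from sklearn.neural_network import MLPRegressor

from cemb.connectome_io import Connectome, FunctionalMatrix
from cemb.embedding import EmbeddingRun
from cemb.reconstruction import fisher_z


@dataclasses.dataclass(frozen=True)
class MLPConfig:
    """Architecture and training schedule of the deep regressor.

    Defaults follow the reference protocol: 4 fully connected hidden layers
    of 350 rectified-linear units, minibatches of 140, 170 epochs, Adam,
    mean-squared-error loss.  ``dropout`` is retained for the record but the
    scikit-learn backend regularizes via the L2 penalty ``alpha`` instead
    (see docs/methods.md).
    """

    hidden_layers: int = 4
    units_per_layer: int = 350
    dropout: float = 0.1
    batch_size: int = 140
    epochs: int = 170
    learning_rate: float = 1e-3
    alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.hidden_layers, self.units_per_layer, self.batch_size, self.epochs) < 1:
            raise ValueError("architecture parameters must be positive")


@dataclasses.dataclass
class EdgeFeatureTable:
    """Per-edge Hadamard features and regression targets.

    One row per unordered node pair; ``features[k] = vec[i] * vec[j]``
    element-wise, ``target[k]`` the Fisher-z functional value of the pair.
    """

    edges: np.ndarray  # (E, 2) int, i < j
    features: np.ndarray  # (E, D)
    target: np.ndarray | None = None  # (E,)

    def __post_init__(self) -> None:
        if self.edges.shape[0] != self.features.shape[0]:
            raise ValueError("edges and features disagree on row count")
        if self.target is not None and self.target.shape[0] != self.edges.shape[0]:
            raise ValueError("target length mismatch")


@dataclasses.dataclass
class MappingModel:
    """A trained edge-feature -> functional-connectivity regressor."""

    regressor: object  # sklearn-like, or (coef, intercept) for OLS
    kind: str  # "mlp" or "linear"
    input_dim: int
    config: MLPConfig | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.input_dim:
            raise ValueError("feature dimension mismatch")
        if self.kind == "linear":
            coef, intercept = self.regressor
            return features @ coef + intercept
        return self.regressor.predict(features)


def all_edges(n_nodes: int) -> np.ndarray:
    """All unordered node pairs (i < j) as an (E, 2) array."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def hadamard_features(
    run: EmbeddingRun | np.ndarray,
    edges: np.ndarray,
    fc: FunctionalMatrix | np.ndarray | None = None,
    fisher: bool = True,
) -> EdgeFeatureTable:
    """Element-wise products of node-vector pairs, optionally with targets.

    Symmetric in (i, j) by construction.  When ``fc`` is given, targets are
    its (Fisher-z by default) values at the edges.
    """
    vec = run.vectors if isinstance(run, EmbeddingRun) else np.asarray(run, float)
    edges = np.asarray(edges, dtype=int)
    feats = vec[edges[:, 0]] * vec[edges[:, 1]]
    target = None
    if fc is not None:
        mat = fc.values if isinstance(fc, FunctionalMatrix) else np.asarray(fc, float)
        if fisher:
            mat = fisher_z(mat)
        target = mat[edges[:, 0], edges[:, 1]]
    return EdgeFeatureTable(edges=edges, features=feats, target=target)


def split_edges(
    n_nodes: int, train_fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test partition of all unordered pairs.

    The test set gets ``floor((1 - train_fraction) * E)`` edges; for 83
    nodes and a 75/25 split that is 2552 train / 851 test of 3403 pairs.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    edges = all_edges(n_nodes)
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(len(edges))
    n_test = int(np.floor((1 - train_fraction) * len(edges)))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return edges[train_idx], edges[test_idx]


def edge_folds(n_edges: int, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Partition edge indices into ``n_folds`` near-equal random folds."""
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(n_edges)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def fit_mlp(train: EdgeFeatureTable, cfg: MLPConfig | None = None) -> MappingModel:
    """Train the deep regressor on an edge-feature table.

    Fixed epoch count (no early stopping), Adam with minibatches, squared
    error.  Deterministic given ``cfg.seed`` and single-threaded execution.
    """
    if cfg is None:
        cfg = MLPConfig()
    x, y = train.features, train.target
    if y is None:
        raise ValueError("training table has no targets")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or targets")
    if len(y) < cfg.batch_size:
        warnings.warn(
            f"{len(y)} training rows is below the batch size {cfg.batch_size}",
            stacklevel=2,
        )
    reg = MLPRegressor(
        hidden_layer_sizes=(cfg.units_per_layer,) * cfg.hidden_layers,
        activation="relu",
        solver="adam",
        alpha=cfg.alpha,
        batch_size=min(cfg.batch_size, len(y)),
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        early_stopping=False,
        n_iter_no_change=cfg.epochs + 1,  # run all epochs
        tol=0.0,
    )
    with warnings.catch_warnings():
        # fixed epoch budget: convergence warnings are expected
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        reg.fit(x, y)
    return MappingModel(
        regressor=reg, kind="mlp", input_dim=x.shape[1], config=cfg
    )


def fit_linear(train: EdgeFeatureTable) -> MappingModel:
    """Ordinary least squares on the same features (minimum-norm solution
    for rank-deficient designs)."""
    x, y = train.features, train.target
    if y is None:
        raise ValueError("training table has no targets")
    design = np.column_stack([x, np.ones(len(x))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MappingModel(
        regressor=(beta[:-1], beta[-1]), kind="linear", input_dim=x.shape[1]
    )


def evaluate_mapping(
    model: MappingModel,
    test: EdgeFeatureTable,
    structural: Connectome | np.ndarray | None = None,
) -> dict[str, float]:
    """Held-out Spearman correlations (and MSE) of predictions vs targets.

    Returns ``rho_all``/``p_all``/``mse_all`` and, when a structural matrix
    is supplied, the same within direct (structural weight > 0) and
    indirect strata.  Constant predictions yield nan rho with a warning.
    """
    if test.target is None or len(test.target) == 0:
        raise ValueError("empty test table")
    pred = model.predict(test.features)
    out: dict[str, float] = {}

    def _stratum(sel: np.ndarray, tag: str) -> None:
        if sel.sum() < 3:
            out[f"rho_{tag}"] = float("nan")
            out[f"p_{tag}"] = float("nan")
            out[f"mse_{tag}"] = float("nan")
            return
        p_, t_ = pred[sel], test.target[sel]
        if np.ptp(p_) == 0:
            warnings.warn("constant predictions: rho undefined", stacklevel=3)
            rho, p = float("nan"), float("nan")
        else:
            rho, p = scipy.stats.spearmanr(p_, t_)
        out[f"rho_{tag}"] = float(rho)
        out[f"p_{tag}"] = float(p)
        out[f"mse_{tag}"] = float(np.mean((p_ - t_) ** 2))

    _stratum(np.ones(len(pred), dtype=bool), "all")
    if structural is not None:
        w = structural.weights if isinstance(structural, Connectome) else structural
        direct = w[test.edges[:, 0], test.edges[:, 1]] > 0
        _stratum(direct, "direct")
        _stratum(~direct, "indirect")
    return out
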