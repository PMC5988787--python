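"""Node embeddings for weighted connectomes.

Two embedders live here.  The primary one follows the node2vec recipe:
biased second-order random walks over the weighted graph (return parameter
``p``, in-out parameter ``q``) provide sentence-like node sequences, and a
continuous-bag-of-words (CBOW) model with negative sampling is trained on
that corpus; the input-layer vectors are the node embeddings.  Because the
stochastic optimisation lands in a different rotation of the embedding space
on every seed, embeddings are managed as *ensembles* of independently seeded
runs; only rotation-invariant quantities (cosine similarities, ranks) are
comparable across runs.  The baseline embedder is a Laplacian eigenmap of
the same weighted graph.

Defaults mirror a localized walk regime: ``p = 0.1``, ``q = 1.6``, 800 walks
of 20 steps per run, 30 dimensions, context window 3.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from cemb.connectome_io import Connectome

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@dataclasses.dataclass(frozen=True)
class WalkConfig:
    """Biased random-walk parameters.

    ``p`` penalizes immediate backtracking (return parameter); ``q``
    interpolates between breadth-first (``q > 1``) and depth-first
    (``q < 1``) exploration.  ``num_walks`` counts walks per run in total
    (round-robin over start nodes) unless ``walks_per_node`` is set, in
    which case every non-isolated node starts ``num_walks`` walks.
    """

    p: float = 0.1
    q: float = 1.6
    walk_length: int = 20
    num_walks: int = 800
    walks_per_node: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.num_walks < 1:
            raise ValueError("num_walks must be >= 1")


@dataclasses.dataclass(frozen=True)
class EmbedConfig:
    """CBOW training hyperparameters.

    The vocabulary is the node set (every node kept at minimum count 1);
    frequency subsampling is off by default because with ~100 node types it
    would discard most of the corpus.
    """

    dimensions: int = 30
    window: int = 3
    epochs: int = 5
    learning_rate: float = 0.025
    negative_samples: int = 5
    subsample_threshold: float = 0.0  # 0 disables frequency subsampling

    def __post_init__(self) -> None:
        if self.dimensions < 1:
            raise ValueError("dimensions must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclasses.dataclass
class WalkCorpus:
    """A bag of node-index walk sequences from one generation pass."""

    sequences: list[np.ndarray]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.sequences)


@dataclasses.dataclass
class EmbeddingRun:
    """One trained embedding: row ``i`` is the vector of node ``i``."""

    vectors: np.ndarray
    seed: int
    walk_config: WalkConfig | None = None
    embed_config: EmbedConfig | None = None
    method: str = "cbow-node2vec"

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dimensions(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass
class EmbeddingEnsemble:
    """An ordered collection of equally configured embedding runs."""

    runs: list[EmbeddingRun]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("ensemble must contain at least one run")
        shapes = {r.vectors.shape for r in self.runs}
        if len(shapes) != 1:
            raise ValueError(f"runs disagree on shape: {shapes}")

    def __len__(self) -> int:
        return len(self.runs)

    def __getitem__(self, i: int) -> EmbeddingRun:
        return self.runs[i]

    def stack(self) -> np.ndarray:
        """All vectors as a ``(n_runs, N, D)`` array."""
        return np.stack([r.vectors for r in self.runs])

    def mean_vectors(self) -> np.ndarray:
        return self.stack().mean(axis=0)

    def subset(self, indices: Sequence[int]) -> "EmbeddingEnsemble":
        return EmbeddingEnsemble([self.runs[i] for i in indices])


# ---------------------------------------------------------------------------
# biased second-order walks
# ---------------------------------------------------------------------------


class TransitionModel:
    """Exact transition distributions of the biased second-order walk.

    For a step standing at ``v`` having arrived from ``t``, the unnormalized
    probability of moving to neighbor ``x`` is ``w(v, x) * alpha`` with
    ``alpha = 1/p`` if ``x == t``, ``1`` if ``x`` neighbors ``t``, and
    ``1/q`` otherwise.  First steps use the plain weight-proportional
    distribution.
    """

    def __init__(self, c: Connectome, p: float, q: float):
        if p <= 0 or q <= 0:
            raise ValueError("p and q must be positive")
        w = c.weights
        n = w.shape[0]
        self.n_nodes = n
        self.neighbors: list[np.ndarray] = []
        self.first_order: list[np.ndarray] = []
        nbr_sets: list[set[int]] = []
        for v in range(n):
            nbr = np.flatnonzero(w[v] > 0)
            self.neighbors.append(nbr)
            nbr_sets.append(set(nbr.tolist()))
            if nbr.size:
                probs = w[v, nbr] / w[v, nbr].sum()
            else:
                probs = np.empty(0)
            self.first_order.append(probs)
        # second-order: keyed by directed edge (t, v)
        self.second_order: dict[tuple[int, int], np.ndarray] = {}
        for t in range(n):
            for v in self.neighbors[t]:
                nbr = self.neighbors[v]
                alpha = np.where(
                    nbr == t,
                    1.0 / p,
                    np.where([x in nbr_sets[t] for x in nbr], 1.0, 1.0 / q),
                )
                un = w[v, nbr] * alpha
                self.second_order[(t, int(v))] = un / un.sum()

    def step_probs(self, prev: int, cur: int) -> tuple[np.ndarray, np.ndarray]:
        """Neighbors of ``cur`` and their transition probabilities given
        the walk arrived from ``prev``."""
        return self.neighbors[cur], self.second_order[(prev, cur)]


def transition_model(c: Connectome, p: float, q: float) -> TransitionModel:
    """Precompute normalized step distributions for every directed edge."""
    return TransitionModel(c, p, q)


def generate_walks(
    c: Connectome, wc: WalkConfig, model: TransitionModel | None = None
) -> WalkCorpus:
    """Generate the walk corpus for one run.

    Start nodes cycle deterministically over all non-isolated nodes in label
    order, so the walk counts per start node differ by at most one.  A start
    at an isolated node would emit a length-1 walk; isolated nodes are
    excluded from the start cycle, but lesioned (all-zero) nodes reached via
    ``walks_per_node`` bookkeeping still emit their singleton walk.
    """
    if model is None:
        model = transition_model(c, wc.p, wc.q)
    non_isolated = [v for v in range(c.n_nodes) if model.neighbors[v].size > 0]
    if not non_isolated:
        raise ValueError("graph has no edges; nothing to walk on")
    if wc.walks_per_node:
        starts = [v for v in non_isolated for _ in range(wc.num_walks)]
    else:
        starts = [non_isolated[i % len(non_isolated)] for i in range(wc.num_walks)]
    rng = np.random.Generator(np.random.PCG64(wc.seed))
    # cumulative distributions for O(log k) sampling
    first_cum = [np.cumsum(pr) for pr in model.first_order]
    second_cum = {k: np.cumsum(v) for k, v in model.second_order.items()}
    sequences: list[np.ndarray] = []
    for start in starts:
        walk = np.empty(wc.walk_length, dtype=np.int64)
        walk[0] = start
        nbr = model.neighbors[start]
        u = rng.random()
        walk[1] = nbr[np.searchsorted(first_cum[start], u)]
        length = 2
        for step in range(2, wc.walk_length):
            prev, cur = walk[step - 2], walk[step - 1]
            nbr = model.neighbors[cur]
            if nbr.size == 0:  # dead end (cannot happen on symmetric graphs)
                break
            u = rng.random()
            walk[step] = nbr[np.searchsorted(second_cum[(int(prev), int(cur))], u)]
            length += 1
        sequences.append(walk[:length].copy())
    return WalkCorpus(sequences=sequences, n_nodes=c.n_nodes)


# ---------------------------------------------------------------------------
# CBOW with negative sampling
# ---------------------------------------------------------------------------


@njit(cache=False)
def _cbow_sgd(
    tokens,  # int64[:] flattened corpus
    offsets,  # int64[:] sequence boundaries, len = n_seq + 1
    order,  # int64[:, :] per-epoch visiting order of positions
    negatives,  # int64[:, :] per-update negative samples
    syn0,  # float64[:, :] input vectors (updated in place)
    syn1,  # float64[:, :] output vectors (updated in place)
    seq_of_pos,  # int64[:] sequence id of each corpus position
    window,
    lr0,
    min_lr,
):
    n_updates = order.shape[0] * order.shape[1]
    dim = syn0.shape[1]
    k = negatives.shape[1]
    upd = 0
    for epoch in range(order.shape[0]):
        for oi in range(order.shape[1]):
            pos = order[epoch, oi]
            lr = lr0 * (1.0 - upd / n_updates)
            if lr < min_lr:
                lr = min_lr
            seq = seq_of_pos[pos]
            lo = offsets[seq]
            hi = offsets[seq + 1]
            c_lo = pos - window
            if c_lo < lo:
                c_lo = lo
            c_hi = pos + window + 1
            if c_hi > hi:
                c_hi = hi
            n_ctx = c_hi - c_lo - 1
            upd += 1
            if n_ctx <= 0:
                continue
            target = tokens[pos]
            # averaged context vector
            h = np.zeros(dim)
            for j in range(c_lo, c_hi):
                if j == pos:
                    continue
                h += syn0[tokens[j]]
            h /= n_ctx
            e = np.zeros(dim)
            for s in range(k + 1):
                if s == 0:
                    u = target
                    label = 1.0
                else:
                    u = negatives[upd - 1, s - 1]
                    if u == target:
                        continue
                    label = 0.0
                f = 0.0
                for d in range(dim):
                    f += syn1[u, d] * h[d]
                if f > 6.0:
                    g = (label - 1.0) * lr
                elif f < -6.0:
                    g = label * lr
                else:
                    g = (label - 1.0 / (1.0 + np.exp(-f))) * lr
                for d in range(dim):
                    e[d] += g * syn1[u, d]
                    syn1[u, d] += g * h[d]
            for j in range(c_lo, c_hi):
                if j == pos:
                    continue
                t2 = tokens[j]
                for d in range(dim):
                    syn0[t2, d] += e[d]
    return syn0


def train_cbow(
    corpus: WalkCorpus, ec: EmbedConfig, seed: int = 0
) -> EmbeddingRun:
    """Train CBOW-with-negative-sampling embeddings on a walk corpus.

    For each corpus position the target node is predicted from the average
    of the input vectors within ``+-window``; parameters follow stochastic
    gradient steps against ``negative_samples`` noise nodes drawn from the
    unigram distribution raised to 3/4.  The learning rate decays linearly
    over all updates.  The returned embedding is the input layer.
    Deterministic given ``seed`` (single-threaded).
    """
    if len(corpus.sequences) == 0:
        raise ValueError("empty corpus")
    tokens = np.concatenate([np.asarray(s, dtype=np.int64) for s in corpus.sequences])
    if tokens.size == 0:
        raise ValueError("empty corpus")
    lengths = np.array([len(s) for s in corpus.sequences], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    seq_of_pos = np.repeat(np.arange(len(lengths), dtype=np.int64), lengths)
    n_nodes = corpus.n_nodes
    rng = np.random.Generator(np.random.PCG64(seed))

    # unigram^(3/4) negative-sampling distribution over observed nodes
    counts = np.bincount(tokens, minlength=n_nodes).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    n_pos = tokens.size
    order = np.empty((ec.epochs, n_pos), dtype=np.int64)
    for ep in range(ec.epochs):
        order[ep] = rng.permutation(n_pos)
    negatives = rng.choice(
        n_nodes, size=(ec.epochs * n_pos, ec.negative_samples), p=noise
    ).astype(np.int64)

    dim = ec.dimensions
    syn0 = (rng.random((n_nodes, dim)) - 0.5) / dim
    syn1 = np.zeros((n_nodes, dim))
    _cbow_sgd(
        tokens,
        offsets.astype(np.int64),
        order,
        negatives,
        syn0,
        syn1,
        seq_of_pos,
        ec.window,
        ec.learning_rate,
        ec.learning_rate * 1e-4,
    )
    if not np.all(np.isfinite(syn0)):
        raise FloatingPointError("non-finite embedding values after training")
    return EmbeddingRun(vectors=syn0, seed=seed, embed_config=ec)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-run seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def embed_ensemble(
    c: Connectome,
    wc: WalkConfig,
    ec: EmbedConfig,
    n_runs: int,
    master_seed: int = 0,
) -> EmbeddingEnsemble:
    """Run walk generation + CBOW training ``n_runs`` times.

    Walks are regenerated per run; per-run seeds derive deterministically
    from ``master_seed``, so the whole ensemble is reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    model = transition_model(c, wc.p, wc.q)
    seeds = derive_seeds(master_seed, n_runs)
    runs = []
    for s in seeds:
        wc_run = dataclasses.replace(wc, seed=s)
        corpus = generate_walks(c, wc_run, model=model)
        run = train_cbow(corpus, ec, seed=s)
        run.walk_config = wc_run
        runs.append(run)
    return EmbeddingEnsemble(runs)


# ---------------------------------------------------------------------------
# spectral baseline
# ---------------------------------------------------------------------------


def spectral_embed(
    c: Connectome, dimensions: int = 30, normalized: bool = True
) -> EmbeddingRun:
    """Laplacian-eigenmaps embedding of the weighted graph.

    Columns are eigenvectors of the (symmetric normalized, by default)
    graph Laplacian belonging to the ``dimensions`` smallest nonzero
    eigenvalues.  Isolated nodes receive zero vectors.  Column signs are
    fixed so each eigenvector's largest-magnitude entry is positive.
    """
    n = c.n_nodes
    if dimensions >= n:
        raise ValueError(f"dimensions must be < n_nodes ({n})")
    w = c.weights
    deg = w.sum(axis=1)
    active = deg > 0
    wa = w[np.ix_(active, active)]
    da = deg[active]
    if normalized:
        inv_sqrt = 1.0 / np.sqrt(da)
        lap = np.eye(wa.shape[0]) - inv_sqrt[:, None] * wa * inv_sqrt[None, :]
    else:
        lap = np.diag(da) - wa
    vals, vecs = scipy.linalg.eigh(lap)
    nonzero = np.flatnonzero(vals > 1e-9)
    if nonzero.size < dimensions:
        raise ValueError(
            f"only {nonzero.size} nonzero Laplacian eigenvalues; cannot embed "
            f"into {dimensions} dimensions"
        )
    cols = vecs[:, nonzero[:dimensions]]
    # deterministic sign convention
    for k in range(cols.shape[1]):
        j = np.argmax(np.abs(cols[:, k]))
        if cols[j, k] < 0:
            cols[:, k] = -cols[:, k]
    out = np.zeros((n, dimensions))
    out[active] = cols
    return EmbeddingRun(vectors=out, seed=0, method="spectral")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Returns ``nan`` for a zero vector; callers exclude such nodes from
    rankings.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


# ---------------------------------------------------------------------------
# ensemble store
# ---------------------------------------------------------------------------


def save_ensemble(directory: str | Path, ens: EmbeddingEnsemble) -> None:
    """One delimited N x D table per run plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_runs": len(ens),
        "n_nodes": ens[0].n_nodes,
        "dimensions": ens[0].dimensions,
        "runs": [],
    }
    for i, run in enumerate(ens.runs):
        fname = f"run_{i:04d}.tsv"
        save_matrix_rect(directory / fname, run.vectors)
        manifest["runs"].append(
            {"file": fname, "seed": int(run.seed), "method": run.method}
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def save_matrix_rect(path: str | Path, matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        for row in np.asarray(matrix, dtype=float):
            fh.write("\t".join("%.17g" % v for v in row) + "\n")


def load_ensemble(directory: str | Path) -> EmbeddingEnsemble:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    runs = []
    for entry in manifest["runs"]:
        rows = []
        with open(directory / entry["file"]) as fh:
            for line in fh:
                if line.strip():
                    rows.append([float(x) for x in line.split()])
        runs.append(
            EmbeddingRun(
                vectors=np.array(rows),
                seed=entry["seed"],
                method=entry.get("method", "cbow-node2vec"),
            )
        )
    return EmbeddingEnsemble(runs)
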