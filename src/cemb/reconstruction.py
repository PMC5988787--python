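"""Cosine-similarity reconstruction of the connectome and its statistics.

The pairwise cosine-similarity matrix of the node vectors is itself a
weighted network — a *reconstruction* of the structural connectome as seen
through the embedding.  This module builds that matrix (per run or as an
ensemble mean), z-scores matrices for comparability, measures how strongly
homotopic inter-hemispheric edges survive thresholding, rank-correlates the
reconstruction with structural and functional matrices (split into direct
node pairs, with a structural edge, and indirect pairs, without), and
correlates embedding dimensions with standard nodal graph metrics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import networkx as nx
import scipy.stats

from cemb.connectome_io import Connectome, FunctionalMatrix
from cemb.embedding import EmbeddingEnsemble, EmbeddingRun

METRIC_NAMES = (
    "degree",
    "strength",
    "eigenvector_centrality",
    "betweenness_centrality",
    "clustering",
)


@dataclasses.dataclass
class ReconMatrix:
    """N x N cosine-similarity matrix with provenance."""

    values: np.ndarray
    provenance: str  # "single-run" or "ensemble-mean"
    missing: np.ndarray | None = None  # nodes with zero vectors, if any


def _run_cosine(run: EmbeddingRun) -> tuple[np.ndarray, np.ndarray]:
    v = run.vectors
    norms = np.linalg.norm(v, axis=1)
    ok = norms > 0
    unit = np.zeros_like(v)
    unit[ok] = v[ok] / norms[ok, None]
    m = np.clip(unit @ unit.T, -1.0, 1.0)
    m[~ok, :] = np.nan
    m[:, ~ok] = np.nan
    return m, ~ok


def cosine_reconstruction(
    ens: EmbeddingEnsemble | EmbeddingRun,
) -> ReconMatrix:
    """Pairwise cosine matrix; for an ensemble, the element-wise mean
    across runs (cross-run cosine structure is stable, so the mean is a
    low-variance estimator of it)."""
    if isinstance(ens, EmbeddingRun):
        m, missing = _run_cosine(ens)
        return ReconMatrix(values=m, provenance="single-run", missing=missing)
    mats = []
    missing = np.zeros(ens[0].n_nodes, dtype=bool)
    for run in ens.runs:
        m, miss = _run_cosine(run)
        mats.append(m)
        missing |= miss
    return ReconMatrix(
        values=np.mean(mats, axis=0), provenance="ensemble-mean", missing=missing
    )


def upper_off_diagonal(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return m[iu]


def zscore_matrix(m: np.ndarray) -> np.ndarray:
    """Z-score a symmetric matrix over its upper-triangle off-diagonal
    entries (zeros included; sample n-1 standard deviation), mirrored back
    to full symmetry.  The diagonal is set to 0 and carries no meaning."""
    m = np.asarray(m, dtype=float)
    vals = upper_off_diagonal(m)
    sd = np.std(vals, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance: matrix cannot be z-scored")
    z = (m - vals.mean()) / sd
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def homotopic_fraction(
    z: np.ndarray, pairs: list[tuple[int, int]], threshold: float = 0.0
) -> tuple[int, int, float]:
    """Fraction of homotopic pairs whose z-scored edge exceeds threshold.

    Returns ``(surviving_count, total_pairs, fraction)``.
    """
    if not pairs:
        raise ValueError("no homotopic pairs")
    count = sum(1 for i, j in pairs if z[i, j] > threshold)
    return count, len(pairs), count / len(pairs)


def matrix_spearman(
    a: np.ndarray,
    b: np.ndarray,
    structural: np.ndarray | None = None,
    mask: str = "all",
) -> tuple[float, float]:
    """Spearman rank correlation between two matrices' upper triangles.

    ``mask`` selects node pairs: ``"all"``, ``"direct"`` (structural weight
    > 0) or ``"indirect"`` (structural weight == 0); the latter two need a
    ``structural`` reference matrix.  Average ranks on ties, two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    va = upper_off_diagonal(a)
    vb = upper_off_diagonal(b)
    if mask != "all":
        if structural is None:
            raise ValueError("direct/indirect masks need a structural matrix")
        vs = upper_off_diagonal(np.asarray(structural, dtype=float))
        sel = vs > 0 if mask == "direct" else vs == 0
        va, vb = va[sel], vb[sel]
    if va.size < 3:
        raise ValueError("fewer than 3 masked entries")
    rho, p = scipy.stats.spearmanr(va, vb)
    return float(rho), float(p)


def fisher_z(fc: FunctionalMatrix | np.ndarray) -> np.ndarray:
    """Fisher z-transform (atanh) of a correlation matrix, element-wise.

    Off-diagonal values at or beyond +-1 are clipped to +-(1 - 1e-7); the
    diagonal is zeroed (it is excluded from all statistics anyway).
    """
    vals = fc.values if isinstance(fc, FunctionalMatrix) else np.asarray(fc, float)
    clipped = np.clip(vals, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, 0.0)
    return z


def metric_profile(c: Connectome) -> dict[str, np.ndarray]:
    """Per-node graph metrics of the weighted connectome.

    degree: count of nonzero edges; strength: weight sum; eigenvector
    centrality: principal eigenvector of the weight matrix (L2-normalized,
    non-negative); betweenness: weighted shortest paths with length
    1/weight; clustering: Onnela weighted formulation.
    """
    w = c.weights
    n = c.n_nodes
    g = nx.from_numpy_array(w)
    for _, _, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    degree = (w > 0).sum(axis=1)
    strength = w.sum(axis=1)
    # principal eigenvector of W; non-negative by Perron-Frobenius on the
    # dominant component, sign-fixed and L2-normalized
    vals, vecs = np.linalg.eigh(w)
    ev = vecs[:, np.argmax(vals)]
    if ev.sum() < 0:
        ev = -ev
    ev = np.abs(ev)
    ev /= np.linalg.norm(ev)
    btw = nx.betweenness_centrality(g, weight="distance", normalized=True)
    clus = nx.clustering(g, weight="weight")
    return {
        "degree": degree.astype(float),
        "strength": strength,
        "eigenvector_centrality": ev,
        "betweenness_centrality": np.array([btw[i] for i in range(n)]),
        "clustering": np.array([clus[i] for i in range(n)]),
    }


def dimension_metric_correlations(
    ens: EmbeddingEnsemble | EmbeddingRun,
    metrics: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Spearman rho and p of each embedding dimension against each metric.

    Uses ensemble-mean vectors; a constant dimension or metric yields nan.
    Returns ``{"rho": D x M, "p": D x M}`` with metric columns in
    :data:`METRIC_NAMES` order.
    """
    vec = (
        ens.vectors if isinstance(ens, EmbeddingRun) else ens.mean_vectors()
    )
    n, d = vec.shape
    if n < 4:
        raise ValueError("need at least 4 nodes")
    names = [k for k in METRIC_NAMES if k in metrics]
    rho = np.full((d, len(names)), np.nan)
    pval = np.full((d, len(names)), np.nan)
    for j, name in enumerate(names):
        m = metrics[name]
        for i in range(d):
            col = vec[:, i]
            if np.ptp(col) == 0 or np.ptp(m) == 0:
                continue
            r, p = scipy.stats.spearmanr(col, m)
            rho[i, j] = r
            pval[i, j] = p
    return {"rho": rho, "p": pval, "metrics": names}
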