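"""Synthetic hemispherically mirrored connectomes with known ground truth.

Real structural connectomes are modular within each hemisphere, nearly
mirror-symmetric across hemispheres, and dominated by homotopic
inter-hemispheric (callosal) edges.  The generator builds one hemisphere as
a stochastic block model with log-normal fiber weights, mirrors it exactly,
wires homotopic pairs with high probability and heavier weights, sprinkles
sparse non-homotopic cross-hemisphere edges, and optionally adds midline
nodes.  Matched functional matrices are produced from a planted function of
edge features of ground-truth latent vectors plus Gaussian noise, so every
downstream stage (embedding, analogies, reconstruction, structure-function
mapping, lesions) can be tested against a known answer.

What this emulates — and what it does not: the generator reproduces the
*statistical* signatures the analyses rely on (homotopy, modularity,
heavy-tailed weights, FC driven by a smooth function of structure), not
spatial geometry, distance-dependent wiring, or biophysical FC dynamics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cemb.connectome_io import Connectome, FunctionalMatrix, homotopic_pairs


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Defaults mirror the scale of an 83-region whole-brain parcellation:
    41 homotopic pairs plus one midline node.  ``within_module_p`` /
    ``between_module_p`` are intra-hemisphere stochastic-block-model edge
    probabilities; ``homotopic_p`` is the probability a homotopic pair gets
    a direct edge (high, emulating callosal wiring); weights are log-normal
    in arbitrary fiber-density units.
    """

    n_pairs: int = 41
    n_midline: int = 1
    modules_per_hemisphere: int = 4
    within_module_p: float = 0.7
    between_module_p: float = 0.15
    homotopic_p: float = 0.8
    cross_hemisphere_p: float = 0.05
    midline_p: float = 0.2
    weight_mu: float = 0.0
    weight_sigma: float = 1.0
    homotopic_weight_scale: float = 2.0
    fc_noise_sigma: float = 0.1
    planted_gain: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 homotopic pairs")
        for p in (
            self.within_module_p,
            self.between_module_p,
            self.homotopic_p,
            self.cross_hemisphere_p,
            self.midline_p,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def generate_symmetric_connectome(cfg: SynthConfig | None = None) -> Connectome:
    """Build a mirrored modular connectome with labels and pairing.

    Left-hemisphere nodes are ``L01..`` with mirrors ``R01..``; module
    membership is contiguous.  The two within-hemisphere blocks are exact
    copies under the pairing permutation.
    """
    if cfg is None:
        cfg = SynthConfig()
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    npair = cfg.n_pairs
    n = 2 * npair + cfg.n_midline

    modules = np.array(
        [i * cfg.modules_per_hemisphere // npair for i in range(npair)]
    )
    # one hemisphere as an SBM with log-normal weights
    hemi = np.zeros((npair, npair))
    for i in range(npair):
        for j in range(i + 1, npair):
            p = (
                cfg.within_module_p
                if modules[i] == modules[j]
                else cfg.between_module_p
            )
            if rng.random() < p:
                hemi[i, j] = hemi[j, i] = rng.lognormal(
                    cfg.weight_mu, cfg.weight_sigma
                )
    w = np.zeros((n, n))
    left = slice(0, npair)
    right = slice(npair, 2 * npair)
    w[left, left] = hemi
    w[right, right] = hemi  # exact mirror
    # homotopic edges: strong, frequent
    for i in range(npair):
        if rng.random() < cfg.homotopic_p:
            wt = cfg.homotopic_weight_scale * rng.lognormal(
                cfg.weight_mu, cfg.weight_sigma
            )
            w[i, npair + i] = w[npair + i, i] = wt
    # sparse non-homotopic cross-hemisphere edges
    for i in range(npair):
        for j in range(npair):
            if j == i:
                continue
            if rng.random() < cfg.cross_hemisphere_p:
                wt = rng.lognormal(cfg.weight_mu, cfg.weight_sigma)
                w[i, npair + j] = w[npair + j, i] = wt
    # midline nodes connect everywhere at moderate probability
    for m in range(2 * npair, n):
        for j in range(2 * npair):
            if rng.random() < cfg.midline_p:
                wt = rng.lognormal(cfg.weight_mu, cfg.weight_sigma)
                w[m, j] = w[j, m] = wt

    width = max(2, len(str(npair)))
    labels = (
        [f"L{i + 1:0{width}d}" for i in range(npair)]
        + [f"R{i + 1:0{width}d}" for i in range(npair)]
        + [f"M{i + 1:02d}" for i in range(cfg.n_midline)]
    )
    hemis = ["left"] * npair + ["right"] * npair + ["midline"] * cfg.n_midline
    partner = np.full(n, -1, dtype=int)
    partner[:npair] = np.arange(npair) + npair
    partner[npair : 2 * npair] = np.arange(npair)
    c = Connectome(labels, hemis, partner, w)
    if (c.weights > 0).sum() == 0:
        raise ValueError("degenerate config produced an empty graph")
    return c


def delete_homotopic_fraction(
    c: Connectome, fraction: float, seed: int = 0
) -> tuple[Connectome, list[tuple[int, int]]]:
    """Remove a random fraction of the existing homotopic edges.

    Deletes ``floor(fraction * n_existing)`` edges; returns the modified
    connectome and the ground-truth list of removed pairs.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    existing = [(i, j) for i, j in homotopic_pairs(c) if c.weights[i, j] > 0]
    n_del = int(np.floor(fraction * len(existing)))
    chosen = rng.choice(len(existing), size=n_del, replace=False) if n_del else []
    deleted = [existing[k] for k in np.sort(np.asarray(chosen, dtype=int))]
    w = c.weights.copy()
    for i, j in deleted:
        w[i, j] = w[j, i] = 0.0
    return c.copy_with_weights(w), deleted


def delete_random_edges(
    c: Connectome,
    n_delete: int,
    seed: int = 0,
    exclude: set[tuple[int, int]] | None = None,
    cross_hemisphere_only: bool = False,
) -> tuple[Connectome, list[tuple[int, int]]]:
    """Remove ``n_delete`` random existing non-homotopic edges.

    Control deletions matched to :func:`delete_homotopic_fraction`; with
    ``cross_hemisphere_only`` the candidates are restricted to non-homotopic
    inter-hemispheric edges, matching the deleted homotopic edges on the
    hemisphere-crossing property (within-hemisphere edges sit inside
    modules whose endpoints share most neighbors, which makes them
    trivially easy to reconstruct and a meaningless control).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    homo = {tuple(sorted(p)) for p in homotopic_pairs(c)}
    excl = (exclude or set()) | homo

    def ok(i: int, j: int) -> bool:
        if cross_hemisphere_only:
            hi, hj = c.hemisphere[i], c.hemisphere[j]
            if hi == hj or "midline" in (hi, hj):
                return False
        return True

    cand = [
        (i, j)
        for i in range(c.n_nodes)
        for j in range(i + 1, c.n_nodes)
        if c.weights[i, j] > 0 and (i, j) not in excl and ok(i, j)
    ]
    if n_delete > len(cand):
        raise ValueError("not enough candidate edges to delete")
    chosen = rng.choice(len(cand), size=n_delete, replace=False)
    deleted = [cand[k] for k in np.sort(chosen)]
    w = c.weights.copy()
    for i, j in deleted:
        w[i, j] = w[j, i] = 0.0
    return c.copy_with_weights(w), deleted


def structural_latent_vectors(
    c: Connectome, dimensions: int = 30, seed: int = 0
) -> np.ndarray:
    """Deterministic ground-truth latent vectors tied to the structure.

    Rows of the weight matrix compressed to ``dimensions`` via truncated
    SVD (columns scaled by singular values), so latent similarity reflects
    connectivity-profile similarity.  Used as the substrate of the planted
    FC map; independent of any learned embedding.
    """
    u, s, _ = np.linalg.svd(c.weights, full_matrices=False)
    k = min(dimensions, len(s))
    vec = u[:, :k] * s[:k]
    if k < dimensions:
        vec = np.pad(vec, ((0, 0), (0, dimensions - k)))
    # fix signs for determinism
    for j in range(vec.shape[1]):
        i = np.argmax(np.abs(vec[:, j]))
        if vec[i, j] < 0:
            vec[:, j] = -vec[:, j]
    return vec


def generate_functional(
    c: Connectome,
    vectors: np.ndarray | None = None,
    cfg: SynthConfig | None = None,
    seed: int | None = None,
) -> tuple[FunctionalMatrix, np.ndarray]:
    """Planted functional matrix: FC(i,j) = tanh(w'(u_i * u_j)) + noise.

    ``vectors`` default to :func:`structural_latent_vectors`, making FC a
    noisy smooth function of structure.  The planted weight vector ``w`` is
    drawn once from the seed and scaled so the pre-noise index has unit
    standard deviation times ``planted_gain`` (enough for the tanh
    curvature to matter).  Returns the matrix and the ground-truth ``w``.
    """
    if cfg is None:
        cfg = SynthConfig()
    rng = np.random.Generator(np.random.PCG64(cfg.seed if seed is None else seed))
    if vectors is None:
        vectors = structural_latent_vectors(c)
    n, d = vectors.shape
    if n != c.n_nodes:
        raise ValueError("vectors do not match node count")
    w = rng.standard_normal(d)
    iu = np.triu_indices(n, k=1)
    feats = vectors[iu[0]] * vectors[iu[1]]
    idx = feats @ w
    sd = idx.std()
    if sd > 0:
        w = w * (cfg.planted_gain / sd)
        idx = idx * (cfg.planted_gain / sd)
    fcvals = np.tanh(idx) + rng.normal(0, cfg.fc_noise_sigma, size=idx.shape)
    fcvals = np.clip(fcvals, -1 + 1e-6, 1 - 1e-6)
    mat = np.zeros((n, n))
    mat[iu] = fcvals
    mat = mat + mat.T
    np.fill_diagonal(mat, 1.0)
    return FunctionalMatrix(list(c.labels), mat), w


def generate_subject_ensemble(
    c: Connectome,
    n_subjects: int,
    edge_dropout: float = 0.2,
    weight_jitter_sigma: float = 0.3,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-subject matrices: edges dropped independently, weights jittered.

    Each existing edge survives with probability ``1 - edge_dropout`` and
    its weight is multiplied by a log-normal factor (sigma =
    ``weight_jitter_sigma``); symmetric per subject.  For exercising the
    group-consensus builder.
    """
    if not 0 <= edge_dropout <= 1:
        raise ValueError("edge_dropout must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    iu = np.triu_indices(c.n_nodes, k=1)
    base = c.weights[iu]
    out = []
    for _ in range(n_subjects):
        keep = rng.random(base.shape) >= edge_dropout
        jitter = rng.lognormal(0.0, weight_jitter_sigma, size=base.shape)
        vals = np.where(keep, base * jitter, 0.0)
        m = np.zeros_like(c.weights)
        m[iu] = vals
        out.append(m + m.T)
    return out
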