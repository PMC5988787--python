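"""Labelled weighted connectomes: data model, text I/O, group consensus.

A connectome here is a non-negative, symmetric, zero-diagonal weight matrix
over named brain regions, each tagged with a hemisphere (``left``, ``right``
or ``midline``) and, where one exists, paired with its homotopic mirror
region in the opposite hemisphere.  Matrices travel as plain delimited text;
node metadata travels in a three-column sidecar (label, hemisphere,
partner label or ``-``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

HEMISPHERES = ("left", "right", "midline")

#: relative asymmetry tolerated before an input matrix is rejected
DEFAULT_SYM_TOL = 1e-6


class ConnectomeError(ValueError):
    """Raised for structurally invalid connectome inputs."""


@dataclasses.dataclass
class Connectome:
    """A weighted, undirected, node-labelled brain network.

    Parameters
    ----------
    labels
        Ordered region names; this order fixes the row/column order of every
        matrix in a session.
    hemisphere
        Per-node tag, one of ``left``/``right``/``midline``.
    homotopic_partner
        Per-node index of the mirror region, or ``-1`` for unpaired nodes.
        The pairing is an involution across hemispheres.
    weights
        ``N x N`` non-negative symmetric matrix of fiber densities
        (arbitrary units) with a zero diagonal.
    """

    labels: list[str]
    hemisphere: list[str]
    homotopic_partner: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.homotopic_partner = np.asarray(self.homotopic_partner, dtype=int)
        validate_connectome(self)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConnectomeError(f"unknown node label: {label!r}") from None

    def copy_with_weights(self, weights: np.ndarray) -> "Connectome":
        """Same node set and pairing, new weight matrix."""
        return Connectome(
            labels=list(self.labels),
            hemisphere=list(self.hemisphere),
            homotopic_partner=self.homotopic_partner.copy(),
            weights=np.asarray(weights, dtype=float).copy(),
        )


@dataclasses.dataclass
class FunctionalMatrix:
    """Symmetric matrix of pairwise Pearson correlations between regions.

    The diagonal (zero or unit) is recorded but excluded from every
    statistic computed downstream.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConnectomeError(
                f"functional matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ConnectomeError("functional matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and np.max(np.abs(off)) > 1 + 1e-12:
            raise ConnectomeError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def validate_connectome(c: Connectome) -> None:
    """Check all structural invariants, raising :class:`ConnectomeError`."""
    n = len(c.labels)
    if len(set(c.labels)) != n:
        raise ConnectomeError("duplicate node labels")
    if len(c.hemisphere) != n:
        raise ConnectomeError("hemisphere tags do not match label count")
    for h in c.hemisphere:
        if h not in HEMISPHERES:
            raise ConnectomeError(f"unknown hemisphere tag: {h!r}")
    if c.weights.shape != (n, n):
        raise ConnectomeError(
            f"weight matrix shape {c.weights.shape} does not match {n} labels"
        )
    if np.any(c.weights < 0):
        raise ConnectomeError("negative weights")
    if not np.array_equal(c.weights, c.weights.T):
        raise ConnectomeError("asymmetric weight matrix")
    if np.any(np.diag(c.weights) != 0):
        raise ConnectomeError("nonzero diagonal")
    if c.homotopic_partner.shape != (n,):
        raise ConnectomeError("homotopic_partner must have one entry per node")
    for i, j in enumerate(c.homotopic_partner):
        if j == -1:
            continue
        if not 0 <= j < n:
            raise ConnectomeError(f"partner index {j} out of range")
        if c.homotopic_partner[j] != i:
            raise ConnectomeError("homotopic pairing is not an involution")
        if i == j or c.hemisphere[i] == c.hemisphere[j]:
            raise ConnectomeError(
                "homotopic partners must lie in opposite hemispheres"
            )


def _split_row(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [f.strip() for f in line.split(",") if f.strip() != ""]
    return line.split()


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square numeric table, whitespace- or comma-delimited.

    An optional first header row of labels is detected by its first field
    being non-numeric.  Returns ``(matrix, labels_or_None)``.
    """
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            fields = _split_row(line)
            if not fields or fields[0].startswith("#"):
                continue
            if header is None and not rows:
                try:
                    float(fields[0])
                except ValueError:
                    header = fields
                    continue
            rows.append([float(f) for f in fields])
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(f"matrix in {path} is not square: {mat.shape}")
    if header is not None and len(header) != mat.shape[0]:
        raise ConnectomeError("header length does not match matrix size")
    return mat, header


def save_matrix(
    path: str | Path,
    matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    fmt: str = "%.17g",
) -> None:
    """Write a square matrix as tab-delimited text (``%.17g`` round-trips
    float64 bit-exactly)."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(fmt % v for v in row) + "\n")


def load_sidecar(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read the node-metadata sidecar: label, hemisphere, partner label."""
    labels: list[str] = []
    hemis: list[str] = []
    partner_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            fields = _split_row(line)
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) != 3:
                raise ConnectomeError(
                    f"sidecar row needs 3 columns, got {len(fields)}: {fields}"
                )
            labels.append(fields[0])
            hemis.append(fields[1].lower())
            partner_names.append(fields[2])
    partner = np.full(len(labels), -1, dtype=int)
    pos = {lab: i for i, lab in enumerate(labels)}
    for i, name in enumerate(partner_names):
        if name == "-":
            continue
        if name not in pos:
            raise ConnectomeError(f"partner label {name!r} not present")
        partner[i] = pos[name]
    return labels, hemis, partner


def save_sidecar(path: str | Path, c: Connectome) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(c.labels):
            j = c.homotopic_partner[i]
            partner = c.labels[j] if j >= 0 else "-"
            fh.write(f"{lab}\t{c.hemisphere[i]}\t{partner}\n")


def symmetrize(matrix: np.ndarray, tol: float = DEFAULT_SYM_TOL) -> np.ndarray:
    """Average a near-symmetric matrix with its transpose.

    Asymmetry is measured relative to the largest magnitude entry; anything
    above ``tol`` is rejected rather than silently averaged away.
    """
    matrix = np.asarray(matrix, dtype=float)
    scale = np.max(np.abs(matrix)) or 1.0
    gap = np.max(np.abs(matrix - matrix.T))
    if gap > tol * scale:
        raise ConnectomeError(
            f"asymmetric input: max |A - A^T| = {gap:g} exceeds tolerance "
            f"{tol:g} (relative to max |A| = {scale:g})"
        )
    return (matrix + matrix.T) / 2.0


def load_connectome(
    matrix_path: str | Path,
    labels_path: str | Path,
    sym_tol: float = DEFAULT_SYM_TOL,
) -> Connectome:
    """Load and validate a connectome from a matrix file plus sidecar.

    The diagonal is forced to zero and near-symmetric matrices (relative
    asymmetry below ``sym_tol``) are symmetrized as ``(A + A.T) / 2``.
    """
    mat, header = load_matrix(matrix_path)
    labels, hemis, partner = load_sidecar(labels_path)
    if mat.shape[0] != len(labels):
        raise ConnectomeError(
            f"matrix is {mat.shape[0]}x{mat.shape[0]} but sidecar has "
            f"{len(labels)} nodes"
        )
    if header is not None and header != labels:
        raise ConnectomeError("matrix header labels disagree with sidecar")
    if np.any(mat < 0):
        raise ConnectomeError("negative weights")
    mat = symmetrize(mat, tol=sym_tol)
    np.fill_diagonal(mat, 0.0)
    return Connectome(labels, hemis, partner, mat)


def save_connectome(
    matrix_path: str | Path, labels_path: str | Path, c: Connectome
) -> None:
    save_matrix(matrix_path, c.weights, labels=c.labels)
    save_sidecar(labels_path, c)


def load_functional(
    matrix_path: str | Path, labels: Sequence[str]
) -> FunctionalMatrix:
    """Load a functional (Pearson correlation) matrix in a fixed node order."""
    mat, header = load_matrix(matrix_path)
    labels = list(labels)
    if header is not None and header != labels:
        raise ConnectomeError("functional header labels disagree with sidecar")
    if mat.shape[0] != len(labels):
        raise ConnectomeError("functional matrix does not match node count")
    return FunctionalMatrix(labels, symmetrize(mat, tol=1e-6))


def build_consensus(
    subject_matrices: Sequence[np.ndarray],
    presence_fraction: float = 0.25,
    average: str = "all",
) -> np.ndarray:
    """Group-consensus weights: keep edges present in enough subjects.

    An edge is *present* in a subject when its weight is strictly positive.
    Edges present in at least ``presence_fraction`` of subjects receive the
    mean weight; all others are zeroed.

    Parameters
    ----------
    average
        ``"all"`` (default) averages over every subject, zeros included;
        ``"present"`` averages over only the subjects carrying the edge.
    """
    if len(subject_matrices) == 0:
        raise ConnectomeError("no subject matrices")
    if not 0 < presence_fraction <= 1:
        raise ConnectomeError("presence_fraction must lie in (0, 1]")
    if average not in ("all", "present"):
        raise ConnectomeError(f"unknown averaging mode {average!r}")
    try:
        stack = np.stack([np.asarray(m, dtype=float) for m in subject_matrices])
    except ValueError as exc:
        raise ConnectomeError(f"subject matrices disagree on shape: {exc}") from None
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ConnectomeError("subject matrices must be square and same shape")
    present = stack > 0
    n_present = present.sum(axis=0)
    keep = n_present >= presence_fraction * stack.shape[0]
    if average == "all":
        mean = stack.mean(axis=0)
    else:
        with np.errstate(invalid="ignore"):
            mean = np.where(n_present > 0, stack.sum(axis=0) / np.maximum(n_present, 1), 0.0)
    return np.where(keep, mean, 0.0)


def homotopic_pairs(c: Connectome) -> list[tuple[int, int]]:
    """All homotopic mirror pairs, each listed once as ``(i, j)`` with i < j.

    Midline and unpaired nodes are excluded; 82 paired nodes yield 41 pairs.
    """
    pairs = []
    for i, j in enumerate(c.homotopic_partner):
        if j > i:
            pairs.append((i, int(j)))
    return pairs
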