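"""Inter-hemispheric analogies test.

The brain's hemispheres mirror each other: the relation between two regions
in one hemisphere should be analogous to the relation between their
homotopic counterparts in the other.  In a linear embedding space this
becomes vector arithmetic — for homotopic pairs (A, A') and (B, B'),
``vec(A') - vec(B') + vec(B)`` should land nearest ``vec(A)``.  Each task
ranks every candidate node by cosine similarity to that combined vector and
logs the 0-based rank of the expected node; low ranks mean the embedding
encodes functional homotopy.  Ranks are aggregated as the per-task median
across ensemble runs, binned at width 5, and embedders are compared by a
chi-square test on their top-5 counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.stats

from cemb.connectome_io import Connectome, homotopic_pairs
from cemb.embedding import EmbeddingEnsemble, EmbeddingRun


@dataclasses.dataclass(frozen=True)
class AnalogyTask:
    """One analogy: predict ``expected`` from src_a - src_b + tgt_b.

    ``src_a`` and ``src_b`` sit in the source hemisphere; ``tgt_b`` is the
    mirror of ``src_b`` and ``expected`` the mirror of ``src_a``.
    """

    src_a: int
    src_b: int
    tgt_b: int
    expected: int


@dataclasses.dataclass
class AnalogyReport:
    """Median ranks per task with binned summary (bin width 5)."""

    tasks: list[AnalogyTask]
    median_ranks: np.ndarray
    bin_width: int
    bin_counts: np.ndarray
    top5_count: int
    top5_total: int

    @property
    def top5_proportion(self) -> float:
        return self.top5_count / self.top5_total


@dataclasses.dataclass
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    table: np.ndarray


def enumerate_tasks(c: Connectome, direction: str = "r2l") -> list[AnalogyTask]:
    """All analogy tasks, one per unordered pair of homotopic pairs.

    With direction ``"r2l"`` (default) the combined vector is built from two
    right-hemisphere nodes plus the left mirror of the second, and the
    expected node is the left mirror of the first; ``"l2r"`` swaps roles.
    41 homotopic pairs yield C(41, 2) = 820 tasks.
    """
    if direction not in ("r2l", "l2r"):
        raise ValueError(f"unknown direction {direction!r}")
    src_hemi = "right" if direction == "r2l" else "left"
    pairs = homotopic_pairs(c)
    if len(pairs) < 2:
        raise ValueError("need at least 2 homotopic pairs")
    # orient each pair as (source-hemisphere node, target-hemisphere node)
    oriented = []
    for i, j in pairs:
        if c.hemisphere[i] == src_hemi:
            oriented.append((i, j))
        else:
            oriented.append((j, i))
    tasks = []
    for a in range(len(oriented)):
        for b in range(a + 1, len(oriented)):
            sa, ta = oriented[a]
            sb, tb = oriented[b]
            tasks.append(AnalogyTask(src_a=sa, src_b=sb, tgt_b=tb, expected=ta))
    return tasks


def analogy_rank(
    run: EmbeddingRun,
    task: AnalogyTask,
    exclude_operands: bool = True,
) -> int:
    """0-based cosine rank of the expected node for one task and run.

    The combined query vector is ``vec(src_a) - vec(src_b) + vec(tgt_b)``;
    candidates are every node except (by default) the three operands,
    ranked by decreasing cosine similarity.  Rank 0 means the expected node
    was the most similar candidate.
    """
    ranks = analogy_ranks_batch(run, [task], exclude_operands=exclude_operands)
    return int(ranks[0])


def analogy_ranks_batch(
    run: EmbeddingRun,
    tasks: list[AnalogyTask],
    exclude_operands: bool = True,
) -> np.ndarray:
    """Vectorized :func:`analogy_rank` over many tasks (same semantics)."""
    vec = run.vectors
    norms = np.linalg.norm(vec, axis=1)
    ok = norms > 0
    unit = np.zeros_like(vec)
    unit[ok] = vec[ok] / norms[ok, None]

    ia = np.array([t.src_a for t in tasks])
    ib = np.array([t.src_b for t in tasks])
    ic = np.array([t.tgt_b for t in tasks])
    ie = np.array([t.expected for t in tasks])
    query = vec[ia] - vec[ib] + vec[ic]
    qn = np.linalg.norm(query, axis=1)
    if np.any(qn == 0):
        raise ValueError("zero combined query vector")
    sims = (query / qn[:, None]) @ unit.T  # tasks x nodes
    sims[:, ~ok] = -np.inf  # zero vectors excluded from candidacy
    if exclude_operands:
        r = np.arange(len(tasks))
        sims[r, ia] = -np.inf
        sims[r, ib] = -np.inf
        sims[r, ic] = -np.inf
    expected_sim = sims[np.arange(len(tasks)), ie]
    if np.any(~np.isfinite(expected_sim)):
        raise ValueError("expected node has a zero vector or is an operand")
    return (sims > expected_sim[:, None]).sum(axis=1)


def lower_median(values: np.ndarray) -> np.ndarray:
    """Median along axis 0; for even counts, the lower central value.

    Keeps medians of integer ranks integral, so bin membership is
    unambiguous.
    """
    v = np.sort(np.asarray(values), axis=0)
    return v[(v.shape[0] - 1) // 2]


def run_test(
    ens: EmbeddingEnsemble,
    c: Connectome,
    direction: str = "r2l",
    bin_width: int = 5,
    exclude_operands: bool = True,
    tasks: list[AnalogyTask] | None = None,
) -> AnalogyReport:
    """Run the analogies test over an ensemble and summarize.

    Per task the median rank across runs is taken (lower median for even
    run counts); ranks are binned as [0, 5), [5, 10), ...; the top-5
    proportion is the fraction of tasks whose median rank falls in the
    first bin.
    """
    if tasks is None:
        tasks = enumerate_tasks(c, direction=direction)
    all_ranks = np.stack(
        [
            analogy_ranks_batch(run, tasks, exclude_operands=exclude_operands)
            for run in ens.runs
        ]
    )
    med = lower_median(all_ranks)
    n_bins = int(np.ceil(c.n_nodes / bin_width))
    counts = np.bincount(med // bin_width, minlength=n_bins)[:n_bins]
    top5 = int((med < bin_width).sum())
    return AnalogyReport(
        tasks=tasks,
        median_ranks=med,
        bin_width=bin_width,
        bin_counts=counts,
        top5_count=top5,
        top5_total=len(tasks),
    )


def chi_square_2x2(
    a_hits: int, a_total: int, b_hits: int, b_total: int
) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a 2x2 hit table.

    Compares two embedders' top-5 counts: rows are methods, columns are
    hit/miss.  Printed group statistics like chi2(1, N=1640) = 223 follow
    this uncorrected form.
    """
    if a_total <= 0 or b_total <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= a_hits <= a_total and 0 <= b_hits <= b_total):
        raise ValueError("hits must lie in [0, total]")
    table = np.array(
        [[a_hits, a_total - a_hits], [b_hits, b_total - b_hits]], dtype=float
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell")
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(scipy.stats.chi2.sf(stat, df=1))
    return ChiSquareResult(statistic=stat, dof=1, p_value=p, table=table.astype(int))


def shuffled_pairing_null(
    ens: EmbeddingEnsemble,
    c: Connectome,
    n_shuffles: int = 1000,
    seed: int = 0,
    direction: str = "r2l",
    exclude_operands: bool = True,
) -> np.ndarray:
    """Chance distribution of the top-5 proportion under shuffled pairing.

    Repeatedly permutes which target-hemisphere node each source-hemisphere
    node is declared homotopic to, re-runs the analogies test against the
    shuffled pairing, and records the top-5 proportion.  The observed
    proportion under the true pairing is compared with this null.
    """
    pairs = homotopic_pairs(c)
    src_hemi = "right" if direction == "r2l" else "left"
    oriented = []
    for i, j in pairs:
        if c.hemisphere[i] == src_hemi:
            oriented.append((i, j))
        else:
            oriented.append((j, i))
    src = np.array([s for s, _ in oriented])
    tgt = np.array([t for _, t in oriented])
    rng = np.random.Generator(np.random.PCG64(seed))
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(tgt))
        tasks = []
        for a in range(len(src)):
            for b in range(a + 1, len(src)):
                tasks.append(
                    AnalogyTask(
                        src_a=src[a],
                        src_b=src[b],
                        tgt_b=tgt[perm[b]],
                        expected=tgt[perm[a]],
                    )
                )
        # shuffles occasionally make an operand coincide with the expected
        # node (fixed point of the permutation is fine; true collisions are
        # excluded by construction since src/tgt hemispheres are disjoint)
        rep = run_test(ens, c, tasks=tasks, exclude_operands=exclude_operands)
        out[s] = rep.top5_proportion
    return out
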