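"""Single-linkage protein clustering across identity/coverage thresholds.

Pairwise similarity comes from optimal local alignment (BLOSUM62,
affine gaps: a gap of length L costs open + (L-1) * extend; defaults
open 11 / extend 1). Tie-breaking is fully specified so results are
deterministic and reproducible by an independent dynamic-programming
oracle: the best cell is the first maximum in row-major order, and
traceback prefers diagonal-from-match, then diagonal-from-gap-in-b,
then diagonal-from-gap-in-a, and closes gaps as early as possible.
An edge exists at a grid cell when percent identity and the coverage of
*both* sequences meet the cell's thresholds; clusters are connected
components of the edge graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

_NEG = -1.0e9


@dataclass(frozen=True)
class AlignmentScoring:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # cost of a length-1 gap
    gap_extend: int = 1  # additional cost per extra gap position


@dataclass(frozen=True)
class PairwiseSimilarity:
    id_a: str
    id_b: str
    identity: float  # percent, matches / aligned columns
    coverage_a: float  # fraction of a's residues inside the alignment
    coverage_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be within [0, 100]")


@dataclass(frozen=True)
class ClusterGridCell:
    identity_threshold: float
    coverage_threshold: float
    n_clusters_ge2: int
    n_seqs_clustered: int
    max_cluster_size: int


_MATRICES: dict[str, tuple[np.ndarray, dict[str, int]]] = {}


def _load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    if name not in _MATRICES:
        m = substitution_matrices.load(name)
        alphabet = str(m.alphabet)
        _MATRICES[name] = (
            np.asarray(m, dtype=np.float64),
            {aa: i for i, aa in enumerate(alphabet)},
        )
    return _MATRICES[name]


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    x = index["X"]
    return np.array([index.get(aa, x) for aa in seq.upper()], dtype=np.intp)


def _affine_local(
    a: str, b: str, scoring: AlignmentScoring
) -> tuple[float, float, float, float]:
    """(score, identity%, coverage_a, coverage_b) of the optimal local
    alignment under the documented tie-breaking."""
    sm, index = _load_matrix(scoring.matrix_name)
    ea, eb = _encode(a, index), _encode(b, index)
    n, m = len(ea), len(eb)
    open_, ext = float(scoring.gap_open), float(scoring.gap_extend)

    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b)
    j_ext = np.arange(m + 1) * ext
    for i in range(1, n + 1):
        s_row = sm[ea[i - 1]][eb]
        diag = np.maximum(np.maximum(M[i - 1, :m], X[i - 1, :m]),
                          Y[i - 1, :m])
        M[i, 1:] = np.maximum(0.0, diag + s_row)
        X[i, :] = np.maximum(M[i - 1, :] - open_, X[i - 1, :] - ext)
        # Y recurrence scans left-to-right within the row
        z = np.empty(m + 1)
        z[0] = _NEG
        z[1:] = M[i, :m] - open_ + j_ext[1:]
        np.maximum.accumulate(z, out=z)
        Y[i, :] = z - j_ext
        Y[i, 0] = _NEG

    best_flat = int(np.argmax(M))  # first maximum, row-major
    best = float(M.flat[best_flat])
    if best <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    i, j = divmod(best_flat, m + 1)

    state = "M"
    cols = matches = used_a = used_b = 0
    while not (state == "M" and M[i, j] <= 0.0):
        if state == "M":
            cols += 1
            used_a += 1
            used_b += 1
            if a[i - 1].upper() == b[j - 1].upper():
                matches += 1
            prev = M[i, j] - sm[ea[i - 1], eb[j - 1]]
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == X[i - 1, j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cols += 1
            used_a += 1
            state = "M" if X[i, j] == M[i - 1, j] - open_ else "X"
            i -= 1
        else:
            cols += 1
            used_b += 1
            state = "M" if Y[i, j] == M[i, j - 1] - open_ else "Y"
            j -= 1
    identity = 100.0 * matches / cols
    return best, identity, used_a / n, used_b / m


def pairwise_similarity(
    id_a: str,
    seq_a: str,
    id_b: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
) -> PairwiseSimilarity:
    """Identity and bilateral coverage of the optimal local alignment.

    The pair is canonically ordered (by length, then sequence) before
    aligning, so the result is symmetric in its arguments. Pairs with no
    positive-scoring alignment report identity 0 and coverage 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or AlignmentScoring()
    if (len(seq_a), seq_a) <= (len(seq_b), seq_b):
        _, ident, cov_a, cov_b = _affine_local(seq_a, seq_b, scoring)
    else:
        _, ident, cov_b, cov_a = _affine_local(seq_b, seq_a, scoring)
    return PairwiseSimilarity(id_a, id_b, ident, cov_a, cov_b)


def all_pairwise(
    proteins: Mapping[str, str],
    scoring: AlignmentScoring | None = None,
) -> list[PairwiseSimilarity]:
    """Similarities for every unordered id pair, in sorted-id order."""
    ids = sorted(proteins)
    return [
        pairwise_similarity(a, proteins[a], b, proteins[b], scoring)
        for a, b in itertools.combinations(ids, 2)
    ]


def cluster_at(
    ids: Sequence[str],
    similarities: Sequence[PairwiseSimilarity],
    min_identity: float,
    min_coverage: float,
) -> list[set[str]]:
    """Connected components under the identity/coverage edge rule.

    ``min_coverage`` is a percentage; it must hold for both sequences.
    Singletons appear as their own clusters.
    """
    index = {tid: i for i, tid in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cov = min_coverage / 100.0
    for sim in similarities:
        if (
            sim.identity >= min_identity
            and sim.coverage_a >= cov
            and sim.coverage_b >= cov
        ):
            ra, rb = find(index[sim.id_a]), find(index[sim.id_b])
            if ra != rb:
                parent[rb] = ra
    comps: dict[int, set[str]] = {}
    for tid, i in index.items():
        comps.setdefault(find(i), set()).add(tid)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


DEFAULT_GRID = tuple(range(30, 100, 5))  # 30..95 step 5


def sweep(
    proteins: Mapping[str, str],
    identity_grid: Sequence[float] = DEFAULT_GRID,
    coverage_grid: Sequence[float] = DEFAULT_GRID,
    scoring: AlignmentScoring | None = None,
    similarities: Sequence[PairwiseSimilarity] | None = None,
) -> list[ClusterGridCell]:
    """Cluster at every (identity, coverage) grid point.

    Similarities are computed once and thresholded per cell; pass
    ``similarities`` to reuse a precomputed set.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to sweep")
    ids = sorted(proteins)
    if similarities is None:
        similarities = all_pairwise(proteins, scoring)
    cells = []
    for ident in identity_grid:
        for cov in coverage_grid:
            clusters = cluster_at(ids, similarities, ident, cov)
            multi = [c for c in clusters if len(c) >= 2]
            cells.append(
                ClusterGridCell(
                    identity_threshold=float(ident),
                    coverage_threshold=float(cov),
                    n_clusters_ge2=len(multi),
                    n_seqs_clustered=sum(len(c) for c in multi),
                    max_cluster_size=max((len(c) for c in clusters), default=0),
                )
            )
    return cells
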