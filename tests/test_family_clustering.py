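"""Tests for pairwise similarity and the clustering sweep.

The pairwise route is checked against an independent pure-Python
affine-gap Smith-Waterman (gap of length L costs open + (L-1) * extend,
matching the implementation's scoring convention).
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from venomexome.family_clustering import (
    DEFAULT_GRID,
    AlignmentScoring,
    PairwiseSimilarity,
    all_pairwise,
    cluster_at,
    pairwise_similarity,
    sweep,
)
from venomexome.redundancy import collapse
from venomexome.synthetic_data import SyntheticConfig, generate_bundle

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {aa: i for i, aa in enumerate(str(_BLOSUM62.alphabet))}


def _score(x, y):
    return int(_BLOSUM62[_B62_INDEX[x], _B62_INDEX[y]])


def oracle_smith_waterman(a, b, gap_open=11, gap_extend=1):
    """Quadratic-time affine local alignment (gap of length L costs
    open + (L-1) * extend) with plain-loop traceback under the
    documented tie-breaking; returns
    (score, identity_pct, coverage_a, coverage_b)."""
    # canonical pair ordering, mirroring the symmetric contract
    if (len(a), a) > (len(b), b):
        score, ident, cov_b, cov_a = oracle_smith_waterman(
            b, a, gap_open, gap_extend
        )
        return score, ident, cov_a, cov_b
    n, m = len(a), len(b)
    NEG = -10**9
    M = [[0] * (m + 1) for _ in range(n + 1)]   # match state
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    best, best_pos = 0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            s = _score(a[i - 1], b[j - 1])
            M[i][j] = max(0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s)
            if M[i][j] > best:  # strict: first maximum in row-major order
                best, best_pos = M[i][j], (i, j)
    if best <= 0:
        return 0, 0.0, 0.0, 0.0
    i, j = best_pos
    state = "M"
    cols = matches = used_a = used_b = 0
    while not (state == "M" and M[i][j] <= 0):
        if state == "M":
            cols += 1
            used_a += 1
            used_b += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = M[i][j] - _score(a[i - 1], b[j - 1])
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cols += 1
            used_a += 1
            state = "M" if X[i][j] == M[i - 1][j] - gap_open else "X"
            i -= 1
        else:
            cols += 1
            used_b += 1
            state = "M" if Y[i][j] == M[i][j - 1] - gap_open else "Y"
            j -= 1
    return best, 100.0 * matches / cols, used_a / n, used_b / m


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        sim = pairwise_similarity("a", "MKVLLAQRST", "b", "MKVLLAQRST")
        assert sim.identity == 100.0
        assert sim.coverage_a == 1.0 and sim.coverage_b == 1.0

    def test_disjoint_alphabets(self):
        sim = pairwise_similarity("a", "KKKKKKKK", "b", "DDDDDDDD")
        assert sim.identity == 0.0
        assert sim.coverage_a == 0.0 and sim.coverage_b == 0.0

    def test_substring(self):
        sim = pairwise_similarity("a", "KVLLA", "b", "MMKVLLAQQ")
        assert sim.identity == 100.0
        assert sim.coverage_a == 1.0
        assert sim.coverage_b == pytest.approx(5 / 9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_similarity("a", "", "b", "MKV")

    def test_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
            ab = pairwise_similarity("a", a, "b", b)
            ba = pairwise_similarity("b", b, "a", a)
            assert ab.identity == pytest.approx(ba.identity)
            assert ab.coverage_a == pytest.approx(ba.coverage_b)
            assert ab.coverage_b == pytest.approx(ba.coverage_a)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            a = "".join(rng.choice(aas, size=60))
            b = "".join(rng.choice(aas, size=60))
            # plant a shared block in half the cases
            if rng.random() < 0.5:
                block = "".join(rng.choice(aas, size=25))
                a = a[:20] + block + a[45:]
                b = b[:10] + block + b[35:]
            score, ident, cov_a, cov_b = oracle_smith_waterman(a, b)
            sim = pairwise_similarity("a", a, "b", b)
            if score <= 0:
                assert sim.identity == 0.0
            else:
                assert sim.identity == pytest.approx(ident)
                assert sim.coverage_a == pytest.approx(cov_a)
                assert sim.coverage_b == pytest.approx(cov_b)


class TestClusterAt:
    def sims(self, edges):
        return [
            PairwiseSimilarity(a, b, ident, cov / 100, cov / 100)
            for a, b, ident, cov in edges
        ]

    def test_single_linkage_transitivity(self):
        sims = self.sims(
            [("A", "B", 90, 90), ("B", "C", 90, 90), ("A", "C", 10, 10)]
        )
        clusters = cluster_at(["A", "B", "C"], sims, 50, 50)
        assert {"A", "B", "C"} in clusters

    def test_no_edges_all_singletons(self):
        clusters = cluster_at(["A", "B"], [], 30, 30)
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_coverage_must_hold_for_both(self):
        sims = [PairwiseSimilarity("A", "B", 100.0, 1.0, 0.2)]
        assert {"A", "B"} not in cluster_at(["A", "B"], sims, 95, 95)
        assert {"A", "B"} in cluster_at(["A", "B"], sims, 95, 15)

    def test_exact_duplicates_match_redundancy_components(self, rng):
        prots = {}
        for i in range(10):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
            prots[f"p{i}a"] = seq
            prots[f"p{i}b"] = seq
        sims = all_pairwise(prots)
        clusters = cluster_at(sorted(prots), sims, 100, 100)
        _, red_clusters = collapse(prots)
        red_sets = sorted(
            [sorted(c.members) for c in red_clusters if len(c.members) > 1]
        )
        clu_sets = sorted([sorted(c) for c in clusters if len(c) > 1])
        assert clu_sets == red_sets


class TestSweep:
    @pytest.fixture(scope="class")
    @staticmethod
    def family_bundle():
        # one short knottin-like family plus long-protein families: short
        # proteins from different families share only their hydrophobic
        # signal segments, which cannot reach 30% coverage of a long one
        cfg = SyntheticConfig(
            seed=3, n_background=0, n_silk_specific=0, n_venom_families=5,
            family_size_range=(3, 4), ick_fraction=0.2,
        )
        return generate_bundle(cfg)

    def test_identical_sequences_one_cluster(self):
        prots = {f"p{i}": "MKVLLAQRSTMKVLLAQRST" for i in range(4)}
        for cell in sweep(prots, (30, 95), (30, 95)):
            assert cell.n_clusters_ge2 == 1
            assert cell.n_seqs_clustered == 4
            assert cell.max_cluster_size == 4

    def test_needs_two_proteins(self):
        with pytest.raises(ValueError):
            sweep({"a": "MKV"})

    def test_monotone_under_relaxation(self, family_bundle):
        prots = dict(
            zip(family_bundle.truth["transcript_id"],
                family_bundle.truth["protein_seq"])
        )
        cells = {
            (c.identity_threshold, c.coverage_threshold): c
            for c in sweep(prots)
        }
        grid = sorted({k[0] for k in cells})
        for gi in grid:
            for gc in grid:
                cell = cells[(gi, gc)]
                for oi, oc in ((gi + 5, gc), (gi, gc + 5)):
                    if (oi, oc) in cells:
                        stricter = cells[(oi, oc)]
                        assert cell.n_seqs_clustered >= stricter.n_seqs_clustered
                        assert cell.max_cluster_size >= stricter.max_cluster_size

    def test_planted_families_recovered_at_permissive_threshold(
        self, family_bundle
    ):
        truth = family_bundle.truth
        prots = dict(zip(truth["transcript_id"], truth["protein_seq"]))
        sims = all_pairwise(prots)
        clusters = cluster_at(sorted(prots), sims, 30, 30)
        truth_fams = {
            fam: set(grp["transcript_id"])
            for fam, grp in truth.groupby("family_id")
        }
        assert sorted(map(sorted, clusters)) == sorted(
            map(sorted, truth_fams.values())
        )

    def test_families_fragment_at_95(self, family_bundle):
        truth = family_bundle.truth
        prots = dict(zip(truth["transcript_id"], truth["protein_seq"]))
        sims = all_pairwise(prots)
        strict = cluster_at(sorted(prots), sims, 95, 95)
        permissive = cluster_at(sorted(prots), sims, 30, 30)
        assert len(strict) > len(permissive)
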