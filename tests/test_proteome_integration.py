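"""Tests for peptide mapping, evidence filtering and the secretome."""

import numpy as np
import pandas as pd
import pytest

from venomexome.proteome_integration import (
    PeptidePlacement,
    canonicalize_il,
    classify_secretome,
    coverage,
    filter_evidence,
    map_peptides,
)
from venomexome.synthetic_data import (
    SyntheticConfig,
    generate_bundle,
    generate_peptide_ids,
    tryptic_digest,
)


def pep_table(rows):
    return pd.DataFrame(rows,
                        columns=["peptide_seq", "peptide_prob", "protein_prob"])


class TestMapPeptides:
    def test_simple_placement(self):
        pls = map_peptides(["AAK"], {"p1": "MAAKQ"})
        assert len(pls) == 1
        assert (pls[0].start, pls[0].end) == (1, 4)
        assert not pls[0].il_equivalent

    def test_il_equivalence(self):
        pls = map_peptides(["PILK"], {"p1": "QQPLLKQQ"})
        assert len(pls) == 1
        assert pls[0].il_equivalent

    def test_il_can_be_disabled(self):
        assert map_peptides(["PILK"], {"p1": "QQPLLKQQ"},
                            il_equivalent=False) == []

    def test_all_occurrences_reported(self):
        pls = map_peptides(["AB".replace("B", "K")], {"p1": "AKQAKQAK"})
        assert [(p.start, p.end) for p in pls] == [(0, 2), (3, 5), (6, 8)]

    def test_empty_peptide_raises(self):
        with pytest.raises(ValueError):
            map_peptides([""], {"p1": "MKV"})

    def test_matches_brute_force_oracle(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        prots = {
            f"p{i}": "".join(rng.choice(aas, size=60)) for i in range(10)
        }
        peptides = ["".join(rng.choice(aas, size=4)) for _ in range(50)]
        pls = map_peptides(peptides, prots)
        got = {(p.peptide_seq, p.protein_id, p.start) for p in pls}
        expected = set()
        for pep in set(peptides):
            cp = canonicalize_il(pep)
            for pid, seq in prots.items():
                cs = canonicalize_il(seq)
                for i in range(len(cs) - len(cp) + 1):
                    if cs[i: i + len(cp)] == cp:
                        expected.add((pep, pid, i))
        assert got == expected


class TestCoverage:
    def test_hand_union(self):
        pls = [PeptidePlacement("x", "p", 0, 5, False),
               PeptidePlacement("y", "p", 3, 8, False)]
        assert coverage("A" * 10, pls) == pytest.approx(80.0)

    def test_no_placements(self):
        assert coverage("A" * 10, []) == 0.0

    def test_full_protein(self):
        pls = [PeptidePlacement("x", "p", 0, 10, False)]
        assert coverage("A" * 10, pls) == 100.0

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            coverage("AAA", [PeptidePlacement("x", "p", 0, 5, False)])

    def test_matches_interval_union_oracle(self, rng):
        length = 100
        for _ in range(50):
            n = int(rng.integers(1, 12))
            pls = []
            for _ in range(n):
                s = int(rng.integers(0, length - 5))
                e = s + int(rng.integers(3, 20))
                pls.append(PeptidePlacement("x", "p", s, min(e, length), False))
            mask = np.zeros(length, bool)
            for p in pls:
                mask[p.start: p.end] = True
            assert coverage("A" * length, pls) == pytest.approx(
                100.0 * mask.sum() / length
            )

    def test_monotone_in_placements(self, rng):
        pls = []
        prev = 0.0
        for s in range(0, 90, 10):
            pls.append(PeptidePlacement("x", "p", s, s + 15, False))
            cur = coverage("A" * 100, pls)
            assert cur >= prev
            prev = cur


class TestFilterEvidence:
    def test_one_unique_peptide_not_confirmed(self):
        prots = {"p1": "MAAAKVVVK"}
        pls = map_peptides(["AAAK".replace("B", "")], prots)
        table = pep_table([("AAAK", 0.99, 0.99)])
        ev = filter_evidence(pls, table, prots)
        assert not ev[0].venom_confirmed
        assert ev[0].n_unique_peptides == 1

    def test_low_protein_prob_not_confirmed(self):
        prots = {"p1": "AAAKVVVKCCCK"}
        pls = map_peptides(["AAAK", "VVVK", "CCCK"], prots)
        table = pep_table([("AAAK", 0.99, 0.90), ("VVVK", 0.99, 0.90),
                           ("CCCK", 0.99, 0.90)])
        ev = filter_evidence(pls, table, prots)
        assert ev[0].n_unique_peptides == 3
        assert not ev[0].venom_confirmed

    def test_confirmed_protein(self):
        prots = {"p1": "AAAKVVVK"}
        pls = map_peptides(["AAAK", "VVVK"], prots)
        table = pep_table([("AAAK", 0.99, 0.99), ("VVVK", 0.99, 0.99)])
        ev = filter_evidence(pls, table, prots)
        assert ev[0].venom_confirmed
        assert ev[0].percent_coverage == 100.0

    def test_low_prob_peptides_discarded(self):
        prots = {"p1": "AAAKVVVK"}
        pls = map_peptides(["AAAK", "VVVK"], prots)
        table = pep_table([("AAAK", 0.3, 0.99), ("VVVK", 0.99, 0.99)])
        ev = filter_evidence(pls, table, prots)
        assert ev[0].n_unique_peptides == 1

    def test_il_variants_count_as_one_unique(self):
        prots = {"p1": "PILKPLLK"}
        pls = map_peptides(["PILK", "PLLK"], prots)
        table = pep_table([("PILK", 0.99, 0.99), ("PLLK", 0.99, 0.99)])
        ev = filter_evidence(pls, table, prots)
        assert ev[0].n_unique_peptides == 1

    def test_order_invariance(self):
        prots = {"p1": "AAAKVVVKWWWK"}
        peps = ["AAAK", "VVVK", "WWWK"]
        rows = [(p, 0.99, 0.99) for p in peps]
        ev1 = filter_evidence(map_peptides(peps, prots),
                              pep_table(rows), prots)
        ev2 = filter_evidence(map_peptides(peps[::-1], prots),
                              pep_table(rows[::-1]), prots)
        assert ev1 == ev2

    def test_removing_peptides_drops_confirmation(self):
        prots = {"p1": "AAAKVVVK"}
        table = pep_table([("AAAK", 0.99, 0.99), ("VVVK", 0.99, 0.99)])
        ev = filter_evidence(map_peptides(["AAAK", "VVVK"], prots),
                             table, prots)
        assert ev[0].venom_confirmed
        ev2 = filter_evidence(map_peptides(["AAAK"], prots),
                              pep_table([("AAAK", 0.99, 0.99)]), prots)
        assert not ev2 or not ev2[0].venom_confirmed

    def test_truth_recovery_with_full_detection(self):
        cfg = SyntheticConfig(seed=1, detect_prob=1.0)
        b = generate_bundle(cfg)
        peptides = generate_peptide_ids(b.truth, cfg)
        truth = b.truth.set_index("transcript_id")
        prots = dict(zip(truth.index, truth["protein_seq"]))
        high = peptides[peptides["peptide_prob"] > 0.95]
        pls = map_peptides(high["peptide_seq"].astype(str), prots)
        ev = filter_evidence(pls, peptides, prots)
        confirmed = {e.protein_id for e in ev if e.venom_confirmed}
        expected = {
            t for t in truth.index[truth["secreted"]]
            if len({canonicalize_il(f)
                    for f in tryptic_digest(truth.loc[t, "protein_seq"])}) >= 2
        }
        assert confirmed == expected


class TestClassifySecretome:
    def _ev(self, pid, confirmed=True):
        return filter_evidence(
            map_peptides(["AAAK", "VVVK"], {pid: "AAAKVVVK"}),
            pep_table([("AAAK", 0.99, 0.99 if confirmed else 0.5),
                       ("VVVK", 0.99, 0.99 if confirmed else 0.5)]),
            {pid: "AAAKVVVK"},
        )

    def test_cell_assignment(self):
        ev = self._ev("p1")
        out = classify_secretome(ev, signal_ids={"p1"}, vst_ids={"p1"})
        cell = out[(out["vst_status"] == "vst")
                   & (out["signal_status"] == "signal")]
        assert int(cell["n"].iloc[0]) == 1
        assert out["n"].sum() == 1

    def test_empty_confirmed_set(self):
        out = classify_secretome([], signal_ids=set(), vst_ids=set())
        assert out["n"].sum() == 0
        assert (out["pct"] == 0).all()

    def test_unclassified_protein_warns(self):
        ev = self._ev("p1")
        with pytest.warns(UserWarning, match="absent"):
            classify_secretome(ev, set(), set(), classified_ids=set())

    def test_truth_cross_tab(self):
        cfg = SyntheticConfig(seed=2, detect_prob=1.0)
        b = generate_bundle(cfg)
        peptides = generate_peptide_ids(b.truth, cfg)
        truth = b.truth.set_index("transcript_id")
        prots = dict(zip(truth.index, truth["protein_seq"]))
        high = peptides[peptides["peptide_prob"] > 0.95]
        ev = filter_evidence(
            map_peptides(high["peptide_seq"].astype(str), prots),
            peptides, prots,
        )
        confirmed = {e.protein_id for e in ev if e.venom_confirmed}
        signal_ids = set(truth.index[truth["secreted"]])
        vst_ids = set(truth.index[truth["label"] == "venom-specific"])
        out = classify_secretome(ev, signal_ids, vst_ids).set_index(
            ["vst_status", "signal_status"]
        )
        expected = {
            ("vst", "signal"): len(confirmed & vst_ids & signal_ids),
            ("vst", "no_signal"): len((confirmed & vst_ids) - signal_ids),
            ("non_vst", "signal"): len((confirmed - vst_ids) & signal_ids),
            ("non_vst", "no_signal"): len(confirmed - vst_ids - signal_ids),
        }
        for cell, n in expected.items():
            assert int(out.loc[cell, "n"]) == n
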