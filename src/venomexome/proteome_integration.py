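"""Map venom peptide identifications onto predicted proteins.

Peptides place at every occurrence in every protein (I and L are
interchangeable by default, being isobaric); proteins are
venom-confirmed when their protein probability exceeds the floor and at
least two distinct (I/L-canonicalized) peptides map to them. Coverage
is the unioned fraction of residues touched by placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

_IL_CANON = str.maketrans("L", "I")


def canonicalize_il(seq: str) -> str:
    """Collapse I/L (mass-indistinguishable) to a single symbol."""
    return seq.translate(_IL_CANON)


@dataclass(frozen=True)
class PeptidePlacement:
    peptide_seq: str
    protein_id: str
    start: int  # 0-based half-open residue coordinates
    end: int
    il_equivalent: bool  # matched only under I/L equivalence


@dataclass(frozen=True)
class ProteomeEvidence:
    protein_id: str
    n_unique_peptides: int
    percent_coverage: float
    max_protein_prob: float
    venom_confirmed: bool
    secreted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_coverage <= 100.0):
            raise ValueError("coverage must be within [0, 100]")


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def map_peptides(
    peptides: Iterable[str],
    proteins: Mapping[str, str],
    il_equivalent: bool = True,
) -> list[PeptidePlacement]:
    """All occurrences of each peptide in each protein."""
    placements: list[PeptidePlacement] = []
    canon_proteins = {
        pid: canonicalize_il(seq) if il_equivalent else seq
        for pid, seq in proteins.items()
    }
    seen: set[str] = set()
    for pep in peptides:
        if not pep:
            raise ValueError("peptide sequences must be non-empty")
        if pep in seen:
            continue
        seen.add(pep)
        query = canonicalize_il(pep) if il_equivalent else pep
        for pid in sorted(proteins):
            target = canon_proteins[pid]
            raw = proteins[pid]
            for i in _find_all(target, query):
                exact = raw[i: i + len(pep)] == pep
                placements.append(
                    PeptidePlacement(
                        peptide_seq=pep,
                        protein_id=pid,
                        start=i,
                        end=i + len(pep),
                        il_equivalent=not exact,
                    )
                )
    return placements


def coverage(protein_seq: str, placements: Sequence[PeptidePlacement]) -> float:
    """Percent of residues covered by the union of placement intervals."""
    length = len(protein_seq)
    intervals = sorted((p.start, p.end) for p in placements)
    covered = 0
    cur_start, cur_end = None, None
    for s, e in intervals:
        if s < 0 or e > length:
            raise ValueError(f"placement [{s},{e}) outside protein of "
                             f"length {length}")
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return 100.0 * covered / length


def filter_evidence(
    placements: Sequence[PeptidePlacement],
    peptide_table: pd.DataFrame,
    proteins: Mapping[str, str],
    min_prob: float = 0.95,
    min_unique: int = 2,
) -> list[ProteomeEvidence]:
    """Per-protein evidence after probability and unique-peptide filters.

    ``peptide_table`` columns: peptide_seq, peptide_prob, protein_prob
    (per-identification probabilities as given by the search engine).
    Peptides with probability <= ``min_prob`` are discarded; a protein
    is venom-confirmed when its best protein probability exceeds
    ``min_prob`` and >= ``min_unique`` distinct (I/L-canonical) peptides
    place on it. Output sorted by protein id.
    """
    pep_prob: dict[str, float] = {}
    prot_prob_of_pep: dict[str, float] = {}
    for row in peptide_table.itertuples(index=False):
        seq = str(row.peptide_seq)
        pep_prob[seq] = max(pep_prob.get(seq, 0.0), float(row.peptide_prob))
        prot_prob_of_pep[seq] = max(
            prot_prob_of_pep.get(seq, 0.0), float(row.protein_prob)
        )

    by_protein: dict[str, list[PeptidePlacement]] = {}
    for pl in placements:
        if pep_prob.get(pl.peptide_seq, 0.0) <= min_prob:
            continue
        by_protein.setdefault(pl.protein_id, []).append(pl)

    out: list[ProteomeEvidence] = []
    for pid in sorted(by_protein):
        pls = by_protein[pid]
        uniq = {canonicalize_il(pl.peptide_seq) for pl in pls}
        max_prot = max(prot_prob_of_pep[pl.peptide_seq] for pl in pls)
        out.append(
            ProteomeEvidence(
                protein_id=pid,
                n_unique_peptides=len(uniq),
                percent_coverage=coverage(proteins[pid], pls),
                max_protein_prob=max_prot,
                venom_confirmed=(
                    max_prot > min_prob and len(uniq) >= min_unique
                ),
            )
        )
    return out


def classify_secretome(
    evidence: Sequence[ProteomeEvidence],
    signal_ids: set[str],
    vst_ids: set[str],
    classified_ids: set[str] | None = None,
) -> pd.DataFrame:
    """2x2 cross-tab of venom-confirmed proteins by VST membership and
    signal-peptide annotation (counts plus percentages of confirmed).

    ``classified_ids`` is the full set of ids that went through
    specificity classification; confirmed proteins outside it are
    counted as non-VST with a warning.
    """
    import warnings

    rows = {
        ("vst", "signal"): 0,
        ("vst", "no_signal"): 0,
        ("non_vst", "signal"): 0,
        ("non_vst", "no_signal"): 0,
    }
    confirmed = [e for e in evidence if e.venom_confirmed]
    for e in confirmed:
        if classified_ids is not None and e.protein_id not in classified_ids:
            warnings.warn(
                f"confirmed protein {e.protein_id} absent from VST "
                "classification; counted as non-VST",
                stacklevel=2,
            )
        vst = "vst" if e.protein_id in vst_ids else "non_vst"
        sig = "signal" if e.protein_id in signal_ids else "no_signal"
        rows[(vst, sig)] += 1
    total = len(confirmed)
    table = pd.DataFrame(
        [
            {"vst_status": v, "signal_status": s, "n": n,
             "pct": (100.0 * n / total) if total else 0.0}
            for (v, s), n in rows.items()
        ]
    )
    return table
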