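"""Six-frame ORF enumeration and best-protein selection.

ORFs are maximal stop-free stretches of codons within each of the six
reading frames (stop-to-stop), reported on forward-strand 0-based
half-open nucleotide coordinates. A "best protein" per transcript is
chosen by preferring the frame of the transcript's best homology hit,
falling back to the longest ORF overall, with an override in favour of
a methionine-initiated ORF when it is stop-bounded on both sides and
long enough relative to the longest ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)

_STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table() -> dict:
    # standard genetic code via biopython, stops kept as '*'
    table = {}
    bases = "ACGT"
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                table[codon] = str(Seq(codon).translate())
    return table


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N (or other ambiguity)
    yields 'X' and never a stop."""
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        return "X"
    return aa


@dataclass(frozen=True)
class OpenReadingFrame:
    """A maximal stop-free translated stretch in one reading frame.

    Coordinates are 0-based half-open on the forward strand; for reverse
    frames ``nt_start`` still refers to the forward strand (frame -1 begins
    at the last base of the sequence).
    """

    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str
    has_internal_mstart: bool
    bounded_5p: bool
    bounded_3p: bool

    def __post_init__(self) -> None:
        if "*" in self.aa_seq:
            raise ValueError("ORF translation contains a stop symbol")
        if self.nt_end - self.nt_start != 3 * len(self.aa_seq):
            raise ValueError("ORF nucleotide span inconsistent with aa length")


@dataclass(frozen=True)
class ProteinPrediction:
    """The selected best protein for a transcript."""

    transcript_id: str
    aa_seq: str
    frame: int
    is_mstart: bool
    rule: str  # frame-of-best-hit | longest-overall | mstart-override

    def __post_init__(self) -> None:
        if self.rule == "mstart-override" and not self.is_mstart:
            raise ValueError("mstart-override prediction must start with M")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _frame_runs(frame_seq: str, frame: int, seq_len: int, min_len: int):
    """Yield ORFs for one frame. ``frame_seq`` is the frame's reading
    sequence (already reverse-complemented for negative frames)."""
    offset = abs(frame) - 1
    n_codons = (len(frame_seq) - offset) // 3
    run_start = None  # codon index of current stop-free run
    aas: list[str] = []
    preceded_by_stop = False

    def emit(start_codon: int, end_codon: int, aa: str, followed_by_stop: bool,
             run_preceded: bool):
        nt_len = 3 * len(aa)
        if nt_len < min_len or nt_len == 0:
            return None
        # coordinates in the reading orientation
        r_start = offset + 3 * start_codon
        r_end = offset + 3 * end_codon
        if frame > 0:
            nt_start, nt_end = r_start, r_end
        else:
            nt_start, nt_end = seq_len - r_end, seq_len - r_start
        return OpenReadingFrame(
            frame=frame,
            nt_start=nt_start,
            nt_end=nt_end,
            aa_seq=aa,
            has_internal_mstart="M" in aa[1:],
            bounded_5p=run_preceded,
            bounded_3p=followed_by_stop,
        )

    orfs = []
    run_preceded = False
    for ci in range(n_codons):
        codon = frame_seq[offset + 3 * ci: offset + 3 * ci + 3]
        aa = translate_codon(codon)
        if aa == "*":
            if run_start is not None:
                orf = emit(run_start, ci, "".join(aas), True, run_preceded)
                if orf is not None:
                    orfs.append(orf)
                run_start = None
                aas = []
            run_preceded = True
        else:
            if run_start is None:
                run_start = ci
            aas.append(aa)
    if run_start is not None:
        orf = emit(run_start, n_codons, "".join(aas), False, run_preceded)
        if orf is not None:
            orfs.append(orf)
    return orfs


def six_frame_orfs(nt_seq: str, min_len: int = 90) -> list[OpenReadingFrame]:
    """Enumerate stop-to-stop ORFs of nucleotide length >= ``min_len``
    in all six frames.

    Codons containing ambiguous bases translate to X and never
    terminate an ORF. Results are sorted by frame order
    (+1,+2,+3,-1,-2,-3) then by start position in reading orientation.
    """
    if min_len % 3 != 0:
        raise ValueError("min_len must be a multiple of 3")
    seq = nt_seq.upper()
    if not seq:
        return []
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    rc = _revcomp(seq)
    out: list[OpenReadingFrame] = []
    for frame in FRAMES:
        frame_seq = seq if frame > 0 else rc
        out.extend(_frame_runs(frame_seq, frame, len(seq), min_len))
    return out


def _tie_key(orf: OpenReadingFrame):
    # longer first; ties by frame order +1,+2,+3,-1,-2,-3 then smaller start
    return (-len(orf.aa_seq), FRAMES.index(orf.frame), orf.nt_start)


def mstart_subsequence(orf: OpenReadingFrame) -> str | None:
    """Sequence from the first M of the ORF to its end, or None."""
    idx = orf.aa_seq.find("M")
    if idx < 0:
        return None
    return orf.aa_seq[idx:]


def select_best_protein(
    orfs: Sequence[OpenReadingFrame],
    transcript_id: str = "",
    best_hit_frame: int | None = None,
    mstart_ratio: float = 0.75,
) -> ProteinPrediction:
    """Apply the best-protein selection rule.

    Candidate = longest ORF in ``best_hit_frame`` when that frame has
    ORFs, otherwise the longest ORF overall. If some ORF that is
    stop-bounded on both sides carries an M-start subsequence of length
    >= ``mstart_ratio`` x the longest ORF's length, the longest such
    M-start sequence wins instead (rule "mstart-override").
    """
    if not orfs:
        raise ValueError(f"no ORFs to select from for {transcript_id!r}")
    ranked = sorted(orfs, key=_tie_key)
    longest_len = len(ranked[0].aa_seq)

    if best_hit_frame is not None:
        in_frame = [o for o in ranked if o.frame == best_hit_frame]
        if in_frame:
            candidate, rule = in_frame[0], "frame-of-best-hit"
        else:
            candidate, rule = ranked[0], "longest-overall"
    else:
        candidate, rule = ranked[0], "longest-overall"

    best_m: tuple[tuple, str, OpenReadingFrame] | None = None
    for orf in ranked:
        if not (orf.bounded_5p and orf.bounded_3p):
            continue
        sub = mstart_subsequence(orf)
        if sub is None or len(sub) < mstart_ratio * longest_len:
            continue
        key = (-len(sub), FRAMES.index(orf.frame), orf.nt_start)
        if best_m is None or key < best_m[0]:
            best_m = (key, sub, orf)
    if best_m is not None:
        _, sub, orf = best_m
        return ProteinPrediction(
            transcript_id=transcript_id,
            aa_seq=sub,
            frame=orf.frame,
            is_mstart=True,
            rule="mstart-override",
        )

    return ProteinPrediction(
        transcript_id=transcript_id,
        aa_seq=candidate.aa_seq,
        frame=candidate.frame,
        is_mstart=candidate.aa_seq.startswith("M"),
        rule=rule,
    )


def predict_proteins(
    transcripts: Mapping[str, str],
    best_hit_frames: Mapping[str, int] | None = None,
    min_len: int = 90,
    mstart_ratio: float = 0.75,
) -> dict[str, ProteinPrediction]:
    """Run ORF prediction + best-protein selection over many transcripts.

    Transcripts with no qualifying ORF are silently omitted.
    """
    best_hit_frames = best_hit_frames or {}
    out: dict[str, ProteinPrediction] = {}
    for tid, seq in transcripts.items():
        orfs = six_frame_orfs(seq, min_len=min_len)
        if not orfs:
            continue
        out[tid] = select_best_protein(
            orfs,
            transcript_id=tid,
            best_hit_frame=best_hit_frames.get(tid),
            mstart_ratio=mstart_ratio,
        )
    return out
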