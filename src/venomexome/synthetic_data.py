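"""Seeded synthetic three-tissue transcriptome bundles with known truth.

Generates transcript sequences (truth proteins encoded in frame +1
between UTRs), negative-binomial expected counts for venom / silk /
cephalothorax libraries, homology annotations, GO assignments,
signal-peptide calls, and in-silico tryptic peptide identifications.
Planted structure: venom-specific gene families (short 8-cysteine
signal-peptide knottin-like proteins and long ankyrin-repeat
latrotoxin-like proteins), silk-specific transcripts, and broadly
expressed background.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

LABEL_VENOM = "venom-specific"
LABEL_SILK = "silk-specific"
LABEL_BROAD = "broad"

# amino acids a truth protein may contain (no ambiguity codes)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_C = _AA.replace("C", "")
_HYDROPHOBIC = "AILVFWM"

_BACK_TO_CODONS: dict[str, list[str]] = {}


def _codon_choices(aa: str) -> list[str]:
    if not _BACK_TO_CODONS:
        table: dict[str, list[str]] = {}
        for codon, res in standard_dna_table.forward_table.items():
            table.setdefault(res, []).append(codon)
        for res in table:
            table[res] = sorted(table[res])
        _BACK_TO_CODONS.update(table)
    return _BACK_TO_CODONS[aa]


@dataclass(frozen=True)
class SyntheticConfig:
    n_background: int = 1500
    n_silk_specific: int = 80
    n_venom_families: int = 8
    family_size_range: tuple[int, int] = (2, 4)
    ick_fraction: float = 0.5
    venom_fold: float = 500.0
    nb_dispersion: float = 0.05
    library_sizes: tuple[int, int, int] = (1_000_000, 800_000, 1_200_000)
    detect_prob: float = 0.9
    decoy_fraction: float = 0.1
    min_peptide_len: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_silk_specific,
               self.n_venom_families) < 0:
            raise ValueError("transcript counts must be >= 0")
        if self.n_background + self.n_silk_specific + self.n_venom_families == 0:
            raise ValueError("zero transcripts requested")
        if not (0.0 <= self.ick_fraction <= 1.0):
            raise ValueError("ick_fraction must lie in [0, 1]")
        if self.venom_fold < 1.0:
            raise ValueError("venom_fold must be >= 1")
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ValueError("detect_prob must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValueError("family_size_range must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticBundle:
    """All generated tables plus the ground truth."""

    transcripts: dict[str, str]
    counts: pd.DataFrame  # transcript_id, venom, silk, ceph, effective_length_nt
    annotations: pd.DataFrame  # transcript_id, hit_description, evalue, hit_frame
    go_terms: pd.DataFrame  # transcript_id, go_id
    signal: pd.DataFrame  # protein_id, has_signal, cleavage_pos
    truth: pd.DataFrame  # per-transcript ground truth
    config: SyntheticConfig


def make_ick_protein(rng: np.random.Generator, length: int = 90) -> str:
    """A knottin-like protein: M + hydrophobic signal segment, then a
    mature region carrying exactly 8 cysteines whose spacing passes the
    default framework screen. Total length < 200 residues.
    """
    if length < 40:
        raise ValueError("length must be >= 40")
    if length >= 200:
        raise ValueError("knottin-like proteins must be < 200 residues")
    signal_len = 18  # incl. the initial M
    mature_len = length - signal_len
    # spacings between the 8 cysteines; index 2 is the near-adjacent pair
    lead_min = 1
    mins = (2, 2, 0, 1, 1, 1, 1)
    caps = (6, 6, 1, 8, 8, 8, 8)  # first two stay <= 16 by construction
    budget = mature_len - 8 - lead_min - sum(mins)
    if budget < 0:
        raise ValueError(
            f"length {length} too small to place 8 cysteines "
            f"(need >= {signal_len + 8 + lead_min + sum(mins)} residues)"
        )
    lead = lead_min + int(rng.integers(0, min(3, budget) + 1))
    budget -= lead - lead_min
    s = []
    for lo, hi in zip(mins, caps):
        extra = int(rng.integers(0, min(hi - lo, budget) + 1))
        s.append(lo + extra)
        budget -= extra
    signal = "M" + "".join(
        rng.choice(list(_HYDROPHOBIC), size=signal_len - 1)
    )
    mature = list(rng.choice(list(_AA_NO_C), size=mature_len))
    pos = lead
    cys_positions = [pos]
    for gap in s:
        pos += gap + 1
        cys_positions.append(pos)
    for p in cys_positions:
        mature[p] = "C"
    return signal + "".join(mature)


def _make_latrotoxin_like(rng: np.random.Generator) -> str:
    """A long ankyrin-repeat protein: conserved N-terminal block, a
    family-specific ~33-residue repeat array, and a C-terminal block."""
    nterm = "M" + "".join(rng.choice(list(_AA), size=int(rng.integers(120, 180))))
    motif = "".join(rng.choice(list(_AA), size=33))
    n_repeats = int(rng.integers(11, 21))
    repeats = []
    for _ in range(n_repeats):
        unit = list(motif)
        for i in range(len(unit)):
            if rng.random() < 0.10:
                unit[i] = str(rng.choice(list(_AA)))
        repeats.append("".join(unit))
    cterm = "".join(rng.choice(list(_AA), size=int(rng.integers(60, 120))))
    return nterm + "".join(repeats) + cterm


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            frozen: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < rate:
            out[i] = str(rng.choice(list(_AA_NO_C)))
    return "".join(out)


def _random_protein(rng: np.random.Generator, lo: int = 100,
                    hi: int = 400) -> str:
    n = int(rng.integers(lo, hi))
    return "M" + "".join(rng.choice(list(_AA), size=n - 1))


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """Uniform choice over synonymous codons, standard genetic code."""
    return "".join(
        _codon_choices(aa)[int(rng.integers(0, len(_codon_choices(aa))))]
        for aa in protein
    )


def _utr(rng: np.random.Generator, multiple_of_3: bool = False) -> str:
    n = int(rng.integers(30, 301))
    if multiple_of_3:
        n -= n % 3
    return "".join(rng.choice(list("ACGT"), size=n))


def _encode_transcript(rng: np.random.Generator, protein: str) -> str:
    """UTR5 (ending in an in-frame stop) + CDS + stop + UTR3, with the
    CDS in frame +1 so the stop-to-stop ORF starts exactly at the M."""
    utr5 = _utr(rng, multiple_of_3=True)
    utr5 = utr5[:-3] + "TAA" if len(utr5) >= 3 else "TAA"
    cds = reverse_translate(rng, protein)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return utr5 + cds + stop + _utr(rng)


_LATRO_DESCRIPTIONS = (
    "alpha-latrotoxin precursor",
    "delta-latroinsectotoxin",
    "alpha-latrocrustotoxin",
)
_ICK_DESCRIPTIONS = (
    "CSTX toxin",
    "omega-ctenitoxin",
    "inhibitor cystine knot toxin",
)
_SILK_DESCRIPTIONS = (
    "major ampullate spidroin",
    "fibroin heavy chain",
    "silk gland protein",
)
_NEUTRAL_DESCRIPTIONS = (
    "actin",
    "ribosomal protein L7",
    "elongation factor 1-alpha",
    "heat shock protein 70",
    "tubulin beta chain",
    "hypothetical protein",
    "ATP synthase subunit",
    "cytochrome c oxidase",
)
_GO_POOL = tuple(f"GO:{7000000 + i:07d}" for i in range(24))
GO_TOXIN = "GO:0090729"  # planted venom-family term
GO_EXTRACELLULAR = "GO:0005576"


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Build the full synthetic bundle deterministically from the seed."""
    rng = np.random.default_rng(config.seed)

    records: list[dict] = []  # one per transcript, truth fields
    proteins: dict[str, str] = {}

    fam_lo, fam_hi = config.family_size_range
    n_ick_families = round(config.n_venom_families * config.ick_fraction)

    idx = 0
    for fam in range(config.n_venom_families):
        is_ick = fam < n_ick_families
        size = int(rng.integers(fam_lo, fam_hi + 1))
        if is_ick:
            base = make_ick_protein(rng, length=int(rng.integers(80, 130)))
            frozen = {i for i, aa in enumerate(base) if aa in "MC" and
                      (i == 0 or aa == "C")}
        else:
            base = _make_latrotoxin_like(rng)
            frozen = {0}
        for _ in range(size):
            prot = _mutate(rng, base, rate=0.10, frozen=frozen)
            tid = f"venom_fam{fam:02d}_t{idx:05d}"
            proteins[tid] = prot
            records.append(
                {
                    "transcript_id": tid,
                    "label": LABEL_VENOM,
                    "family_id": f"fam{fam:02d}",
                    "is_ick_like": is_ick,
                    "signal_start": 0 if is_ick else -1,
                    "signal_end": 18 if is_ick else -1,
                    "secreted": bool(is_ick),
                }
            )
            idx += 1

    for _ in range(config.n_silk_specific):
        tid = f"silk_t{idx:05d}"
        proteins[tid] = _random_protein(rng, 120, 350)
        records.append(
            {
                "transcript_id": tid,
                "label": LABEL_SILK,
                "family_id": "",
                "is_ick_like": False,
                "signal_start": -1,
                "signal_end": -1,
                "secreted": False,
            }
        )
        idx += 1

    for _ in range(config.n_background):
        tid = f"bg_t{idx:05d}"
        proteins[tid] = _random_protein(rng, 100, 400)
        records.append(
            {
                "transcript_id": tid,
                "label": LABEL_BROAD,
                "family_id": "",
                "is_ick_like": False,
                "signal_start": -1,
                "signal_end": -1,
                "secreted": False,
            }
        )
        idx += 1

    truth = pd.DataFrame(records)
    truth["protein_seq"] = truth["transcript_id"].map(proteins)

    transcripts = {
        tid: _encode_transcript(rng, proteins[tid])
        for tid in truth["transcript_id"]
    }

    counts = _simulate_counts(rng, truth, transcripts, config)
    annotations = _make_annotations(rng, truth)
    go_terms = _make_go_terms(rng, truth)
    signal = pd.DataFrame(
        {
            "protein_id": truth["transcript_id"],
            "has_signal": truth["secreted"],
            "cleavage_pos": truth["signal_end"].where(truth["secreted"], -1),
        }
    )
    return SyntheticBundle(
        transcripts=transcripts,
        counts=counts,
        annotations=annotations,
        go_terms=go_terms,
        signal=signal,
        truth=truth,
        config=config,
    )


def _simulate_counts(
    rng: np.random.Generator,
    truth: pd.DataFrame,
    transcripts: dict[str, str],
    config: SyntheticConfig,
) -> pd.DataFrame:
    n = len(truth)
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n)
    mu = np.zeros((n, 3))  # venom, silk, ceph
    labels = truth["label"].to_numpy()
    for i, label in enumerate(labels):
        if label == LABEL_VENOM:
            b = base[i] * 6.0  # venom-family transcripts are well expressed
            mu[i] = (b, b / config.venom_fold, b / config.venom_fold)
        elif label == LABEL_SILK:
            b = base[i] * 4.0
            mu[i] = (b / config.venom_fold, b, b / config.venom_fold)
        else:
            wobble = rng.lognormal(mean=0.0, sigma=0.15, size=3)
            mu[i] = base[i] * wobble
    # scale each tissue so expected totals match the configured library sizes
    for t in range(3):
        mu[:, t] *= config.library_sizes[t] / mu[:, t].sum()

    phi = config.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    obs = rng.poisson(lam)

    lengths = np.array(
        [len(transcripts[t]) for t in truth["transcript_id"]], dtype=int
    )
    eff = np.maximum(lengths - 199, 50)
    return pd.DataFrame(
        {
            "transcript_id": truth["transcript_id"],
            "venom": obs[:, 0],
            "silk": obs[:, 1],
            "ceph": obs[:, 2],
            "effective_length_nt": eff,
        }
    )


def _make_annotations(rng: np.random.Generator,
                      truth: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in truth.itertuples(index=False):
        if row.label == LABEL_VENOM:
            pool = _ICK_DESCRIPTIONS if row.is_ick_like else _LATRO_DESCRIPTIONS
            desc = str(rng.choice(pool))
            log_e = rng.uniform(-120, -20)
        elif row.label == LABEL_SILK:
            desc = str(rng.choice(_SILK_DESCRIPTIONS))
            log_e = rng.uniform(-90, -10)
        else:
            if rng.random() < 0.35:  # a share of background has no hit
                continue
            desc = str(rng.choice(_NEUTRAL_DESCRIPTIONS))
            log_e = rng.uniform(-100, -6)
        rows.append(
            {
                "transcript_id": row.transcript_id,
                "hit_description": desc,
                "evalue": 10.0 ** log_e,
                "hit_frame": 1,
            }
        )
    return pd.DataFrame(rows)


def _make_go_terms(rng: np.random.Generator,
                   truth: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in truth.itertuples(index=False):
        if row.label == LABEL_VENOM:
            rows.append({"transcript_id": row.transcript_id,
                         "go_id": GO_TOXIN})
            if row.is_ick_like:
                rows.append({"transcript_id": row.transcript_id,
                             "go_id": GO_EXTRACELLULAR})
        n_extra = int(rng.integers(0, 3))
        for g in rng.choice(len(_GO_POOL), size=n_extra, replace=False):
            rows.append({"transcript_id": row.transcript_id,
                         "go_id": _GO_POOL[int(g)]})
    return pd.DataFrame(rows, columns=["transcript_id", "go_id"])


_TRYPTIC = re.compile(r"(?<=[KR])(?!P)")


def tryptic_digest(protein: str, min_len: int = 7) -> list[str]:
    """Cleave C-terminal of K/R except before P; keep fragments of at
    least ``min_len`` residues."""
    return [f for f in _TRYPTIC.split(protein) if len(f) >= min_len]


def generate_peptide_ids(
    truth: pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """In-silico peptide identification table for secreted truth proteins.

    Each eligible tryptic fragment of a secreted protein is detected
    with probability ``detect_prob`` (probabilities >= 0.95 for true
    identifications); ``decoy_fraction`` of the detected count is added
    as shuffled decoy peptides with low probabilities.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng([config.seed, 7919])
    rows = []
    secreted = truth[truth["secreted"]]
    for prot_row in secreted.itertuples(index=False):
        protein_prob = float(rng.uniform(0.97, 1.0))
        for frag in tryptic_digest(prot_row.protein_seq,
                                   config.min_peptide_len):
            if rng.random() >= config.detect_prob:
                continue
            rows.append(
                {
                    "peptide_seq": frag,
                    "peptide_prob": float(rng.uniform(0.96, 1.0)),
                    "protein_prob": protein_prob,
                }
            )
    n_decoys = round(len(rows) * config.decoy_fraction)
    true_peps = [r["peptide_seq"] for r in rows]
    for _ in range(n_decoys):
        src = list(true_peps[int(rng.integers(0, len(true_peps)))])
        rng.shuffle(src)
        rows.append(
            {
                "peptide_seq": "".join(src),
                "peptide_prob": float(rng.uniform(0.05, 0.5)),
                "protein_prob": float(rng.uniform(0.05, 0.5)),
            }
        )
    return pd.DataFrame(rows,
                        columns=["peptide_seq", "peptide_prob", "protein_prob"])
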