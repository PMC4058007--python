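"""Toxin candidate screens over venom-gland-specific proteins.

Keyword tagging of homology hits, the small/cysteine-rich candidate
screen, cysteine-framework extraction with a rule-based knottin (ICK)
candidacy check, and category-wise expression summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

NO_HIT = "no_hit"
OTHER = "other"

DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class ToxinCategoryRule:
    name: str
    keywords: tuple[str, ...]
    max_evalue: float = DEFAULT_MAX_EVALUE

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"category {self.name!r} has no keywords")

    def matches(self, description: str) -> bool:
        d = description.lower()
        return any(k.lower() in d for k in self.keywords)


@dataclass(frozen=True)
class CysteineFramework:
    protein_id: str
    mature_start: int
    cys_count: int
    spacings: tuple[int, ...]  # residues between consecutive cysteines
    ick_candidate: bool

    def __post_init__(self) -> None:
        if self.cys_count > 0 and len(self.spacings) != self.cys_count - 1:
            raise ValueError("spacing list must have cys_count - 1 entries")
        if any(s < 0 for s in self.spacings):
            raise ValueError("spacings must be non-negative")


def load_category_rules(path=None) -> list[ToxinCategoryRule]:
    """Load keyword rules from YAML (packaged defaults when path is None)."""
    if path is None:
        text = (
            resources.files("venomexome.data")
            .joinpath("toxin_categories.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    max_e = float(cfg.get("max_evalue", DEFAULT_MAX_EVALUE))
    return [
        ToxinCategoryRule(
            name=c["name"],
            keywords=tuple(str(k) for k in c["keywords"]),
            max_evalue=float(c.get("max_evalue", max_e)),
        )
        for c in cfg["categories"]
    ]


def tag_categories(
    annotations: pd.DataFrame,
    rules: Sequence[ToxinCategoryRule] | None = None,
    transcript_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Assign each transcript a category by first-matching keyword rule.

    ``annotations`` columns: transcript_id, hit_description, evalue.
    Transcripts without a row, or whose hit fails the e-value cutoff,
    are ``no_hit``; hits matching no rule are ``other``.
    """
    if rules is None:
        rules = load_category_rules()
    if annotations["transcript_id"].duplicated().any():
        dups = annotations.loc[
            annotations["transcript_id"].duplicated(), "transcript_id"
        ].head(3)
        raise ValueError(f"duplicate annotation rows, e.g. {list(dups)}")

    by_id = annotations.set_index("transcript_id")
    ids = (
        list(transcript_ids)
        if transcript_ids is not None
        else list(by_id.index)
    )
    out: dict[str, str] = {}
    for tid in ids:
        if tid not in by_id.index:
            out[tid] = NO_HIT
            continue
        row = by_id.loc[tid]
        desc = str(row["hit_description"])
        evalue = float(row["evalue"])
        category = OTHER
        for rule in rules:
            if rule.matches(desc):
                category = rule.name if evalue <= rule.max_evalue else NO_HIT
                break
        else:
            # no keyword matched: e-value still gates hit vs no_hit
            if evalue > DEFAULT_MAX_EVALUE:
                category = NO_HIT
        out[tid] = category
    return out


def screen_cysteine_rich(
    proteins: Mapping[str, str],
    max_len: int = 200,
    min_cys: int = 6,
    require_mstart: bool = True,
) -> list[str]:
    """Ids of small (< max_len residues, strict) cysteine-rich
    (>= min_cys C) proteins, optionally requiring an N-terminal M.

    Output order follows sorted ids (input-order invariant).
    """
    hits = []
    for pid in sorted(proteins):
        seq = proteins[pid]
        if len(seq) >= max_len:
            continue
        if seq.count("C") < min_cys:
            continue
        if require_mstart and not seq.startswith("M"):
            continue
        hits.append(pid)
    return hits


def extract_framework(
    protein_id: str,
    aa_seq: str,
    cleavage_pos: int | None = None,
    min_cys: int = 6,
    max_adjacent_spacing: int = 1,
    adjacent_window: tuple[int, int] = (3, 6),
    max_leading_spacing: int = 16,
) -> CysteineFramework:
    """Cysteine spacing pattern on the mature region and ICK candidacy.

    The mature region starts at ``cleavage_pos`` (0-based index of the
    first mature residue) when a signal peptide is annotated, else at 0.
    Default candidacy rule: >= ``min_cys`` cysteines, at least one
    spacing <= ``max_adjacent_spacing`` between consecutive cysteines
    numbered ``adjacent_window`` (inclusive, 1-based), and the first two
    spacings each <= ``max_leading_spacing``.
    """
    start = 0 if cleavage_pos is None else int(cleavage_pos)
    if start >= len(aa_seq):
        raise ValueError(
            f"cleavage position {start} not within protein {protein_id!r}"
        )
    mature = aa_seq[start:]
    positions = [i for i, aa in enumerate(mature) if aa == "C"]
    spacings = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    n = len(positions)

    candidate = n >= min_cys
    if candidate:
        lo, hi = adjacent_window
        # spacing i (0-based) separates cysteines i+1 and i+2 (1-based)
        window = [
            spacings[i]
            for i in range(len(spacings))
            if lo <= i + 1 and i + 2 <= hi
        ]
        candidate = any(s <= max_adjacent_spacing for s in window)
        candidate = candidate and all(
            s <= max_leading_spacing for s in spacings[:2]
        )
    return CysteineFramework(
        protein_id=protein_id,
        mature_start=start,
        cys_count=n,
        spacings=spacings,
        ick_candidate=bool(candidate),
    )


def cysteine_positions(framework: CysteineFramework) -> list[int]:
    """Reconstruct mature-region cysteine offsets relative to the first
    cysteine (round-trips with the spacing list)."""
    pos = [0]
    for s in framework.spacings:
        pos.append(pos[-1] + s + 1)
    return pos[: framework.cys_count]


def summarize_category_expression(
    venom_fpkm: pd.Series,
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Per-category transcript counts and % of summed VST venom FPKM.

    ``venom_fpkm`` is indexed by VST transcript id; every id must have a
    category. Percentages sum to 100.
    """
    if len(venom_fpkm) == 0:
        raise ValueError("empty VST set")
    missing = [t for t in venom_fpkm.index if t not in categories]
    if missing:
        raise ValueError(f"transcripts lacking a category, e.g. {missing[:3]}")
    cats = pd.Series({t: categories[t] for t in venom_fpkm.index})
    total = float(venom_fpkm.sum())
    if total <= 0:
        raise ValueError("total venom FPKM of the VST set is zero")
    grouped = venom_fpkm.groupby(cats)
    out = pd.DataFrame(
        {
            "n_transcripts": grouped.size(),
            "pct_expression": grouped.sum() / total * 100.0,
        }
    )
    out.index.name = "category"
    return out.sort_values("pct_expression", ascending=False)
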