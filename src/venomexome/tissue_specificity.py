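"""eCPM / FPKM computation and venom-gland-specificity classification.

A transcript is venom-gland specific (VST) when it is either
*exclusive* (venom eCPM above a floor with zero eCPM in both other
tissues) or *ratio_vst* (venom/silk and venom/cephalothorax eCPM ratios
both in the upper tail of the remaining transcripts' ratio
distributions, with at least one venom eCPM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TISSUES = ("venom", "silk", "ceph")

EXCLUSIVE = "exclusive"
RATIO_VST = "ratio_vst"
BACKGROUND = "background"


@dataclass
class SpecificityResult:
    """Per-transcript class labels plus the realized fold cutoffs."""

    table: pd.DataFrame  # index transcript_id; columns eCPM_*, ratio_*, class
    fold_cutoff_silk: float
    fold_cutoff_ceph: float
    quantile: float
    min_ecpm: float

    @property
    def vst_ids(self) -> list[str]:
        cls = self.table["class"]
        return list(self.table.index[(cls == EXCLUSIVE) | (cls == RATIO_VST)])

    def counts(self) -> dict[str, int]:
        return self.table["class"].value_counts().to_dict()


def compute_ecpm(counts: pd.DataFrame, tissues=TISSUES) -> pd.DataFrame:
    """counts per million within each tissue column.

    Raises on an all-zero tissue (eCPM undefined).
    """
    ecpm = pd.DataFrame(index=counts.index)
    for t in tissues:
        total = counts[t].sum()
        if total <= 0:
            raise ValueError(f"tissue {t!r} has zero total counts")
        ecpm[t] = counts[t] / total * 1e6
    return ecpm


def compute_fpkm(
    counts: pd.DataFrame,
    effective_lengths: pd.Series,
    tissues=TISSUES,
) -> pd.DataFrame:
    """Fragments per kilobase of effective length per million fragments."""
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    fpkm = pd.DataFrame(index=counts.index)
    kb = lengths / 1000.0
    for t in tissues:
        total = counts[t].sum()
        if total <= 0:
            raise ValueError(f"tissue {t!r} has zero total counts")
        fpkm[t] = counts[t] / (kb * (total / 1e6))
    return fpkm


def nearest_rank_upper_cutoff(values: np.ndarray, quantile: float) -> float:
    """Value at the (1 - quantile) nearest-rank position (inclusive).

    With n values sorted ascending, the cutoff is the element at 1-based
    rank ceil((1 - quantile) * n); everything >= it is "in the upper
    quantile" under >= comparison.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty distribution")
    rank = max(1, math.ceil((1.0 - quantile) * n))
    return float(v[rank - 1])


def classify_vst(
    ecpm: pd.DataFrame,
    quantile: float = 0.025,
    min_ecpm: float = 1.0,
) -> SpecificityResult:
    """Classify transcripts as exclusive / ratio_vst / background.

    Exclusive: venom eCPM > min_ecpm and zero eCPM in silk and ceph.
    The ratio cutoffs are the upper-``quantile`` nearest-rank values of
    the venom/silk and venom/ceph eCPM ratio distributions over the
    *remaining* transcripts (venom eCPM > 0, not exclusive); a zero
    denominator yields +inf, ranked above all finite ratios. A remaining
    transcript is ratio_vst when both its ratios meet their cutoffs and
    its venom eCPM is >= 1.
    """
    v = ecpm["venom"].to_numpy(float)
    s = ecpm["silk"].to_numpy(float)
    c = ecpm["ceph"].to_numpy(float)

    exclusive = (v > min_ecpm) & (s == 0) & (c == 0)
    remaining = (v > 0) & ~exclusive

    with np.errstate(divide="ignore", invalid="ignore"):
        r_s = np.where(s > 0, v / np.where(s > 0, s, 1.0), np.inf)
        r_c = np.where(c > 0, v / np.where(c > 0, c, 1.0), np.inf)
    r_s = np.where(v > 0, r_s, np.nan)
    r_c = np.where(v > 0, r_c, np.nan)

    n_remaining = int(remaining.sum())
    if n_remaining == 0:
        fold_s = fold_c = math.inf
    else:
        if n_remaining < 40:
            warnings.warn(
                f"only {n_remaining} remaining transcripts; the "
                f"{quantile:.1%} upper-tail cutoff is unstable",
                stacklevel=2,
            )
        fold_s = nearest_rank_upper_cutoff(r_s[remaining], quantile)
        fold_c = nearest_rank_upper_cutoff(r_c[remaining], quantile)

    ratio_vst = (
        remaining
        & (v >= 1.0)
        & (r_s >= fold_s)
        & (r_c >= fold_c)
    )

    cls = np.full(len(ecpm), BACKGROUND, dtype=object)
    cls[exclusive] = EXCLUSIVE
    cls[ratio_vst] = RATIO_VST

    table = pd.DataFrame(
        {
            "eCPM_venom": v,
            "eCPM_silk": s,
            "eCPM_ceph": c,
            "ratio_silk": r_s,
            "ratio_ceph": r_c,
            "class": cls,
        },
        index=ecpm.index,
    )
    return SpecificityResult(
        table=table,
        fold_cutoff_silk=fold_s,
        fold_cutoff_ceph=fold_c,
        quantile=quantile,
        min_ecpm=min_ecpm,
    )
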