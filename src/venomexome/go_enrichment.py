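"""Length-bias-corrected GO overrepresentation by weighted resampling.

The probability-weighting function (PWF) estimates each background
transcript's chance of being in the target set as a smoothed, monotone
function of its length; the null for each GO term is then formed by
repeatedly drawing target-set-sized samples from the background without
replacement, with inclusion probability proportional to the weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # go_id, n_vst, n_bg, p, q, flagged
    n_resamples: int
    alpha: float


def fit_pwf(
    lengths: np.ndarray,
    is_vst: np.ndarray,
    n_bins: int = 20,
    shrinkage: float = 20.0,
) -> np.ndarray:
    """Per-transcript selection weights from binned, isotonic-smoothed
    membership proportions vs length.

    Bins are length quantiles; bin proportions are shrunk toward the
    global rate (pseudo-count mass ``shrinkage``) and regularized
    monotone in whichever direction fits better. Weights are rescaled so
    their sum equals the target-set size, and floored at a small
    positive value. Degenerate input (all lengths equal, or all/none in
    the set) yields uniform weights.
    """
    lengths = np.asarray(lengths, dtype=float)
    is_vst = np.asarray(is_vst, dtype=bool)
    n = lengths.size
    if n == 0:
        raise ValueError("empty background")
    k = int(is_vst.sum())
    p0 = k / n
    if k == 0 or k == n or np.all(lengths == lengths[0]):
        return np.full(n, max(p0, 1e-12))

    n_bins = min(n_bins, n)
    order = np.argsort(lengths, kind="stable")
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)

    bin_n = np.bincount(bin_of, minlength=n_bins).astype(float)
    bin_k = np.bincount(bin_of, weights=is_vst.astype(float), minlength=n_bins)
    occupied = bin_n > 0
    raw = np.zeros(n_bins)
    raw[occupied] = (bin_k[occupied] + shrinkage * p0) / (
        bin_n[occupied] + shrinkage
    )
    bin_len = np.zeros(n_bins)
    np.add.at(bin_len, bin_of, lengths)
    bin_len[occupied] /= bin_n[occupied]

    x = bin_len[occupied]
    y = raw[occupied]
    w = bin_n[occupied]
    best = None
    for increasing in (True, False):
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        fit = iso.fit_transform(x, y, sample_weight=w)
        sse = float(np.sum(w * (fit - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, fit)
    smoothed_occ = best[1]
    smoothed = np.full(n_bins, p0)
    smoothed[occupied] = smoothed_occ

    weights = smoothed[bin_of]
    weights = np.maximum(weights, 1e-12)
    weights = weights * (k / weights.sum())
    return weights


def weighted_sample_indices(
    rng: np.random.Generator,
    weights: np.ndarray,
    size: int,
    n_draws: int,
) -> np.ndarray:
    """``n_draws`` weighted samples of ``size`` indices without
    replacement (Gumbel top-k; equivalent to sequential sampling with
    probability proportional to remaining weight)."""
    n = weights.size
    logw = np.log(weights)
    out = np.empty((n_draws, size), dtype=np.int64)
    for i in range(n_draws):
        keys = logw + rng.gumbel(size=n)
        out[i] = np.argpartition(-keys, size - 1)[:size]
    return out


def weighted_resampling_test(
    go_table: pd.DataFrame,
    vst_ids: set[str],
    background_ids: list[str],
    weights: np.ndarray,
    n_resamples: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-GO-term upper-tail resampling p-values.

    ``go_table`` columns: transcript_id, go_id. Terms whose transcripts
    are all outside the background are skipped with a warning. The
    p-value is (1 + #{resampled count >= observed}) / (1 + n_resamples).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bg_index = {t: i for i, t in enumerate(background_ids)}
    n = len(background_ids)
    vst_in_bg = [t for t in vst_ids if t in bg_index]
    k = len(vst_in_bg)
    if k == 0:
        raise ValueError("no target-set transcripts in the background")

    term_members: dict[str, np.ndarray] = {}
    for go_id, grp in go_table.groupby("go_id"):
        idx = [bg_index[t] for t in grp["transcript_id"] if t in bg_index]
        if not idx:
            warnings.warn(
                f"GO term {go_id} has no background transcripts; skipped",
                stacklevel=2,
            )
            continue
        term_members[go_id] = np.array(sorted(set(idx)), dtype=np.int64)

    vst_mask = np.zeros(n, dtype=bool)
    vst_mask[[bg_index[t] for t in vst_in_bg]] = True

    terms = sorted(term_members)
    membership = np.zeros((len(terms), n), dtype=np.float64)
    for ti, go_id in enumerate(terms):
        membership[ti, term_members[go_id]] = 1.0
    observed = membership @ vst_mask.astype(np.float64)

    draws = weighted_sample_indices(rng, np.asarray(weights, float), k,
                                    n_resamples)
    chosen = np.zeros((n, n_resamples), dtype=np.float64)
    rows = draws.ravel()
    cols = np.repeat(np.arange(n_resamples), k)
    chosen[rows, cols] = 1.0
    null_counts = membership @ chosen  # terms x resamples

    ge = (null_counts >= observed[:, None]).sum(axis=1)
    p = (1.0 + ge) / (1.0 + n_resamples)
    return pd.DataFrame(
        {
            "go_id": terms,
            "n_vst": observed.astype(int),
            "n_bg": [term_members[t].size for t in terms],
            "p": p,
        }
    )


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05):
    """Benjamini–Hochberg step-up q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def enrich(
    go_table: pd.DataFrame,
    vst_ids: set[str],
    background_ids: list[str],
    lengths: np.ndarray,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    n_bins: int = 20,
    seed: int | None = None,
) -> EnrichmentResult:
    """Full enrichment pass: PWF, weighted resampling, BH FDR."""
    is_vst = np.array([t in vst_ids for t in background_ids])
    weights = fit_pwf(lengths, is_vst, n_bins=n_bins)
    table = weighted_resampling_test(
        go_table, vst_ids, background_ids, weights,
        n_resamples=n_resamples, seed=seed,
    )
    q, flagged = bh_fdr(table["p"].to_numpy(), alpha=alpha)
    table = table.assign(q=q, flagged=flagged)
    return EnrichmentResult(table=table, n_resamples=n_resamples, alpha=alpha)


def hypergeom_tail(n_bg: int, n_members: int, n_drawn: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeom(n_bg, n_members, n_drawn);
    reference oracle for the uniform-weight case."""
    return float(stats.hypergeom.sf(observed - 1, n_bg, n_members, n_drawn))
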