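"""Allele-frequency shifts across phenotypic bins.

For every variant the alternative-allele frequency is computed per bin;
all unordered bin pairs are compared and labelled by their "phenotypic
difference level" — the difference in bin indices, so level 1 compares
neighbouring bins and level K-1 the phenotypic extremes.  Absolute
frequency differences at the same level are pooled across replicates, and
candidates are contrasted with noncandidates by a Wilcoxon rank-sum test
(normal approximation with tie correction; exact enumeration for tiny
groups).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import _bins_with_sample_ids, variant_id

__all__ = [
    "bin_allele_freqs",
    "pairwise_level_diffs",
    "compare_candidate_shift",
    "rank_sum_test",
]

_EXACT_MAX_N = 12


def bin_allele_freqs(counts: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Alternative-allele frequency per (variant, replicate, bin).

    Zero-depth bins are skipped for that variant (frequency undefined).
    """
    bins = _bins_with_sample_ids(bins)
    df = counts.copy()
    df["variant_id"] = variant_id(df)
    df = df.merge(bins[["sample", "replicate", "bin_index"]], on="sample", how="inner")
    depth = df["ref_reads"] + df["alt_reads"]
    df = df[depth > 0].copy()
    df["freq"] = df["alt_reads"] / (df["ref_reads"] + df["alt_reads"])
    return df[["variant_id", "replicate", "bin_index", "freq"]].reset_index(drop=True)


def pairwise_level_diffs(freqs: pd.DataFrame) -> pd.DataFrame:
    """Absolute frequency difference for every unordered bin pair.

    One record per (variant, replicate, bin pair); ``level`` is the
    difference of the two bin indices.  For K bins with defined
    frequencies this yields K*(K-1)/2 records with level multiplicities
    K-1, K-2, ..., 1.
    """
    records = []
    for (vid, rep), sub in freqs.groupby(["variant_id", "replicate"], sort=True):
        by_bin = dict(zip(sub["bin_index"], sub["freq"]))
        for b1, b2 in combinations(sorted(by_bin), 2):
            records.append(
                {
                    "variant_id": vid,
                    "replicate": rep,
                    "level": int(b2 - b1),
                    "abs_diff": abs(by_bin[b2] - by_bin[b1]),
                }
            )
    return pd.DataFrame(records, columns=["variant_id", "replicate", "level", "abs_diff"])


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p; exact enumeration for tiny samples.

    The exact path (both groups together <= 12 observations, no ties
    required by scipy) makes the small-sample behaviour testable against
    brute-force enumeration; larger groups use the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return np.nan
    if x.size + y.size <= _EXACT_MAX_N and len(np.unique(np.concatenate([x, y]))) == x.size + y.size:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_candidate_shift(
    diffs: pd.DataFrame, candidate_flags: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Contrast candidate vs noncandidate |frequency difference| per level.

    ``candidate_flags`` maps variant_id -> is_candidate.  Differences from
    both replicates are pooled (not averaged).  Returns a per-level table
    (medians of the two groups and the rank-sum p; NaN when a group is
    empty at that level) plus a joint test across all levels pooled.
    """
    flags = dict(zip(candidate_flags["variant_id"], candidate_flags["is_candidate"]))
    df = diffs.copy()
    df["is_candidate"] = df["variant_id"].map(flags).fillna(False).astype(bool)
    rows = []
    for level, sub in df.groupby("level", sort=True):
        cand = sub.loc[sub["is_candidate"], "abs_diff"].to_numpy()
        non = sub.loc[~sub["is_candidate"], "abs_diff"].to_numpy()
        rows.append(
            {
                "level": int(level),
                "n_candidate": cand.size,
                "n_noncandidate": non.size,
                "median_candidate": float(np.median(cand)) if cand.size else np.nan,
                "median_noncandidate": float(np.median(non)) if non.size else np.nan,
                "p_ranksum": rank_sum_test(cand, non),
            }
        )
    cand_all = df.loc[df["is_candidate"], "abs_diff"].to_numpy()
    non_all = df.loc[~df["is_candidate"], "abs_diff"].to_numpy()
    joint = {
        "median_candidate": float(np.median(cand_all)) if cand_all.size else np.nan,
        "median_noncandidate": float(np.median(non_all)) if non_all.size else np.nan,
        "p_ranksum": rank_sum_test(cand_all, non_all),
    }
    return pd.DataFrame(rows), joint
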