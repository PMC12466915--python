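"""Enrichment of candidate variants in annotation categories and interval
tracks; gene assignment, ranking and gene-set overlap.

The enrichment score is ES = log2 of the ratio of a category's proportion
among candidates to its proportion among background variants; significance
comes from Fisher's exact test on the 2x2 table with Benjamini-Hochberg
adjustment across categories.  Track membership honours the multi-term
support rule: a variant counts for a regulatory factor with more than two
terms only if it overlaps at least two distinct terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .association import bh_adjust, variant_id
from .io import IntervalTrack

__all__ = [
    "ANNOTATION_PRIORITY",
    "resolve_annotation_priority",
    "category_enrichment",
    "track_membership",
    "assign_variants_to_genes",
    "rank_genes",
    "geneset_overlap_enrichment",
]

# lower tier = more severe; nonsense sits at the protein-altering tier,
# above missense within it.  uORF start-codon changes are UTR-tier labels.
ANNOTATION_PRIORITY = {
    "nonsense": (0, 0),
    "missense": (0, 1),
    "synonymous": (1, 0),
    "utr5": (2, 0),
    "utr3": (2, 1),
    "uorf_gain": (2, 2),
    "uorf_loss": (2, 3),
    "intron": (3, 0),
    "intergenic": (4, 0),
}


def resolve_annotation_priority(labels) -> str:
    """Pick the most severe annotation among several labels.

    Priority: protein-altering (nonsense/missense) > synonymous > UTR >
    intron > intergenic.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no annotation labels")
    unknown = [l for l in labels if l not in ANNOTATION_PRIORITY]
    if unknown:
        raise ValueError(f"unknown annotation label(s): {unknown}")
    return min(labels, key=ANNOTATION_PRIORITY.__getitem__)


def _enrichment_row(a: int, b: int, c: int, d: int) -> dict:
    n_cand, n_bg = a + b, c + d
    if n_cand > 0 and n_bg > 0 and c > 0 and a > 0:
        es = float(np.log2((a / n_cand) / (c / n_bg)))
    elif n_cand > 0 and n_bg > 0 and c > 0:
        es = -np.inf if a == 0 else np.nan
    else:
        es = np.nan
    try:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    except ValueError:
        p = np.nan
    return {"a": a, "b": b, "c": c, "d": d, "es": es, "fisher_p": p}


def category_enrichment(
    universe: pd.DataFrame,
    category_col: str = "annotation_class",
    candidate_col: str = "is_candidate",
    background: str = "noncandidate",
) -> pd.DataFrame:
    """Per-category enrichment of candidates against the background set.

    ``universe`` holds one row per variant with its category and candidate
    flag.  The background defaults to noncandidate variants; pass
    ``background="universe"`` to compare against all variants instead.
    BH-adjusted q values are added across categories.
    """
    if background not in ("noncandidate", "universe"):
        raise ValueError(f"unknown background: {background!r}")
    is_cand = universe[candidate_col].astype(bool)
    cand = universe[is_cand]
    bg = universe if background == "universe" else universe[~is_cand]
    rows = []
    for cat in sorted(universe[category_col].dropna().unique()):
        a = int((cand[category_col] == cat).sum())
        b = len(cand) - a
        c = int((bg[category_col] == cat).sum())
        d = len(bg) - c
        rows.append({"category": cat, **_enrichment_row(a, b, c, d)})
    out = pd.DataFrame(rows)
    valid = out["fisher_p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_adjust(out.loc[valid, "fisher_p"])
    return out


def _tree_per_chrom(intervals: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        # stored 1-based inclusive; IntervalTree is half-open, so end + 1
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e) + 1) for s, e in zip(sub["start"], sub["end"])
        )
    return trees


def track_membership(
    variants: pd.DataFrame, tracks: list[IntervalTrack]
) -> pd.DataFrame:
    """Factor membership of each variant under the multi-term support rule.

    A variant belongs to a factor if it overlaps at least one of its terms
    when the factor has <= 2 terms, and at least two distinct terms when
    the factor has more than two.  Returns a variant x factor boolean
    frame indexed by variant_id.
    """
    vids = variant_id(variants)
    by_factor: dict[str, list[IntervalTrack]] = {}
    for tr in tracks:
        by_factor.setdefault(tr.factor, []).append(tr)
    out = pd.DataFrame(index=pd.Index(vids, name="variant_id"))
    for factor, terms in by_factor.items():
        need = 2 if len(terms) > 2 else 1
        hits = np.zeros(len(variants), dtype=int)
        for tr in terms:
            trees = _tree_per_chrom(tr.intervals)
            term_hit = np.array(
                [
                    bool(trees.get(ch) and trees[ch].overlaps_point(int(p)))
                    for ch, p in zip(variants["chrom"], variants["pos"])
                ]
            )
            hits += term_hit.astype(int)
        out[factor] = hits >= need
    return out


def assign_variants_to_genes(
    variants: pd.DataFrame, gene_features: pd.DataFrame
) -> pd.DataFrame:
    """Map variants to genes through coding/UTR/intron feature intervals.

    ``gene_features`` columns: gene_id, chrom, start, end, feature (one of
    coding, utr, intron), with 1-based inclusive coordinates.  Intergenic
    variants are unassigned; a variant inside overlapping genes maps to
    all of them.  Returns a long frame (variant_id, gene_id).
    """
    usable = gene_features[
        gene_features["feature"].isin(["coding", "utr", "utr5", "utr3", "intron"])
    ]
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in usable.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, g)
            for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    vids = variant_id(variants)
    records = []
    for vid, chrom, pos in zip(vids, variants["chrom"], variants["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        genes = {iv.data for iv in tree.at(int(pos))}
        records.extend({"variant_id": vid, "gene_id": g} for g in sorted(genes))
    return pd.DataFrame(records, columns=["variant_id", "gene_id"])


def rank_genes(assignments: pd.DataFrame, qvalues: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the best (smallest) q among their variants.

    Ties break by larger variant count, then lexicographic gene id; genes
    whose variants all lack a q value are excluded.  Ranks are 1..G.
    """
    q_of = dict(zip(qvalues["variant_id"], qvalues["q"]))
    df = assignments.copy()
    df["q"] = df["variant_id"].map(q_of)
    df = df.dropna(subset=["q"])
    agg = (
        df.groupby("gene_id")
        .agg(n_variants=("variant_id", "nunique"), best_q=("q", "min"))
        .reset_index()
    )
    agg = agg.sort_values(
        ["best_q", "n_variants", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def geneset_overlap_enrichment(
    top_genes, geneset, universe, alternative: str = "greater"
) -> tuple[int, float, float]:
    """Overlap of a top-K gene list with a gene set, Fisher-tested.

    Fold enrichment is (hits/K) / (|set|/|universe|); the test is
    one-sided for enrichment by default.  Returns (hits, fold, p).
    """
    top = set(top_genes)
    universe = set(universe)
    gs = set(geneset) & universe
    if not gs:
        raise ValueError("empty gene set (after restriction to the universe)")
    if not top <= universe:
        raise ValueError("top gene list must be a subset of the universe")
    k = len(top)
    hits = len(top & gs)
    fold = (hits / k) / (len(gs) / len(universe))
    table = [
        [hits, k - hits],
        [len(gs) - hits, len(universe) - k - (len(gs) - hits)],
    ]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return hits, float(fold), p
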