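"""Post-calling variant filters for the background (C1/C2) and bin samples.

High-depth pooled sequencing is prone to false variants from sequencing
error and mismapping, so called variants are screened before association:
site quality, a minimum pooled minor-allele count (stricter on autosomes
than on the hemizygous X), an upper depth quantile cutoff against
collapsed-repeat mismapping, a per-sample minimum depth, removal of sites
near indels, and a requirement that the variant be observed in at least
one phenotypic bin of each replicate.

Rules are evaluated independently (order-free) and reported per rule so a
variant's failure is attributable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import variant_id

__all__ = [
    "FilterParams",
    "compute_depth_bounds",
    "apply_variant_filters",
    "flag_near_indels",
    "default_chrom_class",
]

RULE_COLUMNS = [
    "pass_qual",
    "pass_minor_count",
    "pass_depth_upper",
    "pass_min_depth",
    "pass_not_near_indel",
    "pass_both_replicates",
]


@dataclass
class FilterParams:
    """Thresholds of the variant screen.

    Minor-allele counts must be *strictly greater* than the per-class
    threshold (``> 5`` autosomes, ``> 2`` X).  ``depth_extreme_fraction``
    removes the upper tail of the background depth distribution;
    ``min_depth_per_sample`` applies to every background sample (and to
    bin samples as well when ``min_depth_include_bins`` is set).
    """

    min_qual: float = 20.0
    min_minor_autosome: int = 5  # strictly-greater threshold
    min_minor_x: int = 2
    depth_extreme_fraction: float = 0.01
    min_depth_per_sample: int = 50
    indel_window_bp: int = 3
    require_both_replicates: bool = True
    min_depth_include_bins: bool = False

    def __post_init__(self):
        if not 0 < self.depth_extreme_fraction < 1:
            raise ValueError("depth_extreme_fraction must lie in (0, 1)")
        for name in ("min_qual", "min_minor_autosome", "min_minor_x",
                     "min_depth_per_sample", "indel_window_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_chrom_class(chrom: str) -> str:
    """Map a chromosome name to the sex class used by the filters."""
    return "X" if str(chrom).lstrip("chr").upper() == "X" else "autosome"


def compute_depth_bounds(background_depths, fraction: float = 0.01) -> float:
    """Upper depth threshold: the (1 - fraction) empirical quantile.

    Loci with total background depth strictly above the returned value are
    considered depth-extreme and fail the filter.
    """
    depths = np.asarray(background_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth vector for this chromosome class")
    return float(np.quantile(depths, 1.0 - fraction))


def flag_near_indels(
    sites: pd.DataFrame, indel_positions: pd.DataFrame, window_bp: int = 3
) -> pd.DataFrame:
    """Set ``near_indel`` for sites within ``window_bp`` of an indel.

    ``indel_positions`` needs columns chrom, pos; the window is inclusive
    (distance <= window_bp).
    """
    out = sites.copy()
    flags = np.zeros(len(out), dtype=bool)
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in indel_positions.groupby("chrom")}
    for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
        arr = by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            continue
        j = np.searchsorted(arr, pos)
        for k in (j - 1, j):
            if 0 <= k < arr.size and abs(int(arr[k]) - int(pos)) <= window_bp:
                flags[i] = True
    out["near_indel"] = out["near_indel"].to_numpy(dtype=bool) | flags if "near_indel" in out else flags
    return out


def apply_variant_filters(
    background_counts: pd.DataFrame,
    bin_counts: pd.DataFrame,
    sites: pd.DataFrame,
    params: FilterParams | None = None,
    bins: pd.DataFrame | None = None,
    chrom_class=default_chrom_class,
) -> pd.DataFrame:
    """Evaluate every filter rule for every site and report per-rule flags.

    ``background_counts`` hold the C1/C2 pools, ``bin_counts`` the
    phenotypic-bin pools; ``bins`` (the manifest) supplies the sample ->
    replicate mapping for the both-replicates rule.  A site absent from
    the background is flagged (all background-dependent rules fail) but
    is not an error.  ``final_pass`` is the conjunction of all rules.
    """
    params = params or FilterParams()
    sites = sites.copy()
    sites["variant_id"] = variant_id(sites)
    sites["chrom_class"] = sites["chrom"].map(chrom_class)

    bg = background_counts.copy()
    bg["variant_id"] = variant_id(bg)
    bg["depth"] = bg["ref_reads"] + bg["alt_reads"]
    bg_tot = bg.groupby("variant_id")[["ref_reads", "alt_reads", "depth"]].sum()
    bg_samples = sorted(bg["sample"].unique())
    bg_min_depth = bg.pivot_table(
        index="variant_id", columns="sample", values="depth", fill_value=0
    ).reindex(columns=bg_samples, fill_value=0).min(axis=1)

    report = sites[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    in_bg = sites["variant_id"].isin(bg_tot.index).to_numpy()
    report["in_background"] = in_bg

    # rule 1: site quality
    report["pass_qual"] = (sites["qual"] >= params.min_qual).fillna(False).to_numpy()

    # rule 2: pooled minor-allele count, class-specific strict threshold
    ref_tot = sites["variant_id"].map(bg_tot["ref_reads"])
    alt_tot = sites["variant_id"].map(bg_tot["alt_reads"])
    minor = np.minimum(ref_tot, alt_tot)
    # tie at exactly 50%: alt is taken as the minor allele (same count)
    threshold = np.where(
        sites["chrom_class"] == "X", params.min_minor_x, params.min_minor_autosome
    )
    report["pass_minor_count"] = (minor > threshold).fillna(False).to_numpy()

    # rule 3: background depth within the class upper quantile
    depth_tot = sites["variant_id"].map(bg_tot["depth"])
    pass_upper = np.zeros(len(sites), dtype=bool)
    for cls, sub in sites.groupby("chrom_class"):
        cls_depths = depth_tot[sub.index].dropna()
        if cls_depths.empty:
            continue
        bound = compute_depth_bounds(cls_depths, params.depth_extreme_fraction)
        pass_upper[sub.index] = (depth_tot[sub.index] <= bound).fillna(False)
    report["pass_depth_upper"] = pass_upper

    # rule 4: minimum depth in every background sample (optionally bins)
    min_depth = sites["variant_id"].map(bg_min_depth)
    ok_depth = (min_depth >= params.min_depth_per_sample).fillna(False)
    if params.min_depth_include_bins:
        bc = bin_counts.copy()
        bc["variant_id"] = variant_id(bc)
        bc["depth"] = bc["ref_reads"] + bc["alt_reads"]
        bin_min = bc.groupby("variant_id")["depth"].min()
        ok_depth &= (
            sites["variant_id"].map(bin_min) >= params.min_depth_per_sample
        ).fillna(False)
    report["pass_min_depth"] = ok_depth.to_numpy()

    # rule 5: not adjacent to an indel
    report["pass_not_near_indel"] = ~sites["near_indel"].to_numpy(dtype=bool)

    # rule 6: observed (alt reads present) in >= 1 bin sample per replicate
    if params.require_both_replicates:
        bc = bin_counts.copy()
        bc["variant_id"] = variant_id(bc)
        if bins is not None:
            rep_of = dict(zip(bins["sample"], bins["replicate"]))
            bc["replicate"] = bc["sample"].map(rep_of)
        else:
            bc["replicate"] = bc["sample"].str[0]
        n_reps = bc["replicate"].nunique()
        seen = (
            bc[bc["alt_reads"] > 0]
            .groupby("variant_id")["replicate"]
            .nunique()
        )
        report["pass_both_replicates"] = (
            sites["variant_id"].map(seen).fillna(0).to_numpy() >= n_reps
        )
    else:
        report["pass_both_replicates"] = True

    report["final_pass"] = report[RULE_COLUMNS].all(axis=1) & in_bg
    return report
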