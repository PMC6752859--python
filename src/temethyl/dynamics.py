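"""Methylation at TE empty sites and carrier flanks across haplotypes.

For each site-defined polymorphism the haplotype lacking the TE reports the
pre-insertion state (the CG class of the 100 bp tile overlapping the
junction), and each carrier haplotype reports the CG state of the two tiles
abutting — but not overlapping — the element.  Insertions into unmethylated
empty sites whose flanks are methylated in the carrier are methylation
spreading events (candidate epialleles).  Family-level summaries rank
insertion preference (proportion of unmethylated empty sites, families with
>= 10 sites) and spreading rates (families with >= 4 survey-able
unmethylated insertion sites), and consistency is assessed across multiple
absent or carrier haplotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import METHYLATED, NO_DATA, UNMETHYLATED, ThresholdConfig

SPREAD_ONE = "spreading_one_flank"
SPREAD_BOTH = "spreading_both_flanks"
NON_SPREADING = "non_spreading"
NOT_APPLICABLE = "not_applicable"


class _TileIndex:
    """O(1) lookup of tile CG ratio/class by (chrom, tile index)."""

    def __init__(self, tiles: pd.DataFrame, tile_size: int):
        self.ts = tile_size
        self.ratio = {}
        self.cls = {}
        for row in tiles.itertuples():
            key = (row.chrom, row.start // tile_size)
            self.ratio[key] = row.cg_ratio
            self.cls[key] = row.cg_class

    def at(self, chrom: str, tile_idx: int):
        key = (chrom, tile_idx)
        return self.ratio.get(key, np.nan), self.cls.get(key, NO_DATA)


def classify_empty_site(
    chrom: str, pos: int, tiles_absent: pd.DataFrame,
    config: ThresholdConfig = ThresholdConfig(),
) -> tuple[float, str]:
    """CG ratio and class of the tile overlapping the empty-site junction.

    A junction exactly on a tile boundary belongs to the tile to its right
    (half-open tiles).  Returns (ratio, class); class ``no_data`` means the
    site must be dropped from downstream proportions.
    """
    idx = _TileIndex(tiles_absent, config.tile_size)
    return idx.at(chrom, pos // config.tile_size)


def _flank_tile_indices(start: int, end: int, ts: int) -> tuple[int, int]:
    # nearest grid tiles that cannot overlap [start, end)
    left = start // ts - 1
    right = end // ts if end % ts == 0 else end // ts + 1
    return left, right


def present_flank_state(
    chrom: str,
    start: int,
    end: int,
    tiles_present: pd.DataFrame,
    tes_present: pd.DataFrame | None = None,
    config: ThresholdConfig = ThresholdConfig(),
    *,
    focal_id: str | None = None,
    _index: "_TileIndex | None" = None,
) -> dict:
    """CG state of the two tiles immediately abutting a carrier element.

    The flank tiles are the nearest grid tiles that do not overlap
    [start, end).  A flank tile overlapping another TE's body is dropped.
    The mean is over available flank ratios; a single-data-flank site is
    retained and flagged.
    """
    ts = config.tile_size
    idx = _index or _TileIndex(tiles_present, ts)
    li, ri = _flank_tile_indices(start, end, ts)
    out = {}
    for name, ti in (("left", li), ("right", ri)):
        ratio, cls = idx.at(chrom, ti)
        t0, t1 = ti * ts, (ti + 1) * ts
        if ti < 0:
            ratio, cls = np.nan, NO_DATA
        elif tes_present is not None:
            others = tes_present[
                (tes_present["chrom"] == chrom)
                & (tes_present["start"] < t1)
                & (tes_present["end"] > t0)
            ]
            if focal_id is not None:
                others = others[others["id"] != focal_id]
            else:
                others = others[
                    (others["start"] != start) | (others["end"] != end)
                ]
            if len(others):
                ratio, cls = np.nan, NO_DATA
        out[f"{name}_ratio"] = ratio
        out[f"{name}_class"] = cls
    ratios = [v for v in (out["left_ratio"], out["right_ratio"])
              if not np.isnan(v)]
    out["mean_flank_ratio"] = float(np.mean(ratios)) if ratios else np.nan
    out["single_flank"] = len(ratios) == 1
    return out


def detect_spreading(
    empty_class: str, left_class: str, right_class: str
) -> str:
    """Per-flank spreading call for one unmethylated empty site.

    Applies only when the empty site is unmethylated; a flank gains when its
    carrier tile is methylated.  One gaining flank -> spreading_one_flank,
    both -> spreading_both_flanks; no informative flank -> not_applicable.
    """
    if empty_class != UNMETHYLATED:
        return NOT_APPLICABLE
    informative = [c for c in (left_class, right_class) if c != NO_DATA]
    if not informative:
        return NOT_APPLICABLE
    gains = sum(c == METHYLATED for c in (left_class, right_class))
    if gains == 2:
        return SPREAD_BOTH
    if gains == 1:
        return SPREAD_ONE
    return NON_SPREADING


def empty_site_records(
    sites: pd.DataFrame,
    tiles_absent: pd.DataFrame,
    tiles_present: pd.DataFrame,
    tes_present: pd.DataFrame | None = None,
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Per-site table joining the empty-site and carrier-flank states.

    ``sites`` needs columns: site_id, family, chrom + absent_pos (absent
    haplotype), present_chrom + present_start/present_end (carrier).  Sites
    whose empty-site tile has no CG data are dropped.  Both the per-flank
    headline spreading call and the averaged-flank criterion (mean flank
    ratio reaching the methylated cutoff) are reported.
    """
    ts = config.tile_size
    absent_idx = _TileIndex(tiles_absent, ts)
    present_idx = _TileIndex(tiles_present, ts)
    rows = []
    for s in sites.itertuples():
        ratio, cls = absent_idx.at(s.chrom, s.absent_pos // ts)
        if cls == NO_DATA:
            continue
        flank = present_flank_state(
            s.present_chrom, s.present_start, s.present_end, tiles_present,
            tes_present, config,
            focal_id=getattr(s, "site_id", None), _index=present_idx,
        )
        call = detect_spreading(
            cls, flank["left_class"], flank["right_class"]
        )
        mean_r = flank["mean_flank_ratio"]
        rows.append(
            dict(
                site_id=s.site_id, family=s.family, chrom=s.chrom,
                absent_pos=s.absent_pos, empty_ratio=ratio, empty_class=cls,
                **flank,
                spreading=call,
                spreading_avg=(
                    cls == UNMETHYLATED
                    and not np.isnan(mean_r)
                    and mean_r >= config.methylated_min
                ),
            )
        )
    return pd.DataFrame(rows)


def family_insertion_preference(
    records: pd.DataFrame, min_sites: int = 10
) -> pd.DataFrame:
    """Proportion of unmethylated empty sites per family, rank-ordered.

    Families with fewer than ``min_sites`` empty sites with methylation data
    are omitted.
    """
    rows = []
    for family, grp in records.groupby("family"):
        if len(grp) < min_sites:
            continue
        rows.append(
            dict(
                family=family, n_sites=len(grp),
                prop_unmethylated=float(
                    (grp["empty_class"] == UNMETHYLATED).mean()
                ),
            )
        )
    return (
        pd.DataFrame(rows, columns=["family", "n_sites", "prop_unmethylated"])
        .sort_values("prop_unmethylated", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def family_spreading_rate(
    records: pd.DataFrame, min_sites: int = 4
) -> pd.DataFrame:
    """Proportion of unmethylated insertions gaining flank methylation.

    Survey-able sites have an unmethylated empty site and at least one
    informative carrier flank; families with fewer than ``min_sites`` such
    sites are omitted.  Output is rank-ordered by spreading proportion.
    """
    surv = records[
        (records["empty_class"] == UNMETHYLATED)
        & (records["spreading"] != NOT_APPLICABLE)
    ]
    rows = []
    for family, grp in surv.groupby("family"):
        if len(grp) < min_sites:
            continue
        spreading = grp["spreading"].isin([SPREAD_ONE, SPREAD_BOTH])
        rows.append(
            dict(family=family, n_sites=len(grp),
                 prop_spreading=float(spreading.mean()))
        )
    return (
        pd.DataFrame(rows, columns=["family", "n_sites", "prop_spreading"])
        .sort_values("prop_spreading", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def fraction_families_all_spreading(rates: pd.DataFrame) -> float:
    """Fraction of qualifying families where every member spreads."""
    if not len(rates):
        return float("nan")
    return float((rates["prop_spreading"] == 1.0).mean())


def absent_consistency(classes: pd.DataFrame) -> tuple[float, pd.Series]:
    """Cross-genotype consistency over multiple TE-absent haplotypes.

    ``classes`` is a site x genotype table of empty-site CG classes.  A site
    is consistent when every absent haplotype shows the same class and that
    class is unmethylated or methylated.  Returns (fraction consistent,
    per-site flags); sites with any missing/no-data class are excluded.
    """
    valid = classes.notna().all(axis=1) & ~(classes == NO_DATA).any(axis=1)
    sub = classes[valid]
    same = sub.nunique(axis=1) == 1
    in_um = sub.isin([UNMETHYLATED, METHYLATED]).all(axis=1)
    flags = same & in_um
    frac = float(flags.mean()) if len(flags) else float("nan")
    return frac, flags


def carrier_gain_distribution(gains: pd.DataFrame) -> pd.Series:
    """Distribution of per-site gain counts over >= 2 carrier haplotypes.

    ``gains`` is a site x carrier boolean table (True = that carrier shows a
    methylation gain) for unmethylated empty sites.  Returns counts of sites
    by number of carriers with a gain.
    """
    sub = gains[gains.notna().all(axis=1)]
    n_gain = sub.sum(axis=1).astype(int)
    return n_gain.value_counts().sort_index()
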