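"""Fixed-window methylome summarisation and classification.

Per-cytosine calls are pooled over both strands into non-overlapping 100 bp
tiles per context; each tile's ratio is #C/(#C+#T) over the tile and is
classified as unmethylated / intermediate / methylated (CG, CHG; three-state)
or unmethylated / methylated (CHH; binary at a low cutoff).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CONTEXTS,
    INTERMEDIATE,
    METHYLATED,
    NO_DATA,
    UNMETHYLATED,
    ThresholdConfig,
)

ANNOTATION_PRECEDENCE = ["TE", "exon", "intron", "intergenic"]


def classify_methylation(
    ratio, context: str, config: ThresholdConfig = ThresholdConfig()
):
    """Classify a methylation ratio (scalar or array; NaN -> no_data).

    CG/CHG: ratio <= unmethylated_max -> unmethylated; >= methylated_min ->
    methylated; otherwise intermediate.  CHH is binary: ratio >
    chh_methylated_min -> methylated.
    """
    arr = np.asarray(ratio, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > 1)):
        raise ValueError("methylation ratio outside [0, 1]")
    out = np.full(arr.shape, NO_DATA, dtype=object)
    if context == "CHH":
        out[valid & (arr > config.chh_methylated_min)] = METHYLATED
        out[valid & (arr <= config.chh_methylated_min)] = UNMETHYLATED
    elif context in ("CG", "CHG"):
        out[valid] = INTERMEDIATE
        out[valid & (arr <= config.unmethylated_max)] = UNMETHYLATED
        out[valid & (arr >= config.methylated_min)] = METHYLATED
    else:
        raise ValueError(f"unknown context: {context}")
    return out[0] if scalar else out


def tile_methylome(
    calls: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Aggregate per-cytosine calls into classified fixed-size tiles.

    Tiles partition each chromosome into [k*T, (k+1)*T) windows (the last
    window may be short).  Both strands are pooled.  Per context the output
    carries ``{ctx}_mc``, ``{ctx}_total``, ``{ctx}_ratio`` (NaN when the tile
    has fewer than ``config.min_calls`` informative reads) and
    ``{ctx}_class``.
    """
    ts = config.tile_size
    if len(calls):
        bad = calls[calls["mc_count"] > calls["total_count"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"mc_count > total_count at {r['chrom']}:{r['pos']}"
            )
        for chrom, grp in calls.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"calls on unknown chromosome {chrom}")
            over = grp[grp["pos"] >= chrom_sizes[chrom]]
            if len(over):
                raise ValueError(
                    f"call beyond chromosome end: {chrom}:{int(over['pos'].iloc[0])}"
                    f" >= {chrom_sizes[chrom]}"
                )

    frames = []
    for chrom, L in chrom_sizes.items():
        n = -(-L // ts)
        starts = np.arange(n, dtype=np.int64) * ts
        frames.append(
            pd.DataFrame(
                dict(chrom=chrom, start=starts, end=np.minimum(starts + ts, L))
            )
        )
    tiles = pd.concat(frames, ignore_index=True)

    if len(calls):
        work = calls.copy()
        work["start"] = (work["pos"] // ts) * ts
        sums = (
            work.groupby(["chrom", "start", "context"], observed=True)[
                ["mc_count", "total_count"]
            ]
            .sum()
            .unstack("context")
        )
    else:
        sums = None

    for ctx in CONTEXTS:
        lc = ctx.lower()
        if sums is not None and ("mc_count", ctx) in sums.columns:
            mc = sums[("mc_count", ctx)]
            tot = sums[("total_count", ctx)]
            key = pd.MultiIndex.from_frame(tiles[["chrom", "start"]])
            tiles[f"{lc}_mc"] = mc.reindex(key).fillna(0).to_numpy(dtype=np.int64)
            tiles[f"{lc}_total"] = (
                tot.reindex(key).fillna(0).to_numpy(dtype=np.int64)
            )
        else:
            tiles[f"{lc}_mc"] = 0
            tiles[f"{lc}_total"] = 0
        total = tiles[f"{lc}_total"].to_numpy(dtype=float)
        ratio = np.where(
            total >= max(config.min_calls, 1),
            tiles[f"{lc}_mc"] / np.where(total > 0, total, 1),
            np.nan,
        )
        tiles[f"{lc}_ratio"] = ratio
        tiles[f"{lc}_class"] = classify_methylation(ratio, ctx, config)
    return tiles


def _tile_category(
    tiles: pd.DataFrame, annotations: pd.DataFrame, tile_size: int
) -> pd.Series:
    """Highest-precedence annotation category overlapping each tile."""
    unknown = set(annotations["category"]) - set(ANNOTATION_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    cat = pd.Series("intergenic", index=tiles.index, dtype=object)
    rank = {c: i for i, c in enumerate(ANNOTATION_PRECEDENCE)}
    cur_rank = pd.Series(rank["intergenic"], index=tiles.index)
    tile_lookup = {
        (chrom, int(start)): idx
        for idx, (chrom, start) in enumerate(zip(tiles["chrom"], tiles["start"]))
    }
    for row in annotations.itertuples():
        r = rank[row.category]
        first = (row.start // tile_size) * tile_size
        for start in range(first, row.end, tile_size):
            idx = tile_lookup.get((row.chrom, start))
            if idx is not None and r < cur_rank.iloc[idx]:
                cur_rank.iloc[idx] = r
                cat.iloc[idx] = row.category
    return cat


def coverage_by_annotation(
    tiles: pd.DataFrame,
    annotations: pd.DataFrame,
    min_total: int = 2,
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Per-category coverage and methylation-class proportions.

    Each tile gets the highest-precedence overlapping category
    (TE > exon > intron > intergenic); ``annotations`` needs chrom/start/end/
    category columns.  For every (category, context): the fraction of tiles
    with >= ``min_total`` calls, and U/I/M proportions among covered tiles.
    """
    cat = _tile_category(tiles, annotations, config.tile_size)
    rows = []
    for category in ANNOTATION_PRECEDENCE:
        sub = tiles[cat == category]
        if not len(sub):
            continue
        for ctx in CONTEXTS:
            lc = ctx.lower()
            covered = sub[sub[f"{lc}_total"] >= min_total]
            row = dict(
                category=category,
                context=ctx,
                n_tiles=len(sub),
                prop_covered=len(covered) / len(sub),
            )
            for cls in (UNMETHYLATED, INTERMEDIATE, METHYLATED):
                row[f"prop_{cls}"] = (
                    (covered[f"{lc}_class"] == cls).mean() if len(covered) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
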