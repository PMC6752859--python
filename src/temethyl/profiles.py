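"""Oriented per-family TE metaprofiles of methylation and chromatin.

Every 100 bp tile outside TE bodies is assigned to its single closest TE;
flank tiles within 1 kb of a non-nested element plus its length-normalised
body form a 30-bin oriented profile (10 left-flank + 10 body + 10 right-flank
bins).  Elements are oriented so the flank with higher mean CG methylation is
on the left.  Family metaprofiles average member profiles; H/M/L group
summaries and attribute breakdowns follow the same geometry.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import METHYLATED, ProfileConfig
from .synthetic import cytosine_contexts

log = logging.getLogger(__name__)

DEFAULT_SIGNALS = ["cg_ratio", "chg_ratio", "chh_meth"]

GENE_DISTANCE_BINS = ["overlapping", "<1kb", "1-5kb", ">5kb"]
FAMILY_SIZE_BINS = ["20-50", "50-100", "100-200", ">200"]


def flag_nested(tes: pd.DataFrame) -> pd.DataFrame:
    """Mark elements whose interval lies completely within another element.

    Identical intervals are tie-broken deterministically: the element with
    the shorter (then lexicographically smaller) id is flagged as nested.
    """
    out = tes.reset_index(drop=True).copy()
    nested = np.zeros(len(out), dtype=bool)
    for _, sub in out.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        pos = sub.index.to_numpy()
        for chunk in range(0, len(sub), 2048):
            sl = slice(chunk, chunk + 2048)
            strict = (
                (s[None, :] <= s[sl][:, None])
                & (e[None, :] >= e[sl][:, None])
                & ~((s[None, :] == s[sl][:, None]) & (e[None, :] == e[sl][:, None]))
            )
            nested[pos[sl]] = strict.any(axis=1)
        # identical intervals: exactly one (longest/greatest id) stays outer
        for _, dup in sub.groupby(["start", "end"]):
            if len(dup) > 1:
                keep = sorted(dup["id"], key=lambda x: (len(x), x))[-1]
                for j in dup.index:
                    if dup.loc[j, "id"] != keep:
                        nested[j] = True
    out["nested"] = nested
    return out


def assign_flank_tiles(
    tiles: pd.DataFrame,
    tes: pd.DataFrame,
    config: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Assign each non-TE tile to its closest non-nested TE.

    Tiles overlapping any TE body (nested or not) are excluded.  Distance is
    the edge-to-edge gap; ties go to the TE with the smaller start.  Only
    assignments within ``config.max_flank_distance`` are returned, with the
    flank side relative to the TE.
    """
    cand = tes[~tes["nested"]] if "nested" in tes else tes
    rows = []
    for chrom, tsub in tiles.groupby("chrom"):
        all_te = tes[tes["chrom"] == chrom]
        csub = cand[cand["chrom"] == chrom].sort_values(
            "start", kind="stable"
        )
        if not len(csub):
            continue
        t_start = tsub["start"].to_numpy()
        t_end = tsub["end"].to_numpy()
        # drop tiles overlapping any TE body
        a_s = all_te["start"].to_numpy()
        a_e = all_te["end"].to_numpy()
        overlap = np.zeros(len(tsub), dtype=bool)
        for chunk in range(0, len(tsub), 4096):
            sl = slice(chunk, chunk + 4096)
            overlap[sl] = (
                (t_start[sl][:, None] < a_e[None, :])
                & (a_s[None, :] < t_end[sl][:, None])
            ).any(axis=1)
        keep = ~overlap
        c_s = csub["start"].to_numpy()
        c_e = csub["end"].to_numpy()
        ids = csub["id"].to_numpy()
        ks, ke = t_start[keep], t_end[keep]
        kidx = tsub.index[keep]
        for chunk in range(0, ks.size, 4096):
            sl = slice(chunk, chunk + 4096)
            gap = np.maximum(
                c_s[None, :] - ke[sl][:, None], ks[sl][:, None] - c_e[None, :]
            )
            gap = np.maximum(gap, 0)
            best = gap.argmin(axis=1)  # first minimum -> smallest TE start
            bg = gap[np.arange(gap.shape[0]), best]
            for ti, bi, g in zip(kidx[sl], best, bg):
                if g >= config.max_flank_distance:
                    continue
                side = "left" if tiles.at[ti, "end"] <= c_s[bi] else "right"
                rows.append(
                    dict(
                        chrom=chrom,
                        start=int(tiles.at[ti, "start"]),
                        te_id=ids[bi],
                        distance=int(g),
                        side=side,
                    )
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "te_id", "distance", "side"])


def prepare_signal_tiles(tiles: pd.DataFrame) -> pd.DataFrame:
    """Add the binary CHH signal column (1 if tile class methylated)."""
    out = tiles.copy()
    cls = out["chh_class"]
    out["chh_meth"] = np.where(
        cls == METHYLATED, 1.0, np.where(cls == "no_data", np.nan, 0.0)
    )
    return out


def _oriented_matrix(
    te, tile_values: dict, assignment: pd.DataFrame, signals: list[str],
    config: ProfileConfig,
) -> tuple[np.ndarray, bool]:
    """30-bin x n-signal matrix for one element, plus its flip flag."""
    fb, bb, ts = config.flank_bins, config.body_bins, config.tile_size
    mat = np.full((config.n_bins, len(signals)), np.nan)
    counts = np.zeros((config.n_bins, len(signals)))
    acc = np.zeros((config.n_bins, len(signals)))

    sub = assignment.get(te.id)
    for row in (sub.itertuples() if sub is not None else ()):
        vals = tile_values.get((row.chrom, row.start))
        if vals is None:
            continue
        b = row.distance // ts
        bin_idx = (fb - 1 - b) if row.side == "left" else (fb + bb + b)
        ok = ~np.isnan(vals)
        acc[bin_idx, ok] += vals[ok]
        counts[bin_idx, ok] += 1

    body_len = te.end - te.start
    first = (te.start // ts) * ts
    for start in range(first, te.end, ts):
        vals = tile_values.get((te.chrom, start))
        if vals is None:
            continue
        mid = start + ts / 2
        if not (te.start <= mid < te.end):
            continue
        rel = int((mid - te.start) / body_len * bb)
        bin_idx = fb + min(bb - 1, rel)
        ok = ~np.isnan(vals)
        acc[bin_idx, ok] += vals[ok]
        counts[bin_idx, ok] += 1

    has = counts > 0
    mat[has] = acc[has] / counts[has]
    flipped = orient_matrix_needed(mat, signals, config)
    if flipped:
        mat = mat[::-1]
    return mat, flipped


def orient_matrix_needed(
    mat: np.ndarray, signals: list[str], config: ProfileConfig
) -> bool:
    """Flip iff the downstream 1 kb flank has strictly higher mean CG.

    Requires at least one CG-informative tile on each flank; otherwise the
    genomic orientation is kept.  An exact tie keeps the genomic orientation.
    """
    if "cg_ratio" not in signals:
        return False
    j = signals.index("cg_ratio")
    fb = config.flank_bins
    left = mat[:fb, j]
    right = mat[fb + config.body_bins:, j]
    if np.all(np.isnan(left)) or np.all(np.isnan(right)):
        return False
    return bool(np.nanmean(right) > np.nanmean(left))


def element_profiles(
    tiles: pd.DataFrame,
    tes: pd.DataFrame,
    signals: list[str] | None = None,
    config: ProfileConfig = ProfileConfig(),
    assignment: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """Oriented 30-bin profile matrix per non-nested element."""
    signals = signals or DEFAULT_SIGNALS
    work = prepare_signal_tiles(tiles) if "chh_meth" in signals else tiles
    if assignment is None:
        assignment = assign_flank_tiles(tiles, tes, config)
    tile_values = {
        (c, int(s)): np.array([r[sig] for sig in signals], dtype=float)
        for c, s, r in zip(
            work["chrom"], work["start"], work[signals].to_dict("records")
        )
    }
    by_te = {tid: grp for tid, grp in assignment.groupby("te_id")}
    out = {}
    cand = tes[~tes["nested"]] if "nested" in tes else tes
    for te in cand.itertuples():
        mat, _ = _oriented_matrix(te, tile_values, by_te, signals, config)
        out[te.id] = mat
    return out


def family_profiles(
    tiles: pd.DataFrame,
    tes: pd.DataFrame,
    signals: list[str] | None = None,
    config: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Per-family mean metaprofile over oriented member profiles.

    Families with fewer than ``config.min_members`` non-nested members are
    excluded (logged).  Returns a long table (family, order, bin, signal,
    mean, n) where ``n`` counts members contributing to that bin.
    """
    signals = signals or DEFAULT_SIGNALS
    cand = tes[~tes["nested"]] if "nested" in tes else tes
    profs = element_profiles(tiles, tes, signals, config)
    rows = []
    for family, members in cand.groupby("family"):
        if len(members) < config.min_members:
            log.info(
                "family %s excluded: %d non-nested members < %d",
                family, len(members), config.min_members,
            )
            continue
        stack = np.stack([profs[i] for i in members["id"]])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        order = members["order"].iloc[0]
        for b in range(config.n_bins):
            for j, sig in enumerate(signals):
                rows.append(
                    dict(family=family, order=order, bin=b, signal=sig,
                         mean=mean[b, j], n=int(n[b, j]),
                         n_members=len(members))
                )
    return pd.DataFrame(rows)


def window_cpm(counts: pd.DataFrame, total_reads: int | None = None) -> pd.DataFrame:
    """Counts-per-million normalisation of per-window read counts."""
    total = int(counts["count"].sum()) if total_reads is None else total_reads
    if total <= 0:
        raise ValueError("total mapped reads must be > 0")
    out = counts.copy()
    out["cpm"] = out["count"] / total * 1e6
    return out


def group_profiles(
    tiles: pd.DataFrame,
    tes: pd.DataFrame,
    signals: list[str],
    group_col: str = "group",
    tir_min_len: int = 1000,
    config: ProfileConfig = ProfileConfig(),
) -> pd.DataFrame:
    """Mean oriented profile per H/M/L (or other) group.

    TIR elements shorter than ``tir_min_len`` are excluded, mirroring the
    practice of restricting short non-autonomous DNA transposons when signal
    resolution is ~100 bp.  ``tiles`` must already carry the requested signal
    columns (e.g. a merged ``cpm`` column; see :func:`window_cpm`).
    """
    cand = tes[~tes["nested"]] if "nested" in tes else tes
    short_tir = (cand["order"] == "TIR") & (
        (cand["end"] - cand["start"]) < tir_min_len
    )
    kept = cand[~short_tir]
    rows = []
    profs = element_profiles(tiles, kept, signals, config)
    for group, members in cand.groupby(group_col):
        ids = [i for i in members["id"] if i in profs]
        if not ids:
            log.warning("group %s has no elements after length filter", group)
            continue
        stack = np.stack([profs[i] for i in ids])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        for b in range(config.n_bins):
            for j, sig in enumerate(signals):
                rows.append(
                    dict(group=group, bin=b, signal=sig, mean=mean[b, j],
                         n=int(n[b, j]), n_members=len(ids))
                )
    return pd.DataFrame(rows)


def distance_to_gene(tes: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Edge-to-edge gap to the single closest gene (0 when overlapping).

    Ties go to the gene with the smaller start.  Returns te id, gene id,
    distance and whether the two intervals overlap.
    """
    rows = []
    for chrom, tsub in tes.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom].sort_values("start", kind="stable")
        g_s = gsub["start"].to_numpy()
        g_e = gsub["end"].to_numpy()
        g_id = gsub["id"].to_numpy()
        for te in tsub.itertuples():
            if not len(gsub):
                rows.append(dict(te_id=te.id, gene_id=None,
                                 distance=np.nan, overlapping=False))
                continue
            gap = np.maximum(
                np.maximum(g_s - te.end, te.start - g_e), 0
            )
            j = int(gap.argmin())
            rows.append(
                dict(
                    te_id=te.id,
                    gene_id=g_id[j],
                    distance=int(gap[j]),
                    overlapping=bool(
                        g_s[j] < te.end and te.start < g_e[j]
                    ),
                )
            )
    return pd.DataFrame(rows)


def _gene_distance_bin(distance: float, overlapping: bool) -> str:
    if overlapping:
        return "overlapping"
    if distance < 1000:
        return "<1kb"
    if distance <= 5000:
        return "1-5kb"
    return ">5kb"


def _family_size_bin(n: int) -> str:
    if n < 50:
        return "20-50"
    if n < 100:
        return "50-100"
    if n < 200:
        return "100-200"
    return ">200"


def attribute_summary(
    tes: pd.DataFrame,
    genes: pd.DataFrame,
    rpm_table: pd.DataFrame | None = None,
    group_col: str = "group",
) -> dict[str, pd.DataFrame]:
    """Attribute breakdowns per group (superfamily, gene distance, family
    size, length, expression).

    Proportion facets each sum to 1 per group.  ``rpm_table`` is a family x
    tissue RPM matrix (index or ``family`` column); a family is expressed
    when any tissue exceeds RPM 1.
    """
    work = tes.copy()
    dist = distance_to_gene(work, genes).set_index("te_id")
    work["gene_bin"] = [
        _gene_distance_bin(dist.at[i, "distance"], dist.at[i, "overlapping"])
        for i in work["id"]
    ]
    fam_sizes = work.groupby("family")["id"].count()
    work["size_bin"] = [
        _family_size_bin(int(fam_sizes[f])) for f in work["family"]
    ]
    out: dict[str, pd.DataFrame] = {}
    out["superfamily"] = _proportions(work, group_col, "superfamily")
    out["gene_distance"] = _proportions(work, group_col, "gene_bin")
    out["family_size"] = _proportions(work, group_col, "size_bin")
    lengths = work.assign(length=work["end"] - work["start"])
    out["length"] = (
        lengths.groupby(group_col)["length"]
        .describe()[["count", "mean", "50%", "min", "max"]]
        .rename(columns={"50%": "median"})
        .reset_index()
    )
    if rpm_table is not None:
        rpm = rpm_table.set_index("family") if "family" in rpm_table else rpm_table
        expressed = (rpm > 1).any(axis=1)
        fam = work[["family", group_col]].drop_duplicates()
        fam["expressed"] = [
            bool(expressed.get(f, False)) for f in fam["family"]
        ]
        out["expression"] = (
            fam.groupby(group_col)["expressed"].mean().rename(
                "prop_expressed"
            ).reset_index()
        )
    return out


def _proportions(df: pd.DataFrame, group_col: str, facet: str) -> pd.DataFrame:
    counts = df.groupby([group_col, facet], observed=True)["id"].count()
    prop = counts / counts.groupby(level=0).transform("sum")
    return prop.rename("proportion").reset_index()


def cytosine_density(
    genome: dict[str, str],
    tes: pd.DataFrame,
    group_col: str = "group",
    flank_extent: int = 1000,
) -> pd.DataFrame:
    """Mean cytosine sites per 100 bp, per context, for flanks and body."""
    ctx_names = np.array(["CG", "CHG", "CHH"])
    site_maps = {}
    for chrom, seq in genome.items():
        pos, _, ctx = cytosine_contexts(seq)
        site_maps[chrom] = (pos, ctx)
    rows = []
    cand = tes[~tes["nested"]] if "nested" in tes else tes
    for group, members in cand.groupby(group_col):
        acc = {("flank", c): [] for c in ctx_names}
        acc.update({("body", c): [] for c in ctx_names})
        for te in members.itertuples():
            pos, ctx = site_maps[te.chrom]
            for region, lo, hi in (
                ("flank", te.start - flank_extent, te.start),
                ("flank", te.end, te.end + flank_extent),
                ("body", te.start, te.end),
            ):
                lo = max(lo, 0)
                if hi <= lo:
                    continue
                sel = ctx[(pos >= lo) & (pos < hi)]
                for ci, cname in enumerate(ctx_names):
                    acc[(region, cname)].append(
                        np.sum(sel == ci) / (hi - lo) * 100
                    )
        for (region, cname), vals in acc.items():
            rows.append(
                dict(group=group, region=region, context=cname,
                     sites_per_100bp=float(np.mean(vals)) if vals else np.nan)
            )
    return pd.DataFrame(rows)
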