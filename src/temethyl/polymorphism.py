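"""Site-defined TE presence/absence calling between haplotype genomes.

For every annotated TE, two 400 bp flank tags are extracted (centred on the
element's start and end, 200 bp outside + 200 bp inside each boundary) and
placed within a search window of the other genome bounded by the nearest
flanking genes with syntelogs.  A non-shared, site-defined call requires both
tags to place uniquely with the clipped (inside) portion not matching
contiguously, and the left/right junctions to lie within twice the
superfamily's TSD length of each other.  Comparing the element-flanking TSD
copies against the empty-site sequence classifies each event as an
insertion (both copies match), a putative excision (neither matches) or
unknown (one matches, or TSD length 0).

Built-in placement is exact anchored extension: the outermost ``anchor_len``
bases of a tag's outside half must occur exactly once in the window; the
match is then extended inward base by base, so a junction is located even
when the empty site lacks the TSD copy carried by the tag (the excision
case).  Precomputed SAM alignments of the tags can be interpreted under the
same contract instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_TSD_TABLE

TAG_HALF = 200

STATUS_SHARED = "shared"
STATUS_NON_SHARED = "non_shared_site_defined"
STATUS_UNRESOLVED = "unresolved"

EVENT_INSERTION = "insertion"
EVENT_EXCISION = "putative_excision"
EVENT_UNKNOWN = "unknown"


@dataclass(frozen=True)
class FlankTagPair:
    te_id: str
    left_tag: str
    right_tag: str
    left_truncated: bool = False
    right_truncated: bool = False
    inside_overlap: bool = False  # element shorter than the inside half


@dataclass(frozen=True)
class SearchWindow:
    te_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Placement:
    found: bool
    unique: bool
    outer_pos: int = -1       # window-local start of the outer anchor match
    flank_match: int = 0      # matched bases of the outside half (<= TAG_HALF)
    inside_match: int = 0     # contiguous match extending into the inside half
    junction: int = -1        # window-local junction coordinate


@dataclass
class PolymorphicSite:
    te_id: str
    status: str
    chrom: str = ""
    empty_site: int = -1
    gap: int = -1
    tsd_len: int = 0
    left_tsd_seq: str = ""
    right_tsd_seq: str = ""
    left_site_seq: str = ""
    right_site_seq: str = ""
    event_class: str = EVENT_UNKNOWN
    note: str = ""


def extract_flank_tags(te, genome: dict[str, str]) -> FlankTagPair:
    """Extract the two 400 bp flank tags of one annotated element.

    The left tag spans [start-200, start+200), the right tag
    [end-200, end+200); truncation at a chromosome end is flagged, as is an
    element shorter than 200 bp (whose inside tag portions overlap).
    """
    seq = genome[te.chrom]
    if not (0 <= te.start < te.end <= len(seq)):
        raise ValueError(f"TE {te.id} outside genome bounds")
    l0, l1 = te.start - TAG_HALF, te.start + TAG_HALF
    r0, r1 = te.end - TAG_HALF, te.end + TAG_HALF
    return FlankTagPair(
        te_id=te.id,
        left_tag=seq[max(0, l0):min(len(seq), l1)],
        right_tag=seq[max(0, r0):min(len(seq), r1)],
        left_truncated=l0 < 0 or l1 > len(seq),
        right_truncated=r0 < 0 or r1 > len(seq),
        inside_overlap=(te.end - te.start) < TAG_HALF,
    )


def define_search_window(
    te,
    query_genes: pd.DataFrame,
    target_genes: pd.DataFrame,
    synteny: pd.DataFrame,
) -> SearchWindow | None:
    """Window between the target syntelogs of the nearest flanking genes.

    The nearest non-overlapping query gene on each side of the TE must have a
    syntelog in the target genome; otherwise the site is unresolved (None).
    The window spans from the leftmost to the rightmost coordinate of the two
    target genes, so it always contains the projected locus.
    """
    syn = dict(zip(synteny["query_gene"], synteny["target_gene"]))
    tg = target_genes.set_index("id")
    qsub = query_genes[query_genes["chrom"] == te.chrom]
    up = qsub[qsub["end"] <= te.start].sort_values("end")
    dn = qsub[qsub["start"] >= te.end].sort_values("start")
    up_t = next(
        (syn[g] for g in reversed(up["id"].tolist()) if g in syn and syn[g] in tg.index),
        None,
    )
    dn_t = next(
        (syn[g] for g in dn["id"] if g in syn and syn[g] in tg.index), None
    )
    if up_t is None or dn_t is None:
        return None
    a, b = tg.loc[up_t], tg.loc[dn_t]
    if a["chrom"] != b["chrom"]:
        return None
    return SearchWindow(
        te_id=te.id,
        chrom=a["chrom"],
        start=int(min(a["start"], b["start"])),
        end=int(max(a["end"], b["end"])),
    )


def _occurrences(needle: str, haystack: str, limit: int = 3) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1 and len(out) < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def place_tag(
    tag: str, window_seq: str, side: str, anchor_len: int = 100
) -> Placement:
    """Place one flank tag in a window by anchored exact extension.

    The outermost ``anchor_len`` bases of the tag (its start for the left
    tag, its end for the right tag) must occur exactly once in the window;
    the match is then extended toward the element base by base.  The matched
    flank portion is capped at the 200 bp outside half; any contiguous match
    beyond it is reported as ``inside_match`` (the not-soft-clipped TE-side
    span, which must stay small for a non-shared call).
    """
    if len(window_seq) < anchor_len or len(tag) < anchor_len:
        raise ValueError("window shorter than the tag anchor")
    if side == "left":
        anchor = tag[:anchor_len]
    elif side == "right":
        anchor = tag[-anchor_len:]
    else:
        raise ValueError("side must be 'left' or 'right'")
    occ = _occurrences(anchor, window_seq)
    if not occ:
        return Placement(found=False, unique=False)
    if len(occ) > 1:
        return Placement(found=True, unique=False)
    pos = occ[0]
    if side == "left":
        i = anchor_len
        while pos + i < len(window_seq) and i < len(tag) and \
                window_seq[pos + i] == tag[i]:
            i += 1
        flank = min(i, TAG_HALF)
        return Placement(
            found=True, unique=True, outer_pos=pos, flank_match=flank,
            inside_match=max(0, i - TAG_HALF), junction=pos + flank,
        )
    i = anchor_len
    # extend leftward: tag[-(i+1)] against window_seq[pos + anchor_len - i - 1]
    while pos + anchor_len - i - 1 >= 0 and i < len(tag) and \
            window_seq[pos + anchor_len - i - 1] == tag[-(i + 1)]:
        i += 1
    flank = min(i, TAG_HALF)
    return Placement(
        found=True, unique=True, outer_pos=pos, flank_match=flank,
        inside_match=max(0, i - TAG_HALF),
        junction=pos + anchor_len - flank,
    )


def place_tags(
    pair: FlankTagPair, window_seq: str, anchor_len: int = 100
) -> tuple[Placement, Placement]:
    left = place_tag(pair.left_tag, window_seq, "left", anchor_len)
    right = place_tag(pair.right_tag, window_seq, "right", anchor_len)
    return left, right


def call_site_defined_polymorphism(
    te_id: str,
    left: Placement,
    right: Placement,
    tsd_len: int,
    window: SearchWindow,
    window_seq: str,
    *,
    shared_min_inside: int = 50,
) -> PolymorphicSite:
    """Resolve two tag placements into a polymorphism status.

    Both tags present with the full element (inside halves matching
    contiguously) mean the TE is shared.  A non-shared site-defined call
    requires unique placements of both tags and an absolute junction gap
    below twice the superfamily TSD length (a zero-length TSD only admits a
    zero gap).  Everything else is unresolved.
    """
    if not (left.found and right.found):
        return PolymorphicSite(te_id, STATUS_UNRESOLVED, note="tag not found")
    if not (left.unique and right.unique):
        return PolymorphicSite(te_id, STATUS_UNRESOLVED, note="non-unique tag")
    if (left.inside_match >= shared_min_inside
            and right.inside_match >= shared_min_inside):
        return PolymorphicSite(te_id, STATUS_SHARED, chrom=window.chrom)
    if left.inside_match >= shared_min_inside or \
            right.inside_match >= shared_min_inside:
        return PolymorphicSite(
            te_id, STATUS_UNRESOLVED, note="one-sided element match"
        )
    gap = abs(right.junction - left.junction)
    ok = gap < 2 * tsd_len or (tsd_len == 0 and gap == 0)
    if not ok:
        return PolymorphicSite(
            te_id, STATUS_UNRESOLVED, tsd_len=tsd_len, gap=gap,
            note="junction gap >= 2x TSD length",
        )
    lo = min(left.junction, right.junction)
    hi = max(left.junction, right.junction)
    return PolymorphicSite(
        te_id=te_id,
        status=STATUS_NON_SHARED,
        chrom=window.chrom,
        empty_site=window.start + (lo + hi) // 2,
        gap=gap,
        tsd_len=tsd_len,
        left_site_seq=window_seq[left.junction - tsd_len:left.junction]
        if tsd_len else "",
        right_site_seq=window_seq[right.junction:right.junction + tsd_len]
        if tsd_len else "",
    )


def classify_event_by_tsd(site: PolymorphicSite) -> str:
    """Insertion / putative excision / unknown from TSD-vs-empty-site match.

    Both element-flanking TSD copies matching the empty-site sequence mean
    the site never carried the element (an insertion); neither matching means
    the element and its target-site duplication were removed (a putative
    excision); exactly one matching — or a zero-length TSD — is unknown.
    """
    if site.tsd_len == 0:
        return EVENT_UNKNOWN
    left_match = site.left_tsd_seq == site.left_site_seq
    right_match = site.right_tsd_seq == site.right_site_seq
    if left_match and right_match:
        return EVENT_INSERTION
    if not left_match and not right_match:
        return EVENT_EXCISION
    return EVENT_UNKNOWN


def call_polymorphisms(
    query_genome: dict[str, str],
    query_tes: pd.DataFrame,
    query_genes: pd.DataFrame,
    target_genome: dict[str, str],
    target_genes: pd.DataFrame,
    synteny: pd.DataFrame,
    tsd_table: dict[str, int] | None = None,
    anchor_len: int = 100,
) -> pd.DataFrame:
    """Call presence/absence for every query TE against a target genome.

    Returns one row per query element: status, empty-site coordinate on the
    target, junction gap, TSD length and sequences, and the event class.
    """
    tsd_table = DEFAULT_TSD_TABLE if tsd_table is None else tsd_table
    rows = []
    for te in query_tes.itertuples():
        tsd = int(tsd_table.get(te.superfamily, 5))
        pair = extract_flank_tags(te, query_genome)
        if pair.left_truncated or pair.right_truncated:
            site = PolymorphicSite(te.id, STATUS_UNRESOLVED, note="tag truncated")
        else:
            window = define_search_window(te, query_genes, target_genes, synteny)
            if window is None:
                site = PolymorphicSite(
                    te.id, STATUS_UNRESOLVED, note="no flanking syntelogs"
                )
            else:
                wseq = target_genome[window.chrom][window.start:window.end]
                left, right = place_tags(pair, wseq, anchor_len)
                site = call_site_defined_polymorphism(
                    te.id, left, right, tsd, window, wseq
                )
        if site.status == STATUS_NON_SHARED and tsd > 0:
            qseq = query_genome[te.chrom]
            site.left_tsd_seq = qseq[te.start - tsd:te.start]
            site.right_tsd_seq = qseq[te.end:te.end + tsd]
        site.event_class = (
            classify_event_by_tsd(site)
            if site.status == STATUS_NON_SHARED
            else ""
        )
        rows.append(
            dict(
                te_id=site.te_id, status=site.status, chrom=site.chrom,
                empty_site=site.empty_site, gap=site.gap,
                tsd_len=site.tsd_len if site.status == STATUS_NON_SHARED else tsd,
                left_tsd_seq=site.left_tsd_seq,
                right_tsd_seq=site.right_tsd_seq,
                event_class=site.event_class, note=site.note,
                family=getattr(te, "family", ""),
                superfamily=getattr(te, "superfamily", ""),
            )
        )
    return pd.DataFrame(rows)


def placements_from_sam(
    sam_path: str, anchor_len: int = 100
) -> dict[str, dict[str, Placement]]:
    """Interpret precomputed flank-tag alignments (SAM) as placements.

    Reads must be named ``<te_id>/L`` and ``<te_id>/R``.  A tag is uniquely
    placed when exactly one mapped, forward-strand record exists for it; the
    soft-clipped portion is read from the CIGAR, the matched flank span is
    capped at the 200 bp outside half and any aligned extension into the
    inside half is reported, exactly as for built-in placement.  Junction
    coordinates are reference coordinates (use a window starting at 0 or
    shift accordingly).
    """
    import pysam

    hits: dict[str, list] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            hits.setdefault(rec.query_name, []).append(
                (rec.reference_start, rec.query_alignment_start,
                 rec.query_alignment_end, rec.is_reverse,
                 rec.infer_read_length() or 2 * TAG_HALF)
            )
    out: dict[str, dict[str, Placement]] = {}
    for name, recs in hits.items():
        te_id, _, side_code = name.rpartition("/")
        side = "left" if side_code == "L" else "right"
        entry = out.setdefault(te_id, {})
        if len(recs) != 1 or recs[0][3]:
            entry[side] = Placement(found=True, unique=False)
            continue
        ref_start, q0, q1, _, read_len = recs[0]
        if side == "left":
            flank = max(0, min(q1, TAG_HALF) - q0)
            inside = max(0, q1 - TAG_HALF)
            junction = ref_start + (TAG_HALF - q0) if q0 <= TAG_HALF else ref_start
        else:
            inside_half = read_len - TAG_HALF
            flank = max(0, q1 - max(q0, inside_half))
            inside = max(0, inside_half - q0)
            junction = ref_start + max(0, inside_half - q0)
        entry[side] = Placement(
            found=True, unique=True, outer_pos=ref_start,
            flank_match=flank, inside_match=inside, junction=junction,
        )
    return out
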