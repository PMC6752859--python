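"""Synthetic genomes, methylomes and TE polymorphisms with known ground truth.

The generator produces the inputs every downstream stage consumes:

* a reference genome with non-overlapping genes and TE families (optionally
  nested),
* per-cytosine bisulfite-style calls whose flanking-methylation structure
  follows configurable family archetypes (high / moderate / low flanking
  methylation, with optional insertion-triggered spreading),
* a haplotype pair differing by implanted TE insertions and excisions with
  superfamily-specific target-site duplications (TSDs),
* per-100 bp-window chromatin read counts.

All randomness flows through :func:`numpy.random.default_rng` seeded from the
caller, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_TSD_TABLE

log = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])

TRUTH_COLUMNS = [
    "te_id", "chrom", "ref_pos", "event", "family", "superfamily", "order",
    "te_len", "tsd_len", "tsd_seq", "bg_state", "spread_left", "spread_right",
    "present_start", "present_end", "absent_pos",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Size and composition of one synthetic genome."""

    n_chroms: int = 1
    chrom_len: int = 100_000
    gc_content: float = 0.46
    n_genes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_len < 10_000:
            raise ValueError("chrom_len must be >= 10000")
        if self.n_chroms < 1 or self.n_genes < 0:
            raise ValueError("n_chroms must be >= 1 and n_genes >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class TEFamilyConfig:
    """One TE family to place in the reference genome."""

    name: str
    superfamily: str = "RLG"
    n_members: int = 20
    min_len: int = 800
    max_len: int = 1500
    nested_fraction: float = 0.0

    @property
    def order(self) -> str:
        return order_of(self.superfamily)


@dataclass(frozen=True)
class FamilyArchetype:
    """Methylation behaviour of a TE family.

    CG/CHG probability is ``body_level`` inside the element and decays with
    distance d from the edge as ``plateau + (body - plateau) * exp(-d /
    decay_length)`` in the 1 kb flanks.  CHH gets an edge peak of height
    ``chh_edge_peak`` within 200 bp of each edge.  When
    ``flank_follows_background`` is set the decay model is skipped and flanks
    keep the background state unless a spreading overlay raises them — the
    mode used for implanted polymorphic elements, where the flank state is
    the experiment's readout rather than a family trait.
    """

    label: str
    body_level: float = 0.85
    flank_plateau: float = 0.05
    decay_length: float = 150.0
    chh_edge_peak: float = 0.0
    spread_probability: float = 0.0
    flank_follows_background: bool = False

    def __post_init__(self) -> None:
        for name in ("body_level", "flank_plateau", "chh_edge_peak",
                     "spread_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def flank_p(self, d: np.ndarray) -> np.ndarray:
        """Closed-form flanking CG/CHG level at distance ``d`` (bp) from the edge."""
        return self.flank_plateau + (
            self.body_level - self.flank_plateau
        ) * np.exp(-np.asarray(d, dtype=float) / self.decay_length)


#: Default H/M/L archetypes: identical high body methylation, flank plateaus
#: ordered H > M > L.  The low-flank archetype carries the strongest CHH edge
#: peak, mirroring RdDM activity at TEs bordering open chromatin.
DEFAULT_ARCHETYPES: dict[str, FamilyArchetype] = {
    "H": FamilyArchetype("H", 0.85, 0.85, 200.0, chh_edge_peak=0.04),
    "M": FamilyArchetype("M", 0.85, 0.40, 200.0, chh_edge_peak=0.08),
    "L": FamilyArchetype("L", 0.85, 0.05, 150.0, chh_edge_peak=0.15),
}

#: Archetype for implanted polymorphic elements: methylated body, flanks left
#: to the background unless spreading is triggered.
INSERTION_ARCHETYPE = FamilyArchetype(
    "insertion", 0.85, 0.05, 150.0, chh_edge_peak=0.10,
    flank_follows_background=True,
)


@dataclass(frozen=True)
class MethylationLevels:
    """Background methylation levels per context.

    The non-TE, non-gene background is a two-component mixture of mostly
    methylated sequence and a minority of unmethylated patches, which gives
    tile-level CG/CHG distributions their characteristic bimodality.
    """

    bg_meth_cg: float = 0.80
    bg_meth_chg: float = 0.70
    bg_unmeth: float = 0.05
    chh_background: float = 0.01
    chh_body: float = 0.05


def order_of(superfamily: str) -> str:
    if superfamily.startswith("RL"):
        return "LTR"
    if superfamily.startswith("DT"):
        return "TIR"
    return "other"


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


class PlacementError(ValueError):
    """Raised when a chromosome is too short to host the requested features."""


class _Occupancy:
    """Sorted interval set supporting padded rejection sampling."""

    def __init__(self) -> None:
        self._starts: list[int] = []
        self._ends: list[int] = []

    def add(self, start: int, end: int) -> None:
        i = bisect_left(self._starts, start)
        self._starts.insert(i, start)
        self._ends.insert(i, end)

    def clashes(self, start: int, end: int) -> bool:
        i = bisect_left(self._starts, end)
        if i < len(self._starts) and self._starts[i] < end:
            return True
        if i > 0 and self._ends[i - 1] > start:
            return True
        # neighbours on either side
        if i < len(self._starts) and self._starts[i] < end:
            return True
        return False

    def place(self, rng, lo: int, hi: int, length: int, pad: int,
              tries: int = 400) -> int:
        if hi - lo < length:
            raise PlacementError("chromosome too short to host requested features")
        for _ in range(tries):
            start = int(rng.integers(lo, hi - length + 1))
            if not self.clashes(start - pad, start + length + pad):
                self.add(start, start + length)
                return start
        raise PlacementError("chromosome too short to host requested features")


def generate_reference(
    spec: GenomeSpec,
    families: list[TEFamilyConfig] | None = None,
    *,
    te_spacing: int = 2100,
    gene_pad: int = 300,
    edge_margin: int = 2000,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate a reference genome with gene and TE annotations.

    Genes are placed on a jittered regular grid (guaranteeing flanking genes
    for polymorphism search windows); non-nested TEs are rejection-sampled
    into the remaining space with ``te_spacing`` bp of clearance so 1 kb
    flanks stay unambiguous; nested members are dropped inside previously
    placed hosts of the same genome.

    Returns ``(genome, genes, tes)`` with 0-based half-open coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    gene_rows: list[dict] = []
    te_rows: list[dict] = []
    families = families or []

    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        L = spec.chrom_len
        genome[chrom] = random_sequence(rng, L, spec.gc_content)
        occ = _Occupancy()

        if spec.n_genes > 0:
            usable = L - 2 * edge_margin
            slot = usable / spec.n_genes
            for gi in range(spec.n_genes):
                glen = int(rng.integers(400, min(1200, max(401, int(slot * 0.6)))))
                lo = edge_margin + int(gi * slot)
                start = lo + int(rng.integers(0, max(1, int(slot) - glen)))
                occ.add(start, start + glen)
                gene_rows.append(
                    dict(chrom=chrom, start=start, end=start + glen,
                         id=f"{chrom}_gene{gi:04d}",
                         strand="+" if rng.random() < 0.5 else "-")
                )

        hosts: list[tuple[int, int]] = []  # non-nested TEs usable as nest hosts
        for fam in families:
            n_nested = int(round(fam.n_members * fam.nested_fraction))
            for mi in range(fam.n_members):
                tlen = int(rng.integers(fam.min_len, fam.max_len + 1))
                nested = mi < n_nested
                if nested:
                    cands = [h for h in hosts if h[1] - h[0] >= tlen + 40]
                    if not cands:
                        nested = False
                if nested:
                    hs, he = cands[int(rng.integers(len(cands)))]
                    start = hs + int(rng.integers(10, he - hs - tlen - 10))
                else:
                    start = occ.place(rng, edge_margin, L - edge_margin,
                                      tlen, pad=max(te_spacing, gene_pad))
                    hosts.append((start, start + tlen))
                te_rows.append(
                    dict(chrom=chrom, start=start, end=start + tlen,
                         id=f"{chrom}_{fam.name}_{mi:04d}",
                         strand="+" if rng.random() < 0.5 else "-",
                         order=fam.order, superfamily=fam.superfamily,
                         family=fam.name, nested=nested)
                )

    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "id", "strand"]
    )
    tes = pd.DataFrame(
        te_rows,
        columns=["chrom", "start", "end", "id", "strand", "order",
                 "superfamily", "family", "nested"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genome, genes, tes


def draw_background(
    chrom_sizes: dict[str, int],
    seed: int,
    *,
    meth_weight: float = 0.7,
    mean_patch_len: float = 3000.0,
    min_patch_len: int = 300,
) -> pd.DataFrame:
    """Draw the two-state background patch map (methylated vs unmethylated).

    Patch lengths are exponential with mean ``mean_patch_len`` (floored at
    ``min_patch_len``); states are i.i.d. Bernoulli(``meth_weight``) for the
    methylated state.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, L in chrom_sizes.items():
        pos = 0
        while pos < L:
            ln = int(max(min_patch_len, rng.exponential(mean_patch_len)))
            end = min(L, pos + ln)
            state = "methylated" if rng.random() < meth_weight else "unmethylated"
            rows.append(dict(chrom=chrom, start=pos, end=end, state=state))
            pos = end
    return pd.DataFrame(rows)


def _background_state_at(background: pd.DataFrame, chrom: str, pos: int) -> str:
    sub = background[background["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    return hit.iloc[0]["state"] if len(hit) else "methylated"


def simulate_methylome(
    genome: dict[str, str],
    tes: pd.DataFrame,
    archetypes: dict[str, FamilyArchetype],
    *,
    depth: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    levels: MethylationLevels = MethylationLevels(),
    flank_extent: int = 1000,
    chh_edge_extent: int = 200,
    spread_extent: int = 300,
) -> pd.DataFrame:
    """Simulate per-cytosine methylation calls for one haplotype.

    For each cytosine the methylated count is Binomial(``depth``, p) where p
    is ``body_level`` inside TEs, follows the archetype's exponential flank
    decay within ``flank_extent`` of non-nested TE edges, and is the
    background level elsewhere.  CHH receives an edge peak within
    ``chh_edge_extent`` of TE edges.  TE rows may carry boolean
    ``spread_left`` / ``spread_right`` columns; flagged flanks are raised to
    ``body_level`` over ``spread_extent`` bp.  ``noise_sd`` adds truncated
    Gaussian jitter to p per cytosine.

    Returns a calls table (chrom, pos, strand, context, mc_count,
    total_count) sorted by position.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    unknown = set(tes["family"]) - set(archetypes)
    if unknown:
        raise ValueError(f"no archetype for families: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, seq in genome.items():
        L = len(seq)
        p_cg = np.full(L, levels.bg_unmeth)
        p_chg = np.full(L, levels.bg_unmeth)
        p_chh = np.full(L, levels.chh_background)
        if background is not None:
            for row in background[background["chrom"] == chrom].itertuples():
                if row.state == "methylated":
                    p_cg[row.start:row.end] = levels.bg_meth_cg
                    p_chg[row.start:row.end] = levels.bg_meth_chg
        if genes is not None:
            for row in genes[genes["chrom"] == chrom].itertuples():
                p_cg[row.start:row.end] = levels.bg_unmeth
                p_chg[row.start:row.end] = levels.bg_unmeth
                p_chh[row.start:row.end] = levels.chh_background

        ctes = tes[tes["chrom"] == chrom]
        nested_col = ctes["nested"] if "nested" in ctes else pd.Series(
            False, index=ctes.index
        )
        # flank decay first (non-nested only), then bodies override
        for row, nested in zip(ctes.itertuples(), nested_col):
            arch = archetypes[row.family]
            if nested or arch.flank_follows_background:
                continue
            dl = np.arange(1, min(flank_extent, row.start) + 1)
            if dl.size:
                vals = arch.flank_p(dl)
                p_cg[row.start - dl] = vals
                p_chg[row.start - dl] = vals
            dr = np.arange(1, min(flank_extent, L - row.end) + 1)
            if dr.size:
                vals = arch.flank_p(dr)
                p_cg[row.end + dr - 1] = vals
                p_chg[row.end + dr - 1] = vals
        for row in ctes.itertuples():
            arch = archetypes[row.family]
            p_cg[row.start:row.end] = arch.body_level
            p_chg[row.start:row.end] = arch.body_level
            p_chh[row.start:row.end] = levels.chh_body
            if arch.chh_edge_peak > 0:
                for edge in (row.start, row.end):
                    lo = max(0, edge - chh_edge_extent)
                    hi = min(L, edge + chh_edge_extent)
                    p_chh[lo:hi] = np.maximum(p_chh[lo:hi], arch.chh_edge_peak)
        # spreading overlay (per-flank flags set by the implanter)
        for row in ctes.itertuples():
            arch = archetypes[row.family]
            if getattr(row, "spread_left", False) == True:  # noqa: E712 (NaN-safe)
                lo = max(0, row.start - spread_extent)
                p_cg[lo:row.start] = arch.body_level
                p_chg[lo:row.start] = arch.body_level
            if getattr(row, "spread_right", False) == True:  # noqa: E712
                hi = min(L, row.end + spread_extent)
                p_cg[row.end:hi] = arch.body_level
                p_chg[row.end:hi] = arch.body_level

        pos, strand, ctx = cytosine_contexts(seq)
        p = np.empty(pos.size)
        for code, arr in ((0, p_cg), (1, p_chg), (2, p_chh)):
            m = ctx == code
            p[m] = arr[pos[m]]
        if noise_sd > 0:
            p = np.clip(p + rng.normal(0.0, noise_sd, size=p.size), 0.0, 1.0)
        mc = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                dict(
                    chrom=chrom,
                    pos=pos,
                    strand=np.where(strand, "+", "-"),
                    context=np.array(["CG", "CHG", "CHH"])[ctx],
                    mc_count=mc,
                    total_count=depth,
                )
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return calls.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def cytosine_contexts(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, strands and contexts of every cytosine in ``seq``.

    Returns (pos, is_plus, ctx_code) with ctx codes 0=CG, 1=CHG, 2=CHH.
    Cytosines within 2 bp of the chromosome end fall back to CHH.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    nxt1 = np.concatenate([is_g[1:], [False]])
    nxt2 = np.concatenate([is_g[2:], [False, False]])
    prv1 = np.concatenate([[False], is_c[:-1]])
    prv2 = np.concatenate([[False, False], is_c[:-2]])

    plus_pos = np.flatnonzero(is_c)
    plus_ctx = np.where(nxt1[plus_pos], 0, np.where(nxt2[plus_pos], 1, 2))
    minus_pos = np.flatnonzero(is_g)
    minus_ctx = np.where(prv1[minus_pos], 0, np.where(prv2[minus_pos], 1, 2))

    pos = np.concatenate([plus_pos, minus_pos])
    strand = np.concatenate(
        [np.ones(plus_pos.size, bool), np.zeros(minus_pos.size, bool)]
    )
    ctx = np.concatenate([plus_ctx, minus_ctx])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], ctx[order]


def archetype_flank_features(
    n_per_archetype: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    archetypes: dict[str, FamilyArchetype] | None = None,
    flank_bins: int = 10,
    tile_size: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Family flank feature vectors drawn directly from archetype curves.

    Each family's 40 features (20 CG + 20 CHG oriented flank bins) are the
    closed-form per-bin means of its archetype's flank decay curve plus
    i.i.d. Gaussian bin noise, clipped to [0, 1].  Returns (vectors, truth
    labels); column names and bin order match
    :func:`temethyl.clustering.family_feature_vectors`.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)
    bin_means = {}
    for label, arch in archetypes.items():
        vals = [
            arch.flank_p(np.arange(b * tile_size + 1, (b + 1) * tile_size + 1)).mean()
            for b in range(flank_bins)
        ]  # vals[0] = nearest bin
        left = vals[::-1]               # oriented: bin 0 farthest ... 9 nearest
        right = vals                    # bin 10 nearest ... 19 farthest
        bin_means[label] = np.array(left + right)
    rows, labels, names = [], [], []
    for label in archetypes:
        for i in range(n_per_archetype):
            base = np.concatenate([bin_means[label], bin_means[label]])
            noisy = np.clip(base + rng.normal(0, noise_sd, base.size), 0, 1)
            rows.append(noisy)
            labels.append(label)
            names.append(f"fam_{label}_{i:03d}")
    cols = [f"cg_flank_{i:02d}" for i in range(2 * flank_bins)] + [
        f"chg_flank_{i:02d}" for i in range(2 * flank_bins)
    ]
    vectors = pd.DataFrame(rows, index=names, columns=cols)
    return vectors, pd.Series(labels, index=names, name="archetype")


# ---------------------------------------------------------------------------
# polymorphism implantation


def make_donor_library(
    families: list[TEFamilyConfig], seed: int, *, gc: float = 0.46
) -> pd.DataFrame:
    """Random donor element sequences, one per family (re-used across events)."""
    rng = np.random.default_rng(seed)
    rows = []
    for fam in families:
        tlen = int(rng.integers(fam.min_len, fam.max_len + 1))
        rows.append(
            dict(family=fam.name, superfamily=fam.superfamily,
                 order=fam.order, seq=random_sequence(rng, tlen, gc))
        )
    return pd.DataFrame(rows)


def _unambiguous_excision_site(ref: str, pos: int, tsd: int) -> bool:
    """True when the empty-site junction left by an excision is unambiguous.

    Ground truth requires that (a) exact-extension placement stops exactly at
    the junction on both sides and (b) neither empty-site sequence window
    coincidentally equals the TSD, so the event is classifiable from sequence
    alone.
    """
    if tsd == 0:
        return True
    tsd_seq = ref[pos - tsd:pos]
    if ref[pos] == ref[pos - tsd]:
        return False
    if ref[pos - 1] == ref[pos - tsd - 1]:
        return False
    if ref[pos:pos + tsd] == tsd_seq:
        return False
    if ref[pos - 2 * tsd:pos - tsd] == tsd_seq:
        return False
    return True


def implant_te_polymorphisms(
    reference: dict[str, str],
    donors: pd.DataFrame,
    n_insertions: int,
    *,
    tsd_table: dict[str, int] | None = None,
    excision_fraction: float = 0.0,
    seed: int = 0,
    genes: pd.DataFrame | None = None,
    existing_tes: pd.DataFrame | None = None,
    background: pd.DataFrame | None = None,
    p_unmethylated: dict[str, float] | float | None = None,
    spread_probability: float = 0.0,
    min_spacing: int = 2500,
    edge_margin: int = 2000,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Create a haplotype pair differing by implanted TE polymorphisms.

    ``n_insertions`` events are drawn from ``donors``; a fraction
    ``excision_fraction`` of them are excision events.  An insertion
    duplicates the ``tsd_len`` bases left of the insertion point on both
    sides of the element in the *present* haplotype.  An excision leaves the
    element (with both TSD copies) in the present haplotype but removes the
    TSD from the *absent* haplotype, so neither TSD copy matches at the empty
    site.  Event positions avoid genes, existing TEs and each other by
    ``min_spacing`` and are re-sampled until the junction is sequence-
    unambiguous, so the returned truth table is exact.

    When ``background`` is given, ``p_unmethylated`` (scalar or per-family
    map) steers each family's insertion points into unmethylated patches with
    that probability, and insertions into unmethylated background trigger
    per-flank spreading with ``spread_probability``.

    Returns ``(absent_genome, present_genome, truth_table)``.
    """
    tsd_table = DEFAULT_TSD_TABLE if tsd_table is None else tsd_table
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    lens = np.array([len(reference[c]) for c in chroms], dtype=float)
    n_per_chrom = rng.multinomial(n_insertions, lens / lens.sum())
    n_exc = int(round(excision_fraction * n_insertions))
    exc_flags = np.zeros(n_insertions, dtype=bool)
    exc_flags[:n_exc] = True
    rng.shuffle(exc_flags)

    truth_rows = []
    absent_genome: dict[str, str] = {}
    present_genome: dict[str, str] = {}
    counter = 0

    for chrom, n_events in zip(chroms, n_per_chrom):
        ref = reference[chrom]
        L = len(ref)
        allowed = np.ones(L, bool)
        allowed[: edge_margin] = False
        allowed[L - edge_margin:] = False
        for df, pad in ((genes, 600), (existing_tes, 1300)):
            if df is None:
                continue
            for row in df[df["chrom"] == chrom].itertuples():
                allowed[max(0, row.start - pad): row.end + pad] = False
        if genes is not None:
            gsub = genes[genes["chrom"] == chrom]
            if len(gsub):
                # keep a flanking gene on each side (search-window bounds)
                allowed[: int(gsub["end"].min())] = False
                allowed[int(gsub["start"].max()):] = False
        state_mask = None
        if background is not None:
            state_mask = np.zeros(L, bool)  # True = unmethylated
            for row in background[background["chrom"] == chrom].itertuples():
                if row.state == "unmethylated":
                    state_mask[row.start:row.end] = True
            # ground truth demands an unambiguous local state: only accept
            # junctions whose +/-400 bp neighbourhood sits in one patch
            half = 400
            csum = np.concatenate([[0], np.cumsum(state_mask)])
            lo = np.maximum(np.arange(L) - half, 0)
            hi = np.minimum(np.arange(L) + half + 1, L)
            win = csum[hi] - csum[lo]
            size = hi - lo
            uniform = (win == 0) | (win == size)
            allowed &= uniform

        events = []
        for _ in range(int(n_events)):
            donor = donors.iloc[int(rng.integers(len(donors)))]
            tsd = int(tsd_table.get(donor["superfamily"], 5))
            is_excision = bool(exc_flags[counter])
            if isinstance(p_unmethylated, dict):
                p_u = p_unmethylated.get(donor["family"])
            else:
                p_u = p_unmethylated
            want_state = None
            if state_mask is not None and p_u is not None:
                want_state = rng.random() < p_u  # True = unmethylated target
            pos = _sample_event_pos(
                rng, ref, allowed, state_mask, want_state, tsd, is_excision
            )
            if pos is None:
                raise PlacementError(
                    "chromosome too short to host requested polymorphisms"
                )
            allowed[max(0, pos - min_spacing): pos + min_spacing] = False
            bg_state = (
                _state_str(state_mask, pos) if state_mask is not None else ""
            )
            spread_left = spread_right = False
            if (not is_excision and bg_state == "unmethylated"
                    and spread_probability > 0):
                spread_left = bool(rng.random() < spread_probability)
                spread_right = bool(rng.random() < spread_probability)
            events.append(
                dict(
                    te_id=f"poly{counter:05d}", chrom=chrom, ref_pos=pos,
                    event="excision" if is_excision else "insertion",
                    family=donor["family"], superfamily=donor["superfamily"],
                    order=donor["order"], te_len=len(donor["seq"]),
                    tsd_len=tsd, tsd_seq=ref[pos - tsd:pos] if tsd else "",
                    bg_state=bg_state, spread_left=spread_left,
                    spread_right=spread_right, seq=donor["seq"],
                )
            )
            counter += 1

        events.sort(key=lambda e: e["ref_pos"])
        parts_p, parts_a = [], []
        last = 0
        off_p = 0  # present-genome shift accumulated so far
        off_a = 0  # absent-genome shift (deletions are negative)
        for ev in events:
            pos, tsd = ev["ref_pos"], ev["tsd_len"]
            parts_p.append(ref[last:pos])
            parts_p.append(ev["seq"])
            parts_p.append(ref[pos - tsd:pos] if tsd else "")
            if ev["event"] == "excision":
                parts_a.append(ref[last:pos - tsd])
                ev["absent_pos"] = pos - tsd + off_a
                off_a -= tsd
            else:
                parts_a.append(ref[last:pos])
                ev["absent_pos"] = pos + off_a
            ev["present_start"] = pos + off_p
            ev["present_end"] = pos + off_p + ev["te_len"]
            off_p += ev["te_len"] + tsd
            last = pos
        parts_p.append(ref[last:])
        parts_a.append(ref[last:])
        present_genome[chrom] = "".join(parts_p)
        absent_genome[chrom] = "".join(parts_a)
        truth_rows.extend(events)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS + ["seq"])
    truth = truth.drop(columns=["seq"])
    return absent_genome, present_genome, truth


def _state_str(state_mask: np.ndarray, pos: int) -> str:
    return "unmethylated" if state_mask[pos] else "methylated"


def _sample_event_pos(rng, ref, allowed, state_mask, want_unmeth, tsd,
                      is_excision, tries: int = 200) -> int | None:
    mask = allowed
    if state_mask is not None and want_unmeth is not None:
        mask = allowed & (state_mask == want_unmeth)
        if not mask.any():
            log.warning(
                "no %smethylated positions left; state targeting degraded",
                "un" if want_unmeth else "",
            )
            mask = allowed
    cand = np.flatnonzero(mask)
    if cand.size == 0:
        return None
    for _ in range(tries):
        pos = int(cand[int(rng.integers(cand.size))])
        if not is_excision:
            return pos
        if _unambiguous_excision_site(ref, pos, tsd):
            return pos
    return None


def liftover_positions(
    positions: np.ndarray, truth: pd.DataFrame, chrom: str, haplotype: str
) -> np.ndarray:
    """Map reference coordinates to present/absent haplotype coordinates.

    ``haplotype`` is ``"present"`` (all events add te_len + tsd at ref_pos) or
    ``"absent"`` (excisions delete tsd bp ending at ref_pos).
    """
    sub = truth[truth["chrom"] == chrom].sort_values("ref_pos")
    pos = np.asarray(positions, dtype=np.int64)
    if haplotype == "present":
        ev_pos = sub["ref_pos"].to_numpy()
        deltas = (sub["te_len"] + sub["tsd_len"]).to_numpy()
        cum = np.concatenate([[0], np.cumsum(deltas)])
        idx = np.searchsorted(ev_pos, pos, side="right")
        return pos + cum[idx]
    if haplotype == "absent":
        exc = sub[sub["event"] == "excision"]
        out = pos.astype(np.int64).copy()
        shift = np.zeros(pos.size, dtype=np.int64)
        for row in exc.itertuples():
            d0, d1 = row.ref_pos - row.tsd_len, row.ref_pos
            shift += np.clip(out - d0, 0, d1 - d0)
        return out - shift
    raise ValueError("haplotype must be 'present' or 'absent'")


def liftover_intervals(
    df: pd.DataFrame, truth: pd.DataFrame, haplotype: str
) -> pd.DataFrame:
    """Lift an interval table (chrom/start/end) onto one haplotype."""
    out = df.copy()
    for chrom in out["chrom"].unique():
        m = out["chrom"] == chrom
        out.loc[m, "start"] = liftover_positions(
            out.loc[m, "start"].to_numpy(), truth, chrom, haplotype
        )
        out.loc[m, "end"] = liftover_positions(
            out.loc[m, "end"].to_numpy(), truth, chrom, haplotype
        )
    return out


def implanted_te_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """TE annotation rows (present-haplotype coordinates) for implanted events."""
    return pd.DataFrame(
        dict(
            chrom=truth["chrom"],
            start=truth["present_start"],
            end=truth["present_end"],
            id=truth["te_id"],
            strand="+",
            order=truth["order"],
            superfamily=truth["superfamily"],
            family=truth["family"],
            nested=False,
            spread_left=truth["spread_left"],
            spread_right=truth["spread_right"],
        )
    )


@dataclass
class PolymorphismStudy:
    """Everything needed to analyse one synthetic haplotype pair."""

    reference: dict[str, str]
    absent_genome: dict[str, str]
    present_genome: dict[str, str]
    genes_absent: pd.DataFrame
    genes_present: pd.DataFrame
    tes_present: pd.DataFrame
    truth: pd.DataFrame
    background: pd.DataFrame | None
    calls_absent: pd.DataFrame
    calls_present: pd.DataFrame
    synteny: pd.DataFrame

    def sites(self) -> pd.DataFrame:
        """Truth-table view shaped for :func:`temethyl.dynamics.empty_site_records`."""
        t = self.truth
        return pd.DataFrame(
            dict(site_id=t["te_id"], family=t["family"], chrom=t["chrom"],
                 absent_pos=t["absent_pos"], present_chrom=t["chrom"],
                 present_start=t["present_start"],
                 present_end=t["present_end"])
        )


def simulate_polymorphism_study(
    *,
    chrom_len: int = 1_000_000,
    n_genes: int = 200,
    n_insertions: int = 60,
    donor_families: list[TEFamilyConfig] | None = None,
    reference_families: list[TEFamilyConfig] | None = None,
    excision_fraction: float = 0.0,
    p_unmethylated: dict[str, float] | float | None = None,
    spread_probability: float = 0.0,
    with_background: bool = True,
    meth_weight: float = 0.5,
    mean_patch_len: float = 2500.0,
    depth: int = 20,
    noise_sd: float = 0.0,
    min_spacing: int = 2000,
    tsd_table: dict[str, int] | None = None,
    seed: int = 0,
) -> PolymorphismStudy:
    """One-call synthetic study: haplotype pair + methylomes + ground truth.

    Generates a gene-rich reference, implants TE polymorphisms (optionally
    steered into unmethylated background patches and triggering flank
    spreading), lifts annotations onto both haplotypes, and simulates both
    methylomes with the implanted elements methylated and their flanks
    following the background except where spreading was triggered.  Gene
    synteny across the pair is identity by construction.
    """
    rng = np.random.default_rng(seed)
    s = [int(x) for x in rng.integers(0, 2**31 - 1, size=6)]
    spec = GenomeSpec(chrom_len=chrom_len, n_genes=n_genes, seed=s[0])
    reference, genes, ref_tes = generate_reference(
        spec, reference_families or []
    )
    sizes = {c: len(v) for c, v in reference.items()}
    background = (
        draw_background(sizes, s[1], meth_weight=meth_weight,
                        mean_patch_len=mean_patch_len)
        if with_background else None
    )
    donor_families = donor_families or [
        TEFamilyConfig(name="polyfam", superfamily="DTA",
                       min_len=500, max_len=700)
    ]
    donors = make_donor_library(donor_families, s[2])
    absent, present, truth = implant_te_polymorphisms(
        reference, donors, n_insertions, tsd_table=tsd_table,
        excision_fraction=excision_fraction, seed=s[3], genes=genes,
        existing_tes=ref_tes if len(ref_tes) else None,
        background=background, p_unmethylated=p_unmethylated,
        spread_probability=spread_probability, min_spacing=min_spacing,
    )
    genes_p = liftover_intervals(genes, truth, "present")
    genes_a = liftover_intervals(genes, truth, "absent")
    tes_p = implanted_te_annotation(truth)
    if len(ref_tes):
        shared = liftover_intervals(ref_tes, truth, "present")
        shared["spread_left"] = False
        shared["spread_right"] = False
        tes_p = (
            pd.concat([tes_p, shared], ignore_index=True)
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
    bg_p = (
        liftover_intervals(background, truth, "present")
        if background is not None else None
    )
    bg_a = (
        liftover_intervals(background, truth, "absent")
        if background is not None else None
    )
    archetypes = {f.name: INSERTION_ARCHETYPE for f in donor_families}
    for f in reference_families or []:
        archetypes.setdefault(f.name, DEFAULT_ARCHETYPES["H"])
    calls_p = simulate_methylome(
        present, tes_p, archetypes, depth=depth, noise_sd=noise_sd,
        seed=s[4], background=bg_p, genes=genes_p,
    )
    tes_a = (
        liftover_intervals(ref_tes, truth, "absent")
        if len(ref_tes) else tes_p.iloc[0:0]
    )
    calls_a = simulate_methylome(
        absent, tes_a, archetypes, depth=depth, noise_sd=noise_sd,
        seed=s[5], background=bg_a, genes=genes_a,
    )
    synteny = pd.DataFrame(
        dict(query_gene=genes_p["id"], target_gene=genes_a["id"])
    )
    return PolymorphismStudy(
        reference=reference, absent_genome=absent, present_genome=present,
        genes_absent=genes_a, genes_present=genes_p, tes_present=tes_p,
        truth=truth, background=background, calls_absent=calls_a,
        calls_present=calls_p, synteny=synteny,
    )


# ---------------------------------------------------------------------------
# chromatin counts


def simulate_chromatin_counts(
    chrom_sizes: dict[str, int],
    tes: pd.DataFrame,
    total_reads: int,
    *,
    group_profiles: dict[str, dict[str, float]] | None = None,
    group_col: str = "family",
    flank_extent: int = 1000,
    window: int = 100,
    baseline: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial per-window read counts with group-dependent intensity.

    ``group_profiles`` maps a TE group label (values of ``group_col``) to
    ``{"body": x, "flank": y}`` intensity multipliers applied to windows
    overlapping the TE body or its ``flank_extent`` flanks; all other windows
    get ``baseline`` intensity.  Counts sum exactly to ``total_reads``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    intensities = []
    for chrom, L in chrom_sizes.items():
        n_win = -(-L // window)
        starts = np.arange(n_win) * window
        inten = np.full(n_win, float(baseline))
        if group_profiles:
            for row in tes[tes["chrom"] == chrom].itertuples():
                prof = group_profiles.get(getattr(row, group_col))
                if prof is None:
                    continue
                b0, b1 = row.start // window, -(-row.end // window)
                f0 = max(0, (row.start - flank_extent) // window)
                f1 = min(n_win, -(-(row.end + flank_extent) // window))
                inten[f0:b0] = prof.get("flank", baseline)
                inten[b1:f1] = prof.get("flank", baseline)
                inten[b0:b1] = prof.get("body", baseline)
        frames.append(
            pd.DataFrame(
                dict(chrom=chrom, start=starts,
                     end=np.minimum(starts + window, L))
            )
        )
        intensities.append(inten)
    out = pd.concat(frames, ignore_index=True)
    inten = np.concatenate(intensities)
    if total_reads == 0:
        out["count"] = 0
    else:
        out["count"] = rng.multinomial(total_reads, inten / inten.sum())
    return out
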