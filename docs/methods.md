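# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.  Coordinates are 0-based half-open
throughout the library; 1-based closed intervals appear only at GFF3
boundaries.

## Tile methylome classification

Per-cytosine calls (chrom, position, strand, context, methylated count,
total count — the shape of BSMAP-style methratio output) are pooled over
both strands into non-overlapping tiles of `tile_size` (default 100 bp; the
last tile of a chromosome may be short).  The tile-level methylation level
is the pooled ratio #C/(#C+#T), not a mean of per-site ratios, so deeply
covered cytosines weigh more.

Classification cutoffs (`ThresholdConfig`):

| parameter          | default | meaning                                        |
|--------------------|---------|------------------------------------------------|
| `unmethylated_max` | 0.20    | CG/CHG ratio ≤ this → unmethylated             |
| `methylated_min`   | 0.40    | CG/CHG ratio ≥ this → methylated               |
| `chh_methylated_min` | 0.02  | CHH ratio > this → methylated (binary)         |
| `min_calls`        | 2       | informative reads needed before a ratio exists |
| `tile_size`        | 100 bp  | window size                                    |

Boundary inclusivity is ≥ 0.40 / ≤ 0.20 (both cutoffs configurable).  No
per-tile minimum evidence is universally standard; the default of two
informative reads per context mirrors the common "2× coverage" framing for
calling a window covered and is deliberately exposed in config rather than
hard-coded.  Tiles below it are `no_data` and are excluded from every
downstream proportion rather than imputed.

Annotation-stratified summaries assign each tile the highest-precedence
overlapping category (TE > exon > intron > intergenic) and report, per
category and context, the covered fraction and U/I/M class proportions
among covered tiles.

## Oriented TE metaprofiles

*Nesting.*  An element is nested when its interval is strictly contained in
another element's interval.  Identical intervals are a degenerate tie: the
element with the shorter (then lexicographically smaller) id is flagged
nested so exactly one member of the pair stays outer, deterministically.

*Nearest-TE assignment.*  Every tile that does not overlap any TE body is
assigned to the single closest non-nested TE by edge-to-edge gap (adjacent
= 0); ties go to the TE with the smaller start.  A tile inside any TE body
is never a flank tile of another element, which is what excludes the flanks
of nested TEs.  Only assignments within 1 kb enter profiles.  Restricting
candidates to non-nested elements is equivalent to using all elements: an
outside tile is always at least as close to the host as to anything nested
inside it.

*Profile geometry.*  Each element yields a 30-bin × signal matrix: 10 left
flank bins at fixed 100 bp resolution, 10 body bins by proportional
position of the tile midpoint (the body is length-normalised; 10 bins is a
choice — the resolution is configurable via `ProfileConfig.body_bins`), 10
right flank bins.  Elements whose flank is truncated by a chromosome end
contribute only existing bins; per-bin member counts are tracked and
missing bins are ignored in means.

*Orientation.*  TIR element orientation is rarely known, so elements are
oriented by data: if the downstream 1 kb flank has strictly higher mean CG
methylation than the upstream flank, the whole 30-bin profile is reversed.
An exact tie, or a flank with no CG-informative tile, keeps genomic
orientation.  Orientation is idempotent: an oriented profile never flips
again.

*Family and group summaries.*  Families require ≥ 20 non-nested members by
default (below-threshold families are logged and skipped).  Chromatin
signals are counts-per-million: window count / total mapped reads × 1e6.
Group (H/M/L) chromatin profiles exclude TIR elements shorter than 1 kb,
because many TIR families are dominated by short non-autonomous copies at
or below the resolution of 100 bp window counts; LTR elements are
essentially all longer than that and are not filtered.  Distance to gene is
the edge-to-edge gap to the single closest gene (0 when overlapping, ties
to the smaller start), binned overlapping / <1 kb / 1–5 kb / >5 kb; family
sizes bin at 20–50 / 50–100 / 100–200 / >200; a family is "expressed" when
any tissue in the supplied RPM table exceeds 1 (expression quantification
itself is consumed, never computed).

## H/M/L clustering

The feature vector per family is the 20 CG + 20 CHG oriented flank bins
(40 values in [0, 1]); body bins are excluded because all groups share
uniformly high body methylation and would only dilute the flank signal.
k-means uses k = 3 with k-means++ initialisation, `n_init=10` and a fixed
seed; LTR and TIR families are clustered separately.  Features are used as
raw ratios by default — they share a scale, so z-scoring is unnecessary —
with a `standardize` switch.  Families with more than 50% missing features
are excluded; remaining missing values are mean-imputed per feature, both
logged.  Clusters are labelled H/M/L by descending centroid mean over all
40 features, with exact ties broken by the CG-feature mean (logged); the
family→label map is therefore invariant to cluster index permutation and
input order.  A `k_sweep` diagnostic reports inertia for k = 2..5.

## Site-defined polymorphism calling

Two 400 bp flank tags per element are centred on its start and end
coordinates: 200 bp outside + 200 bp inside each boundary.  Search windows
span between the target-genome syntelogs of the nearest non-overlapping
flanking genes; a missing syntelog on either side leaves the site
unresolved.  For synthetic pairs the synteny map is identity by
construction.

*Placement.*  At desk scale an external aligner is unnecessary: the
built-in placement anchors the outermost 100 bp of a tag (its start for the
left tag, its end for the right tag), requires exactly one occurrence of
the anchor in the window, and extends the match base by base toward the
element.  The matched flank span is capped at the 200 bp outside half; any
contiguous match beyond it is the "not-soft-clipped" TE-side span.  The
anchored-extension design matters for excisions: the tag's inner bases
include the TSD, which is absent at an excision empty site, so a plain
substring search of the full outside half would fail exactly where the
interesting events are.  Both tags matching deep into the element
(inside span ≥ 50 bp) means the element is present — status shared.  A SAM
interpreter (`placements_from_sam`) maps precomputed alignments onto the
same contract (unique mapped forward-strand record; soft-clips from the
CIGAR; flank span capped at 200 bp), for use with a real aligner's output.

*Gap rule.*  With both tags placed uniquely and neither matching the
element interior, the junction gap |right − left| must be **below twice the
superfamily TSD length**: an insertion leaves one TSD copy between the two
flank junctions (gap = TSD length), an excision removes it (gap = 0), and
anything larger indicates a rearranged or misplaced locus.  A zero-length
TSD admits only a zero gap, and such events are classified `unknown` since
TSD evidence does not exist.  The empty-site coordinate is the midpoint of
the two junctions, 0-based on the target genome.

*Event classification.*  The element's two TSD copies (the `tsd_len` bases
immediately flanking it in the carrier haplotype) are compared with the
empty-site sequence at the corresponding junction sides: both matching →
`insertion` (the site shows the pre-duplication state); neither →
`putative_excision` (element and duplication both gone); exactly one →
`unknown`.

Default TSD lengths per superfamily follow standard TE biology and live in
config, not code: hAT (DTA) 8, CACTA (DTC) 3, PIF/Harbinger (DTH) 3,
Mutator (DTM) 9, Tc1/Mariner (DTT) 2, LTR superfamilies (RLC/RLG/RLX) 5.

## Empty sites and methylation spreading

The pre-insertion state of a polymorphic TE is read from the 100 bp tile
overlapping the empty-site junction in the haplotype lacking the element;
a junction exactly on a tile boundary belongs to the tile to its right
(half-open convention).  Sites whose empty-site tile lacks CG data are
dropped from all proportions.  In the carrier, the flank state comes from
the two nearest grid tiles that do not overlap the element; a flank tile
overlapping another TE's body is dropped, and single-data-flank sites are
retained with a flag rather than discarded.

Spreading applies only to unmethylated empty sites.  A flank "gains" when
its carrier tile classifies methylated (≥ 0.40).  The headline call is
per-flank (one gaining flank suffices; one- vs both-flank spreading is
distinguished), and the averaged criterion — mean flank CG ratio reaching
the methylated cutoff — is emitted alongside as `spreading_avg`, since both
statistics are natural readings of "the flanks gained methylation" and they
can disagree for single-flank gains.

Family summaries require ≥ 10 empty sites with methylation data (insertion
preference: proportion of unmethylated empty sites, rank-ordered) and ≥ 4
survey-able unmethylated insertions (spreading rate), with the fraction of
families spreading at every site reported separately.  Cross-haplotype
consistency calls a multi-absent site consistent when every absent
haplotype shows the same class and that class is U or M; for unmethylated
sites with several carriers, the distribution of gain counts over carriers
is reported.  Every proportion is recomputable by brute-force counting over
the emitted per-site table, and the test suite does exactly that.

## The synthetic-data generator

The generator defines the study conditions; it emulates the *structure* of
the real data, not maize itself.

*Genome and annotations.*  Chromosomes are i.i.d. sequence at a set GC
content (default 0.46).  Genes sit on a jittered regular grid, which
guarantees flanking genes for polymorphism search windows.  Non-nested TEs
are rejection-sampled with 2.1 kb clearance so 1 kb flanks are unambiguous;
nested members are placed inside previously placed hosts.

*Methylome.*  Per-cytosine methylated counts are Binomial(depth, p), depth
20 by default.  p is the family archetype's `body_level` inside elements
(0.85 for CG/CHG), follows `plateau + (body − plateau)·exp(−d/decay)` with
distance d from the edge in the 1 kb flanks, and is the background
elsewhere.  The default H/M/L archetypes share the body level and differ in
flank plateau (0.85 / 0.40 / 0.05); CHH gets a flat edge peak within 200 bp
of element edges, strongest for the low-flank archetype (RdDM is most
active where TEs border open chromatin).  Optional Gaussian jitter
(`noise_sd`) perturbs p per cytosine before sampling.  The non-TE, non-gene
background is a two-state patch mosaic (exponential patch lengths, mean
2.5–3 kb; mostly-methylated majority at 0.80 CG / 0.70 CHG, unmethylated
minority at 0.05), which reproduces the bimodal tile-level distribution of
real plant methylomes.  Gene bodies are held unmethylated.

*Polymorphisms.*  An insertion duplicates the `tsd_len` bases left of the
insertion point on both sides of the element in the present haplotype.  An
excision leaves the element (with both TSD copies) in the present haplotype
and removes the TSD from the absent haplotype, so neither copy matches the
empty site.  Implant positions avoid genes, existing TEs, chromosome ends
and each other (2–2.5 kb spacing).  Because the truth table must be exact
to be a ground truth, sites are additionally re-sampled until they are
sequence-unambiguous: excision junction bases must not coincidentally
extend the flank match, the empty-site windows must not coincidentally
equal the TSD (relevant for 2–3 bp TSDs), and state-targeted insertions
must sit in a background patch that is uniform over ±400 bp so the
empty-site tile state is unequivocal.  These constraints reject only a few
percent of candidate positions and do not alter the statistical conditions.

*Insertion preference and spreading.*  With a background map, each family's
insertion points land in unmethylated patches with probability
`p_unmethylated`.  Insertions into unmethylated background trigger
spreading per flank, independently, with probability `spread_probability`;
a triggered flank's CG/CHG level is raised to the body level over
`spread_extent` (default 300 bp — a free parameter of the generator, not a
claim about any organism, since no quantitative spreading-extent
distribution is established).  Implanted elements use an archetype whose
flanks follow the background (`flank_follows_background`), because for the
spreading analysis the flank state is the readout, not a family trait.
The per-flank gain frequency among unmethylated insertions estimates
`spread_probability` directly; the per-site family spreading rate estimates
`1 − (1 − p)²`.

*Chromatin.*  Per-100 bp window counts are a single multinomial draw over
windows with group-dependent intensity multipliers on TE bodies and flanks,
so counts sum exactly to the requested total.

*What passing tests do and do not show.*  The generator has uniform
mappability, no bisulfite conversion error, no read-level artefacts, exact
annotations, identity synteny and unique flank sequence.  Perfect
precision/recall and exact truth recovery on it validate the *logic* of the
pipeline — coordinate arithmetic, TSD bookkeeping, threshold handling,
estimator consistency — not robustness to alignment noise, repetitive
flanks or annotation error in real genomes.

## Verification problem sizes and numerical choices

The verification script and acceptance tests use: a 100 kb chromosome for
the tile oracle; 200 random TEs / 1,000 tiles for the nearest-assignment
oracle; 30 elements across three archetype families for orientation; 20
seeds × 60 families for clustering recovery (ARI and label accuracy against
generator archetypes); a 700 kb pair with 50 insertions + 10 excisions
(plus shared reference elements as negative controls) for polymorphism
precision/recall; and a 6 Mb pair with 500 implanted sites
(`p_unmethylated` = 0.9, `spread_probability` = 0.6) for rate recovery
within three binomial standard errors.  Cross-haplotype consistency is
assessed on three absent-haplotype replicates simulated at 100× depth, at
which binomial sampling cannot move a tile across a class boundary — at
20× a CG-poor tile crosses the 0.20 cutoff about once in a thousand sites,
which is sampling noise, not methylome disagreement.

Tie-breaks are deterministic everywhere (documented above); means over
bins ignore missing values with counts tracked; k-means determinism comes
from the fixed seed and `n_init` restarts.  Degenerate inputs — empty call
streams, zero genes, zero reads, zero-length TSDs, truncated flank tags,
elements shorter than a tag half — are handled explicitly and tested.

## Limitations

Real WGBS and ChIP data enter as precomputed per-cytosine calls and window
counts; short-read alignment, conversion-rate estimation and TE expression
quantification are out of scope.  The SAM placement interpreter assumes
forward-strand tag alignments without indels in the flank span.  Nested
polymorphisms (an insertion inside another polymorphic element) are not
resolved.  The built-in placement relies on locally unique flank sequence
and will return `unresolved` in repetitive flanks where a real aligner
would too.
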