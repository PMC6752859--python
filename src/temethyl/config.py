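"""Shared configuration objects and constants.

Coordinates are 0-based half-open everywhere inside the package; 1-based
coordinates appear only when reading or writing GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# methylation tile classes
UNMETHYLATED = "unmethylated"
INTERMEDIATE = "intermediate"
METHYLATED = "methylated"
NO_DATA = "no_data"

CONTEXTS = ("CG", "CHG", "CHH")

#: Default target-site-duplication length (bp) per TE superfamily.  These are
#: the canonical values from TE biology: hAT elements make 8 bp TSDs, CACTA 3,
#: PIF/Harbinger 3, Mutator 9, Tc1/Mariner 2 (TA), and LTR retrotransposons
#: (copia/gypsy/unknown) 5.  Editable by passing a custom mapping.
DEFAULT_TSD_TABLE: dict[str, int] = {
    "DTA": 8,
    "DTC": 3,
    "DTH": 3,
    "DTM": 9,
    "DTT": 2,
    "DTX": 5,
    "RLC": 5,
    "RLG": 5,
    "RLX": 5,
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs for per-tile methylation classification.

    CG and CHG tiles are three-state: unmethylated (ratio <= unmethylated_max),
    methylated (ratio >= methylated_min), intermediate in between.  CHH tiles
    are binary: methylated when the ratio exceeds ``chh_methylated_min``.
    A tile needs at least ``min_calls`` informative reads in a context before
    a ratio is reported; otherwise the tile is ``no_data`` for that context.
    """

    unmethylated_max: float = 0.20
    methylated_min: float = 0.40
    chh_methylated_min: float = 0.02
    min_calls: int = 2
    tile_size: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.unmethylated_max < self.methylated_min <= 1.0):
            raise ValueError(
                "require 0 <= unmethylated_max < methylated_min <= 1, got "
                f"{self.unmethylated_max}, {self.methylated_min}"
            )
        if self.min_calls < 0 or self.tile_size <= 0:
            raise ValueError("min_calls must be >= 0 and tile_size > 0")


@dataclass(frozen=True)
class ProfileConfig:
    """Geometry of oriented TE metaprofiles.

    Flanks extend 1 kb on each side at tile resolution (10 bins of 100 bp);
    the TE body is length-normalised to ``body_bins`` relative bins.
    """

    flank_bins: int = 10
    body_bins: int = 10
    tile_size: int = 100
    min_members: int = 20
    max_flank_distance: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "max_flank_distance", self.flank_bins * self.tile_size
        )

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins
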