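"""Published input datasets small enough to ship as constants.

The tetrad class counts below are the published I3bc pollen-tetrad scores for
the three genotypes (wild-type Col, asy1-4/+ heterozygote, asy1-4 homozygote);
they are inputs to the Perkins/Malkova engine, not results. The I3bc
fluorescent-transgene positions on chromosome 3 are the interval boundaries
the colors mark (CFP, YFP, dsRed2; bp, TAIR10).
"""

from __future__ import annotations

from .tetrad_ftl import TetradCounts

__all__ = ["I3BC_FTL_POSITIONS_BP", "i3bc_tetrad_counts"]

#: chromosome-3 positions of the three fluorescent transgenes (CFP, YFP, dsRed2)
I3BC_FTL_POSITIONS_BP = (498_916, 3_126_994, 4_319_513)

_COUNTS = {
    # class order A..L
    "wild_type": (2338, 328, 1313, 12, 8, 13, 14, 3, 5, 0, 0, 0),
    "asy1_het": (2092, 317, 1574, 16, 17, 10, 13, 2, 8, 0, 0, 0),
    "asy1_hom": (913, 46, 113, 6, 1, 0, 1, 2, 5, 1, 1, 0),
}


def i3bc_tetrad_counts(genotype: str) -> TetradCounts:
    """Published I3bc tetrad class counts for ``wild_type``, ``asy1_het`` or
    ``asy1_hom``."""
    if genotype not in _COUNTS:
        raise KeyError(f"unknown genotype {genotype!r}; choose from {sorted(_COUNTS)}")
    return TetradCounts.from_array(_COUNTS[genotype])
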