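"""Genome layout: chromosome lengths and centromere/pericentromere intervals.

All coordinates are 1-based inclusive. Arms run from a telomere to the
midpoint of the centromere interval; telomere-distance math and scaled
telomere->centromere profiles both derive from this layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = ["ChromosomeLayout", "GenomeLayout", "read_layout", "write_layout"]


class LayoutError(ValueError):
    """Raised when a genome layout violates its coordinate invariants."""


@dataclass(frozen=True)
class ChromosomeLayout:
    """One chromosome: length plus centromere and pericentromere intervals."""

    name: str
    length: int
    cen_start: int
    cen_end: int
    pericen_start: int
    pericen_end: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise LayoutError(f"{self.name}: non-positive length")
        if not (0 < self.cen_start < self.cen_end <= self.length):
            raise LayoutError(f"{self.name}: centromere interval outside chromosome")
        if not (
            0 < self.pericen_start <= self.cen_start
            and self.cen_end <= self.pericen_end <= self.length
        ):
            raise LayoutError(f"{self.name}: pericentromere must contain centromere")

    @property
    def cen_mid(self) -> int:
        """Midpoint of the centromere interval (arm boundary)."""
        return (self.cen_start + self.cen_end) // 2

    @property
    def arms(self) -> tuple[tuple[int, int, bool], ...]:
        """The two arms as (start, end, oriented_leftward) in 1-based coords.

        ``oriented_leftward`` is True for the left arm, whose telomere is at
        coordinate 1 (so telomere->centromere runs left to right already).
        """
        return (
            (1, self.cen_mid, True),
            (min(self.cen_mid + 1, self.length), self.length, False),
        )


class GenomeLayout(Mapping[str, ChromosomeLayout]):
    """Ordered mapping of chromosome id -> :class:`ChromosomeLayout`."""

    def __init__(self, chromosomes: list[ChromosomeLayout] | dict[str, ChromosomeLayout]):
        if isinstance(chromosomes, dict):
            chromosomes = list(chromosomes.values())
        self._chroms: dict[str, ChromosomeLayout] = {}
        for c in chromosomes:
            if c.name in self._chroms:
                raise LayoutError(f"duplicate chromosome {c.name}")
            self._chroms[c.name] = c

    def __getitem__(self, name: str) -> ChromosomeLayout:
        return self._chroms[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeLayout({list(self._chroms)})"

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.values())


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a layout TSV with columns chrom/length/cen_start/cen_end/pericen_start/pericen_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "length", "cen_start", "cen_end", "pericen_start", "pericen_end"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"layout file missing columns: {sorted(missing)}")
    return GenomeLayout(
        [
            ChromosomeLayout(
                str(r.chrom),
                int(r.length),
                int(r.cen_start),
                int(r.cen_end),
                int(r.pericen_start),
                int(r.pericen_end),
            )
            for r in df.itertuples()
        ]
    )


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c.name,
                "length": c.length,
                "cen_start": c.cen_start,
                "cen_end": c.cen_end,
                "pericen_start": c.pericen_start,
                "pericen_end": c.pericen_end,
            }
            for c in layout.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def arabidopsis_layout() -> GenomeLayout:
    """TAIR10-like five-chromosome layout (Mb-scale lengths, rounded).

    Centromere/pericentromere coordinates are approximate intervals of the
    kind supplied as analysis input; they are bundled so simulations and
    examples run without any external file.
    """
    rows = [
        # name, length, cen_start, cen_end, pericen_start, pericen_end
        ("Chr1", 30_427_671, 14_200_000, 15_600_000, 11_500_000, 18_100_000),
        ("Chr2", 19_698_289, 3_100_000, 3_900_000, 1_100_000, 7_200_000),
        ("Chr3", 23_459_830, 13_600_000, 14_800_000, 10_300_000, 17_300_000),
        ("Chr4", 18_585_056, 3_000_000, 4_000_000, 1_500_000, 6_300_000),
        ("Chr5", 26_975_502, 11_000_000, 12_400_000, 9_000_000, 16_000_000),
    ]
    return GenomeLayout([ChromosomeLayout(*row) for row in rows])
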