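"""F2 genotype-block tables and crossover extraction.

An F2 individual genotyped against two parental haplotypes (P1, P2) decomposes
each chromosome into contiguous blocks of state P1, HET or P2 (the downstream
product of sliding-window genotyping pipelines such as TIGER). A crossover is
located in the interval between two adjacent blocks of different state: a
P1<->HET or HET<->P2 step is one crossover; a direct P1<->P2 step requires two
(one in each contributing gamete) and is counted as two events at the same
interval.

Coordinates are 1-based inclusive throughout. The crossover point is taken as
the midpoint of the inter-block interval; the interval bounds are retained for
double-crossover width matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout

__all__ = [
    "BlockValidationError",
    "CrossoverEvent",
    "F2BlockSet",
    "PopulationCounts",
    "read_blocks",
    "write_blocks",
    "crossovers_from_blocks",
    "write_crossovers_bed",
    "population_counts",
    "count_length_correlation",
]

STATES = ("P1", "HET", "P2")

BLOCK_COLUMNS = ["indiv", "chrom", "start", "end", "state"]


class BlockValidationError(ValueError):
    """A genotype-block table violates the block invariants."""


@dataclass(frozen=True)
class CrossoverEvent:
    """A located crossover: the inter-block interval and its midpoint."""

    indiv: str
    chrom: str
    start: int  # end of the left block (bp, 1-based)
    end: int  # start of the right block
    midpoint: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("crossover interval start must precede end")

    @property
    def width(self) -> int:
        return self.end - self.start


class F2BlockSet:
    """Validated per-individual genotype blocks for one F2 population.

    Wraps a DataFrame with columns ``indiv, chrom, start, end, state`` sorted by
    (indiv, chrom, start), plus the genome layout the coordinates refer to.
    """

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout, n_individuals: int | None = None):
        self.df = _validate_blocks(df, layout)
        self.layout = layout
        observed = self.df["indiv"].nunique()
        self.n_individuals = int(n_individuals) if n_individuals is not None else observed
        if self.n_individuals < observed:
            raise BlockValidationError(
                f"n_individuals={n_individuals} below the {observed} individuals present"
            )

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["indiv"].unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, F2BlockSet):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


def _validate_blocks(df: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise BlockValidationError(f"block table missing columns: {sorted(missing)}")
    df = df[BLOCK_COLUMNS].copy()
    df["indiv"] = df["indiv"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["state"] = df["state"].astype(str)

    bad_state = ~df["state"].isin(STATES)
    if bad_state.any():
        raise BlockValidationError(
            f"unknown genotype states: {sorted(df.loc[bad_state, 'state'].unique())}"
        )
    unknown = set(df["chrom"].unique()) - set(layout)
    if unknown:
        raise BlockValidationError(f"chromosomes absent from layout: {sorted(unknown)}")
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise BlockValidationError(f"block start > end for {bad.indiv} {bad.chrom}")

    for (indiv, chrom), grp in df.groupby(["indiv", "chrom"], sort=False):
        length = layout[chrom].length
        if (grp["start"] < 1).any() or (grp["end"] > length).any():
            raise BlockValidationError(f"block outside chromosome for {indiv} {chrom}")
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        states = g["state"].to_numpy()
        if not np.array_equal(starts, np.sort(grp["start"].to_numpy())):  # pragma: no cover
            raise BlockValidationError(f"unsorted blocks for {indiv} {chrom}")
        if len(g) > 1:
            if (starts[1:] <= ends[:-1]).any():
                raise BlockValidationError(f"overlapping blocks for {indiv} {chrom}")
            if (states[1:] == states[:-1]).any():
                raise BlockValidationError(
                    f"adjacent blocks share state for {indiv} {chrom}"
                )

    return df.sort_values(["indiv", "chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_blocks(path: str | Path, layout: GenomeLayout, n_individuals: int | None = None) -> F2BlockSet:
    """Read a block-table TSV (columns indiv/chrom/start/end/state) and validate it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return F2BlockSet(df, layout, n_individuals=n_individuals)


def write_blocks(blocks: F2BlockSet, path: str | Path) -> None:
    blocks.df.to_csv(path, sep="\t", index=False)


def crossovers_from_blocks(blocks: F2BlockSet) -> list[CrossoverEvent]:
    """One event per P1<->HET / HET<->P2 step; a direct P1<->P2 step yields two.

    The event interval is (end of left block, start of right block); the
    midpoint is floor((start + end) / 2).
    """
    events: list[CrossoverEvent] = []
    state_level = {"P1": 0, "HET": 1, "P2": 2}
    df = blocks.df
    for (indiv, chrom), grp in df.groupby(["indiv", "chrom"], sort=True):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        levels = grp["state"].map(state_level).to_numpy()
        for i in range(len(grp) - 1):
            n_cos = abs(int(levels[i + 1]) - int(levels[i]))
            lo, hi = int(ends[i]), int(starts[i + 1])
            mid = (lo + hi) // 2
            events.extend(
                CrossoverEvent(str(indiv), str(chrom), lo, hi, mid) for _ in range(n_cos)
            )
    return events


def write_crossovers_bed(events: list[CrossoverEvent], path: str | Path) -> None:
    """Export crossovers as a BED-like TSV (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write("# crossover intervals, 0-based half-open; columns: "
                 "chrom start end indiv midpoint\n")
        for e in events:
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.indiv}\t{e.midpoint}\n")


def read_crossovers_bed(path: str | Path) -> list[CrossoverEvent]:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start0", "end", "indiv", "midpoint"],
    )
    return [
        CrossoverEvent(str(r.indiv), str(r.chrom), int(r.start0) + 1, int(r.end),
                       int(r.midpoint))
        for r in df.itertuples()
    ]


@dataclass
class PopulationCounts:
    """Per-individual crossover counts and per-chromosome means for one population."""

    per_individual: pd.Series  # index: indiv, value: crossover count (zeros included)
    per_chromosome_total: pd.Series  # index: chrom, value: total events
    n_individuals: int

    @property
    def per_chromosome_mean(self) -> pd.Series:
        return self.per_chromosome_total / self.n_individuals

    @property
    def mean(self) -> float:
        return float(self.per_individual.mean())


def population_counts(
    events: list[CrossoverEvent], n_individuals: int, layout: GenomeLayout
) -> PopulationCounts:
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    indivs = pd.Series([e.indiv for e in events], dtype=str)
    chroms = pd.Series([e.chrom for e in events], dtype=str)
    per_indiv = indivs.value_counts()
    observed = len(per_indiv)
    if observed > n_individuals:
        raise ValueError("more individuals in events than n_individuals")
    # pad with zero-crossover individuals so the histogram denominator is honest
    zeros = pd.Series(0, index=[f"_zero{i}" for i in range(n_individuals - observed)])
    per_indiv = pd.concat([per_indiv, zeros]).astype(int)
    per_chrom = chroms.value_counts().reindex(list(layout), fill_value=0).astype(int)
    return PopulationCounts(per_indiv, per_chrom, n_individuals)


def count_length_correlation(
    per_chromosome_counts: "pd.Series | np.ndarray | list[float]",
    lengths: "pd.Series | np.ndarray | list[float]",
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of per-chromosome crossover counts vs length."""
    x = np.asarray(per_chromosome_counts, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched counts/lengths for >= 3 chromosomes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
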