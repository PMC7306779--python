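"""Three-color fluorescent pollen-tetrad genetics.

A pollen tetrad from a plant hemizygous for three linked fluorescent-protein
transgenes (all in coupling) exposes the products of a single male meiosis:
each of the four spores either carries or lacks each color. Two adjacent
genetic intervals are delimited by the three transgene loci (interval 1
between colors 1 and 2, interval 2 between colors 2 and 3; for the I3bc
system on chromosome 3 these are I3b and I3c). The observable color patterns
fall into 12 classes A-L:

========  =================  =================
class     interval-1 ditype  interval-2 ditype
========  =================  =================
A (NCO)   PD                 PD
B         PD                 TT
C         TT                 PD
D         TT                 TT   (two-strand DCO: 2 parental + 2 double-recombinant spores)
E         TT                 TT   (three-strand DCO retaining the all-color parental spore)
F         TT                 TT   (three-strand DCO retaining the no-color parental spore)
G         TT                 TT   (four-strand DCO: no parental spores)
H         PD                 NPD
I         NPD                PD
J         TT                 NPD
K         NPD                TT
L         NPD                NPD
========  =================  =================

Map distances use the Perkins tetrad estimator X = 100*(TT/2 + 3*NPD)/n per
interval, where single-crossover-in-interval classes contribute to TT and
observed within-interval double-crossover classes are NPD-equivalent.
Interference is quantified by the Malkova ratio: the Perkins distance of a
test interval among tetrads *with* a crossover in the adjacent interval,
divided by the distance among tetrads *without*; values near 0 indicate
strong interference and values near 1 its absence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES",
    "TetradPattern",
    "TetradCounts",
    "PerkinsResult",
    "InterferenceRatioResult",
    "SegregationError",
    "classify_tetrad",
    "classify_patterns",
    "perkins_distance",
    "conditional_perkins",
    "interference_ratio",
    "compare_map_distances",
    "compare_interference_ratios",
]

CLASSES = tuple("ABCDEFGHIJKL")

#: (interval-1 ditype, interval-2 ditype) per class.
CLASS_DITYPES: dict[str, tuple[str, str]] = {
    "A": ("PD", "PD"),
    "B": ("PD", "TT"),
    "C": ("TT", "PD"),
    "D": ("TT", "TT"),
    "E": ("TT", "TT"),
    "F": ("TT", "TT"),
    "G": ("TT", "TT"),
    "H": ("PD", "NPD"),
    "I": ("NPD", "PD"),
    "J": ("TT", "NPD"),
    "K": ("NPD", "TT"),
    "L": ("NPD", "NPD"),
}

Spore = tuple[int, int, int]
TetradPattern = tuple[Spore, Spore, Spore, Spore]


class SegregationError(ValueError):
    """A tetrad violates 2:2 segregation for at least one color."""


class UnclassifiableTetradError(ValueError):
    """A spore set not producible by <=2 crossovers per interval."""


def _ditype(spores: list[Spore], locus_a: int, locus_b: int) -> str:
    """PD/TT/NPD of one interval from per-spore recombination status."""
    n_rec = sum(1 for s in spores if s[locus_a] != s[locus_b])
    return {0: "PD", 2: "TT", 4: "NPD"}[n_rec]


def classify_tetrad(pattern) -> str:
    """Classify one tetrad (4 spores x 3 color flags) into class A..L.

    The class is a function of the unordered spore set. Raises
    :class:`SegregationError` if any color is not present in exactly two of
    the four spores.
    """
    spores = [tuple(int(bool(f)) for f in spore) for spore in pattern]
    if len(spores) != 4 or any(len(s) != 3 for s in spores):
        raise ValueError("a tetrad is 4 spores x 3 color flags")
    for locus in range(3):
        if sum(s[locus] for s in spores) != 2:
            raise SegregationError(f"color {locus + 1} violates 2:2 segregation")

    d1 = _ditype(spores, 0, 1)
    d2 = _ditype(spores, 1, 2)
    if (d1, d2) != ("TT", "TT"):
        for cls, dd in CLASS_DITYPES.items():
            if dd == (d1, d2) and cls not in "DEFG":
                return cls
        raise UnclassifiableTetradError(f"no class for ditypes {(d1, d2)}")  # pragma: no cover

    # TT/TT: distinguish D-G by which spores carry each interval's recombination
    rec1 = {i for i, s in enumerate(spores) if s[0] != s[1]}
    rec2 = {i for i, s in enumerate(spores) if s[1] != s[2]}
    overlap = len(rec1 & rec2)
    parentals = [s for i, s in enumerate(spores) if i not in rec1 | rec2]
    if overlap == 2:
        if sorted(parentals) != [(0, 0, 0), (1, 1, 1)]:
            raise UnclassifiableTetradError("two-strand DCO pattern without parental pair")
        return "D"
    if overlap == 1:
        if len(parentals) != 1 or parentals[0] not in ((0, 0, 0), (1, 1, 1)):
            raise UnclassifiableTetradError("three-strand DCO pattern without a parental spore")
        return "E" if parentals[0] == (1, 1, 1) else "F"
    if overlap == 0:
        if parentals:
            raise UnclassifiableTetradError("four-strand DCO pattern with a parental spore")
        return "G"
    raise UnclassifiableTetradError("inconsistent TT/TT spore set")  # pragma: no cover


@dataclass
class TetradCounts:
    """Counts of tetrad classes A..L for one genotype."""

    counts: dict[str, int]
    rejected: int = 0  # tetrads failing 2:2 segregation, counted not dropped silently

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown tetrad classes: {sorted(unknown)}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in CLASSES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, cls: str) -> int:
        return self.counts[cls]

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CLASSES], dtype=int)

    @classmethod
    def from_array(cls, arr) -> "TetradCounts":
        return cls(dict(zip(CLASSES, (int(v) for v in arr))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": CLASSES, "count": self.as_array()})


def classify_patterns(patterns) -> TetradCounts:
    """Classify many tetrads; 2:2 violations are rejected and counted."""
    tally: Counter[str] = Counter()
    rejected = 0
    for p in patterns:
        try:
            tally[classify_tetrad(p)] += 1
        except SegregationError:
            rejected += 1
    return TetradCounts(dict(tally), rejected=rejected)


def read_tetrads(path: str | Path) -> TetradCounts:
    """Read a tetrad TSV: 12 binary columns (4 spores x 3 colors), one row per tetrad."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 12:
        raise ValueError("tetrad table needs 12 binary columns (4 spores x 3 colors)")
    pats = [
        tuple(tuple(int(row[3 * s + c]) for c in range(3)) for s in range(4))
        for row in df.to_numpy()
    ]
    return classify_patterns(pats)


def read_class_counts(path: str | Path) -> TetradCounts:
    """Read a pre-tabulated class-count TSV with columns class/count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return TetradCounts(dict(zip(df["class"].astype(str), df["count"].astype(int))))


# class -> TT / NPD membership per interval, applied uniformly to both intervals:
# single-CO-in-interval classes are tetratype, within-interval-DCO classes NPD-equivalent.
_TT_CLASSES = {1: set("CDEFGJ"), 2: set("BDEFGK")}
_NPD_CLASSES = {1: set("IKL"), 2: set("HJL")}
#: classes with no crossover in the given interval (PD there)
_PD_CLASSES = {1: set("ABH"), 2: set("ACI")}


@dataclass
class PerkinsResult:
    """Perkins map distance for one interval: cM = 100*(TT/2 + 3*NPD)/n."""

    interval: int
    cM: float
    se: float
    n: int
    tt: int
    npd: int


def _perkins(tt: int, npd: int, n: int, interval: int) -> PerkinsResult:
    if n <= 0:
        raise ValueError("zero tetrads in stratum")
    cm = 100.0 * (tt / 2 + 3 * npd) / n
    p_t, p_n = tt / n, npd / n
    # multinomial delta method on (TT, NPD) proportions
    var = (p_t * (1 - p_t) / 4 + 9 * p_n * (1 - p_n) - 3 * p_t * p_n) / n
    se = 100.0 * float(np.sqrt(max(var, 0.0)))
    return PerkinsResult(interval, cm, se, n, tt, npd)


def perkins_distance(counts: TetradCounts, interval: int) -> PerkinsResult:
    """Perkins estimator over all tetrads for interval 1 (I3b) or 2 (I3c)."""
    if interval not in (1, 2):
        raise ValueError("interval must be 1 or 2")
    tt = sum(counts[c] for c in _TT_CLASSES[interval])
    npd = sum(counts[c] for c in _NPD_CLASSES[interval])
    return _perkins(tt, npd, counts.total, interval)


def conditional_perkins(
    counts: TetradCounts, test_interval: int, condition_interval: int
) -> tuple[PerkinsResult, PerkinsResult]:
    """Perkins distance of the test interval with / without a CO in the other.

    Tetrads are stratified by presence of any crossover in the condition
    interval; the class -> TT/NPD mapping for the test interval is applied
    within each stratum. Returns (with, without).
    """
    if {test_interval, condition_interval} != {1, 2}:
        raise ValueError("test and condition intervals must be 1 and 2")
    without_classes = _PD_CLASSES[condition_interval]
    with_classes = set(CLASSES) - without_classes

    def stratum(classes: set[str]) -> PerkinsResult:
        tt = sum(counts[c] for c in classes & _TT_CLASSES[test_interval])
        npd = sum(counts[c] for c in classes & _NPD_CLASSES[test_interval])
        n = sum(counts[c] for c in classes)
        if n == 0:
            raise ValueError("empty stratum for conditional Perkins distance")
        return _perkins(tt, npd, n, test_interval)

    return stratum(with_classes), stratum(without_classes)


@dataclass
class InterferenceRatioResult:
    """Malkova interference ratio cM_with / cM_without for an interval pair."""

    cM_with: float
    cM_without: float
    ratio: float
    n_with: int
    n_without: int
    p_value: float | None = None  # vs a reference genotype, when computed


def interference_ratio(
    counts: TetradCounts, test_interval: int = 1, condition_interval: int = 2
) -> InterferenceRatioResult:
    with_res, without_res = conditional_perkins(counts, test_interval, condition_interval)
    if without_res.cM <= 0:
        raise ZeroDivisionError("undefined ratio: zero map distance in the without stratum")
    return InterferenceRatioResult(
        cM_with=with_res.cM,
        cM_without=without_res.cM,
        ratio=with_res.cM / without_res.cM,
        n_with=with_res.n,
        n_without=without_res.n,
    )


def compare_map_distances(result_a: PerkinsResult, result_b: PerkinsResult) -> float:
    """Two-sided z-test on the difference of two Perkins distances."""
    se = float(np.hypot(result_a.se, result_b.se))
    if se == 0:
        raise ValueError("zero standard error in both results")
    z = (result_a.cM - result_b.cM) / se
    return float(2 * stats.norm.sf(abs(z)))


def compare_interference_ratios(
    counts_a: TetradCounts,
    counts_b: TetradCounts,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    test_interval: int = 1,
    condition_interval: int = 2,
) -> float:
    """Bootstrap p-value for a difference in interference ratios.

    Under the pooled null both genotypes share one multinomial over the 12
    classes; each replicate resamples both class-count vectors from it and
    recomputes the ratio difference. The p-value is the two-sided tail
    probability of the observed difference (with the +1 small-sample
    correction). Replicates whose strata are empty or whose without-stratum
    distance is zero are dropped; more than 10% such replicates is an error.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def ratio(c: TetradCounts) -> float:
        return interference_ratio(c, test_interval, condition_interval).ratio

    observed = abs(ratio(counts_a) - ratio(counts_b))
    pooled = counts_a.as_array() + counts_b.as_array()
    p_pool = pooled / pooled.sum()
    n_a, n_b = counts_a.total, counts_b.total

    draws_a = rng.multinomial(n_a, p_pool, size=n_boot)
    draws_b = rng.multinomial(n_b, p_pool, size=n_boot)
    exceed = 0
    unresolved = 0
    for i in range(n_boot):
        try:
            d = abs(
                ratio(TetradCounts.from_array(draws_a[i]))
                - ratio(TetradCounts.from_array(draws_b[i]))
            )
        except (ValueError, ZeroDivisionError):
            unresolved += 1
            continue
        if d >= observed:
            exceed += 1
    if unresolved > 0.1 * n_boot:
        raise ValueError(f"{unresolved}/{n_boot} bootstrap resamples had unresolvable strata")
    valid = n_boot - unresolved
    return float((exceed + 1) / (valid + 1))


def table_summary(counts: TetradCounts) -> pd.DataFrame:
    """Per-genotype summary in the shape of a published tetrad table block."""
    i1 = perkins_distance(counts, 1)
    i2 = perkins_distance(counts, 2)
    with_res, without_res = conditional_perkins(counts, 1, 2)
    ratio = interference_ratio(counts)
    rows = {f"class_{c}": counts[c] for c in CLASSES}
    rows.update(
        {
            "total": counts.total,
            "interval1_cM": i1.cM,
            "interval1_se": i1.se,
            "interval2_cM": i2.cM,
            "interval2_se": i2.se,
            "interval1_cM_without_adjacent_CO": without_res.cM,
            "interval1_cM_with_adjacent_CO": with_res.cM,
            "interference_ratio": ratio.ratio,
        }
    )
    return pd.DataFrame([rows])
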