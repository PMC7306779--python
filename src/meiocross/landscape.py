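"""Telomere-distance recombination landscape analysis.

Crossovers are assigned a distance to the nearest telomere and counted in
fixed-width windows on that common axis. Two populations are compared per
window with a 2x2 chi-square test (window vs elsewhere x population A vs B)
under multiple-testing correction; distal windows that are significantly
enriched in the perturbed population define a telomere-led zone. The module
also builds proportionally scaled telomere->centromere arm profiles and the
moving-average smoother used for chromosome-scale plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeLayout
from .genotype_blocks import CrossoverEvent

__all__ = [
    "distance_to_nearest_telomere",
    "telomere_window_counts",
    "TelomereWindowTable",
    "compare_window_counts",
    "scaled_arm_profile",
    "ScaledArmProfile",
    "moving_average",
]

logger = logging.getLogger(__name__)


def distance_to_nearest_telomere(position: int, chromosome: str, layout: GenomeLayout) -> int:
    """min(position - 1, length - position) for a 1-based position."""
    length = layout[chromosome].length
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside {chromosome} (1..{length})")
    return min(position - 1, length - position)


@dataclass
class TelomereWindowTable:
    """Crossover counts per nearest-telomere-distance window for one population."""

    window_bp: int
    counts: np.ndarray  # events per window
    footprint_bp: np.ndarray  # genomic bp mapping into each window (both telomeres pooled)
    population_size: int

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def per_f2_frequency(self) -> np.ndarray:
        return self.counts / self.population_size

    def to_frame(self) -> pd.DataFrame:
        lo = np.arange(self.n_windows) * self.window_bp
        return pd.DataFrame(
            {
                "window": np.arange(self.n_windows),
                "dist_lo": lo,
                "dist_hi": lo + self.window_bp,
                "count": self.counts,
                "footprint_bp": self.footprint_bp,
                "per_f2": self.per_f2_frequency,
            }
        )


def _window_footprints(layout: GenomeLayout, window_bp: int, n_windows: int) -> np.ndarray:
    """Total bp per distance window across all chromosomes (both telomeres pooled).

    A position at distance d from its nearest telomere exists on each
    chromosome for d in [0, (length-1)/2]; each distance below that midpoint is
    hit from both ends.
    """
    foot = np.zeros(n_windows, dtype=float)
    for c in layout.values():
        max_d = (c.length - 1) / 2  # nearest-telomere distance of the central base
        for w in range(n_windows):
            lo, hi = w * window_bp, (w + 1) * window_bp
            span = max(0.0, min(hi, max_d) - lo)
            foot[w] += 2 * span
    return foot


def telomere_window_counts(
    events: list[CrossoverEvent],
    window_bp: int,
    layout: GenomeLayout,
    population_size: int,
    n_windows: int | None = None,
) -> TelomereWindowTable:
    """Count crossover midpoints in fixed windows of nearest-telomere distance."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    max_d = max((c.length - 1) // 2 for c in layout.values())
    if n_windows is None:
        n_windows = int(max_d // window_bp) + 1
    counts = np.zeros(n_windows, dtype=int)
    for e in events:
        d = distance_to_nearest_telomere(e.midpoint, e.chrom, layout)
        w = d // window_bp
        if w < n_windows:
            counts[w] += 1
    return TelomereWindowTable(
        window_bp, counts, _window_footprints(layout, window_bp, n_windows), population_size
    )


def compare_window_counts(
    table_a: TelomereWindowTable,
    table_b: TelomereWindowTable,
    yates: bool = False,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-window 2x2 chi-square between two populations, with p adjustment.

    For each window the 2x2 table is (count in window vs elsewhere) x
    (population A vs B). ``direction`` is the sign of the per-F2 frequency
    difference A - B. Windows where both populations have zero counts get
    chi2 = 0, p = 1.
    """
    if table_a.window_bp != table_b.window_bp or table_a.n_windows != table_b.n_windows:
        raise ValueError("window tables must share windowing")
    tot_a, tot_b = table_a.total, table_b.total
    if tot_a == 0 or tot_b == 0:
        raise ValueError("zero total crossovers in a population")
    rows = []
    grand = tot_a + tot_b
    for w in range(table_a.n_windows):
        a, b = int(table_a.counts[w]), int(table_b.counts[w])
        col = a + b
        expected_min = min(
            tot_a * col, tot_b * col, tot_a * (grand - col), tot_b * (grand - col)
        ) / grand
        if a == 0 and b == 0:
            chi2, p = 0.0, 1.0
        else:
            obs = np.array([[a, tot_a - a], [b, tot_b - b]])
            chi2, p, _, _ = stats.chi2_contingency(obs, correction=yates)
        freq_a = a / table_a.population_size
        freq_b = b / table_b.population_size
        rows.append(
            {
                "window": w,
                "dist_lo": w * table_a.window_bp,
                "dist_hi": (w + 1) * table_a.window_bp,
                "count_a": a,
                "count_b": b,
                "chi2": float(chi2),
                "p": float(p),
                "direction": int(np.sign(freq_a - freq_b)),
                "expected_min": float(expected_min),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method=method)[1]
    return out


@dataclass
class ScaledArmProfile:
    """Mean signal in proportional telomere->centromere bins, pooled over arms."""

    n_bins: int
    mean: np.ndarray
    n: np.ndarray  # source windows contributing per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


def scaled_arm_profile(
    values_or_events,
    layout: GenomeLayout,
    n_bins: int,
    source_window_bp: int = 10_000,
) -> ScaledArmProfile:
    """Average a windowed track (or crossover events) over proportional arm bins.

    Each arm runs from its telomere to the centromere-interval midpoint. Source
    windows of ``source_window_bp`` are assigned to one of ``n_bins``
    proportional bins by window-center position along the oriented arm; bin
    means pool all source windows of all arms. ``values_or_events`` is either a
    mapping chrom -> per-window value vector (10-kb windows by default) or a
    list of :class:`CrossoverEvent` (binned as counts per source window first).

    Arms shorter than one source window are skipped with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    if isinstance(values_or_events, dict):
        per_chrom = {k: np.asarray(v, dtype=float) for k, v in values_or_events.items()}
    else:
        per_chrom = {}
        for c in layout.values():
            nw = int(np.ceil(c.length / source_window_bp))
            per_chrom[c.name] = np.zeros(nw)
        for e in values_or_events:
            per_chrom[e.chrom][(e.midpoint - 1) // source_window_bp] += 1

    sums = np.zeros(n_bins)
    ns = np.zeros(n_bins, dtype=int)
    for c in layout.values():
        if c.name not in per_chrom:
            continue
        vals = per_chrom[c.name]
        for arm_start, arm_end, leftward in c.arms:
            arm_len = arm_end - arm_start + 1
            if arm_len < source_window_bp:
                logger.warning("skipping arm of %s shorter than one source window", c.name)
                continue
            # source windows whose centers fall within the arm
            first_w = (arm_start - 1) // source_window_bp
            last_w = (arm_end - 1) // source_window_bp
            for w in range(first_w, min(last_w + 1, len(vals))):
                center = w * source_window_bp + source_window_bp / 2  # 0-based bp
                if not (arm_start - 1 <= center < arm_end):
                    continue
                if leftward:
                    frac = (center - (arm_start - 1)) / arm_len
                else:
                    frac = (arm_end - center) / arm_len
                b = min(int(frac * n_bins), n_bins - 1)
                sums[b] += vals[w]
                ns[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return ScaledArmProfile(n_bins, mean, ns)


def moving_average(values, span: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``span`` must be odd; edge positions are averaged over the part of the
    window that overlaps the vector.
    """
    x = np.asarray(values, dtype=float)
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be an odd positive integer")
    if span > len(x):
        raise ValueError("span exceeds vector length")
    half = span // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
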