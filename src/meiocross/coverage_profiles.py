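"""ChIP-seq-style coverage processing.

Implements the downstream coverage arithmetic of a ChIP-seq enrichment
analysis: per-read alignment filtering (unique vs multi-mapping rules),
library-sum normalization, log2(ChIP/input) windows, proportional gene
metaprofiles with w0 empty-window handling, and windowed rank correlations
restricted to arms or pericentromeres.

Coordinates are 1-based inclusive, matching the rest of the package; bedGraph
import/export uses the standard 0-based half-open convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout

__all__ = [
    "AlignmentRecord",
    "CoverageTrack",
    "MetaprofileMatrix",
    "filter_alignments",
    "filter_sam",
    "normalize_library_sum",
    "normalize_log2_ratio",
    "windowed_coverage",
    "gene_metaprofile",
    "track_correlation",
    "read_bedgraph",
    "write_bedgraph",
    "read_features",
]

logger = logging.getLogger(__name__)

UNIQUE_MAPQ = 42
MULTI_MIN_MAPQ = 10
MAX_MISMATCHES = 2


@dataclass(frozen=True)
class AlignmentRecord:
    """The alignment fields the filtering rules consult."""

    read_id: str
    mate: int  # 1 or 2
    chrom: str
    position: int
    mapq: int
    has_secondary_score: bool  # SAM optional field XS present
    mismatches: int  # SAM optional field XM
    proper_pair: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError("MAPQ must be in [0, 60]")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")


def filter_alignments(
    records: list[AlignmentRecord], rng: np.random.Generator
) -> AlignmentRecord | None:
    """Select at most one alignment from all candidates of one read (mate).

    Alignments with more than two mismatches are discarded. A read is unique
    iff a candidate has no secondary-alignment score and MAPQ >= 42; otherwise
    the multi-mapping rule applies: keep candidates with MAPQ >= 10, select
    the maximum MAPQ, breaking ties with the seeded generator. Reads with
    MAPQ in [10, 41] and no secondary score are handled under the
    multi-mapping rule and logged.
    """
    cands = [r for r in records if r.mismatches <= MAX_MISMATCHES]
    if not cands:
        return None
    unique = [r for r in cands if not r.has_secondary_score and r.mapq >= UNIQUE_MAPQ]
    if unique:
        return max(unique, key=lambda r: r.mapq)
    ambiguous = [r for r in cands if not r.has_secondary_score and r.mapq >= MULTI_MIN_MAPQ]
    if ambiguous:
        logger.debug(
            "%d sub-42 MAPQ alignments without secondary score treated as multi",
            len(ambiguous),
        )
    multi = [r for r in cands if r.mapq >= MULTI_MIN_MAPQ]
    if not multi:
        return None
    best_mapq = max(r.mapq for r in multi)
    best = [r for r in multi if r.mapq == best_mapq]
    if len(best) == 1:
        return best[0]
    return best[int(rng.integers(len(best)))]


def filter_sam(path: str | Path, seed: int = 0) -> list[AlignmentRecord]:
    """Apply the per-read filtering rules to a SAM stream.

    Candidates are grouped by read id and mate; pairs with only one surviving
    mate are discarded. Returns the kept alignments in input order of first
    appearance.
    """
    import pysam

    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, int], list[AlignmentRecord]] = {}
    order: list[tuple[str, int]] = []
    paired: dict[str, bool] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            mate = 2 if aln.is_paired and aln.is_read2 else 1
            paired[aln.query_name] = paired.get(aln.query_name, False) or aln.is_paired
            rec = AlignmentRecord(
                read_id=aln.query_name,
                mate=mate,
                chrom=aln.reference_name,
                position=aln.reference_start + 1,
                mapq=aln.mapping_quality,
                has_secondary_score=aln.has_tag("XS"),
                mismatches=int(aln.get_tag("XM")) if aln.has_tag("XM") else 0,
                proper_pair=aln.is_proper_pair,
            )
            key = (rec.read_id, rec.mate)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(rec)

    kept: dict[tuple[str, int], AlignmentRecord] = {}
    for key in order:
        choice = filter_alignments(groups[key], rng)
        if choice is not None:
            kept[key] = choice
    out: list[AlignmentRecord] = []
    for key in order:
        if key not in kept:
            continue
        read_id, mate = key
        if paired[read_id]:
            other = (read_id, 3 - mate)
            if other not in kept:
                continue  # discard pairs with only one aligned mate
        out.append(kept[key])
    return out


@dataclass
class CoverageTrack:
    """Windowed per-chromosome signal with its windowing and normalization tag."""

    window_bp: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    normalization: str = "raw"  # raw | per-billion | log2-ratio
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}

    def same_windowing(self, other: "CoverageTrack") -> bool:
        return (
            self.window_bp == other.window_bp
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def windowed_coverage(per_base: dict[str, np.ndarray], window_bp: int) -> CoverageTrack:
    """Mean coverage in adjacent windows; the terminal partial window is
    averaged over its actual width."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, vals in per_base.items():
        x = np.asarray(vals, dtype=float)
        n = len(x)
        edges = np.arange(0, n, window_bp)
        sums = np.add.reduceat(x, edges)
        widths = np.minimum(edges + window_bp, n) - edges
        out[chrom] = sums / widths
    return CoverageTrack(window_bp, out, normalization="raw")


def normalize_library_sum(track: CoverageTrack, scale: float = 1e9) -> CoverageTrack:
    """Scale so the width-weighted sum of coverage equals ``scale`` (reads-per-billion
    by default); makes libraries of different depth comparable before ratios."""
    weighted = 0.0
    for chrom, vals in track.values.items():
        widths = np.full(len(vals), float(track.window_bp))
        # terminal window may be partial; its weight is irrelevant for ratios but
        # kept proportional for the conservation invariant
        weighted += float((vals * widths).sum())
    if weighted == 0:
        raise ValueError("cannot normalize an all-zero track")
    factor = scale / weighted
    return CoverageTrack(
        track.window_bp,
        {c: v * factor for c, v in track.values.items()},
        normalization="per-billion",
    )


def normalize_log2_ratio(
    chip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-window log2((chip + pc) / (input + pc)); both tracks must share windowing."""
    if not chip.same_windowing(input_track):
        raise ValueError("windowing mismatch between ChIP and input tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = {
        c: np.log2((chip.values[c] + pseudocount) / (input_track.values[c] + pseudocount))
        for c in chip.values
    }
    return CoverageTrack(chip.window_bp, out, normalization="log2-ratio", pseudocount=pseudocount)


def _interval_mean(vals: np.ndarray, window_bp: int, start: float, end: float) -> float:
    """Overlap-weighted mean of track windows over [start, end) in 0-based bp.

    Returns 0.0 for windows with no overlapping signal (the w0 convention).
    """
    if end <= start:
        return 0.0
    first = int(start // window_bp)
    last = int(np.ceil(end / window_bp))
    total = 0.0
    weight = 0.0
    for w in range(max(first, 0), min(last, len(vals))):
        lo = max(start, w * window_bp)
        hi = min(end, (w + 1) * window_bp)
        if hi > lo:
            total += vals[w] * (hi - lo)
            weight += hi - lo
    return total / weight if weight > 0 else 0.0


@dataclass
class MetaprofileMatrix:
    """Features x windows coverage matrix around scaled gene bodies."""

    matrix: np.ndarray
    body_bins: int
    flank_window_bp: int
    flank_bp: int

    @property
    def n_flank_windows(self) -> int:
        return self.flank_bp // self.flank_window_bp

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def gene_metaprofile(
    track: CoverageTrack,
    features: pd.DataFrame,
    body_bins: int = 20,
    flank_bp: int = 2000,
    flank_window_bp: int = 20,
) -> MetaprofileMatrix:
    """Coverage matrix over proportionally scaled feature bodies plus fixed flanks.

    ``features`` needs columns chrom/start/end/strand (1-based inclusive).
    Bodies are split into ``body_bins`` proportional windows, each flank into
    ``flank_bp // flank_window_bp`` fixed windows; each window's value is the
    overlap-weighted mean of the track with empty windows set to 0 (w0).
    Minus-strand rows are reversed so all run TSS -> TTS.
    """
    if flank_bp % flank_window_bp:
        raise ValueError("flank_bp must be a multiple of flank_window_bp")
    n_flank = flank_bp // flank_window_bp
    ncol = n_flank + body_bins + n_flank
    rows = []
    for f in features.itertuples():
        chrom = str(f.chrom)
        if chrom not in track.values:
            raise ValueError(f"feature chromosome {chrom} absent from track")
        vals = track.values[chrom]
        chrom_len = len(vals) * track.window_bp
        start0, end0 = int(f.start) - 1, int(f.end)  # to 0-based half-open
        if start0 < 0 or end0 > chrom_len:
            raise ValueError(f"feature outside track on {chrom}")
        row = np.zeros(ncol)
        # upstream flank, body, downstream flank in genomic orientation
        for k in range(n_flank):
            lo = start0 - flank_bp + k * flank_window_bp
            row[k] = _interval_mean(vals, track.window_bp, max(lo, 0.0),
                                    max(lo + flank_window_bp, 0.0))
        body_len = end0 - start0
        edges = start0 + body_len * np.arange(body_bins + 1) / body_bins
        for k in range(body_bins):
            row[n_flank + k] = _interval_mean(vals, track.window_bp, edges[k], edges[k + 1])
        for k in range(n_flank):
            lo = end0 + k * flank_window_bp
            row[n_flank + body_bins + k] = _interval_mean(
                vals, track.window_bp, min(lo, float(chrom_len)),
                min(lo + flank_window_bp, float(chrom_len)),
            )
        if str(getattr(f, "strand", "+")) == "-":
            row = row[::-1]
        rows.append(row)
    return MetaprofileMatrix(np.array(rows), body_bins, flank_window_bp, flank_bp)


def _region_mask(track: CoverageTrack, layout: GenomeLayout, region: str, chrom: str) -> np.ndarray:
    n = len(track.values[chrom])
    centers = np.arange(n) * track.window_bp + track.window_bp / 2 + 0.5  # ~1-based
    c = layout[chrom]
    in_pericen = (centers >= c.pericen_start) & (centers <= c.pericen_end)
    if region == "all":
        return np.ones(n, dtype=bool)
    if region == "pericentromeres":
        return in_pericen
    if region == "arms":
        return ~in_pericen
    raise ValueError("region must be one of all/arms/pericentromeres")


def track_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    layout: GenomeLayout,
    region: str = "all",
) -> float:
    """Spearman rank correlation over windows whose centers fall in the region."""
    if not track_a.same_windowing(track_b):
        raise ValueError("windowing mismatch between tracks")
    xs, ys = [], []
    for chrom in track_a.values:
        mask = _region_mask(track_a, layout, region, chrom)
        xs.append(track_a.values[chrom][mask])
        ys.append(track_b.values[chrom][mask])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("fewer than 3 windows in region")
    rs, _ = stats.spearmanr(x, y)
    return float(rs)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            for w, v in enumerate(vals):
                fh.write(f"{chrom}\t{w * track.window_bp}\t{(w + 1) * track.window_bp}\t{v:g}\n")


def read_bedgraph(path: str | Path, window_bp: int) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "start", "end", "value"])
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        n = int(np.ceil(g["end"].max() / window_bp))
        vals = np.zeros(n)
        idx = (g["start"].to_numpy() // window_bp).astype(int)
        vals[idx] = g["value"].to_numpy()
        out[str(chrom)] = vals
    return CoverageTrack(window_bp, out)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read features from 6-column BED or GFF3 into chrom/start/end/strand (1-based)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score", "strand",
                   "phase", "attributes"],
        )
        return df[["chrom", "start", "end", "strand"]].astype(
            {"start": int, "end": int}
        ).reset_index(drop=True)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    out = df[["chrom", "start", "end", "strand"]].copy()
    out["start"] = out["start"].astype(int) + 1  # BED is 0-based half-open
    out["end"] = out["end"].astype(int)
    return out
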