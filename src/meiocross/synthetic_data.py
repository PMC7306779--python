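"""Synthetic meioses, F2 populations, tetrads and coverage tracks.

The generator produces every input the analysis consumes, under a
gamma-renewal crossover model that separates the two biological axes the
analyses probe:

* **interference** — inter-crossover distances on the *genetic* scale are
  gamma distributed with shape ``nu`` and rate ``2 * nu`` per Morgan, so the
  bivalent event count has mean 2 x map length (in Morgans) for every ``nu``;
  ``nu = 1`` is a Poisson process (no interference) and larger ``nu`` gives
  progressively more regular spacing. Stationarity is enforced by drawing the
  first event from the equilibrium forward-recurrence distribution, which
  avoids edge artifacts that would bias telomere windows.
* **landscape** — a piecewise-constant crossover intensity (cM/Mb) maps
  genetic positions to physical bp by inverting the cumulative intensity, so
  telomere-biased landscapes can be simulated at a fixed total map length.

Each crossover picks one of the two chromatids of each homolog independently
(no chromatid interference); the four gametes are traced through the
resulting exchanges, giving correct tetrad (PD:TT:NPD) statistics. An F2
individual is the union of one gamete from each of two independent meioses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coverage_profiles import CoverageTrack
from .genome import GenomeLayout
from .genotype_blocks import F2BlockSet
from .tetrad_ftl import TetradPattern

__all__ = [
    "ChromosomeMap",
    "SimConfig",
    "SimulatedMeiosis",
    "simulate_bivalent_cos",
    "make_gametes",
    "make_tetrad_pattern",
    "simulate_tetrads",
    "make_f2_population",
    "make_gradient_track",
]


@dataclass(frozen=True)
class ChromosomeMap:
    """Crossover intensity landscape of one chromosome.

    Piecewise-constant intensity over physical segments; ``edges_bp`` has one
    more entry than ``cum_morgans`` is implied by: cum_morgans[i] is the map
    position (Morgans) at edges_bp[i], increasing, starting at 0.
    """

    length_bp: int
    edges_bp: np.ndarray  # segment boundaries, starts at 0, ends at length_bp
    cum_morgans: np.ndarray  # cumulative genetic position at each edge

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_bp, dtype=float)
        c = np.asarray(self.cum_morgans, dtype=float)
        if len(e) != len(c) or len(e) < 2:
            raise ValueError("edges and cumulative map must align")
        if e[0] != 0 or e[-1] != self.length_bp:
            raise ValueError("edges must span [0, length_bp]")
        if np.any(np.diff(e) <= 0) or np.any(np.diff(c) < 0) or c[0] != 0:
            raise ValueError("non-integrable intensity")
        object.__setattr__(self, "edges_bp", e)
        object.__setattr__(self, "cum_morgans", c)

    @property
    def total_morgans(self) -> float:
        return float(self.cum_morgans[-1])

    def genetic_to_physical(self, g) -> np.ndarray:
        """Invert the cumulative intensity: map positions (Morgans) -> bp."""
        return np.interp(np.asarray(g, dtype=float), self.cum_morgans, self.edges_bp)

    @classmethod
    def uniform(cls, length_bp: int, morgans: float) -> "ChromosomeMap":
        return cls(length_bp, np.array([0.0, length_bp]), np.array([0.0, morgans]))

    @classmethod
    def from_intensity(cls, length_bp: int, edges_bp, cm_per_mb) -> "ChromosomeMap":
        """Build from segment boundaries (bp) and per-segment intensity in cM/Mb."""
        e = np.asarray(edges_bp, dtype=float)
        inten = np.asarray(cm_per_mb, dtype=float)
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        seg_morgans = inten * np.diff(e) / 1e8  # cM/Mb * bp -> Morgans
        cum = np.concatenate([[0.0], np.cumsum(seg_morgans)])
        return cls(length_bp, e, cum)

    @classmethod
    def telomere_biased(
        cls, length_bp: int, morgans: float, bias: float, zone_bp: int = 1_000_000
    ) -> "ChromosomeMap":
        """Uniform landscape with ``bias``-fold intensity within ``zone_bp`` of
        each telomere, rescaled to keep the total map length fixed."""
        z = min(zone_bp, length_bp // 2)
        edges = np.array([0.0, z, length_bp - z, length_bp])
        weights = np.array([bias * z, 1.0 * (length_bp - 2 * z), bias * z])
        cum = np.concatenate([[0.0], np.cumsum(weights)]) * (morgans / weights.sum())
        return cls(length_bp, edges, cum)


def _equilibrium_first_interval(nu: float, rate: float, rng: np.random.Generator) -> float:
    """Draw the stationary forward-recurrence time of a gamma(nu, rate) renewal.

    For integer nu this is an equal-weight mixture of gamma(k, rate),
    k = 1..nu (Erlang decomposition); otherwise the equilibrium CDF
    F_e(x) = (rate/nu) * x * (1 - G_nu(x)) + G_{nu+1}(x) is inverted
    numerically.
    """
    if float(nu).is_integer():
        k = int(rng.integers(1, int(nu) + 1))
        return float(rng.gamma(k, 1.0 / rate))
    u = float(rng.uniform())
    g_nu = stats.gamma(nu, scale=1.0 / rate)
    g_nu1 = stats.gamma(nu + 1, scale=1.0 / rate)

    def f(x: float) -> float:
        return (rate / nu) * x * g_nu.sf(x) + g_nu1.cdf(x) - u

    hi = g_nu.mean() * 2
    while f(hi) < 0:
        hi *= 2
    return float(optimize.brentq(f, 0.0, hi))


def simulate_bivalent_cos(
    rng: np.random.Generator,
    chrom_map: ChromosomeMap,
    nu: float = 1.0,
    obligate: bool = False,
    _max_resample: int = 100_000,
) -> np.ndarray:
    """Crossover positions (bp) of one bivalent under the gamma renewal model.

    Events occur on the genetic axis at rate 2 per Morgan (mean count
    2 x map length), with gamma(nu) inter-event distances; physical positions
    come from inverting the cumulative intensity. ``obligate`` resamples empty
    bivalents until at least one event occurs, preserving the conditional
    inter-event distribution.
    """
    if nu < 1:
        raise ValueError("gamma shape nu must be >= 1")
    L = chrom_map.total_morgans
    if L < 0:
        raise ValueError("negative map length")
    rate = 2.0 * nu  # per Morgan: mean inter-event distance 1/2 Morgan
    for _ in range(_max_resample):
        if L == 0:
            positions: list[float] = []
        else:
            positions = []
            g = _equilibrium_first_interval(nu, rate, rng)
            while g < L:
                positions.append(g)
                g += float(rng.gamma(nu, 1.0 / rate))
        if positions or not obligate:
            return chrom_map.genetic_to_physical(np.array(positions))
    raise RuntimeError("obligate-CO resampling failed to produce an event")


@dataclass
class SimulatedMeiosis:
    """One chromosome's bivalent: CO positions, chromatid choices, 4 gametes.

    Gametes are (start_origin, breakpoints): ``start_origin`` is 0 (parent 1)
    or 1 (parent 2) at the left end, flipping at each breakpoint. Each CO
    position appears in exactly two gametes.
    """

    positions: np.ndarray  # bp, sorted
    chromatids: np.ndarray  # shape (n_cos, 2): chromatid index of each homolog
    gametes: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def gamete_origin_at(self, gamete: int, positions) -> np.ndarray:
        """Parental origin (0/1) of one gamete at the given bp positions."""
        start, brk = self.gametes[gamete]
        flips = np.searchsorted(brk, np.asarray(positions, dtype=float), side="left")
        return (start + flips) % 2


def make_gametes(
    positions: np.ndarray, rng: np.random.Generator, chromatids: np.ndarray | None = None
) -> SimulatedMeiosis:
    """Resolve COs into four gamete haplotypes with no chromatid interference.

    Each CO independently involves one of the two chromatids of each homolog.
    The four chromatids are traced left to right through the exchanges: a
    chromatid following strand s switches to the partner strand at every CO
    involving s, flipping its parental origin.
    """
    pos = np.asarray(positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("CO positions must be sorted")
    n = len(pos)
    if chromatids is None:
        chromatids = rng.integers(0, 2, size=(n, 2))
    chromatids = np.asarray(chromatids, dtype=int).reshape(n, 2)

    gametes: list[tuple[int, np.ndarray]] = []
    for origin0, strand0 in ((0, 0), (0, 1), (1, 0), (1, 1)):
        # strand identity within the homolog; origin flips when the trace
        # crosses onto the other homolog
        origin = origin0
        strand = strand0
        brks: list[float] = []
        for k in range(n):
            involved = chromatids[k, origin]
            if involved == strand:
                origin = 1 - origin
                strand = chromatids[k, origin]
                brks.append(pos[k])
        gametes.append((origin0, np.array(brks)))
    return SimulatedMeiosis(pos, chromatids, gametes)


def make_tetrad_pattern(meiosis: SimulatedMeiosis, ftl_positions) -> TetradPattern:
    """Spore color flags: presence of the parent-1 (transgene) allele at each
    color locus on each gamete."""
    ftl = np.asarray(ftl_positions, dtype=float)
    spores = []
    for g in range(4):
        origins = meiosis.gamete_origin_at(g, ftl)
        spores.append(tuple(int(o == 0) for o in origins))
    return tuple(spores)  # type: ignore[return-value]


def simulate_tetrads(
    n: int,
    chrom_map: ChromosomeMap,
    ftl_positions,
    nu: float = 1.0,
    obligate: bool = False,
    seed: int | np.random.Generator = 0,
) -> list[TetradPattern]:
    """n independent meioses scored as three-color tetrad patterns."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ftl = np.asarray(ftl_positions, dtype=float)
    if np.any(ftl < 0) or np.any(ftl > chrom_map.length_bp):
        raise ValueError("FTL position outside chromosome")
    out = []
    for _ in range(n):
        pos = simulate_bivalent_cos(rng, chrom_map, nu=nu, obligate=obligate)
        mei = make_gametes(pos, rng)
        out.append(make_tetrad_pattern(mei, ftl))
    return out


@dataclass
class SimConfig:
    """Full parameterization of the synthetic F2 / tetrad / coverage generators."""

    layout: GenomeLayout
    maps: dict[str, ChromosomeMap]
    nu: float = 1.0
    obligate: bool = False
    marker_spacing_bp: int = 100_000
    n_individuals: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.layout) - set(self.maps)
        if missing:
            raise ValueError(f"no chromosome map for: {sorted(missing)}")
        if self.nu < 1:
            raise ValueError("nu must be >= 1")

    @property
    def total_morgans(self) -> float:
        return sum(m.total_morgans for m in self.maps.values())

    @classmethod
    def uniform(
        cls, layout: GenomeLayout, total_morgans: float = 4.0, **kw
    ) -> "SimConfig":
        """Uniform intensity, map length split across chromosomes by bp length."""
        total_bp = layout.total_length
        maps = {
            c.name: ChromosomeMap.uniform(c.length, total_morgans * c.length / total_bp)
            for c in layout.values()
        }
        return cls(layout, maps, **kw)

    @classmethod
    def telomere_biased(
        cls,
        layout: GenomeLayout,
        total_morgans: float = 4.0,
        bias: float = 3.0,
        zone_bp: int = 1_000_000,
        **kw,
    ) -> "SimConfig":
        """Same per-chromosome map lengths as :meth:`uniform`, with the
        intensity concentrated ``bias``-fold into the terminal zones."""
        total_bp = layout.total_length
        maps = {
            c.name: ChromosomeMap.telomere_biased(
                c.length, total_morgans * c.length / total_bp, bias, zone_bp
            )
            for c in layout.values()
        }
        return cls(layout, maps, **kw)


def _marker_positions(length: int, spacing: int) -> np.ndarray:
    """1-based marker panel: every ``spacing`` bp starting at spacing/2."""
    return np.arange(spacing // 2, length + 1, spacing, dtype=float)


def make_f2_population(config: SimConfig, seed: int | np.random.Generator | None = None) -> F2BlockSet:
    """Simulate a selfed-F2 population as a validated genotype-block set.

    Each individual combines one random gamete from each of two independent
    meioses; marker genotypes are the sum of parental origins (0 -> P1,
    1 -> HET, 2 -> P2), and blocks merge equal-genotype marker runs, so block
    boundaries sit at marker positions exactly as in sliding-window
    genotyping output.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state_name = {0: "P1", 1: "HET", 2: "P2"}
    records: list[tuple[str, str, int, int, str]] = []
    markers = {
        name: _marker_positions(config.layout[name].length, config.marker_spacing_bp)
        for name in config.layout
    }
    for i in range(config.n_individuals):
        indiv = f"F2_{i:04d}"
        for name in config.layout:
            mk = markers[name]
            genos = np.zeros(len(mk), dtype=int)
            for _ in range(2):  # two independent meioses (male and female gametes)
                pos = simulate_bivalent_cos(
                    rng, config.maps[name], nu=config.nu, obligate=config.obligate
                )
                mei = make_gametes(pos, rng)
                gamete = int(rng.integers(4))
                genos += mei.gamete_origin_at(gamete, mk)
            change = np.flatnonzero(np.diff(genos)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change - 1, [len(mk) - 1]])
            for s, e in zip(starts, ends):
                records.append(
                    (indiv, name, int(mk[s]), int(mk[e]), state_name[int(genos[s])])
                )
    df = pd.DataFrame(records, columns=["indiv", "chrom", "start", "end", "state"])
    return F2BlockSet(df, config.layout, n_individuals=config.n_individuals)


def make_gradient_track(
    layout: GenomeLayout,
    telomere_value: float,
    centromere_value: float,
    noise_sd: float = 0.0,
    window_bp: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> CoverageTrack:
    """Windowed track interpolating linearly from telomere to centromere along
    each arm (emulating an axis-protein ChIP gradient), plus Gaussian noise."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for c in layout.values():
        n = int(np.ceil(c.length / window_bp))
        centers = np.arange(n) * window_bp + window_bp / 2
        cen_mid = float(c.cen_mid)
        frac = np.where(
            centers <= cen_mid,
            centers / cen_mid,
            (c.length - centers) / max(c.length - cen_mid, 1.0),
        )
        frac = np.clip(frac, 0.0, 1.0)  # 0 at telomere, 1 at centromere
        vals = telomere_value + (centromere_value - telomere_value) * frac
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=n)
        # coverage-like signal is non-negative
        values[c.name] = np.clip(vals, 0.0, None)
    return CoverageTrack(window_bp, values, normalization="raw")
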