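"""Simulation of maize-style tetrad genotype data with known meiotic events.

A single meiosis produces four haploid microspores (a tetrad).  Each
chromosome enters meiosis as a bivalent of four chromatids, two carrying the
SK haplotype and two the Zheng58 ("Zh") haplotype.  Crossovers (COs)
reciprocally exchange the material distal to the exchange point between one
SK- and one Zh-derived chromatid, so outside gene-conversion tracts every
marker segregates 2:2 among the four cells.  A CO-associated conversion
tract overwrites a short stretch of the recipient chromatid with the
homologous parent's alleles, producing local 3:1 segregation.

The simulator is calibrated to the structure of a published maize
single-microspore study: 24 tetrads, ~38 COs per tetrad, median inter-marker
spacing of 235 bp, per-cell marker coverage ~41%, amplification error rate
1e-6..1e-7 per call, and conversion tracts of 220-1,875 bp at ~20% of COs.
Crossover interference follows a stationary gamma renewal process in
genetic distance; chromatid interference follows a two-parameter
chromatid-reuse model.

Every stochastic operation takes an explicit seed and is deterministic
given that seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SK",
    "ZH",
    "MISSING",
    "PARENT_NAMES",
    "PARENT_CODES",
    "Chromosome",
    "GenomeSpec",
    "MarkerMap",
    "MeiosisParams",
    "ObservationParams",
    "CrossoverTruth",
    "ConversionTruth",
    "TetradTruth",
    "GenotypeMatrix",
    "default_genome",
    "build_marker_map",
    "simulate_tetrads",
    "observe_tetrads",
]

# Integer codes used throughout the package for parental-origin calls.
SK: int = 0
ZH: int = 1
MISSING: int = -1

PARENT_NAMES: dict[int, str] = {SK: "SK", ZH: "Zh"}
PARENT_CODES: dict[str, int] = {"SK": SK, "Zh": ZH, "ZH": ZH, "NA": MISSING, ".": MISSING}


# ---------------------------------------------------------------------------
# Genome and marker map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, physical length and centromere position (bp, 1-based)."""

    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"chromosome {self.name}: centromere must lie strictly inside (0, length)"
            )


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered set of chromosomes with centromere coordinates.

    Centromere positions are used to assign chromosome arms and the
    centromere-spanning parental identity of each chromatid.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __iter__(self):
        return iter(self.chromosomes)


def default_genome(
    n_chromosomes: int = 10,
    chrom_length: int = 5_000_000,
    centromere_frac: float = 0.45,
) -> GenomeSpec:
    """A compact stand-in genome with the karyotype structure of maize.

    Ten chromosomes with internal centromeres.  Lengths are scaled down
    from the ~2.1-Gb maize genome so that simulations at the study's marker
    density (235-bp median spacing) stay tractable; CO counts are controlled
    independently through :class:`MeiosisParams`, so the recombination
    structure per tetrad is preserved.
    """
    chroms = tuple(
        Chromosome(
            name=f"chr{i + 1}",
            length=int(chrom_length),
            centromere=max(1, int(chrom_length * centromere_frac)),
        )
        for i in range(n_chromosomes)
    )
    return GenomeSpec(chroms)


@dataclass(frozen=True)
class MarkerMap:
    """Per-chromosome sorted positions of diagnostic (SK vs Zh) markers.

    Positions are 1-based, strictly increasing, and at least 4 bp apart
    (mirroring the minimum diagnostic-SNP spacing used when comparing the
    parental genomes).
    """

    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) == 0:
                continue
            gaps = np.diff(pos)
            if len(gaps) and gaps.min() < 4:
                raise ValueError(f"{chrom}: marker spacing below 4 bp")
            if len(gaps) and gaps.min() <= 0:
                raise ValueError(f"{chrom}: positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def chroms(self) -> list[str]:
        return list(self.positions.keys())

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"chrom": chrom, "pos": pos})
            for chrom, pos in self.positions.items()
        ]
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos"])
        return pd.concat(parts, ignore_index=True)

    def median_spacing(self) -> float:
        gaps = np.concatenate(
            [np.diff(p) for p in self.positions.values() if len(p) > 1]
        )
        return float(np.median(gaps)) if len(gaps) else math.nan


def build_marker_map(
    genome: GenomeSpec, median_spacing: float = 235.0, seed: int = 0
) -> MarkerMap:
    """Draw a random marker map with a target median inter-marker spacing.

    Gaps are 4 bp plus an exponential excess whose scale is chosen so the
    continuous gap median equals ``median_spacing``; the >=4 bp minimum
    spacing holds by construction.  The realized median lands within a few
    percent of the request.
    """
    if median_spacing < 4:
        raise ValueError("median_spacing must be >= 4 bp")
    rng = np.random.default_rng(seed)
    scale = (median_spacing - 4.0) / math.log(2.0) if median_spacing > 4 else 0.0
    positions: dict[str, np.ndarray] = {}
    for chrom in genome:
        pos_list: list[np.ndarray] = []
        current = 0.0
        remaining = chrom.length
        # draw in batches until the chromosome is covered
        while current < chrom.length:
            n = max(64, int(remaining / max(median_spacing, 4.0) * 1.3))
            gaps = 4.0 + rng.exponential(scale, size=n) if scale > 0 else np.full(n, 4.0)
            cum = current + np.cumsum(gaps)
            keep = cum <= chrom.length
            pos_list.append(np.rint(cum[keep]).astype(np.int64))
            if not keep.all():
                current = chrom.length  # done
            else:
                current = cum[-1]
                remaining = chrom.length - current
        pos = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=np.int64)
        # rounding can in principle collapse a gap below 4; enforce by rejection
        if len(pos) > 1:
            keep_mask = np.ones(len(pos), dtype=bool)
            last = pos[0]
            for i in range(1, len(pos)):
                if pos[i] - last < 4:
                    keep_mask[i] = False
                else:
                    last = pos[i]
            pos = pos[keep_mask]
        positions[chrom.name] = pos
    return MarkerMap(positions)


# ---------------------------------------------------------------------------
# Meiosis parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeiosisParams:
    """Parameters of the meiosis model.

    co_mean_per_tetrad
        Expected genome-wide CO count per tetrad (study mean: 38).
    interference_shape
        Shape nu of the stationary gamma renewal process placing COs in
        genetic distance; nu = 1 gives a Poisson process (no interference),
        nu > 1 positive interference.
    reuse_prob_sk, reuse_prob_zh
        Probability that a CO engages the same SK (resp. Zh) chromatid as
        the previous CO on that chromosome; 0.5 means no chromatid
        interference.  Implied strand-category frequencies for consecutive
        CO pairs are f2 = r_sk*r_zh, f3(SK-shared) = r_sk*(1-r_zh),
        f3(Zh-shared) = (1-r_sk)*r_zh, f4 = (1-r_sk)*(1-r_zh).
    gc_prob_per_co
        Probability that a CO carries a detectable conversion tract
        (study: ~20% of COs).
    gc_length_min, gc_length_max
        Conversion-tract length range in bp (study: 220-1,875 bp),
        drawn uniformly.
    obligate_co
        If true, chromosomes with zero COs are redrawn until at least one
        occurs (conditioning that raises the realized genome-wide mean).
    cm_per_mb
        Uniform genetic map density; the study reports no genome-wide map
        function, so physical and genetic distance are proportional by
        default (1 cM/Mb).
    rate_map
        Optional per-chromosome piecewise recombination rates overriding
        ``cm_per_mb``: chrom -> (bin edges in bp starting at 0 and ending at
        the chromosome length, rates in cM/Mb per bin).  Used to model
        recombination-active regions.
    """

    co_mean_per_tetrad: float = 38.0
    interference_shape: float = 1.0
    reuse_prob_sk: float = 0.5
    reuse_prob_zh: float = 0.5
    gc_prob_per_co: float = 0.2
    gc_length_min: int = 220
    gc_length_max: int = 1875
    obligate_co: bool = False
    cm_per_mb: float = 1.0
    rate_map: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None

    def __post_init__(self) -> None:
        if self.co_mean_per_tetrad < 0:
            raise ValueError("co_mean_per_tetrad must be >= 0")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be > 0")
        for r in (self.reuse_prob_sk, self.reuse_prob_zh, self.gc_prob_per_co):
            if not 0.0 <= r <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.gc_length_min <= self.gc_length_max:
            raise ValueError("require 0 < gc_length_min <= gc_length_max")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")

    def strand_category_probs(self) -> dict[str, float]:
        """Closed-form strand-reuse category probabilities for consecutive COs."""
        rs, rz = self.reuse_prob_sk, self.reuse_prob_zh
        return {
            "2chr": rs * rz,
            "3chr_SK": rs * (1 - rz),
            "3chr_Zh": (1 - rs) * rz,
            "4chr": (1 - rs) * (1 - rz),
        }


@dataclass(frozen=True)
class ObservationParams:
    """Observation model: i.i.d. per-call dropout plus allele-flip error."""

    coverage: float = 0.41
    error_rate: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossoverTruth:
    """A simulated crossover: position and the engaged chromatids.

    ``sk_chromatid``/``zh_chromatid`` index the physical strand (1 or 2) on
    each homolog; ``carrier_cells`` are the two cells (1-4) whose parental
    origin switches at ``pos``.
    """

    chrom: str
    pos: int
    sk_chromatid: int
    zh_chromatid: int
    carrier_cells: tuple[int, int]


@dataclass(frozen=True)
class ConversionTruth:
    """A simulated CO-associated conversion tract on ``recipient_cell``.

    Interval is half-open [start, end); the recipient carries the donor
    parent's alleles inside the tract, giving 3:1 segregation there.
    """

    co_index: int
    chrom: str
    recipient_cell: int
    donor: int
    start: int
    end: int


@dataclass
class _ChromatidHaplotype:
    """Piecewise-constant parental origin: position p has origin
    ``origins[searchsorted(breaks, p, 'right')]``."""

    breaks: np.ndarray
    origins: np.ndarray

    def at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks, positions, side="right")
        return self.origins[idx]


@dataclass
class TetradTruth:
    """Ground truth for one simulated tetrad.

    ``haplotypes[chrom]`` holds four chromatid haplotypes in cell order
    1-4; cells 1-2 carry SK centromeres, cells 3-4 Zh centromeres.
    """

    tetrad_id: int
    haplotypes: dict[str, list[_ChromatidHaplotype]]
    co_events: list[CrossoverTruth]
    gc_events: list[ConversionTruth]

    SK_CELLS = (1, 2)
    ZH_CELLS = (3, 4)

    def haplotype(self, chrom: str, cell: int, positions: np.ndarray) -> np.ndarray:
        """Parental-origin codes of one cell at the given positions."""
        return self.haplotypes[chrom][cell - 1].at(np.asarray(positions))

    def co_positions(self, chrom: str | None = None) -> list[int]:
        return [c.pos for c in self.co_events if chrom is None or c.chrom == chrom]

    @property
    def n_cos(self) -> int:
        return len(self.co_events)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Markers x cells matrix of parental-origin calls.

    ``calls`` is an int8 array with values ``SK`` (0), ``ZH`` (1) or
    ``MISSING`` (-1); rows follow ``markers`` (columns ``chrom``, ``pos``),
    columns follow ``cells`` (columns ``tetrad``, ``cell`` with cell ids
    1-4 within each tetrad).
    """

    def __init__(
        self,
        markers: pd.DataFrame,
        cells: pd.DataFrame,
        calls: np.ndarray,
        marker_map: MarkerMap | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(cells)):
            raise ValueError("calls shape must be (n_markers, n_cells)")
        for tetrad, grp in cells.groupby("tetrad"):
            if sorted(grp["cell"]) != [1, 2, 3, 4]:
                raise ValueError(
                    f"tetrad {tetrad}: cell ids must be exactly {{1,2,3,4}}"
                )
        if marker_map is not None:
            for chrom, grp in markers.groupby("chrom", sort=False):
                known = marker_map.positions.get(str(chrom))
                if known is None or not np.isin(grp["pos"].to_numpy(), known).all():
                    raise ValueError(f"marker positions on {chrom} absent from marker map")
        self.markers = markers.reset_index(drop=True)
        self.cells = cells.reset_index(drop=True)
        self.calls = calls
        self.marker_map = marker_map

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def tetrads(self) -> list[int]:
        return list(dict.fromkeys(self.cells["tetrad"].tolist()))

    def cell_columns(self, tetrad: int) -> np.ndarray:
        """Column indices of the four cells of a tetrad, ordered by cell id."""
        mask = self.cells["tetrad"] == tetrad
        idx = self.cells.index[mask].to_numpy()
        order = np.argsort(self.cells.loc[mask, "cell"].to_numpy())
        return idx[order]

    def marker_rows(self, chrom: str) -> np.ndarray:
        return self.markers.index[self.markers["chrom"] == chrom].to_numpy()

    def subset_markers(self, row_mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.loc[row_mask].reset_index(drop=True),
            self.cells.copy(),
            self.calls[row_mask],
            self.marker_map,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.copy(), self.cells.copy(), self.calls.copy(), self.marker_map
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with columns chrom, pos, tetrad, cell, call."""
        n_m, n_c = self.calls.shape
        frame = pd.DataFrame(
            {
                "chrom": np.repeat(self.markers["chrom"].to_numpy(), n_c),
                "pos": np.repeat(self.markers["pos"].to_numpy(), n_c),
                "tetrad": np.tile(self.cells["tetrad"].to_numpy(), n_m),
                "cell": np.tile(self.cells["cell"].to_numpy(), n_m),
                "call": self.calls.ravel(),
            }
        )
        frame["call"] = frame["call"].map(
            {SK: "SK", ZH: "Zh", MISSING: "NA"}
        )
        return frame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.markers.equals(other.markers)
            and self.cells.equals(other.cells)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Genetic map helper
# ---------------------------------------------------------------------------


class _GeneticMap:
    """Piecewise-linear physical<->genetic mapping for one chromosome."""

    def __init__(self, length: int, cm_per_mb: float,
                 piecewise: tuple[Sequence[float], Sequence[float]] | None = None):
        if piecewise is None:
            edges = np.array([0.0, float(length)])
            rates = np.array([cm_per_mb])
        else:
            edges = np.asarray(piecewise[0], dtype=float)
            rates = np.asarray(piecewise[1], dtype=float)
            if len(edges) != len(rates) + 1 or edges[0] != 0 or edges[-1] != length:
                raise ValueError("rate_map edges must span [0, length]")
            if (rates < 0).any():
                raise ValueError("recombination rates must be >= 0")
        self.edges = edges
        # cumulative genetic position (cM) at each edge
        seg_cm = np.diff(edges) / 1e6 * rates
        self.cum_cm = np.concatenate([[0.0], np.cumsum(seg_cm)])
        self.rates = rates
        self.length_cm = float(self.cum_cm[-1])

    def to_physical(self, genetic: np.ndarray) -> np.ndarray:
        return np.interp(genetic, self.cum_cm, self.edges)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _stationary_gamma_renewal(
    rng: np.random.Generator, length: float, mean_gap: float, shape: float
) -> np.ndarray:
    """Event positions of a stationary gamma renewal process on [0, length).

    Stationarity is obtained by starting the process a long burn-in before
    the origin and discarding events below zero, so the expected event count
    is length / mean_gap irrespective of the shape parameter.
    """
    if length <= 0 or mean_gap <= 0 or not np.isfinite(mean_gap):
        return np.empty(0)
    scale = mean_gap / shape
    burn = 20.0 * mean_gap
    t = -burn
    events: list[float] = []
    # draw gaps in batches
    while t < length:
        n = max(16, int((length - t) / mean_gap * 1.5))
        gaps = rng.gamma(shape, scale, size=n)
        cum = t + np.cumsum(gaps)
        events.extend(cum[(cum >= 0) & (cum < length)].tolist())
        t = cum[-1]
    return np.array(sorted(events))


def _assign_strands(
    rng: np.random.Generator, n: int, r_sk: float, r_zh: float
) -> tuple[np.ndarray, np.ndarray]:
    """Chromatid indices (0/1 per homolog) for n successive COs under the
    reuse model: the first CO picks uniformly, each later CO keeps the
    previous CO's chromatid with probability r per homolog."""
    sk = np.empty(n, dtype=np.int64)
    zh = np.empty(n, dtype=np.int64)
    if n == 0:
        return sk, zh
    sk[0] = rng.integers(2)
    zh[0] = rng.integers(2)
    u_sk = rng.random(n - 1)
    u_zh = rng.random(n - 1)
    for i in range(1, n):
        sk[i] = sk[i - 1] if u_sk[i - 1] < r_sk else 1 - sk[i - 1]
        zh[i] = zh[i - 1] if u_zh[i - 1] < r_zh else 1 - zh[i - 1]
    return sk, zh


def _trace_carriers(
    positions: np.ndarray,
    sk_strand: np.ndarray,
    zh_strand: np.ndarray,
    centromere: int,
) -> list[tuple[int, int]]:
    """Carrier cells (1-4) for each CO by following physical strands.

    Cells 1,2 start on SK strands 1,2 and cells 3,4 on Zh strands 1,2 at the
    centromere.  Arms are traced outward from the centromere; at each CO the
    cells currently copying the engaged SK and Zh strands exchange strands,
    so exactly two cells switch parental origin at every CO.
    """
    carriers: list[tuple[int, int] | None] = [None] * len(positions)
    right = [i for i in range(len(positions)) if positions[i] >= centromere]
    left = [i for i in range(len(positions)) if positions[i] < centromere]
    for idx_list in (sorted(right, key=lambda i: positions[i]),
                     sorted(left, key=lambda i: -positions[i])):
        # strand -> cell map at the centromere: SK strands 0,1 -> cells 1,2;
        # Zh strands 0,1 -> cells 3,4
        cell_of_strand = {("SK", 0): 1, ("SK", 1): 2, ("ZH", 0): 3, ("ZH", 1): 4}
        for i in idx_list:
            a = cell_of_strand[("SK", int(sk_strand[i]))]
            b = cell_of_strand[("ZH", int(zh_strand[i]))]
            carriers[i] = (a, b)
            cell_of_strand[("SK", int(sk_strand[i]))] = b
            cell_of_strand[("ZH", int(zh_strand[i]))] = a
    assert all(c is not None for c in carriers)
    return carriers  # type: ignore[return-value]


def simulate_tetrads(
    genome: GenomeSpec,
    marker_map: MarkerMap,
    params: MeiosisParams,
    n_tetrads: int,
    seed: int = 0,
) -> list[TetradTruth]:
    """Simulate ``n_tetrads`` meioses and return their ground truth.

    CO positions follow a stationary gamma renewal process in genetic
    distance with shape ``params.interference_shape``, scaled so the
    expected genome-wide total per tetrad equals ``params.co_mean_per_tetrad``.
    Chromatids are engaged by the reuse model; conversion tracts are placed
    distal to the CO breakpoint on one recombinant chromatid, with the
    homologous (centromere-proximal) parent as donor.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    rng = np.random.default_rng(seed)
    gmaps = {
        c.name: _GeneticMap(
            c.length,
            params.cm_per_mb,
            None if params.rate_map is None else params.rate_map.get(c.name),
        )
        for c in genome
    }
    total_cm = sum(g.length_cm for g in gmaps.values())
    mean_gap_cm = (
        total_cm / params.co_mean_per_tetrad if params.co_mean_per_tetrad > 0 else math.inf
    )

    truths: list[TetradTruth] = []
    for t in range(n_tetrads):
        co_events: list[CrossoverTruth] = []
        gc_events: list[ConversionTruth] = []
        haplotypes: dict[str, list[_ChromatidHaplotype]] = {}
        for chrom in genome:
            gmap = gmaps[chrom.name]
            for _attempt in range(1000):
                genetic = _stationary_gamma_renewal(
                    rng, gmap.length_cm, mean_gap_cm, params.interference_shape
                )
                if len(genetic) or not params.obligate_co or mean_gap_cm == math.inf:
                    break
            phys = np.unique(
                np.clip(np.rint(gmap.to_physical(genetic)).astype(np.int64), 1,
                        chrom.length - 1)
            )
            n = len(phys)
            sk_strand, zh_strand = _assign_strands(
                rng, n, params.reuse_prob_sk, params.reuse_prob_zh
            )
            carriers = _trace_carriers(phys, sk_strand, zh_strand, chrom.centromere)

            # per-cell switch positions keyed by local CO index
            switch_pos: dict[int, list[tuple[int, int]]] = {c: [] for c in (1, 2, 3, 4)}
            for i in range(n):
                a, b = carriers[i]
                switch_pos[a].append((int(phys[i]), i))
                switch_pos[b].append((int(phys[i]), i))

            base_index = len(co_events)
            for i in range(n):
                co_events.append(
                    CrossoverTruth(
                        chrom=chrom.name,
                        pos=int(phys[i]),
                        sk_chromatid=int(sk_strand[i]) + 1,
                        zh_chromatid=int(zh_strand[i]) + 1,
                        carrier_cells=carriers[i],
                    )
                )

            # conversion tracts: displace the recipient's switch point distally
            for i in range(n):
                if params.gc_prob_per_co <= 0 or rng.random() >= params.gc_prob_per_co:
                    continue
                tract_len = int(
                    rng.integers(params.gc_length_min, params.gc_length_max + 1)
                )
                recipient = carriers[i][int(rng.integers(2))]
                x = int(phys[i])
                own = sorted(p for p, _ in switch_pos[recipient])
                if x >= chrom.centromere:
                    nxt = [p for p in own if p > x]
                    bound = min(nxt) if nxt else chrom.length
                    end = min(x + tract_len, bound, chrom.length)
                    start = x
                else:
                    prv = [p for p in own if p < x]
                    bound = max(prv) if prv else 0
                    start = max(x - tract_len, bound + 1, 1)
                    end = x
                if end <= start:
                    continue
                # move the recipient's switch for this CO to the tract's distal edge
                entry = switch_pos[recipient]
                j = entry.index((x, i))
                entry[j] = (end if x >= chrom.centromere else start, i)
                # donor is the recipient's centromere-proximal parent at the CO
                donor = _proximal_origin(recipient, switch_pos[recipient], x,
                                         chrom.centromere)
                gc_events.append(
                    ConversionTruth(
                        co_index=base_index + i,
                        chrom=chrom.name,
                        recipient_cell=recipient,
                        donor=donor,
                        start=start,
                        end=end,
                    )
                )

            haplotypes[chrom.name] = [
                _build_haplotype([p for p, _ in switch_pos[c]], chrom.centromere,
                                 SK if c in (1, 2) else ZH)
                for c in (1, 2, 3, 4)
            ]
        truths.append(
            TetradTruth(
                tetrad_id=t + 1,
                haplotypes=haplotypes,
                co_events=co_events,
                gc_events=gc_events,
            )
        )
    return truths


def _proximal_origin(
    cell: int, switches: list[tuple[int, int]], x: int, centromere: int
) -> int:
    """Parental origin of ``cell`` on the centromere side of position x,
    given its (possibly displaced) switch positions."""
    base = SK if cell in (1, 2) else ZH
    if x >= centromere:
        n = sum(1 for p, _ in switches if centromere <= p < x)
    else:
        n = sum(1 for p, _ in switches if x < p < centromere)
    return base ^ (n & 1)


def _build_haplotype(
    switch_positions: Iterable[int], centromere: int, base: int
) -> _ChromatidHaplotype:
    """Piecewise origin from switch positions: crossing any switch flips the
    origin; the segment containing the centromere carries ``base``."""
    breaks = np.array(sorted(switch_positions), dtype=np.int64)
    n_seg = len(breaks) + 1
    cen_seg = int(np.searchsorted(breaks, centromere, side="right"))
    origins = np.empty(n_seg, dtype=np.int8)
    for s in range(n_seg):
        origins[s] = base ^ (abs(s - cen_seg) & 1)
    return _ChromatidHaplotype(breaks=breaks, origins=origins)


def observe_tetrads(
    truths: Sequence[TetradTruth],
    marker_map: MarkerMap,
    obs: ObservationParams,
) -> GenotypeMatrix:
    """Apply the observation model to simulated truth.

    Each call is observed with probability ``coverage``; an observed call is
    flipped to the other parent with probability ``error_rate``.  Calls are
    i.i.d.; the output is deterministic given ``obs.seed``.
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    rng = np.random.default_rng(obs.seed)
    markers = MarkerMap(marker_map.positions).to_frame()
    chrom_rows = {
        chrom: np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        for chrom in marker_map.chroms()
    }
    cells = pd.DataFrame(
        {
            "tetrad": np.repeat([t.tetrad_id for t in truths], 4),
            "cell": np.tile([1, 2, 3, 4], len(truths)),
        }
    )
    calls = np.full((len(markers), len(cells)), MISSING, dtype=np.int8)
    col = 0
    for truth in truths:
        for cell in (1, 2, 3, 4):
            for chrom in marker_map.chroms():
                pos = marker_map.positions[chrom]
                if len(pos) == 0:
                    continue
                alleles = truth.haplotype(chrom, cell, pos).astype(np.int8)
                u = rng.random(len(pos))
                observed = u < obs.coverage
                flip = rng.random(len(pos)) < obs.error_rate
                out = np.where(flip, 1 - alleles, alleles).astype(np.int8)
                out[~observed] = MISSING
                calls[chrom_rows[chrom], col] = out
            col += 1
    return GenotypeMatrix(markers, cells, calls, marker_map)
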