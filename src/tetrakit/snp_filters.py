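"""Three-layer SNP filtering for tetrad genotype data.

1. Parental diagnostic-SNP calling: sites homozygous in both parents with
   differing alleles, passing quality/depth/unique-depth thresholds, with a
   minimum spacing of 4 bp enforced greedily left to right.
2. Population-level filtering of the microspore genotype matrix: a
   minor-allele-frequency floor, a minimum-call-count floor, and masking of
   short discordant "singleton" haplotype runs seen in few cells.
3. A 10-marker quality-control panel testing 2:2 segregation per tetrad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sim_meiosis import MISSING, SK, ZH, GenotypeMatrix

__all__ = [
    "ParentalSiteCall",
    "DiagnosticSNP",
    "FilterConfig",
    "call_parental_snps",
    "filter_population_snps",
    "qc_marker_panel",
]

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "hom_alt", "het", "nocall")


@dataclass(frozen=True)
class ParentalSiteCall:
    """One parental site: genotype plus quality and depth summaries."""

    chrom: str
    pos: int
    genotype: str  # hom_ref | hom_alt | het | nocall
    allele: str  # called base for homozygous genotypes
    quality: float
    depth: int
    unique_depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not 0 <= self.unique_depth <= self.depth:
            raise ValueError("require depth >= unique_depth >= 0")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class DiagnosticSNP:
    """A site homozygous-different between SK and Zh, informative for
    parental origin."""

    chrom: str
    pos: int
    allele_sk: str
    allele_zh: str

    def __post_init__(self) -> None:
        if self.allele_sk == self.allele_zh:
            raise ValueError("diagnostic SNP alleles must differ")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for all three filter layers.

    Parental thresholds follow conventional short-read heuristics
    (configurable): quality >= 20, depth in [3, max_depth], >= 2 uniquely
    mapped reads.  ``max_depth=None`` means three times the genome-wide
    mean depth of the respective parent, computed from the input.
    """

    min_quality: float = 20.0
    min_depth: int = 3
    max_depth: int | None = None
    min_unique_depth: int = 2
    min_spacing: int = 4
    maf_min: float = 0.1
    min_cells: int = 10
    singleton_max_snps: int = 20
    singleton_max_cells: int = 5  # exclusive bound: runs seen in < 5 cells

    def __post_init__(self) -> None:
        if self.maf_min > 0.5 or self.maf_min < 0:
            raise ValueError("maf_min must lie in [0, 0.5]")
        for v in (self.min_depth, self.min_unique_depth, self.min_spacing,
                  self.min_cells, self.singleton_max_snps, self.singleton_max_cells):
            if v < 0:
                raise ValueError("thresholds must be >= 0")


class OrderingError(ValueError):
    """Input records are not sorted by (chrom, pos) or contain duplicates."""


def _check_sorted(calls: Sequence[ParentalSiteCall], label: str) -> None:
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    for c in calls:
        key = (c.chrom, c.pos)
        if last is not None:
            if c.chrom == last[0]:
                if c.pos == last[1]:
                    raise OrderingError(
                        f"{label}: duplicated position {c.chrom}:{c.pos}"
                    )
                if c.pos < last[1]:
                    raise OrderingError(f"{label}: unsorted at {c.chrom}:{c.pos}")
            elif c.chrom in seen_chroms:
                raise OrderingError(f"{label}: chromosome {c.chrom} not contiguous")
        if last is None or c.chrom != last[0]:
            seen_chroms.add(c.chrom)
        last = key


def call_parental_snps(
    p1: Sequence[ParentalSiteCall],
    p2: Sequence[ParentalSiteCall],
    cfg: FilterConfig = FilterConfig(),
) -> list[DiagnosticSNP]:
    """Call diagnostic SNPs from two parents' site calls (SK first, Zh second).

    A site is retained when both parents are homozygous with different
    alleles and both pass the quality, depth and unique-depth thresholds.
    The >= ``min_spacing`` rule is applied greedily scanning left to right:
    a candidate closer than the spacing to the last retained SNP is dropped.
    """
    _check_sorted(p1, "parent 1")
    _check_sorted(p2, "parent 2")
    by_pos = {(c.chrom, c.pos): c for c in p2}

    def max_depth_for(calls: Sequence[ParentalSiteCall]) -> float:
        if cfg.max_depth is not None:
            return float(cfg.max_depth)
        depths = [c.depth for c in calls]
        return 3.0 * (sum(depths) / len(depths)) if depths else float("inf")

    max1, max2 = max_depth_for(p1), max_depth_for(p2)

    def passes(c: ParentalSiteCall, max_depth: float) -> bool:
        return (
            c.genotype in ("hom_ref", "hom_alt")
            and c.quality >= cfg.min_quality
            and cfg.min_depth <= c.depth <= max_depth
            and c.unique_depth >= cfg.min_unique_depth
        )

    out: list[DiagnosticSNP] = []
    last_kept: dict[str, int] = {}
    for c1 in p1:
        c2 = by_pos.get((c1.chrom, c1.pos))
        if c2 is None:
            continue
        if not (passes(c1, max1) and passes(c2, max2)):
            continue
        if c1.allele == c2.allele:
            continue
        last = last_kept.get(c1.chrom)
        if last is not None and c1.pos - last < cfg.min_spacing:
            continue
        out.append(
            DiagnosticSNP(chrom=c1.chrom, pos=c1.pos, allele_sk=c1.allele,
                          allele_zh=c2.allele)
        )
        last_kept[c1.chrom] = c1.pos
    return out


# ---------------------------------------------------------------------------
# Population-level filtering
# ---------------------------------------------------------------------------


def filter_population_snps(
    gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> GenotypeMatrix:
    """Apply the three population-level rules, in order.

    1. Remove markers whose minor-allele frequency over non-missing calls
       is below ``maf_min``.
    2. Remove markers called in fewer than ``min_cells`` cells.
    3. Mask (set missing), per cell, maximal runs of consecutive markers
       discordant with both flanking runs, when the run spans at most
       ``singleton_max_snps`` markers and the same discordant run (same
       parent, overlapping span) is present in fewer than
       ``singleton_max_cells`` cells.

    Returns a new matrix; the input is unchanged.
    """
    if len(gm.tetrads) < 1 or gm.n_markers == 0:
        logger.warning("filter_population_snps: empty genotype matrix")
        return gm.copy()
    calls = gm.calls
    n_sk = (calls == SK).sum(axis=1)
    n_zh = (calls == ZH).sum(axis=1)
    n_called = n_sk + n_zh
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(n_sk, n_zh) / np.where(n_called > 0, n_called, 1)
    keep = (maf >= cfg.maf_min) & (n_called > 0)  # rule 1
    keep &= n_called >= cfg.min_cells  # rule 2
    out = gm.subset_markers(keep)
    _mask_singleton_runs(out, cfg)  # rule 3, in place on the copy
    return out


def _cell_runs(calls: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs over non-missing calls: (start_idx, end_idx,
    parent), indices into the full marker axis."""
    idx = np.flatnonzero(calls != MISSING)
    runs: list[tuple[int, int, int]] = []
    if len(idx) == 0:
        return runs
    vals = calls[idx]
    start = 0
    for i in range(1, len(idx) + 1):
        if i == len(idx) or vals[i] != vals[start]:
            runs.append((int(idx[start]), int(idx[i - 1]), int(vals[start])))
            start = i
    return runs


def _mask_singleton_runs(gm: GenotypeMatrix, cfg: FilterConfig) -> None:
    """Rule 3: mask short internal discordant runs shared by few cells.

    A candidate is an internal run (it has flanking runs on both sides in
    the same cell, which with biallelic calls necessarily disagree with it)
    of at most ``singleton_max_snps`` markers.  Support is the number of
    cells carrying a discordant run of the same parent overlapping the same
    markers; candidates supported by fewer than ``singleton_max_cells``
    cells are masked in every supporting cell.
    """
    chroms = list(dict.fromkeys(gm.markers["chrom"].tolist()))
    for chrom in chroms:
        rows = gm.marker_rows(chrom)
        if len(rows) == 0:
            continue
        # collect internal runs per cell
        cand: list[tuple[int, int, int, int]] = []  # (col, start, end, parent)
        per_col_internal: dict[int, list[tuple[int, int, int]]] = {}
        for col in range(gm.n_cells):
            runs = _cell_runs(gm.calls[rows, col])
            internal = runs[1:-1]
            per_col_internal[col] = internal
            for (s, e, p) in internal:
                if e - s + 1 <= cfg.singleton_max_snps:
                    cand.append((col, s, e, p))
        for (col, s, e, p) in cand:
            support_cols = [
                c
                for c, runs in per_col_internal.items()
                if any(rp == p and rs <= e and re >= s for (rs, re, rp) in runs)
            ]
            if len(support_cols) < cfg.singleton_max_cells:
                gm.calls[rows[s : e + 1], col] = MISSING


# ---------------------------------------------------------------------------
# Tetrad QC panel
# ---------------------------------------------------------------------------


def qc_marker_panel(
    panel_calls: np.ndarray | pd.DataFrame, max_failures: int = 2
) -> tuple[bool, pd.DataFrame]:
    """Judge one tetrad from a small marker panel (up to 10 markers x 4 cells).

    A marker fails when its non-missing calls are incompatible with 2:2
    segregation (either allele counted more than twice) or when fewer than
    2 cells are called.  The tetrad passes when at most ``max_failures``
    markers fail.  Returns (passed, per-marker report).
    """
    calls = np.asarray(panel_calls, dtype=np.int8)
    if calls.ndim != 2 or calls.shape[1] != 4:
        raise ValueError("panel must have shape (n_markers, 4 cells)")
    if not 1 <= calls.shape[0] <= 10:
        raise ValueError("panel must contain between 1 and 10 markers")
    n_sk = (calls == SK).sum(axis=1)
    n_zh = (calls == ZH).sum(axis=1)
    n_called = n_sk + n_zh
    fails = (n_sk > 2) | (n_zh > 2) | (n_called < 2)
    report = pd.DataFrame(
        {
            "marker": np.arange(calls.shape[0]),
            "n_sk": n_sk,
            "n_zh": n_zh,
            "n_called": n_called,
            "status": np.where(fails, "fail", "ok"),
        }
    )
    return bool(fails.sum() <= max_failures), report
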