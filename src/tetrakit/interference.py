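"""Crossover and chromatid interference statistics.

Coefficient of coincidence (CoC): the genome is cut into fixed windows
(default 1 Mb); for every ordered window pair on a chromosome the observed
joint crossover rate D is compared with the product of the single-window
rates q1*q2, CoC = D / (q1*q2).  CoC < 1 is positive interference (double
crossovers rarer than expected), CoC > 1 negative interference.  Rates are
presence/absence frequencies across tetrads, or across single cells when
``level="cell"`` (a cell has a crossover when it is one of the two carrier
chromatids).

Chromatid interference: pairs of crossovers on one chromosome are
classified by how many distinct chromatids they engage - ``2chr`` (same
two cells), ``3chr_SK``/``3chr_Zh`` (the shared cell's centromere parent
names the class via the chromatids involved: sharing the SK-centromere
cell leaves one SK + two Zh chromatids engaged, labelled 3chr_SK), and
``4chr`` (no shared cell).  Counts are compared with the 1:1:1:1
expectation by a chi-square goodness-of-fit test, with a
subsample-bootstrap (15 of 24 tetrads, 100 replicates) summarizing
stability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sim_meiosis import SK, ZH, MISSING, PARENT_NAMES, GenomeSpec, GenotypeMatrix
from .tetrad_caller import CrossoverEvent, HaplotypeBlock

__all__ = [
    "CoCProfile",
    "STRAND_CATEGORIES",
    "ChromatidInterferenceResult",
    "CoCountSummary",
    "StrandInconsistencyError",
    "coc_profile",
    "adjacent_co_distances",
    "co_density",
    "classify_strand_involvement",
    "chromatid_interference_analysis",
    "summarize_co_counts",
    "assign_centromere_origins",
    "two_group_t_from_summary",
]

logger = logging.getLogger(__name__)

STRAND_CATEGORIES = ("2chr", "3chr_SK", "3chr_Zh", "4chr")


class StrandInconsistencyError(ValueError):
    """Carrier cells of one crossover share a centromere parent, so the
    one-chromatid-from-each-homolog decomposition fails."""


# ---------------------------------------------------------------------------
# CoC
# ---------------------------------------------------------------------------


@dataclass
class CoCProfile:
    """Window-pair CoC table plus a per-distance summary.

    ``pairs`` columns: chrom, win_a, win_b, distance (bp between window
    centers), q1, q2, d, coc.  ``by_distance`` aggregates the mean CoC per
    inter-window distance over all eligible pairs genome-wide.
    """

    window: int
    level: str
    pairs: pd.DataFrame
    by_distance: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if len(self.pairs):
            self.by_distance = (
                self.pairs.groupby("distance", as_index=False)
                .agg(mean_coc=("coc", "mean"), n_pairs=("coc", "size"))
            )
        else:
            self.by_distance = pd.DataFrame(columns=["distance", "mean_coc", "n_pairs"])

    @property
    def mean_coc(self) -> float:
        """Unweighted mean CoC over all eligible window pairs."""
        return float(self.pairs["coc"].mean()) if len(self.pairs) else math.nan


def _window_presence(
    cos: Sequence[CrossoverEvent],
    genome: GenomeSpec,
    window: int,
    level: str,
    tetrads: Sequence[int] | None = None,
) -> tuple[dict[str, np.ndarray], list]:
    """Presence/absence matrix (windows x units) per chromosome.

    Units are tetrads, or (tetrad, cell) pairs at the single-cell level.
    """
    tetrads = sorted({e.tetrad for e in cos} if tetrads is None else tetrads)
    if level == "tetrad":
        units: list = tetrads
        unit_index = {t: i for i, t in enumerate(tetrads)}
    elif level == "cell":
        units = [(t, c) for t in tetrads for c in (1, 2, 3, 4)]
        unit_index = {u: i for i, u in enumerate(units)}
    else:
        raise ValueError("level must be 'tetrad' or 'cell'")
    presence = {
        c.name: np.zeros((int(np.ceil(c.length / window)), len(units)), dtype=bool)
        for c in genome
    }
    for e in cos:
        w = min(e.midpoint // window, presence[e.chrom].shape[0] - 1)
        if level == "tetrad":
            presence[e.chrom][w, unit_index[e.tetrad]] = True
        else:
            for cell in e.carrier_cells:
                presence[e.chrom][w, unit_index[(e.tetrad, cell)]] = True
    return presence, units


def coc_profile(
    cos: Sequence[CrossoverEvent],
    genome: GenomeSpec,
    window: int = 1_000_000,
    level: str = "tetrad",
    tetrads: Sequence[int] | None = None,
) -> CoCProfile:
    """Coefficient-of-coincidence profile over all window pairs.

    For each pair of distinct windows on a chromosome: q1, q2 are the
    frequencies of units (tetrads or cells) with at least one crossover
    midpoint in the window; D is the joint frequency; CoC = D/(q1*q2).
    Pairs with q1*q2 = 0 are excluded.  ``tetrads`` names the full
    population (so tetrads without any crossover still count in the
    denominators); by default the tetrads present in ``cos``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    pop = set(tetrads) if tetrads is not None else {e.tetrad for e in cos}
    if len(pop) < 2:
        raise ValueError("coc_profile requires >= 2 tetrads")
    presence, units = _window_presence(cos, genome, window, level, tetrads)
    n_units = len(units)
    rows = []
    for chrom, mat in presence.items():
        n_win = mat.shape[0]
        if n_win < 2:
            continue
        q = mat.mean(axis=1)
        joint = (mat.astype(np.float64) @ mat.T.astype(np.float64)) / n_units
        for i in range(n_win):
            if q[i] == 0:
                continue
            for j in range(i + 1, n_win):
                if q[j] == 0:
                    continue
                rows.append(
                    (chrom, i, j, (j - i) * window, q[i], q[j], joint[i, j],
                     joint[i, j] / (q[i] * q[j]))
                )
    pairs = pd.DataFrame(
        rows, columns=["chrom", "win_a", "win_b", "distance", "q1", "q2", "d", "coc"]
    )
    return CoCProfile(window=window, level=level, pairs=pairs)


def adjacent_co_distances(cos: Sequence[CrossoverEvent]) -> pd.DataFrame:
    """Distances (bp) between consecutive crossover midpoints, per tetrad
    and chromosome."""
    rows = []
    by_key: dict[tuple[int, str], list[int]] = {}
    for e in cos:
        by_key.setdefault((e.tetrad, e.chrom), []).append(e.midpoint)
    for (tetrad, chrom), mids in sorted(by_key.items()):
        mids.sort()
        for a, b in zip(mids, mids[1:]):
            rows.append((tetrad, chrom, b - a))
    return pd.DataFrame(rows, columns=["tetrad", "chrom", "distance"])


def co_density(
    cos: Sequence[CrossoverEvent], genome: GenomeSpec, window: int = 3_000_000
) -> pd.DataFrame:
    """Counts of crossover midpoints per non-overlapping window."""
    if window <= 0:
        raise ValueError("window must be > 0")
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for e in cos:
        by_chrom.setdefault(e.chrom, []).append(e.midpoint)
    for c in genome:
        n_win = int(np.ceil(c.length / window))
        counts = np.zeros(n_win, dtype=int)
        for m in by_chrom.get(c.name, []):
            counts[min(m // window, n_win - 1)] += 1
        for w in range(n_win):
            rows.append(
                (c.name, w * window, min((w + 1) * window, c.length), counts[w])
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# Chromatid (strand) interference
# ---------------------------------------------------------------------------


def classify_strand_involvement(
    co_a: CrossoverEvent,
    co_b: CrossoverEvent,
    centromere_origins: Mapping[int, int],
) -> str:
    """Category of a crossover pair by the chromatids they engage.

    ``centromere_origins`` maps each cell to its centromere parent (SK/ZH
    codes).  The category is defined on the union of the two crossovers'
    carrier cells: two cells -> ``2chr``, four -> ``4chr``; three cells ->
    3chr, labelled by the chromatids engaged (one SK-centromere plus two
    Zh-centromere cells is ``3chr_SK``, the reverse ``3chr_Zh``).

    A crossover is always an exchange between one chromatid of each
    homolog, so a two-cell union means the same two physical strands were
    engaged twice (``2chr``) even when, after an earlier exchange, both
    cells' centromere-spanning haplotypes show the same parent.  A
    three-cell union whose centromere parents are not 2+1 indicates an
    inconsistent origin assignment and raises
    :class:`StrandInconsistencyError`.
    """
    if (co_a.tetrad, co_a.chrom) != (co_b.tetrad, co_b.chrom):
        raise ValueError("crossovers must come from the same tetrad and chromosome")
    union = set(co_a.carrier_cells) | set(co_b.carrier_cells)
    if len(union) == 2:
        return "2chr"
    if len(union) == 4:
        return "4chr"
    n_sk = sum(1 for c in union if centromere_origins[c] == SK)
    if n_sk not in (1, 2):
        raise StrandInconsistencyError(
            f"tetrad {co_a.tetrad} {co_a.chrom}: three carrier cells with "
            f"centromere parents {n_sk} SK : {3 - n_sk} Zh"
        )
    return "3chr_SK" if n_sk == 1 else "3chr_Zh"


def assign_centromere_origins(
    blocks: Mapping[tuple[int, str], Sequence[Sequence[HaplotypeBlock]]],
    genome: GenomeSpec,
) -> dict[tuple[int, str], dict[int, int]]:
    """Centromere parent of each cell from its centromere-spanning block.

    Centromeres do not recombine, so the haplotype block covering (or, if
    dropout leaves a gap, nearest to) the centromere carries the cell's
    parental identity for the whole chromosome.  Tetrad-chromosomes whose
    four assignments are not 2 SK : 2 Zh are dropped with a log record.
    """
    out: dict[tuple[int, str], dict[int, int]] = {}
    for (tetrad, chrom), per_cell in blocks.items():
        cen = genome[chrom].centromere
        origins: dict[int, int] = {}
        for cell_blocks in per_cell:
            best = None
            best_d = None
            for b in cell_blocks:
                d = max(b.first - cen, cen - b.last, 0)
                if best_d is None or d < best_d:
                    best, best_d = b, d
            if best is not None:
                origins[best.cell] = best.parent
        if len(origins) == 4 and sorted(origins.values()) == [SK, SK, ZH, ZH]:
            out[(tetrad, chrom)] = origins
        else:
            logger.info(
                "tetrad %s %s: centromere origins not 2 SK : 2 Zh, excluded",
                tetrad, chrom,
            )
    return out


@dataclass
class ChromatidInterferenceResult:
    """Strand-category counts with bootstrap summaries and a chi-square
    goodness-of-fit against 1:1:1:1."""

    level: int
    counts: dict[str, int]
    n_pairs_excluded: int
    bootstrap: pd.DataFrame  # replicate x category counts
    chi2: float
    pvalue: float

    def bootstrap_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(STRAND_CATEGORIES),
                "mean": [self.bootstrap[c].mean() for c in STRAND_CATEGORIES],
                "sd": [self.bootstrap[c].std(ddof=1) for c in STRAND_CATEGORIES],
            }
        )


def _eligible_pairs(
    cos: Sequence[CrossoverEvent],
    genome: GenomeSpec,
    level: int,
    adjacent_only: bool = True,
) -> dict[int, list[tuple[CrossoverEvent, CrossoverEvent]]]:
    """CO pairs per tetrad: level 1 = one on each arm of a chromosome (all
    cross-arm pairs), level 2 = adjacent pairs within one arm."""
    by_key: dict[tuple[int, str], list[CrossoverEvent]] = {}
    for e in cos:
        by_key.setdefault((e.tetrad, e.chrom), []).append(e)
    pairs: dict[int, list[tuple[CrossoverEvent, CrossoverEvent]]] = {}
    for (tetrad, chrom), evs in by_key.items():
        cen = genome[chrom].centromere
        evs = sorted(evs, key=lambda e: e.midpoint)
        left = [e for e in evs if e.midpoint < cen]
        right = [e for e in evs if e.midpoint >= cen]
        out = pairs.setdefault(tetrad, [])
        if level == 1:
            out.extend((a, b) for a in left for b in right)
        elif level == 2:
            for arm in (left, right):
                if adjacent_only:
                    out.extend(zip(arm, arm[1:]))
                else:
                    out.extend(
                        (arm[i], arm[j])
                        for i in range(len(arm))
                        for j in range(i + 1, len(arm))
                    )
        else:
            raise ValueError("level must be 1 (inter-arm) or 2 (intra-arm)")
    return pairs


def chromatid_interference_analysis(
    cos: Sequence[CrossoverEvent],
    genome: GenomeSpec,
    centromere_origins: Mapping[tuple[int, str], Mapping[int, int]],
    level: int = 2,
    n_boot: int = 100,
    boot_k: int = 15,
    seed: int = 0,
    adjacent_only: bool = True,
) -> ChromatidInterferenceResult:
    """Tally strand categories over eligible CO pairs and bootstrap them.

    The bootstrap subsamples ``boot_k`` tetrads without replacement,
    ``n_boot`` times, and records per-replicate category counts.  The
    goodness-of-fit statistic is a chi-square of the pooled observed counts
    against the uniform 1:1:1:1 expectation (df 3).  Pairs whose carriers
    cannot be decomposed one-per-homolog are excluded and counted.
    """
    pairs_by_tetrad = _eligible_pairs(cos, genome, level, adjacent_only)
    cat_by_tetrad: dict[int, dict[str, int]] = {}
    excluded = 0
    for tetrad, pairs in pairs_by_tetrad.items():
        tally = {c: 0 for c in STRAND_CATEGORIES}
        for a, b in pairs:
            origins = centromere_origins.get((tetrad, a.chrom))
            if origins is None:
                excluded += 1
                continue
            try:
                tally[classify_strand_involvement(a, b, origins)] += 1
            except StrandInconsistencyError:
                excluded += 1
        cat_by_tetrad[tetrad] = tally
    tetrads = sorted(cat_by_tetrad)
    counts = {
        c: sum(cat_by_tetrad[t][c] for t in tetrads) for c in STRAND_CATEGORIES
    }
    total = sum(counts.values())
    if total == 0:
        logger.warning("chromatid_interference_analysis: no eligible pairs")
        return ChromatidInterferenceResult(
            level=level, counts=counts, n_pairs_excluded=excluded,
            bootstrap=pd.DataFrame(columns=list(STRAND_CATEGORIES)),
            chi2=math.nan, pvalue=math.nan,
        )
    chi2, pvalue = stats.chisquare(list(counts.values()))
    rng = np.random.default_rng(seed)
    reps = []
    k = min(boot_k, len(tetrads))
    for _ in range(n_boot):
        chosen = rng.choice(tetrads, size=k, replace=False)
        reps.append(
            {c: sum(cat_by_tetrad[t][c] for t in chosen) for c in STRAND_CATEGORIES}
        )
    return ChromatidInterferenceResult(
        level=level, counts=counts, n_pairs_excluded=excluded,
        bootstrap=pd.DataFrame(reps), chi2=float(chi2), pvalue=float(pvalue),
    )


# ---------------------------------------------------------------------------
# CO count summaries
# ---------------------------------------------------------------------------


@dataclass
class CoCountSummary:
    """Per-tetrad and per-cell crossover counts with group comparisons."""

    per_tetrad: pd.DataFrame  # tetrad, group, n_cos
    per_cell: pd.DataFrame  # tetrad, cell, n_cos
    group_stats: pd.DataFrame  # group, n, mean, sd, min, max
    f_stat: float
    pvalue: float


def summarize_co_counts(
    cos: Sequence[CrossoverEvent],
    groups: Mapping[int, str] | None = None,
) -> CoCountSummary:
    """Per-tetrad and per-cell CO counts, group summaries and a one-way
    ANOVA across groups (equivalent to a pooled two-sample t-test for two
    groups).  With fewer than two groups of size >= 2 the test is skipped
    (NaN statistics)."""
    tetrads = sorted({e.tetrad for e in cos})
    per_tetrad = pd.DataFrame(
        {
            "tetrad": tetrads,
            "group": [groups.get(t, "all") if groups else "all" for t in tetrads],
            "n_cos": [sum(1 for e in cos if e.tetrad == t) for t in tetrads],
        }
    )
    cell_rows = []
    for t in tetrads:
        for c in (1, 2, 3, 4):
            cell_rows.append(
                (t, c, sum(1 for e in cos if e.tetrad == t and c in e.carrier_cells))
            )
    per_cell = pd.DataFrame(cell_rows, columns=["tetrad", "cell", "n_cos"])
    group_stats = (
        per_tetrad.groupby("group", as_index=False)["n_cos"]
        .agg(n="size", mean="mean", sd="std", min="min", max="max")
    )
    samples = [
        grp["n_cos"].to_numpy()
        for _, grp in per_tetrad.groupby("group")
        if len(grp) >= 2
    ]
    if len(samples) >= 2:
        grand = np.concatenate(samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
        if ss_between == 0:
            f_stat, pvalue = 0.0, 1.0  # identical group means
        elif ss_within == 0:
            f_stat, pvalue = math.inf, 0.0
        else:
            f_stat, pvalue = stats.f_oneway(*samples)
    else:
        f_stat, pvalue = math.nan, math.nan
        logger.info("summarize_co_counts: fewer than two groups, test skipped")
    return CoCountSummary(
        per_tetrad=per_tetrad, per_cell=per_cell, group_stats=group_stats,
        f_stat=float(f_stat), pvalue=float(pvalue),
    )


def two_group_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from group summary statistics.

    Returns (t, two-sided p) with n1+n2-2 degrees of freedom; for two
    groups this is equivalent to a one-way ANOVA (F = t^2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean2 - mean1) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
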