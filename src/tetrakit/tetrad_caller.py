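"""Crossover and conversion-tract calling from tetrad genotype matrices.

Each microspore is segmented into parental haplotype blocks with a
two-state hidden chain (states SK/Zh, symmetric emission error, constant
per-interval switch probability) decoded by Viterbi.  Block boundaries are
candidate crossovers; candidates from two cells of the same tetrad with
opposite transitions and compatible intervals are merged into reciprocal
crossover events.  Markers segregating 3:1 among the four cells mark
conversion tracts, which are tied to nearby crossovers.

Markers with a complete non-Mendelian segregation class (3:1 or 4:0) are
masked before segmentation so conversion tracts do not displace the called
crossover interval; they are analysed separately by
:func:`detect_conversion_tracts`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .sim_meiosis import (
    MISSING,
    SK,
    ZH,
    PARENT_NAMES,
    GenomeSpec,
    GenotypeMatrix,
)

__all__ = [
    "HaplotypeBlock",
    "CrossoverEvent",
    "ConversionTract",
    "SegregationTable",
    "SEG_2_2",
    "SEG_3_1_SK",
    "SEG_3_1_ZH",
    "SEG_4_0",
    "SEG_INCOMPLETE",
    "segment_haplotypes",
    "segment_tetrads",
    "detect_crossovers",
    "classify_marker_segregation",
    "detect_conversion_tracts",
    "call_tetrads",
]

logger = logging.getLogger(__name__)

# Segregation class codes (per marker per tetrad).
SEG_2_2 = 0
SEG_3_1_SK = 1
SEG_3_1_ZH = 2
SEG_4_0 = 3
SEG_INCOMPLETE = 4

SEG_NAMES = {
    SEG_2_2: "2:2",
    SEG_3_1_SK: "3:1-SK",
    SEG_3_1_ZH: "3:1-Zh",
    SEG_4_0: "4:0",
    SEG_INCOMPLETE: "incomplete",
}


@dataclass(frozen=True)
class HaplotypeBlock:
    """A maximal run of one parental origin in one cell.

    ``first``/``last`` are the positions of the first and last informative
    (non-missing, non-masked) markers supporting the block.
    """

    tetrad: int
    cell: int
    chrom: str
    first: int
    last: int
    parent: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("block first must be <= last")
        if self.n_markers < 1:
            raise ValueError("block must contain >= 1 marker")


@dataclass(frozen=True)
class CrossoverEvent:
    """One crossover: half-open 1-based interval (left, right] between the
    flanking informative markers, carried by exactly two cells."""

    tetrad: int
    chrom: str
    left: int
    right: int
    carrier_cells: tuple[int, int]
    reciprocal: bool

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("require left < right")
        if len(set(self.carrier_cells)) != 2:
            raise ValueError("carrier_cells must hold two distinct cell ids")

    @property
    def midpoint(self) -> int:
        return (self.left + self.right) // 2

    @property
    def tract_length(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class ConversionTract:
    """A run of 3:1 markers tied to a crossover.

    ``donor`` is the majority-allele parent; ``span`` runs from the first to
    the last 3:1 marker.  Single-marker tracts are flagged low-confidence
    (possible false discovery).
    """

    tetrad: int
    chrom: str
    co_index: int | None
    donor: int
    recipient_cell: int | None
    start: int
    end: int
    n_markers: int

    @property
    def confidence(self) -> str:
        return "multi-marker" if self.n_markers >= 2 else "single-marker"


class SegregationTable:
    """Per-marker, per-tetrad segregation classes (codes ``SEG_*``)."""

    def __init__(self, markers: pd.DataFrame, tetrads: list[int], classes: np.ndarray):
        if classes.shape != (len(markers), len(tetrads)):
            raise ValueError("classes shape must be (n_markers, n_tetrads)")
        self.markers = markers.reset_index(drop=True)
        self.tetrads = tetrads
        self.classes = classes

    def column(self, tetrad: int) -> np.ndarray:
        return self.classes[:, self.tetrads.index(tetrad)]

    def to_frame(self) -> pd.DataFrame:
        frame = self.markers.copy()
        for j, t in enumerate(self.tetrads):
            frame[f"tetrad_{t}"] = [SEG_NAMES[c] for c in self.classes[:, j]]
        return frame


# ---------------------------------------------------------------------------
# Haplotype segmentation
# ---------------------------------------------------------------------------


def segment_haplotypes(
    positions: Sequence[int],
    calls: Sequence[int],
    epsilon: float = 0.01,
    switch_penalty: float = 1e-4,
    tetrad: int = 0,
    cell: int = 0,
    chrom: str = "",
) -> list[HaplotypeBlock]:
    """Segment one cell's ordered marker calls into parental blocks.

    Maximum-a-posteriori path of a two-state chain: emission error
    ``epsilon`` per call, switch probability ``switch_penalty`` per interval
    between consecutive informative markers.  Ties are broken toward fewer
    switches.  Missing calls are skipped; an all-missing cell yields an
    empty list with a warning.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if not 0 < switch_penalty < 0.5:
        raise ValueError("switch_penalty must lie in (0, 0.5)")
    positions = np.asarray(positions)
    calls = np.asarray(calls)
    keep = calls != MISSING
    pos = positions[keep]
    obs = calls[keep]
    if len(obs) == 0:
        logger.warning("cell %s/%s on %s: no informative markers", tetrad, cell, chrom)
        return []

    w_match = math.log1p(-epsilon)
    w_mis = math.log(epsilon)
    t_stay = math.log1p(-switch_penalty)
    t_switch = math.log(switch_penalty)

    obs_list = obs.tolist()
    first = obs_list[0]
    s_sk = w_match if first == SK else w_mis
    s_zh = w_match if first == ZH else w_mis
    back: list[int] = []  # packed backpointers: bit0 -> SK came from ZH, bit1 -> ZH came from SK
    for o in obs_list[1:]:
        e_sk = w_match if o == SK else w_mis
        e_zh = w_match if o == ZH else w_mis
        # ties resolved toward staying (fewer switches)
        stay_sk = s_sk + t_stay
        swit_sk = s_zh + t_switch
        stay_zh = s_zh + t_stay
        swit_zh = s_sk + t_switch
        b = 0
        if swit_sk > stay_sk:
            s_sk_new = swit_sk + e_sk
            b |= 1
        else:
            s_sk_new = stay_sk + e_sk
        if swit_zh > stay_zh:
            s_zh_new = swit_zh + e_zh
            b |= 2
        else:
            s_zh_new = stay_zh + e_zh
        back.append(b)
        s_sk, s_zh = s_sk_new, s_zh_new

    state = SK if s_sk >= s_zh else ZH
    states = [state]
    for b in reversed(back):
        if state == SK:
            state = ZH if (b & 1) else SK
        else:
            state = SK if (b & 2) else ZH
        states.append(state)
    states.reverse()

    blocks: list[HaplotypeBlock] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            blocks.append(
                HaplotypeBlock(
                    tetrad=tetrad,
                    cell=cell,
                    chrom=chrom,
                    first=int(pos[start]),
                    last=int(pos[i - 1]),
                    parent=states[start],
                    n_markers=i - start,
                )
            )
            start = i
    return blocks


def segment_tetrads(
    gm: GenotypeMatrix,
    epsilon: float = 0.01,
    switch_penalty: float = 1e-4,
    mask_non_mendelian: bool = True,
    seg: SegregationTable | None = None,
) -> dict[tuple[int, str], list[list[HaplotypeBlock]]]:
    """Segment every cell of every tetrad, chromosome by chromosome.

    When ``mask_non_mendelian`` is set, markers whose complete segregation
    class in a tetrad is 3:1 or 4:0 are treated as uninformative for that
    tetrad before segmentation.  Returns blocks keyed by (tetrad, chrom) as
    four per-cell lists.
    """
    if seg is None and mask_non_mendelian:
        seg = classify_marker_segregation(gm)
    out: dict[tuple[int, str], list[list[HaplotypeBlock]]] = {}
    chroms = list(dict.fromkeys(gm.markers["chrom"].tolist()))
    for tetrad in gm.tetrads:
        cols = gm.cell_columns(tetrad)
        seg_col = seg.column(tetrad) if mask_non_mendelian and seg is not None else None
        for chrom in chroms:
            rows = gm.marker_rows(chrom)
            pos = gm.markers["pos"].to_numpy()[rows]
            cell_blocks: list[list[HaplotypeBlock]] = []
            for ci, cell in enumerate((1, 2, 3, 4)):
                calls = gm.calls[rows, cols[ci]].copy()
                if seg_col is not None:
                    bad = np.isin(seg_col[rows], (SEG_3_1_SK, SEG_3_1_ZH, SEG_4_0))
                    calls[bad] = MISSING
                cell_blocks.append(
                    segment_haplotypes(
                        pos, calls, epsilon, switch_penalty,
                        tetrad=tetrad, cell=cell, chrom=chrom,
                    )
                )
            out[(tetrad, chrom)] = cell_blocks
    return out


# ---------------------------------------------------------------------------
# Crossover detection
# ---------------------------------------------------------------------------


def _merge_interval(
    a: "_Candidate", b: "_Candidate", centromere: int | None
) -> tuple[int, int]:
    inter_left, inter_right = max(a.left, b.left), min(a.right, b.right)
    hull_left, hull_right = min(a.left, b.left), max(a.right, b.right)
    if centromere is None:
        return (inter_left, inter_right) if inter_left < inter_right else (
            hull_left, hull_right
        )
    # A conversion tract displaces the recipient's apparent switch strictly
    # away from the centromere while the partner switches at the true
    # exchange point.  On the right arm both switches are therefore >= the
    # true position, so (min of lefts, min of rights] always contains it;
    # mirrored on the left arm.  Without displacement this reduces to an
    # interval between the intersection and the hull.
    mid = (a.left + a.right + b.left + b.right) / 4.0
    if mid >= centromere:  # right arm: displacement rightward
        left, right = hull_left, inter_right
    else:  # left arm: displacement leftward
        left, right = inter_left, hull_right
    if left >= right:
        return hull_left, hull_right
    return left, right


@dataclass(frozen=True)
class _Candidate:
    cell: int
    left: int
    right: int
    from_parent: int
    to_parent: int


def _block_candidates(blocks: list[HaplotypeBlock]) -> list[_Candidate]:
    cands = []
    for a, b in zip(blocks, blocks[1:]):
        cands.append(
            _Candidate(
                cell=a.cell, left=a.last, right=b.first,
                from_parent=a.parent, to_parent=b.parent,
            )
        )
    return cands


def detect_crossovers(
    tetrad_blocks: Mapping[int, list[HaplotypeBlock]] | list[list[HaplotypeBlock]],
    tetrad: int | None = None,
    chrom: str | None = None,
    merge_slack: int = 2500,
    centromere: int | None = None,
) -> list[CrossoverEvent]:
    """Merge per-cell haplotype switches of one tetrad into crossover events.

    Every block boundary is a candidate; candidates in two different cells
    with opposite transitions whose intervals overlap (within
    ``merge_slack`` bp, which absorbs breakpoint displacement by conversion
    tracts under dropout) merge into one reciprocal event.  Unmatched
    candidates are emitted with ``reciprocal=False`` and logged.

    Without a centromere coordinate the merged interval is the intersection
    of the two candidate intervals (their spanning hull when slack-merged).
    With a centromere, the interval accounts for conversion tracts, which
    displace the recipient chromatid's apparent switch away from the
    centromere: the exchange point equals the centromere-proximal switch,
    so the merged interval is the proximal candidate interval truncated at
    the distal candidate's far (centromere-distal) bound.
    """
    if isinstance(tetrad_blocks, Mapping):
        per_cell = [tetrad_blocks.get(c, []) for c in (1, 2, 3, 4)]
    else:
        per_cell = list(tetrad_blocks)
    if len(per_cell) != 4:
        raise ValueError("a tetrad requires blocks for exactly 4 cells")
    flat = [b for blocks in per_cell for b in blocks]
    if flat:
        tetrads = {b.tetrad for b in flat}
        chroms = {b.chrom for b in flat}
        if len(tetrads) > 1 or len(chroms) > 1:
            raise ValueError("blocks mix tetrads or chromosomes")
        tetrad = tetrad if tetrad is not None else flat[0].tetrad
        chrom = chrom if chrom is not None else flat[0].chrom
    cands: list[_Candidate] = []
    for blocks in per_cell:
        cands.extend(_block_candidates(blocks))

    # reciprocal exchange pairs one SK->Zh switch with one Zh->SK switch in
    # another cell: a bipartite assignment maximizing the number of merged
    # pairs, then minimizing total midpoint distance (a greedy nearest-pair
    # scan can orphan the two switches of a double-CO carrier)
    side_a = [c for c in cands if c.from_parent == SK]
    side_b = [c for c in cands if c.from_parent == ZH]
    pairs: list[tuple[_Candidate, _Candidate]] = []
    unmatched: list[_Candidate] = list(cands)
    if side_a and side_b:
        big = float(
            sum(abs(a.left + a.right - b.left - b.right) for a in side_a for b in side_b)
            + 1
        )
        cost = np.full((len(side_a), len(side_b)), big)
        for i, a in enumerate(side_a):
            for j, b in enumerate(side_b):
                if b.cell == a.cell:
                    continue
                if a.left >= b.right + merge_slack or b.left >= a.right + merge_slack:
                    continue
                cost[i, j] = abs((a.left + a.right) - (b.left + b.right)) / 2.0
        rows, cols = linear_sum_assignment(cost)
        taken = set()
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                pairs.append((side_a[i], side_b[j]))
                taken.add(id(side_a[i]))
                taken.add(id(side_b[j]))
        unmatched = [c for c in cands if id(c) not in taken]

    events: list[CrossoverEvent] = []
    for a, b in pairs:
        left, right = _merge_interval(a, b, centromere)
        events.append(
            CrossoverEvent(
                tetrad=int(tetrad or 0), chrom=str(chrom or ""),
                left=int(left), right=int(right),
                carrier_cells=tuple(sorted((a.cell, b.cell))),  # type: ignore[arg-type]
                reciprocal=True,
            )
        )
    for a in unmatched:
        logger.info(
            "tetrad %s %s: unmatched haplotype switch in cell %s at (%s, %s]",
            tetrad, chrom, a.cell, a.left, a.right,
        )
        other = [c for c in (1, 2, 3, 4) if c != a.cell]
        events.append(
            CrossoverEvent(
                tetrad=int(tetrad or 0), chrom=str(chrom or ""),
                left=a.left, right=a.right,
                carrier_cells=(a.cell, other[0]),
                reciprocal=False,
            )
        )
    events.sort(key=lambda e: e.midpoint)
    return events


# ---------------------------------------------------------------------------
# Segregation classification
# ---------------------------------------------------------------------------


def classify_marker_segregation(gm: GenotypeMatrix) -> SegregationTable:
    """Classify every marker in every tetrad by its allele ratio.

    2+2 -> 2:2, 3+1 -> 3:1 with the majority parent, 4+0 -> 4:0, anything
    with fewer than four non-missing calls -> incomplete.
    """
    tetrads = gm.tetrads
    classes = np.full((gm.n_markers, len(tetrads)), SEG_INCOMPLETE, dtype=np.int8)
    for j, tetrad in enumerate(tetrads):
        cols = gm.cell_columns(tetrad)
        sub = gm.calls[:, cols]
        n_called = (sub != MISSING).sum(axis=1)
        n_sk = (sub == SK).sum(axis=1)
        complete = n_called == 4
        classes[complete & (n_sk == 2), j] = SEG_2_2
        classes[complete & (n_sk == 3), j] = SEG_3_1_SK
        classes[complete & (n_sk == 1), j] = SEG_3_1_ZH
        classes[complete & np.isin(n_sk, (0, 4)), j] = SEG_4_0
    return SegregationTable(gm.markers.copy(), tetrads, classes)


# ---------------------------------------------------------------------------
# Conversion tracts
# ---------------------------------------------------------------------------


def detect_conversion_tracts(
    gm: GenotypeMatrix,
    seg: SegregationTable,
    cos: Sequence[CrossoverEvent],
    search_window: int = 20_000,
) -> list[ConversionTract]:
    """Detect CO-associated conversion tracts from 3:1 segregation.

    For each tetrad and chromosome, maximal runs of 3:1 markers with a
    common majority parent (uninterrupted by complete non-3:1 markers;
    incomplete markers do not break a run) become candidate tracts.  A
    tract is tied to the nearest crossover within ``search_window`` bp of
    its span; the majority parent is the donor.  4:0 markers never start or
    extend a tract.  The recipient cell is left unresolved here: inside the
    tract both carriers show the donor allele, so telling the converted
    chromatid from its exchange partner needs block context and a
    centromere coordinate (see :func:`call_tetrads`).
    """
    chroms = list(dict.fromkeys(gm.markers["chrom"].tolist()))
    pos_all = gm.markers["pos"].to_numpy()
    tracts: list[ConversionTract] = []
    co_by_key: dict[tuple[int, str], list[tuple[int, CrossoverEvent]]] = {}
    for k, ev in enumerate(cos):
        co_by_key.setdefault((ev.tetrad, ev.chrom), []).append((k, ev))

    for tetrad in gm.tetrads:
        seg_col = seg.column(tetrad)
        for chrom in chroms:
            rows = gm.marker_rows(chrom)
            if len(rows) == 0:
                continue
            cls = seg_col[rows]
            pos = pos_all[rows]
            runs = _find_31_runs(cls)
            for (i0, i1, majority) in runs:
                start, end = int(pos[i0]), int(pos[i1])
                n_markers = int(
                    np.isin(cls[i0 : i1 + 1], (SEG_3_1_SK, SEG_3_1_ZH)).sum()
                )
                donor = SK if majority == SEG_3_1_SK else ZH
                co_index, recipient = _attach_to_co(
                    co_by_key.get((tetrad, chrom), []), start, end, search_window
                )
                if co_index is None:
                    logger.info(
                        "tetrad %s %s: 3:1 run at [%s, %s] with no crossover within "
                        "%s bp (possible NCO-associated conversion; not called)",
                        tetrad, chrom, start, end, search_window,
                    )
                    continue
                tracts.append(
                    ConversionTract(
                        tetrad=tetrad, chrom=chrom, co_index=co_index,
                        donor=donor, recipient_cell=recipient,
                        start=start, end=end, n_markers=n_markers,
                    )
                )
    return tracts


def _find_31_runs(cls: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs (first idx, last idx, class) of same-majority 3:1 markers.

    Complete non-3:1 markers (2:2 or 4:0) break runs; incomplete markers are
    transparent.  4:0 markers never join a run.
    """
    runs: list[tuple[int, int, int]] = []
    cur_cls: int | None = None
    cur_start = -1
    cur_last = -1
    for i, c in enumerate(cls):
        if c in (SEG_3_1_SK, SEG_3_1_ZH):
            if cur_cls == c:
                cur_last = i
            else:
                if cur_cls is not None:
                    runs.append((cur_start, cur_last, cur_cls))
                cur_cls, cur_start, cur_last = int(c), i, i
        elif c in (SEG_2_2, SEG_4_0):
            if cur_cls is not None:
                runs.append((cur_start, cur_last, cur_cls))
                cur_cls = None
        # incomplete: transparent
    if cur_cls is not None:
        runs.append((cur_start, cur_last, cur_cls))
    return runs


def _attach_to_co(
    cos: list[tuple[int, CrossoverEvent]],
    start: int,
    end: int,
    search_window: int,
) -> tuple[int | None, int | None]:
    best: tuple[int, CrossoverEvent] | None = None
    best_d = None
    for k, ev in cos:
        d = max(ev.left - end, start - ev.right, 0)
        if d <= search_window and (best_d is None or d < best_d):
            best, best_d = (k, ev), d
    if best is None:
        return None, None
    # recipient resolution needs per-carrier block boundaries; done in
    # call_tetrads via _resolve_recipient
    return best[0], None


def call_tetrads(
    gm: GenotypeMatrix,
    epsilon: float = 0.01,
    switch_penalty: float = 1e-4,
    merge_slack: int = 2500,
    search_window: int = 20_000,
    genome: GenomeSpec | None = None,
) -> tuple[list[CrossoverEvent], list[ConversionTract], SegregationTable]:
    """Full calling pipeline: segregation classes, haplotype segmentation,
    crossovers and conversion tracts, with recipients resolved when a
    genome (centromere table) is supplied."""
    seg = classify_marker_segregation(gm)
    blocks = segment_tetrads(gm, epsilon, switch_penalty, seg=seg)
    events: list[CrossoverEvent] = []
    for (tetrad, chrom), per_cell in blocks.items():
        events.extend(
            detect_crossovers(
                per_cell, tetrad=tetrad, chrom=chrom, merge_slack=merge_slack,
                centromere=genome[chrom].centromere if genome is not None else None,
            )
        )
    tracts = detect_conversion_tracts(gm, seg, events, search_window)
    if genome is not None:
        tracts = [
            replace(t, recipient_cell=_resolve_recipient(t, events, gm, genome))
            for t in tracts
        ]
    return events, tracts, seg


def _resolve_recipient(
    tract: ConversionTract,
    events: Sequence[CrossoverEvent],
    gm: GenotypeMatrix,
    genome: GenomeSpec,
) -> int | None:
    """Identify the converted chromatid among the two carriers.

    Inside the tract both carriers show the donor allele; the recipient is
    the carrier that still matches the donor on the centromere-proximal
    side of the tract (its apparent breakpoint was displaced distally by
    the conversion), while its exchange partner switched proximally and
    shows the other parent there.
    """
    if tract.co_index is None:
        return None
    ev = events[tract.co_index]
    cen = genome[tract.chrom].centromere
    mid = (tract.start + tract.end) / 2.0
    rows = gm.marker_rows(tract.chrom)
    pos = gm.markers["pos"].to_numpy()[rows]
    cols = gm.cell_columns(tract.tetrad)
    if mid >= cen:
        proximal = np.flatnonzero(pos < tract.start)[::-1]  # nearest first
    else:
        proximal = np.flatnonzero(pos > tract.end)
    for cell in ev.carrier_cells:
        col = cols[cell - 1]
        for i in proximal:
            call = gm.calls[rows[i], col]
            if call != MISSING:
                if call == tract.donor:
                    return cell
                break
    return None
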