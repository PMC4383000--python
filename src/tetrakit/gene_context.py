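"""Crossover positions relative to gene models.

Crossover midpoints are compared with transcript coordinates after a
length normalization: the physical offset of a crossover from the ATG of
its nearest transcript is divided by that transcript's ATG-UGA length and
multiplied by a standard gene length (2,500 bp, the maize average), so
genes of different sizes become comparable.  Observed distributions are
compared with uniformly simulated control positions by a two-sample
Kolmogorov-Smirnov test, and summarized in a 10-bin gene-relative
histogram (2 bins 5'-UTR / 6 bins gene body / 2 bins 3'-UTR, the body
taken as 60% of the transcript).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sim_meiosis import GenomeSpec

__all__ = [
    "TranscriptModel",
    "ScaledDistanceSet",
    "GeneRelativeHistogram",
    "nearest_transcript_distance",
    "simulate_random_controls",
    "ks_two_sample",
    "gene_relative_histogram",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its translation start (ATG) and stop (UGA) sites.

    Coordinates are 1-based; for '+' strand atg < uga, reversed for '-'.
    """

    id: str
    chrom: str
    strand: str
    atg: int
    uga: int
    transcript_start: int
    transcript_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        lo, hi = self.transcript_start, self.transcript_end
        if not (lo <= self.atg <= hi and lo <= self.uga <= hi):
            raise ValueError(f"{self.id}: ATG/UGA outside the transcript span")
        if self.strand == "+" and not self.atg < self.uga:
            raise ValueError(f"{self.id}: '+' strand requires atg < uga")
        if self.strand == "-" and not self.atg > self.uga:
            raise ValueError(f"{self.id}: '-' strand requires atg > uga")

    @property
    def span(self) -> tuple[int, int]:
        """ATG-UGA span in genomic order (lo, hi)."""
        return (min(self.atg, self.uga), max(self.atg, self.uga))

    @property
    def body_length(self) -> int:
        return abs(self.uga - self.atg)


@dataclass
class ScaledDistanceSet:
    """Per-crossover nearest transcript and normalized distance.

    ``scaled`` is the strand-aware offset from the ATG in bp-equivalents
    after normalization: negative upstream of the ATG (5'), 0 at the ATG,
    ``gene_norm_length`` at the UGA, larger past the 3' end.  ``raw`` is
    the unsigned physical distance to the ATG-UGA span (0 inside).
    ``raw_to_atg`` is the strand-aware physical offset from the ATG.
    """

    table: pd.DataFrame  # columns: position, chrom, transcript, raw, raw_to_atg, scaled
    gene_norm_length: int = 2500

    @property
    def scaled(self) -> np.ndarray:
        return self.table["scaled"].to_numpy()


@dataclass
class GeneRelativeHistogram:
    """Counts of crossovers in 10 gene-relative bins (20/60/20 layout)."""

    counts: np.ndarray  # length 10
    n_outside: int
    bin_labels: tuple[str, ...] = (
        "5'UTR.1", "5'UTR.2",
        "body.1", "body.2", "body.3", "body.4", "body.5", "body.6",
        "3'UTR.1", "3'UTR.2",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": list(self.bin_labels), "count": self.counts})


def nearest_transcript_distance(
    co_positions: Sequence[tuple[str, int]] | pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    gene_norm_length: int = 2500,
) -> ScaledDistanceSet:
    """Nearest-transcript normalized distances for crossover midpoints.

    For each position the transcript minimizing the unsigned distance to
    its ATG-UGA span is selected (distance 0 inside the span; ties go to
    the first transcript in input order).  The scaled coordinate is the
    strand-aware offset from the ATG times ``gene_norm_length`` over the
    transcript's ATG-UGA length.  Positions on chromosomes absent from the
    annotation are skipped with a warning.
    """
    if isinstance(co_positions, pd.DataFrame):
        items = list(zip(co_positions["chrom"], co_positions["pos"]))
    else:
        items = list(co_positions)
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    arrays = {
        chrom: (
            np.array([t.span[0] for t in ts]),
            np.array([t.span[1] for t in ts]),
        )
        for chrom, ts in by_chrom.items()
    }
    rows = []
    skipped = 0
    for chrom, pos in items:
        ts = by_chrom.get(chrom)
        if not ts:
            skipped += 1
            continue
        lo, hi = arrays[chrom]
        dist = np.maximum.reduce([lo - pos, pos - hi, np.zeros(len(lo))])
        k = int(np.argmin(dist))
        t = ts[k]
        offset = pos - t.atg if t.strand == "+" else t.atg - pos
        scaled = offset * gene_norm_length / t.body_length
        rows.append(
            {
                "chrom": chrom,
                "position": pos,
                "transcript": t.id,
                "raw": float(dist[k]),
                "raw_to_atg": float(offset),
                "scaled": float(scaled),
            }
        )
    if skipped:
        logger.warning(
            "nearest_transcript_distance: %d positions on chromosomes missing "
            "from the annotation were skipped", skipped,
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "position", "transcript", "raw", "raw_to_atg", "scaled"]
    )
    return ScaledDistanceSet(table=table, gene_norm_length=gene_norm_length)


def simulate_random_controls(
    genome: GenomeSpec,
    n_per_set: int = 581,
    n_sets: int = 5,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Uniform random genome positions as negative controls.

    Positions are uniform over the concatenated chromosome lengths,
    independent across the ``n_sets`` sets; deterministic given ``seed``.
    """
    if not genome.chromosomes:
        raise ValueError("genome must contain at least one chromosome")
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length for c in genome], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    names = genome.names
    out = []
    for _ in range(n_sets):
        flat = rng.integers(0, offsets[-1], size=n_per_set)
        idx = np.searchsorted(offsets, flat, side="right") - 1
        pos = flat - offsets[idx] + 1
        out.append(
            pd.DataFrame({"chrom": [names[i] for i in idx], "pos": pos.astype(np.int64)})
        )
    return out


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum of the absolute difference between the two empirical
    CDFs.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def gene_relative_histogram(
    distances: ScaledDistanceSet,
    transcripts: Sequence[TranscriptModel] | None = None,
) -> GeneRelativeHistogram:
    """Bin crossovers into the 10-bin gene-relative layout.

    The normalized transcript is ``gene_norm_length`` long between ATG and
    UGA (six body bins, 60% of the transcript); each UTR is 20% of the
    transcript, i.e. ``gene_norm_length``/3 on either side, split into two
    bins.  Bins are left-closed; positions beyond the normalized transcript
    are excluded and counted in ``n_outside``.
    """
    g = float(distances.gene_norm_length)
    utr = g / 3.0  # 20% of the transcript when the body is 60%
    edges = np.concatenate(
        [
            np.linspace(-utr, 0.0, 3),  # two 5'UTR bins
            np.linspace(0.0, g, 7)[1:],  # six body bins
            np.linspace(g, g + utr, 3)[1:],  # two 3'UTR bins
        ]
    )
    x = distances.scaled
    inside = (x >= edges[0]) & (x < edges[-1])
    counts, _ = np.histogram(x[inside], bins=edges)
    return GeneRelativeHistogram(
        counts=counts.astype(int), n_outside=int((~inside).sum())
    )
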