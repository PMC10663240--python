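"""Intergenic-region extraction and insulator-candidate classification.

An intergenic region is the span between the termini of two genes that are
adjacent by rank on one seqid. Candidates are regions whose flanking pair is
divergent (head-to-head) or convergent (tail-to-tail), whose length falls in
a configured window, and whose flanking genes differ in expression: fold
change >= min_fc with the higher-expressed gene in the top fraction of all
transcripts, and — for convergent pairs — exactly one flanking gene in that
top set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from insulmine.annotation_io import GenomeIndex

DIVERGENT = "divergent"
CONVERGENT = "convergent"
TANDEM = "tandem"


def orientation_of(left_strand: str, right_strand: str) -> str:
    """Orientation class of a left-to-right ordered strand pair.

    (-,+) is divergent (5' ends adjacent, transcription away from each
    other); (+,-) is convergent (3' ends adjacent); equal strands are tandem.
    """
    if left_strand == "-" and right_strand == "+":
        return DIVERGENT
    if left_strand == "+" and right_strand == "-":
        return CONVERGENT
    return TANDEM


@dataclass(frozen=True)
class IntergenicRegion:
    region_id: str
    seqid: str
    start: int  # left gene's end
    end: int  # right gene's start; end >= start (zero length allowed pre-filter)
    left_gene_id: str
    right_gene_id: str
    orientation: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateRegion:
    """An intergenic region with its expression classification attached."""

    region_id: str
    seqid: str
    start: int
    end: int
    left_gene_id: str
    right_gene_id: str
    orientation: str
    fpkm_left: float
    fpkm_right: float
    fold_change: float  # max/min; inf when min == 0 < max; nan when both 0
    high_gene_id: str
    passes_core_filter: bool
    is_short: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MinerParams:
    """Thresholds of the candidate classifier (all inclusive)."""

    min_len: int = 50
    max_len: int = 20_000
    min_fc: float = 1.5
    top_fraction: float = 0.5
    short_max: int = 1_000

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(f"need 0 < min_len <= max_len, got {self.min_len}, {self.max_len}")
        if self.min_fc < 1:
            raise ValueError(f"min_fc must be >= 1, got {self.min_fc}")
        if not (0 < self.top_fraction <= 1):
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.short_max <= 0:
            raise ValueError(f"short_max must be positive, got {self.short_max}")


def extract_intergenic(index: GenomeIndex) -> list[IntergenicRegion]:
    """One region per adjacent, non-overlapping gene pair per seqid.

    Pairs whose genes overlap (including nesting) yield no region but do not
    block the following pair of consecutive ranks. Regions never span a
    seqid boundary. A shared terminus yields a zero-length region, removed
    later by the length filter.
    """
    regions: list[IntergenicRegion] = []
    for seqid in sorted(index.by_seqid):
        genes = index.by_seqid[seqid]
        for i in range(len(genes) - 1):
            left, right = genes[i], genes[i + 1]
            if right.start < left.end:  # overlapping or nested
                continue
            regions.append(
                IntergenicRegion(
                    region_id=f"{seqid}_ig{i:05d}",
                    seqid=seqid,
                    start=left.end,
                    end=right.start,
                    left_gene_id=left.gene_id,
                    right_gene_id=right.gene_id,
                    orientation=orientation_of(left.strand, right.strand),
                )
            )
    return regions


def expression_threshold(all_fpkm: Iterable[float], top_fraction: float = 0.5) -> float:
    """FPKM cutoff such that values >= cutoff are the top ``top_fraction``.

    The cutoff is the k-th largest value with k = ceil(n * top_fraction), so
    membership in the top set is determined by the observed order statistics
    and ties at the cutoff are included.
    """
    values = sorted(all_fpkm, reverse=True)
    if not values:
        raise ValueError("expression_threshold: empty FPKM collection")
    k = max(1, math.ceil(len(values) * top_fraction))
    return values[k - 1]


def fold_change(f1: float, f2: float) -> float:
    """Ratio of the higher to the lower FPKM.

    inf when exactly one value is zero (maximally different expression);
    nan when both are zero (no expression evidence, pair always fails).
    """
    lo, hi = min(f1, f2), max(f1, f2)
    if hi == 0:
        return math.nan
    if lo == 0:
        return math.inf
    return hi / lo


def call_candidates(
    regions: Sequence[IntergenicRegion],
    index: GenomeIndex,
    params: MinerParams = MinerParams(),
) -> list[CandidateRegion]:
    """Apply the orientation + expression classification to every region.

    passes_core_filter is true iff all of: length within [min_len, max_len];
    orientation divergent or convergent; fold change >= min_fc; the
    higher-expressed flanking gene in the top expression set; and, for
    convergent pairs, exactly one flanking gene in the top set.
    """
    cutoff = expression_threshold(index.fpkm_values(), params.top_fraction)
    out: list[CandidateRegion] = []
    for r in regions:
        left = index.gene(r.left_gene_id)
        right = index.gene(r.right_gene_id)
        fc = fold_change(left.fpkm, right.fpkm)
        high = left if left.fpkm >= right.fpkm else right
        left_top = left.fpkm >= cutoff
        right_top = right.fpkm >= cutoff
        ok = (
            params.min_len <= r.length <= params.max_len
            and r.orientation in (DIVERGENT, CONVERGENT)
            and not math.isnan(fc)
            and fc >= params.min_fc
            and high.fpkm >= cutoff
        )
        if ok and r.orientation == CONVERGENT:
            ok = left_top != right_top  # exactly one flanking gene highly expressed
        out.append(
            CandidateRegion(
                region_id=r.region_id,
                seqid=r.seqid,
                start=r.start,
                end=r.end,
                left_gene_id=r.left_gene_id,
                right_gene_id=r.right_gene_id,
                orientation=r.orientation,
                fpkm_left=left.fpkm,
                fpkm_right=right.fpkm,
                fold_change=fc,
                high_gene_id=high.gene_id,
                passes_core_filter=ok,
                is_short=r.length <= params.short_max,
            )
        )
    return out


def filter_short(
    candidates: Sequence[CandidateRegion], short_max: int = 1_000
) -> tuple[list[CandidateRegion], float]:
    """Passing candidates no longer than ``short_max`` bp, plus the retained
    fraction of all passing candidates (0.0 when none pass)."""
    passing = [c for c in candidates if c.passes_core_filter]
    short = [c for c in passing if c.length <= short_max]
    fraction = len(short) / len(passing) if passing else 0.0
    return short, fraction


def candidates_to_frame(candidates: Sequence[CandidateRegion]):
    """Tabular view of candidate calls (the per-region TSV the CLI writes)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "seqid": c.seqid,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "orientation": c.orientation,
                "left_gene_id": c.left_gene_id,
                "right_gene_id": c.right_gene_id,
                "fpkm_left": c.fpkm_left,
                "fpkm_right": c.fpkm_right,
                "fold_change": c.fold_change,
                "high_gene_id": c.high_gene_id,
                "passes_core_filter": c.passes_core_filter,
                "is_short": c.is_short,
            }
            for c in candidates
        ]
    )
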