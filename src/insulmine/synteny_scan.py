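"""Microsynteny scanning and rearrangement classification.

For each candidate region the flanking gene pair is looked up, via BLASTP
hits, in each subject genome. A hit pair is admissible when both subject
genes lie on one seqid with at most ``max_between`` genes between them. The
selected pair is classified against the query configuration:

* orientation conserved and intervening gene counts equal -> high_quality
* orientation conserved, counts differ                    -> indel
* exactly one gene's relative orientation flipped, counts equal -> inversion
* anything else, or no admissible pair                    -> none

Orientation is compared on the relative configuration: the subject pair is
canonically oriented so the counterpart of the query's left gene comes
first (reversing order flips both strands), making every verdict invariant
under reversal of a whole subject chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from insulmine.annotation_io import GenomeIndex, OrthologHit
from insulmine.candidate_miner import CandidateRegion

logger = logging.getLogger(__name__)

HIGH_QUALITY = "high_quality"
INDEL = "indel"
INVERSION = "inversion"
NONE = "none"
KLASSES = (HIGH_QUALITY, INDEL, INVERSION, NONE)

_FLIP = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class SyntenyParams:
    max_between: int = 5  # inclusive: <= 5 genes between the pair
    evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if self.max_between < 0:
            raise ValueError("max_between must be >= 0")


@dataclass(frozen=True)
class SyntenyCall:
    """Conservation verdict for one (candidate region, subject genome) cell."""

    region_id: str
    subject_genome_id: str
    klass: str
    subject_left_gene: str | None = None
    subject_right_gene: str | None = None
    intervening_query: int = 0
    intervening_subject: int = 0


def _hits_by_query(hits: Sequence[OrthologHit]) -> dict[str, list[OrthologHit]]:
    by_query: dict[str, list[OrthologHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_gene_id, []).append(h)
    return by_query


def scan_region(
    candidate: CandidateRegion,
    query_index: GenomeIndex,
    subject_index: GenomeIndex,
    hits: Sequence[OrthologHit] | Mapping[str, Sequence[OrthologHit]],
    params: SyntenyParams = SyntenyParams(),
) -> SyntenyCall:
    """Classify conservation of one candidate's flanking pair in one subject.

    Among admissible hit pairs the one with the fewest intervening subject
    genes wins; ties break by smaller summed e-value, then lexicographic
    subject gene ids. A flanking gene with no hits yields klass "none".
    """
    genome_id = subject_index.genome_id
    by_query = hits if isinstance(hits, Mapping) else _hits_by_query(hits)
    left_hits = by_query.get(candidate.left_gene_id, ())
    right_hits = by_query.get(candidate.right_gene_id, ())
    no_call = SyntenyCall(candidate.region_id, genome_id, NONE)
    if not left_hits or not right_hits:
        return no_call

    lq = query_index.gene(candidate.left_gene_id)
    rq = query_index.gene(candidate.right_gene_id)
    _, lrank = query_index.rank(candidate.left_gene_id)
    _, rrank = query_index.rank(candidate.right_gene_id)
    intervening_query = abs(rrank - lrank) - 1

    best = None  # (intervening, evalue_sum, sl_id, sr_id, hl, hr)
    for hl in left_hits:
        if hl.subject_gene_id not in subject_index:
            continue
        sl_seq, sl_rank = subject_index.rank(hl.subject_gene_id)
        for hr in right_hits:
            if hr.subject_gene_id not in subject_index:
                continue
            sr_seq, sr_rank = subject_index.rank(hr.subject_gene_id)
            if sl_seq != sr_seq or sl_rank == sr_rank:
                continue
            intervening = abs(sr_rank - sl_rank) - 1
            if intervening > params.max_between:
                continue
            key = (
                intervening,
                hl.evalue + hr.evalue,
                hl.subject_gene_id,
                hr.subject_gene_id,
            )
            if best is None or key < best[0]:
                best = (key, hl, hr, sl_rank, sr_rank)
    if best is None:
        return no_call

    _, hl, hr, sl_rank, sr_rank = best
    sl = subject_index.gene(hl.subject_gene_id)
    sr = subject_index.gene(hr.subject_gene_id)
    # Canonical orientation: if the subject counterparts appear in reversed
    # rank order, mirror the subject pair (reverse order, flip both strands)
    # so each subject gene is compared against its own query gene.
    if sl_rank < sr_rank:
        matches = (sl.strand == lq.strand) + (sr.strand == rq.strand)
    else:
        matches = (_FLIP[sl.strand] == lq.strand) + (_FLIP[sr.strand] == rq.strand)
    intervening_subject = abs(sr_rank - sl_rank) - 1

    if matches == 2:
        klass = HIGH_QUALITY if intervening_subject == intervening_query else INDEL
    elif matches == 1 and intervening_subject == intervening_query:
        klass = INVERSION
    else:
        klass = NONE
    return SyntenyCall(
        region_id=candidate.region_id,
        subject_genome_id=genome_id,
        klass=klass,
        subject_left_gene=sl.gene_id,
        subject_right_gene=sr.gene_id,
        intervening_query=intervening_query,
        intervening_subject=intervening_subject,
    )


@dataclass
class PresenceAbsenceMatrix:
    """Regions x subject-genomes table of conservation verdicts."""

    table: pd.DataFrame  # cells hold klass strings; "none" encodes absence

    @property
    def region_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.table.columns)

    def breadth(self) -> pd.Series:
        """Per-region number of genomes with any conservation (klass != none)."""
        if self.table.empty:
            return pd.Series(0, index=self.table.index, dtype=int)
        return (self.table != NONE).sum(axis=1)

    def per_genome_syntenic(self) -> pd.Series:
        """Per-genome count of syntenic candidate pairs."""
        if self.table.empty:
            return pd.Series(dtype=int)
        return (self.table != NONE).sum(axis=0)

    def syntenic_region_ids(self) -> list[str]:
        """Regions conserved (any class) in at least one subject genome."""
        b = self.breadth()
        return list(b.index[b > 0])

    def klass(self, region_id: str, genome_id: str) -> str:
        return self.table.at[region_id, genome_id]


def build_matrix(
    candidates: Sequence[CandidateRegion],
    query_index: GenomeIndex,
    subject_indexes: Mapping[str, GenomeIndex],
    hit_tables: Mapping[str, Sequence[OrthologHit]],
    params: SyntenyParams = SyntenyParams(),
) -> tuple[PresenceAbsenceMatrix, list[SyntenyCall]]:
    """Scan every candidate against every subject genome.

    Returns the presence-absence matrix plus the flat list of calls (the
    per-genome TSV the CLI writes).
    """
    calls: list[SyntenyCall] = []
    genome_ids = sorted(subject_indexes)
    cells: dict[str, dict[str, str]] = {c.region_id: {} for c in candidates}
    for gid in genome_ids:
        by_query = _hits_by_query(hit_tables.get(gid, ()))
        for cand in candidates:
            call = scan_region(cand, query_index, subject_indexes[gid], by_query, params)
            calls.append(call)
            cells[cand.region_id][gid] = call.klass
    table = pd.DataFrame.from_dict(cells, orient="index", columns=genome_ids).fillna(NONE)
    table = table.reindex([c.region_id for c in candidates])
    if genome_ids:
        table = table[genome_ids]
    return PresenceAbsenceMatrix(table=table), calls


def high_confidence(
    candidates: Sequence[CandidateRegion],
    matrix: PresenceAbsenceMatrix,
    fc_min: float = 10.0,
    len_max: int = 1_000,
) -> tuple[list[str], dict]:
    """High-confidence candidates: short, strongly differential, conserved.

    Keeps candidates with length <= len_max, fold change strictly > fc_min,
    and a high_quality verdict in at least one subject genome. Also reports
    the count and its percentage of the syntenic set (conserved anywhere).
    """
    hq_rows = set()
    if not matrix.table.empty:
        mask = (matrix.table == HIGH_QUALITY).any(axis=1)
        hq_rows = set(mask.index[mask])
    kept = [
        c.region_id
        for c in candidates
        if c.length <= len_max and c.fold_change > fc_min and c.region_id in hq_rows
    ]
    n_syntenic = len(matrix.syntenic_region_ids())
    pct = round(100.0 * len(kept) / n_syntenic, 1) if n_syntenic else 0.0
    return kept, {"n_high_confidence": len(kept), "n_syntenic": n_syntenic, "pct_of_syntenic": pct}


def _fc_sort_key(c: CandidateRegion) -> tuple:
    # infinite fold changes outrank all finite ones; among them, higher
    # expression of the high gene wins
    high_fpkm = max(c.fpkm_left, c.fpkm_right)
    if math.isinf(c.fold_change):
        primary = (0, -high_fpkm)
    elif math.isnan(c.fold_change):
        primary = (2, 0.0)
    else:
        primary = (1, -c.fold_change)
    return (*primary, c.length, c.region_id)


def select_for_validation(
    candidates: Sequence[CandidateRegion],
    matrix: PresenceAbsenceMatrix,
    k: int = 9,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Two validation shortlists, each ignoring orientation class.

    List A: top k by fold change (infinite fold changes first, then by the
    high gene's FPKM). List B: top k by synteny breadth. Ties break by
    region length ascending then region_id.
    """
    pool = [c for c in candidates if c.passes_core_filter]
    if k > len(pool):
        logger.warning("requested k=%d but only %d candidates; returning all", k, len(pool))
    by_fc = sorted(pool, key=_fc_sort_key)[:k]
    breadth = matrix.breadth()
    by_breadth = sorted(
        pool,
        key=lambda c: (-int(breadth.get(c.region_id, 0)), c.length, c.region_id),
    )[:k]
    return by_fc, by_breadth


def calls_to_frame(calls: Sequence[SyntenyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "subject_genome_id": c.subject_genome_id,
                "klass": c.klass,
                "subject_left_gene": c.subject_left_gene,
                "subject_right_gene": c.subject_right_gene,
                "intervening_query": c.intervening_query,
                "intervening_subject": c.intervening_subject,
            }
            for c in calls
        ]
    )
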