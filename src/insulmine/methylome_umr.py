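"""Tile-based methylome summaries and unmethylated-region (UMR) calling.

Per-cytosine bisulfite counts (allc-style records) are summarised in 100-bp
non-overlapping tiles per sequence context (CG, CHG, CHH). Tiles with too
few cytosines or too little coverage are "missing"; tiles where every
context present stays below the methylation threshold are "unmethylated".
Runs of unmethylated and missing tiles merge into UMRs subject to span and
missing-data constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

CONTEXTS = ("CG", "CHG", "CHH")

MISSING = "missing"
UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"


def classify_context(context: str) -> str:
    """Collapse a trinucleotide context (e.g. CGA, CAG, CTT) to CG/CHG/CHH."""
    if context in CONTEXTS:
        return context
    if len(context) == 3 and context[0] == "C":
        if context[1] == "G":
            return "CG"
        if context[2] == "G":
            return "CHG"
        return "CHH"
    raise ValueError(f"unrecognised methylation context {context!r}")


@dataclass(frozen=True)
class MethylationSite:
    """One cytosine's bisulfite counts (0-based position)."""

    seqid: str
    pos: int
    strand: str
    context: str  # CG | CHG | CHH
    mc_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.mc_reads <= self.total_reads):
            raise ValueError(
                f"site {self.seqid}:{self.pos}: need 0 <= mc ({self.mc_reads}) "
                f"<= total ({self.total_reads})"
            )


@dataclass(frozen=True)
class UmrParams:
    tile_size: int = 100
    min_cytosines: int = 2
    min_coverage: float = 5.0
    max_level: float = 0.10  # strict: level < max_level to count as unmethylated
    max_missing_frac: float = 1 / 3  # inclusive
    min_span: int = 300  # bp, inclusive
    missing_rule: str = "or"  # "or": either condition marks a tile missing

    def __post_init__(self) -> None:
        if self.missing_rule not in ("or", "and"):
            raise ValueError(f"missing_rule must be 'or' or 'and', got {self.missing_rule!r}")


@dataclass
class ContextSummary:
    n_cytosines: int = 0
    n_covered: int = 0  # cytosines with >= 1 read
    mc_sum: int = 0
    cov_sum: int = 0

    @property
    def level(self) -> float:
        """Weighted methylation level: mc reads / total reads; nan if no coverage."""
        return self.mc_sum / self.cov_sum if self.cov_sum > 0 else math.nan


@dataclass
class Tile:
    """A 100-bp (or terminal shorter) methylation summary window."""

    seqid: str
    start: int
    end: int
    contexts: dict[str, ContextSummary] = field(
        default_factory=lambda: {c: ContextSummary() for c in CONTEXTS}
    )
    status: str = MISSING

    @property
    def n_cytosines_all(self) -> int:
        return sum(c.n_cytosines for c in self.contexts.values())

    @property
    def mean_coverage(self) -> float:
        """Mean total reads per covered cytosine (cytosines with >= 1 read)."""
        cov = sum(c.cov_sum for c in self.contexts.values())
        n_cov = sum(c.n_covered for c in self.contexts.values())
        return cov / n_cov if n_cov else 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UMR:
    """A merged unmethylated region: a maximal run of unmethylated/missing
    tiles, trimmed of flanking missing tiles, satisfying span and
    missing-fraction constraints."""

    seqid: str
    start: int
    end: int
    n_tiles: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_tiles


def read_allc(path: str | Path) -> list[MethylationSite]:
    """Read an allc-style TSV (seqid, pos, strand, context, mc, total[, call]).

    File positions are 1-based; the internal model is 0-based.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=range(6),
        names=["seqid", "pos", "strand", "context", "mc", "total"],
        dtype={"seqid": str, "strand": str, "context": str},
    )
    return [
        MethylationSite(
            seqid=r.seqid,
            pos=int(r.pos) - 1,
            strand=r.strand,
            context=classify_context(r.context),
            mc_reads=int(r.mc),
            total_reads=int(r.total),
        )
        for r in df.itertuples(index=False)
    ]


def write_allc(sites: Sequence[MethylationSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.seqid}\t{s.pos + 1}\t{s.strand}\t{s.context}\t{s.mc_reads}\t"
                f"{s.total_reads}\t1\n"
            )


def tile_methylome(
    sites: Iterable[MethylationSite],
    seqid_lengths: Mapping[str, int] | None = None,
    params: UmrParams = UmrParams(),
) -> list[Tile]:
    """Summarise sites in non-overlapping tiles and call each tile's status.

    Each site lands in the tile floor(pos / tile_size). Tiles with no sites
    are emitted as missing so that runs and missing fractions are computed
    over the full extent of each seqid. The extent is ``seqid_lengths`` when
    given, else the smallest tile-aligned span covering the observed sites.
    A site with zero total reads counts as a cytosine but contributes no
    coverage.
    """
    ts = params.tile_size
    by_tile: dict[tuple[str, int], list[MethylationSite]] = {}
    max_pos: dict[str, int] = {}
    for s in sites:
        by_tile.setdefault((s.seqid, s.pos // ts), []).append(s)
        max_pos[s.seqid] = max(max_pos.get(s.seqid, 0), s.pos)
    extents: dict[str, int] = dict(seqid_lengths or {})
    for seqid, mp in max_pos.items():
        extents.setdefault(seqid, mp + 1)

    tiles: list[Tile] = []
    for seqid in sorted(extents):
        length = extents[seqid]
        n_tiles = max(1, math.ceil(length / ts))
        for i in range(n_tiles):
            tile = Tile(seqid=seqid, start=i * ts, end=min((i + 1) * ts, length))
            for s in by_tile.get((seqid, i), ()):
                ctx = tile.contexts[s.context]
                ctx.n_cytosines += 1
                if s.total_reads > 0:
                    ctx.mc_sum += s.mc_reads
                    ctx.cov_sum += s.total_reads
                    ctx.n_covered += 1
            tile.status = call_status(tile, params)
            tiles.append(tile)
    return tiles


def call_status(tile: Tile, params: UmrParams = UmrParams()) -> str:
    """Call a tile missing / unmethylated / methylated.

    Missing-data rule: with missing_rule "or" (default) a tile is missing
    when it has fewer than min_cytosines cytosines OR mean coverage below
    min_coverage; "and" requires both. Unmethylated requires every context
    that has cytosines in the tile to sit strictly below max_level; a
    context with no cytosines passes vacuously.
    """
    few = tile.n_cytosines_all < params.min_cytosines
    shallow = tile.mean_coverage < params.min_coverage
    missing = (few or shallow) if params.missing_rule == "or" else (few and shallow)
    if missing:
        return MISSING
    for ctx in tile.contexts.values():
        if ctx.n_cytosines > 0 and ctx.cov_sum > 0 and ctx.level >= params.max_level:
            return METHYLATED
    return UNMETHYLATED


def merge_umrs(tiles: Sequence[Tile], params: UmrParams = UmrParams()) -> list[UMR]:
    """Merge runs of unmethylated/missing tiles into UMRs.

    Maximal runs of consecutive (by coordinate) non-methylated tiles are
    trimmed of leading/trailing missing tiles — UMR boundaries must be
    supported by data — then kept iff span >= min_span bp and missing-tile
    fraction <= max_missing_frac. The fraction test is exact in tile counts
    (3 * n_missing <= n_tiles for the 1/3 default), so a one-in-three
    missing run sits on the boundary and is retained.
    """
    umrs: list[UMR] = []
    by_seqid: dict[str, list[Tile]] = {}
    for t in tiles:
        by_seqid.setdefault(t.seqid, []).append(t)
    for seqid in sorted(by_seqid):
        ordered = sorted(by_seqid[seqid], key=lambda t: t.start)
        run: list[Tile] = []
        for t in ordered:
            contiguous = bool(run) and run[-1].end == t.start
            if t.status != METHYLATED and (not run or contiguous):
                run.append(t)
            else:
                _emit_run(run, umrs, params)
                run = [t] if t.status != METHYLATED else []
        _emit_run(run, umrs, params)
    return umrs


def _emit_run(run: list[Tile], out: list[UMR], params: UmrParams) -> None:
    while run and run[0].status == MISSING:
        run.pop(0)
    while run and run[-1].status == MISSING:
        run.pop()
    if not run:
        return
    span = run[-1].end - run[0].start
    n_missing = sum(1 for t in run if t.status == MISSING)
    # exact rational comparison; avoids 0.3333... float trouble at the boundary
    frac = params.max_missing_frac
    ok_frac = n_missing * 3 <= len(run) if abs(frac - 1 / 3) < 1e-12 else (
        n_missing <= frac * len(run)
    )
    if span >= params.min_span and ok_frac:
        out.append(
            UMR(
                seqid=run[0].seqid,
                start=run[0].start,
                end=run[-1].end,
                n_tiles=len(run),
                n_missing=n_missing,
            )
        )


def global_levels(sites: Sequence[MethylationSite]) -> dict[str, float]:
    """Genome-wide weighted methylation level per context plus aggregate.

    Weighted level = sum(mc reads) / sum(total reads) over covered sites;
    nan where a context has no coverage.
    """
    if not sites:
        raise ValueError("global_levels: empty site set")
    mc = {c: 0 for c in CONTEXTS}
    cov = {c: 0 for c in CONTEXTS}
    for s in sites:
        if s.total_reads > 0:
            mc[s.context] += s.mc_reads
            cov[s.context] += s.total_reads
    out = {c: (mc[c] / cov[c] if cov[c] else math.nan) for c in CONTEXTS}
    total_cov = sum(cov.values())
    out["all"] = sum(mc.values()) / total_cov if total_cov else math.nan
    return out


def overlap_candidates(candidates: Sequence, umrs: Sequence[UMR]) -> dict:
    """Fraction of candidate regions sharing >= 1 bp with any UMR.

    Returns counts, the percentage (1 decimal) and mean lengths of both
    interval sets. Intervals are half-open, so a shared endpoint is not an
    overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for u in umrs:
        if u.length > 0:
            trees.setdefault(u.seqid, IntervalTree()).addi(u.start, u.end)
    n_overlap = sum(
        1
        for c in candidates
        if c.seqid in trees and c.end > c.start and trees[c.seqid].overlap(c.start, c.end)
    )
    n_total = len(candidates)
    return {
        "n_overlapping": n_overlap,
        "n_candidates": n_total,
        "pct_overlapping": round(100.0 * n_overlap / n_total, 1) if n_total else 0.0,
        "mean_candidate_length": (
            sum(c.end - c.start for c in candidates) / n_total if n_total else math.nan
        ),
        "mean_umr_length": (sum(u.length for u in umrs) / len(umrs) if umrs else math.nan),
        "n_umrs": len(umrs),
    }


def tiles_to_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    rows = []
    for t in tiles:
        row = {
            "seqid": t.seqid,
            "start": t.start,
            "end": t.end,
            "n_cytosines": t.n_cytosines_all,
            "mean_coverage": t.mean_coverage,
            "status": t.status,
        }
        for c in CONTEXTS:
            row[f"n_{c}"] = t.contexts[c].n_cytosines
            row[f"level_{c}"] = t.contexts[c].level
        rows.append(row)
    return pd.DataFrame(rows)
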