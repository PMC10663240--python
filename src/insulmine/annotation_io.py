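"""Genomic file I/O and the shared coordinate model.

All coordinates inside the package are 0-based half-open (BED convention);
GFF3 and allc positions are converted at the I/O boundary. Gene models carry
a single scalar FPKM expression value attached from a separate table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: columns of NCBI BLAST tabular output (-outfmt 6)
BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True, order=True)
class GeneModel:
    """A located, stranded gene with one FPKM expression value.

    Coordinates are 0-based half-open; ``end - start`` is the gene length in bp.
    """

    seqid: str
    start: int
    end: int
    gene_id: str
    strand: str
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id}: fpkm must be >= 0, got {self.fpkm}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeIndex:
    """Per-seqid ordered gene lists with positional ranks.

    Genes are sorted by (start, end, gene_id) within each seqid; the rank of a
    gene is its 0-based position in that order. Ranks drive the "genes
    between a pair" counting used by the microsynteny scanner.
    """

    genome_id: str
    by_seqid: dict[str, list[GeneModel]] = field(default_factory=dict)
    _rank: dict[str, tuple[str, int]] = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, genome_id: str, genes: Iterable[GeneModel]) -> "GenomeIndex":
        by_seqid: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            by_seqid.setdefault(g.seqid, []).append(g)
        rank: dict[str, tuple[str, int]] = {}
        for seqid, glist in by_seqid.items():
            glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(glist):
                rank[g.gene_id] = (seqid, i)
        return cls(genome_id=genome_id, by_seqid=by_seqid, _rank=rank)

    def __len__(self) -> int:
        return len(self._rank)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    @property
    def genes(self) -> list[GeneModel]:
        return [g for seqid in sorted(self.by_seqid) for g in self.by_seqid[seqid]]

    def rank(self, gene_id: str) -> tuple[str, int]:
        """Return ``(seqid, rank)`` of a gene. KeyError if unknown."""
        return self._rank[gene_id]

    def gene(self, gene_id: str) -> GeneModel:
        seqid, i = self._rank[gene_id]
        return self.by_seqid[seqid][i]

    def fpkm_values(self) -> list[float]:
        return [g.fpkm for g in self.genes]


def _read_expression(path: str | Path, aggregate: str = "max") -> dict[str, float]:
    """Read a gene_id -> FPKM table.

    Multiple tissue columns, if present, are collapsed with ``aggregate``
    (default max across columns).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.columns[0] != "gene_id":
        raise ValueError(f"{path}: expression table must have header gene_id,fpkm[,...]")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r} in expression table")
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise")
    if (values < 0).any().any():
        raise ValueError(f"{path}: negative FPKM value")
    agg = values.agg(aggregate, axis=1)
    return dict(zip(df["gene_id"], agg.astype(float)))


_GFF3_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _parse_gff3_genes(path: str | Path, feature_type: str) -> list[tuple[str, int, int, str, str]]:
    """Parse the ``feature_type`` rows of a minimal GFF3 file.

    Returns (seqid, start0, end, gene_id, strand) tuples with coordinates
    converted from 1-based inclusive to 0-based half-open.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates start={start1} end={end1}"
                )
            m = _GFF3_ATTR_ID.search(attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: feature has no ID attribute")
            out.append((seqid, start1 - 1, end1, m.group(1), strand))
    return out


def _parse_gene_tsv(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Parse a flat TSV gene table (gene_id, seqid, start, end, strand).

    Coordinates are taken as already 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seqid": str})
    needed = {"gene_id", "seqid", "start", "end", "strand"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: gene TSV must have columns {sorted(needed)}")
    return [
        (r.seqid, int(r.start), int(r.end), r.gene_id, r.strand)
        for r in df.itertuples(index=False)
    ]


def read_gene_models(
    path: str | Path,
    expression_path: str | Path | None = None,
    *,
    genome_id: str | None = None,
    feature_type: str = "gene",
    aggregate: str = "max",
) -> GenomeIndex:
    """Read gene models (GFF3 or TSV) plus an FPKM table into a GenomeIndex.

    GFF3 input is recognised by suffix (.gff, .gff3); anything else is read as
    a flat TSV with 0-based half-open coordinates. Genes absent from the
    expression table are kept with fpkm = 0 and a warning — dropping them
    would silently merge intergenic regions.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = _parse_gff3_genes(path, feature_type)
    else:
        rows = _parse_gene_tsv(path)
    fpkm = _read_expression(expression_path, aggregate) if expression_path else {}
    genes = []
    n_missing = 0
    for seqid, start, end, gene_id, strand in rows:
        if gene_id not in fpkm:
            n_missing += 1
            logger.warning("gene %s has no expression value; using fpkm=0", gene_id)
        genes.append(
            GeneModel(
                seqid=seqid,
                start=start,
                end=end,
                gene_id=gene_id,
                strand=strand,
                fpkm=fpkm.get(gene_id, 0.0),
            )
        )
    if n_missing:
        logger.warning("%d of %d genes lacked expression values", n_missing, len(genes))
    return GenomeIndex.build(genome_id or path.stem, genes)


def write_gff3(index: GenomeIndex, path: str | Path, *, feature_type: str = "gene") -> None:
    """Write a GenomeIndex back to minimal GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in index.genes:
            fh.write(
                f"{g.seqid}\tinsulmine\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_expression(index: GenomeIndex, path: str | Path) -> None:
    """Write the gene_id -> fpkm table of an index."""
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for g in index.genes:
            fh.write(f"{g.gene_id}\t{g.fpkm!r}\n")


def write_bed(regions: Sequence, path: str | Path) -> None:
    """Write located intervals as BED6.

    Each region needs seqid/start/end attributes plus, optionally, region_id
    (name column) and fold_change (score column; 0 when undefined or
    infinite). Strand is "." — intergenic regions are unstranded.
    """
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "region_id", ".")
            fc = getattr(r, "fold_change", None)
            score = 0.0 if fc is None or fc != fc or fc == float("inf") else fc
            fh.write(f"{r.seqid}\t{r.start}\t{r.end}\t{name}\t{score:g}\t.\n")


@dataclass(frozen=True)
class BedInterval:
    seqid: str
    start: int
    end: int
    region_id: str
    score: float
    strand: str


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read BED6 back into simple interval records (round-trip of write_bed)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seqid, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(BedInterval(seqid, int(start), int(end), name, float(score), strand))
    return out


@dataclass(frozen=True)
class OrthologHit:
    """One retained BLASTP hit of a query gene in a subject genome."""

    query_gene_id: str
    subject_genome_id: str
    subject_gene_id: str
    evalue: float
    bitscore: float


def read_ortholog_hits(
    path: str | Path,
    subject_genome_id: str,
    *,
    evalue_max: float = 1e-5,
    subject_index: GenomeIndex | None = None,
) -> list[OrthologHit]:
    """Read a BLAST outfmt-6 table, keeping hits with evalue <= evalue_max.

    The e-value threshold is inclusive. Hits to subject genes absent from
    ``subject_index`` (when given) are dropped with a warning rather than an
    error: stale hit tables are common and should not abort a scan.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        return []
    ev = pd.to_numeric(df["evalue"], errors="coerce")
    if ev.isna().any():
        bad = int(ev.isna().idxmax()) + 1
        raise ValueError(f"{path}: non-numeric evalue on data line {bad}")
    df = df[ev <= evalue_max]
    hits = []
    n_unknown = 0
    for r in df.itertuples(index=False):
        if subject_index is not None and r.sseqid not in subject_index:
            n_unknown += 1
            continue
        hits.append(
            OrthologHit(
                query_gene_id=str(r.qseqid),
                subject_genome_id=subject_genome_id,
                subject_gene_id=str(r.sseqid),
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
            )
        )
    if n_unknown:
        logger.warning(
            "%s: dropped %d hits to genes absent from subject index %s",
            path,
            n_unknown,
            subject_genome_id,
        )
    logger.info("%s: retained %d hits (evalue <= %g)", path, len(hits), evalue_max)
    return hits


def write_ortholog_hits(hits: Sequence[OrthologHit], path: str | Path) -> None:
    """Write hits as minimal BLAST outfmt-6 rows (alignment columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene_id}\t{h.subject_gene_id}\t100.0\t100\t0\t0\t1\t100\t1\t100\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )
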