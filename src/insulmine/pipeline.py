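"""End-to-end orchestration: miner -> synteny -> UMR -> assay.

A single declarative config (YAML file or dict) names the inputs and every
threshold; stages with absent inputs are skipped cleanly. The run produces
per-stage TSV/BED outputs plus a JSON summary report in which every
percentage is recomputable from the counts printed beside it and every
threshold used is echoed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from insulmine import annotation_io, candidate_miner, methylome_umr, reporter_stats, synteny_scan
from insulmine.candidate_miner import MinerParams
from insulmine.methylome_umr import UmrParams
from insulmine.synteny_scan import SyntenyParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (annotation + expression are required; the rest optional)
    annotations: str | None = None
    expression: str | None = None
    subject_annotations: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    hit_tables: dict[str, str] = field(default_factory=dict)  # genome_id -> path
    allc: str | None = None
    seqid_lengths: dict[str, int] = field(default_factory=dict)
    assay: str | None = None
    control_construct: str = reporter_stats.DEFAULT_CONTROL
    out_dir: str = "insulmine_out"
    seed: int = 0
    # stage parameters
    miner: MinerParams = field(default_factory=MinerParams)
    synteny: SyntenyParams = field(default_factory=SyntenyParams)
    umr: UmrParams = field(default_factory=UmrParams)
    fc_min_hc: float = 10.0
    len_max_hc: int = 1_000
    k_select: int = 9
    alpha: float = 0.05


_NESTED = {"miner": MinerParams, "synteny": SyntenyParams, "umr": UmrParams}


def validate_config(raw: dict[str, Any] | str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a dict or YAML file.

    Unknown keys are rejected; nested parameter blocks are validated by
    their own dataclasses (which enforce bounds, e.g. min_fc >= 1).
    """
    if not isinstance(raw, dict):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(value) - sub_known
            if sub_unknown:
                raise ValueError(f"unknown {key} parameter keys: {sorted(sub_unknown)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _jsonable(x):
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
    return x


def run(config: PipelineConfig) -> dict:
    """Run all requested stages; returns (and writes) the summary report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {
            "miner": dataclasses.asdict(config.miner),
            "synteny": dataclasses.asdict(config.synteny),
            "umr": dataclasses.asdict(config.umr),
            "fc_min_hc": config.fc_min_hc,
            "len_max_hc": config.len_max_hc,
            "k_select": config.k_select,
            "alpha": config.alpha,
            "seed": config.seed,
        }
    }

    if not config.annotations:
        raise ValueError("pipeline requires an annotations input")
    logger.info("[miner] reading gene models from %s", config.annotations)
    index = annotation_io.read_gene_models(config.annotations, config.expression)
    regions = candidate_miner.extract_intergenic(index)
    candidates = candidate_miner.call_candidates(regions, index, config.miner)
    passing = [c for c in candidates if c.passes_core_filter]
    short, short_fraction = candidate_miner.filter_short(candidates, config.miner.short_max)
    n_div = sum(1 for c in passing if c.orientation == candidate_miner.DIVERGENT)
    n_con = sum(1 for c in passing if c.orientation == candidate_miner.CONVERGENT)
    candidate_miner.candidates_to_frame(candidates).to_csv(
        out_dir / "candidates.tsv", sep="\t", index=False
    )
    annotation_io.write_bed(passing, out_dir / "candidates.bed")
    report["candidates"] = {
        "n_genes": len(index),
        "n_intergenic_regions": len(regions),
        "n_passing": len(passing),
        "n_divergent": n_div,
        "n_convergent": n_con,
        "n_short": len(short),
        "short_fraction": round(short_fraction, 4),
    }
    logger.info(
        "[miner] %d candidates pass (%d divergent + %d convergent); %d short",
        len(passing),
        n_div,
        n_con,
        len(short),
    )

    if config.subject_annotations and config.hit_tables:
        subject_indexes = {
            gid: annotation_io.read_gene_models(path, genome_id=gid)
            for gid, path in config.subject_annotations.items()
        }
        hit_tables = {
            gid: annotation_io.read_ortholog_hits(
                path,
                gid,
                evalue_max=config.synteny.evalue_max,
                subject_index=subject_indexes.get(gid),
            )
            for gid, path in config.hit_tables.items()
        }
        matrix, calls = synteny_scan.build_matrix(
            passing, index, subject_indexes, hit_tables, config.synteny
        )
        hc_ids, hc_stats = synteny_scan.high_confidence(
            passing, matrix, config.fc_min_hc, config.len_max_hc
        )
        by_fc, by_breadth = synteny_scan.select_for_validation(passing, matrix, config.k_select)
        synteny_scan.calls_to_frame(calls).to_csv(
            out_dir / "synteny_calls.tsv", sep="\t", index=False
        )
        matrix.table.to_csv(out_dir / "presence_absence.tsv", sep="\t")
        with open(out_dir / "validation_shortlists.tsv", "w") as fh:
            fh.write("list\trank\tregion_id\tfold_change\tbreadth\n")
            breadth = matrix.breadth()
            for label, lst in (("by_fold_change", by_fc), ("by_breadth", by_breadth)):
                for i, c in enumerate(lst, 1):
                    fh.write(
                        f"{label}\t{i}\t{c.region_id}\t{_jsonable(c.fold_change)}\t"
                        f"{int(breadth.get(c.region_id, 0))}\n"
                    )
        report["synteny"] = {
            "n_subject_genomes": len(subject_indexes),
            "n_syntenic": hc_stats["n_syntenic"],
            "per_genome_syntenic": {
                k: int(v) for k, v in matrix.per_genome_syntenic().items()
            },
            "n_high_confidence": hc_stats["n_high_confidence"],
            "pct_high_confidence_of_syntenic": hc_stats["pct_of_syntenic"],
            "shortlist_by_fold_change": [c.region_id for c in by_fc],
            "shortlist_by_breadth": [c.region_id for c in by_breadth],
        }
        logger.info(
            "[synteny] %d syntenic, %d high confidence (%.1f%%)",
            hc_stats["n_syntenic"],
            hc_stats["n_high_confidence"],
            hc_stats["pct_of_syntenic"],
        )
    else:
        report["synteny"] = {"skipped": True}
        logger.info("[synteny] skipped (no subject annotations / hit tables)")

    if config.allc:
        sites = methylome_umr.read_allc(config.allc)
        tiles = methylome_umr.tile_methylome(
            sites, config.seqid_lengths or None, config.umr
        )
        umrs = methylome_umr.merge_umrs(tiles, config.umr)
        levels = methylome_umr.global_levels(sites)
        overlap = methylome_umr.overlap_candidates(passing, umrs)
        methylome_umr.tiles_to_frame(tiles).to_csv(out_dir / "tiles.tsv", sep="\t", index=False)
        annotation_io.write_bed(umrs, out_dir / "umrs.bed")
        report["methylation"] = {
            "global_levels": {k: _jsonable(round(v, 4)) for k, v in levels.items()},
            "n_tiles": len(tiles),
            "n_umrs": overlap["n_umrs"],
            "mean_umr_length": _jsonable(round(overlap["mean_umr_length"], 1)),
            "mean_candidate_length": _jsonable(round(overlap["mean_candidate_length"], 1)),
            "n_overlapping": overlap["n_overlapping"],
            "n_candidates": overlap["n_candidates"],
            "pct_overlapping": overlap["pct_overlapping"],
        }
        logger.info(
            "[umr] %d UMRs; %d/%d candidates overlap (%.1f%%)",
            overlap["n_umrs"],
            overlap["n_overlapping"],
            overlap["n_candidates"],
            overlap["pct_overlapping"],
        )
    else:
        report["methylation"] = {"skipped": True}
        logger.info("[umr] skipped (no allc input)")

    if config.assay:
        records = reporter_stats.read_assay(config.assay)
        results = reporter_stats.summarize_assay(records, config.control_construct, config.alpha)
        reporter_stats.results_to_frame(results).to_csv(
            out_dir / "assay_results.tsv", sep="\t", index=False
        )
        report["assay"] = {
            "control": config.control_construct,
            "constructs": {
                r.construct_id: {
                    "n": r.n,
                    "mean_ratio": round(r.mean_ratio, 6),
                    "fc": round(r.fc, 6),
                    "letter": r.group_letter,
                }
                for r in results
            },
        }
        logger.info("[assay] %d constructs summarised", len(results))
    else:
        report["assay"] = {"skipped": True}
        logger.info("[assay] skipped (no assay input)")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of the summary report."""
    lines = ["insulmine summary", "=" * 17]
    c = report.get("candidates", {})
    if c:
        lines += [
            f"genes: {c['n_genes']}  intergenic regions: {c['n_intergenic_regions']}",
            f"passing candidates: {c['n_passing']} "
            f"({c['n_divergent']} divergent + {c['n_convergent']} convergent)",
            f"short (<= short_max): {c['n_short']} ({100 * c['short_fraction']:.1f}% of passing)",
        ]
    s = report.get("synteny", {})
    if s and not s.get("skipped"):
        lines += [
            f"syntenic in >= 1 genome: {s['n_syntenic']}",
            f"high confidence: {s['n_high_confidence']} "
            f"({s['pct_high_confidence_of_syntenic']}% of syntenic)",
        ]
    m = report.get("methylation", {})
    if m and not m.get("skipped"):
        lines += [
            f"UMRs: {m['n_umrs']} (mean {m['mean_umr_length']} bp)",
            f"candidates overlapping a UMR: {m['n_overlapping']}/{m['n_candidates']} "
            f"({m['pct_overlapping']}%)",
        ]
    a = report.get("assay", {})
    if a and not a.get("skipped"):
        for cid, r in a["constructs"].items():
            lines.append(
                f"assay {cid}: n={r['n']} mean_ratio={r['mean_ratio']:.4f} "
                f"fc={r['fc']:.4f} group={r['letter']}"
            )
    return "\n".join(lines) + "\n"
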