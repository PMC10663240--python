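"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study system: a compact genome whose adjacent
gene pairs carry mixed orientations and log-normal expression with planted
fold-change structure; subject genomes derived from it by insertions,
flank-gene deletions and single-gene inversions plus BLAST-hit dropout; a
lightly methylated genome with planted unmethylated regions against
per-context background methylation under Poisson coverage; and plate-reader
fluorescence with planted insulator strengths and multiplicative noise.

Layout strategy for the gene planter: genes are laid out in "pair slots"
(genes 2i and 2i+1) separated by spacer gaps longer than the miner's
maximum intergenic length, so only within-slot pairs can ever pass the
filter and sensitivity/specificity against planted truth are well defined.
Expression values are drawn from two truncated log-normal bands (lowly vs
highly expressed) with exactly half of all genes in the high band, so the
top-50% expression cutoff separates the bands exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from insulmine.annotation_io import GeneModel, GenomeIndex, OrthologHit
from insulmine.candidate_miner import CONVERGENT, DIVERGENT, TANDEM
from insulmine.methylome_umr import MethylationSite
from insulmine.synteny_scan import HIGH_QUALITY, INDEL, INVERSION, NONE

# pair-slot plans
PLANT_DIVERGENT = "planted_divergent"
PLANT_CONVERGENT = "planted_convergent"
NEG_TANDEM = "negative_tandem"
NEG_LOW_FC = "negative_low_fc"
NEG_SHORT_GAP = "negative_short_gap"
NEG_BOTH_TOP_CONVERGENT = "negative_both_top_convergent"
NEG_OVERLAP = "negative_overlap"

PLANTED_KINDS = (PLANT_DIVERGENT, PLANT_CONVERGENT)
NEGATIVE_KINDS = (
    NEG_TANDEM,
    NEG_LOW_FC,
    NEG_SHORT_GAP,
    NEG_BOTH_TOP_CONVERGENT,
    NEG_OVERLAP,
)


@dataclass(frozen=True)
class PlantedPair:
    left_gene_id: str
    right_gene_id: str
    kind: str
    orientation: str
    fold_change: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.left_gene_id, self.right_gene_id)


@dataclass
class SyntheticTruth:
    """Planted intent per generated object, keyed so tests can match it."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_synteny: dict[tuple[tuple[str, str], str], str] = field(default_factory=dict)
    planted_umrs: list[tuple[str, int, int]] = field(default_factory=list)
    planted_insulators: dict[str, float] = field(default_factory=dict)

    def positive_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.planted_pairs if p.kind in PLANTED_KINDS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study system (defaults are the test conditions)."""

    seed: int = 0
    n_chrom: int = 1
    pairs_per_chrom: int = 50
    # truncated log-normal bands for gene length (bp)
    gene_len_mu: float = math.log(1500)
    gene_len_sigma: float = 0.4
    # gap (intergenic) lengths for planted pairs, log-normal within [gap_min, gap_max]
    gap_mu: float = math.log(400)
    gap_sigma: float = 0.6
    gap_min: int = 60
    gap_max: int = 950
    spacer_gap: int = 25_000  # between pair slots; beyond the miner's max_len
    # expression bands (log-normal, truncated to disjoint ranges)
    fpkm_low_mu: float = 0.0
    fpkm_low_sigma: float = 0.5
    fpkm_low_max: float = 2.0
    fpkm_high_mu: float = 4.0
    fpkm_high_sigma: float = 0.5
    fpkm_high_min: float = 20.0
    # fraction of pair slots planted as candidates (split evenly div/conv)
    planted_fraction: float = 0.4
    # subject-genome rearrangement probabilities per planted locus
    p_high_quality: float = 0.4
    p_indel: float = 0.2
    p_inversion: float = 0.2
    p_none: float = 0.2
    hit_dropout: float = 0.0
    hit_evalue_mu: float = -40.0  # log10 e-value centre for emitted hits
    # methylome
    cytosine_spacing: float = 3.0  # mean bp between cytosines, both strands (geometric)
    context_probs: tuple[float, float, float] = (0.3, 0.25, 0.45)  # CG, CHG, CHH
    background_levels: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.45, "CHH": 0.4}
    )
    umr_level: float = 0.01
    coverage_depth: float = 20.0
    # reporter assay
    n_replicates: int = 3
    assay_noise_cv: float = 0.0
    base_mcherry: float = 10_000.0
    base_ratio: float = 2.0

    def __post_init__(self) -> None:
        probs = (self.p_high_quality, self.p_indel, self.p_inversion, self.p_none)
        if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("rearrangement probabilities must be in [0,1] and sum to 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.hit_dropout <= 1:
            raise ValueError("hit_dropout must be in [0, 1]")


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = float(rng.lognormal(mu, sigma))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated log-normal rejection failed; widen the band")


def _sample_gap(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    return int(round(_truncated_lognormal(rng, cfg.gap_mu, cfg.gap_sigma, cfg.gap_min, cfg.gap_max)))


def gen_genome(config: GeneratorConfig) -> tuple[GenomeIndex, SyntheticTruth]:
    """Generate the query genome with planted candidate pairs.

    Each chromosome holds ``pairs_per_chrom`` two-gene slots. A configured
    fraction of slots is planted as true candidates (divergent/convergent in
    equal numbers); the rest cycle through explicit negatives — tandem
    pairs, sub-threshold fold changes, too-short gaps, convergent pairs with
    both genes highly expressed, and overlapping pairs — so specificity is
    measurable. Exactly half of all genes sit in the high expression band.
    """
    rng = np.random.default_rng(config.seed)
    n_slots = config.n_chrom * config.pairs_per_chrom
    n_planted = int(round(config.planted_fraction * n_slots))
    plans: list[str] = []
    for i in range(n_planted):
        plans.append(PLANT_DIVERGENT if i % 2 == 0 else PLANT_CONVERGENT)
    for i in range(n_slots - n_planted):
        plans.append(NEGATIVE_KINDS[i % len(NEGATIVE_KINDS)])
    order = rng.permutation(n_slots)
    plans = [plans[i] for i in order]

    # expression-band bookkeeping: exactly half of the 2*n_slots genes high
    n_genes = 2 * n_slots
    highs_needed = n_genes // 2

    def draw_low() -> float:
        return _truncated_lognormal(
            rng, config.fpkm_low_mu, config.fpkm_low_sigma, 0.0, config.fpkm_low_max
        )

    def draw_high() -> float:
        return _truncated_lognormal(
            rng, config.fpkm_high_mu, config.fpkm_high_sigma, config.fpkm_high_min, math.inf
        )

    # decide per-slot band usage first so the global balance can be enforced
    slot_bands: list[tuple[bool, bool]] = []  # (left_high, right_high)
    for plan in plans:
        if plan in (PLANT_DIVERGENT, PLANT_CONVERGENT):
            left_high = bool(rng.integers(2))
            slot_bands.append((left_high, not left_high))
        elif plan in (NEG_LOW_FC, NEG_BOTH_TOP_CONVERGENT):
            slot_bands.append((True, True))
        else:  # tandem / short gap / overlap: bands irrelevant, fill later
            slot_bands.append((None, None))
    fixed_highs = sum(b for pair in slot_bands for b in pair if b is not None)
    free = [i for i, pair in enumerate(slot_bands) if pair[0] is None]
    remaining = highs_needed - fixed_highs
    if remaining < 0 or remaining > 2 * len(free):
        raise ValueError(
            "infeasible config: cannot balance expression bands; "
            "adjust planted_fraction or pairs_per_chrom"
        )
    filled: list[tuple[bool, bool]] = []
    todo = remaining
    for n_left, idx in enumerate(free):
        slots_left = len(free) - n_left
        # keep per-slot assignment feasible: 0..2 highs per slot
        lo_bound = max(0, todo - 2 * (slots_left - 1))
        hi_bound = min(2, todo)
        take = int(rng.integers(lo_bound, hi_bound + 1))
        if take == 1:
            left_high = bool(rng.integers(2))
            filled.append((left_high, not left_high))
        else:
            filled.append((take == 2, take == 2))
        todo -= take
    for idx, bands in zip(free, filled):
        slot_bands[idx] = bands

    genes: list[GeneModel] = []
    truth = SyntheticTruth()
    gid = 0
    for chrom_i in range(config.n_chrom):
        seqid = f"chr{chrom_i + 1}"
        pos = 1000
        for slot_i in range(config.pairs_per_chrom):
            slot = chrom_i * config.pairs_per_chrom + slot_i
            plan = plans[slot]
            left_high, right_high = slot_bands[slot]
            f_left = draw_high() if left_high else draw_low()
            f_right = draw_high() if right_high else draw_low()
            len_l = int(round(rng.lognormal(config.gene_len_mu, config.gene_len_sigma)))
            len_r = int(round(rng.lognormal(config.gene_len_mu, config.gene_len_sigma)))

            if plan == PLANT_DIVERGENT:
                strands, gap = ("-", "+"), _sample_gap(rng, config)
            elif plan == PLANT_CONVERGENT:
                strands, gap = ("+", "-"), _sample_gap(rng, config)
            elif plan == NEG_TANDEM:
                strands = ("+", "+") if rng.integers(2) else ("-", "-")
                gap = _sample_gap(rng, config)
            elif plan == NEG_LOW_FC:
                strands, gap = ("-", "+"), _sample_gap(rng, config)
                f_right = f_left * float(rng.uniform(1.05, 1.45))  # fc < 1.5
            elif plan == NEG_BOTH_TOP_CONVERGENT:
                strands, gap = ("+", "-"), _sample_gap(rng, config)
                f_right = f_left * float(rng.uniform(1.6, 3.0))  # fc passes, both top
            elif plan == NEG_SHORT_GAP:
                strands, gap = ("-", "+"), int(rng.integers(1, 50))  # below the 50-bp floor
            elif plan == NEG_OVERLAP:
                strands, gap = ("-", "+"), -min(200, len_l // 2)  # genes overlap
            else:  # pragma: no cover
                raise AssertionError(plan)

            left = GeneModel(
                seqid=seqid,
                start=pos,
                end=pos + len_l,
                gene_id=f"g{gid:05d}",
                strand=strands[0],
                fpkm=round(f_left, 4),
            )
            right_start = left.end + gap
            right = GeneModel(
                seqid=seqid,
                start=right_start,
                end=right_start + len_r,
                gene_id=f"g{gid + 1:05d}",
                strand=strands[1],
                fpkm=round(f_right, 4),
            )
            gid += 2
            genes.extend((left, right))
            fc = max(left.fpkm, right.fpkm) / min(left.fpkm, right.fpkm)
            truth.planted_pairs.append(
                PlantedPair(
                    left_gene_id=left.gene_id,
                    right_gene_id=right.gene_id,
                    kind=plan,
                    orientation={
                        PLANT_DIVERGENT: DIVERGENT,
                        PLANT_CONVERGENT: CONVERGENT,
                        NEG_TANDEM: TANDEM,
                        NEG_LOW_FC: DIVERGENT,
                        NEG_BOTH_TOP_CONVERGENT: CONVERGENT,
                        NEG_SHORT_GAP: DIVERGENT,
                        NEG_OVERLAP: DIVERGENT,
                    }[plan],
                    fold_change=round(fc, 6),
                )
            )
            pos = max(left.end, right.end) + config.spacer_gap
    index = GenomeIndex.build("query", genes)
    return index, truth


def gen_subject_genomes(
    query_index: GenomeIndex,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    n_genomes: int = 5,
) -> tuple[dict[str, GenomeIndex], dict[str, list[OrthologHit]]]:
    """Derive subject genomes from the query by per-locus rearrangements.

    Each subject starts as a gene-order copy of the query. At each planted
    candidate locus one outcome is drawn: conserved (high_quality),
    insertion of 1..max_between dummy genes (indel), a single flanking-gene
    strand flip (inversion), or loss — either a flank-gene deletion or an
    insertion of more than max_between genes (none). Hits are emitted for
    every surviving query gene, minus random dropout. Truth records the
    intended verdict per (pair, genome).
    """
    rng = np.random.default_rng(config.seed + 7_919)
    planted = {p.key: p for p in truth.planted_pairs if p.kind in PLANTED_KINDS}
    subject_indexes: dict[str, GenomeIndex] = {}
    hit_tables: dict[str, list[OrthologHit]] = {}
    outcomes = (HIGH_QUALITY, INDEL, INVERSION, NONE)
    probs = (config.p_high_quality, config.p_indel, config.p_inversion, config.p_none)

    for gi in range(n_genomes):
        genome_id = f"subject{gi + 1}"
        genes: list[GeneModel] = []
        orthologs: list[tuple[str, str]] = []  # (query gene, subject gene)
        extra = 0

        def new_gene(seqid: str, pos: int, strand: str) -> GeneModel:
            nonlocal extra
            extra += 1
            return GeneModel(
                seqid=seqid,
                start=pos,
                end=pos + 1000,
                gene_id=f"{genome_id}_x{extra:05d}",
                strand=strand,
            )

        for seqid in sorted(query_index.by_seqid):
            out_rows: list[tuple[GeneModel | None, str | None]] = []
            qgenes = query_index.by_seqid[seqid]
            i = 0
            while i < len(qgenes):
                g = qgenes[i]
                nxt = qgenes[i + 1] if i + 1 < len(qgenes) else None
                key = (g.gene_id, nxt.gene_id) if nxt else None
                if key in planted:
                    klass = outcomes[rng.choice(4, p=probs)]
                    truth.planted_synteny[(key, genome_id)] = klass
                    left_strand, right_strand = g.strand, nxt.strand
                    insert_n = 0
                    drop_left = drop_right = False
                    if klass == INDEL:
                        insert_n = int(rng.integers(1, 6))
                    elif klass == INVERSION:
                        if rng.integers(2):
                            left_strand = "-" if left_strand == "+" else "+"
                        else:
                            right_strand = "-" if right_strand == "+" else "+"
                    elif klass == NONE:
                        if rng.integers(2):
                            if rng.integers(2):
                                drop_left = True
                            else:
                                drop_right = True
                        else:
                            insert_n = int(rng.integers(6, 9))
                    if not drop_left:
                        out_rows.append(((g, left_strand), g.gene_id))
                    for _ in range(insert_n):
                        out_rows.append(((None, "+"), None))
                    if not drop_right:
                        out_rows.append(((nxt, right_strand), nxt.gene_id))
                    i += 2
                else:
                    out_rows.append(((g, g.strand), g.gene_id))
                    i += 1
            pos = 500
            for (query_gene, strand), qid in out_rows:
                if query_gene is None:
                    sg = new_gene(seqid, pos, strand)
                else:
                    extra += 1
                    sg = GeneModel(
                        seqid=seqid,
                        start=pos,
                        end=pos + query_gene.length,
                        gene_id=f"{genome_id}_o{extra:05d}",
                        strand=strand,
                    )
                    orthologs.append((query_gene.gene_id, sg.gene_id))
                genes.append(sg)
                pos = sg.end + 500

        subject_indexes[genome_id] = GenomeIndex.build(genome_id, genes)
        hits: list[OrthologHit] = []
        for qid, sid in orthologs:
            if config.hit_dropout > 0 and rng.random() < config.hit_dropout:
                # dropping a flank hit makes a planted call unrecoverable
                key_hits = [k for k in truth.planted_synteny if qid in k[0] and k[1] == genome_id]
                for k in key_hits:
                    truth.planted_synteny[k] = NONE
                continue
            evalue = 10.0 ** float(rng.normal(config.hit_evalue_mu, 3.0))
            hits.append(
                OrthologHit(
                    query_gene_id=qid,
                    subject_genome_id=genome_id,
                    subject_gene_id=sid,
                    evalue=min(evalue, 1e-6),
                    bitscore=float(rng.uniform(100, 500)),
                )
            )
        hit_tables[genome_id] = hits
    return subject_indexes, hit_tables


def gen_methylome(
    seqid_lengths: Mapping[str, int],
    planted_umrs: Sequence[tuple[str, int, int]],
    config: GeneratorConfig,
) -> tuple[list[MethylationSite], SyntheticTruth]:
    """Simulate allc-style records with planted unmethylated intervals.

    Cytosines are placed with geometric spacing; contexts follow the
    configured CG/CHG/CHH proportions; coverage is Poisson around the
    configured depth and methylated read counts are binomial with the
    per-context background probability outside planted intervals and the
    (shared) low UMR probability inside them.
    """
    for (s1, a1, b1) in planted_umrs:
        if b1 - a1 < 300:
            raise ValueError(f"planted UMR {s1}:{a1}-{b1} shorter than 300 bp")
        if a1 < 0 or b1 > seqid_lengths[s1]:
            raise ValueError(f"planted UMR {s1}:{a1}-{b1} outside genome extent")
        for (s2, a2, b2) in planted_umrs:
            if (s1, a1, b1) != (s2, a2, b2) and s1 == s2 and a1 < b2 and a2 < b1:
                raise ValueError("planted UMRs overlap")
    rng = np.random.default_rng(config.seed + 104_729)
    sites: list[MethylationSite] = []
    contexts = np.array(["CG", "CHG", "CHH"])
    for seqid in sorted(seqid_lengths):
        length = seqid_lengths[seqid]
        in_umr = sorted((a, b) for (s, a, b) in planted_umrs if s == seqid)
        pos = int(rng.geometric(1.0 / config.cytosine_spacing))
        while pos < length:
            ctx = str(contexts[rng.choice(3, p=np.asarray(config.context_probs))])
            inside = any(a <= pos < b for a, b in in_umr)
            p = config.umr_level if inside else float(config.background_levels[ctx])
            cov = int(rng.poisson(config.coverage_depth))
            mc = int(rng.binomial(cov, p)) if cov > 0 else 0
            strand = "+" if rng.integers(2) else "-"
            sites.append(
                MethylationSite(
                    seqid=seqid, pos=pos, strand=strand, context=ctx, mc_reads=mc, total_reads=cov
                )
            )
            pos += int(rng.geometric(1.0 / config.cytosine_spacing))
    truth = SyntheticTruth(planted_umrs=list(planted_umrs))
    return sites, truth


def gen_assay(
    strengths: Mapping[str, float],
    config: GeneratorConfig,
):
    """Simulate plate readings for constructs with planted insulator strengths.

    ``strengths`` maps construct id -> intended ratio multiple of the
    control (the spacer control must be present with strength 1). Per
    replicate mcherry is log-normal around a base signal and
    gfp = strength * base_ratio * mcherry * noise, with multiplicative
    log-normal noise of the configured CV.
    """
    import pandas as pd

    from insulmine.reporter_stats import DEFAULT_CONTROL

    if DEFAULT_CONTROL not in strengths or strengths[DEFAULT_CONTROL] != 1:
        raise ValueError(f"strengths must include control {DEFAULT_CONTROL!r} with strength 1")
    rng = np.random.default_rng(config.seed + 224_737)
    cv = config.assay_noise_cv
    sigma = math.sqrt(math.log(1 + cv * cv)) if cv > 0 else 0.0
    rows = []
    for construct, s in strengths.items():
        for rep in range(1, config.n_replicates + 1):
            mcherry = float(rng.lognormal(math.log(config.base_mcherry), 0.15))
            noise = float(rng.lognormal(-0.5 * sigma * sigma, sigma)) if sigma > 0 else 1.0
            gfp = s * config.base_ratio * mcherry * noise
            rows.append(
                {
                    "construct_id": construct,
                    "replicate": rep,
                    "gfp": gfp,
                    "mcherry": mcherry,
                }
            )
    return pd.DataFrame(rows)
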