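import numpy as np
import pytest

from insulmine.annotation_io import GeneModel, GenomeIndex, OrthologHit
from insulmine.candidate_miner import CandidateRegion, call_candidates, extract_intergenic
from insulmine.synteny_scan import (
    HIGH_QUALITY,
    INDEL,
    INVERSION,
    NONE,
    SyntenyParams,
    build_matrix,
    high_confidence,
    scan_region,
    select_for_validation,
)
from insulmine.synthetic_data import GeneratorConfig, gen_genome, gen_subject_genomes

from conftest import make_index
from oracles import brute_force_scan


def _candidate(left="qL", right="qR", region_id="r1", fc=2.0, length=500):
    return CandidateRegion(
        region_id=region_id,
        seqid="c1",
        start=1000,
        end=1000 + length,
        left_gene_id=left,
        right_gene_id=right,
        orientation="divergent",
        fpkm_left=10.0,
        fpkm_right=10.0 * fc if fc != float("inf") else 0.0,
        fold_change=fc,
        high_gene_id=right,
        passes_core_filter=True,
        is_short=length <= 1000,
    )


def _index(gene_rows, genome_id="sub"):
    """gene_rows: (gene_id, strand) laid out left to right on one seqid."""
    genes = [
        ("%s" % gid, "s1", 1000 * i, 1000 * i + 500, strand, 0.0)
        for i, (gid, strand) in enumerate(gene_rows)
    ]
    return make_index(genes, genome_id=genome_id)


def _hits(pairs):
    return [
        OrthologHit(q, "sub", s, evalue, 200.0)
        for q, s, evalue in pairs
    ]


@pytest.fixture
def query_index():
    # divergent adjacent pair qL(-) qR(+) on c1
    return make_index(
        [("qL", "c1", 0, 900, "-", 10.0), ("qR", "c1", 1500, 2400, "+", 20.0)],
        genome_id="query",
    )


class TestScanRegion:
    def test_identity_copy_is_high_quality(self, query_index):
        sub = _index([("sL", "-"), ("sR", "+")])
        call = scan_region(_candidate(), query_index, sub,
                           _hits([("qL", "sL", 1e-20), ("qR", "sR", 1e-20)]))
        assert call.klass == HIGH_QUALITY
        assert call.intervening_query == call.intervening_subject == 0

    def test_two_inserted_genes_is_indel(self, query_index):
        sub = _index([("sL", "-"), ("x1", "+"), ("x2", "+"), ("sR", "+")])
        call = scan_region(_candidate(), query_index, sub,
                           _hits([("qL", "sL", 1e-20), ("qR", "sR", 1e-20)]))
        assert call.klass == INDEL
        assert (call.intervening_query, call.intervening_subject) == (0, 2)

    def test_one_strand_flip_is_inversion(self, query_index):
        sub = _index([("sL", "-"), ("sR", "-")])  # right gene flipped in place
        call = scan_region(_candidate(), query_index, sub,
                           _hits([("qL", "sL", 1e-20), ("qR", "sR", 1e-20)]))
        assert call.klass == INVERSION

    def test_both_strands_changed_is_none(self, query_index):
        sub = _index([("sL", "+"), ("sR", "-")])
        call = scan_region(_candidate(), query_index, sub,
                           _hits([("qL", "sL", 1e-20), ("qR", "sR", 1e-20)]))
        assert call.klass == NONE

    @pytest.mark.parametrize("n_between,expected", [(5, INDEL), (6, NONE)])
    def test_max_between_boundary(self, query_index, n_between, expected):
        """Five intervening genes is still admissible; six is not."""
        rows = [("sL", "-")] + [(f"x{i}", "+") for i in range(n_between)] + [("sR", "+")]
        call = scan_region(_candidate(), query_index, _index(rows),
                           _hits([("qL", "sL", 1e-20), ("qR", "sR", 1e-20)]))
        assert call.klass == expected

    def test_missing_flank_hit_is_none_not_error(self, query_index):
        sub = _index([("sL", "-"), ("sR", "+")])
        call = scan_region(_candidate(), query_index, sub, _hits([("qL", "sL", 1e-20)]))
        assert call.klass == NONE

    def test_subject_chromosome_reversal_invariance(self, query_index):
        """Reversing a whole subject chromosome leaves every verdict unchanged."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 8))
            rows = [(f"s{i}", "+" if rng.integers(2) else "-") for i in range(n)]
            li, ri = sorted(rng.choice(n, size=2, replace=False))
            hits = _hits([("qL", f"s{li}", 1e-20), ("qR", f"s{ri}", 1e-20)])
            fwd = scan_region(_candidate(), query_index, _index(rows), hits)
            flip = {"+": "-", "-": "+"}
            rev_rows = [(gid, flip[s]) for gid, s in reversed(rows)]
            rev = scan_region(_candidate(), query_index, _index(rev_rows), hits)
            assert rev.klass == fwd.klass

    def test_multiple_hits_select_min_intervening_then_evalue(self, query_index):
        # qR hits both a far gene (2 intervening) and a near one (0 intervening)
        sub = _index([("sL", "-"), ("near", "+"), ("x", "+"), ("far", "+")])
        call = scan_region(
            _candidate(), query_index, sub,
            _hits([("qL", "sL", 1e-20), ("qR", "far", 1e-80), ("qR", "near", 1e-10)]),
        )
        assert call.subject_right_gene == "near"
        assert call.klass == HIGH_QUALITY

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n_sub = int(rng.integers(2, 30))
        rows = [(f"s{i}", "+" if rng.integers(2) else "-") for i in range(n_sub)]
        sub = _index(rows)
        n_hits = int(rng.integers(0, 50))
        hit_rows = [
            (
                "qL" if rng.integers(2) else "qR",
                f"s{rng.integers(n_sub)}",
                float(10.0 ** -rng.integers(6, 60)),
            )
            for _ in range(n_hits)
        ]
        qidx = make_index(
            [("qL", "c1", 0, 900, "-", 10.0), ("qR", "c1", 1500, 2400, "+", 20.0)],
            genome_id="query",
        )
        got = scan_region(_candidate(), qidx, sub, _hits(hit_rows)).klass
        query_genes = [("qL", "c1", 0, 900, "-"), ("qR", "c1", 1500, 2400, "+")]
        subject_genes = [
            (gid, "s1", 1000 * i, 1000 * i + 500, s) for i, (gid, s) in enumerate(rows)
        ]
        expected = brute_force_scan(("qL", "qR"), query_genes, subject_genes, hit_rows)
        assert got == expected


class TestBuildMatrix:
    def test_no_subject_genomes_gives_empty_matrix(self, query_index):
        cands = [_candidate()]
        matrix, calls = build_matrix(cands, query_index, {}, {})
        assert calls == []
        assert list(matrix.breadth()) == [0]

    def test_identity_genome_breadth_one(self):
        index, truth = gen_genome(GeneratorConfig(seed=3, pairs_per_chrom=10))
        cfg = GeneratorConfig(seed=3, pairs_per_chrom=10, p_high_quality=1.0,
                              p_indel=0, p_inversion=0, p_none=0)
        subs, hits = gen_subject_genomes(index, truth, cfg, n_genomes=1)
        cands = [c for c in call_candidates(extract_intergenic(index), index)
                 if c.passes_core_filter]
        matrix, _ = build_matrix(cands, index, subs, hits)
        assert (matrix.breadth() == 1).all()
        assert (matrix.table == HIGH_QUALITY).all().all()

    def test_planted_conservation_confusion_matrix_is_diagonal(self):
        index, truth = gen_genome(GeneratorConfig(seed=9))
        cfg = GeneratorConfig(seed=9)
        subs, hits = gen_subject_genomes(index, truth, cfg, n_genomes=5)
        cands = [c for c in call_candidates(extract_intergenic(index), index)
                 if c.passes_core_filter]
        matrix, _ = build_matrix(cands, index, subs, hits)
        by_key = {(c.left_gene_id, c.right_gene_id): c.region_id for c in cands}
        checked = 0
        for (key, gid), expected in truth.planted_synteny.items():
            assert matrix.klass(by_key[key], gid) == expected
            checked += 1
        assert checked == len(cands) * 5


class TestHighConfidence:
    def _setup(self, fcs_lengths_klass):
        cands, cells = [], {}
        for i, (fc, length, klass) in enumerate(fcs_lengths_klass):
            c = _candidate(left=f"L{i}", right=f"R{i}", region_id=f"r{i}", fc=fc,
                           length=length)
            cands.append(c)
            cells[c.region_id] = {"g1": klass}
        import pandas as pd

        from insulmine.synteny_scan import PresenceAbsenceMatrix

        matrix = PresenceAbsenceMatrix(pd.DataFrame.from_dict(cells, orient="index"))
        return cands, matrix

    def test_fc_threshold_is_strict(self):
        cands, matrix = self._setup([(10.0, 800, HIGH_QUALITY), (12.0, 800, HIGH_QUALITY)])
        kept, stats = high_confidence(cands, matrix)
        assert kept == ["r1"]
        assert stats == {"n_high_confidence": 1, "n_syntenic": 2, "pct_of_syntenic": 50.0}

    def test_requires_high_quality_not_just_syntenic(self):
        cands, matrix = self._setup([(12.0, 800, INDEL), (12.0, 800, HIGH_QUALITY),
                                     (12.0, 1200, HIGH_QUALITY)])
        kept, stats = high_confidence(cands, matrix)
        assert kept == ["r1"]
        assert stats["n_syntenic"] == 3

    def test_high_confidence_subset_of_syntenic(self):
        index, truth = gen_genome(GeneratorConfig(seed=12))
        cfg = GeneratorConfig(seed=12)
        subs, hits = gen_subject_genomes(index, truth, cfg, 4)
        cands = [c for c in call_candidates(extract_intergenic(index), index)
                 if c.passes_core_filter]
        matrix, _ = build_matrix(cands, index, subs, hits)
        kept, _ = high_confidence(cands, matrix)
        assert set(kept) <= set(matrix.syntenic_region_ids())

    def test_raising_max_between_is_monotone(self, query_index):
        index, truth = gen_genome(GeneratorConfig(seed=13))
        cfg = GeneratorConfig(seed=13)
        subs, hits = gen_subject_genomes(index, truth, cfg, 3)
        cands = [c for c in call_candidates(extract_intergenic(index), index)
                 if c.passes_core_filter]
        counts = []
        for mb in (0, 2, 5, 8):
            matrix, _ = build_matrix(cands, index, subs, hits, SyntenyParams(max_between=mb))
            counts.append(int((matrix.table != NONE).sum().sum()))
        assert counts == sorted(counts)


class TestSelectForValidation:
    def _matrix(self, cands, breadths):
        import pandas as pd

        from insulmine.synteny_scan import PresenceAbsenceMatrix

        cells = {
            c.region_id: {f"g{j}": (HIGH_QUALITY if j < b else NONE) for j in range(5)}
            for c, b in zip(cands, breadths)
        }
        return PresenceAbsenceMatrix(pd.DataFrame.from_dict(cells, orient="index"))

    def test_top_by_fold_change(self):
        cands = [_candidate(region_id=f"r{i}", left=f"L{i}", right=f"R{i}", fc=fc)
                 for i, fc in enumerate([2.0, 30.0, 5.0])]
        a, _ = select_for_validation(cands, self._matrix(cands, [0, 0, 0]), k=1)
        assert [c.region_id for c in a] == ["r1"]

    def test_infinite_fc_ranks_first(self):
        cands = [_candidate(region_id="r0", left="L0", right="R0", fc=float("inf")),
                 _candidate(region_id="r1", left="L1", right="R1", fc=500.0)]
        a, _ = select_for_validation(cands, self._matrix(cands, [0, 0]), k=2)
        assert [c.region_id for c in a] == ["r0", "r1"]

    def test_breadth_ties_broken_by_length(self):
        lengths = [400, 900, 300, 700]
        cands = [
            _candidate(region_id=f"r{i}", left=f"L{i}", right=f"R{i}", fc=2.0,
                       length=lengths[i])
            for i in range(4)
        ]
        _, b = select_for_validation(cands, self._matrix(cands, [0, 3, 3, 1]), k=2)
        assert [c.region_id for c in b] == ["r2", "r1"]

    def test_k_larger_than_pool_returns_all_with_warning(self, caplog):
        cands = [_candidate(region_id=f"r{i}", left=f"L{i}", right=f"R{i}", fc=2.0)
                 for i in range(6)]
        with caplog.at_level("WARNING"):
            a, b = select_for_validation(cands, self._matrix(cands, [0] * 6), k=9)
        assert len(a) == len(b) == 6
        assert any("returning all" in r.message for r in caplog.records)
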