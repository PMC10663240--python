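"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's own code paths: plain loops over
explicitly enumerated pairs, with the classification rules restated from
first principles. They are only run on tiny instances.
"""

from __future__ import annotations

import math


def brute_force_intergenic(genes):
    """All adjacent non-overlapping pairs from a flat gene tuple list.

    genes: (gene_id, seqid, start, end, strand, fpkm) tuples, any order.
    Returns {(left_id, right_id): (start, end, orientation)}.
    """
    out = {}
    seqids = {g[1] for g in genes}
    for seqid in seqids:
        onseq = sorted(
            (g for g in genes if g[1] == seqid), key=lambda g: (g[2], g[3], g[0])
        )
        for a, b in zip(onseq, onseq[1:]):
            if b[2] < a[3]:  # right start before left end: overlap
                continue
            if a[4] == "-" and b[4] == "+":
                ori = "divergent"
            elif a[4] == "+" and b[4] == "-":
                ori = "convergent"
            else:
                ori = "tandem"
            out[(a[0], b[0])] = (a[3], b[2], ori)
    return out


def brute_force_candidates(genes, min_len=50, max_len=20_000, min_fc=1.5, top_fraction=0.5):
    """Per-pair predicate evaluation of the candidate filter.

    Returns the set of (left_id, right_id) keys that pass.
    """
    fpkm = {g[0]: g[5] for g in genes}
    values = sorted(fpkm.values(), reverse=True)
    k = max(1, math.ceil(len(values) * top_fraction))
    cutoff = values[k - 1]
    passing = set()
    for (lid, rid), (start, end, ori) in brute_force_intergenic(genes).items():
        length = end - start
        if not (min_len <= length <= max_len):
            continue
        if ori not in ("divergent", "convergent"):
            continue
        f1, f2 = fpkm[lid], fpkm[rid]
        hi, lo = max(f1, f2), min(f1, f2)
        if hi == 0:
            continue  # no expression evidence at all
        fc = math.inf if lo == 0 else hi / lo
        if fc < min_fc:
            continue
        if hi < cutoff:
            continue  # higher-expressed gene must be in the top set
        if ori == "convergent" and (f1 >= cutoff) == (f2 >= cutoff):
            continue  # convergent needs exactly one highly expressed gene
        passing.add((lid, rid))
    return passing


def brute_force_scan(
    query_pair, query_genes, subject_genes, hits, max_between=5
):
    """Classify one flanking pair in one subject genome by full enumeration.

    query_pair: (left_id, right_id). query_genes / subject_genes:
    (gene_id, seqid, start, end, strand) tuples. hits: (query_id,
    subject_id, evalue) tuples. Returns the klass string.
    """

    def ranks(genes):
        r = {}
        seqids = {g[1] for g in genes}
        for seqid in seqids:
            onseq = sorted(
                (g for g in genes if g[1] == seqid), key=lambda g: (g[2], g[3], g[0])
            )
            for i, g in enumerate(onseq):
                r[g[0]] = (seqid, i, g[4])
        return r

    qr = ranks(query_genes)
    sr = ranks(subject_genes)
    lid, rid = query_pair
    _, lrank, lstrand = qr[lid]
    _, rrank, rstrand = qr[rid]
    iq = abs(rrank - lrank) - 1
    flip = {"+": "-", "-": "+"}

    candidates = []
    for (q1, s1, e1) in hits:
        if q1 != lid or s1 not in sr:
            continue
        for (q2, s2, e2) in hits:
            if q2 != rid or s2 not in sr:
                continue
            seq1, rank1, strand1 = sr[s1]
            seq2, rank2, strand2 = sr[s2]
            if seq1 != seq2 or rank1 == rank2:
                continue
            isub = abs(rank2 - rank1) - 1
            if isub > max_between:
                continue
            candidates.append((isub, e1 + e2, s1, s2, rank1, rank2, strand1, strand2))
    if not candidates:
        return "none"
    isub, _, s1, s2, rank1, rank2, strand1, strand2 = min(candidates)
    if rank1 > rank2:  # mirror the subject pair so order matches the query
        strand1, strand2 = flip[strand1], flip[strand2]
    matches = (strand1 == lstrand) + (strand2 == rstrand)
    if matches == 2:
        return "high_quality" if isub == iq else "indel"
    if matches == 1 and isub == iq:
        return "inversion"
    return "none"
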