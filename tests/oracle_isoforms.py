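"""Brute-force transcript-model classifier used as an independent oracle.

Transcribes the category definitions literally over plain lists of
transcripts, using exhaustive enumeration and per-base interval
arithmetic — no index structures shared with the implementation under
test. Transcripts are (transcript_id, gene_id, chrom, strand, exons)
tuples with 0-based half-open exons.
"""


def _chain(exons):
    return tuple((exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1))


def _reciprocal_50(a, b):
    ov = min(a[1], b[1]) - max(a[0], b[0])
    return ov > 0 and ov >= 0.5 * (a[1] - a[0]) and ov >= 0.5 * (b[1] - b[0])


def _overlap_bases(exons_a, exons_b):
    bases_a = set()
    for s, e in exons_a:
        bases_a.update(range(s, e))
    bases_b = set()
    for s, e in exons_b:
        bases_b.update(range(s, e))
    return len(bases_a & bases_b)


def _gene_span(transcripts):
    lo = min(t[4][0][0] for t in transcripts)
    hi = max(t[4][-1][1] for t in transcripts)
    return lo, hi


def oracle_classify(chrom, strand, exons, transcripts):
    """Literal brute-force category call for one model.

    Categories: known (chain equality, truncation subchain, or mono-exon
    reciprocal overlap with a mono-exon transcript); intergenic (no gene
    span overlap); ME (mono-exon inside one host-gene exon); MIR
    (mono-exon retaining a complete host intron); IR (multi-exon
    retaining a complete host intron); CJ (all junctions annotated in
    the host gene); CS (all splice sites annotated on the chrom+strand);
    else discarded.
    """
    exons = [tuple(e) for e in exons]
    chain = _chain(exons)
    same = [t for t in transcripts if t[2] == chrom and t[3] == strand]

    # -- known -----------------------------------------------------------
    if not chain:
        for t in same:
            if len(t[4]) == 1 and _reciprocal_50(exons[0], t[4][0]):
                return "known"
    else:
        for t in same:
            tc = _chain(t[4])
            if tc == chain:
                return "known"
            n = len(chain)
            for off in range(len(tc) - n + 1):
                if tc[off : off + n] == chain:
                    if exons[0][0] >= t[4][off][0] and exons[-1][1] <= t[4][off + n][1]:
                        return "known"

    # -- host gene: same-strand gene maximizing exonic base overlap ------
    genes = {}
    for t in transcripts:
        genes.setdefault(t[1], []).append(t)
    best_gene, best_ov = None, 0
    for gid in sorted(genes):
        members = genes[gid]
        if members[0][2] != chrom or members[0][3] != strand:
            continue
        gene_exons = [e for t in members for e in t[4]]
        ov = _overlap_bases(exons, gene_exons)
        if ov > best_ov:
            best_gene, best_ov = gid, ov
    host = best_gene if best_ov > 0 else None

    def overlaps_any_gene_span(s, e):
        for gid, members in genes.items():
            if members[0][2] != chrom:
                continue
            lo, hi = _gene_span(members)
            if max(lo, s) < min(hi, e):
                return True
        return False

    host_introns = set()
    if host is not None:
        for t in genes[host]:
            host_introns.update(_chain(t[4]))

    def retains_intron():
        for s, e in exons:
            for d, a in host_introns:
                if s < d and a < e:
                    return True
        return False

    # -- mono-exon -------------------------------------------------------
    if not chain:
        s, e = exons[0]
        if not overlaps_any_gene_span(s, e):
            return "intergenic"
        if host is not None:
            for t in genes[host]:
                for xs, xe in t[4]:
                    if xs <= s and e <= xe:
                        return "ME"
            if retains_intron():
                return "MIR"
        return "discarded"

    # -- multi-exon ------------------------------------------------------
    if host is None:
        if any(overlaps_any_gene_span(s, e) for s, e in exons):
            return "discarded"
        return "intergenic"
    if retains_intron():
        return "IR"
    if all(j in host_introns for j in chain):
        return "CJ"
    left = {e for t in same for (e, _s) in _chain(t[4])}
    right = {s for t in same for (_e, s) in _chain(t[4])}
    if all(d in left and a in right for d, a in chain):
        return "CS"
    return "discarded"
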