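"""Independent brute-force ROH caller used as the oracle in equivalence tests.

Deliberately naive: enumerates every window by slicing, every per-SNP
window membership by scanning, and every maximal run by walking the flag
list. Shares no code with rohscan.roh.
"""

MISSING = -1


def bruteforce_detect(snp_map, geno, params, min_snps_floor):
    """All ROH segments as tuples (individual, chrom, start_bp, end_bp, n_snps)."""
    out = []
    for i, ind in enumerate(geno.individuals):
        for chrom in snp_map.chromosomes:
            sl = snp_map.chrom_slice(chrom)
            g = list(int(v) for v in geno.calls[i, sl])
            pos = list(int(v) for v in snp_map.pos[sl])
            flags = _flags(g, params)
            for run in _runs(flags, pos, params.max_gap_kb * 1000.0):
                a, b = run[0], run[-1]
                n = len(run)
                length_kb = (pos[b] - pos[a] + 1) / 1000.0
                if n < min_snps_floor:
                    continue
                if length_kb < params.min_length_kb:
                    continue
                if length_kb / n > params.max_density_kb_per_snp:
                    continue
                out.append((ind, chrom, pos[a], pos[b], n))
    out.sort()
    return out


def _flags(g, params):
    n = len(g)
    w = params.window_snps
    if n < w:
        return [False] * n
    window_ok = []
    for s in range(n - w + 1):
        win = g[s : s + w]
        n_het = sum(1 for v in win if v == 1)
        n_mis = sum(1 for v in win if v == MISSING)
        window_ok.append(
            n_het <= params.window_het_max and n_mis <= params.window_missing_max
        )
    flags = []
    for j in range(n):
        containing = [s for s in range(n - w + 1) if s <= j < s + w]
        frac = sum(window_ok[s] for s in containing) / len(containing)
        flags.append(frac >= params.hit_threshold)
    return flags


def _runs(flags, pos, max_gap_bp):
    runs = []
    current = []
    for j, f in enumerate(flags):
        if not f:
            if current:
                runs.append(current)
                current = []
            continue
        if current and pos[j] - pos[current[-1]] > max_gap_bp:
            runs.append(current)
            current = []
        current.append(j)
    if current:
        runs.append(current)
    return runs
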