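"""Independent reference implementations used to check the package.

These are deliberately naive: full-matrix dynamic programming per window
length for the off-target scan, all-pairs loops for interval work, plain
per-record predicates for filtering. They share no code with the
production paths they verify.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def rc(seq: str) -> str:
    return "".join(COMP.get(b, "N") for b in reversed(seq))


def pam_ok(pattern: str, seq: str) -> bool:
    return len(seq) == len(pattern) and all(s in IUPAC[p] for p, s in zip(pattern, seq))


def full_dp_cost(guide: str, window: str, bulge_cost: int, max_bulges: int,
                 ) -> Optional[Tuple[int, int]]:
    """Minimal (cost, bulge_bases) aligning all of ``guide`` to all of
    ``window`` with at most ``max_bulges`` total unpaired bases.

    Full (len(guide)+1) x (len(window)+1) x (max_bulges+1) matrix, no
    banding, no pruning. Lexicographic minimum over (cost, bulges).
    """
    G, W = len(guide), len(window)
    INF = (10 ** 9, 10 ** 9)
    dp = [[[INF] * (max_bulges + 1) for _ in range(W + 1)] for _ in range(G + 1)]
    dp[0][0][0] = (0, 0)
    for i in range(G + 1):
        for j in range(W + 1):
            for nb in range(max_bulges + 1):
                cur = dp[i][j][nb]
                if cur == INF:
                    continue
                cost, bulges = cur
                if i < G and j < W:
                    mism = not (guide[i] == window[j] and guide[i] in "ACGT"
                                and window[j] in "ACGT")
                    cand = (cost + int(mism), bulges)
                    if cand < dp[i + 1][j + 1][nb]:
                        dp[i + 1][j + 1][nb] = cand
                if nb < max_bulges:
                    if i < G:
                        cand = (cost + bulge_cost, bulges + 1)
                        if cand < dp[i + 1][j][nb + 1]:
                            dp[i + 1][j][nb + 1] = cand
                    if j < W:
                        cand = (cost + bulge_cost, bulges + 1)
                        if cand < dp[i][j + 1][nb + 1]:
                            dp[i][j + 1][nb + 1] = cand
    best = min(dp[G][W])
    return None if best == INF else best


def oracle_scan(genome: Dict[str, str], protospacer: str, pam: str,
                max_penalty: int, bulge_cost: int, max_bulge_len: int,
                ) -> List[Tuple[str, int, int, str, int, int]]:
    """Every candidate site, one representative per overlapping cluster.

    Returns (chrom, start, end, strand, penalty, bulge_bases) tuples in
    genome coordinates, deduplicated with the minimal-penalty /
    fewer-bulges / longest-target rule.
    """
    maxb = min(max_bulge_len, max_penalty // bulge_cost)
    G = len(protospacer)
    raw = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for p in range(G - maxb, n - len(pam) + 1):
                if not pam_ok(pam, s[p:p + len(pam)]):
                    continue
                best = None  # (cost, bulges, -L)
                for L in range(max(0, G - maxb), G + maxb + 1):
                    if p - L < 0:
                        continue
                    hit = full_dp_cost(protospacer, s[p - L:p], bulge_cost, maxb)
                    if hit is None or hit[0] > max_penalty:
                        continue
                    cand = (hit[0], hit[1], -L)
                    if best is None or cand < best:
                        best = cand
                if best is None:
                    continue
                cost, bulges, negL = best
                L = -negL
                start, end = p - L, p
                if strand == "-":
                    start, end = n - end, n - start
                raw.append((chrom, start, end, strand, cost, bulges))
    return oracle_dedup(raw)


def oracle_dedup(raw: List[Tuple[str, int, int, str, int, int]]):
    """Keep the best site per transitive-overlap cluster (per chrom+strand)."""
    remaining = list(raw)
    out = []
    while remaining:
        seed = remaining.pop()
        cluster = [seed]
        changed = True
        while changed:
            changed = False
            for site in list(remaining):
                if any(site[0] == c[0] and site[3] == c[3]
                       and site[1] < c[2] and site[2] > c[1] for c in cluster):
                    cluster.append(site)
                    remaining.remove(site)
                    changed = True
        out.append(min(cluster, key=lambda s: (s[4], s[5], s[1])))
    return sorted(out)


def oracle_scan_fast(genome: Dict[str, str], protospacer: str, pam: str,
                     max_penalty: int, bulge_cost: int, max_bulge_len: int,
                     ) -> List[Tuple[str, int, int, str, int, int]]:
    """Same exhaustive per-window DP as :func:`oracle_scan`, vectorized
    across anchors with numpy so whole-genome sweeps stay fast.

    Full matrices per window length, no banding and no cost pruning;
    (cost, bulges) pairs are encoded as cost*8 + bulges so a single
    integer minimum realizes the lexicographic order (bulges < 8 always
    holds since max_bulge_len is tiny).
    """
    import numpy as np

    maxb = min(max_bulge_len, max_penalty // bulge_cost)
    assert maxb < 8
    G = len(protospacer)
    guide_bytes = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    BIG = np.int32(1 << 20)
    raw = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            pam_pos = np.array([p for p in range(n - len(pam) + 1)
                                if pam_ok(pam, s[p:p + len(pam)])], dtype=np.int64)
            pam_pos = pam_pos[pam_pos >= G - maxb]
            if pam_pos.size == 0:
                continue
            # best encoded (cost, bulges) and the L realizing it, per anchor
            best_key = np.full(pam_pos.size, BIG, dtype=np.int32)
            best_L = np.zeros(pam_pos.size, dtype=np.int64)
            for L in range(max(0, G - maxb), G + maxb + 1):
                ok = pam_pos - L >= 0
                anchors = pam_pos[ok]
                if anchors.size == 0:
                    continue
                win = arr[anchors[:, None] - L + np.arange(L)[None, :]]  # (A, L)
                win_bad = ~np.isin(win, acgt)
                A = anchors.size
                NB = maxb + 1
                prev = np.full((A, L + 1, NB), BIG, dtype=np.int32)
                prev[:, 0, 0] = 0
                # dna bulges along row 0 (guide not yet consumed)
                for j in range(1, L + 1):
                    prev[:, j, 1:] = np.minimum(
                        prev[:, j, 1:], prev[:, j - 1, :-1] + bulge_cost * 8 + 1)
                for i in range(1, G + 1):
                    cur = np.full((A, L + 1, NB), BIG, dtype=np.int32)
                    # rna bulge: consume guide base, no target base
                    cur[:, :, 1:] = np.minimum(
                        cur[:, :, 1:], prev[:, :, :-1] + bulge_cost * 8 + 1)
                    # match / mismatch
                    mism = (win != guide_bytes[i - 1]) | win_bad
                    sub = (mism.astype(np.int32) * 8)[:, :, None]  # (A, L, 1)
                    cur[:, 1:, :] = np.minimum(cur[:, 1:, :], prev[:, :-1, :] + sub)
                    # dna bulge: consume target base within this row
                    for j in range(1, L + 1):
                        cur[:, j, 1:] = np.minimum(
                            cur[:, j, 1:], cur[:, j - 1, :-1] + bulge_cost * 8 + 1)
                    prev = cur
                key = prev[:, L, :].min(axis=1)
                improve = key < best_key[ok]
                tie = (key == best_key[ok])  # larger L preferred on ties
                upd = improve | tie
                idx = np.nonzero(ok)[0][upd]
                best_key[idx] = key[upd]
                best_L[idx] = L
            for a in range(pam_pos.size):
                cost, bulges = int(best_key[a]) >> 3, int(best_key[a]) & 7
                if best_key[a] >= BIG or cost > max_penalty:
                    continue
                p = int(pam_pos[a])
                L = int(best_L[a])
                start, end = p - L, p
                if strand == "-":
                    start, end = n - end, n - start
                raw.append((chrom, start, end, strand, cost, bulges))
    return oracle_dedup(raw)


# ---------------------------------------------------------------------------
# crossref oracles

def oracle_filter_predicate(call, min_support=4, min_mq=30.0, min_qual=20.0,
                            max_indel_len=50) -> bool:
    """Threshold predicate for one indel record (no proximity rules)."""
    return (call.support >= min_support and call.mq >= min_mq
            and call.qual >= min_qual and call.indel_len < max_indel_len)


def oracle_exclusive_windowed(edited, control, window):
    """Brute-force pairwise matcher for windowed exclusivity."""
    out = []
    for e in edited:
        hit = False
        for c in control:
            if (c.chrom == e.chrom and abs(c.pos - e.pos) <= window
                    and c.indel_len == e.indel_len):
                hit = True
        if not hit:
            out.append(e)
    return out


def oracle_indel_interval(call) -> Tuple[int, int]:
    p0 = call.pos - 1
    if len(call.ref) > len(call.alt):
        return p0 + 1, p0 + 1 + (len(call.ref) - len(call.alt))
    return p0 + 1, p0 + 1


def oracle_all_pairs_hits(sites, indels, windows):
    """All-pairs distance computation; returns {window: set(site indices)}
    and the list of (site_idx, indel_idx, distance, window)."""
    per_window = {w: set() for w in windows}
    hits = []
    for i, site in enumerate(sites):
        for j, call in enumerate(indels):
            if site.chrom != call.chrom:
                continue
            a, b = oracle_indel_interval(call)
            d = max(0, a - site.end, site.start - b)
            for w in windows:
                if d <= w:
                    per_window[w].add(i)
                    hits.append((i, j, d, w))
    return per_window, hits


# ---------------------------------------------------------------------------
# genotype oracle

def oracle_bands_by_counting(wt: float, het: float, homo: float, n_cells: int = 200000):
    """Band percentages from explicit allele counting over a discrete cell
    population (no algebra shared with the closed-form model)."""
    n_wt = round(n_cells * wt / 100.0)
    n_het = round(n_cells * het / 100.0)
    n_homo = n_cells - n_wt - n_het
    # unsorted lane
    wt_alleles = 2 * n_wt + n_het
    car_alleles = n_het + 2 * n_homo
    total = wt_alleles + car_alleles
    C = 100.0 * wt_alleles / total
    D = 100.0 * car_alleles / total
    # sorted lane: cassette-positive cells only
    s_wt = n_het
    s_car = n_het + 2 * n_homo
    A = 100.0 * s_wt / (s_wt + s_car)
    B = 100.0 * s_car / (s_wt + s_car)
    return A, B, C, D
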