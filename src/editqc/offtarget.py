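"""PAM-anchored off-target site enumeration under a mismatch + bulge budget.

A candidate site is any genomic window, on either strand, whose best
alignment to the guide spacer costs no more than ``max_penalty``
mismatch-equivalents, where each unpaired (bulged) base — whether an extra
target base (DNA bulge) or an extra guide base (RNA bulge) — costs
``bulge_cost_per_base`` mismatch-equivalents (default 2), and which is
followed by a PAM matching the IUPAC pattern on the protospacer strand.

The alignment is anchored at the PAM-proximal end of the protospacer (no
end gaps on the PAM side; the PAM-distal end may shift by up to the bulge
allowance), computed by a banded dynamic program over guide position,
target bases consumed, and total bulged bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from editqc.guides import GuideError, GuideSpec, IUPAC_CODES, iupac_match, revcomp


class ScanInputError(ValueError):
    """Invalid genome or guide input to the scanner."""


@dataclass(frozen=True)
class ScanParams:
    """Penalty model for the off-target scan.

    ``max_penalty`` is the total budget in mismatch-equivalents; a bulged
    base costs ``bulge_cost_per_base`` of it. ``max_bulge_len`` caps the
    total number of bulged bases in one alignment (with the defaults the
    budget itself already implies at most two). Sites whose interval lies
    within ``exclude_on_target_radius`` of the guide's on-target position
    are reported separately rather than counted as off-targets.
    """

    max_penalty: int = 5
    bulge_cost_per_base: int = 2
    max_bulge_len: int = 2
    pam_pattern: str = "NRG"
    exclude_on_target_radius: int = 1000

    def __post_init__(self) -> None:
        if self.max_penalty < 0:
            raise ScanInputError("max_penalty must be >= 0")
        if self.bulge_cost_per_base < 1:
            raise ScanInputError("bulge_cost_per_base must be >= 1")
        if self.max_bulge_len < 0:
            raise ScanInputError("max_bulge_len must be >= 0")
        if any(b not in IUPAC_CODES for b in self.pam_pattern.upper()):
            raise ScanInputError(f"non-IUPAC PAM pattern: {self.pam_pattern}")
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())

    @property
    def effective_max_bulge(self) -> int:
        """Bulge-base allowance after pruning by the penalty budget."""
        return min(self.max_bulge_len, self.max_penalty // self.bulge_cost_per_base)


@dataclass(frozen=True)
class CandidateSite:
    """One candidate protospacer locus.

    Coordinates are 0-based half-open over the aligned target bases
    (the PAM is *not* included in ``start``/``end``). ``aligned_guide``
    and ``aligned_target`` are gapped strings written 5'->3' on the
    protospacer strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    penalty: int
    mismatches: int
    dna_bulge_bases: int
    rna_bulge_bases: int
    aligned_guide: str = ""
    aligned_target: str = ""
    pam_observed: str = ""
    guide_name: str = "guide"

    @property
    def bulge_bases(self) -> int:
        return self.dna_bulge_bases + self.rna_bulge_bases

    def key(self) -> Tuple:
        return (self.chrom, self.start, self.end, self.strand, self.penalty,
                self.mismatches, self.dna_bulge_bases, self.rna_bulge_bases)


@dataclass
class ScanResult:
    """Off-target sites plus the separately reported on-target-region sites."""

    sites: List[CandidateSite]
    on_target_sites: List[CandidateSite]
    params: ScanParams
    guide: GuideSpec

    def __len__(self) -> int:
        return len(self.sites)


# ---------------------------------------------------------------------------
# genome input

def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read a (optionally gzipped) FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ScanInputError(f"no FASTA records in {path}")
    return records


def _as_genome(genome: Union[str, Path, Dict[str, str]]) -> Dict[str, str]:
    if isinstance(genome, (str, Path)):
        return read_fasta(genome)
    if not genome:
        raise ScanInputError("empty genome")
    return {name: seq.upper() for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# core alignment

def _pam_anchor_positions(seq: str, pattern: str) -> np.ndarray:
    """Positions p where seq[p:p+len(pattern)] matches the IUPAC pattern.

    Vectorized over the chromosome: one boolean mask per pattern symbol,
    AND-ed with shifts.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    plen = len(pattern)
    if n < plen:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - plen + 1, dtype=bool)
    for off, sym in enumerate(pattern):
        allowed = np.frombuffer(IUPAC_CODES[sym].encode(), dtype=np.uint8)
        ok &= np.isin(arr[off:n - plen + 1 + off], allowed)
    return np.nonzero(ok)[0]


def _align_anchored(
    guide_rev: str,
    window_rev: str,
    params: ScanParams,
) -> Optional[Tuple[int, int, int, int, int, str, str]]:
    """Best PAM-anchored alignment of the guide against a target window.

    Both inputs are reversed so index 0 is the base adjacent to the PAM.
    Returns ``(penalty, mismatches, dna_bulges, rna_bulges, target_len,
    aligned_guide, aligned_target)`` for the best end state, or None when
    nothing fits the budget. Ties break on fewer bulged bases, then on the
    longest target (which maps to the leftmost genomic start on + and is
    normalized later for -).

    State space: (guide bases consumed i, target bases consumed j, total
    bulged bases nb), cost pruned at ``max_penalty``. Any non-ACGT target
    base mismatches every guide base.
    """
    G = len(guide_rev)
    maxb = params.effective_max_bulge
    bc = params.bulge_cost_per_base
    budget = params.max_penalty
    W = len(window_rev)

    # best[(i, j, nb)] = (cost, parent_state, move); move in {M, X, D, I}
    best: Dict[Tuple[int, int, int], Tuple[int, Optional[Tuple[int, int, int]], str]] = {
        (0, 0, 0): (0, None, "")
    }
    frontier = [(0, 0, 0)]
    for _ in range(G + maxb):
        new_frontier = []
        for state in frontier:
            i, j, nb = state
            cost = best[state][0]
            if cost > best.get(state, (cost,))[0]:
                continue
            if i < G and j < W:
                sub = 0 if (window_rev[j] == guide_rev[i] and guide_rev[i] in "ACGT"
                            and window_rev[j] in "ACGT") else 1
                nxt = (i + 1, j + 1, nb)
                c = cost + sub
                if c <= budget and c < best.get(nxt, (c + 1,))[0]:
                    best[nxt] = (c, state, "M" if sub == 0 else "X")
                    new_frontier.append(nxt)
            if nb < maxb:
                # RNA bulge: guide base left unpaired
                if i < G:
                    nxt = (i + 1, j, nb + 1)
                    c = cost + bc
                    if c <= budget and c < best.get(nxt, (c + 1,))[0]:
                        best[nxt] = (c, state, "I")
                        new_frontier.append(nxt)
                # DNA bulge: extra target base
                if j < W:
                    nxt = (i, j + 1, nb + 1)
                    c = cost + bc
                    if c <= budget and c < best.get(nxt, (c + 1,))[0]:
                        best[nxt] = (c, state, "D")
                        new_frontier.append(nxt)
        if not new_frontier:
            break
        frontier = new_frontier

    # end states: all guide bases consumed
    ends = [(s, v[0]) for s, v in best.items() if s[0] == G]
    if not ends:
        return None
    # minimal cost, then fewer bulges, then longest target (leftmost start on +)
    state, cost = min(ends, key=lambda e: (e[1], e[0][2], -e[0][1]))
    _, target_len, nb = state

    # traceback
    moves = []
    s: Optional[Tuple[int, int, int]] = state
    while s is not None and best[s][1] is not None:
        _, parent, move = best[s]
        moves.append(move)
        s = parent
    moves.reverse()

    ag, at = [], []
    gi = tj = 0
    mismatches = dna_b = rna_b = 0
    for move in moves:
        if move in "MX":
            ag.append(guide_rev[gi])
            at.append(window_rev[tj])
            mismatches += move == "X"
            gi += 1
            tj += 1
        elif move == "I":
            ag.append(guide_rev[gi])
            at.append("-")
            rna_b += 1
            gi += 1
        else:
            ag.append("-")
            at.append(window_rev[tj])
            dna_b += 1
            tj += 1
    # inputs were PAM-proximal-first; restore 5'->3'
    aligned_guide = "".join(ag)[::-1]
    aligned_target = "".join(at)[::-1]
    return cost, mismatches, dna_b, rna_b, target_len, aligned_guide, aligned_target


def dedup_sites(sites: Sequence[CandidateSite]) -> List[CandidateSite]:
    """One representative per locus.

    Overlapping intervals on the same chromosome and strand are clustered
    transitively; the representative is the minimal-penalty site, ties
    broken by fewer bulged bases, then leftmost start.
    """
    out: List[CandidateSite] = []
    by_group: Dict[Tuple[str, str], List[CandidateSite]] = {}
    for s in sites:
        by_group.setdefault((s.chrom, s.strand), []).append(s)
    for group in by_group.values():
        group.sort(key=lambda s: (s.start, s.end))
        cluster: List[CandidateSite] = []
        cluster_end = -1
        for s in group:
            if cluster and s.start >= cluster_end:
                out.append(min(cluster, key=lambda c: (c.penalty, c.bulge_bases, c.start)))
                cluster = []
            cluster.append(s)
            cluster_end = max(cluster_end, s.end)
        if cluster:
            out.append(min(cluster, key=lambda c: (c.penalty, c.bulge_bases, c.start)))
    out.sort(key=lambda s: (s.chrom, s.start, s.end, s.strand))
    return out


def _scan_strand(
    chrom: str,
    seq: str,
    strand: str,
    guide: GuideSpec,
    params: ScanParams,
) -> List[CandidateSite]:
    """All raw (pre-dedup) sites on one strand of one chromosome."""
    spacer = guide.protospacer
    G = len(spacer)
    maxb = params.effective_max_bulge
    s = seq if strand == "+" else revcomp(seq)
    L = len(s)
    guide_rev = spacer[::-1]
    pam_len = len(params.pam_pattern)
    sites: List[CandidateSite] = []
    for p in _pam_anchor_positions(s, params.pam_pattern):
        if p < G - maxb:
            continue
        win_start = max(0, p - G - maxb)
        window_rev = s[win_start:p][::-1]
        hit = _align_anchored(guide_rev, window_rev, params)
        if hit is None:
            continue
        penalty, mm, db, rb, tlen, ag, at = hit
        start, end = p - tlen, p
        pam_obs = s[p:p + pam_len]
        if strand == "-":
            start, end = L - end, L - start
        sites.append(CandidateSite(
            chrom=chrom, start=int(start), end=int(end), strand=strand,
            penalty=penalty, mismatches=mm, dna_bulge_bases=db, rna_bulge_bases=rb,
            aligned_guide=ag, aligned_target=at, pam_observed=pam_obs,
            guide_name=guide.name,
        ))
    return sites


def scan_offtargets(
    genome: Union[str, Path, Dict[str, str]],
    guide: GuideSpec,
    params: Optional[ScanParams] = None,
) -> ScanResult:
    """Enumerate candidate sites for ``guide`` across ``genome``.

    Parameters
    ----------
    genome:
        FASTA path (plain or gzipped) or a ``{name: sequence}`` mapping.
    guide:
        The sgRNA specification. Its ``on_target`` locus, when set,
        defines the region whose sites are reported separately in
        :attr:`ScanResult.on_target_sites`.
    params:
        Penalty model; defaults to ``ScanParams()`` except that a PAM
        pattern given on the guide takes precedence.

    Returns
    -------
    ScanResult
        Off-target sites sorted by (chrom, start), one representative per
        locus, plus the excluded on-target-region sites.
    """
    params = params or ScanParams(pam_pattern=guide.pam_pattern)
    seqs = _as_genome(genome)
    raw: List[CandidateSite] = []
    for chrom, seq in seqs.items():
        if not seq:
            continue
        for strand in "+-":
            raw.extend(_scan_strand(chrom, seq, strand, guide, params))
    sites = dedup_sites(raw)

    on_target: List[CandidateSite] = []
    if guide.on_target is not None:
        ot_chrom, ot_pos1, _ = guide.on_target
        ot = ot_pos1 - 1
        r = params.exclude_on_target_radius
        kept = []
        for s in sites:
            dist = 0 if s.start <= ot < s.end else min(abs(s.start - ot), abs(s.end - 1 - ot))
            (on_target if s.chrom == ot_chrom and dist <= r else kept).append(s)
        sites = kept
    return ScanResult(sites=sites, on_target_sites=on_target, params=params, guide=guide)


# ---------------------------------------------------------------------------
# BED / TSV artifacts

def write_sites_bed(sites: Iterable[CandidateSite], path: Union[str, Path]) -> None:
    """Write sites as BED6 (0-based half-open; score = penalty).

    The name field encodes the penalty decomposition and observed PAM as
    ``guide|mm<j>|db<k>|rb<l>|<PAM>`` so the file round-trips through
    :func:`read_sites_bed`.
    """
    sites = sorted(sites, key=lambda s: (s.chrom, s.start, s.end, s.strand))
    with open(path, "w") as fh:
        fh.write("# editqc candidate sites: chrom start end name(guide|mm|db|rb|pam) penalty strand\n")
        for s in sites:
            name = f"{s.guide_name}|mm{s.mismatches}|db{s.dna_bulge_bases}|rb{s.rna_bulge_bases}|{s.pam_observed}"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.penalty}\t{s.strand}\n")


def read_sites_bed(path: Union[str, Path]) -> List[CandidateSite]:
    """Read a BED6 written by :func:`write_sites_bed`.

    Alignment strings are not stored in BED and come back empty; interval,
    strand, penalty and its decomposition are restored exactly.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            parts = name.split("|")
            mm = db = rb = 0
            pam = ""
            gname = parts[0] if parts else "guide"
            for part in parts[1:]:
                if part.startswith("mm"):
                    mm = int(part[2:])
                elif part.startswith("db"):
                    db = int(part[2:])
                elif part.startswith("rb"):
                    rb = int(part[2:])
                else:
                    pam = part
            sites.append(CandidateSite(
                chrom=chrom, start=int(start), end=int(end), strand=strand,
                penalty=int(score), mismatches=mm, dna_bulge_bases=db,
                rna_bulge_bases=rb, pam_observed=pam, guide_name=gname,
            ))
    return sites


def write_sites_tsv(sites: Iterable[CandidateSite], path: Union[str, Path]) -> None:
    """Full site table including gapped alignment strings."""
    cols = ["chrom", "start", "end", "strand", "penalty", "mismatches",
            "dna_bulge_bases", "rna_bulge_bases", "pam_observed",
            "aligned_guide", "aligned_target", "guide_name"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.start, s.end, s.strand)):
            fh.write("\t".join(str(getattr(s, c)) for c in cols) + "\n")
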