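"""Read-level quantification of editing outcomes from amplicon sequencing.

Replaces service-style readouts (Sanger trace deconvolution, hosted
deep-sequencing portals) with an explicit classifier: each read is labelled
HDR when it carries the donor-specific junction k-mer, otherwise globally
aligned to the wild-type amplicon and labelled WT or INDEL according to
whether an alignment gap touches the quantification window around the
predicted cut site.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

from editqc.guides import revcomp


class AmpliconError(ValueError):
    """Invalid amplicon specification or unusable read set."""


@dataclass(frozen=True)
class AmpliconSpec:
    """Wild-type amplicon, cut site and donor signature for one locus.

    ``cut_site`` is the 0-based offset of the blunt double-strand cut in
    the reference (for SpCas9, between protospacer positions 17 and 18,
    3 bp 5' of the PAM). An alignment gap is attributed to editing when it
    touches ``cut_site +/- quant_window``. ``hdr_signature`` is a
    donor-specific subsequence (canonically the 30-mer spanning the
    knock-in junction) that must be absent from the reference.
    """

    reference: str
    cut_site: int
    hdr_signature: str
    quant_window: int = 2
    min_read_len: int = 50
    name: str = "amplicon"

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        object.__setattr__(self, "hdr_signature", self.hdr_signature.upper())
        if not 0 < self.cut_site < len(self.reference):
            raise AmpliconError("cut_site must fall strictly inside the reference")
        if self.hdr_signature and self.hdr_signature in self.reference:
            raise AmpliconError("hdr_signature occurs in the wild-type reference")
        if self.quant_window < 0 or self.min_read_len < 0:
            raise AmpliconError("quant_window and min_read_len must be >= 0")


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring and identity gates for read classification."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    wt_min_identity: float = 0.9
    fail_identity: float = 0.6
    hdr_max_mismatches: int = 1
    trim_quality: int = 20


@dataclass(frozen=True)
class ReadClass:
    """Per-read outcome label.

    ``indel_len`` is the signed net length change of gaps inside the
    quantification window (negative for deletions); zero unless the label
    is INDEL. FAIL reads are excluded from all denominators.
    """

    read_id: str
    label: str  # WT | INDEL | HDR | AMBIGUOUS | FAIL
    indel_len: int = 0
    alignment_score: float = 0.0
    reason: str = ""


@dataclass
class QuantResult:
    """Aggregate editing-outcome counts and percentages for one amplicon."""

    n_total: int
    n_pass: int
    n_wt: int
    n_indel: int
    n_hdr: int
    n_ambiguous: int
    indel_pct: float
    hdr_pct: float
    ci95_indel: Tuple[float, float]
    ci95_hdr: Tuple[float, float]

    def to_dict(self) -> Dict:
        return {
            "n_total": self.n_total, "n_pass": self.n_pass,
            "n_wt": self.n_wt, "n_indel": self.n_indel,
            "n_hdr": self.n_hdr, "n_ambiguous": self.n_ambiguous,
            "indel_pct": self.indel_pct, "hdr_pct": self.hdr_pct,
            "ci95_indel": list(self.ci95_indel), "ci95_hdr": list(self.ci95_hdr),
        }


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact binomial confidence interval for a proportion, as percentages."""
    from scipy.stats import beta

    if n == 0:
        return (0.0, 100.0)
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (100.0 * lo, 100.0 * hi)


# ---------------------------------------------------------------------------
# read handling

def _quality_trim(seq: str, qual: Optional[Sequence[int]], q_floor: int) -> str:
    """Trim low-quality bases from both ends (fixed-threshold end trim)."""
    if qual is None:
        return seq
    lo, hi = 0, len(seq)
    while lo < hi and qual[lo] < q_floor:
        lo += 1
    while hi > lo and qual[hi - 1] < q_floor:
        hi -= 1
    return seq[lo:hi]


def _kmer_hits(read: str, kmer: str, max_mm: int) -> bool:
    """Does ``kmer`` occur in ``read`` with at most ``max_mm`` mismatches?"""
    k = len(kmer)
    if k == 0 or len(read) < k:
        return False
    if max_mm == 0:
        return kmer in read
    for i in range(len(read) - k + 1):
        mm = 0
        window = read[i:i + k]
        for a, b in zip(window, kmer):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def _make_aligner(p: AlignParams):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    # reads may be sub-fragments of the amplicon (or carry adapter
    # overhangs): end gaps on either sequence are free
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _gaps_and_identity(alignment) -> Tuple[List[Tuple[int, int, int]], float]:
    """Gap list [(ref_start, ref_end, signed_len)] and identity of an alignment.

    A deletion in the read spans reference bases [ref_start, ref_end) with
    signed_len = -(ref_end - ref_start); an insertion sits at a single
    reference coordinate with signed_len > 0. End overhangs of the
    reference (read shorter than amplicon) are not counted as gaps.
    Identity = matches / aligned (non-gap) columns.
    """
    t_blocks, q_blocks = alignment.aligned
    target, query = alignment.target, alignment.query
    gaps: List[Tuple[int, int, int]] = []
    matches = aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        matches += sum(1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b)
    for i in range(1, len(t_blocks)):
        t_gap = t_blocks[i][0] - t_blocks[i - 1][1]
        q_gap = q_blocks[i][0] - q_blocks[i - 1][1]
        if t_gap > 0:  # read skips reference bases: deletion
            gaps.append((t_blocks[i - 1][1], t_blocks[i][0], -t_gap))
        if q_gap > 0:  # extra read bases: insertion at this reference point
            gaps.append((t_blocks[i - 1][1], t_blocks[i - 1][1], q_gap))
    identity = matches / aligned_cols if aligned_cols else 0.0
    return gaps, identity, matches


def classify_read(
    read: str,
    spec: AmpliconSpec,
    align_params: Optional[AlignParams] = None,
    qual: Optional[Sequence[int]] = None,
    read_id: str = "read",
) -> ReadClass:
    """Label one read as WT, INDEL, HDR, AMBIGUOUS or FAIL.

    Order of decision: quality-trim; FAIL when shorter than
    ``spec.min_read_len``; HDR when the donor signature (either
    orientation) occurs with at most ``hdr_max_mismatches`` mismatches;
    otherwise align globally to the wild-type reference — FAIL below the
    identity floor, INDEL when a gap touches the quantification window,
    WT when gap-free around the cut and above ``wt_min_identity``,
    AMBIGUOUS otherwise.
    """
    p = align_params or AlignParams()
    seq = _quality_trim(read.upper(), qual, p.trim_quality)
    if len(seq) < spec.min_read_len:
        return ReadClass(read_id, "FAIL", reason="short_read")
    if spec.hdr_signature and (
        _kmer_hits(seq, spec.hdr_signature, p.hdr_max_mismatches)
        or _kmer_hits(seq, revcomp(spec.hdr_signature), p.hdr_max_mismatches)
    ):
        return ReadClass(read_id, "HDR")
    if seq == spec.reference:
        return ReadClass(read_id, "WT", alignment_score=p.match * len(seq))

    aligner = _make_aligner(p)
    alignment = aligner.align(spec.reference, seq)[0]
    gaps, identity, matches = _gaps_and_identity(alignment)
    # two gates: local identity among aligned columns, and the fraction of
    # the read actually matched (catches unrelated sequence that aligns a
    # high-identity sliver under free end gaps)
    if identity < p.fail_identity or matches < p.fail_identity * len(seq):
        return ReadClass(read_id, "FAIL", alignment_score=alignment.score,
                         reason="low_identity")
    lo, hi = spec.cut_site - spec.quant_window, spec.cut_site + spec.quant_window
    net = 0
    for gs, ge, signed_len in gaps:
        touches = (gs <= hi and ge >= lo) if gs < ge else (lo <= gs <= hi)
        if touches:
            net += signed_len
    if net != 0 or any((gs <= hi and ge >= lo) if gs < ge else (lo <= gs <= hi)
                       for gs, ge, _ in gaps):
        return ReadClass(read_id, "INDEL", indel_len=net,
                         alignment_score=alignment.score)
    if identity >= p.wt_min_identity:
        return ReadClass(read_id, "WT", alignment_score=alignment.score)
    return ReadClass(read_id, "AMBIGUOUS", alignment_score=alignment.score)


# ---------------------------------------------------------------------------
# aggregation

def read_fastq(path: Union[str, Path]) -> Iterator[Tuple[str, str, List[int]]]:
    """Yield (id, sequence, quality) from a FASTQ file, gzipped or plain."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def quantify_amplicon(
    reads: Union[str, Path, Iterable[Tuple[str, str, Optional[Sequence[int]]]]],
    spec: AmpliconSpec,
    align_params: Optional[AlignParams] = None,
    min_pass_reads: int = 100,
    per_read: Optional[List[ReadClass]] = None,
) -> QuantResult:
    """Aggregate :func:`classify_read` over a read set.

    ``reads`` is a FASTQ path or an iterable of (id, sequence, quality)
    triples. Counts are order-independent. Raises when fewer than
    ``min_pass_reads`` reads pass (confidence intervals would be
    meaningless); set the floor to 0 to disable.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    counts = {"WT": 0, "INDEL": 0, "HDR": 0, "AMBIGUOUS": 0, "FAIL": 0}
    n_total = 0
    for read_id, seq, qual in reads:
        rc = classify_read(seq, spec, align_params, qual=qual, read_id=read_id)
        counts[rc.label] += 1
        n_total += 1
        if per_read is not None:
            per_read.append(rc)
    n_pass = n_total - counts["FAIL"]
    if n_pass == 0:
        raise AmpliconError("no reads passed filtering; cannot quantify")
    if n_pass < min_pass_reads:
        raise AmpliconError(
            f"only {n_pass} passing reads (< {min_pass_reads}); "
            "lower min_pass_reads to force quantification"
        )
    return QuantResult(
        n_total=n_total, n_pass=n_pass,
        n_wt=counts["WT"], n_indel=counts["INDEL"], n_hdr=counts["HDR"],
        n_ambiguous=counts["AMBIGUOUS"],
        indel_pct=100.0 * counts["INDEL"] / n_pass,
        hdr_pct=100.0 * counts["HDR"] / n_pass,
        ci95_indel=clopper_pearson(counts["INDEL"], n_pass),
        ci95_hdr=clopper_pearson(counts["HDR"], n_pass),
    )


def write_quant_json(result: QuantResult, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
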