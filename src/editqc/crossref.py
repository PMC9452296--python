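"""Edited-vs-control indel cross-referencing against candidate off-target sites.

The workflow mirrors the WGS arm of a knock-in product QC: indel calls from
an edited sample and its unedited control are quality-filtered, indels seen
only in the edited sample are extracted, and those edited-exclusive indels
are intersected with +/-15 bp and +/-200 bp windows around candidate
off-target sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from editqc.offtarget import CandidateSite


class CrossrefInputError(ValueError):
    """Malformed indel input (e.g. a multi-allelic or non-indel record)."""


@dataclass(frozen=True)
class IndelCall:
    """A normalized, bi-allelic indel call.

    ``pos`` is the 1-based VCF position of the anchor base; ``ref`` and
    ``alt`` are the VCF allele strings, exactly one of which is longer
    than the other. ``support`` is the number of reads supporting the
    alternate allele, ``mq`` the RMS mapping quality, ``qual`` the
    phred-scaled site quality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    mq: float
    support: int
    sample: str = "edited"

    def __post_init__(self) -> None:
        if (len(self.ref) > len(self.alt)) == (len(self.ref) < len(self.alt)):
            raise CrossrefInputError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt} is not a pure indel"
            )
        if min(self.qual, self.mq, self.support) < 0:
            raise CrossrefInputError("qual, mq and support must be >= 0")

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    def affected_interval(self) -> Tuple[int, int]:
        """0-based half-open reference interval affected by the indel.

        Deletions affect the deleted bases (anchor excluded); insertions
        affect the zero-length insertion point just after the anchor.
        """
        p0 = self.pos - 1
        if self.is_deletion:
            return p0 + 1, p0 + 1 + self.indel_len
        return p0 + 1, p0 + 1

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for indel call filtering.

    A call is kept only if its alt-supporting read count is at least
    ``min_support`` (default 4), mapping quality at least ``min_mq``
    (default 30), site QUAL at least ``min_qual`` (default 20), indel
    length strictly below ``max_indel_len`` (default 50), no other variant
    lies within ``near_variant_dist`` bases, and it does not touch any
    ``exclusion_bed`` interval (pseudoautosomal regions and the like).
    """

    min_support: int = 4
    min_mq: float = 30.0
    min_qual: float = 20.0
    max_indel_len: int = 50
    near_variant_dist: int = 10
    exclusion_bed: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if min(self.min_support, self.min_mq, self.min_qual,
               self.max_indel_len, self.near_variant_dist) < 0:
            raise ValueError("filter thresholds must be >= 0")
        object.__setattr__(self, "exclusion_bed", tuple(tuple(iv) for iv in self.exclusion_bed))


@dataclass(frozen=True)
class ProximityHit:
    """One (site, indel) pair within one distance window."""

    site: CandidateSite
    indel: IndelCall
    distance: int
    window_class: str  # "within_15" / "within_200" style labels

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


# ---------------------------------------------------------------------------
# VCF input / text output

def read_indels_vcf(
    path: Union[str, Path],
    sample: str,
    mq_key: str = "MQ",
    support_key: str = "AD",
) -> List[IndelCall]:
    """Read pure-indel records from a VCF into :class:`IndelCall` objects.

    ``mq_key`` names an INFO field; ``support_key`` names a FORMAT field
    holding per-allele depths (alt depth is taken as support) or, as a
    fallback, an INFO field with a scalar support count. Multi-allelic
    records are refused: split them upstream (``bcftools norm -m-``).
    SNV records are ignored.
    """
    import pysam

    calls: List[IndelCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                raise CrossrefInputError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "split with 'bcftools norm -m-' before filtering"
                )
            alt = rec.alts[0]
            if alt is None or len(alt) == len(rec.ref):
                continue  # SNV / MNV: not an indel
            mq = float(rec.info.get(mq_key, 0.0))
            support = 0
            if rec.samples and support_key in rec.samples[0]:
                val = rec.samples[0][support_key]
                support = int(val[-1]) if isinstance(val, tuple) else int(val)
            elif support_key in rec.info:
                val = rec.info[support_key]
                support = int(val[-1]) if isinstance(val, tuple) else int(val)
            calls.append(IndelCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                qual=float(rec.qual if rec.qual is not None else 0.0),
                mq=mq, support=support, sample=sample,
            ))
    return calls


def read_bed_intervals(path: Union[str, Path]) -> List[Tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_indels_tsv(calls: Iterable[IndelCall], path: Union[str, Path],
                     provenance: Optional[Dict[Tuple, str]] = None) -> None:
    """Write calls as TSV; optional per-call provenance (e.g. removal reason)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tindel_len\tqual\tmq\tsupport\tsample\tnote\n")
        for c in calls:
            note = (provenance or {}).get(c.key(), "")
            fh.write(f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.indel_len}\t"
                     f"{c.qual:g}\t{c.mq:g}\t{c.support}\t{c.sample}\t{note}\n")


# ---------------------------------------------------------------------------
# filtering

@dataclass
class FilterResult:
    kept: List[IndelCall]
    removed: List[Tuple[IndelCall, str]]


def filter_indels(
    calls: Sequence[IndelCall],
    params: Optional[FilterParams] = None,
    all_variants: Optional[Sequence[Tuple[str, int]]] = None,
) -> FilterResult:
    """Apply the quality / length / proximity / exclusion-region filter.

    ``all_variants`` is an optional list of (chrom, 1-based pos) for every
    variant call (SNVs included) used by the near-variant rule; when
    omitted, the rule is evaluated against the indel calls themselves.
    Each removed call is recorded with the first failing rule, checked in
    the order support, mq, qual, length, near-variant, exclusion region.
    """
    params = params or FilterParams()
    variant_pos: Dict[str, List[int]] = {}
    source = all_variants if all_variants is not None else [(c.chrom, c.pos) for c in calls]
    for chrom, pos in source:
        variant_pos.setdefault(chrom, []).append(pos)
    for positions in variant_pos.values():
        positions.sort()

    import bisect

    def near_other_variant(c: IndelCall) -> bool:
        positions = variant_pos.get(c.chrom, [])
        lo = bisect.bisect_left(positions, c.pos - params.near_variant_dist)
        hi = bisect.bisect_right(positions, c.pos + params.near_variant_dist)
        n_near = hi - lo
        if all_variants is None and lo < hi:
            n_near -= 1  # the call's own entry
        return n_near > 0

    def in_exclusion(c: IndelCall) -> bool:
        a, b = c.affected_interval()
        a0, b0 = c.pos - 1, max(b, c.pos)  # include the anchor base
        for chrom, s, e in params.exclusion_bed:
            if chrom == c.chrom and a0 < e and b0 > s:
                return True
        return False

    kept, removed = [], []
    for c in calls:
        if c.support < params.min_support:
            removed.append((c, "support"))
        elif c.mq < params.min_mq:
            removed.append((c, "mq"))
        elif c.qual < params.min_qual:
            removed.append((c, "qual"))
        elif c.indel_len >= params.max_indel_len:
            removed.append((c, "indel_len"))
        elif near_other_variant(c):
            removed.append((c, "near_variant"))
        elif in_exclusion(c):
            removed.append((c, "exclusion_region"))
        else:
            kept.append(c)
    return FilterResult(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# exclusivity

def exclusive_indels(
    edited: Sequence[IndelCall],
    control: Sequence[IndelCall],
    match_mode: str = "exact",
    window: int = 3,
) -> List[IndelCall]:
    """Edited calls with no matching control call.

    ``match_mode='exact'`` matches on (chrom, pos, ref, alt);
    ``match_mode='windowed'`` matches any control indel on the same
    chromosome with the same indel length within ``window`` bp — tolerant
    of small left-alignment differences between call sets.
    """
    for name, lst in (("edited", edited), ("control", control)):
        labels = {c.sample for c in lst}
        if len(labels) > 1:
            raise CrossrefInputError(f"mixed sample labels in {name} list: {sorted(labels)}")
    if match_mode == "exact":
        control_keys = {c.key() for c in control}
        return [c for c in edited if c.key() not in control_keys]
    if match_mode == "windowed":
        by_chrom: Dict[str, List[IndelCall]] = {}
        for c in control:
            by_chrom.setdefault(c.chrom, []).append(c)

        def matched(e: IndelCall) -> bool:
            return any(abs(c.pos - e.pos) <= window and c.indel_len == e.indel_len
                       for c in by_chrom.get(e.chrom, []))

        return [e for e in edited if not matched(e)]
    raise ValueError(f"unknown match_mode {match_mode!r}")


# ---------------------------------------------------------------------------
# window intersection

def site_indel_distance(site: CandidateSite, indel: IndelCall) -> Optional[int]:
    """Reference distance between a site interval and an indel.

    0 when the indel's affected interval overlaps or abuts the site,
    otherwise the number of bases separating the nearest boundaries.
    None when on different chromosomes.
    """
    if site.chrom != indel.chrom:
        return None
    a, b = indel.affected_interval()
    return max(0, a - site.end, site.start - b)


@dataclass
class IntersectionSummary:
    """Distinct-site counts per window radius, e.g. {15: 0, 200: 8}."""

    sites_within: Dict[int, int]
    hits: List[ProximityHit]


def intersect_windows(
    sites: Sequence[CandidateSite],
    indels: Sequence[IndelCall],
    windows: Sequence[int] = (15, 200),
) -> IntersectionSummary:
    """Intersect indels with distance windows around candidate sites.

    Emits one :class:`ProximityHit` per (site, indel) pair per satisfied
    window radius, and counts the distinct sites having at least one hit
    in each window.
    """
    windows = sorted(windows)
    if windows and windows[0] < 0:
        raise ValueError("window radii must be >= 0")
    hits: List[ProximityHit] = []
    sites_hit: Dict[int, set] = {w: set() for w in windows}
    by_chrom: Dict[str, List[IndelCall]] = {}
    for c in indels:
        by_chrom.setdefault(c.chrom, []).append(c)
    for idx, site in enumerate(sites):
        for indel in by_chrom.get(site.chrom, []):
            d = site_indel_distance(site, indel)
            if d is None:
                continue
            for w in windows:
                if d <= w:
                    hits.append(ProximityHit(site=site, indel=indel,
                                             distance=d, window_class=f"within_{w}"))
                    sites_hit[w].add(idx)
    return IntersectionSummary(
        sites_within={w: len(sites_hit[w]) for w in windows},
        hits=hits,
    )


def write_hits_tsv(hits: Iterable[ProximityHit], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsite_start\tsite_end\tsite_strand\tsite_penalty\t"
                 "indel_pos\tindel_ref\tindel_alt\tdistance\twindow_class\n")
        for h in hits:
            s, c = h.site, h.indel
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\t{s.penalty}\t"
                     f"{c.pos}\t{c.ref}\t{c.alt}\t{h.distance}\t{h.window_class}\n")
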