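"""Seed-deterministic synthetic fixtures with machine-readable ground truth.

Every generator emits the standard format its consuming stage reads
(FASTA/BED/VCF/FASTQ) plus an explicit truth record, so each pipeline
stage can be tested end to end without any external download:

* :func:`make_genome` — a random genome with planted protospacer
  variants realizing exact mismatch/bulge/PAM descriptions.
* :func:`make_vcf_pair` — paired edited/control indel call sets in which
  edited-exclusive indels sit at requested distances from planted sites.
* :func:`make_reads` — amplicon reads drawn at known indel/HDR fractions
  with a uniform substitution error rate.
* Band intensities for genotype deconvolution come from
  :func:`editqc.genotype.simulate_bands`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from editqc.amplicon import AmpliconSpec
from editqc.guides import GuideSpec, IUPAC_CODES, revcomp
from editqc.offtarget import ScanParams

BASES = "ACGT"


class SimulationError(ValueError):
    """Infeasible plant or simulation specification."""


# ---------------------------------------------------------------------------
# genomes with planted sites

@dataclass(frozen=True)
class PlantedSite:
    """Description of one planted near-match protospacer.

    ``offset`` is the 0-based genome position of the planted element
    (protospacer + PAM on the + strand; the reverse complement is written
    for ``strand='-'``). ``bulges`` lists ``(kind, guide_pos, length)``
    with kind ``'dna'`` (extra target bases) or ``'rna'`` (guide bases
    missing from the target). ``pam_ok=False`` plants a PAM violating the
    pattern, so the site must not be reported.
    """

    offset: int
    strand: str = "+"
    mismatches: int = 0
    bulges: Tuple[Tuple[str, int, int], ...] = ()
    pam_ok: bool = True


@dataclass(frozen=True)
class PlantSpec:
    guide: GuideSpec
    sites: Tuple[PlantedSite, ...]
    genome_len: int = 5000
    gc_content: float = 0.5
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))


@dataclass(frozen=True)
class PlantedTruth:
    """Realized coordinates and intended penalty of one planted site."""

    chrom: str
    start: int  # protospacer interval, 0-based half-open
    end: int
    strand: str
    penalty: int
    mismatches: int
    dna_bulge_bases: int
    rna_bulge_bases: int
    pam_ok: bool


def _sample_pam(pattern: str, rng: np.random.Generator, ok: bool) -> str:
    """A concrete PAM matching (ok) or violating (not ok) the IUPAC pattern."""
    if ok:
        return "".join(rng.choice(list(IUPAC_CODES[sym])) for sym in pattern)
    # Violate the most restrictive position and, where possible, keep its
    # required bases out of every position: a bad PAM containing (say) a G
    # one base off a shifted anchor could otherwise re-create a valid NRG.
    sym_pos = min(range(len(pattern)), key=lambda i: len(IUPAC_CODES[pattern[i]]))
    required = IUPAC_CODES[pattern[sym_pos]]
    if len(required) == 4:
        raise SimulationError(f"pattern {pattern} matches everything; cannot plant pam_ok=False")
    avoid = [b for b in BASES if b not in required]
    return "".join(str(rng.choice(avoid)) for _ in pattern)


def _mutate_target(guide: str, site: PlantedSite, rng: np.random.Generator) -> str:
    """Build the planted target sequence realizing the site description."""
    target = list(guide)
    bulge_guide_pos = set()
    # apply bulges right-to-left so earlier positions stay valid
    for kind, gpos, length in sorted(site.bulges, key=lambda b: -b[1]):
        if not 0 < gpos < len(guide):
            raise SimulationError(f"bulge position {gpos} not interior to the guide")
        if kind == "rna":
            if gpos + length > len(guide):
                raise SimulationError("rna bulge runs past the guide end")
            del target[gpos:gpos + length]
            bulge_guide_pos.update(range(max(0, gpos - 1), min(len(guide), gpos + length + 1)))
        elif kind == "dna":
            flank = {guide[gpos - 1], guide[gpos]}
            ins = [str(rng.choice([b for b in BASES if b not in flank]))
                   for _ in range(length)]
            target[gpos:gpos] = ins
            bulge_guide_pos.update({gpos - 1, gpos, gpos + 1})
        else:
            raise SimulationError(f"unknown bulge kind {kind!r}")
    # substitutions at positions away from bulges (so the intended
    # alignment stays the cheapest one)
    candidates = [i for i in range(len(guide)) if i not in bulge_guide_pos]
    if site.mismatches > len(candidates):
        raise SimulationError("more mismatches requested than available positions")
    mm_pos = rng.choice(len(candidates), size=site.mismatches, replace=False)
    chosen = sorted(candidates[i] for i in mm_pos)
    # map guide positions onto the mutated target under the intended alignment
    tpos_of_gpos = dict(_alignment_map(guide, site))
    for gp in chosen:
        tp = tpos_of_gpos.get(gp)
        if tp is None:
            continue
        current = target[tp]
        target[tp] = str(rng.choice([b for b in BASES if b != current]))
    return "".join(target)


def _alignment_map(guide: str, site: PlantedSite) -> List[Tuple[int, int]]:
    """(guide_pos, target_pos) pairs under the intended alignment."""
    pairs = []
    skip_guide = {}
    ins_before = {}
    for kind, gpos, length in site.bulges:
        if kind == "rna":
            for k in range(length):
                skip_guide[gpos + k] = True
        else:
            ins_before[gpos] = ins_before.get(gpos, 0) + length
    tp = 0
    for gp in range(len(guide)):
        tp += ins_before.get(gp, 0)
        if skip_guide.get(gp):
            continue
        pairs.append((gp, tp))
        tp += 1
    return pairs


def make_genome(
    spec: PlantSpec,
    params: Optional[ScanParams] = None,
) -> Tuple[Dict[str, str], List[PlantedTruth]]:
    """Random genome with planted near-match protospacers.

    Returns the genome as ``{chrom: sequence}`` and the list of realized
    planted sites with their intended penalties (mismatches plus
    ``bulge_cost_per_base`` per bulged base). Planted elements must not
    overlap; the random background is drawn base by base with the
    requested GC content.
    """
    params = params or ScanParams(pam_pattern=spec.guide.pam_pattern)
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_content / 2.0
    probs = [(1 - spec.gc_content) / 2, p_gc, p_gc, (1 - spec.gc_content) / 2]
    genome = list(rng.choice(list(BASES), size=spec.genome_len, p=probs))

    pam_len = len(params.pam_pattern)
    truth: List[PlantedTruth] = []
    occupied: List[Tuple[int, int]] = []
    for site in spec.sites:
        target = _mutate_target(spec.guide.protospacer, site, rng)
        pam = _sample_pam(params.pam_pattern, rng, site.pam_ok)
        element = target + pam
        if site.strand == "-":
            element = revcomp(element)
        start, end = site.offset, site.offset + len(element)
        if start < 0 or end > spec.genome_len:
            raise SimulationError(f"planted site at {start} runs off the genome")
        for s, e in occupied:
            if start < e and end > s:
                raise SimulationError("planted sites overlap")
        occupied.append((start, end))
        genome[start:end] = list(element)
        if site.strand == "+":
            proto_iv = (start, start + len(target))
        else:
            proto_iv = (start + pam_len, start + pam_len + len(target))
        n_dna = sum(l for k, _, l in site.bulges if k == "dna")
        n_rna = sum(l for k, _, l in site.bulges if k == "rna")
        truth.append(PlantedTruth(
            chrom=spec.chrom, start=proto_iv[0], end=proto_iv[1],
            strand=site.strand,
            penalty=site.mismatches + params.bulge_cost_per_base * (n_dna + n_rna),
            mismatches=site.mismatches,
            dna_bulge_bases=n_dna, rna_bulge_bases=n_rna,
            pam_ok=site.pam_ok,
        ))
    return {spec.chrom: "".join(genome)}, truth


def write_genome_fasta(genome: Dict[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_bed(truth: Sequence[PlantedTruth], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("# planted sites: chrom start end mm|db|rb|pam_ok penalty strand\n")
        for t in truth:
            name = f"mm{t.mismatches}|db{t.dna_bulge_bases}|rb{t.rna_bulge_bases}|pam{int(t.pam_ok)}"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t{t.penalty}\t{t.strand}\n")


# ---------------------------------------------------------------------------
# paired VCFs

@dataclass(frozen=True)
class PlantedIndel:
    """One edited-exclusive indel: placed ``distance`` bp beyond the right
    boundary of planted site ``site_index`` (0 = abutting/overlapping),
    ``indel_len`` signed (negative deletion, positive insertion)."""

    site_index: int
    distance: int
    indel_len: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise SimulationError("distance must be >= 0")
        if self.indel_len == 0:
            raise SimulationError("indel_len must be nonzero")


@dataclass
class VcfPairTruth:
    """Per-planted-indel truth plus the expected window summary."""

    records: List[Dict]
    sites_within: Dict[int, int]


def _draw_quality(rng: np.random.Generator, passing: Optional[bool] = None) -> Tuple[int, float, float]:
    """(support, MQ, QUAL) from the synthetic quality model.

    Independent draws — support ~ Poisson(30), MQ ~ 60 − Exp(8) clipped
    to [0, 60], QUAL ~ Gamma(4, 15) — chosen to straddle the default
    filter thresholds. ``passing`` forces the draw to the passing or
    failing side of the default thresholds.
    """
    for _ in range(1000):
        support = int(rng.poisson(30))
        mq = float(np.clip(60.0 - rng.exponential(8.0), 0.0, 60.0))
        qual = float(rng.gamma(4.0, 15.0))
        ok = support >= 4 and mq >= 30.0 and qual >= 20.0
        if passing is None or ok == passing:
            return support, mq, qual
    raise SimulationError("could not draw requested quality profile")


def make_vcf_pair(
    genome: Dict[str, str],
    truth_sites: Sequence[PlantedTruth],
    planted_exclusive: Sequence[PlantedIndel],
    background_rate: float = 2e-4,
    seed: int = 0,
    windows: Sequence[int] = (15, 200),
    exclusive_passing: Optional[bool] = True,
) -> Tuple[List[Dict], List[Dict], VcfPairTruth]:
    """Edited/control call sets with known edited-exclusive indels.

    Background indels are shared between the two samples (identical
    records and quality values, so filtering treats them symmetrically)
    and are kept at least 25 bp from every other variant and at least
    ``max(windows)+50`` bp from every planted site, so the expected
    window summary is exactly the one induced by the planted exclusives.
    Planted exclusives appear only in the edited sample, with qualities
    forced to the passing side of the default thresholds unless
    ``exclusive_passing`` says otherwise.

    Returns (edited_records, control_records, truth); records are dicts
    consumable by :func:`write_vcf`.
    """
    rng = np.random.default_rng(seed)
    chrom = truth_sites[0].chrom if truth_sites else next(iter(genome))
    seq = genome[chrom]
    glen = len(seq)
    maxw = max(windows) if windows else 200

    used_pos: List[int] = []

    def far_from_everything(p: int, min_gap: int = 25) -> bool:
        if any(abs(p - q) < min_gap for q in used_pos):
            return False
        return all(not (t.start - maxw - 50 <= p <= t.end + maxw + 50) for t in truth_sites)

    # planted exclusives
    exclusive_records: List[Dict] = []
    truth_rows: List[Dict] = []
    for pe in planted_exclusive:
        site = truth_sites[pe.site_index]
        L = abs(pe.indel_len)
        if pe.indel_len < 0:
            a = site.end + pe.distance  # first deleted base, 0-based
            pos = a  # 1-based anchor = a-1+1
            if a - 1 < 0 or a + L > glen:
                raise SimulationError("deletion runs off the genome")
            ref = seq[a - 1:a + L]
            alt = seq[a - 1]
        else:
            ip = site.end + pe.distance  # 0-based insertion point
            pos = ip
            if ip - 1 < 0 or ip > glen:
                raise SimulationError("insertion point off the genome")
            ref = seq[ip - 1]
            alt = ref + "".join(rng.choice(list(BASES), size=L))
        support, mq, qual = _draw_quality(rng, passing=exclusive_passing)
        rec = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
               "support": support, "mq": mq, "qual": qual}
        exclusive_records.append(rec)
        used_pos.append(pos)
        truth_rows.append({
            **rec, "site_index": pe.site_index, "distance": pe.distance,
            "indel_len": pe.indel_len,
            "passes_filter": support >= 4 and mq >= 30 and qual >= 20,
        })

    # shared background
    n_background = int(rng.poisson(background_rate * glen))
    background: List[Dict] = []
    attempts = 0
    while len(background) < n_background and attempts < 50 * (n_background + 1):
        attempts += 1
        pos = int(rng.integers(2, glen - 12))
        if not far_from_everything(pos):
            continue
        L = int(rng.integers(1, 6))
        if rng.random() < 0.5:
            ref, alt = seq[pos - 1:pos + L], seq[pos - 1]
        else:
            ref = seq[pos - 1]
            alt = ref + "".join(rng.choice(list(BASES), size=L))
        support, mq, qual = _draw_quality(rng)
        background.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                           "support": support, "mq": mq, "qual": qual})
        used_pos.append(pos)

    edited = sorted(background + exclusive_records, key=lambda r: (r["chrom"], r["pos"]))
    control = sorted(background, key=lambda r: (r["chrom"], r["pos"]))

    sites_hit: Dict[int, set] = {w: set() for w in windows}
    for row in truth_rows:
        if not row["passes_filter"]:
            continue
        for w in windows:
            if row["distance"] <= w:
                sites_hit[w].add(row["site_index"])
    truth = VcfPairTruth(
        records=truth_rows,
        sites_within={w: len(sites_hit[w]) for w in windows},
    )
    return edited, control, truth


def write_vcf(records: Sequence[Dict], genome: Dict[str, str],
              path: Union[str, Path], sample: str = "SAMPLE") -> None:
    """Write call records as a minimal, pysam-parseable VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in sorted(records, key=lambda r: (r["chrom"], r["pos"])):
            ref_depth = max(0, 60 - r["support"])
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t"
                     f"{r['qual']:.1f}\t.\tMQ={r['mq']:.1f}\t"
                     f"GT:AD\t0/1:{ref_depth},{r['support']}\n")


# ---------------------------------------------------------------------------
# amplicon reads

@dataclass(frozen=True)
class EditSimSpec:
    """True class fractions and error model for simulated amplicon reads.

    The default indel-size distribution (60% 1-bp deletions, 20% 1-bp
    insertions, 20% 2–10-bp deletions) reflects the typical NHEJ outcome
    spectrum at a blunt Cas9 cut.
    """

    true_indel_fraction: float
    true_hdr_fraction: float
    n_reads: int = 10000
    substitution_error_rate: float = 0.001
    seed: int = 0
    indel_size_probs: Tuple[Tuple[int, float], ...] = (
        (-1, 0.6), (+1, 0.2), (0, 0.2),  # 0 stands for "2-10 bp deletion"
    )

    def __post_init__(self) -> None:
        if self.true_indel_fraction < 0 or self.true_hdr_fraction < 0:
            raise SimulationError("fractions must be >= 0")
        if self.true_indel_fraction + self.true_hdr_fraction > 1.0 + 1e-12:
            raise SimulationError("class fractions sum above 1")
        if self.n_reads <= 0:
            raise SimulationError("n_reads must be positive")


def make_amplicon(seed: int = 0, length: int = 240, cut_site: int = 120,
                  signature_len: int = 30) -> AmpliconSpec:
    """A random amplicon plus a donor signature absent from it."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        ref = "".join(rng.choice(list(BASES), size=length))
        sig = "".join(rng.choice(list(BASES), size=signature_len))
        if sig not in ref and revcomp(sig) not in ref:
            return AmpliconSpec(reference=ref, cut_site=cut_site,
                                hdr_signature=sig, name="synthetic_amplicon")
    raise SimulationError("could not draw a signature absent from the reference")


def _lesion(ref: str, cut: int, size_code: int, rng: np.random.Generator) -> Tuple[str, int]:
    """Apply one NHEJ lesion at the cut site; returns (sequence, signed length)."""
    if size_code == -1:
        L, kind = 1, "del"
    elif size_code == +1:
        L, kind = 1, "ins"
    else:
        L, kind = int(rng.integers(2, 11)), "del"
    if kind == "del":
        start = cut - int(rng.integers(0, L))  # deletion always covers the cut
        start = max(1, min(start, len(ref) - L - 1))
        return ref[:start] + ref[start + L:], -L
    ins = "".join(rng.choice(list(BASES), size=L))
    return ref[:cut] + ins + ref[cut:], L


def make_reads(
    spec: EditSimSpec,
    amplicon: AmpliconSpec,
) -> Tuple[List[Tuple[str, str, List[int]]], List[Dict]]:
    """Simulated full-length amplicon reads with per-read truth labels.

    Classes are drawn i.i.d. at the true fractions; INDEL reads carry a
    lesion overlapping the cut site, HDR reads carry the donor signature
    inserted at the cut, and uniform substitution errors are applied to
    every read. Returns (reads, truth) where each read is
    (id, sequence, phred_qualities).
    """
    if len(amplicon.hdr_signature) > len(amplicon.reference):
        raise SimulationError("hdr_signature longer than the amplicon")
    rng = np.random.default_rng(spec.seed)
    ref, cut = amplicon.reference, amplicon.cut_site
    p_wt = 1.0 - spec.true_indel_fraction - spec.true_hdr_fraction
    reads: List[Tuple[str, str, List[int]]] = []
    truth: List[Dict] = []
    labels = rng.choice(
        ["INDEL", "HDR", "WT"], size=spec.n_reads,
        p=[spec.true_indel_fraction, spec.true_hdr_fraction, p_wt],
    )
    size_codes = [c for c, _ in spec.indel_size_probs]
    size_p = [p for _, p in spec.indel_size_probs]
    for i, label in enumerate(labels):
        if label == "WT":
            seq, net = ref, 0
        elif label == "INDEL":
            code = int(rng.choice(size_codes, p=size_p))
            seq, net = _lesion(ref, cut, code, rng)
        else:
            seq, net = ref[:cut] + amplicon.hdr_signature + ref[cut:], 0
        n_err = 0
        if spec.substitution_error_rate > 0:
            err_mask = rng.random(len(seq)) < spec.substitution_error_rate
            if err_mask.any():
                s = list(seq)
                for j in np.nonzero(err_mask)[0]:
                    s[j] = str(rng.choice([b for b in BASES if b != s[j]]))
                    n_err += 1
                seq = "".join(s)
        read_id = f"read_{i:06d}_{label}"
        reads.append((read_id, seq, [30] * len(seq)))
        truth.append({"read_id": read_id, "label": str(label),
                      "indel_len": net, "n_errors": n_err})
    return reads, truth


def write_fastq(reads: Sequence[Tuple[str, str, Sequence[int]]],
                path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")
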