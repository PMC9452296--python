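"""Guide (sgRNA) specifications and IUPAC sequence utilities."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes mapped to the concrete bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA sequence (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True when ``seq`` satisfies the IUPAC ``pattern`` position by position.

    An ``N`` (or any ambiguous base) in the *target* never satisfies a
    concrete pattern symbol: unresolved genome bases are treated
    conservatively as non-matching.
    """
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern, seq):
        if s not in IUPAC_CODES[p]:
            return False
    return True


class GuideError(ValueError):
    """Invalid guide or PAM specification."""


@dataclass(frozen=True)
class GuideSpec:
    """An sgRNA spacer with its PAM requirement and optional on-target locus.

    Parameters
    ----------
    protospacer:
        Spacer sequence, 5'->3', RNA or DNA alphabet (``U`` is normalized
        to ``T``). Canonically 20 nt; 18–24 nt accepted.
    pam_pattern:
        IUPAC motif required immediately 3' of the protospacer on the
        protospacer strand (SpCas9 convention), default ``NRG``.
    on_target:
        Optional ``(chrom, pos, strand)`` of the intended target;
        ``pos`` is 1-based.
    name:
        Label used in output files.
    """

    protospacer: str
    pam_pattern: str = "NRG"
    on_target: Optional[Tuple[str, int, str]] = None
    name: str = "guide"

    def __post_init__(self) -> None:
        spacer = self.protospacer.upper().replace("U", "T")
        object.__setattr__(self, "protospacer", spacer)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if not 18 <= len(spacer) <= 24:
            raise GuideError(
                f"protospacer length {len(spacer)} outside the supported 18-24 nt range"
            )
        if any(b not in "ACGT" for b in spacer):
            raise GuideError(f"protospacer contains non-ACGT bases: {spacer}")
        if len(self.pam_pattern) < 1:
            raise GuideError("PAM pattern must contain at least one base")
        if any(b not in IUPAC_CODES for b in self.pam_pattern):
            raise GuideError(f"PAM pattern contains non-IUPAC symbols: {self.pam_pattern}")
        if self.on_target is not None:
            chrom, pos, strand = self.on_target
            if strand not in "+-" or pos < 1:
                raise GuideError(f"invalid on-target locus {self.on_target!r}")


# Guides in routine use for therapeutic knock-in T-cell engineering,
# with their 1-based human (GRCh38) target coordinates. Spacers are given
# as synthesized (RNA for the first three); GuideSpec normalizes U->T.
KNOWN_GUIDES = {
    "AAVS1": GuideSpec("AGAGCUAGCACAGACUAGAG", on_target=("chr19", 55115996, "+"), name="AAVS1"),
    "PD1_site1": GuideSpec("CGACUGGCCAGGGCGCCUGU", on_target=("chr2", 241858824, "+"), name="PD1_site1"),
    "PD1_site2": GuideSpec("GGGCGGUGCUACAACUGGGC", on_target=("chr2", 241858788, "+"), name="PD1_site2"),
    "TRAC": GuideSpec("AGAGCAACAGTGCTGTGGCC", on_target=("chr14", 22547693, "+"), name="TRAC"),
    "B2M": GuideSpec("GAGTAGCGCGAGCACAGCTA", on_target=("chr15", 44711569, "+"), name="B2M"),
}

# Three-primer genotyping design for the PD1 CAR knock-in: one forward
# primer inside the CAR cassette, one forward primer in the left homology
# arm, one reverse primer outside the right homology arm.
GENOTYPING_PRIMERS = {
    "car_forward": "CCCTGCAACTGATGGTGACT",
    "genomic_forward": "GACAGTTTCCCTTCCGCTCA",
    "genomic_reverse": "TCACAGTGTACACAGAGGGC",
}
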