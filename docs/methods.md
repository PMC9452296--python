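# Methods

`editqc` implements the genome-integrity analyses used to qualify
CRISPR-engineered, knock-in cell products (for example CAR-T cells made by
non-viral, homology-directed insertion of the CAR cassette into a target
locus such as *PDCD1*). This note records the models, the parameters that
matter, the synthetic-data assumptions, and the numerical choices.

## 1. Off-target site enumeration (`editqc.offtarget`)

**Model.** A candidate off-target site is a genomic window, on either
strand, that (a) is followed on the protospacer strand by a PAM matching an
IUPAC pattern (default `NRG`, the relaxed SpCas9 motif), and (b) aligns to
the guide spacer with penalty ≤ `max_penalty` (default 5), where each
substitution costs 1 and each unpaired base costs `bulge_cost_per_base`
(default 2) — a DNA bulge is an extra target base, an RNA bulge an extra
guide base. The alignment is anchored at the PAM-proximal end (no end gaps
on the PAM side); the PAM-distal end may shift by up to the bulge
allowance. `max_bulge_len` (default 2) caps the *total* number of bulged
bases per alignment; with the defaults the penalty budget already implies
the same cap (⌊5/2⌋ = 2), so the two constraints coincide.

**Algorithm.** For every PAM match (found with vectorized byte masks), a
banded dynamic program over states (guide bases consumed, target bases
consumed, bulged bases used) computes the minimal penalty and a traceback
alignment; cost is pruned at the budget. Per anchor the best end state is
chosen by (penalty, fewer bulged bases, longest target). Overlapping
alignments on the same chromosome and strand are clustered transitively and
reduced to one representative (minimal penalty, then fewer bulged bases,
then leftmost start), since a site count is only meaningful with one entry
per locus.

**Conventions.** Coordinates are 0-based half-open internally and in BED
output; stated loci such as chr2:241,858,824 are interpreted as 1-based.
Windows containing any non-ACGT base never match at that position (an `N`
is a mismatch against every guide base) — conservative and deterministic.
Sites whose interval lies within `exclude_on_target_radius` (default
1,000 bp; the source protocol excludes "around the on-target site" without
a radius) of the declared on-target position are reported separately, not
counted.

**Scope.** The scanner is a straightforward per-anchor DP intended for the
correctness surface of this package (genomes up to tens of megabases in
reasonable time), not an indexed search structure tuned for routine
whole-human-genome screens. No activity scoring (CFD/MIT) is attempted.
Reproducing the published whole-genome count of 2,219 candidate sites for
the PD1 site-1 guide additionally depends on unstated bulge conventions
(maximum length, whether several bulges may co-occur) and the genome build;
the count is treated as an external target and is exercised by an
acceptance test only where a local human reference exists.

## 2. Exclusive-indel cross-referencing (`editqc.crossref`)

Indel calls (< 50 bp, bi-allelic, pre-split) from an edited sample and its
unedited control are filtered with the thresholds used in the source QC:
alt-supporting reads ≥ 4, mapping quality ≥ 30, QUAL ≥ 20, plus removal of
calls near other variants and calls inside exclusion regions (e.g. the
pseudoautosomal regions — supplied as a BED, never hard-coded). The
near-variant distance is not stated in the source protocol; the default is
10 bp, applied against all supplied variant positions (SNVs included) when
given, otherwise against the indel calls themselves. Each removed call is
logged with the first failing rule (order: support, mq, qual, length,
near-variant, exclusion region).

Edited-exclusive indels are edited calls with no matching control call —
exact matching on (chrom, pos, ref, alt) by default, or windowed matching
(same chromosome, same indel length, positions within *w* bp, default 3) to
tolerate left-alignment differences between call sets.

**Distance convention.** The affected reference interval of a deletion is
the deleted bases (anchor excluded); an insertion affects the zero-length
insertion point after its anchor. Distance between a site and an indel is
0 when the intervals overlap or abut, otherwise the number of bases
strictly between the nearest boundaries; "±15 bp" means distance ≤ 15.
One proximity hit is emitted per (site, indel) pair per satisfied window
(default radii 15 and 200), and the summary counts distinct sites per
window. Whether the published "eight sites within ±200 bp" used this or a
center-to-center convention is not stated; this convention is fixed and
documented here.

## 3. Amplicon editing-outcome quantification (`editqc.amplicon`)

Service-style readouts (Sanger-trace deconvolution, hosted deep-sequencing
portals) report only percentages; this module defines the classifier
explicitly so the numbers are reproducible. Per read, after a fixed Q20
end-trim (trimming policy is not part of the source protocol):

1. **FAIL** if shorter than `min_read_len` (default 50 nt).
2. **HDR** if the donor-specific junction k-mer (canonically a 30-mer
   absent from the wild-type amplicon) occurs in either orientation with at
   most 1 mismatch. k-mer detection rather than full junction alignment is
   the default because it is robust for short reads; the aligner path below
   still handles reads where the signature is disrupted.
3. Otherwise the read is globally aligned to the wild-type amplicon
   (match +1, mismatch −1, gap open −4, gap extend −1, end gaps free —
   Biopython `PairwiseAligner`). **FAIL** if identity over aligned columns
   < 0.6 *or* matched bases < 0.6 × read length (the second gate rejects
   unrelated sequence that would otherwise align a short high-identity
   sliver under free end gaps). **INDEL** if any alignment gap touches the
   quantification window `cut_site ± 2 bp`; the signed net gap length in
   the window is reported. **WT** if gap-free around the cut with identity
   ≥ 0.9; **AMBIGUOUS** otherwise.

The cut site defaults to the blunt SpCas9 cut between protospacer positions
17/18 (3 bp 5′ of the PAM). The ±2 bp window attributes only cut-adjacent
lesions to editing, keeping the false-indel rate on unedited material below
1% at sequencing error rates ≤ 0.5%. Percentages are computed over passing
reads with exact (Clopper–Pearson) 95% binomial intervals; counts are
order-independent, and quantification refuses to run below a configurable
floor of passing reads (default 100).

## 4. Knock-in genotype deconvolution (`editqc.genotype`)

A three-primer semiquantitative PCR yields a wild-type/indel band and a
cassette band; densitometry in unsorted cells and sorted cassette-positive
cells gives the quadruple (A, B, C, D). Assuming the two amplicons amplify
with equal efficiency (implicit in the source equations; no correction for
amplicon-length bias is attempted), genotype percentages follow in closed
form:

    wt_indel = (B·C − A·D)/B,   het = 2·A·D/B,   homo = (B − A)·D/B

The forward model (cell mixture → bands) used for validation is explicit:
per 100 cells the unsorted lane sees C = (2·wt + het)/2 wild-type alleles
and D = (het + 2·homo)/2 cassette alleles; the sorted lane contains only
het and homo cells, giving A = het/(2(het+homo)) and
B = (het+2·homo)/(2(het+homo)) (×100). The equations invert this model
exactly, and wt + het + homo = C + D holds as an algebraic identity. Band
percentages are treated as within-lane normalized (A+B = 100, C+D = 100);
the inverse accepts unnormalized inputs since only the ratios A/B and the
C, D values enter. Physically inconsistent inputs (negative components,
possible with noisy lanes) are flagged, never clamped, so QC can reject the
lane. The noise simulator perturbs each band with multiplicative
Normal(1, σ) factors and renormalizes per lane; at σ = 0.05 the mixture is
recovered with mean absolute error below 2 percentage points.

## 5. Synthetic data (`editqc.simulate`)

All generators are seed-deterministic (`numpy.random.default_rng`) and emit
the standard formats their consuming stages read, plus machine-readable
truth.

- **Genomes** are uniform-random by default (GC content configurable), with
  planted protospacer variants realizing exact mismatch/bulge/PAM
  descriptions. Substitution positions avoid bulge-adjacent bases so the
  intended alignment is the cheapest realization. Planted "bad-PAM" sites
  draw their PAM from bases outside the pattern's required set so a shifted
  anchor cannot re-create a valid PAM from the plant itself; over-budget
  plants in the seeded validation worlds are substitution-only, because a
  bulge-carrying plant can legitimately admit a cheaper ungapped alignment
  through a neighbouring PAM on unlucky backgrounds.
- **VCF pairs** share identical background records (including quality
  values) between edited and control, so the edited-exclusive truth is
  exactly the planted set; backgrounds keep ≥ 25 bp from other variants and
  ≥ window + 50 bp from planted sites so proximity rules are inert unless a
  test plants them deliberately. Qualities are independent draws (support ~
  Poisson(30), MQ ~ 60 − Exp(8), QUAL ~ Gamma(4, 15)) chosen to straddle
  the filter thresholds; planted exclusives can be forced to either side.
- **Amplicon reads** are full-length molecules drawn i.i.d. at the true
  class fractions — the default operating regime (60% indel, 20% HDR)
  matches the reported PD1 knock-in product range — with NHEJ lesions
  covering the cut site (60% 1-bp deletions, 20% 1-bp insertions, 20%
  2–10-bp deletions), HDR junction insertions, and uniform substitution
  errors (default 0.1%). Real error profiles (position-dependent quality,
  indel errors, chimeras) are deliberately not modelled; a green test
  establishes correctness of the classifier's decision rules, not
  robustness to every sequencing artifact.

## 6. Pipeline and provenance (`editqc.pipeline`)

Stages communicate only through files in standard formats (BED, VCF, FASTQ,
TSV, JSON), so any stage can be replaced by externally supplied outputs.
The QC report embeds package version, seed and a parameter hash; re-running
an identical configuration reproduces the report byte-for-byte except for
the timestamp field.

## Known limitations

- The scanner's per-anchor DP is exact but not indexed; whole-human-genome
  scans take minutes-to-hours, not seconds.
- No paired-end merging beyond treating reads as full amplicon molecules,
  no UMIs, no chimera detection, no Sanger-trace deconvolution.
- No statistical enrichment testing of indels near candidate sites (the
  upstream protocol performs none); the module reports counts.
- Variant calling, alignment and duplicate marking are upstream of this
  package; it consumes VCF.
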