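"""Closed-form knock-in genotype deconvolution from PCR band intensities.

A semiquantitative three-primer PCR on a knock-in locus produces two bands:
a wild-type/indel band from the unmodified (or NHEJ-repaired) allele and a
cassette-specific band from the knock-in allele. Densitometry of the two
bands in unsorted cells and in sorted cassette-positive cells gives four
percentages:

* ``A`` — wild-type/indel band in sorted cells,
* ``B`` — cassette band in sorted cells,
* ``C`` — wild-type/indel band in unsorted cells,
* ``D`` — cassette band in unsorted cells.

Assuming unbiased amplification of the two alleles, the cell-level
genotype fractions follow in closed form::

    wt_indel (%) = (B*C - A*D) / B * 100
    het      (%) = 2*A*D / B * 100
    homo     (%) = (B - A)*D / B * 100

The module also provides the forward model (cell mixture -> band
intensities) used as the inversion oracle and as a noise simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    """Invalid band intensities (out of range, or B = 0)."""


@dataclass(frozen=True)
class BandIntensities:
    """The A-D band-percentage quadruple (all values in [0, 100])."""

    A: float
    B: float
    C: float
    D: float

    def __post_init__(self) -> None:
        for name in "ABCD":
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise GenotypeError(f"band {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class GenotypeFractions:
    """WT-or-indel / heterozygous / homozygous knock-in percentages.

    ``consistent`` is False when any component is negative — possible for
    noisy or mis-normalized band inputs; components are reported
    un-clamped so downstream QC can reject the lane.
    """

    wt_indel_pct: float
    het_pct: float
    homo_pct: float
    consistent: bool = True

    @property
    def total(self) -> float:
        return self.wt_indel_pct + self.het_pct + self.homo_pct


def deconvolve_genotypes(bands: BandIntensities) -> GenotypeFractions:
    """Invert band intensities to genotype fractions (closed form).

    Requires ``B > 0`` (a sorted lane with no cassette band cannot come
    from cassette-positive cells). Physically inconsistent inputs yield
    negative components, flagged via ``consistent=False`` and never
    clamped.
    """
    A, B, C, D = bands.A, bands.B, bands.C, bands.D
    if B == 0:
        raise GenotypeError("B = 0: deconvolution undefined (no cassette band in sorted lane)")
    wt = (B * C - A * D) / B
    het = 2.0 * A * D / B
    homo = (B - A) * D / B
    return GenotypeFractions(
        wt_indel_pct=wt, het_pct=het, homo_pct=homo,
        consistent=min(wt, het, homo) >= 0.0,
    )


def forward_bands(mix: GenotypeFractions) -> BandIntensities:
    """Noise-free band intensities for a WT/het/homo cell mixture.

    Under unbiased allelic amplification, band intensity is proportional
    to allele count. Unsorted lane: ``C = (2*wt + het)/2``,
    ``D = (het + 2*homo)/2``. Sorted (cassette-positive) lane contains
    only het and homo cells: ``A = het / (2*(het + homo))``,
    ``B = (het + 2*homo) / (2*(het + homo))`` (scaled to percent).
    """
    wt, het, homo = mix.wt_indel_pct, mix.het_pct, mix.homo_pct
    if min(wt, het, homo) < 0 or abs(wt + het + homo - 100.0) > 1e-6:
        raise GenotypeError("mixture fractions must be >= 0 and sum to 100")
    if het + homo == 0:
        raise GenotypeError("no cassette-positive cells: sorted lane undefined")
    sorted_alleles = 2.0 * (het + homo)
    return BandIntensities(
        A=100.0 * het / sorted_alleles,
        B=100.0 * (het + 2.0 * homo) / sorted_alleles,
        C=(2.0 * wt + het) / 2.0,
        D=(het + 2.0 * homo) / 2.0,
    )


def simulate_bands(
    mix: GenotypeFractions,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> BandIntensities:
    """Forward model plus multiplicative Gaussian intensity noise.

    Each of the four band intensities is perturbed by an independent
    ``Normal(1, noise_sd)`` factor (truncated at 0), then each lane is
    renormalized to 100%, mimicking within-lane densitometry.
    """
    if noise_sd < 0:
        raise GenotypeError("noise_sd must be >= 0")
    clean = forward_bands(mix)
    if noise_sd == 0:
        return clean
    rng = rng if rng is not None else np.random.default_rng()
    factors = np.clip(rng.normal(1.0, noise_sd, size=4), 0.0, None)
    a, b = clean.A * factors[0], clean.B * factors[1]
    c, d = clean.C * factors[2], clean.D * factors[3]
    sorted_total, unsorted_total = a + b, c + d
    if sorted_total == 0 or unsorted_total == 0:
        raise GenotypeError("noise wiped out a lane; re-draw with lower noise_sd")
    return BandIntensities(
        A=100.0 * a / sorted_total, B=100.0 * b / sorted_total,
        C=100.0 * c / unsorted_total, D=100.0 * d / unsorted_total,
    )


def deconvolve_table(bands_tsv: Union[str, Path]) -> pd.DataFrame:
    """Deconvolve a TSV with columns sample, A, B, C, D into a genotype table."""
    df = pd.read_csv(bands_tsv, sep="\t")
    missing = {"sample", "A", "B", "C", "D"} - set(df.columns)
    if missing:
        raise GenotypeError(f"bands table lacks columns: {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        g = deconvolve_genotypes(BandIntensities(row.A, row.B, row.C, row.D))
        rows.append({
            "sample": row["sample"],
            "wt_indel_pct": g.wt_indel_pct,
            "het_pct": g.het_pct,
            "homo_pct": g.homo_pct,
            "consistent": g.consistent,
        })
    return pd.DataFrame(rows)
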