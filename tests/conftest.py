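import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from editqc import GuideSpec, ScanParams
from editqc.simulate import PlantSpec, PlantedSite, make_amplicon, make_genome


@pytest.fixture(scope="session")
def pd1_guide() -> GuideSpec:
    return GuideSpec("CGACUGGCCAGGGCGCCUGU", name="PD1_site1")


@pytest.fixture(scope="session")
def amplicon():
    return make_amplicon(seed=5)


def planted_world(guide: GuideSpec, seed: int, genome_len: int = 1500):
    """A genome with one plant per penalty class 0-6 plus a bad-PAM plant."""
    spec = PlantSpec(guide=guide, sites=(
        PlantedSite(200, "+", 0),
        PlantedSite(400, "-", 3),
        PlantedSite(600, "+", 3, (("dna", 10, 1),)),     # penalty 5
        PlantedSite(800, "+", 5),
        PlantedSite(1000, "-", 4, (("rna", 9, 1),)),     # penalty 6: over budget
        PlantedSite(1200, "+", 6),                       # penalty 6: over budget
    ), genome_len=genome_len, seed=seed)
    return make_genome(spec)


def random_indel_calls(rng: np.random.Generator, n: int, chrom: str = "chr1",
                       sample: str = "edited"):
    """Random IndelCall records with qualities straddling every threshold,
    spaced >= 25 bp so the near-variant rule never fires."""
    from editqc.crossref import IndelCall

    positions = np.sort(rng.choice(np.arange(100, 100 + 40 * n, 40), size=n, replace=False))
    calls = []
    for pos in positions:
        L = int(rng.integers(1, 60))  # lengths on both sides of the 50-bp cap
        if rng.random() < 0.5:
            ref, alt = "A" + "T" * L, "A"
        else:
            ref, alt = "A", "A" + "C" * L
        calls.append(IndelCall(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt,
            qual=float(rng.gamma(3.0, 10.0)),
            mq=float(np.clip(rng.normal(35, 10), 0, 60)),
            support=int(rng.poisson(5)),
            sample=sample,
        ))
    return calls
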