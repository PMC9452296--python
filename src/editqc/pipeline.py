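"""End-to-end orchestration of the QC stages into a single report.

Stages communicate through files in the standard formats (BED/VCF/FASTQ/
TSV), so any stage can be skipped and its outputs supplied externally.
The report bundles every stage summary next to the artifact it was
derived from, with full parameter provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

import editqc
from editqc.amplicon import AlignParams, AmpliconSpec, quantify_amplicon, write_quant_json
from editqc.crossref import (
    FilterParams,
    exclusive_indels,
    filter_indels,
    intersect_windows,
    read_bed_intervals,
    read_indels_vcf,
    write_hits_tsv,
    write_indels_tsv,
)
from editqc.genotype import deconvolve_table
from editqc.guides import GuideSpec
from editqc.offtarget import (
    ScanParams,
    read_sites_bed,
    scan_offtargets,
    write_sites_bed,
    write_sites_tsv,
)

logger = logging.getLogger("editqc")


class ConfigError(ValueError):
    """A stage is missing an input that no earlier stage produced."""


@dataclass
class QCReport:
    """Machine-readable QC summary; every number re-derivable from the
    stage artifacts written beside it."""

    metadata: Dict
    scan: Optional[Dict] = None
    crossref: Optional[Dict] = None
    amplicon: Optional[Dict] = None
    genotype: Optional[List[Dict]] = None

    def to_dict(self) -> Dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_markdown(self, path: Union[str, Path]) -> None:
        lines = ["# editqc QC report", ""]
        if self.scan:
            s = self.scan
            lines += ["## Off-target scan",
                      f"- guide: {s['guide']}",
                      f"- candidate sites: {s['n_sites']}",
                      f"- sites excluded around on-target: {s['n_on_target_excluded']}", ""]
        if self.crossref:
            c = self.crossref
            lines += ["## Edited-exclusive indel cross-reference",
                      f"- edited calls kept after filtering: {c['n_edited_kept']}",
                      f"- control calls kept after filtering: {c['n_control_kept']}",
                      f"- edited-exclusive indels: {c['n_exclusive']}"]
            for w, n in sorted(c["sites_within"].items(), key=lambda kv: int(kv[0])):
                lines.append(f"- sites with an exclusive indel within ±{w} bp: {n}")
            lines.append("")
        if self.amplicon:
            a = self.amplicon
            lines += ["## Amplicon editing outcomes",
                      f"- reads passing: {a['n_pass']} / {a['n_total']}",
                      f"- indel %: {a['indel_pct']:.2f} "
                      f"(95% CI {a['ci95_indel'][0]:.2f}–{a['ci95_indel'][1]:.2f})",
                      f"- HDR %: {a['hdr_pct']:.2f} "
                      f"(95% CI {a['ci95_hdr'][0]:.2f}–{a['ci95_hdr'][1]:.2f})", ""]
        if self.genotype:
            lines += ["## Knock-in genotype deconvolution",
                      "| sample | WT/indel % | het % | homo % | consistent |",
                      "|---|---|---|---|---|"]
            for row in self.genotype:
                lines.append(f"| {row['sample']} | {row['wt_indel_pct']:.1f} | "
                             f"{row['het_pct']:.1f} | {row['homo_pct']:.1f} | "
                             f"{row['consistent']} |")
            lines.append("")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))


def _param_hash(config: Dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _guide_from_config(cfg: Dict) -> GuideSpec:
    on_target = cfg.get("on_target")
    if on_target is not None:
        on_target = (on_target[0], int(on_target[1]), on_target[2])
    return GuideSpec(
        protospacer=cfg["protospacer"],
        pam_pattern=cfg.get("pam", "NRG"),
        on_target=on_target,
        name=cfg.get("name", "guide"),
    )


def run_pipeline(config: Dict, outdir: Union[str, Path]) -> QCReport:
    """Run the stages named in ``config`` in dependency order.

    ``config`` holds one block per stage (``scan``, ``crossref``,
    ``amplicon``, ``genotype``); any stage may be omitted, in which case
    a downstream stage must name its inputs explicitly. Raises
    :class:`ConfigError` when a dependency is neither configured nor
    produced by an earlier stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not any(k in config for k in ("scan", "crossref", "amplicon", "genotype")):
        raise ConfigError("config names no stage to run")

    report = QCReport(metadata={
        "editqc_version": editqc.__version__,
        "parameter_hash": _param_hash(config),
        "seed": config.get("seed"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })

    sites = None
    if "scan" in config:
        cfg = config["scan"]
        logger.info("[scan] starting")
        guide = _guide_from_config(cfg["guide"])
        params = ScanParams(**cfg.get("params", {}))
        result = scan_offtargets(cfg["genome"], guide, params)
        sites = result.sites
        write_sites_bed(result.sites, outdir / "sites.bed")
        write_sites_tsv(result.sites, outdir / "sites.tsv")
        write_sites_bed(result.on_target_sites, outdir / "sites_on_target.bed")
        report.scan = {
            "guide": guide.name,
            "n_sites": len(result.sites),
            "n_on_target_excluded": len(result.on_target_sites),
            "params": asdict(params),
            "penalty_histogram": _penalty_histogram(result.sites),
        }
        logger.info("[scan] %d candidate sites", len(result.sites))

    if "crossref" in config:
        cfg = config["crossref"]
        logger.info("[crossref] starting")
        if "sites" in cfg:
            sites = read_sites_bed(cfg["sites"])
        if sites is None:
            raise ConfigError("crossref needs candidate sites: run scan or set crossref.sites")
        for key in ("edited", "control"):
            if key not in cfg:
                raise ConfigError(f"crossref.{key} VCF not configured")
        fp_kwargs = dict(cfg.get("filter", {}))
        if "exclude" in cfg:
            fp_kwargs["exclusion_bed"] = tuple(read_bed_intervals(cfg["exclude"]))
        fparams = FilterParams(**fp_kwargs)
        edited = read_indels_vcf(cfg["edited"], sample="edited")
        control = read_indels_vcf(cfg["control"], sample="control")
        f_e = filter_indels(edited, fparams)
        f_c = filter_indels(control, fparams)
        exclusive = exclusive_indels(f_e.kept, f_c.kept,
                                     match_mode=cfg.get("match_mode", "exact"))
        windows = tuple(cfg.get("windows", (15, 200)))
        summary = intersect_windows(sites, exclusive, windows)
        write_indels_tsv(
            exclusive, outdir / "exclusive_indels.tsv",
            provenance={c.key(): "edited_exclusive" for c in exclusive})
        write_hits_tsv(summary.hits, outdir / "proximity_hits.tsv")
        report.crossref = {
            "n_edited_total": len(edited), "n_edited_kept": len(f_e.kept),
            "n_control_total": len(control), "n_control_kept": len(f_c.kept),
            "n_exclusive": len(exclusive),
            "sites_within": {str(w): n for w, n in summary.sites_within.items()},
            "filter_params": {k: v for k, v in asdict(fparams).items()
                              if k != "exclusion_bed"},
        }
        with open(outdir / "crossref_summary.json", "w") as fh:
            json.dump({f"sites_within_{w}": n for w, n in summary.sites_within.items()},
                      fh, indent=2, sort_keys=True)
        logger.info("[crossref] %d exclusive indels; window summary %s",
                    len(exclusive), summary.sites_within)

    if "amplicon" in config:
        cfg = config["amplicon"]
        logger.info("[amplicon] starting")
        reference = cfg["reference"]
        if isinstance(reference, str) and Path(reference).exists():
            from editqc.offtarget import read_fasta
            reference = next(iter(read_fasta(reference).values()))
        spec = AmpliconSpec(
            reference=reference,
            cut_site=int(cfg["cut_site"]),
            hdr_signature=cfg.get("hdr_signature", ""),
            quant_window=int(cfg.get("quant_window", 2)),
            min_read_len=int(cfg.get("min_read_len", 50)),
        )
        align = AlignParams(**cfg.get("align", {}))
        quant = quantify_amplicon(cfg["reads"], spec, align,
                                  min_pass_reads=int(cfg.get("min_pass_reads", 100)))
        write_quant_json(quant, outdir / "amplicon_quant.json")
        report.amplicon = quant.to_dict()
        logger.info("[amplicon] indel %.2f%% HDR %.2f%%", quant.indel_pct, quant.hdr_pct)

    if "genotype" in config:
        cfg = config["genotype"]
        logger.info("[genotype] starting")
        table = deconvolve_table(cfg["bands"])
        table.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        report.genotype = table.to_dict(orient="records")
        logger.info("[genotype] %d samples deconvolved", len(table))

    report.to_json(outdir / "report.json")
    report.to_markdown(outdir / "report.md")
    return report


def _penalty_histogram(sites) -> Dict[str, int]:
    hist: Dict[str, int] = {}
    for s in sites:
        hist[str(s.penalty)] = hist.get(str(s.penalty), 0) + 1
    return dict(sorted(hist.items()))


def load_config(path: Union[str, Path]) -> Dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# fully synthetic end-to-end run

def run_synthetic(seed: int, outdir: Union[str, Path]) -> Dict:
    """Generate a complete synthetic data set and push it through every
    stage, returning the report plus the generators' truth for comparison.

    The synthetic world: a 5-kb genome with planted off-target sites of
    the PD1 guide spanning penalties 0–6, edited/control VCFs with
    exclusive indels at distances straddling the 15-bp window boundary,
    10,000 amplicon reads at 60% indel / 20% HDR (the operating regime of
    a PD1 knock-in product), and band intensities from a 50/30/20
    WT/het/homo mixture.
    """
    from editqc.genotype import BandIntensities, GenotypeFractions, simulate_bands
    from editqc.guides import KNOWN_GUIDES
    from editqc.simulate import (
        EditSimSpec, PlantSpec, PlantedIndel, PlantedSite,
        make_amplicon, make_genome, make_reads, make_vcf_pair,
        write_fastq, write_genome_fasta, write_truth_bed, write_vcf,
    )
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    guide = GuideSpec(KNOWN_GUIDES["PD1_site1"].protospacer, name="PD1_site1")

    plant = PlantSpec(
        guide=guide,
        sites=(
            PlantedSite(offset=400, strand="+", mismatches=0),
            PlantedSite(offset=1200, strand="-", mismatches=3),
            PlantedSite(offset=2000, strand="+", mismatches=3,
                        bulges=(("dna", 10, 1),)),
            PlantedSite(offset=2800, strand="+", mismatches=5),
            # over-budget plants are substitution-only: a bulge-carrying
            # plant can legitimately admit a cheaper ungapped alignment
            # through a neighbouring PAM on unlucky backgrounds
            PlantedSite(offset=3600, strand="-", mismatches=6),
            PlantedSite(offset=4400, strand="+", mismatches=7),
        ),
        genome_len=5000, seed=seed,
    )
    genome, truth_sites = make_genome(plant)
    write_genome_fasta(genome, outdir / "genome.fa")
    write_truth_bed(truth_sites, outdir / "planted_sites.bed")

    in_budget = [t for t in truth_sites if t.penalty <= 5 and t.pam_ok]
    edited, control, vcf_truth = make_vcf_pair(
        genome, in_budget,
        planted_exclusive=[
            PlantedIndel(site_index=0, distance=10, indel_len=-2),
            PlantedIndel(site_index=1, distance=15, indel_len=+1),
            PlantedIndel(site_index=2, distance=16, indel_len=-1),
            PlantedIndel(site_index=3, distance=120, indel_len=-3),
        ],
        seed=seed + 1,
    )
    write_vcf(edited, genome, outdir / "edited.vcf", sample="edited")
    write_vcf(control, genome, outdir / "control.vcf", sample="control")

    amplicon = make_amplicon(seed=seed + 2)
    sim = EditSimSpec(true_indel_fraction=0.6, true_hdr_fraction=0.2,
                      n_reads=10000, substitution_error_rate=0.001,
                      seed=seed + 3)
    reads, read_truth = make_reads(sim, amplicon)
    write_fastq(reads, outdir / "reads.fastq")

    mix = GenotypeFractions(50.0, 30.0, 20.0)
    rng = np.random.default_rng(seed + 4)
    with open(outdir / "bands.tsv", "w") as fh:
        fh.write("sample\tA\tB\tC\tD\n")
        clean = simulate_bands(mix, 0.0)
        noisy = simulate_bands(mix, 0.05, rng)
        fh.write(f"noise_free\t{clean.A:.6g}\t{clean.B:.6g}\t{clean.C:.6g}\t{clean.D:.6g}\n")
        fh.write(f"noisy\t{noisy.A:.6g}\t{noisy.B:.6g}\t{noisy.C:.6g}\t{noisy.D:.6g}\n")

    config = {
        "seed": seed,
        "scan": {
            "genome": str(outdir / "genome.fa"),
            "guide": {"protospacer": guide.protospacer, "name": guide.name},
        },
        "crossref": {
            "edited": str(outdir / "edited.vcf"),
            "control": str(outdir / "control.vcf"),
        },
        "amplicon": {
            "reads": str(outdir / "reads.fastq"),
            "reference": amplicon.reference,
            "cut_site": amplicon.cut_site,
            "hdr_signature": amplicon.hdr_signature,
        },
        "genotype": {"bands": str(outdir / "bands.tsv")},
    }
    report = run_pipeline(config, outdir)
    truth = {
        "planted_sites_in_budget": len(in_budget),
        "sites_within": vcf_truth.sites_within,
        "true_indel_fraction": sim.true_indel_fraction,
        "true_hdr_fraction": sim.true_hdr_fraction,
        "genotype_mix": {"wt_indel_pct": mix.wt_indel_pct,
                         "het_pct": mix.het_pct, "homo_pct": mix.homo_pct},
    }
    return {"report": report.to_dict(), "truth": truth, "config": config}
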