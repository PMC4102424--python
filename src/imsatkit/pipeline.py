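"""Umbrella pipeline: scan -> call -> population summaries.

Chains microsatellite detection on a reference FASTA, interruption calling
against a population VCF, and the downstream summaries (interruption-type
tables, population-sharing Venn counts, per-locus F_ST, binned
heterozygosity with a bootstrap KS comparison, and max-r^2 LD partners when
phased haplotypes are available).  Every stage is individually re-runnable
from its written intermediates; the manifest records per-stage counts and
the resolved configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as kio
from .popgen_stats import fst, het_distribution, heterozygosity, ks_boot, max_ld_partner
from .population_interruptions import (
    DEFAULT_AF_MIN,
    DEFAULT_POPULATIONS,
    annotate_exonic,
    call_interruptions,
    sharing_partition,
)
from .repeat_detection import STATUS_PERFECT, ThresholdConfig, scan_fasta


@dataclass
class PipelineConfig:
    fasta: str
    vcf: str
    out_dir: str
    preset: str = "population"
    af_min: float = DEFAULT_AF_MIN
    populations: tuple = DEFAULT_POPULATIONS
    ks_iterations: int = 10_000
    bootstrap: int = 1000
    rng_seed: int = 0
    exons: str | None = None  # exon annotation TSV (chrom/start/end/gene)
    cds: str | None = None    # CDS annotation TSV (adds strand/frame)

    def to_dict(self) -> dict:
        return asdict(self)


def interruption_type_table(calls, populations) -> dict:
    """Per-population counts of distinct loci and SNP/indel x
    death/degeneration interruptions (Table-1 style)."""
    table = {}
    for pop in populations:
        pop_calls = [c for c in calls if c.population == pop]
        loci = {(c.locus.sequence_id, c.locus.start, c.locus.end) for c in pop_calls}
        row = {"total_loci": len(loci)}
        for mech_label, mechs in (
            ("SNP", ("SNP",)),
            ("indel", ("indel-insertion", "indel-deletion")),
        ):
            for fate in ("death", "degeneration"):
                row[f"{mech_label}_{fate}"] = sum(
                    1
                    for c in pop_calls
                    if c.mechanism in mechs and c.fate == fate
                )
        table[pop] = row
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = ThresholdConfig.preset(config.preset)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # stage 1: detection
    genome = kio.read_fasta(config.fasta)
    loci = scan_fasta(genome, cfg)
    kio.write_loci_bed(loci, out_dir / "loci.bed")
    perfect = [l for l in loci if l.status == STATUS_PERFECT]
    manifest["stages"]["scan"] = {
        "loci": len(loci),
        "perfect": len(perfect),
    }

    # stage 2: interruption calling
    variants = kio.read_vcf_variants(config.vcf, populations=config.populations)
    calls = call_interruptions(
        variants, perfect, cfg, af_min=config.af_min,
        populations=config.populations,
    )
    kio.write_calls_tsv(calls, out_dir / "calls.tsv")
    manifest["stages"]["call"] = {"variants": len(variants), "calls": len(calls)}

    # stage 3: summaries
    table1 = interruption_type_table(calls, config.populations)
    kio.write_json(table1, out_dir / "interruption_types.json")
    venn = {
        "|".join(k): v for k, v in sharing_partition(calls).items()
    }
    kio.write_json(venn, out_dir / "sharing_venn.json")

    # exonic gene summary (interrupted genes per population and mechanism)
    if config.exons:
        exons = kio.read_regions_tsv(config.exons, kind="exon")
        cds = kio.read_regions_tsv(config.cds, kind="cds") if config.cds else []
        gene_table = {}
        for pop in config.populations:
            pop_calls = [c for c in calls if c.population == pop]
            annotated, genes = annotate_exonic(pop_calls, exons, cds, genome)
            gene_table[pop] = {
                "genes": len(genes),
                "SNP": sum(1 for a in annotated if a.call.mechanism == "SNP"),
                "indel": sum(
                    1 for a in annotated if a.call.mechanism != "SNP"
                ),
                "effects": {
                    eff: sum(1 for a in annotated if a.effect == eff)
                    for eff in sorted({a.effect for a in annotated})
                },
            }
        kio.write_json(gene_table, out_dir / "exonic_genes.json")
        manifest["stages"]["exonic"] = {
            pop: row["genes"] for pop, row in gene_table.items()
        }

    # F_ST over calls present in every population
    by_key: dict[tuple, dict] = {}
    for c in calls:
        by_key.setdefault(c.key, {})[c.population] = c.allele_frequency
    fst_rows = []
    for key, freqs in by_key.items():
        if len(freqs) == len(config.populations):
            res = fst([freqs[p] for p in config.populations])
            fst_rows.append(
                {"key": key, "h_s": res.h_s, "h_t": res.h_t, "fst": res.fst}
            )
    defined = [r["fst"] for r in fst_rows if r["fst"] is not None]
    fst_summary = {
        "n_loci": len(fst_rows),
        "n_undefined": sum(1 for r in fst_rows if r["fst"] is None),
        "mean": float(np.mean(defined)) if defined else None,
        "median": float(np.median(defined)) if defined else None,
        "sd": float(np.std(defined, ddof=1)) if len(defined) > 1 else None,
    }
    kio.write_json(
        {"summary": fst_summary, "loci": [
            {**r, "key": list(r["key"])} for r in fst_rows
        ]},
        out_dir / "fst.json",
    )
    manifest["stages"]["fst"] = fst_summary

    # heterozygosity distributions: interruption alleles vs other variants
    called_keys = {c.variant.key for c in calls}
    ks_report = {}
    for pop in config.populations:
        h_ims = [
            heterozygosity(v.allele_frequency.get(pop, 0.0))
            for v in variants
            if v.key in called_keys and v.allele_frequency.get(pop, 0.0) > 0
        ]
        h_other = [
            heterozygosity(v.allele_frequency.get(pop, 0.0))
            for v in variants
            if v.key not in called_keys and v.allele_frequency.get(pop, 0.0) > 0
        ]
        entry: dict = {"n_ims": len(h_ims), "n_other": len(h_other)}
        if h_ims:
            edges, freqs = het_distribution(h_ims)
            entry["ims_histogram"] = freqs.tolist()
        if h_ims and h_other:
            entry["ks"] = ks_boot(
                h_ims, h_other,
                iterations=config.ks_iterations,
                rng_seed=config.rng_seed,
            )
        ks_report[pop] = entry
    kio.write_json(ks_report, out_dir / "heterozygosity_ks.json")

    # LD: max-r^2 partner per interruption-causing indel, if phased
    haplotypes = kio.read_vcf_haplotypes(config.vcf)
    ld_rows = []
    if haplotypes:
        snp_keys = [
            (v, haplotypes[v.key])
            for v in variants
            if v.kind == "SNP" and v.key in haplotypes
        ]
        for c in calls:
            if c.mechanism == "SNP" or c.variant.key not in haplotypes:
                continue
            partner = max_ld_partner(
                c.variant.position,
                haplotypes[c.variant.key],
                (
                    (f"{v.sequence_id}:{v.position}", v.position, haps)
                    for v, haps in snp_keys
                ),
            )
            if partner is not None:
                ld_rows.append(
                    {
                        "indel": list(c.variant.key),
                        "population": c.population,
                        "snp": partner.snp_id,
                        "r2": partner.r2,
                        "perfect": partner.perfect,
                    }
                )
        kio.write_json(ld_rows, out_dir / "ld_partners.json")
    manifest["stages"]["ld"] = {"pairs": len(ld_rows)}

    kio.write_json(manifest, out_dir / "manifest.json")
    return {
        "loci": loci,
        "calls": calls,
        "table1": table1,
        "venn": venn,
        "fst": fst_summary,
        "ks": ks_report,
        "ld": ld_rows,
        "manifest": manifest,
    }
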