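"""Readers and writers for the formats the pipeline consumes and emits.

FASTA via Biopython, VCF via pysam, tables via pandas.  All text I/O is
gzip-transparent.  Locus tables are BED6+ (0-based half-open, with a
dedicated 1-based position column for genome-browser style interchange);
coordinate conventions are asserted at every boundary.
"""

from __future__ import annotations

import gzip
import json

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import Motif
from .ortholog_mutability import MutabilityEstimate, OrthologPair
from .population_interruptions import InterruptionCall, PopulationVariant
from .repeat_detection import Interruption, MicrosatelliteLocus


def open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA -------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open_text(path, "wt") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# -- locus BED6+ --------------------------------------------------------------

LOCUS_BED_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "start_1based", "status", "repeat_number", "n_interruptions",
    "interruption_spec",
]


def _interruption_spec(locus: MicrosatelliteLocus) -> str:
    if not locus.interruptions:
        return "."
    return ";".join(f"{i.offset_in_locus}:{i.sequence}" for i in locus.interruptions)


def write_loci_bed(loci, path) -> None:
    rows = []
    for locus in loci:
        rows.append(
            {
                "chrom": locus.sequence_id,
                "start": locus.start,
                "end": locus.end,
                "name": locus.motif.sequence,
                "score": int(round(locus.repeat_number * 100)),
                "strand": ".",
                "start_1based": locus.start + 1,
                "status": locus.status,
                "repeat_number": locus.repeat_number,
                "n_interruptions": len(locus.interruptions),
                "interruption_spec": _interruption_spec(locus),
            }
        )
    df = pd.DataFrame(rows, columns=LOCUS_BED_COLUMNS)
    with open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_loci_bed(path) -> list[MicrosatelliteLocus]:
    with open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"interruption_spec": str})
    missing = set(LOCUS_BED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus BED missing columns: {sorted(missing)}")
    loci = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.end <= row.start or row.start < 0:
            raise ValueError(f"invalid interval on line {line_no}")
        if int(row.start_1based) != int(row.start) + 1:
            raise ValueError(
                f"1-based/0-based coordinate mismatch on line {line_no}"
            )
        interruptions = []
        if isinstance(row.interruption_spec, str) and row.interruption_spec != ".":
            for token in row.interruption_spec.split(";"):
                offset, seq = token.split(":")
                interruptions.append(
                    Interruption(int(offset), len(seq), seq)
                )
        motif = Motif(row.name)
        length = int(row.end) - int(row.start)
        interrupting = sum(i.length for i in interruptions)
        sequence = ""
        if not interruptions:
            sequence = motif.sequence * (length // motif.size)
        loci.append(
            MicrosatelliteLocus(
                sequence_id=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                motif=motif,
                interruptions=tuple(interruptions),
                status=str(row.status),
                repeat_number=(length - interrupting) / motif.size,
                sequence=sequence,
            )
        )
    return loci


# -- VCF ----------------------------------------------------------------------


def read_vcf_variants(path, populations=None) -> list[PopulationVariant]:
    """Read a normalized biallelic VCF; per-population allele frequencies
    are taken from ``<POP>_AF`` INFO fields (``populations`` defaults to
    every such field present in the header)."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        if populations is None:
            populations = [
                key[: -len("_AF")]
                for key in vcf.header.info
                if key.endswith("_AF")
            ]
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "decompose first"
                )
            afs = {}
            for pop in populations:
                value = rec.info.get(f"{pop}_AF")
                if isinstance(value, tuple):
                    value = value[0]
                afs[pop] = float(value) if value is not None else 0.0
            variants.append(
                PopulationVariant(
                    sequence_id=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    allele_frequency=afs,
                    variant_id=rec.id or ".",
                )
            )
    return variants


def read_vcf_haplotypes(path) -> dict[tuple, list[int]]:
    """Phased haplotype vectors keyed by (chrom, pos, ref, alt)."""
    haplotypes: dict[tuple, list[int]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            return {}
        for rec in vcf:
            haps: list[int] = []
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                haps.extend(0 if a in (None, 0) else 1 for a in gt)
            haplotypes[(rec.chrom, rec.pos, rec.ref, rec.alts[0])] = haps
    return haplotypes


# -- ortholog pair tables ------------------------------------------------------

_PAIR_COLUMNS = [
    "locus_id", "motif_a", "motif_b", "repeat_number_a", "repeat_number_b",
    "n_interruptions_a", "n_interruptions_b", "flank_identity",
    "min_flank_phred", "flank_low_complexity", "distance_to_nearest_locus_bp",
    "interrupting_bases_a", "interrupting_bases_b",
    "interruption_context_a", "interruption_context_b", "position_class",
]


def write_pairs_tsv(pairs, path) -> None:
    df = pd.DataFrame([vars(p) for p in pairs], columns=_PAIR_COLUMNS)
    with open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_pairs_tsv(path) -> list[OrthologPair]:
    with open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    missing = set(_PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        row["flank_low_complexity"] = bool(row["flank_low_complexity"])
        out.append(OrthologPair(**{k: row[k] for k in _PAIR_COLUMNS}))
    return out


def write_mutability_tsv(estimates: list[MutabilityEstimate], path) -> None:
    rows = [
        {
            "motif_size": est.bin_label[0],
            "repeat_number": est.bin_label[1],
            "stratum": est.bin_label[2],
            "mu": est.mu,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "n_loci": est.n_loci,
            "low_confidence": est.low_confidence,
        }
        for est in estimates
    ]
    with open_text(path, "wt") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# -- interruption calls --------------------------------------------------------

_CALL_COLUMNS = [
    "chrom", "locus_start", "locus_end", "motif", "position", "ref", "alt",
    "mechanism", "fate", "population", "allele_frequency",
]


def write_calls_tsv(calls: list[InterruptionCall], path) -> None:
    rows = [
        {
            "chrom": c.locus.sequence_id,
            "locus_start": c.locus.start,
            "locus_end": c.locus.end,
            "motif": c.locus.motif.sequence,
            "position": c.variant.position,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "mechanism": c.mechanism,
            "fate": c.fate,
            "population": c.population,
            "allele_frequency": c.allele_frequency,
        }
        for c in calls
    ]
    with open_text(path, "wt") as fh:
        pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(fh, sep="\t", index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    with open_text(path, "wt") as fh:
        json.dump(obj, fh, indent=1, default=_default)


# -- exon / CDS tables ---------------------------------------------------------


def read_regions_tsv(path, kind: str = "exon"):
    """Read exon or CDS annotation tables (BED-like TSV with a header)."""
    from .population_interruptions import CdsRegion, ExonRegion

    with open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    out = []
    for row in df.to_dict("records"):
        if kind == "exon":
            out.append(
                ExonRegion(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    str(row["gene"]),
                )
            )
        else:
            out.append(
                CdsRegion(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    str(row["gene"]), str(row.get("strand", "+")),
                    int(row.get("frame", 0)),
                )
            )
    return out
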