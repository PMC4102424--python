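"""Interruption polymorphism calling from population variant sets.

Variants (SNPs and non-whole-motif indels) at allele frequency >= 0.05 that
fall strictly inside a perfect microsatellite, excluding its first and last
repeat unit, are interruption calls.  Each call is classified by mechanism
(SNP / indel-insertion / indel-deletion) and fate: *degeneration* when the
interrupted allele retains a perfect tandem stretch at or above the
threshold length for its motif size, *death* otherwise.  Calls are keyed per
population and partitioned by population sharing; exonic calls are annotated
with their coding consequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .motifs import Motif, rotation_canonical, reverse_complement
from .repeat_detection import (
    MicrosatelliteLocus,
    STATUS_PERFECT,
    ThresholdConfig,
)
from .structures import annotate_structure, parse_structure

DEFAULT_POPULATIONS = ("AFR", "EUR", "ASN", "AMR")
DEFAULT_AF_MIN = 0.05

MECH_SNP = "SNP"
MECH_INSERTION = "indel-insertion"
MECH_DELETION = "indel-deletion"

FATE_DEATH = "death"
FATE_DEGENERATION = "degeneration"


@dataclass(frozen=True)
class PopulationVariant:
    """A normalized, biallelic variant with per-population allele
    frequencies.  ``position`` is 1-based (VCF convention)."""

    sequence_id: str
    position: int
    ref: str
    alt: str
    allele_frequency: dict[str, float] = field(default_factory=dict)
    variant_id: str = "."

    def __post_init__(self) -> None:
        if "," in self.alt:
            raise ValueError(
                f"multi-allelic record at {self.sequence_id}:{self.position}; "
                "decompose into biallelic records first"
            )
        for pop, af in self.allele_frequency.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {pop} outside [0,1]: {af}")

    @property
    def kind(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple:
        return (self.sequence_id, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class InterruptionCall:
    locus: MicrosatelliteLocus
    variant: PopulationVariant
    mechanism: str
    fate: str
    population: str
    allele_frequency: float

    @property
    def key(self) -> tuple:
        """Locus+variant identity, shared across populations."""
        return (
            self.locus.sequence_id,
            self.locus.start,
            self.locus.end,
        ) + self.variant.key[1:]


def apply_variant_to_span(
    span_seq: str, span_start: int, variant: PopulationVariant
) -> str:
    """Apply a variant to a sequence window starting at 0-based
    ``span_start`` on the same contig; the REF allele is checked."""
    rel = variant.position - 1 - span_start
    if rel < 0 or rel + len(variant.ref) > len(span_seq):
        raise ValueError("variant does not fit inside the span")
    if span_seq[rel : rel + len(variant.ref)] != variant.ref:
        raise ValueError(
            f"REF mismatch at {variant.sequence_id}:{variant.position}: "
            f"expected {variant.ref}, span has "
            f"{span_seq[rel : rel + len(variant.ref)]}"
        )
    return span_seq[:rel] + variant.alt + span_seq[rel + len(variant.ref) :]


def longest_perfect_tract_bp(seq: str, motif: Motif) -> int:
    """Length in bp of the longest whole-unit tandem run of the motif's
    rotation class within ``seq``."""
    m = motif.size
    mclass = motif.rotation_class
    best = 0
    i = 0
    n = len(seq)
    while i + m <= n:
        word = seq[i : i + m]
        if "N" not in word and rotation_canonical(word) == mclass:
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            units = (j - i) // m
            best = max(best, units * m)
            i = j - m + 1
        else:
            i += 1
    return best


def _locus_sequence(locus: MicrosatelliteLocus) -> str:
    if locus.sequence:
        return locus.sequence
    # perfect locus sequences are reconstructable from the leading unit
    units = locus.length // locus.motif.size
    return locus.motif.sequence * units


def _affected_interior(
    locus: MicrosatelliteLocus, variant: PopulationVariant
) -> bool:
    """True if the variant's affected span lies inside the locus excluding
    the first and last repeat unit (the unit as a whole, motif.size bases
    at each end)."""
    m = locus.motif.size
    interior_start = locus.start + m
    interior_end = locus.end - m
    pos0 = variant.position - 1
    if variant.kind == "SNP":
        return interior_start <= pos0 < interior_end
    if len(variant.ref) > len(variant.alt):  # deletion of ref[1:]
        del_start = pos0 + 1
        del_end = pos0 + len(variant.ref)
        return interior_start <= del_start and del_end <= interior_end
    # insertion of alt[1:] between pos0 and pos0+1
    point = pos0 + 1
    return interior_start <= point <= interior_end


def classify_fate(
    locus: MicrosatelliteLocus,
    variant: PopulationVariant,
    cfg: ThresholdConfig,
) -> str:
    """Death vs degeneration: apply the variant to the locus sequence and
    test whether any residual perfect tandem stretch of the motif reaches
    the threshold length for that motif size."""
    alt_seq = apply_variant_to_span(
        _locus_sequence(locus), locus.start, variant
    )
    residual = longest_perfect_tract_bp(alt_seq, locus.motif)
    threshold = cfg.threshold_bp(locus.motif.size)
    return FATE_DEGENERATION if residual >= threshold else FATE_DEATH


def call_interruptions(
    variants,
    loci,
    cfg: ThresholdConfig,
    af_min: float = DEFAULT_AF_MIN,
    populations=None,
    enforce_window: bool = True,
) -> list[InterruptionCall]:
    """Intersect population variants with perfect microsatellites.

    A variant yields one call per population in which its allele frequency
    is >= ``af_min``, provided (a) its affected span lies inside the locus
    minus the terminal repeat units, (b) for indels the net length change is
    not a whole number of motif units, and (c) the resulting allele is no
    longer a perfect tandem of the motif.
    """
    loci = [l for l in loci if l.status == STATUS_PERFECT]
    if enforce_window:
        loci = [l for l in loci if cfg.in_window(l.motif.size, l.length)]
    by_contig: dict[str, list[MicrosatelliteLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.sequence_id, []).append(locus)
    for contig_loci in by_contig.values():
        contig_loci.sort(key=lambda l: l.start)

    calls: list[InterruptionCall] = []
    for variant in variants:
        for locus in by_contig.get(variant.sequence_id, ()):
            if variant.position - 1 >= locus.end:
                continue
            if variant.position - 1 + max(len(variant.ref), 1) <= locus.start:
                continue
            m = locus.motif.size
            if not _affected_interior(locus, variant):
                continue
            if variant.kind == "indel":
                if abs(variant.net_length_change) % m == 0:
                    continue  # whole-motif (or multiple) indel: slippage, not interruption
                mech = (
                    MECH_INSERTION
                    if variant.net_length_change > 0
                    else MECH_DELETION
                )
            else:
                mech = MECH_SNP
            alt_seq = apply_variant_to_span(
                _locus_sequence(locus), locus.start, variant
            )
            if _is_perfect_tandem(alt_seq, locus.motif):
                continue  # periodicity preserved: not an interruption
            fate = classify_fate(locus, variant, cfg)
            pops = populations or sorted(variant.allele_frequency)
            for pop in pops:
                af = variant.allele_frequency.get(pop, 0.0)
                if af >= af_min:
                    calls.append(
                        InterruptionCall(
                            locus=locus,
                            variant=variant,
                            mechanism=mech,
                            fate=fate,
                            population=pop,
                            allele_frequency=af,
                        )
                    )
    return calls


def _is_perfect_tandem(seq: str, motif: Motif) -> bool:
    m = motif.size
    if len(seq) % m:
        return False
    return longest_perfect_tract_bp(seq, motif) == len(seq)


def sharing_partition(calls: list[InterruptionCall]) -> dict[tuple, int]:
    """Venn partition of distinct (locus, variant) calls by the exact set
    of populations they were called in.  Counts sum to the number of
    distinct calls and are invariant to processing order."""
    membership: dict[tuple, set[str]] = {}
    for call in calls:
        membership.setdefault(call.key, set()).add(call.population)
    partition: dict[tuple, int] = {}
    for pops in membership.values():
        key = tuple(sorted(pops))
        partition[key] = partition.get(key, 0) + 1
    return partition


def sharing_class(populations, n_total: int = 4) -> str:
    k = len(set(populations))
    if k == 1:
        return "population-specific"
    if k == n_total:
        return "common-to-all"
    return f"shared-{k}"


# -- exonic annotation -------------------------------------------------------

EFFECT_FRAMESHIFT = "frameshift"
EFFECT_NONSYNONYMOUS = "nonsynonymous"
EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NONSENSE = "nonsense"
EFFECT_NONCODING = "noncoding"


@dataclass(frozen=True)
class ExonRegion:
    sequence_id: str
    start: int
    end: int
    gene: str


@dataclass(frozen=True)
class CdsRegion:
    sequence_id: str
    start: int
    end: int
    gene: str
    strand: str = "+"
    frame: int = 0


@dataclass(frozen=True)
class AnnotatedCall:
    call: InterruptionCall
    gene: str
    effect: str


def _snp_effect(variant: PopulationVariant, cds: CdsRegion, genome: dict) -> str:
    seq = genome[cds.sequence_id]
    pos0 = variant.position - 1
    if cds.strand == "+":
        offset = pos0 - (cds.start + cds.frame)
        if offset < 0:
            return EFFECT_NONCODING
        codon_start = cds.start + cds.frame + 3 * (offset // 3)
        if codon_start + 3 > cds.end:
            return EFFECT_NONCODING
        codon = seq[codon_start : codon_start + 3]
        idx = pos0 - codon_start
        new_codon = codon[:idx] + variant.alt + codon[idx + 1 :]
    else:
        coding = reverse_complement(seq[cds.start : cds.end])
        cpos = (cds.end - 1 - pos0) - cds.frame
        if cpos < 0:
            return EFFECT_NONCODING
        codon_start = 3 * (cpos // 3)
        if codon_start + 3 > len(coding):
            return EFFECT_NONCODING
        codon = coding[codon_start : codon_start + 3]
        idx = cpos - codon_start
        new_codon = codon[:idx] + reverse_complement(variant.alt) + codon[idx + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == "*" and old_aa != "*":
        return EFFECT_NONSENSE
    if new_aa == old_aa:
        return EFFECT_SYNONYMOUS
    return EFFECT_NONSYNONYMOUS


def annotate_exonic(
    calls: list[InterruptionCall],
    exons: list[ExonRegion],
    cds_regions: list[CdsRegion] | None = None,
    genome: dict | None = None,
) -> tuple[list[AnnotatedCall], list[str]]:
    """Annotate calls overlapping exons with their functional effect.

    Indels with a net length change not divisible by 3 inside a CDS are
    frameshifts; in-frame indels are reported nonsynonymous.  SNP effects
    translate the affected codon (strand- and frame-aware; requires the
    reference ``genome`` mapping).  Exonic positions outside any CDS are
    noncoding (UTR).  The returned gene list is deduplicated.
    """
    cds_regions = cds_regions or []
    annotated: list[AnnotatedCall] = []
    genes: list[str] = []
    seen_keys = set()
    for call in calls:
        pos0 = call.variant.position - 1
        span_end = pos0 + max(len(call.variant.ref), 1)
        exon_hits = [
            e
            for e in exons
            if e.sequence_id == call.locus.sequence_id
            and e.start < span_end
            and pos0 < e.end
        ]
        if not exon_hits:
            continue
        cds_hits = [
            c
            for c in cds_regions
            if c.sequence_id == call.locus.sequence_id
            and c.start <= pos0 < c.end
        ]
        if not cds_hits:
            effect = EFFECT_NONCODING
            gene = exon_hits[0].gene
        else:
            cds = cds_hits[0]
            gene = cds.gene
            if len(cds_hits) > 1:
                warnings.warn(
                    f"variant {call.variant.key} overlaps multiple CDS records; "
                    "using the first"
                )
            if call.variant.kind == "indel":
                net = abs(call.variant.net_length_change)
                effect = (
                    EFFECT_FRAMESHIFT if net % 3 else EFFECT_NONSYNONYMOUS
                )
            else:
                if genome is None:
                    raise ValueError(
                        "SNP effect annotation requires the reference genome"
                    )
                effect = _snp_effect(call.variant, cds, genome)
        annotated.append(AnnotatedCall(call=call, gene=gene, effect=effect))
        if (gene, call.key) not in seen_keys:
            seen_keys.add((gene, call.key))
            if gene not in genes:
                genes.append(gene)
    return annotated, genes


# -- disease-locus allele tabulation ----------------------------------------


@dataclass(frozen=True)
class DiseaseLocus:
    locus_id: str
    sequence_id: str
    start: int  # 0-based
    end: int
    motif: str
    structure: str  # annotated reference repeat structure over [start, end)


@dataclass(frozen=True)
class DiseaseAllele:
    locus_id: str
    population: str
    structure: str
    frequency: float
    is_reference: bool


def tabulate_disease_loci(
    variants,
    disease_loci: list[DiseaseLocus],
    populations=DEFAULT_POPULATIONS,
    af_min: float = DEFAULT_AF_MIN,
) -> tuple[list[DiseaseAllele], list[PopulationVariant]]:
    """Reconstruct per-population allele structures at annotated disease
    microsatellite loci.

    Each qualifying variant (AF >= ``af_min`` in the population, contained
    in the annotated span) yields an alternative allele whose repeat
    structure is re-annotated against the locus motif; the reference allele
    carries the residual frequency.  Variants falling outside the annotated
    structure are returned as flagged/excluded.
    """
    alleles: list[DiseaseAllele] = []
    excluded: list[PopulationVariant] = []
    variants = list(variants)
    for locus in disease_loci:
        ref_seq = parse_structure(locus.structure)
        if len(ref_seq) != locus.end - locus.start:
            raise ValueError(
                f"{locus.locus_id}: structure length {len(ref_seq)} != span "
                f"{locus.end - locus.start}"
            )
        overlapping = []
        for v in variants:
            if v.sequence_id != locus.sequence_id:
                continue
            pos0 = v.position - 1
            if pos0 >= locus.end or pos0 + len(v.ref) <= locus.start:
                continue
            if pos0 < locus.start or pos0 + len(v.ref) > locus.end:
                excluded.append(v)
                continue
            overlapping.append(v)
        for pop in populations:
            variant_total = 0.0
            for v in overlapping:
                af = v.allele_frequency.get(pop, 0.0)
                if af < af_min:
                    continue
                alt_seq = apply_variant_to_span(ref_seq, locus.start, v)
                alleles.append(
                    DiseaseAllele(
                        locus_id=locus.locus_id,
                        population=pop,
                        structure=annotate_structure(alt_seq, locus.motif),
                        frequency=af,
                        is_reference=False,
                    )
                )
                variant_total += af
            alleles.append(
                DiseaseAllele(
                    locus_id=locus.locus_id,
                    population=pop,
                    structure=annotate_structure(ref_seq, locus.motif),
                    frequency=max(0.0, 1.0 - variant_total),
                    is_reference=True,
                )
            )
    return alleles, excluded
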