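import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imsatkit.motifs import Motif
from imsatkit.population_interruptions import (
    CdsRegion,
    DiseaseLocus,
    ExonRegion,
    InterruptionCall,
    PopulationVariant,
    annotate_exonic,
    apply_variant_to_span,
    call_interruptions,
    classify_fate,
    sharing_partition,
    sharing_class,
    tabulate_disease_loci,
)
from imsatkit.repeat_detection import (
    MicrosatelliteLocus,
    STATUS_PERFECT,
    ThresholdConfig,
)
from imsatkit.structures import annotate_structure, parse_structure


def perfect_locus(motif: str, units: int, start: int = 100, chrom: str = "chr1"):
    m = Motif(motif)
    seq = motif * units
    return MicrosatelliteLocus(
        sequence_id=chrom,
        start=start,
        end=start + len(seq),
        motif=m,
        status=STATUS_PERFECT,
        repeat_number=float(units),
        sequence=seq,
    )


def variant(pos: int, ref: str, alt: str, afs=None, chrom: str = "chr1"):
    return PopulationVariant(
        sequence_id=chrom, position=pos, ref=ref, alt=alt,
        allele_frequency=afs or {"AFR": 0.3},
    )


@pytest.fixture(scope="module")
def pop_cfg():
    return ThresholdConfig.preset("population")


# -- calling rules ---------------------------------------------------------------


def test_terminal_unit_variants_are_not_calls(pop_cfg):
    locus = perfect_locus("A", 9)  # spans [100, 109)
    first_unit = variant(101, "A", "T", {"AFR": 0.3})
    last_unit = variant(109, "A", "G", {"AFR": 0.3})
    interior = variant(105, "A", "T", {"AFR": 0.3})
    calls = call_interruptions(
        [first_unit, last_unit, interior], [locus], pop_cfg
    )
    assert [c.variant.position for c in calls] == [105]
    assert calls[0].mechanism == "SNP"


def test_whole_motif_indel_is_not_a_call(pop_cfg):
    locus = perfect_locus("AC", 7)  # 14 bp, window 10-18
    # deletion of one whole AC unit, interior
    whole = variant(104, "CAC", "C", {"AFR": 0.5})
    # 1-bp insertion: net length not a unit multiple
    partial = variant(105, "A", "AT", {"AFR": 0.5})
    calls = call_interruptions([whole, partial], [locus], pop_cfg)
    assert [c.variant.position for c in calls] == [105]
    assert calls[0].mechanism == "indel-insertion"


def test_af_threshold_is_inclusive(pop_cfg):
    locus = perfect_locus("A", 9)
    low = variant(104, "A", "T", {"AFR": 0.04})
    boundary = variant(105, "A", "T", {"AFR": 0.05})
    calls = call_interruptions([low, boundary], [locus], pop_cfg)
    assert [(c.variant.position, c.population) for c in calls] == [(105, "AFR")]


def test_one_call_per_qualifying_population(pop_cfg):
    locus = perfect_locus("A", 9)
    v = variant(105, "A", "T", {"AFR": 0.3, "EUR": 0.2, "ASN": 0.01, "AMR": 0.0})
    calls = call_interruptions([v], [locus], pop_cfg)
    assert sorted(c.population for c in calls) == ["AFR", "EUR"]


def test_out_of_window_loci_are_skipped(pop_cfg):
    long_locus = perfect_locus("A", 15)  # above the 10 bp mono upper bound
    v = variant(107, "A", "T", {"AFR": 0.3})
    assert call_interruptions([v], [long_locus], pop_cfg) == []


def test_multiallelic_record_is_rejected():
    with pytest.raises(ValueError):
        variant(105, "A", "T,G")


@settings(max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=8))
def test_no_call_ever_references_a_terminal_unit_fuzz(offset):
    cfg = ThresholdConfig.preset("population")
    locus = perfect_locus("A", 9)
    v = variant(101 + offset, "A", "T", {"AFR": 0.2})
    calls = call_interruptions([v], [locus], cfg)
    for c in calls:
        pos0 = c.variant.position - 1
        assert locus.start + 1 <= pos0 < locus.end - 1


# -- death vs degeneration --------------------------------------------------------


def test_fate_examples(pop_cfg):
    # (A)10 with a SNP after unit 8: residual (A)8 >= 8 bp -> degeneration
    a10 = perfect_locus("A", 10)
    snp_late = variant(109, "A", "T")
    assert classify_fate(a10, snp_late, pop_cfg) == "degeneration"

    # (A)8 with a mid SNP: residuals (A)3 and (A)4 -> death
    a8 = perfect_locus("A", 8)
    snp_mid = variant(104, "A", "T")
    assert classify_fate(a8, snp_mid, pop_cfg) == "death"

    # (AC)9 with a central 1-bp insertion: both arms below 10 bp -> death
    ac9 = perfect_locus("AC", 9)
    central_ins = variant(109, "A", "AT")
    assert classify_fate(ac9, central_ins, pop_cfg) == "death"


def test_fate_partitions_all_calls(pop_cfg):
    rng = np.random.default_rng(4)
    loci = [perfect_locus("A", 9, start=100 + 60 * i) for i in range(20)]
    variants = [
        variant(
            int(l.start + 1 + rng.integers(1, 8)) + 1, "A",
            str(rng.choice(["T", "C", "G"])), {"AFR": 0.3},
        )
        for l in loci
    ]
    calls = call_interruptions(variants, loci, pop_cfg)
    assert calls
    assert all(c.fate in ("death", "degeneration") for c in calls)


# -- sharing ---------------------------------------------------------------------


def test_sharing_partition_and_classes(pop_cfg):
    locus = perfect_locus("A", 9)
    v_all = variant(105, "A", "T", {p: 0.2 for p in ("AFR", "EUR", "ASN", "AMR")})
    calls = call_interruptions([v_all], [locus], pop_cfg)
    part = sharing_partition(calls)
    assert part == {("AFR", "AMR", "ASN", "EUR"): 1}
    assert sharing_class(("AFR", "AMR", "ASN", "EUR")) == "common-to-all"
    assert sharing_class(("AFR",)) == "population-specific"
    assert sharing_class(("AFR", "EUR")) == "shared-2"


def test_single_population_input_all_specific(pop_cfg):
    loci = [perfect_locus("A", 9, start=100 + 40 * i) for i in range(3)]
    vs = [variant(l.start + 5, "A", "T", {"EUR": 0.2}) for l in loci]
    calls = call_interruptions(vs, loci, pop_cfg)
    part = sharing_partition(calls)
    assert part == {("EUR",): 3}
    # invariant to processing order
    assert sharing_partition(list(reversed(calls))) == part


# -- exonic annotation -------------------------------------------------------------


def _call_for(locus, v, pop_cfg):
    calls = call_interruptions([v], [locus], pop_cfg)
    assert len(calls) == 1
    return calls[0]


def test_exonic_effects(pop_cfg):
    # CDS starts at 90 in frame 0; (A)9 sits at [100, 109) so the codon at
    # pos0 102 reads AAA; an (AC)7 locus follows at [110, 124)
    a_locus = perfect_locus("A", 9)
    ac_locus = perfect_locus("AC", 7, start=110)
    genome = {
        "chr1": "G" * 90 + "ATGGCAGCTC" + "A" * 9 + "G" + "AC" * 7
        + "CATCC" + "G" * 40
    }
    exons = [ExonRegion("chr1", 85, 140, "GENE1")]
    cds = [CdsRegion("chr1", 90, 138, "GENE1", "+", 0)]

    # A->T at the first base of codon AAA (pos0 102) creates TAA: nonsense
    nonsense = _call_for(a_locus, variant(103, "A", "T", {"AFR": 0.2}), pop_cfg)
    # 1-bp insertion into the dinucleotide repeat: frameshift
    fs = _call_for(ac_locus, variant(115, "A", "AT", {"AFR": 0.2}), pop_cfg)
    annotated, genes = annotate_exonic([nonsense, fs], exons, cds, genome)
    effects = {a.call.variant.position: a.effect for a in annotated}
    assert effects[103] == "nonsense"
    assert effects[115] == "frameshift"
    assert genes == ["GENE1"]


def test_exon_without_cds_is_noncoding(pop_cfg):
    locus = perfect_locus("A", 9)
    call = _call_for(locus, variant(105, "A", "T", {"AFR": 0.2}), pop_cfg)
    annotated, genes = annotate_exonic(
        [call], [ExonRegion("chr1", 95, 130, "UTRGENE")], [], None
    )
    assert annotated[0].effect == "noncoding"
    assert genes == ["UTRGENE"]


def test_gene_list_deduplicated(pop_cfg):
    locus = perfect_locus("A", 9)
    calls = [
        _call_for(locus, variant(pos, "A", "T", {"AFR": 0.2}), pop_cfg)
        for pos in (104, 106)
    ]
    _, genes = annotate_exonic(
        calls, [ExonRegion("chr1", 95, 130, "G1")], [], None
    )
    assert genes == ["G1"]


# -- structure strings and disease loci --------------------------------------------


def test_structure_round_trip():
    structure = "(CAG)_6 CAA (CAG)_9"
    seq = parse_structure(structure)
    assert seq == "CAG" * 6 + "CAA" + "CAG" * 9
    assert annotate_structure(seq, "CAG") == structure
    assert parse_structure("[A]_3 T [A]_4") == "AAATAAAA"


def test_disease_locus_reconstruction():
    structure = "(CAG)_6 CAA (CAG)_9"
    seq = parse_structure(structure)
    start = 500
    locus = DiseaseLocus("AIB1-like", "chr1", start, start + len(seq), "CAG", structure)

    # variant removing the interruption: CAA -> CAG at the A (offset 20)
    pos = start + 20 + 1
    v = PopulationVariant(
        "chr1", pos, "A", "G",
        {"AFR": 0.3, "EUR": 0.1, "ASN": 0.02, "AMR": 0.0},
    )
    alleles, excluded = tabulate_disease_loci([v], [locus])
    assert excluded == []
    by_pop = {}
    for allele in alleles:
        by_pop.setdefault(allele.population, []).append(allele)
    # AFR and EUR see the perfected allele; ASN/AMR only the reference
    afr = {a.structure: a.frequency for a in by_pop["AFR"]}
    assert afr["(CAG)_16"] == pytest.approx(0.3)
    assert afr[structure] == pytest.approx(0.7)
    assert {a.structure for a in by_pop["ASN"]} == {structure}
    for pop_alleles in by_pop.values():
        assert sum(a.frequency for a in pop_alleles) == pytest.approx(1.0)


def test_disease_locus_variant_outside_span_is_flagged():
    structure = "(CAG)_4"
    locus = DiseaseLocus("L", "chr1", 100, 112, "CAG", structure)
    outside = PopulationVariant("chr1", 111, "GCC", "G", {"AFR": 0.3})
    alleles, excluded = tabulate_disease_loci([outside], [locus])
    assert excluded == [outside]
    assert all(a.is_reference for a in alleles)


def test_apply_variant_checks_ref():
    with pytest.raises(ValueError):
        apply_variant_to_span("AAAA", 100, variant(102, "T", "G"))
    assert apply_variant_to_span("AAAA", 100, variant(102, "A", "G")) == "AGAA"
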