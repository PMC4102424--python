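import numpy as np
import pytest

from imsatkit import io as kio
from imsatkit.polymerase_fidelity import classify_events
from imsatkit.population_interruptions import call_interruptions, sharing_partition
from imsatkit.repeat_detection import (
    STATUS_COMPOUND,
    STATUS_PERFECT,
    ThresholdConfig,
    scan_fasta,
)
from imsatkit.synthetic_data import (
    LABEL_EXPECTED,
    LABEL_LD_PARTNER,
    default_reporter_template,
    gen_genome,
    gen_mutant_collection,
    gen_ortholog_pairs,
    gen_population_vcf,
    write_vcf,
)


def truth_key_set(truth):
    return {
        (
            t["start"], t["end"], t["status"], t["repeat_number"],
            tuple((i["offset"], i["sequence"]) for i in t["interruptions"]),
        )
        for t in truth
    }


def detected_key_set(loci):
    return {
        (
            l.start, l.end, l.status, int(l.repeat_number),
            tuple((i.offset_in_locus, i.sequence) for i in l.interruptions),
        )
        for l in loci
    }


# -- genome generator ---------------------------------------------------------


def test_empty_genome_is_flank_only(primate_cfg):
    genome, truth = gen_genome(rng_seed=0)
    assert truth == []
    assert scan_fasta(genome, primate_cfg) == []


def test_generators_are_deterministic():
    g1, t1 = gen_genome(n_perfect=10, n_interrupted=5, rng_seed=3)
    g2, t2 = gen_genome(n_perfect=10, n_interrupted=5, rng_seed=3)
    assert g1 == g2 and t1 == t2
    g3, _ = gen_genome(n_perfect=10, n_interrupted=5, rng_seed=4)
    assert g3 != g1


@pytest.mark.parametrize("rng_seed", [7, 11])
def test_scan_recovers_planted_truth_exactly(primate_cfg, rng_seed):
    genome, truth = gen_genome(
        n_perfect=40, n_interrupted=30, n_compound=5,
        preset="primate", rng_seed=rng_seed,
    )
    loci = scan_fasta(genome, primate_cfg)
    assert detected_key_set(loci) == truth_key_set(truth)


def test_planted_compound_pair_is_flagged(primate_cfg):
    genome, truth = gen_genome(n_compound=3, rng_seed=1)
    loci = scan_fasta(genome, primate_cfg)
    assert len(loci) == 6
    assert all(l.status == STATUS_COMPOUND for l in loci)
    assert all(t["status"] == STATUS_COMPOUND for t in truth)


def test_population_preset_loci_fit_windows(population_cfg):
    genome, truth = gen_genome(n_perfect=30, preset="population", rng_seed=9)
    for t in truth:
        assert population_cfg.in_window(len(t["motif"]), t["end"] - t["start"])


def test_flank_spacing(primate_cfg):
    genome, truth = gen_genome(n_perfect=10, rng_seed=5, flank_len=35)
    starts = sorted((t["start"], t["end"]) for t in truth)
    prev_end = 0
    for start, end in starts:
        assert start - prev_end >= 30
        prev_end = end
    with pytest.raises(ValueError):
        gen_genome(n_perfect=1, flank_len=10)


# -- ortholog generator -------------------------------------------------------


def test_ortholog_null_case_k1():
    perfect, interrupted, truth = gen_ortholog_pairs(
        n_perfect=3000, n_interrupted=3000, base_rate=0.05,
        fold_reduction=1.0, generations=20, rng_seed=14,
    )
    exp = truth["expected_mutability"]
    assert exp["perfect"] == exp["interrupted"]
    from imsatkit.ortholog_mutability import mutability

    assert mutability(perfect) == pytest.approx(mutability(interrupted), rel=0.15)


def test_ortholog_zero_generations_zero_mutability():
    perfect, interrupted, _ = gen_ortholog_pairs(
        n_perfect=100, n_interrupted=100, base_rate=0.05,
        fold_reduction=4, generations=0, rng_seed=0,
    )
    from imsatkit.ortholog_mutability import mutability

    assert mutability(perfect) == 0.0
    assert mutability(interrupted) == 0.0


def test_ortholog_determinism():
    a = gen_ortholog_pairs(n_perfect=50, n_interrupted=50, rng_seed=6)
    b = gen_ortholog_pairs(n_perfect=50, n_interrupted=50, rng_seed=6)
    assert a[0] == b[0] and a[1] == b[1]


# -- population VCF generator --------------------------------------------------


@pytest.fixture(scope="module")
def vcf_bundle(tmp_path_factory):
    genome, locus_truth, variants, manifest = gen_population_vcf(
        rng_seed=5, n_ld_pairs=2, planted_af_vectors=[(0.1, 0.2, 0.3, 0.4)]
    )
    path = tmp_path_factory.mktemp("vcf") / "pop.vcf"
    chrom = next(iter(genome))
    write_vcf(variants, path, contig=chrom, contig_length=len(genome[chrom]))
    return genome, locus_truth, variants, manifest, path


def test_vcf_round_trip(vcf_bundle):
    genome, _, variants, _, path = vcf_bundle
    parsed = kio.read_vcf_variants(path)
    assert len(parsed) == len(variants)
    by_pos = {v.position: v for v in variants}
    for p in parsed:
        v = by_pos[p.position]
        assert (p.ref, p.alt) == (v.ref, v.alt)
        for pop, af in v.afs.items():
            assert p.allele_frequency[pop] == pytest.approx(af, abs=1e-4)


def test_all_decoys_yield_no_calls(population_cfg, vcf_bundle):
    genome, _, variants, _, path = vcf_bundle
    loci = [
        l for l in scan_fasta(genome, population_cfg)
        if l.status == STATUS_PERFECT
    ]
    parsed = kio.read_vcf_variants(path)
    decoy_positions = {
        v.position for v in variants
        if v.label not in (LABEL_EXPECTED, LABEL_LD_PARTNER, "noise-snp")
    }
    calls = call_interruptions(parsed, loci, population_cfg)
    assert decoy_positions
    assert not decoy_positions & {c.variant.position for c in calls}


def test_sharing_plan_recovered_exactly(population_cfg, vcf_bundle):
    genome, _, variants, manifest, path = vcf_bundle
    loci = [
        l for l in scan_fasta(genome, population_cfg)
        if l.status == STATUS_PERFECT
    ]
    calls = call_interruptions(kio.read_vcf_variants(path), loci, population_cfg)
    part = sharing_partition(calls)
    expected = {}
    for v in variants:
        if v.label == LABEL_EXPECTED:
            expected[v.sharing_populations] = (
                expected.get(v.sharing_populations, 0) + 1
            )
    assert part == expected


def test_planted_haplotypes_are_phased_and_polymorphic(vcf_bundle):
    _, _, variants, _, path = vcf_bundle
    haps = kio.read_vcf_haplotypes(path)
    planted = [v for v in variants if v.haplotypes]
    assert planted
    for v in planted:
        stored = haps[(v.chrom, v.position, v.ref, v.alt)]
        assert stored == next(iter(v.haplotypes.values()))
        assert 0 < sum(stored) < len(stored)


# -- mutant collection ---------------------------------------------------------


def test_planted_unit_deletions_classify_as_planted(gt10_template):
    counts, records, truth = gen_mutant_collection(
        gt10_template, {"unit-deletion": 1.0}, n_mutants=8, rng_seed=2
    )
    for rec in records:
        events = classify_events(rec, gt10_template)
        assert [e.kind for e in events] == ["unit-based indel"]
        assert events[0].ref in ("GT", "TG")


def test_planted_spectrum_recovered(gt10_template):
    spectrum = {
        "interruption-substitution": 0.6,
        "interruption-deletion": 0.29,
        "interruption-insertion": 0.11,
    }
    counts, records, truth = gen_mutant_collection(
        gt10_template, spectrum, n_mutants=100, rng_seed=4
    )
    planted = truth["planted_classes"]
    assert planted.count("interruption-substitution") == 60
    from imsatkit.polymerase_fidelity import spectrum_report

    for rec in records:
        classify_events(rec, gt10_template)
    props = spectrum_report(records)["proportions"]
    assert props["substitution"] == pytest.approx(0.60)
    assert props["deletion"] == pytest.approx(0.29)
    assert props["insertion"] == pytest.approx(0.11)


def test_mf_triple_realised(gt10_template):
    from imsatkit.polymerase_fidelity import mutant_frequency, pol_ef

    counts, _, truth = gen_mutant_collection(
        gt10_template, {"unit-deletion": 1.0}, n_mutants=5,
        mf_triple=(5e-4, 1e-4, 1e-4), rng_seed=0,
    )
    ef = pol_ef(
        mutant_frequency(counts["reaction"]),
        mutant_frequency(counts["background"]),
        mutant_frequency(counts["outside"]),
    )
    assert ef == pytest.approx(3e-4)
    assert truth["expected_pol_ef"] == pytest.approx(3e-4)


def test_spectrum_must_sum_to_one(gt10_template):
    with pytest.raises(ValueError):
        gen_mutant_collection(gt10_template, {"unit-deletion": 0.7}, 10)
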