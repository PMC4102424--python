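"""Synthetic datasets with full ground truth for every pipeline stage.

Generators emit (data, truth) pairs: contigs with planted perfect,
interrupted and compound microsatellites; two-species ortholog cohorts
evolved under a symmetric stepwise slippage model with an
interruption-dependent rate reduction; multi-population variant sets with
controlled allele frequencies, sharing classes and decoy records; and
reporter-assay mutant collections with planted error spectra.  Every
generator is deterministic under (seed, parameters), and the truth object
alone suffices to score pipeline output.

Planted loci are separated by non-repetitive flanks (rejection-sampled so
they contain no seed-length repeats and do not extend or bridge adjacent
loci), which makes detection unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .motifs import is_primitive, rotation_canonical
from .ortholog_mutability import OrthologPair
from .polymerase_fidelity import ReporterTemplate, ColonyCounts, MutantRecord
from .population_interruptions import DEFAULT_POPULATIONS
from .repeat_detection import (
    PRIMATE_MIN_UNITS,
    STATUS_COMPOUND,
    STATUS_INTERRUPTED,
    STATUS_PERFECT,
    ThresholdConfig,
)

BASES = "ACGT"
MIN_FLANK_BP = 30


# --------------------------------------------------------------------------
# genomes with planted loci
# --------------------------------------------------------------------------


def _random_primitive_motif(rng: np.random.Generator, size: int) -> str:
    while True:
        motif = "".join(rng.choice(list(BASES), size=size))
        if is_primitive(motif):
            return motif


def _has_forbidden_repeat(seq: str, cfg: ThresholdConfig) -> bool:
    """True if any periodic run long enough to seed (with a 2-unit safety
    margin, floored at 2 units) occurs in ``seq``."""
    n = len(seq)
    for m, thr in cfg.min_units.items():
        limit = max(2, thr - 2)
        i = 0
        while i + m <= n:
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            if (j - i) // m >= limit:
                return True
            i = max(i + 1, j - m + 1)
    return False


def _starts_with_two_units(seq: str, mclass: str, m: int) -> bool:
    """True when ``seq`` begins with >= 2 complete units of one rotation of
    the motif class (the extension absorption rule)."""
    if len(seq) < 2 * m:
        return False
    unit = seq[:m]
    return rotation_canonical(unit) == mclass and seq[m : 2 * m] == unit


def _ends_with_two_units(seq: str, mclass: str, m: int) -> bool:
    if len(seq) < 2 * m:
        return False
    unit = seq[-m:]
    return rotation_canonical(unit) == mclass and seq[-2 * m : -m] == unit


def _clean_after_locus(flank: str, locus_seq: str, mclass: str, m: int) -> bool:
    """Flank immediately 3' of a planted locus must not extend it: no whole
    continuation unit, and no >= 2-unit same-class run within gap reach."""
    if flank[:m] == locus_seq[-m:]:
        return False
    return not any(
        _starts_with_two_units(flank[g:], mclass, m) for g in range(m + 1)
    )


def _clean_before_locus(flank: str, locus_seq: str, mclass: str, m: int) -> bool:
    """Flank immediately 5' of a planted locus must not shift its periodic
    tract start (no 1-base phase continuation) nor offer an absorbable run."""
    if flank and flank[-1] == locus_seq[m - 1]:
        return False
    return not any(
        _ends_with_two_units(flank[: len(flank) - g], mclass, m)
        for g in range(m + 1)
    )


def _make_flank(
    rng: np.random.Generator,
    length: int,
    cfg: ThresholdConfig,
    left_locus: tuple[str, str, int] | None,
    right_locus: tuple[str, str, int] | None,
    max_tries: int = 5000,
) -> str:
    """Random flank free of seedable repeats and junction artefacts.
    ``left_locus``/``right_locus`` are (sequence, rotation class, motif size)
    of the adjacent planted loci, if any."""
    for _ in range(max_tries):
        flank = "".join(rng.choice(list(BASES), size=length))
        if _has_forbidden_repeat(flank, cfg):
            continue
        if left_locus and not _clean_after_locus(
            flank, left_locus[0], left_locus[1], left_locus[2]
        ):
            continue
        if right_locus and not _clean_before_locus(
            flank, right_locus[0], right_locus[1], right_locus[2]
        ):
            continue
        return flank
    raise RuntimeError("could not sample a clean flank (infeasible packing)")


def _gap_is_clean(arm1: str, gap: str, arm2: str, mclass: str, m: int) -> bool:
    """The detector must absorb across exactly the planted gap: at every
    shorter gap offset, no >= 2-unit run may start (rightward scan) or end
    (leftward scan)."""
    right_context = gap + arm2
    for g in range(len(gap)):
        if _starts_with_two_units(right_context[g:], mclass, m):
            return False
    left_context = arm1 + gap
    for g in range(len(gap)):
        tail = left_context[: len(left_context) - g]
        if len(tail) >= 2 * m:
            unit = tail[-m:]
            if rotation_canonical(unit) == mclass and tail[-2 * m : -m] == unit:
                return False
    return True


@dataclass
class PlantedLocus:
    motif: str
    status: str
    sequence: str
    repeat_number: int
    interruptions: list[dict] = field(default_factory=list)
    start: int = -1
    end: int = -1
    chrom: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _build_perfect(rng: np.random.Generator, cfg: ThresholdConfig) -> PlantedLocus:
    size = int(rng.integers(1, 5))
    motif = _random_primitive_motif(rng, size)
    thr = cfg.min_units[size]
    if cfg.length_window_bp:
        lo, hi = cfg.length_window_bp[size]
        units = int(rng.integers(max(thr, -(-lo // size)), hi // size + 1))
    else:
        units = int(rng.integers(thr, thr + 7))
    return PlantedLocus(
        motif=motif,
        status=STATUS_PERFECT,
        sequence=motif * units,
        repeat_number=units,
    )


def _build_interrupted(
    rng: np.random.Generator, cfg: ThresholdConfig, max_tries: int = 500
) -> PlantedLocus:
    size = int(rng.integers(1, 5))
    motif = _random_primitive_motif(rng, size)
    mclass = rotation_canonical(motif)
    thr = cfg.min_units[size]
    for _ in range(max_tries):
        u1 = int(rng.integers(thr, thr + 4))
        u2 = int(rng.integers(2, thr + 2))
        if rng.random() < 0.5:
            u1, u2 = u2, u1
        if max(u1, u2) < thr:
            continue
        gap_len = int(rng.integers(1, size + 1))
        gap = "".join(rng.choice(list(BASES), size=gap_len))
        arm1, arm2 = motif * u1, motif * u2
        if not _gap_is_clean(arm1, gap, arm2, mclass, size):
            continue
        seq = arm1 + gap + arm2
        return PlantedLocus(
            motif=motif,
            status=STATUS_INTERRUPTED,
            sequence=seq,
            repeat_number=u1 + u2,
            interruptions=[
                {"offset": len(arm1), "length": gap_len, "sequence": gap}
            ],
        )
    raise RuntimeError("could not sample a clean interrupted locus")


def _build_compound(
    rng: np.random.Generator, cfg: ThresholdConfig, max_tries: int = 500
) -> tuple[PlantedLocus, PlantedLocus, str]:
    """Two adjacent seeds of different motif classes (both discarded)."""
    for _ in range(max_tries):
        s1 = int(rng.integers(1, 5))
        s2 = int(rng.integers(1, 5))
        m1 = _random_primitive_motif(rng, s1)
        m2 = _random_primitive_motif(rng, s2)
        if rotation_canonical(m1) == rotation_canonical(m2):
            continue
        u1 = cfg.min_units[s1] + int(rng.integers(0, 3))
        u2 = cfg.min_units[s2] + int(rng.integers(0, 3))
        seq1, seq2 = m1 * u1, m2 * u2
        # seed spans must stay exact: the junction may neither continue a
        # phase nor offer an absorbable same-class run to either seed
        if not _clean_after_locus(seq2, seq1, rotation_canonical(m1), s1):
            continue
        if not _clean_before_locus(seq1, seq2, rotation_canonical(m2), s2):
            continue
        if seq2[0] == seq1[-s1]:  # 1-base rightward phase continuation
            continue
        a = PlantedLocus(m1, STATUS_COMPOUND, seq1, u1)
        b = PlantedLocus(m2, STATUS_COMPOUND, seq2, u2)
        return a, b, seq1 + seq2
    raise RuntimeError("could not sample a compound pair")


def gen_genome(
    n_perfect: int = 0,
    n_interrupted: int = 0,
    n_compound: int = 0,
    preset: str = "primate",
    rng_seed: int = 0,
    chrom: str = "chr1",
    flank_len: int = 40,
) -> tuple[dict[str, str], list[dict]]:
    """Generate a contig with planted loci and its ground truth.

    Returns ({chrom: sequence}, truth records).  Compound pairs contribute
    two truth records each, flagged ``compound-discarded``.
    """
    if flank_len < MIN_FLANK_BP:
        raise ValueError(f"flanks must be >= {MIN_FLANK_BP} bp")
    cfg = ThresholdConfig.preset(preset)
    rng = np.random.default_rng(rng_seed)

    blocks: list[list[PlantedLocus]] = []
    for _ in range(n_perfect):
        blocks.append([_build_perfect(rng, cfg)])
    for _ in range(n_interrupted):
        blocks.append([_build_interrupted(rng, cfg)])
    for _ in range(n_compound):
        a, b, _ = _build_compound(rng, cfg)
        blocks.append([a, b])
    order = rng.permutation(len(blocks)) if blocks else []
    blocks = [blocks[i] for i in order]

    pieces: list[str] = []
    pos = 0
    truth: list[dict] = []
    prev_locus: tuple[str, str, int] | None = None
    for block in blocks:
        block_seq = "".join(p.sequence for p in block)
        first = block[0]
        flank = _make_flank(
            rng,
            flank_len,
            cfg,
            left_locus=prev_locus,
            right_locus=(
                block_seq,
                rotation_canonical(first.motif),
                len(first.motif),
            ),
        )
        pieces.append(flank)
        pos += len(flank)
        for planted in block:
            planted.chrom = chrom
            planted.start = pos
            planted.end = pos + len(planted.sequence)
            pieces.append(planted.sequence)
            pos = planted.end
            truth.append(planted.to_dict())
        last = block[-1]
        prev_locus = (block_seq, rotation_canonical(last.motif), len(last.motif))
    pieces.append(
        _make_flank(rng, flank_len, cfg, left_locus=prev_locus, right_locus=None)
    )
    genome = {chrom: "".join(pieces)}
    return genome, truth


# --------------------------------------------------------------------------
# two-species ortholog cohorts under stepwise slippage
# --------------------------------------------------------------------------


def _stepwise_displacement(
    rng: np.random.Generator, n: int, rate: float, generations: int
) -> np.ndarray:
    """Net repeat-number change after ``generations`` rounds of symmetric
    +-1-unit slippage occurring with probability ``rate`` per generation."""
    steps = rng.binomial(generations, rate, size=n)
    up = rng.binomial(steps, 0.5)
    return 2 * up - steps


def gen_ortholog_pairs(
    n_perfect: int = 2000,
    n_interrupted: int = 2000,
    base_rate: float = 0.05,
    fold_reduction: float = 4.0,
    generations: int = 20,
    rng_seed: int = 0,
    motif: str = "A",
    start_repeat_number: int = 20,
) -> tuple[list[OrthologPair], list[OrthologPair], dict]:
    """Evolve perfect and interrupted cohorts from a common ancestor.

    Each lineage accrues +-1-unit slippage at rate ``base_rate`` per
    generation for perfect loci and ``base_rate / fold_reduction`` for
    interrupted loci (the reduction emulates the division of the repeat
    into shorter perfect tracts by the interruption).  Expected mutability
    is 2 * generations * rate, so the planted fold-change equals
    ``fold_reduction`` exactly in expectation.
    """
    if base_rate * generations > start_repeat_number / 2:
        raise ValueError("slippage budget too large for the repeat window")
    rng = np.random.default_rng(rng_seed)
    cohorts: dict[str, list[OrthologPair]] = {}
    rates = {
        "perfect": base_rate,
        "interrupted": base_rate / fold_reduction,
    }
    sizes = {"perfect": n_perfect, "interrupted": n_interrupted}
    for name, rate in rates.items():
        n = sizes[name]
        d_a = _stepwise_displacement(rng, n, rate, generations)
        d_b = _stepwise_displacement(rng, n, rate, generations)
        interrupted = name == "interrupted"
        pairs = [
            OrthologPair(
                locus_id=f"{name}_{i}",
                motif_a=motif,
                motif_b=motif,
                repeat_number_a=float(start_repeat_number + d_a[i]),
                repeat_number_b=float(start_repeat_number + d_b[i]),
                n_interruptions_a=1 if interrupted else 0,
                n_interruptions_b=1 if interrupted else 0,
                interrupting_bases_a="T" if interrupted else "",
                interrupting_bases_b="T" if interrupted else "",
                interruption_context_a="A|A" if interrupted else "",
                interruption_context_b="A|A" if interrupted else "",
                position_class="middle" if interrupted else "",
            )
            for i in range(n)
        ]
        cohorts[name] = pairs
    truth = {
        "rng_seed": rng_seed,
        "base_rate": base_rate,
        "fold_reduction": fold_reduction,
        "generations": generations,
        "expected_mutability": {
            name: 2.0 * generations * rate for name, rate in rates.items()
        },
    }
    return cohorts["perfect"], cohorts["interrupted"], truth


# --------------------------------------------------------------------------
# multi-population variant sets
# --------------------------------------------------------------------------

LABEL_EXPECTED = "expected-call"
LABEL_DECOY_AF = "decoy-AF"
LABEL_DECOY_TERMINAL = "decoy-terminal"
LABEL_DECOY_WHOLE_MOTIF = "decoy-whole-motif"
LABEL_LD_PARTNER = "ld-partner"
LABEL_NOISE_SNP = "noise-snp"


@dataclass
class SyntheticVariant:
    chrom: str
    position: int  # 1-based
    ref: str
    alt: str
    afs: dict[str, float]
    label: str
    locus_index: int = -1
    haplotypes: dict[str, list[int]] | None = None

    @property
    def sharing_populations(self) -> tuple[str, ...]:
        return tuple(sorted(p for p, af in self.afs.items() if af >= 0.05))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def _plant_snp(
    rng: np.random.Generator, genome_seq: str, locus: dict, terminal: bool
) -> tuple[int, str, str]:
    m = len(locus["motif"])
    start, end = locus["start"], locus["end"]
    if terminal:
        offsets = list(range(start, start + m)) + list(range(end - m, end))
        pos0 = int(offsets[int(rng.integers(0, len(offsets)))])
    else:
        pos0 = int(rng.integers(start + m, end - m))
    ref = genome_seq[pos0]
    return pos0 + 1, ref, _other_base(rng, ref)


def _plant_interruption_indel(
    rng: np.random.Generator, genome_seq: str, locus: dict
) -> tuple[int, str, str]:
    """1-bp insertion strictly inside the interior (motif size >= 2)."""
    m = len(locus["motif"])
    start, end = locus["start"], locus["end"]
    pos0 = int(rng.integers(start + m, end - m))  # anchor; insert after it
    anchor = genome_seq[pos0]
    inserted = _other_base(rng, genome_seq[pos0 + 1])
    return pos0 + 1, anchor, anchor + inserted


def _plant_whole_motif_indel(
    rng: np.random.Generator, genome_seq: str, locus: dict
) -> tuple[int, str, str]:
    """Deletion of exactly one whole motif unit inside the interior."""
    m = len(locus["motif"])
    start, end = locus["start"], locus["end"]
    pos0 = int(rng.integers(start + m - 1, end - 2 * m))
    ref = genome_seq[pos0 : pos0 + 1 + m]
    return pos0 + 1, ref, ref[0]


def _random_afs(
    rng: np.random.Generator,
    populations,
    members,
    af_low: float = 0.05,
    af_high: float = 0.5,
) -> dict[str, float]:
    return {
        pop: (
            round(float(rng.uniform(af_low, af_high)), 4)
            if pop in members
            else 0.0
        )
        for pop in populations
    }


def gen_population_vcf(
    sharing_plan: dict[tuple, int] | None = None,
    populations=DEFAULT_POPULATIONS,
    n_decoy_af: int = 5,
    n_decoy_terminal: int = 5,
    n_decoy_whole_motif: int = 5,
    planted_af_vectors: list[tuple] | None = None,
    n_ld_pairs: int = 0,
    n_noise_snps_per_ld: int = 4,
    n_haplotypes: int = 40,
    rng_seed: int = 0,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[dict], list[SyntheticVariant], dict]:
    """Multi-population variant set over planted perfect loci.

    ``sharing_plan`` maps population subsets (tuples of labels) to the
    number of expected interruption calls shared by exactly that subset.
    Decoy records are planted below the allele-frequency cutoff, inside
    terminal repeat units, or as whole-motif indels; none may be called.
    ``planted_af_vectors`` plants variants with exact per-population
    frequencies (for differentiation statistics).  With ``n_ld_pairs`` > 0,
    phased haplotypes are attached: each interruption-causing indel gets a
    perfect-LD SNP partner plus noise SNPs nearby.

    Returns (genome, locus truth, variant truth, manifest).
    """
    if sharing_plan is None:
        sharing_plan = {
            (populations[0],): 4,
            (populations[0], populations[1]): 3,
            tuple(populations[:3]): 2,
            tuple(populations): 3,
        }
    planted_af_vectors = planted_af_vectors or []
    rng = np.random.default_rng(rng_seed)
    n_expected = sum(sharing_plan.values())
    n_variants = (
        n_expected
        + n_decoy_af
        + n_decoy_terminal
        + n_decoy_whole_motif
        + len(planted_af_vectors)
        + n_ld_pairs
    )
    # over-provision: LD indels need di+ motifs with a roomy interior, and
    # whole-motif decoys need interior space, so not every locus qualifies
    genome, locus_truth = gen_genome(
        n_perfect=n_variants + max(4, n_variants // 2),
        preset="population",
        rng_seed=int(rng.integers(2**31)),
        chrom=chrom,
        flank_len=60 if n_ld_pairs else 40,
    )
    seq = genome[chrom]
    variants: list[SyntheticVariant] = []
    unused = list(range(len(locus_truth)))

    def next_locus(min_motif_size: int = 1, min_interior: int = 0) -> int:
        for pos, idx in enumerate(unused):
            locus = locus_truth[idx]
            m = len(locus["motif"])
            interior = locus["end"] - locus["start"] - 2 * m
            if m >= min_motif_size and interior >= min_interior:
                unused.pop(pos)
                return idx
        raise RuntimeError("ran out of planted loci")

    for members, count in sharing_plan.items():
        for _ in range(count):
            idx = next_locus()
            locus = locus_truth[idx]
            pos, ref, alt = _plant_snp(rng, seq, locus, terminal=False)
            variants.append(
                SyntheticVariant(
                    chrom, pos, ref, alt,
                    _random_afs(rng, populations, set(members)),
                    LABEL_EXPECTED, idx,
                )
            )
    for _ in range(n_decoy_af):
        idx = next_locus()
        locus = locus_truth[idx]
        pos, ref, alt = _plant_snp(rng, seq, locus, terminal=False)
        afs = {
            pop: round(float(rng.uniform(0.005, 0.049)), 4) for pop in populations
        }
        variants.append(
            SyntheticVariant(chrom, pos, ref, alt, afs, LABEL_DECOY_AF, idx)
        )
    for _ in range(n_decoy_terminal):
        idx = next_locus()
        locus = locus_truth[idx]
        pos, ref, alt = _plant_snp(rng, seq, locus, terminal=True)
        variants.append(
            SyntheticVariant(
                chrom, pos, ref, alt,
                _random_afs(rng, populations, set(populations)),
                LABEL_DECOY_TERMINAL, idx,
            )
        )
    for _ in range(n_decoy_whole_motif):
        idx = next_locus(min_interior=2)
        locus = locus_truth[idx]
        pos, ref, alt = _plant_whole_motif_indel(rng, seq, locus)
        variants.append(
            SyntheticVariant(
                chrom, pos, ref, alt,
                _random_afs(rng, populations, set(populations)),
                LABEL_DECOY_WHOLE_MOTIF, idx,
            )
        )
    for vec in planted_af_vectors:
        idx = next_locus()
        locus = locus_truth[idx]
        pos, ref, alt = _plant_snp(rng, seq, locus, terminal=False)
        afs = {pop: float(v) for pop, v in zip(populations, vec)}
        variants.append(
            SyntheticVariant(chrom, pos, ref, alt, afs, LABEL_EXPECTED, idx)
        )

    manifest = {
        "rng_seed": rng_seed,
        "populations": list(populations),
        "sharing_plan": {
            "|".join(k): v for k, v in sharing_plan.items()
        },
        "n_haplotypes": n_haplotypes if n_ld_pairs else 0,
    }

    if n_ld_pairs:
        half = n_haplotypes // 2 * 2  # phased diploid samples
        used_positions = {v.position for v in variants}

        def fresh_position(base: int, lo: int, hi: int, sign: int) -> int:
            for _ in range(100):
                pos = base + sign * int(rng.integers(lo, hi))
                if pos not in used_positions and pos >= 1:
                    used_positions.add(pos)
                    return pos
            raise RuntimeError("could not place a flank SNP without collision")

        for _ in range(n_ld_pairs):
            idx = next_locus(min_motif_size=2, min_interior=2)
            locus = locus_truth[idx]
            pos, ref, alt = _plant_interruption_indel(rng, seq, locus)
            used_positions.add(pos)
            hap = rng.integers(0, 2, size=half)
            while hap.sum() in (0, half):
                hap = rng.integers(0, 2, size=half)
            af = round(float(hap.mean()), 4)
            afs = {pop: max(af, 0.05) for pop in populations}
            haps = {pop: hap.tolist() for pop in populations}
            variants.append(
                SyntheticVariant(
                    chrom, pos, ref, alt, afs, LABEL_EXPECTED, idx, haps
                )
            )
            # perfect-LD partner in the right flank, outside any locus
            partner_pos = fresh_position(locus["end"], 5, 25, +1)
            pref = seq[partner_pos - 1]
            variants.append(
                SyntheticVariant(
                    chrom, partner_pos, pref, _other_base(rng, pref),
                    afs, LABEL_LD_PARTNER, idx, haps,
                )
            )
            for k in range(n_noise_snps_per_ld):
                noise_pos = fresh_position(locus["start"], 5 + k, 25 + k, -1)
                nref = seq[noise_pos - 1]
                noise_hap = hap.copy()
                flip = rng.integers(0, half, size=max(1, half // 4))
                noise_hap[flip] = 1 - noise_hap[flip]
                if noise_hap.sum() in (0, half):
                    noise_hap[0] = 1 - noise_hap[0]
                if np.array_equal(noise_hap, hap):
                    noise_hap[0] = 1 - noise_hap[0]
                variants.append(
                    SyntheticVariant(
                        chrom, noise_pos, nref, _other_base(rng, nref),
                        {pop: round(float(noise_hap.mean()), 4) for pop in populations},
                        LABEL_NOISE_SNP, idx,
                        {pop: noise_hap.tolist() for pop in populations},
                    )
                )

    variants.sort(key=lambda v: v.position)
    return genome, locus_truth, variants, manifest


def write_vcf(
    variants: list[SyntheticVariant],
    path,
    populations=DEFAULT_POPULATIONS,
    contig: str = "chr1",
    contig_length: int = 10_000_000,
) -> None:
    """Serialize synthetic variants as a normalized, biallelic VCF v4.2.

    Per-population frequencies go to ``<POP>_AF`` INFO fields; phased
    haplotypes (when present) become diploid ``GT`` sample columns.
    """
    with_gt = any(v.haplotypes for v in variants)
    n_samples = 0
    if with_gt:
        n_samples = max(
            len(next(iter(v.haplotypes.values()))) for v in variants if v.haplotypes
        ) // 2
    lines = ["##fileformat=VCFv4.2"]
    lines.append(f"##contig=<ID={contig},length={contig_length}>")
    for pop in populations:
        lines.append(
            f'##INFO=<ID={pop}_AF,Number=1,Type=Float,Description='
            f'"{pop} alternate allele frequency">'
        )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if with_gt:
        lines.append(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
        header += ["FORMAT"] + [f"sample{i}" for i in range(n_samples)]
    lines.append("\t".join(header))
    for v in variants:
        info = ";".join(
            f"{pop}_AF={v.afs.get(pop, 0.0):.4f}" for pop in populations
        )
        row = [v.chrom, str(v.position), ".", v.ref, v.alt, ".", "PASS", info]
        if with_gt:
            row.append("GT")
            if v.haplotypes:
                hap = next(iter(v.haplotypes.values()))
                gts = [
                    f"{hap[2 * i]}|{hap[2 * i + 1]}" for i in range(n_samples)
                ]
            else:
                gts = ["0|0"] * n_samples
            row += gts
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# reporter-assay mutant collections
# --------------------------------------------------------------------------


def default_reporter_template(
    repeat_structure: str = "[GT]_10", template_id: str = "synthetic-reporter"
) -> ReporterTemplate:
    """A synthetic in-frame reporter context for desk-scale assays.

    The coding flanks are hand-built synthetic sequence (not the natural
    reporter gene): repeat-free, stop-free in the declared frame, and
    phase-breaking at both repeat junctions so planted events classify
    unambiguously.
    """
    return ReporterTemplate(
        template_id=template_id,
        upstream="ATGGCACTGAACGACTTCCGA",
        repeat_structure=repeat_structure,
        downstream="ACCAGACTCAACGCCATGCTTCACTAA",
        frame_offset=0,
    )

EVENT_UNIT_DELETION = "unit-deletion"
EVENT_UNIT_INSERTION = "unit-insertion"
EVENT_INT_SUB = "interruption-substitution"
EVENT_INT_DEL = "interruption-deletion"
EVENT_INT_INS = "interruption-insertion"

_EVENT_CLASSES = (
    EVENT_UNIT_DELETION,
    EVENT_UNIT_INSERTION,
    EVENT_INT_SUB,
    EVENT_INT_DEL,
    EVENT_INT_INS,
)


def _apply_planted_event(
    rng: np.random.Generator, template: ReporterTemplate, klass: str, seq: str
) -> str:
    r0 = len(template.upstream)
    r1 = r0 + len(template.repeat_seq)
    m = template.motif.size
    if klass == EVENT_UNIT_DELETION:
        return seq[: r1 - m] + seq[r1:]
    if klass == EVENT_UNIT_INSERTION:
        return seq[:r1] + seq[r1 - m : r1] + seq[r1:]
    if klass == EVENT_INT_SUB:
        pos = int(rng.integers(r0 + 1, r1 - 1))
        return seq[:pos] + _other_base(rng, seq[pos]) + seq[pos + 1 :]
    if klass == EVENT_INT_DEL:
        if m < 2:
            raise ValueError("interruption indels need motif size >= 2")
        pos = int(rng.integers(r0 + 1, r1 - 1))
        return seq[:pos] + seq[pos + 1 :]
    if klass == EVENT_INT_INS:
        if m < 2:
            raise ValueError("interruption indels need motif size >= 2")
        pos = int(rng.integers(r0 + 1, r1 - 1))
        return seq[:pos] + _other_base(rng, seq[pos]) + seq[pos:]
    raise ValueError(f"unknown event class {klass!r}")


def _apportion(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n items over exact proportions."""
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def gen_mutant_collection(
    template: ReporterTemplate,
    spectrum: dict[str, float],
    n_mutants: int = 100,
    mf_triple: tuple[float, float, float] = (5e-4, 1e-4, 1e-4),
    rng_seed: int = 0,
    colonies: int = 200_000,
) -> tuple[dict[str, ColonyCounts], list[MutantRecord], dict]:
    """Mutant collection with a planted event-class spectrum.

    ``spectrum`` maps event classes (unit-deletion, unit-insertion,
    interruption-substitution/-deletion/-insertion) to proportions summing
    to 1; class counts are apportioned exactly (largest remainder), so the
    planted spectrum is recovered exactly by classification.  Colony counts
    realise the (observed, ssDNA background, outside-target) mutant
    frequencies in ``mf_triple``.
    """
    for klass in spectrum:
        if klass not in _EVENT_CLASSES:
            raise ValueError(f"unknown event class {klass!r}")
    props = [spectrum.get(k, 0.0) for k in _EVENT_CLASSES]
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("spectrum proportions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    counts = _apportion(n_mutants, props)
    records: list[MutantRecord] = []
    planted: list[str] = []
    for klass, k in zip(_EVENT_CLASSES, counts):
        for _ in range(k):
            mutant = _apply_planted_event(rng, template, klass, template.sequence)
            records.append(
                MutantRecord(
                    template_id=template.template_id,
                    mutant_sequence=mutant,
                    mutant_id=f"mut{len(records)}",
                )
            )
            planted.append(klass)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    planted = [planted[i] for i in order]
    mf_obs, mf_bg, mf_out = mf_triple
    colony_counts = {
        "reaction": ColonyCounts(round(mf_obs * colonies), colonies, "polymerase reaction"),
        "background": ColonyCounts(round(mf_bg * colonies), colonies, "ssDNA background"),
        "outside": ColonyCounts(round(mf_out * colonies), colonies, "outside-target"),
    }
    truth = {
        "rng_seed": rng_seed,
        "spectrum": dict(spectrum),
        "planted_classes": planted,
        "mf_triple": list(mf_triple),
        "expected_pol_ef": max(0.0, mf_obs - mf_bg - mf_out),
    }
    return colony_counts, records, truth


def save_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
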