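"""Mutability of orthologous microsatellites between two genomes.

Mutability is the mean squared difference in repeat number between the two
species' alleles of a locus, computed over cohorts of orthologous loci that
survive eight quality filters (proximity, flank base quality, flank
complexity, flank identity, motif identity, interruption count, interruption
identity, interruption context).  Confidence bands are percentile bootstrap
intervals over loci.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .motifs import rotation_canonical

FILTER_NAMES = (
    "proximity",            # 1: loci within 25 bp of each other
    "flank_quality",        # 2: any flank base with PHRED < 20
    "flank_low_complexity", # 3: low-complexity 20 bp flanks
    "flank_identity",       # 4: flank identity < 85% between species
    "motif_mismatch",       # 5: repeated motif differs between species
    "interruption_count",   # 6: > 2 interruptions in any species
    "interruption_bases",   # 7: interrupting nucleotides differ
    "interruption_context", # 8: repeat bases flanking the interruption differ
)

MIN_LOCUS_DISTANCE_BP = 25
MIN_FLANK_PHRED = 20
MIN_FLANK_IDENTITY = 0.85
MAX_INTERRUPTIONS = 2


@dataclass(frozen=True)
class OrthologPair:
    """One orthologous microsatellite locus observed in two species.

    Species A occupies the "human" slot: stratified analyses bin loci by its
    repeat number.  ``interrupting_bases_*`` hold the concatenated
    interrupting nucleotides; ``interruption_context_*`` the repeat
    nucleotides immediately flanking each interruption (one base each side,
    per interruption, concatenated).  Both are empty strings for perfect
    loci.
    """

    locus_id: str
    motif_a: str
    motif_b: str
    repeat_number_a: float
    repeat_number_b: float
    n_interruptions_a: int = 0
    n_interruptions_b: int = 0
    flank_identity: float = 1.0
    min_flank_phred: int = 60
    flank_low_complexity: bool = False
    distance_to_nearest_locus_bp: int = 10_000
    interrupting_bases_a: str = ""
    interrupting_bases_b: str = ""
    interruption_context_a: str = ""
    interruption_context_b: str = ""
    position_class: str = ""

    @property
    def motif_size(self) -> int:
        return len(self.motif_a)

    @property
    def squared_difference(self) -> float:
        return (self.repeat_number_a - self.repeat_number_b) ** 2


def dust_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the trinucleotide composition of ``seq``;
    a conventional low-complexity proxy."""
    if len(seq) < 3:
        return 0.0
    tris = Counter(seq[i : i + 3] for i in range(len(seq) - 2))
    total = sum(tris.values())
    return -sum((c / total) * math.log2(c / total) for c in tris.values())


def is_low_complexity(
    flank: str, max_run_bp: int = 8, min_entropy: float = 1.5
) -> bool:
    """Flag a flank as low complexity if it contains a mono- or dinucleotide
    tandem run of >= ``max_run_bp`` bp, or its trinucleotide entropy falls
    below ``min_entropy`` bits."""
    n = len(flank)
    for m in (1, 2):
        i = 0
        while i + m <= n:
            j = i + m
            while j < n and flank[j] == flank[j - m]:
                j += 1
            if j - i >= max_run_bp:
                return True
            i = max(i + 1, j - m + 1)
    return dust_entropy(flank) < min_entropy


def filter_orthologs(
    pairs: list[OrthologPair],
) -> tuple[list[OrthologPair], dict[str, int]]:
    """Apply the eight ortholog quality filters in order.

    Returns the surviving pairs and a rejection log counting, per filter,
    the pairs whose *first* failing filter it was.
    """
    kept: list[OrthologPair] = []
    log: dict[str, int] = {name: 0 for name in FILTER_NAMES}
    for pair in pairs:
        failed = _first_failing_filter(pair)
        if failed is None:
            kept.append(pair)
        else:
            log[failed] += 1
    return kept, log


def _first_failing_filter(pair: OrthologPair) -> str | None:
    if pair.distance_to_nearest_locus_bp is None:
        raise ValueError("missing distance_to_nearest_locus_bp (filter proximity)")
    if pair.distance_to_nearest_locus_bp < MIN_LOCUS_DISTANCE_BP:
        return "proximity"
    if pair.min_flank_phred is None:
        raise ValueError("missing min_flank_phred (filter flank_quality)")
    if pair.min_flank_phred < MIN_FLANK_PHRED:
        return "flank_quality"
    if pair.flank_low_complexity:
        return "flank_low_complexity"
    if pair.flank_identity is None:
        raise ValueError("missing flank_identity (filter flank_identity)")
    if pair.flank_identity < MIN_FLANK_IDENTITY:
        return "flank_identity"
    if rotation_canonical(pair.motif_a) != rotation_canonical(pair.motif_b):
        return "motif_mismatch"
    if max(pair.n_interruptions_a, pair.n_interruptions_b) > MAX_INTERRUPTIONS:
        return "interruption_count"
    if pair.interrupting_bases_a != pair.interrupting_bases_b:
        return "interruption_bases"
    if pair.interruption_context_a != pair.interruption_context_b:
        return "interruption_context"
    return None


def mutability(pairs: list[OrthologPair]) -> float:
    """Mean squared repeat-number difference between the two species."""
    if not pairs:
        raise ValueError("mutability of an empty cohort is undefined")
    return float(np.mean([p.squared_difference for p in pairs]))


def bootstrap_ci(
    pairs: list[OrthologPair], B: int = 1000, rng_seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap (2.5th/97.5th) of mutability, resampling loci."""
    if not pairs:
        raise ValueError("cannot bootstrap an empty cohort")
    if B < 1:
        raise ValueError("B must be >= 1")
    sq = np.array([p.squared_difference for p in pairs])
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, len(sq), size=(B, len(sq)))
    boots = sq[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_fold_change_ci(
    reference: list[OrthologPair],
    contrast: list[OrthologPair],
    B: int = 1000,
    rng_seed: int | None = None,
) -> tuple[float, float, float]:
    """Fold-change mutability(reference)/mutability(contrast) with a joint
    percentile bootstrap CI (both cohorts resampled independently).

    Bootstrap replicates with a zero contrast mutability are mapped to
    +inf, which percentile bounds handle naturally.
    """
    if not reference or not contrast:
        raise ValueError("both cohorts must be nonempty")
    ref = np.array([p.squared_difference for p in reference])
    con = np.array([p.squared_difference for p in contrast])
    point = float(np.mean(ref) / np.mean(con)) if np.mean(con) > 0 else math.inf
    rng = np.random.default_rng(rng_seed)
    ref_means = ref[rng.integers(0, len(ref), size=(B, len(ref)))].mean(axis=1)
    con_means = con[rng.integers(0, len(con), size=(B, len(con)))].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.where(con_means > 0, ref_means / con_means, np.inf)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return point, float(lo), float(hi)


@dataclass(frozen=True)
class MutabilityEstimate:
    """Mutability of one stratum, with its percentile bootstrap band."""

    bin_label: tuple
    mu: float
    ci_low: float
    ci_high: float
    n_loci: int
    low_confidence: bool = False


STRATA = ("interruptions", "position", "identity")


def stratified_mutability(
    pairs: list[OrthologPair],
    strata: str = "interruptions",
    B: int = 1000,
    rng_seed: int | None = None,
    min_bin_size: int = 20,
) -> list[MutabilityEstimate]:
    """Mutability per (motif size, species-A repeat-number bin, stratum).

    ``strata`` selects the third binning axis: interruption count
    (``interruptions``), interruption position class (``position``), or
    interrupting-base identity (``identity``).  Motif sizes are never
    pooled.  Bins smaller than ``min_bin_size`` loci are reported but
    flagged ``low_confidence``.
    """
    if strata not in STRATA:
        raise ValueError(f"unknown stratum key {strata!r}; use one of {STRATA}")
    bins: dict[tuple, list[OrthologPair]] = {}
    for p in pairs:
        if strata == "interruptions":
            third = p.n_interruptions_a
        elif strata == "position":
            third = p.position_class or "perfect"
        else:
            third = p.interrupting_bases_a or "perfect"
        key = (p.motif_size, int(round(p.repeat_number_a)), third)
        bins.setdefault(key, []).append(p)
    out = []
    rng = np.random.default_rng(rng_seed)
    for key in sorted(bins, key=str):
        members = bins[key]
        mu = mutability(members)
        lo, hi = bootstrap_ci(members, B=B, rng_seed=int(rng.integers(2**31)))
        out.append(
            MutabilityEstimate(
                bin_label=key,
                mu=mu,
                ci_low=lo,
                ci_high=hi,
                n_loci=len(members),
                low_confidence=len(members) < min_bin_size,
            )
        )
    return out
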