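"""Perfect microsatellite seed detection and iterative extension.

The scan proceeds in two stages, mirroring classic seed-and-extend tandem
repeat pipelines:

1. :func:`find_perfect_seeds` — exhaustive detection of maximal perfect
   tandem repeats ("seeds") of primitive 1-4 bp motifs at or above a
   per-motif-size unit threshold (9/5/4/3 units for mono- through
   tetranucleotides in the default ``primate`` preset).
2. :func:`extend_seed` — iterative bidirectional extension of a focal seed.
   On each flank, runs of >= 2 complete units of the same (rotation-class)
   motif are absorbed, allowing up to ``motif.size`` intervening non-repeat
   bases; each absorbed intervening run becomes an :class:`Interruption`.
   A locus that absorbed at least one interruption is *interrupted*,
   otherwise *perfect*.  A seed of a *different* motif class adjacent to the
   locus marks it *compound-discarded*.

All coordinates are 0-based half-open.  The repeat number of a locus is
``(length - sum of interruption lengths) / motif size`` and is always a
whole number because every absorbed repeat base belongs to a complete unit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import DNA_ALPHABET, Motif, is_primitive, rotation_canonical

STATUS_PERFECT = "perfect"
STATUS_INTERRUPTED = "interrupted"
STATUS_COMPOUND = "compound-discarded"

#: seed thresholds in repeat units, per motif size (comparative-genomics mode)
PRIMATE_MIN_UNITS = {1: 9, 2: 5, 3: 4, 4: 3}
#: locus length windows in bp, per motif size (population variant-calling
#: mode); lower bounds are the mutability thresholds, upper bounds the length
#: up to which short-read indel calls are reliable
POPULATION_WINDOWS_BP = {1: (8, 10), 2: (10, 18), 3: (12, 24), 4: (16, 28)}


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-motif-size seed thresholds, with optional bp length windows.

    ``min_units[m]`` is the minimum number of repeat units (inclusive) for a
    seed of motif size ``m``.  ``length_window_bp``, when set, gives the
    inclusive [low, high] locus length window in bp used to select loci for
    population variant intersection and for death/degeneration calls.
    """

    min_units: dict[int, int]
    length_window_bp: dict[int, tuple[int, int]] | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        for m, u in self.min_units.items():
            if u < 1:
                raise ValueError(f"min units for motif size {m} must be >= 1")
        if self.length_window_bp is not None:
            for m, (lo, hi) in self.length_window_bp.items():
                if lo > hi:
                    raise ValueError(f"window for motif size {m}: {lo} > {hi}")

    @classmethod
    def preset(cls, name: str) -> "ThresholdConfig":
        if name == "primate":
            return cls(min_units=dict(PRIMATE_MIN_UNITS), name="primate")
        if name == "population":
            # seed thresholds derived from the window lower bounds
            min_units = {
                m: -(-lo // m) for m, (lo, _hi) in POPULATION_WINDOWS_BP.items()
            }
            return cls(
                min_units=min_units,
                length_window_bp={
                    m: w for m, w in POPULATION_WINDOWS_BP.items()
                },
                name="population",
            )
        raise ValueError(f"unknown preset {name!r}; use 'primate' or 'population'")

    def threshold_bp(self, motif_size: int) -> int:
        """Mutability threshold in bp for a motif size (window lower bound
        when a window is configured, else min_units * size)."""
        if self.length_window_bp and motif_size in self.length_window_bp:
            return self.length_window_bp[motif_size][0]
        return self.min_units[motif_size] * motif_size

    def in_window(self, motif_size: int, length_bp: int) -> bool:
        if not self.length_window_bp or motif_size not in self.length_window_bp:
            return True
        lo, hi = self.length_window_bp[motif_size]
        return lo <= length_bp <= hi


@dataclass(frozen=True)
class Seed:
    """A maximal perfect tandem repeat at or above the unit threshold."""

    motif: Motif
    start: int
    end: int
    units: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.units * self.motif.size:
            raise ValueError("seed span must equal units * motif size")


@dataclass(frozen=True)
class Interruption:
    """A run of non-repeat bases absorbed inside a locus.

    ``kind`` is mechanistic provenance when known (population calling fills
    it in); sequence-only detection leaves it ``unknown``.
    """

    offset_in_locus: int
    length: int
    sequence: str
    kind: str = "unknown"

    def __post_init__(self) -> None:
        if self.length < 1 or len(self.sequence) != self.length:
            raise ValueError("interruption length/sequence mismatch")


@dataclass(frozen=True)
class MicrosatelliteLocus:
    sequence_id: str
    start: int
    end: int
    motif: Motif
    interruptions: tuple[Interruption, ...] = ()
    status: str = STATUS_PERFECT
    repeat_number: float = 0.0
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        interrupting = sum(i.length for i in self.interruptions)
        if (self.length - interrupting) % self.motif.size:
            raise ValueError("repeat bases are not whole motif units")
        expected = (self.length - interrupting) / self.motif.size
        if abs(expected - self.repeat_number) > 1e-9:
            raise ValueError("repeat_number inconsistent with span")
        for i in self.interruptions:
            if i.length > self.motif.size:
                raise ValueError("interruption longer than motif size")


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - (DNA_ALPHABET | {"N"}):
        bad = sorted(set(seq) - (DNA_ALPHABET | {"N"}))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return seq


def find_perfect_seeds(seq: str, cfg: ThresholdConfig) -> list[Seed]:
    """Exhaustively find maximal perfect tandem-repeat seeds.

    A seed is anchored at the start of a maximal periodic tract (it cannot be
    slid or extended left or right in the same phase) and trimmed to whole
    units.  Motifs that are repeats of a shorter motif are reported under the
    shorter motif only; N bases terminate tracts.
    """
    seq = _validate_sequence(seq)
    n = len(seq)
    seeds: list[Seed] = []
    for m in sorted(cfg.min_units):
        thr = cfg.min_units[m]
        i = 0
        while i + m <= n:
            word = seq[i : i + m]
            if "N" in word or not is_primitive(word):
                i += 1
                continue
            # periodic tract starting at i: extend while seq[j] == seq[j - m]
            j = i + m
            while j < n and seq[j] != "N" and seq[j] == seq[j - m]:
                j += 1
            units = (j - i) // m
            if units >= thr:
                seeds.append(Seed(Motif(word), i, i + units * m, units))
            # next tract of period m can only start after this one ends
            # minus (m - 1) overlap; tract starts are where periodicity broke
            i = j - m + 1 if j - m + 1 > i else i + 1
    seeds.sort(key=lambda s: (s.start, s.motif.size, s.motif.sequence))
    return seeds


def _run_units_right(seq: str, pos: int, motif_class: str, m: int) -> int:
    """Complete units of a single motif rotation in the tandem run starting
    at ``pos`` (0 if the unit there is not in the motif class)."""
    n = len(seq)
    if pos + m > n:
        return 0
    word = seq[pos : pos + m]
    if "N" in word or rotation_canonical(word) != motif_class:
        return 0
    j = pos + m
    while j < n and seq[j] != "N" and seq[j] == seq[j - m]:
        j += 1
    return (j - pos) // m


def _run_units_left(seq: str, pos: int, motif_class: str, m: int) -> int:
    """Complete units of a single motif rotation in the tandem run ending
    exactly at ``pos``."""
    if pos - m < 0:
        return 0
    word = seq[pos - m : pos]
    if "N" in word or rotation_canonical(word) != motif_class:
        return 0
    j = pos - m - 1
    while j >= 0 and seq[j] != "N" and seq[j] == seq[j + m]:
        j -= 1
    return (pos - (j + 1)) // m


def extend_seed(
    seq: str,
    focal: Seed,
    cfg: ThresholdConfig,
    sequence_id: str = "seq",
    all_seeds: list[Seed] | None = None,
) -> MicrosatelliteLocus:
    """Iteratively extend a focal seed into a microsatellite locus.

    On each flank the nearest run of >= 2 complete same-class units is
    absorbed, provided at most ``motif.size`` non-repeat bases intervene;
    those bases become an interruption.  Terminal additions of exactly one
    complete unit are rejected.  Extension halts when neither flank yields a
    run.  Adjacency (within ``motif.size`` bp) to a seed of a different motif
    class marks the locus compound-discarded.
    """
    seq = _validate_sequence(seq)
    m = focal.motif.size
    mclass = focal.motif.rotation_class
    s, e = focal.start, focal.end
    left_breaks: list[tuple[int, int]] = []  # (start, length) of interruptions
    right_breaks: list[tuple[int, int]] = []

    grew = True
    while grew:
        grew = False
        # right flank: smallest gap first (gap 0 = contiguous, no interruption)
        for g in range(0, m + 1):
            units = _run_units_right(seq, e + g, mclass, m)
            if units >= 2:
                if g:
                    right_breaks.append((e, g))
                e = e + g + units * m
                grew = True
                break
        # left flank
        for g in range(0, m + 1):
            units = _run_units_left(seq, s - g, mclass, m)
            if units >= 2:
                if g:
                    left_breaks.append((s - g, g))
                s = s - g - units * m
                grew = True
                break

    interruptions = tuple(
        Interruption(b - s, length, seq[b : b + length])
        for b, length in sorted(left_breaks + right_breaks)
    )
    status = STATUS_INTERRUPTED if interruptions else STATUS_PERFECT

    if all_seeds is None:
        all_seeds = find_perfect_seeds(seq, cfg)
    for other in all_seeds:
        if other.motif.rotation_class == mclass:
            continue
        if other.start <= e + m and other.end >= s - m:
            status = STATUS_COMPOUND
            break

    interrupting = sum(i.length for i in interruptions)
    locus = MicrosatelliteLocus(
        sequence_id=sequence_id,
        start=s,
        end=e,
        motif=Motif(seq[s : s + m]),
        interruptions=interruptions,
        status=status,
        repeat_number=(e - s - interrupting) / m,
        sequence=seq[s:e],
    )
    locus.validate()
    return locus


def scan_sequence(
    seq: str, cfg: ThresholdConfig, sequence_id: str = "seq"
) -> list[MicrosatelliteLocus]:
    """Find seeds and extend each into a locus, deduplicating loci reached
    from multiple seeds.  Output is sorted by start coordinate."""
    seq = _validate_sequence(seq)
    seeds = find_perfect_seeds(seq, cfg)
    loci: dict[tuple, MicrosatelliteLocus] = {}
    for seed in seeds:
        locus = extend_seed(seq, seed, cfg, sequence_id, all_seeds=seeds)
        key = (locus.start, locus.end, locus.motif.rotation_class)
        if key not in loci:
            loci[key] = locus
    out = sorted(loci.values(), key=lambda l: (l.start, l.end, l.motif.sequence))
    return out


def scan_fasta(
    records: dict[str, str], cfg: ThresholdConfig
) -> list[MicrosatelliteLocus]:
    """Scan every record of a FASTA-like mapping {id: sequence}."""
    loci: list[MicrosatelliteLocus] = []
    for name, seq in records.items():
        loci.extend(scan_sequence(seq, cfg, sequence_id=name))
    return loci


POSITION_MIDDLE = "middle"
POSITION_FRINGE = "fringe"
POSITION_OTHER = "other"


def interruption_position_class(
    locus: MicrosatelliteLocus, interruption: Interruption
) -> str:
    """Classify an interruption by its midpoint position within the locus:
    *middle* = central 25% band (midpoint/length in [0.375, 0.625)),
    *fringe* = outer 25% at either end (< 0.25 or >= 0.75), else *other*."""
    L = locus.length
    if L <= 0:
        raise ValueError("locus has non-positive length")
    if not 0 <= interruption.offset_in_locus <= L - interruption.length:
        raise ValueError("interruption lies outside the locus")
    frac = (interruption.offset_in_locus + interruption.length / 2.0) / L
    if 0.375 <= frac < 0.625:
        return POSITION_MIDDLE
    if frac < 0.25 or frac >= 0.75:
        return POSITION_FRINGE
    return POSITION_OTHER
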