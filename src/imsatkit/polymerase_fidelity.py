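"""DNA-polymerase error frequencies and mutational spectra from
reporter-assay data.

The assay inserts a microsatellite in-frame within a selectable reporter
gene; synthesis errors that inactivate the reporter are scored as mutant
colonies.  This module computes:

* the observed mutant frequency MF = resistant / total colonies;
* the background-corrected polymerase error frequency
  Pol EF = observed MF - ssDNA background MF - outside-target MF;
* per-mutant mutational events from a repeat-aware alignment of each
  sequenced mutant against its template, classified as unit-based indels
  (whole motif units gained or lost), interruptions (substitutions or
  non-unit indels that break the repeat periodicity), or coding-region
  events outside the repeat;
* detectability (frameshifts always; base substitutions only when they
  change an amino acid or create a stop codon — within the microsatellite,
  only when a stop is created), and tandem grouping (events <= 1 nt apart);
* the multiple-event-corrected Pol EF_est and event-class-specific error
  frequencies EF_class = (class proportion among detectable events) x
  Pol EF_est.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Seq import Seq

from .motifs import Motif, rotation_canonical
from .structures import parse_structure

CONTEXT_REACTION = "polymerase reaction"
CONTEXT_BACKGROUND = "ssDNA background"
CONTEXT_OUTSIDE = "outside-target"

KIND_UNIT_INDEL = "unit-based indel"
KIND_INT_SUB = "interruption-substitution"
KIND_INT_INS = "interruption-insertion"
KIND_INT_DEL = "interruption-deletion"
KIND_CODING = "coding-region event"

INTERRUPTION_KINDS = (KIND_INT_SUB, KIND_INT_INS, KIND_INT_DEL)


@dataclass(frozen=True)
class ColonyCounts:
    """Selective (FUdR^R Cm^R) and total (Cm^R) colony counts."""

    fudr_cm: int
    cm: int
    context: str = CONTEXT_REACTION

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("total colony count must be positive")
        if not 0 <= self.fudr_cm <= self.cm:
            raise ValueError("mutant colonies must be within [0, total]")


def mutant_frequency(counts: ColonyCounts) -> float:
    """Observed mutant frequency: resistant colonies / total colonies."""
    return counts.fudr_cm / counts.cm


def pol_ef(observed: float, background: float, outside: float) -> float:
    """Background-corrected polymerase error frequency; negative
    differences are floored at zero with a warning."""
    for v in (observed, background, outside):
        if not 0.0 <= v <= 1.0:
            raise ValueError("mutant frequencies must be in [0, 1]")
    value = observed - background - outside
    if value < 0:
        warnings.warn(
            f"Pol EF {value:.3g} < 0 after background subtraction; floored to 0"
        )
        return 0.0
    return value


@dataclass(frozen=True)
class ReporterTemplate:
    """A reporter construct: in-frame coding flanks around a repeat tract.

    ``repeat_structure`` is an annotated allele string such as ``[GT]_10``
    or ``[A]_3 T [A]_4``.  ``frame_offset`` is the 0-based position within
    the full target at which the reading frame begins.
    """

    template_id: str
    upstream: str
    repeat_structure: str
    downstream: str
    frame_offset: int = 0

    @property
    def repeat_seq(self) -> str:
        return parse_structure(self.repeat_structure)

    @property
    def motif(self) -> Motif:
        token = self.repeat_structure.strip()
        open_idx = min(
            (token.find(c) for c in "([" if token.find(c) >= 0), default=-1
        )
        if open_idx < 0:
            raise ValueError(f"no repeat block in {self.repeat_structure!r}")
        close = min(i for i in (token.find(")"), token.find("]")) if i > 0)
        return Motif(token[open_idx + 1 : close])

    @property
    def sequence(self) -> str:
        return self.upstream + self.repeat_seq + self.downstream

    @property
    def repeat_span(self) -> tuple[int, int]:
        r0 = len(self.upstream)
        return r0, r0 + len(self.repeat_seq)


@dataclass(frozen=True)
class MutationalEvent:
    """One mutational difference between mutant and template, in template
    coordinates (indels canonically placed at the 3' end of repeat runs)."""

    position: int
    kind: str
    ref: str  # deleted/substituted template bases ('' for insertions)
    alt: str  # inserted/substituted mutant bases ('' for deletions)
    detectable: bool = False
    tandem_group_id: int = 0

    @property
    def net_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        return self.position + len(self.ref)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class MutantRecord:
    template_id: str
    mutant_sequence: str
    mutant_id: str = ""
    events: list[MutationalEvent] = field(default_factory=list)


class UnalignableRecord(ValueError):
    """Raised when a mutant cannot be plausibly aligned to its template."""


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    return aligner


def _raw_edits(template: str, mutant: str) -> list[tuple[str, int, str, str]]:
    """(op, template position, ref, alt) edits from a global alignment."""
    aln = _aligner().align(template, mutant)[0]
    identity = aln.score / max(len(template), 1)
    if identity < 0.5:
        raise UnalignableRecord(
            f"alignment identity too low (score {aln.score})"
        )
    t_blocks, q_blocks = aln.aligned
    edits: list[tuple[str, int, str, str]] = []
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > prev_t:
            edits.append(("del", prev_t, template[prev_t:ts], ""))
        if qs > prev_q:
            edits.append(("ins", ts, "", mutant[prev_q:qs]))
        for k in range(te - ts):
            if template[ts + k] != mutant[qs + k]:
                # one event per substituted base; adjacent substitutions are
                # separate events that the tandem grouper ties together
                edits.append(
                    ("sub", ts + k, template[ts + k], mutant[qs + k])
                )
        prev_t, prev_q = te, qe
    if prev_t < len(template):
        edits.append(("del", prev_t, template[prev_t:], ""))
    if prev_q < len(mutant):
        edits.append(("ins", len(template), "", mutant[prev_q:]))
    return edits


def _shift_right(template: str, op: str, pos: int, seq: str) -> tuple[int, str]:
    """Canonically place an indel at the 3' end of its repeat run."""
    n = len(template)
    if op == "del":
        L = len(seq)
        while pos + L < n and template[pos] == template[pos + L]:
            pos += 1
        return pos, template[pos : pos + L]
    while pos < n and seq and seq[0] == template[pos]:
        seq = seq[1:] + template[pos]
        pos += 1
    return pos, seq


def _translate(seq: str, frame_offset: int) -> str:
    coding = seq[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def _substitution_detectable(
    template: ReporterTemplate, pos: int, ref: str, alt: str, in_repeat: bool
) -> bool:
    seq = template.sequence
    mutated = seq[:pos] + alt + seq[pos + len(ref) :]
    old_prot = _translate(seq, template.frame_offset)
    new_prot = _translate(mutated, template.frame_offset)
    stop_created = any(
        n == "*" and o != "*" for o, n in zip(old_prot, new_prot)
    )
    if in_repeat:
        return stop_created
    return new_prot != old_prot


def _is_motif_units(seq: str, motif: Motif) -> bool:
    m = motif.size
    if not seq or len(seq) % m:
        return False
    unit = seq[:m]
    if rotation_canonical(unit) != motif.rotation_class:
        return False
    return seq == unit * (len(seq) // m)


def classify_events(
    record: MutantRecord, template: ReporterTemplate
) -> list[MutationalEvent]:
    """Align a sequenced mutant to its template and classify every
    difference; fills and returns ``record.events``."""
    tseq = template.sequence
    r0, r1 = template.repeat_span
    motif = template.motif
    m = motif.size
    events: list[MutationalEvent] = []
    for op, pos, ref, alt in _raw_edits(tseq, record.mutant_sequence):
        if op in ("del", "ins"):
            seq = ref if op == "del" else alt
            pos, seq = _shift_right(tseq, op, pos, seq)
            ref, alt = (seq, "") if op == "del" else ("", seq)
        span_end = pos + len(ref)
        if op == "ins":
            in_repeat = r0 < pos <= r1 or (
                pos == r0 and _is_motif_units(alt, motif)
            )
        else:
            in_repeat = pos < r1 and span_end > r0
        if not in_repeat:
            kind = KIND_CODING
        elif op == "sub":
            kind = KIND_INT_SUB
        else:
            seq = ref or alt
            if len(seq) % m == 0 and _is_motif_units(seq, motif):
                kind = KIND_UNIT_INDEL
            else:
                kind = KIND_INT_INS if op == "ins" else KIND_INT_DEL
        if op == "sub":
            detectable = _substitution_detectable(
                template, pos, ref, alt, in_repeat
            )
        else:
            detectable = (len(ref) + len(alt)) % 3 != 0
        events.append(
            MutationalEvent(
                position=pos, kind=kind, ref=ref, alt=alt, detectable=detectable
            )
        )
    events.sort(key=lambda e: (e.position, e.end))
    grouped: list[MutationalEvent] = []
    group_id = -1
    prev_end: int | None = None
    for ev in events:
        if prev_end is None or ev.position - prev_end > 1:
            group_id += 1
        grouped.append(replace(ev, tandem_group_id=group_id))
        prev_end = ev.end
    record.events = grouped
    return grouped


def apply_events(template_seq: str, events: list[MutationalEvent]) -> str:
    """Apply an event list to the template; inverse of classification."""
    out = template_seq
    for ev in sorted(events, key=lambda e: e.position, reverse=True):
        out = out[: ev.position] + ev.alt + out[ev.position + len(ev.ref) :]
    return out


def correct_multiple_events(
    pol_ef_value: float, records: list[MutantRecord]
) -> float:
    """Correct Pol EF for mutants carrying multiple nontandem events.

    Pol EF_est = Pol EF x (detectable event groups across mutants, a tandem
    group counting once) / (number of mutants); identical to Pol EF when
    every mutant carries exactly one detectable event group.
    """
    if not records:
        raise ValueError("no mutant records")
    total_groups = 0
    for rec in records:
        total_groups += len(
            {e.tandem_group_id for e in rec.events if e.detectable}
        )
    return pol_ef_value * total_groups / len(records)


def event_class_ef(
    pol_ef_est: float,
    events: list[MutationalEvent],
    class_filter,
) -> float:
    """Error frequency of one event class: the class's share of detectable
    events times Pol EF_est.  ``class_filter`` is a kind name, a tuple of
    kind names, or a predicate on events."""
    detectable = [e for e in events if e.detectable]
    if not detectable:
        raise ValueError("no detectable events to apportion")
    if callable(class_filter):
        pred = class_filter
    else:
        kinds = (
            (class_filter,) if isinstance(class_filter, str) else tuple(class_filter)
        )
        pred = lambda e: e.kind in kinds
    n_class = sum(1 for e in detectable if pred(e))
    return n_class / len(detectable) * pol_ef_est


def spectrum_report(records: list[MutantRecord]) -> dict:
    """Interruption mechanism spectrum over all (detectable and
    undetectable) interruption events, plus the fraction of mutants whose
    product carries two or more interruptions."""
    interruptions = [
        e for r in records for e in r.events if e.kind in INTERRUPTION_KINDS
    ]
    n = len(interruptions)
    proportions = {
        "substitution": 0.0 if not n else
        sum(e.kind == KIND_INT_SUB for e in interruptions) / n,
        "insertion": 0.0 if not n else
        sum(e.kind == KIND_INT_INS for e in interruptions) / n,
        "deletion": 0.0 if not n else
        sum(e.kind == KIND_INT_DEL for e in interruptions) / n,
    }
    with_any = [
        r
        for r in records
        if any(e.kind in INTERRUPTION_KINDS for e in r.events)
    ]
    multi = [
        r
        for r in with_any
        if sum(e.kind in INTERRUPTION_KINDS for e in r.events) >= 2
    ]
    return {
        "proportions": proportions,
        "n_interruption_events": n,
        "multi_interruption_fraction": (
            len(multi) / len(with_any) if with_any else 0.0
        ),
    }


@dataclass
class PolErrorSummary:
    """Derived error-frequency estimates for one polymerase x template."""

    observed_mf: float
    background_mf: float
    outside_mf: float
    pol_ef: float
    pol_ef_est: float
    n_records: int
    n_events: int
    class_counts: dict
    class_efs: dict
    spectrum: dict


def summarize(
    reaction: ColonyCounts,
    background: ColonyCounts,
    outside: ColonyCounts,
    records: list[MutantRecord],
    template: ReporterTemplate,
) -> PolErrorSummary:
    """Full reporter-assay analysis for one polymerase on one template."""
    for rec in records:
        if not rec.events:
            classify_events(rec, template)
    observed = mutant_frequency(reaction)
    bg = mutant_frequency(background)
    out = mutant_frequency(outside)
    ef = pol_ef(observed, bg, out)
    ef_est = correct_multiple_events(ef, records)
    all_events = [e for r in records for e in r.events]
    counts: dict[str, int] = {}
    for e in all_events:
        counts[e.kind] = counts.get(e.kind, 0) + 1
    kinds_present = sorted(counts)
    class_efs = {
        kind: event_class_ef(ef_est, all_events, kind) for kind in kinds_present
    } if any(e.detectable for e in all_events) else {}
    return PolErrorSummary(
        observed_mf=observed,
        background_mf=bg,
        outside_mf=out,
        pol_ef=ef,
        pol_ef_est=ef_est,
        n_records=len(records),
        n_events=len(all_events),
        class_counts=counts,
        class_efs=class_efs,
        spectrum=spectrum_report(records),
    )
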