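"""Annotated repeat-structure strings, e.g. ``(CAG)_6 CAA (CAG)_9``.

These strings describe a microsatellite allele as alternating tandem blocks
``(MOTIF)_n`` (square brackets accepted too) and literal interrupting bases.
They appear in disease-locus tables and in reporter-assay template
registries; parsing and re-annotation are exact inverses for sequences
decomposed against a fixed-phase motif.
"""

from __future__ import annotations

import re

_BLOCK = re.compile(r"[\(\[]([ACGT]+)[\)\]](?:_?\{?(\d+)\}?)?|([ACGT]+)")


def parse_structure(structure: str) -> str:
    """Expand a repeat-structure string into its DNA sequence."""
    seq = []
    pos = 0
    for match in _BLOCK.finditer(structure.replace(" ", "")):
        if match.start() != pos:
            raise ValueError(f"unparseable structure at {structure!r}")
        motif, count, literal = match.groups()
        if literal is not None:
            seq.append(literal)
        else:
            seq.append(motif * int(count or 1))
        pos = match.end()
    if pos != len(structure.replace(" ", "")):
        raise ValueError(f"unparseable structure {structure!r}")
    return "".join(seq)


def annotate_structure(seq: str, motif: str, bracket: str = "()") -> str:
    """Decompose ``seq`` into tandem blocks of ``motif`` (fixed phase) and
    literal interrupting runs; inverse of :func:`parse_structure`."""
    lo, hi = bracket
    m = len(motif)
    parts: list[str] = []
    i = 0
    literal: list[str] = []
    while i < len(seq):
        if seq[i : i + m] == motif:
            if literal:
                parts.append("".join(literal))
                literal = []
            k = 0
            while seq[i : i + m] == motif:
                k += 1
                i += m
            parts.append(f"{lo}{motif}{hi}_{k}")
        else:
            literal.append(seq[i])
            i += 1
    if literal:
        parts.append("".join(literal))
    return " ".join(parts)
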