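"""Independent brute-force reference implementations used as test oracles.

Coded from the textual rules with plain string operations, deliberately
avoiding the periodicity-array logic of the package's scanner.
"""

from __future__ import annotations


def _primitive(word: str) -> bool:
    n = len(word)
    return not any(
        n % d == 0 and word == word[:d] * (n // d) for d in range(1, n)
    )


def _rot_class(word: str) -> str:
    return min(word[i:] + word[:i] for i in range(len(word)))


def oracle_seeds(seq: str, cfg) -> list[tuple]:
    """Every maximal perfect tandem repeat meeting the unit threshold, by
    testing exact motif copies from every start position."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for m, thr in sorted(cfg.min_units.items()):
        for s in range(n - m + 1):
            motif = seq[s : s + m]
            if "N" in motif or not _primitive(motif):
                continue
            u = 1
            while seq[s + u * m : s + (u + 1) * m] == motif:
                u += 1
            if u < thr:
                continue
            # maximal: cannot slide or extend leftward in the same phase
            if s > 0 and seq[s - 1] == seq[s + m - 1]:
                continue
            out.append((motif, s, s + u * m, u))
    out.sort(key=lambda t: (t[1], len(t[0]), t[0]))
    return out


def _units_right(seq: str, pos: int, mclass: str, m: int) -> int:
    unit = seq[pos : pos + m]
    if len(unit) < m or "N" in unit or _rot_class(unit) != mclass:
        return 0
    u = 0
    while seq[pos + u * m : pos + (u + 1) * m] == unit:
        u += 1
    return u


def _units_left(seq: str, pos: int, mclass: str, m: int) -> int:
    unit = seq[pos - m : pos]
    if pos - m < 0 or "N" in unit or _rot_class(unit) != mclass:
        return 0
    u = 0
    while pos - (u + 1) * m >= 0 and seq[pos - (u + 1) * m : pos - u * m] == unit:
        u += 1
    return u


def oracle_loci(seq: str, cfg) -> set[tuple]:
    """Greedy textual extension of every seed; returns the deduplicated set
    of (start, end, rotation class, status, interruptions, repeat number)."""
    seq = seq.upper()
    seeds = oracle_seeds(seq, cfg)
    results = set()
    for motif, s0, e0, _u in seeds:
        m = len(motif)
        mclass = _rot_class(motif)
        s, e = s0, e0
        breaks: list[tuple[int, int]] = []
        changed = True
        while changed:
            changed = False
            for g in range(m + 1):
                u = _units_right(seq, e + g, mclass, m)
                if u >= 2:
                    if g:
                        breaks.append((e, g))
                    e = e + g + u * m
                    changed = True
                    break
            for g in range(m + 1):
                u = _units_left(seq, s - g, mclass, m)
                if u >= 2:
                    if g:
                        breaks.append((s - g, g))
                    s = s - g - u * m
                    changed = True
                    break
        compound = any(
            _rot_class(om) != mclass and os <= e + m and oe >= s - m
            for om, os, oe, _ou in seeds
        )
        interruptions = tuple(
            (b - s, seq[b : b + length]) for b, length in sorted(breaks)
        )
        status = (
            "compound-discarded"
            if compound
            else ("interrupted" if interruptions else "perfect")
        )
        total_break = sum(len(b) for _o, b in interruptions)
        results.add(
            (s, e, mclass, status, interruptions, (e - s - total_break) // m)
        )
    return results


def locus_key_set(loci) -> set[tuple]:
    """Project package loci onto the oracle's comparison key."""
    return {
        (
            locus.start,
            locus.end,
            locus.motif.rotation_class,
            locus.status,
            tuple((i.offset_in_locus, i.sequence) for i in locus.interruptions),
            int(locus.repeat_number),
        )
        for locus in loci
    }
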