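"""Structural hallmarks of SINE insertions.

Target site duplications (TSDs) are the short direct repeats (typically
4-14 bp) left at both flanks of an insertion by staggered endonuclease
cuts; published element records often include the two TSD copies at the
printed termini, so the finder supports both a *terminal* mode (shared
prefix/suffix of a printed element) and a *flanking* mode (upstream vs
downstream genomic windows around a mapped locus).

The 3' tail annotator looks for the transcription-relevant tail signals:
an oligo-T tract, a tandem simple repeat at the 3' terminus (e.g. ACT
trinucleotide runs), a TC dinucleotide immediately upstream of the
A/T-rich stretch, and overall A/T content of the tail window.

TSD matching is exact: partially degraded duplications (one or two
residues diverged, a sign of an old insertion) are deliberately not
matched; use ``find_near_miss_tsd`` to report them separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "TsdAnnotation",
    "TailAnnotation",
    "TerminalMotifReport",
    "find_tsd_terminal",
    "find_tsd_flanking",
    "find_near_miss_tsd",
    "annotate_tail",
    "check_terminal_motifs",
]


@dataclass
class TsdAnnotation:
    """A direct repeat found at (or flanking) an element's termini.

    Offsets are measured from the respective sequence ends: in terminal
    mode, left_offset is the start of the 5' copy from position 0 and
    right_offset the distance from the end of the 3' copy to the sequence
    end; in flanking mode they are distances from the element boundary to
    the nearer end of each copy.
    """

    tsd_seq: str
    length_nt: int
    mode: str  # "terminal" | "flanking"
    left_offset: int
    right_offset: int
    mismatches: int = 0


@dataclass
class TailAnnotation:
    """3'-tail hallmarks of one element."""

    oligo_t: Optional[Tuple[int, int]] = None  # (start, run_length)
    tc_motif_present: bool = False
    tc_motif_pos: Optional[int] = None
    repeat_unit: Optional[str] = None
    repeat_count: int = 0
    repeat_start: Optional[int] = None
    at_fraction_3prime: float = 0.0


@dataclass
class TerminalMotifReport:
    """Descriptive flags for the bookkeeping motifs seen in tRNA-derived
    elements: a residual CCA end in the 5' tRNA-related region and an
    ACATT motif."""

    cca_positions: list
    acatt_positions: list

    @property
    def cca_present(self) -> bool:
        return bool(self.cca_positions)

    @property
    def acatt_present(self) -> bool:
        return bool(self.acatt_positions)


def find_tsd_terminal(
    seq: str,
    min_len: int = 4,
    max_len: int = 20,
    max_end_offset: int = 0,
) -> Optional[TsdAnnotation]:
    """Longest exact direct repeat shared by the two termini of a printed
    element.

    Scans k from max_len down to min_len for a k-mer starting within
    max_end_offset of position 0 that equals a k-mer ending within
    max_end_offset of the sequence end; ties at equal k are broken toward
    the smallest offsets. Returns None when no such repeat exists or the
    sequence is shorter than two copies.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(seq)
    if n < 2 * min_len:
        return None
    for k in range(min(max_len, n // 2), min_len - 1, -1):
        for loff in range(max_end_offset + 1):
            left = seq[loff : loff + k]
            if len(left) < k:
                continue
            for roff in range(max_end_offset + 1):
                rstart = n - roff - k
                if rstart < loff + k:  # copies must not overlap
                    continue
                if seq[rstart : rstart + k] == left:
                    return TsdAnnotation(left, k, "terminal", loff, roff)
    return None


def _longest_common_substring(a: str, b: str) -> Tuple[int, int, int]:
    """(length, end_in_a, start_in_b) of the longest common substring;
    ties prefer the copy ending latest in a (closest to the element) and
    then starting earliest in b."""
    best = (0, 0, 0)
    na, nb = len(a), len(b)
    # dp over suffix lengths; inputs are small windows so O(na*nb) is fine
    prev = [0] * (nb + 1)
    for i in range(1, na + 1):
        cur = [0] * (nb + 1)
        for j in range(1, nb + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                L = cur[j]
                cand = (L, i, j - L)
                if L > best[0] or (
                    L == best[0] and (i > best[1] or (i == best[1] and j - L < best[2]))
                ):
                    best = cand
        prev = cur
    return best


def find_tsd_flanking(
    genome_seq: str,
    element_interval: Tuple[int, int],
    window: int = 30,
    min_len: int = 4,
    max_len: int = 20,
) -> Optional[TsdAnnotation]:
    """Longest exact repeat shared by the upstream and downstream flanks
    of an element interval on a contig.

    The 5' copy must lie within ``window`` nt upstream of the element
    start and the 3' copy within ``window`` nt downstream of its end.
    Flanks truncated by a contig edge are searched as far as available;
    with no flank sequence at all the result is None.
    """
    start, end = element_interval
    n = len(genome_seq)
    if not (0 <= start < end <= n):
        raise ValueError("element interval outside the contig")
    up = genome_seq[max(0, start - window) : start]
    down = genome_seq[end : end + window]
    if not up or not down:
        return None
    length, end_in_up, start_in_down = _longest_common_substring(up, down)
    if length < min_len:
        return None
    if length > max_len:  # keep the common suffix on both sides
        start_in_down += length - max_len
        length = max_len
    tsd = up[end_in_up - length : end_in_up]
    left_offset = len(up) - end_in_up
    right_offset = start_in_down
    return TsdAnnotation(tsd, length, "flanking", left_offset, right_offset)


def find_near_miss_tsd(
    seq: str,
    min_len: int = 4,
    max_len: int = 20,
    max_mismatch: int = 2,
) -> Optional[TsdAnnotation]:
    """Report a degraded terminal direct repeat (<= max_mismatch
    substitutions between the two copies), longest first; purely
    descriptive - degraded repeats never count as intact TSDs."""
    n = len(seq)
    if n < 2 * min_len:
        return None
    for k in range(min(max_len, n // 2), min_len - 1, -1):
        left, right = seq[:k], seq[n - k :]
        mm = sum(1 for x, y in zip(left, right) if x != y)
        if 0 < mm <= max_mismatch:
            return TsdAnnotation(left, k, "terminal", 0, 0, mismatches=mm)
    return None


def _primitive_unit(unit: str) -> str:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return unit[:p]
    return unit


def _best_tandem_run(seq: str, region_start: int, max_unit: int = 6):
    """Best tandem repeat (primitive unit 1..max_unit, >=3 copies) whose
    run overlaps seq[region_start:].

    Maximises total run length, then prefers the smallest unit; rotations
    of the same repeat tract tie on length, so the canonical
    (lexicographically smallest) unit is preferred, then the leftmost run.
    """
    n = len(seq)
    best = None  # (total_len, -unit_len, unit-rank, -start) maximised
    for ulen in range(1, max_unit + 1):
        for i in range(n - ulen + 1):
            unit = seq[i : i + ulen]
            if _primitive_unit(unit) != unit:
                continue
            if i >= ulen and seq[i - ulen : i] == unit:
                continue  # not the leftmost start of this run
            j = i + ulen
            while j + ulen <= n and seq[j : j + ulen] == unit:
                j += ulen
            count = (j - i) // ulen
            if count >= 3 and j > region_start:
                key = (j - i, -ulen, [-ord(c) for c in unit], -i)
                if best is None or key > best[0]:
                    best = (key, unit, count, i)
    if best is None:
        return None
    _, unit, count, start = best
    return unit, count, start


def annotate_tail(seq: str, tail_window: int = 50) -> TailAnnotation:
    """Annotate 3'-tail hallmarks within the final ``tail_window`` nt.

    Runs are required to overlap the tail window but are reported at
    their full extent: printed elements carry their 3' TSD copy after the
    biological tail, which can push most of a tail run just upstream of
    the window.
    """
    if len(seq) < tail_window:
        raise ValueError("sequence shorter than the tail window")
    n = len(seq)
    region_start = n - tail_window
    ann = TailAnnotation()
    # longest oligo-T tract overlapping the window (sense strand only)
    t_runs = [m for m in re.finditer(r"T+", seq) if m.end() > region_start]
    if t_runs:
        run = max(t_runs, key=lambda m: (len(m.group()), m.start()))
        if len(run.group()) >= 4:
            ann.oligo_t = (run.start(), len(run.group()))
    # maximal tandem simple repeat near the 3' terminus
    tandem = _best_tandem_run(seq, region_start)
    if tandem is not None:
        unit, count, start = tandem
        ann.repeat_unit, ann.repeat_count, ann.repeat_start = unit, count, start
    # TC dinucleotide immediately upstream of the A/T-rich stretch
    anchor = None
    if ann.oligo_t is not None:
        anchor = ann.oligo_t[0]
    elif ann.repeat_unit is not None and set(ann.repeat_unit) <= set("AT"):
        anchor = ann.repeat_start
    if anchor is not None and anchor >= 2 and seq[anchor - 2 : anchor] == "TC":
        ann.tc_motif_present = True
        ann.tc_motif_pos = anchor - 2
    tail = seq[region_start:]
    ann.at_fraction_3prime = sum(c in "AT" for c in tail) / len(tail)
    return ann


def check_terminal_motifs(seq: str, five_prime_window: int = 120) -> TerminalMotifReport:
    """Flag the residual tRNA CCA end within the 5' region and any ACATT
    motif; descriptive annotations only."""
    head = seq[:five_prime_window]
    cca = [m.start() for m in re.finditer("(?=CCA)", head)]
    acatt = [m.start() for m in re.finditer("(?=ACATT)", seq)]
    return TerminalMotifReport(cca, acatt)
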