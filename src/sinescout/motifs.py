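"""RNA polymerase III internal promoter and terminator detection.

SINEs retain the internal pol III promoter of their source gene: a type-2
promoter (A box + B box, sometimes an extra downstream B' box) for
tRNA-derived elements, and a type-1 promoter (A, intermediate element and
C boxes) for 5S rRNA-derived elements. Both are degenerate in old
elements, so every model is an IUPAC consensus with a mismatch budget.

The pol III termination signal searched for in the 5S-derived context is
GCTTTTCG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "MotifModel",
    "MotifHit",
    "PromoterAnnotation",
    "scan_motif",
    "annotate_type2_promoter",
    "annotate_type1_promoter",
    "load_motif_set",
    "TERMINATOR_MODEL",
    "DEFAULT_TYPE2_MODELS",
    "DEFAULT_TYPE1_MODELS",
    "AFUSINE_BOX_SEQUENCES",
]

_IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# bitmask carried by each sequence base; N carries no bits so it only
# matches a consensus N (mask 15), which matches everything
_BASE_BITS = np.array([1, 2, 4, 8, 0], dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifModel:
    """A degenerate motif: IUPAC consensus plus a mismatch budget.

    search_window, when given, is a 0-based half-open interval relative to
    the element start; windowed scans are forward-strand only.
    """

    name: str
    consensus: str
    max_mismatch: int = 0
    search_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if len(cons) < 4:
            raise ValueError(f"motif {self.name}: consensus shorter than 4 nt")
        if any(c not in _IUPAC for c in cons):
            raise ValueError(f"motif {self.name}: non-IUPAC character in consensus")
        if not 0 <= self.max_mismatch < len(cons):
            raise ValueError(f"motif {self.name}: max_mismatch out of range")
        object.__setattr__(self, "consensus", cons)


@dataclass
class MotifHit:
    """A motif occurrence; start/end are 0-based half-open on the element."""

    model_name: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched_seq: str


@dataclass
class PromoterAnnotation:
    """Outcome of promoter annotation on one element."""

    promoter_type: str  # "type1" | "type2" | "none"
    hits: Dict[str, MotifHit] = field(default_factory=dict)
    ab_spacer_nt: Optional[int] = None
    b_bprime_spacer_nt: Optional[int] = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_forward(seq: str, model: MotifModel) -> List[Tuple[int, int]]:
    """Return (start, mismatches) for every forward-strand placement."""
    m = len(model.consensus)
    n = len(seq)
    if n < m:
        return []
    codes = np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=n)
    allowed = np.zeros((m, 5), dtype=bool)
    for i, sym in enumerate(model.consensus):
        mask = _IUPAC[sym]
        allowed[i] = (mask == 15) | ((_BASE_BITS & mask) != 0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    ok = allowed[np.arange(m)[None, :], windows]
    mism = m - ok.sum(axis=1)
    starts = np.nonzero(mism <= model.max_mismatch)[0]
    return [(int(s), int(mism[s])) for s in starts]


def scan_motif(seq: str, model: MotifModel) -> List[MotifHit]:
    """All placements of the model with <= max_mismatch mismatches.

    Both strands are scanned unless the model carries a search window, in
    which case only forward-strand hits fully inside the window are
    returned. Overlapping hits are allowed; output is sorted by
    (start, strand) with + before -.
    """
    seq = seq.upper()
    m = len(model.consensus)
    hits: List[MotifHit] = []
    if model.search_window is not None:
        w0, w1 = model.search_window
        sub_start = max(0, w0)
        sub = seq[sub_start : max(sub_start, w1)]
        for s, mm in _scan_forward(sub, model):
            start = sub_start + s
            hits.append(MotifHit(model.name, start, start + m, "+", mm, seq[start : start + m]))
    else:
        for s, mm in _scan_forward(seq, model):
            hits.append(MotifHit(model.name, s, s + m, "+", mm, seq[s : s + m]))
        rc = reverse_complement(seq)
        L = len(seq)
        for s, mm in _scan_forward(rc, model):
            start, end = L - s - m, L - s
            hits.append(MotifHit(model.name, start, end, "-", mm, rc[s : s + m]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _forward_hits(seq: str, model: MotifModel) -> List[MotifHit]:
    return [h for h in scan_motif(seq, model) if h.strand == "+"]


def annotate_type2_promoter(
    seq: str,
    a_model: MotifModel,
    b_model: MotifModel,
    bprime_model: Optional[MotifModel] = None,
    spacer_bounds: Tuple[int, int] = (10, 150),
) -> PromoterAnnotation:
    """Call a tRNA-type (A box + B box) internal promoter on an element.

    The A/B pair with the fewest combined mismatches (then leftmost) whose
    spacer - nucleotides strictly between the A-box end and the B-box
    start - lies within bounds is selected; a B' box is then sought
    downstream of the chosen B box.
    """
    lo, hi = spacer_bounds
    if lo > hi:
        raise ValueError("spacer_bounds min must be <= max")
    a_hits = _forward_hits(seq, a_model)
    b_hits = _forward_hits(seq, b_model)
    best: Optional[Tuple[int, int, int]] = None
    pair: Optional[Tuple[MotifHit, MotifHit]] = None
    for a in a_hits:
        for b in b_hits:
            spacer = b.start - a.end
            if lo <= spacer <= hi:
                key = (a.mismatches + b.mismatches, a.start, b.start)
                if best is None or key < best:
                    best, pair = key, (a, b)
    if pair is None:
        return PromoterAnnotation("none")
    a, b = pair
    ann = PromoterAnnotation(
        "type2", {"A_box": a, "B_box": b}, ab_spacer_nt=b.start - a.end
    )
    if bprime_model is not None:
        down = [h for h in _forward_hits(seq, bprime_model) if h.start >= b.end]
        if down:
            bp = min(down, key=lambda h: (h.mismatches, h.start))
            ann.hits["Bprime_box"] = bp
            ann.b_bprime_spacer_nt = bp.start - b.end
    return ann


def annotate_type1_promoter(
    seq: str,
    a_model: MotifModel,
    ie_model: MotifModel,
    c_model: MotifModel,
    window_layout: Optional[Dict[str, Tuple[int, int]]] = None,
) -> PromoterAnnotation:
    """Call a 5S-type (A / IE / C box) internal promoter.

    Each box is sought in its own window relative to the element start
    (canonical 5S internal-control-region geometry by default); the call
    is type1 when at least two of the three boxes are found in A < IE < C
    order.
    """
    layout = dict(DEFAULT_TYPE1_WINDOWS)
    if window_layout:
        layout.update(window_layout)
    chosen: Dict[str, MotifHit] = {}
    for key, model in (("type1_A", a_model), ("type1_IE", ie_model), ("type1_C", c_model)):
        window = model.search_window or layout.get(key)
        windowed = MotifModel(model.name, model.consensus, model.max_mismatch, window)
        cand = scan_motif(seq, windowed) if window else _forward_hits(seq, model)
        if cand:
            chosen[key] = min(cand, key=lambda h: (h.mismatches, h.start))
    order = [chosen[k].start for k in ("type1_A", "type1_IE", "type1_C") if k in chosen]
    ptype = "type1" if len(chosen) >= 2 and order == sorted(order) else "none"
    return PromoterAnnotation(ptype, chosen)


def load_motif_set(path: str | Path) -> Dict[str, MotifModel]:
    """Read motif models from a plain-text table.

    One model per line: ``name consensus max_mismatch [win_start win_end]``;
    blank lines and #-comments are ignored.
    """
    models: Dict[str, MotifModel] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 5):
            raise ValueError(f"bad motif line: {line!r}")
        window = (int(parts[3]), int(parts[4])) if len(parts) == 5 else None
        models[parts[0]] = MotifModel(parts[0], parts[1], int(parts[2]), window)
    return models


# The pol III termination signal in the 5S-derived context.
TERMINATOR_MODEL = MotifModel("terminator", "GCTTTTCG", 0)

# Degenerate default models. The tRNA-type boxes generalise the canonical
# tRNA internal control regions; users studying a particular element
# family should override them (the exact per-element boxes annotated for
# the AfuSINE catalogue are shipped below as an alternative model set).
DEFAULT_TYPE2_MODELS: Dict[str, MotifModel] = {
    "A_box": MotifModel("A_box", "TRGCNNARYNNG", 2),
    "B_box": MotifModel("B_box", "GKTTCGANNC", 2),
    "Bprime_box": MotifModel("Bprime_box", "GGTTCGATTCC", 1),
}

# 5S-type defaults: windows follow canonical 5S internal-control-region
# geometry (A box ~ +50..+64, IE ~ +67..+72, C box ~ +80..+97 of the 5S
# gene); consensus strings are degenerate summaries of the boxes observed
# in the Af293 5S-derived elements.
DEFAULT_TYPE1_WINDOWS: Dict[str, Tuple[int, int]] = {
    "type1_A": (45, 75),
    "type1_IE": (65, 90),
    "type1_C": (75, 110),
}
DEFAULT_TYPE1_MODELS: Dict[str, MotifModel] = {
    "type1_A": MotifModel("type1_A", "AYTYAARCCANNNN", 2),
    "type1_IE": MotifModel("type1_IE", "NTRGT", 1),
    "type1_C": MotifModel("type1_C", "TANAWGCNNCCNTWANGN", 4),
}

# Exact promoter-box strings annotated on each element of the packaged
# AfuSINE catalogue, usable as a per-element strict model set.
AFUSINE_BOX_SEQUENCES: Dict[str, Dict[str, str]] = {
    "AfuSINE2-1a": {"A_box": "TAGCGTAGTGG", "B_box": "GATTGGTGACC", "Bprime_box": "GGTTCGATTCC"},
    "AfuSINE2-3a": {"A_box": "TGGAGGGACTGG", "B_box": "GGTTGGATAAC"},
    "AfuSINE2-4a": {"A_box": "TGCGGCCTGG", "B_box": "GTAAGTATTCC"},
    "AfuSINE2-7a": {"A_box": "TGGCGGAATGG", "B_box": "TGTTCGAATAG"},
    "AfuSINE2-5d": {"A_box": "AGGCTTAATGG", "B_box": "TGTTCAATCCC"},
    "AfuSINE2-3c": {"A_box": "TGGCAAAGCCGT", "B_box": "AGTTCAAATCT"},
    "AfuSINE2-4c": {"A_box": "TCCTGCAATGG", "B_box": "GGATCGATTCC"},
    "AfuSINE2-7e": {"A_box": "TAGCAGAGTGG", "B_box": "GATTCGATTTC"},
    "AfuSINE3-1a": {"type1_A": "ACTTAAGCCAGGTG", "type1_IE": "GTGGT", "type1_C": "TAGAAAGCCCTTTTGCCT"},
    "AfuSINE3-3a": {"type1_A": "ACTTAAGCCACATG", "type1_IE": "GTGGT", "type1_C": "TATATGCGCCCTTAATGG"},
    "AfuSINE3-3c": {"type1_A": "ACTTAAGCCACACG", "type1_IE": "GTGGT", "type1_C": "TAGAAAGCCTTTTTGCTT"},
    "AfuSINE3-4a": {"type1_A": "ATTCAAACCAGTAT", "type1_IE": "TTGGT", "type1_C": "TATATGCGTCCCTAAAGG"},
    "AfuSINE3-5c": {"type1_A": "ACTTAAGCCAGTAT", "type1_IE": "ATAGT", "type1_C": "TATATGCACCCTTAAAGG"},
}
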