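"""Synthetic genomes with planted SINE insertions and ground truth.

The generator emulates the statistical structure the annotation pipeline
assumes: i.i.d. background nucleotides at a chosen GC content, planted
elements carrying a 4-14 bp target site duplication copied exactly to
both flanks, internal pol III promoter boxes at fixed offsets, a 3' tail
signal (oligo-T tract or tandem simple repeat), and point-mutation
divergence between copies of a family. Indels are not simulated by
default; background has no repeat structure beyond chance.

Everything is reproducible from the single seed in SimConfig.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import Catalogue, ElementRecord
from .motifs import reverse_complement
from .scan import FeatureParams, _first_tail_end

__all__ = [
    "ElementTemplate",
    "SimConfig",
    "TruthRecord",
    "random_sequence",
    "mutate",
    "simulate_genome",
    "write_truth_gff3",
]

_BASES = np.array(list("ACGT"))


def random_sequence(length: int, gc_content: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotides with P(G)=P(C)=gc_content/2."""
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def mutate(seq: str, rate: float, seed) -> str:
    """Per-site substitution at the given rate to a uniformly chosen
    different base; deterministic per seed (an int or a Generator)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


@dataclass(frozen=True)
class ElementTemplate:
    """Architecture of a planted element.

    Layout: [lead][A box][spacer][B box][optional B' after bprime_spacer]
    [body][tail]. The body and spacer are sampled conditioned on carrying
    no tail-like signal (oligo-T run or long tandem repeat), because an
    element's annotated 3' end is by definition the first such signal
    downstream of its promoter. head_seq, when given, replaces the lead +
    A-box region with a fixed 5' head (e.g. a reference-gene head for
    classification tests).
    """

    a_box: str = "TAGCGTAGTGG"
    b_box: str = "GATTGGTGACC"
    bprime_box: Optional[str] = None
    lead_len: int = 5
    spacer_len: int = 20
    bprime_spacer: int = 20
    body_len: int = 100
    tail_kind: str = "oligo_t"  # "oligo_t" | "tandem"
    tail_unit: str = "T"
    tail_count: int = 10
    head_seq: Optional[str] = None

    def tail_seq(self) -> str:
        return self.tail_unit * self.tail_count

    def build(self, gc_content: float, rng: np.random.Generator) -> Tuple[str, Dict[str, int]]:
        """Assemble one master element; returns (seq, box offsets)."""
        fp = FeatureParams()
        parts: List[str] = []
        if self.head_seq is not None:
            parts.append(self.head_seq)
        else:
            parts.append(random_sequence(self.lead_len, gc_content, rng))
        a_off = len(parts[0])
        parts.append(self.a_box)
        offsets = {"A_box": a_off}
        for _ in range(200):
            middle = [random_sequence(self.spacer_len, gc_content, rng), self.b_box]
            if self.bprime_box:
                middle.append(random_sequence(self.bprime_spacer, gc_content, rng))
                middle.append(self.bprime_box)
            middle.append(random_sequence(self.body_len, gc_content, rng))
            post_b = "".join(middle)
            b_local = self.spacer_len
            # the only tail signal downstream of the B box must be the tail
            probe = post_b[b_local + len(self.b_box) :] + self.tail_seq()
            if _first_tail_end(probe, 0, len(probe), fp) == len(probe):
                break
        else:  # pragma: no cover - rejection loop exhausts only on tiny alphabets
            raise RuntimeError("could not sample a tail-free element body")
        offsets["B_box"] = a_off + len(self.a_box) + self.spacer_len
        if self.bprime_box:
            offsets["Bprime_box"] = offsets["B_box"] + len(self.b_box) + self.bprime_spacer
        parts.append(post_b)
        parts.append(self.tail_seq())
        return "".join(parts), offsets


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome."""

    seed: int = 0
    contig_lengths: Tuple[int, ...] = (50_000,)
    gc_content: float = 0.5
    n_elements: int = 1
    copies_per_element: int = 5
    tsd_len_range: Tuple[int, int] = (4, 14)
    divergence: float = 0.0
    template: ElementTemplate = field(default_factory=ElementTemplate)
    minus_strand_fraction: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.gc_content, self.divergence, self.minus_strand_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one planted copy; interval covers the element
    only (TSD copies sit immediately adjacent on both flanks)."""

    element_id: str
    family_id: str
    contig: str
    start: int
    end: int
    strand: str
    tsd_seq: str
    box_offsets: Dict[str, int]
    tail: str


def simulate_genome(
    config: SimConfig,
) -> Tuple[Catalogue, List[TruthRecord], Catalogue]:
    """Generate contigs with planted elements.

    Returns (genome, truth records, master elements): each family's
    master is the undiverged consensus from which its copies were mutated
    - the natural query for copy mapping.
    """
    rng = np.random.default_rng(config.seed)
    masters = []
    for e in range(config.n_elements):
        seq, offsets = config.template.build(config.gc_content, rng)
        masters.append((f"elem{e + 1}", seq, offsets))
    # assign copies to contigs round-robin, evenly spaced with jitter
    jobs: List[Tuple[int, str, str, Dict[str, int]]] = []  # (contig idx, family, seq, offsets)
    ci = 0
    for fam, seq, offsets in masters:
        for c in range(config.copies_per_element):
            copy = mutate(seq, config.divergence, rng) if config.divergence > 0 else seq
            jobs.append((ci % len(config.contig_lengths), fam, copy, offsets))
            ci += 1
    contigs: List[ElementRecord] = []
    truth: List[TruthRecord] = []
    copy_no = 0
    for k, length in enumerate(config.contig_lengths):
        my = [j for j in jobs if j[0] == k]
        name = f"contig{k + 1}"
        bg = random_sequence(length, config.gc_content, rng)
        n = len(my)
        if n == 0:
            contigs.append(ElementRecord(id=name, seq=bg))
            continue
        need = sum(len(s) for _, _, s, _ in my) + n * 2 * config.tsd_len_range[1]
        if need >= length:
            raise ValueError(f"planted elements do not fit in a {length} nt contig")
        slot = length // (n + 1)
        positions = sorted(
            int(slot * (i + 1) + rng.integers(-slot // 4, slot // 4 + 1))
            for i in range(n)
        )
        pieces: List[str] = []
        prev = 0
        offset = 0  # accumulated inserted length
        for pos, (_, fam, copy, offsets) in zip(positions, my):
            copy_no += 1
            tsd_len = int(rng.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
            tsd = random_sequence(tsd_len, config.gc_content, rng)
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            planted = copy if strand == "+" else reverse_complement(copy)
            pieces.append(bg[prev:pos])
            pieces.append(tsd + planted + tsd)
            start = pos + offset + tsd_len
            truth.append(
                TruthRecord(
                    element_id=f"{fam}.copy{copy_no}",
                    family_id=fam,
                    contig=name,
                    start=start,
                    end=start + len(planted),
                    strand=strand,
                    tsd_seq=tsd,
                    box_offsets=dict(offsets),
                    tail=config.template.tail_seq(),
                )
            )
            offset += len(planted) + 2 * tsd_len
            prev = pos
        pieces.append(bg[prev:])
        contigs.append(ElementRecord(id=name, seq="".join(pieces)))
    families = Catalogue([ElementRecord(id=f, seq=s) for f, s, _ in masters])
    return Catalogue(contigs), truth, families


def write_truth_gff3(truth: List[TruthRecord], path: str | Path) -> None:
    """Write planted-copy ground truth as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            attrs = f"ID={t.element_id};family={t.family_id};tsd={t.tsd_seq}"
            fh.write(
                f"{t.contig}\tsinescout_sim\tdispersed_repeat\t{t.start + 1}\t{t.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )
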