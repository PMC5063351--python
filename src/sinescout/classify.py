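"""Family assignment of candidate elements.

A candidate is called SINE3 (5S rRNA-derived) when its 5' head aligns to
a 5S reference at >= 60% identity over a >= 60-nt overlap; the 5S test
runs first because the conserved 5S head is the decisive signature and a
tRNA-isotype call on a 5S head would be spurious. Failing that, a
candidate is called SINE2 (tRNA-derived) when its head meets the same
thresholds against a tRNA reference, or when it carries a type-2 pol III
promoter (A box + B box). Anything else stays unclassified.

Similarity of a candidate's 3' terminus to a LINE 3' UTR - the signal by
which non-autonomous SINEs borrow the retrotransposition machinery of a
partner LINE - is reported as evidence only and never changes the family
call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

from .align import LocalAlignment, ScoringScheme, best_head_identity, local_align
from .io import Catalogue, ElementRecord
from .motifs import (
    DEFAULT_TYPE2_MODELS,
    MotifModel,
    PromoterAnnotation,
    annotate_type2_promoter,
)

__all__ = [
    "Thresholds",
    "ClassificationResult",
    "ConfigurationError",
    "classify_element",
    "true_gene_filter",
    "line_3prime_similarity",
]


class ConfigurationError(ValueError):
    """Raised when classification is requested without usable references."""


@dataclass(frozen=True)
class Thresholds:
    """Head-homology thresholds: identity percent and overlap in nt over
    the first head_len nucleotides of the candidate."""

    id_threshold: float = 60.0
    overlap_threshold: int = 60
    head_len: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.id_threshold <= 100:
            raise ValueError("id_threshold must be in (0, 100]")
        if self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be >= 1")


@dataclass
class ClassificationResult:
    family: str  # "SINE2" | "SINE3" | "unclassified"
    head_alignment: Optional[LocalAlignment] = None
    promoter: Optional[PromoterAnnotation] = None
    origin_call: Optional[str] = None
    line_3prime_match: Optional[LocalAlignment] = None

    @property
    def promoter_type(self) -> str:
        return self.promoter.promoter_type if self.promoter else "none"


def _best_meeting(candidate, refs, thresholds, scheme):
    """Best alignment among references meeting the thresholds (by
    identity then overlap; ties keep reference order), else the overall
    best for evidence. Returns (alignment, met, tied_refs)."""
    head = candidate.seq[: thresholds.head_len]
    met = []
    overall = None
    for ref in refs:
        aln = local_align(head, ref.seq, scheme)
        aln.subject_id = ref.id
        key = (aln.identity_pct, aln.overlap_nt)
        if overall is None or key > (overall.identity_pct, overall.overlap_nt):
            overall = aln
        if aln.meets(thresholds.id_threshold, thresholds.overlap_threshold):
            met.append((key, ref, aln))
    if not met:
        return overall, False, []
    best_key = max(k for k, _, _ in met)
    winners = [(r, a) for k, r, a in met if k == best_key]
    return winners[0][1], True, [r for r, _ in winners]


def _isotype(ref: ElementRecord) -> Optional[str]:
    if ref.origin_label.startswith("tRNA/"):
        return ref.origin_label.split("/", 1)[1]
    return None


def classify_element(
    candidate: ElementRecord,
    refs_trna: Optional[Iterable[ElementRecord]] = None,
    refs_5s: Optional[Iterable[ElementRecord]] = None,
    thresholds: Thresholds = Thresholds(),
    motif_models: Optional[dict] = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> ClassificationResult:
    """Assign a candidate to SINE3, SINE2 or unclassified.

    Deterministic given inputs: the 5S head test runs first, then the tRNA
    head test, then the type-2 promoter test; isotype ties between equally
    scoring tRNA references are reported as "ambiguous".
    """
    refs_trna = list(refs_trna) if refs_trna else []
    refs_5s = list(refs_5s) if refs_5s else []
    if motif_models is None:
        motif_models = DEFAULT_TYPE2_MODELS
    if not refs_trna and not refs_5s and not motif_models:
        raise ConfigurationError(
            "classification needs a tRNA or 5S reference set, or promoter motif models"
        )
    result = ClassificationResult("unclassified")
    if refs_5s:
        aln, ok, _ = _best_meeting(candidate, refs_5s, thresholds, scheme)
        result.head_alignment = aln
        if ok:
            result.family = "SINE3"
            result.origin_call = "5S"
            return result
    if refs_trna:
        aln, ok, winners = _best_meeting(candidate, refs_trna, thresholds, scheme)
        if ok:
            result.family = "SINE2"
            result.head_alignment = aln
            isotypes = {_isotype(r) or r.id for r in winners}
            result.origin_call = isotypes.pop() if len(isotypes) == 1 else "ambiguous"
            return result
        if result.head_alignment is None:
            result.head_alignment = aln
    if motif_models and "A_box" in motif_models and "B_box" in motif_models:
        prom = annotate_type2_promoter(
            candidate.seq,
            motif_models["A_box"],
            motif_models["B_box"],
            motif_models.get("Bprime_box"),
        )
        result.promoter = prom
        if prom.promoter_type == "type2":
            result.family = "SINE2"
    return result


def true_gene_filter(
    candidate: ElementRecord,
    refs: Iterable[ElementRecord],
    full_len_id_threshold: float = 90.0,
    coverage_threshold: float = 0.9,
    scheme: ScoringScheme = ScoringScheme(),
    candidate_interval: Optional[Tuple[str, int, int]] = None,
    exclusion_intervals: Optional[Iterable[Tuple[str, int, int]]] = None,
    min_exclusion_overlap: float = 0.5,
) -> bool:
    """True to keep the candidate, False to discard it as a true gene.

    A candidate that aligns to any reference gene at
    >= full_len_id_threshold identity covering >= coverage_threshold of
    the reference length IS that gene (a real tRNA or 5S rRNA), not a
    derived element. Candidates whose genomic interval overlaps a known
    gene annotation by >= min_exclusion_overlap of their own length are
    discarded likewise.
    """
    refs = list(refs)
    if not refs and exclusion_intervals is None:
        raise ConfigurationError("true_gene_filter needs references or an exclusion list")
    for ref in refs:
        aln = local_align(candidate.seq, ref.seq, scheme)
        if (
            aln.identity_pct >= full_len_id_threshold
            and aln.overlap_nt >= coverage_threshold * len(ref.seq)
        ):
            return False
    if candidate_interval is not None and exclusion_intervals:
        contig, start, end = candidate_interval
        length = end - start
        for econtig, estart, eend in exclusion_intervals:
            if econtig != contig:
                continue
            overlap = min(end, eend) - max(start, estart)
            if overlap > 0 and overlap / length >= min_exclusion_overlap:
                return False
    return True


def line_3prime_similarity(
    candidate: ElementRecord,
    refs_line: Iterable[ElementRecord],
    window: int = 150,
    scheme: ScoringScheme = ScoringScheme(),
) -> Optional[LocalAlignment]:
    """Best forward-strand local alignment of the candidate's 3' terminus
    against each LINE 3'-UTR reference; evidence only."""
    refs_line = list(refs_line)
    if not refs_line:
        raise ConfigurationError("LINE reference set is empty")
    tail = candidate.seq[-window:]
    best: Optional[LocalAlignment] = None
    for ref in refs_line:
        aln = local_align(tail, ref.seq, scheme)
        aln.subject_id = ref.id
        if best is None or (aln.score, aln.identity_pct) > (best.score, best.identity_pct):
            best = aln
    return best
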