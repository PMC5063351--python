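"""Local pairwise alignment with affine gaps.

A from-scratch Smith-Waterman/Gotoh implementation used for head-identity
classification (the 60%-identity / 60-nt-overlap rule for 5S-derived
elements) and for seed extension during genome copy mapping.

Conventions that matter for reproducibility of the identity rule:

* a gap of length L costs ``gap_open + L * gap_extend`` (the first gapped
  position pays both open and extend);
* ``identity_pct`` uses aligned columns including gap columns as the
  denominator;
* N never matches anything, including another N;
* traceback ties are broken toward the diagonal, then up (gap in the
  subject), then left, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

__all__ = ["ScoringScheme", "LocalAlignment", "local_align", "best_head_identity"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -(2**30)


@dataclass(frozen=True)
class ScoringScheme:
    """Integer scoring for nucleotide local alignment.

    Defaults (+2/-1, gap open -5, extend -1) are ordinary nucleotide
    settings; the identity thresholds, not the scores, carry the
    biological meaning, so the scheme is exposed in configuration.
    """

    match: int = 2
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class LocalAlignment:
    """Result of an optimal local alignment.

    query_interval / subject_interval are 0-based half-open on the input
    sequences; overlap_nt counts subject positions covered; identity_pct
    is 100 * matches / aligned_length with gap columns in the denominator.
    """

    score: int
    query_interval: Tuple[int, int]
    subject_interval: Tuple[int, int]
    aligned_length: int
    matches: int
    identity_pct: float
    overlap_nt: int
    subject_id: Optional[str] = None

    def meets(self, id_threshold: float, overlap_threshold: int) -> bool:
        return self.identity_pct >= id_threshold and self.overlap_nt >= overlap_threshold


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as e:  # pragma: no cover - records normalise to ACGTN
        raise ValueError(f"invalid nucleotide {e.args[0]!r}") from None


@njit(cache=True)
def _fill(a, b, match, mismatch, go, ge):  # pragma: no cover - compiled
    n, m = a.shape[0], b.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            up = S[i - 1, j] + go + ge
            if Ix[i - 1, j] + ge > up:
                up = Ix[i - 1, j] + ge
            Ix[i, j] = up
            left = S[i, j - 1] + go + ge
            if Iy[i, j - 1] + ge > left:
                left = Iy[i, j - 1] + ge
            Iy[i, j] = left
            if ai == b[j - 1] and ai != 4:
                sub = match
            else:
                sub = mismatch
            best = S[i - 1, j - 1] + sub
            if up > best:
                best = up
            if left > best:
                best = left
            if best < 0:
                best = 0
            S[i, j] = best
    return S, Ix, Iy


def local_align(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> LocalAlignment:
    """Optimal local alignment of query ``a`` against subject ``b``."""
    if not a or not b:
        raise ValueError("local_align requires two non-empty sequences")
    ac, bc = _encode(a.upper()), _encode(b.upper())
    S, Ix, Iy = _fill(ac, bc, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    flat = int(np.argmax(S))
    i, j = divmod(flat, S.shape[1])
    score = int(S[i, j])
    if score == 0:
        # no positively scoring pairing at all
        return LocalAlignment(0, (0, 0), (0, 0), 0, 0, 0.0, 0)
    qe, se = i, j
    matches = 0
    cols = 0
    goge = scheme.gap_open + scheme.gap_extend
    while S[i, j] > 0:
        is_match = ac[i - 1] == bc[j - 1] and ac[i - 1] != 4
        sub = scheme.match if is_match else scheme.mismatch
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + sub:
            cols += 1
            if is_match:
                matches += 1
            i -= 1
            j -= 1
        elif S[i, j] == Ix[i, j]:
            # gap in subject: walk up through the Ix chain
            while True:
                cols += 1
                if Ix[i, j] == S[i - 1, j] + goge:
                    i -= 1
                    break
                i -= 1
        else:
            while True:
                cols += 1
                if Iy[i, j] == S[i, j - 1] + goge:
                    j -= 1
                    break
                j -= 1
    qs, ss = i, j
    return LocalAlignment(
        score=score,
        query_interval=(qs, qe),
        subject_interval=(ss, se),
        aligned_length=cols,
        matches=matches,
        identity_pct=100.0 * matches / cols,
        overlap_nt=se - ss,
    )


def best_head_identity(
    candidate,
    refs,
    head_len: int = 100,
    scheme: ScoringScheme = ScoringScheme(),
) -> LocalAlignment:
    """Align the 5' head of a candidate against every reference.

    Returns the alignment maximising (identity_pct, overlap_nt); ties keep
    the earlier reference. Used for the head-homology rule by which
    5S-derived elements are recognised from their conserved 5' region.
    """
    if head_len < 1:
        raise ValueError("head_len must be >= 1")
    refs = list(refs)
    if not refs:
        raise ValueError("reference set is empty")
    head = candidate.seq[:head_len]
    best: Optional[LocalAlignment] = None
    for ref in refs:
        aln = local_align(head, ref.seq, scheme)
        aln.subject_id = ref.id
        if best is None or (aln.identity_pct, aln.overlap_nt) > (
            best.identity_pct,
            best.overlap_nt,
        ):
            best = aln
    return best
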