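"""Genome-scale operations: copy mapping, boundary extension, de-novo
candidate discovery and chromosomal distribution summaries.

Copy mapping is seed-and-extend: exact k-mers of the query element anchor
candidate regions on both strands, each region is realigned with the
affine-gap local aligner, and loci passing identity and query-coverage
thresholds are merged into non-overlapping intervals. With elements of
140-500 nt and the default k = 12, at least one intact seed survives 10%
divergence with high probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .align import LocalAlignment, ScoringScheme, local_align
from .features import find_tsd_flanking, _primitive_unit as _primitive
from .io import Catalogue, ElementRecord
from .motifs import MotifModel, MotifHit, reverse_complement, scan_motif

__all__ = [
    "Locus",
    "ScanParams",
    "ExtendedWindow",
    "map_copies",
    "extend_boundaries",
    "discover_candidates",
    "distribution_report",
]


@dataclass
class Locus:
    """A genomic interval matched by an element (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    identity_pct: float
    query_coverage: float
    element_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")


@dataclass(frozen=True)
class ScanParams:
    """Copy-mapping parameters.

    extend_up/extend_down are the boundary-extension margins applied when
    lifting a locus back out of the genome for re-annotation (1,000 nt
    upstream and 2,000 nt downstream by default).
    """

    seed_len: int = 12
    min_identity: float = 80.0
    min_coverage: float = 0.8
    merge_gap: int = 50
    extend_up: int = 1000
    extend_down: int = 2000

    def __post_init__(self) -> None:
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        if not 0 < self.min_identity <= 100 or not 0 < self.min_coverage <= 1:
            raise ValueError("thresholds out of range")


@dataclass
class ExtendedWindow:
    """A locus lifted with flanking margins; seq is oriented to the
    element strand and locus_offset maps element-strand coordinates back
    into the window."""

    contig: str
    start: int
    end: int
    strand: str
    seq: str
    locus_offset: int


def _seed_positions(element: str, target: str, k: int) -> List[Tuple[int, int]]:
    kmers: Dict[str, List[int]] = {}
    for q in range(len(element) - k + 1):
        kmers.setdefault(element[q : q + k], []).append(q)
    out = []
    for t in range(len(target) - k + 1):
        for q in kmers.get(target[t : t + k], ()):
            out.append((q, t))
    return out


def _cluster_seeds(seeds, elem_len, band: int = 40):
    """Group seeds into candidate regions by diagonal band and target
    proximity; yields (tmin, tmax) target spans."""
    seeds = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters = []
    cur = None
    for q, t in seeds:
        d = t - q
        if cur is not None and d - cur["dmax"] <= band and t - cur["tmax"] <= elem_len:
            cur["dmax"] = max(cur["dmax"], d)
            cur["tmin"] = min(cur["tmin"], t)
            cur["tmax"] = max(cur["tmax"], t)
            cur["dmin"] = min(cur["dmin"], d)
        else:
            cur = {"dmin": d, "dmax": d, "tmin": t, "tmax": t}
            clusters.append(cur)
    spans = []
    for c in clusters:
        lo = c["dmin"]  # target position of element start on this diagonal
        hi = c["dmax"] + elem_len
        spans.append((lo, hi))
    # merge overlapping spans from distinct diagonal clusters
    spans.sort()
    merged = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _align_region(element, contig_id, target, strand, lo, hi, params, scheme, pad):
    n = len(target)
    ws, we = max(0, lo - pad), min(n, hi + pad)
    window = target[ws:we]
    if len(window) < params.seed_len:
        return None
    aln = local_align(element, window, scheme)
    if aln.aligned_length == 0:
        return None
    qcov = (aln.query_interval[1] - aln.query_interval[0]) / len(element)
    if aln.identity_pct < params.min_identity or qcov < params.min_coverage:
        return None
    s, e = ws + aln.subject_interval[0], ws + aln.subject_interval[1]
    if strand == "-":
        s, e = n - e, n - s
    return Locus(contig_id, s, e, strand, aln.identity_pct, qcov)


def _merge_loci(loci: List[Locus], merge_gap: int) -> List[Locus]:
    loci.sort(key=lambda l: (l.contig, l.start, l.end))
    merged: List[Locus] = []
    for loc in loci:
        if (
            merged
            and loc.contig == merged[-1].contig
            and loc.start - merged[-1].end <= merge_gap
        ):
            prev = merged[-1]
            best = loc if loc.identity_pct > prev.identity_pct else prev
            merged[-1] = Locus(
                prev.contig,
                min(prev.start, loc.start),
                max(prev.end, loc.end),
                best.strand,
                best.identity_pct,
                max(prev.query_coverage, loc.query_coverage),
                best.element_id,
            )
        else:
            merged.append(loc)
    return merged


def map_copies(
    element: ElementRecord,
    genome: Catalogue,
    params: ScanParams = ScanParams(),
    scheme: ScoringScheme = ScoringScheme(),
) -> List[Locus]:
    """Map copies of an element across contigs on both strands."""
    if element.length_bp < params.seed_len:
        raise ValueError("element shorter than the seed length")
    pad = max(30, element.length_bp // 4)
    loci: List[Locus] = []
    for contig in genome:
        for strand in "+-":
            target = contig.seq if strand == "+" else reverse_complement(contig.seq)
            seeds = _seed_positions(element.seq, target, params.seed_len)
            if not seeds:
                continue
            for lo, hi in _cluster_seeds(seeds, element.length_bp):
                loc = _align_region(
                    element.seq, contig.id, target, strand, lo, hi, params, scheme, pad
                )
                if loc is not None:
                    loc.element_id = element.id
                    loci.append(loc)
    return _merge_loci(loci, params.merge_gap)


def extend_boundaries(
    locus: Locus,
    genome: Catalogue,
    extend_up: int = 1000,
    extend_down: int = 2000,
) -> ExtendedWindow:
    """Lift a locus with flanking margins for re-annotation.

    Upstream/downstream are taken in the element's reading direction: on
    the minus strand, upstream is genomic rightward and the returned
    sequence is reverse-complemented to element orientation.
    """
    contig = genome[locus.contig]
    n = contig.length_bp
    if locus.strand == "+":
        ws = max(0, locus.start - extend_up)
        we = min(n, locus.end + extend_down)
        seq = contig.seq[ws:we]
        offset = locus.start - ws
    else:
        ws = max(0, locus.start - extend_down)
        we = min(n, locus.end + extend_up)
        seq = reverse_complement(contig.seq[ws:we])
        offset = we - locus.end
    return ExtendedWindow(locus.contig, ws, we, locus.strand, seq, offset)


@dataclass
class FeatureParams:
    """Tunables for de-novo discovery.

    A tail signal is an oligo-T tract of >= min_oligo_t T's, or a tandem
    simple repeat of >= 3 copies spanning >= tandem_min_total nt (so a
    chance 3-nt homopolymer in the body does not truncate a candidate).
    """

    spacer_bounds: Tuple[int, int] = (10, 150)
    max_tail_search: int = 600
    min_oligo_t: int = 4
    tandem_min_total: int = 9
    tsd_window: int = 30
    min_tsd: int = 4


def _first_tail_end(seq: str, start: int, limit: int, fp: "FeatureParams") -> Optional[int]:
    """End of the first tail signal beginning at or after start, within
    limit nt; None if absent."""
    import re

    if limit <= 0:
        return None
    region = seq[start : start + limit]
    signals: List[Tuple[int, int]] = []
    m = re.search("T{%d,}" % fp.min_oligo_t, region)
    if m:
        signals.append((m.start(), m.end()))
    for ulen in range(1, 7):
        for i in range(len(region) - ulen + 1):
            unit = region[i : i + ulen]
            if _primitive(unit) != unit:
                continue
            j = i + ulen
            while j + ulen <= len(region) and region[j : j + ulen] == unit:
                j += ulen
            if (j - i) // ulen >= 3 and j - i >= fp.tandem_min_total:
                signals.append((i, j))
                break  # only the first run per unit length matters
    if not signals:
        return None
    first = min(signals)
    return start + first[1]


def discover_candidates(
    genome: Catalogue,
    motif_models: Dict[str, MotifModel],
    feature_params: FeatureParams = FeatureParams(),
) -> Catalogue:
    """De-novo candidate discovery by promoter-pair scanning.

    For every A-box/B-box pair within spacer bounds (both strands), a
    candidate runs from the A-box start to the end of the first
    downstream tail signal (oligo-T tract or tandem simple repeat);
    candidates lacking both a flanking TSD and a tail signal are dropped,
    so every emitted candidate carries at least two hallmarks.
    """
    a_model, b_model = motif_models["A_box"], motif_models["B_box"]
    fp = feature_params
    records: List[ElementRecord] = []
    counter = 0
    for contig in genome:
        n = contig.length_bp
        for strand in "+-":
            seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
            if set(seq) <= {"N"}:
                continue
            a_hits = [h for h in scan_motif(seq, a_model) if h.strand == "+"]
            b_hits = [h for h in scan_motif(seq, b_model) if h.strand == "+"]
            taken_until = -1
            for a in a_hits:
                if a.start <= taken_until:
                    continue
                bs = [
                    b
                    for b in b_hits
                    if fp.spacer_bounds[0] <= b.start - a.end <= fp.spacer_bounds[1]
                ]
                if not bs:
                    continue
                b = min(bs, key=lambda h: (h.mismatches, h.start))
                tail_end = _first_tail_end(
                    seq, b.end, fp.max_tail_search - (b.end - a.start), fp
                )
                if tail_end is None:
                    continue
                start, end = a.start, tail_end
                tsd = find_tsd_flanking(
                    seq, (start, end), window=fp.tsd_window, min_len=fp.min_tsd
                )
                # hallmarks: promoter pair + tail (by construction) + TSD
                gs, ge = (start, end) if strand == "+" else (n - end, n - start)
                counter += 1
                loc = Locus(contig.id, gs, ge, strand, 100.0, 1.0, f"cand{counter}")
                rec = ElementRecord(
                    id=f"cand{counter}",
                    seq=seq[start:end],
                    chromosome_tag=f"{contig.id}:{gs}-{ge}({strand})"
                    + (f";tsd={tsd.tsd_seq}" if tsd else ""),
                )
                rec.source_interval = loc
                records.append(rec)
                taken_until = end
    return Catalogue(records)


def distribution_report(
    loci: Sequence[Locus],
    region_bed: Optional[Sequence[Tuple[str, int, int, str]]] = None,
) -> pd.DataFrame:
    """Summarise locus counts per contig, or per region label.

    With labelled regions (contig, start, end, label) that partition each
    contig, adds per-label counts and a one-sided binomial enrichment
    test with expected proportion equal to the label's length fraction.
    """
    if region_bed is None:
        counts = pd.Series([l.contig for l in loci]).value_counts().sort_index()
        return pd.DataFrame({"contig": counts.index, "n_loci": counts.values})
    by_contig: Dict[str, List[Tuple[int, int, str]]] = {}
    for contig, start, end, label in region_bed:
        by_contig.setdefault(contig, []).append((start, end, label))
    for contig, regions in by_contig.items():
        regions.sort()
        for (s1, e1, _), (s2, e2, _) in zip(regions, regions[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping regions on {contig}")
    label_len: Dict[str, int] = {}
    total_len = 0
    for regions in by_contig.values():
        for s, e, lab in regions:
            label_len[lab] = label_len.get(lab, 0) + (e - s)
            total_len += e - s
    label_count: Dict[str, int] = {lab: 0 for lab in label_len}
    for loc in loci:
        mid = (loc.start + loc.end) // 2
        for s, e, lab in by_contig.get(loc.contig, ()):
            if s <= mid < e:
                label_count[lab] += 1
                break
    n = len(loci)
    rows = []
    for lab in sorted(label_len):
        k = label_count[lab]
        p = label_len[lab] / total_len
        pval = stats.binomtest(k, n, p, alternative="greater").pvalue if n else 1.0
        rows.append(
            {
                "label": lab,
                "n_loci": k,
                "length_fraction": p,
                "expected": n * p,
                "enrichment_p": float(pval),
            }
        )
    return pd.DataFrame(rows)
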