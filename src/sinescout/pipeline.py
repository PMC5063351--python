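"""End-to-end annotation pipeline.

Order of operations: true-gene filtering (drop candidates that ARE a
reference tRNA/5S gene or overlap an exclusion interval), hallmark
annotation (TSD, promoter, tail, terminator, terminal motifs),
classification, and - when a genome is supplied - copy mapping. Every
threshold used is logged, and reruns with the same configuration
byte-reproduce all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import yaml

from . import features, io, motifs
from .align import ScoringScheme
from .classify import (
    ClassificationResult,
    ConfigurationError,
    Thresholds,
    classify_element,
    line_3prime_similarity,
    true_gene_filter,
)
from .scan import Locus, ScanParams, map_copies

__all__ = ["RefSets", "PipelineConfig", "ElementAnnotation", "run_pipeline", "annotation_table"]

logger = logging.getLogger("sinescout")


@dataclass
class RefSets:
    """Reference sequence sets for classification and filtering.

    trna / r5s drive the head-identity classification; true_genes (full
    gene sequences) drive the true-gene filter; line holds LINE 3'-UTR
    references for the evidence-only 3' similarity report.
    """

    trna: Optional[io.Catalogue] = None
    r5s: Optional[io.Catalogue] = None
    true_genes: Optional[io.Catalogue] = None
    line: Optional[io.Catalogue] = None
    exclusion_intervals: Optional[List[Tuple[str, int, int]]] = None


@dataclass
class PipelineConfig:
    """All tunables in one place; defaults are the reference conditions
    under which the AfuSINE catalogue was characterised (60%/60-nt head
    rule, 4-14 bp TSDs with headroom to 20, GCTTTTCG terminator)."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    scan_params: ScanParams = field(default_factory=ScanParams)
    tsd_min_len: int = 4
    tsd_max_len: int = 20
    tsd_max_end_offset: int = 0
    tail_window: int = 50
    spacer_bounds: Tuple[int, int] = (10, 150)
    line_window: int = 150
    type2_models: Dict[str, motifs.MotifModel] = field(
        default_factory=lambda: dict(motifs.DEFAULT_TYPE2_MODELS)
    )
    terminator_model: motifs.MotifModel = field(default=motifs.TERMINATOR_MODEL)

    def to_dict(self) -> dict:
        d = {
            "thresholds": asdict(self.thresholds),
            "scheme": asdict(self.scheme),
            "scan_params": asdict(self.scan_params),
            "tsd_min_len": self.tsd_min_len,
            "tsd_max_len": self.tsd_max_len,
            "tsd_max_end_offset": self.tsd_max_end_offset,
            "tail_window": self.tail_window,
            "spacer_bounds": list(self.spacer_bounds),
            "line_window": self.line_window,
            "type2_models": {
                k: {"consensus": m.consensus, "max_mismatch": m.max_mismatch}
                for k, m in self.type2_models.items()
            },
            "terminator": {
                "consensus": self.terminator_model.consensus,
                "max_mismatch": self.terminator_model.max_mismatch,
            },
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "thresholds" in raw:
            cfg.thresholds = Thresholds(**raw["thresholds"])
        if "scheme" in raw:
            cfg.scheme = ScoringScheme(**raw["scheme"])
        if "scan_params" in raw:
            cfg.scan_params = ScanParams(**raw["scan_params"])
        for key in (
            "tsd_min_len",
            "tsd_max_len",
            "tsd_max_end_offset",
            "tail_window",
            "line_window",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "spacer_bounds" in raw:
            cfg.spacer_bounds = tuple(raw["spacer_bounds"])
        if "type2_models" in raw:
            cfg.type2_models = {
                k: motifs.MotifModel(k, v["consensus"], v.get("max_mismatch", 0))
                for k, v in raw["type2_models"].items()
            }
        return cfg


@dataclass
class ElementAnnotation:
    """The full hallmark bundle for one element."""

    record: io.ElementRecord
    kept: bool = True
    tsd: Optional[features.TsdAnnotation] = None
    promoter: Optional[motifs.PromoterAnnotation] = None
    tail: Optional[features.TailAnnotation] = None
    terminator_hit: Optional[motifs.MotifHit] = None
    terminal_motifs: Optional[features.TerminalMotifReport] = None
    classification: Optional[ClassificationResult] = None
    loci: List[Locus] = field(default_factory=list)


def run_pipeline(
    candidates: io.Catalogue,
    refs: RefSets,
    genome: Optional[io.Catalogue] = None,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
) -> List[ElementAnnotation]:
    """Annotate, classify and (optionally) map every candidate element."""
    if len(candidates) == 0:
        raise ConfigurationError("candidate set is empty")
    if refs.trna is None and refs.r5s is None:
        raise ConfigurationError(
            "classification needs a tRNA and/or 5S reference set; "
            "pass --trna/--r5s FASTA files or a RefSets with at least one of them"
        )
    cfg = config or PipelineConfig()
    logger.info("pipeline configuration: %s", cfg.to_dict())
    annotations: List[ElementAnnotation] = []
    for rec in candidates:
        ann = ElementAnnotation(record=rec)
        if refs.true_genes is not None and len(refs.true_genes) > 0:
            ann.kept = true_gene_filter(
                rec,
                refs.true_genes,
                scheme=cfg.scheme,
                exclusion_intervals=refs.exclusion_intervals,
            )
            if not ann.kept:
                logger.info("discarded %s as a true gene", rec.id)
                annotations.append(ann)
                continue
        ann.tsd = features.find_tsd_terminal(
            rec.seq, cfg.tsd_min_len, cfg.tsd_max_len, cfg.tsd_max_end_offset
        )
        ann.promoter = motifs.annotate_type2_promoter(
            rec.seq,
            cfg.type2_models["A_box"],
            cfg.type2_models["B_box"],
            cfg.type2_models.get("Bprime_box"),
            cfg.spacer_bounds,
        )
        if rec.length_bp >= cfg.tail_window:
            ann.tail = features.annotate_tail(rec.seq, cfg.tail_window)
        term_hits = [
            h for h in motifs.scan_motif(rec.seq, cfg.terminator_model) if h.strand == "+"
        ]
        ann.terminator_hit = term_hits[0] if term_hits else None
        ann.terminal_motifs = features.check_terminal_motifs(rec.seq)
        ann.classification = classify_element(
            rec,
            refs.trna,
            refs.r5s,
            cfg.thresholds,
            cfg.type2_models,
            cfg.scheme,
        )
        if refs.line is not None and len(refs.line) > 0:
            ann.classification.line_3prime_match = line_3prime_similarity(
                rec, refs.line, cfg.line_window, cfg.scheme
            )
        if genome is not None:
            ann.loci = map_copies(rec, genome, cfg.scan_params, cfg.scheme)
        annotations.append(ann)
    kept = [a for a in annotations if a.kept]
    if not kept:
        logger.warning("no candidates survived true-gene filtering")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        annotation_table(annotations).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        all_loci = [loc for a in annotations for loc in a.loci]
        io.write_gff3(all_loci, outdir / "loci.gff3")
        (outdir / "run_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return annotations


def annotation_table(annotations: Iterable[ElementAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the tabular report."""
    rows = []
    for a in annotations:
        cls = a.classification
        tail = a.tail
        rows.append(
            {
                "id": a.record.id,
                "length_bp": a.record.length_bp,
                "kept": a.kept,
                "family": cls.family if cls else "",
                "origin_call": (cls.origin_call or "") if cls else "",
                "head_id_pct": round(cls.head_alignment.identity_pct, 1)
                if cls and cls.head_alignment
                else float("nan"),
                "overlap_nt": cls.head_alignment.overlap_nt if cls and cls.head_alignment else 0,
                "promoter_type": a.promoter.promoter_type if a.promoter else "none",
                "tsd_len": a.tsd.length_nt if a.tsd else 0,
                "tsd_seq": a.tsd.tsd_seq if a.tsd else "",
                "tail_unit": (tail.repeat_unit or "") if tail else "",
                "tail_count": tail.repeat_count if tail else 0,
                "oligoT_len": tail.oligo_t[1] if tail and tail.oligo_t else 0,
                "tc_motif": tail.tc_motif_present if tail else False,
                "at_fraction": round(tail.at_fraction_3prime, 3) if tail else float("nan"),
                "terminator": a.terminator_hit is not None,
                "n_loci": len(a.loci),
            }
        )
    return pd.DataFrame(rows)
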