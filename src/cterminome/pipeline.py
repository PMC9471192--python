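"""End-to-end analysis orchestration.

``run_all`` chains ingestion, terminal annotation, labeling QC,
enrichment/reproducibility metrics, and the positional logo into one
deterministic run that writes a TSV per analysis plus a single top-level
summary. Outputs carry no timestamps, so identical inputs give
byte-identical output trees.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import labeling_qc, logo, metrics
from .metrics import DEFAULT_CTERM_CLASSES
from .proteome_io import read_fasta
from .psm_model import PsmRecord, group_peptides, read_psm_table
from .terminal_annotation import (ProteomeIndex, annotate_peptides,
                                  annotations_to_frame, truncation_census)

log = logging.getLogger("cterminome")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    fasta: Path
    psm_tables: list[Path]
    output_dir: Path
    dialect: str = "canonical"
    strict: bool = False
    cterm_classes: frozenset[str] = DEFAULT_CTERM_CLASSES
    logo_anchor: str = "C"
    logo_span: int = 10
    logo_alpha: float = 0.05
    n_replicates: int | None = None   # None = infer from tables

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.psm_tables = [Path(p) for p in self.psm_tables]
        self.output_dir = Path(self.output_dir)
        missing = [str(p) for p in [self.fasta, *self.psm_tables]
                   if not p.is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class RunReport:
    summary: dict
    annotations_frame: pd.DataFrame
    stages_completed: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> RunReport:
    """Run every analysis stage and write the report bundle."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {}

    def stage_done(name: str) -> None:
        manifest.append(name)
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")

    try:
        proteins = read_fasta(config.fasta)
        index = ProteomeIndex(proteins)
        log.info("stage=read_fasta proteins=%d", len(proteins))
        stage_done("read_fasta")

        psms: list[PsmRecord] = []
        n_dropped = 0
        for path in config.psm_tables:
            recs, errors = read_psm_table(path, config.dialect,
                                          config.strict)
            psms.extend(recs)
            n_dropped += len(errors)
            log.info("stage=ingest table=%s rows=%d dropped=%d",
                     path.name, len(recs), len(errors))
        if not psms:
            raise ValueError("no valid PSMs across input tables")
        summary["n_psms"] = len(psms)
        summary["n_psms_dropped"] = n_dropped
        stage_done("ingest")

        groups = group_peptides(psms, key_mods=set())
        replicates = sorted({p.replicate for p in psms})
        n_reps = config.n_replicates or len(replicates)
        summary["n_unique_peptides"] = len(groups)
        summary["n_replicates"] = n_reps

        annotations = annotate_peptides((g.sequence for g in groups), index)
        ann_frame = annotations_to_frame(annotations)
        _write_tsv(ann_frame, out / "annotations.tsv")
        class_counts = ann_frame["terminal_class"].value_counts().to_dict()
        summary["peptides_by_class"] = {
            k: int(v) for k, v in sorted(class_counts.items())}
        log.info("stage=annotate peptides=%d", len(annotations))
        stage_done("annotate")

        census = truncation_census(annotations)
        _write_tsv(census.table, out / "truncation_census.tsv")
        summary["truncation_neo_peptides"] = census.n_neo_peptides
        summary["truncation_proteins"] = census.n_proteins
        stage_done("truncation_census")

        report = labeling_qc.labeling_efficiency(psms)
        _write_tsv(pd.DataFrame(
            [{"sequence": s.sequence, "psm_total": s.psm_total,
              "psm_pca": s.psm_pca, "efficiency": s.efficiency,
              "category": s.category, "eligible": s.eligible}
             for s in report.summaries]), out / "labeling_efficiency.tsv")
        summary["labeling_category_fractions"] = {
            k: round(v, 10) for k, v in report.category_fractions.items()}
        blocking = labeling_qc.site_blocking(psms)
        summary["alpha_blocked_fraction"] = blocking.alpha_blocked_fraction
        summary["epsilon_blocked_fraction"] = (
            blocking.epsilon_blocked_fraction)
        profile = labeling_qc.first_residues_profile(report.summaries)
        _write_tsv(profile, out / "first_residues_profile.tsv")
        ptm = labeling_qc.ptm_distribution(psms, annotations)
        _write_tsv(ptm.on_cterm_peptides, out / "ptm_on_cterm.tsv")
        _write_tsv(ptm.on_last_residue, out / "ptm_on_last_residue.tsv")
        summary["psm_with_ptm_fraction"] = ptm.with_ptm_fraction
        log.info("stage=labeling_qc peptides=%d", len(report.summaries))
        stage_done("labeling_qc")

        enrich = metrics.enrichment_efficiency(
            annotations, groups, config.cterm_classes)
        summary["enrichment_efficiency"] = enrich.efficiency
        summary["n_cterm_peptides"] = enrich.n_cterm
        summary["n_proteins_with_cterm"] = enrich.n_proteins_with_cterm
        overlap = metrics.replicate_overlap(groups, n_reps, replicates)
        summary["replicate_overlap_fractions"] = {
            str(k): round(v, 10) for k, v in overlap.fractions.items()}
        if len(replicates) >= 2:
            pairs = metrics.replicate_correlation(groups)
            summary["pearson_by_pair"] = {
                f"{p.replicate_a}|{p.replicate_b}":
                    (None if pd.isna(p.pearson) else round(p.pearson, 10))
                for p in pairs}
        pooled_intensities = [v for g in groups
                              for v in g.intensity_by_replicate.values()]
        summary["dynamic_range_orders"] = metrics.dynamic_range(
            pooled_intensities)
        stage_done("metrics")

        cterm_seqs = sorted(
            seq for seq, ann in annotations.items()
            if ann.terminal_class in config.cterm_classes)
        if cterm_seqs:
            cells = logo.differential_logo(
                cterm_seqs, logo.proteome_composition(proteins),
                anchor=config.logo_anchor, span=config.logo_span,
                alpha=config.logo_alpha)
            _write_tsv(logo.logo_to_frame(cells), out / "logo.tsv")
            summary["logo_significant_cells"] = sum(
                c.significant for c in cells)
        stage_done("logo")

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True,
                      default=float)
            fh.write("\n")
        stage_done("summary")
    except Exception:
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
        raise
    return RunReport(summary=summary, annotations_frame=ann_frame,
                     stages_completed=manifest)
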