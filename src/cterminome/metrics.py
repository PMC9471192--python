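"""Enrichment, reproducibility, and physicochemical metrics.

Covers the headline quality metrics of a negative-selection C-terminomics
experiment: the selective enrichment efficiency (fraction of C-terminal
peptides among all identified peptides), replicate overlap, pairwise
intensity correlation, abundance dynamic range, and the Kyte–Doolittle
GRAVY hydropathy score.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .psm_model import PeptideGroup
from .terminal_annotation import TerminalAnnotation

#: Kyte–Doolittle hydropathy values for the 20 standard residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Terminal classes counted as C-terminal evidence by default: original
#: protein C-termini plus truncation-derived neo C-termini.
DEFAULT_CTERM_CLASSES = frozenset(
    {"protein_cterm", "both_termini", "neo_cterm"})


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value.

    Negative values are hydrophilic. Raises for residues outside the
    20-letter scale (B/Z/X/U/O have no defined hydropathy).
    """
    if not sequence:
        raise ValueError("empty sequence")
    total = 0.0
    for aa in sequence:
        try:
            total += KYTE_DOOLITTLE[aa]
        except KeyError:
            raise ValueError(f"no hydropathy value for residue {aa!r}")
    return total / len(sequence)


@dataclass
class EnrichmentReport:
    """Selective enrichment efficiency (C-terminal / all peptides)."""

    n_peptides_total: int
    n_cterm: int
    efficiency: float
    n_proteins_with_cterm: int
    per_replicate: dict[str, tuple[int, int, float]] = field(
        default_factory=dict)  # replicate -> (n_cterm, n_total, efficiency)


def enrichment_efficiency(
    annotations: Mapping[str, TerminalAnnotation],
    groups: Sequence[PeptideGroup] | None = None,
    cterm_classes: frozenset[str] | set[str] = DEFAULT_CTERM_CLASSES,
) -> EnrichmentReport:
    """Fraction of unique peptides classified C-terminal.

    ``annotations`` maps each unique peptide sequence to its terminal
    annotation; ``groups`` (optional) adds per-replicate breakdowns from
    replicate membership.
    """
    if not annotations:
        raise ValueError("no annotated peptides")
    n_total = len(annotations)
    cterm_seqs = {seq for seq, ann in annotations.items()
                  if ann.terminal_class in cterm_classes}
    proteins = set()
    for seq in cterm_seqs:
        proteins.update(annotations[seq].accessions)
    per_rep: dict[str, tuple[int, int, float]] = {}
    if groups is not None:
        seqs_by_rep: dict[str, set[str]] = {}
        for g in groups:
            for rep in g.replicates_seen:
                seqs_by_rep.setdefault(rep, set()).add(g.sequence)
        for rep in sorted(seqs_by_rep):
            seqs = {s for s in seqs_by_rep[rep] if s in annotations}
            nc = len(seqs & cterm_seqs)
            per_rep[rep] = (nc, len(seqs),
                            nc / len(seqs) if seqs else float("nan"))
    return EnrichmentReport(
        n_peptides_total=n_total,
        n_cterm=len(cterm_seqs),
        efficiency=len(cterm_seqs) / n_total,
        n_proteins_with_cterm=len(proteins),
        per_replicate=per_rep,
    )


@dataclass
class ReplicateOverlap:
    """Histogram of peptide detection frequency across replicates."""

    n_replicates: int
    counts: dict[int, int]          # exactly-k -> number of peptides
    fractions: dict[int, float]
    cumulative_ge: dict[int, float]  # at-least-k -> fraction


def replicate_overlap(groups: Sequence[PeptideGroup],
                      n_replicates: int,
                      replicate_labels: Iterable[str] | None = None
                      ) -> ReplicateOverlap:
    """Peptides seen in exactly / at least k of n replicates."""
    if replicate_labels is not None:
        declared = set(replicate_labels)
        for g in groups:
            undeclared = g.replicates_seen - declared
            if undeclared:
                raise ValueError(
                    f"group {g.sequence!r} cites undeclared replicate(s) "
                    f"{sorted(undeclared)}")
    counts = {k: 0 for k in range(1, n_replicates + 1)}
    for g in groups:
        k = len(g.replicates_seen)
        if k not in counts:
            raise ValueError(
                f"group {g.sequence!r} seen in {k} replicates but only "
                f"{n_replicates} declared")
        counts[k] += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else float("nan"))
                 for k, v in counts.items()}
    cumulative = {}
    for k in range(1, n_replicates + 1):
        cumulative[k] = sum(fractions[j] for j in range(k, n_replicates + 1))
    return ReplicateOverlap(n_replicates, counts, fractions, cumulative)


@dataclass
class PairCorrelation:
    replicate_a: str
    replicate_b: str
    pearson: float      # NaN when undefined
    n_shared: int


def replicate_correlation(groups: Sequence[PeptideGroup],
                          log_scale: bool = True,
                          min_shared: int = 3) -> list[PairCorrelation]:
    """Pairwise Pearson correlation of peptide intensities.

    Only peptides quantified (intensity > 0) in both members of a pair
    enter that pair's computation, on log10 intensities by default. Pairs
    with fewer than ``min_shared`` shared peptides are reported NaN.
    """
    reps = sorted({r for g in groups for r in g.replicates_seen})
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates")
    wide = pd.DataFrame(
        {rep: {g.key: g.intensity_by_replicate.get(rep, 0.0)
               for g in groups} for rep in reps})
    out = []
    for a, b in itertools.combinations(reps, 2):
        shared = wide[(wide[a] > 0) & (wide[b] > 0)]
        if len(shared) < min_shared:
            out.append(PairCorrelation(a, b, float("nan"), len(shared)))
            continue
        x, y = shared[a].to_numpy(), shared[b].to_numpy()
        if log_scale:
            x, y = np.log10(x), np.log10(y)
        r = float(np.corrcoef(x, y)[0, 1])
        out.append(PairCorrelation(a, b, r, len(shared)))
    return out


def dynamic_range(intensities: Iterable[float]) -> float:
    """log10 span between the largest and smallest positive intensity.

    Zeros (missing quantification) are excluded; fewer than two positive
    values yields NaN.
    """
    vals = [v for v in intensities if v > 0]
    if len(vals) < 2:
        return float("nan")
    return math.log10(max(vals)) - math.log10(min(vals))
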