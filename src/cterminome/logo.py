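"""Positional amino-acid enrichment statistics (sequence-logo style).

Compares per-position residue frequencies of an experimental peptide set
against a reference — either another sequence set or a background
composition table (e.g. proteome-wide residue frequencies) — and flags
over/under-represented (position, residue) cells with a two-sided z-test,
the convention of consensus-difference logo tools. Positions are indexed
+1..+span from the N-terminus or −span..−1 up to the C-terminal residue
(−1 is the last residue).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import ProteinRecord

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


def _positions(anchor: str, span: int) -> list[int]:
    if anchor == "N":
        return list(range(1, span + 1))
    if anchor == "C":
        return list(range(-span, 0))
    raise ValueError(f"anchor must be 'N' or 'C', got {anchor!r}")


def positional_frequencies(sequences: Sequence[str], anchor: str = "C",
                           span: int = 10) -> pd.DataFrame:
    """Per (position, residue) counts and frequencies.

    Shorter sequences contribute only to the positions they cover.
    Returns a frame with columns position, residue, count, frequency,
    coverage (sequences contributing to that position).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    counts: dict[int, defaultdict[str, int]] = {
        p: defaultdict(int) for p in _positions(anchor, span)}
    coverage = {p: 0 for p in counts}
    for seq in sequences:
        n = len(seq)
        for p in counts:
            idx = p - 1 if p > 0 else n + p
            if 0 <= idx < n:
                counts[p][seq[idx]] += 1
                coverage[p] += 1
    rows = []
    for p in counts:
        cov = coverage[p]
        for res in sorted(counts[p]):
            rows.append({"position": p, "residue": res,
                         "count": counts[p][res],
                         "frequency": counts[p][res] / cov,
                         "coverage": cov})
    return pd.DataFrame(rows, columns=["position", "residue", "count",
                                       "frequency", "coverage"])


def proteome_composition(proteins: Iterable[ProteinRecord]
                         ) -> dict[str, float]:
    """Overall residue frequencies of a protein database (standard 20
    letters only)."""
    counts: defaultdict[str, int] = defaultdict(int)
    for prot in proteins:
        for aa in prot.sequence:
            if aa in RESIDUES:
                counts[aa] += 1
    total = sum(counts.values())
    if not total:
        raise ValueError("no standard residues in proteome")
    return {aa: counts.get(aa, 0) / total for aa in RESIDUES}


def reference_composition() -> dict[str, float]:
    """Bundled average human proteome residue composition."""
    with resources.as_file(
            resources.files("cterminome.data")
            .joinpath("aa_composition_human.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["residue"], df["frequency"]))


@dataclass(frozen=True)
class LogoCell:
    """One (position, residue) comparison result."""

    position: int
    residue: str
    f_exp: float
    f_ref: float
    diff: float
    z: float
    p_value: float
    significant: bool


def differential_logo(exp_sequences: Sequence[str],
                      reference: Sequence[str] | Mapping[str, float],
                      anchor: str = "C", span: int = 10,
                      alpha: float = 0.05,
                      bonferroni: bool = False) -> list[LogoCell]:
    """Positional over/under-representation against a reference.

    With a background composition table the test is a one-sample z-test
    of the experimental frequency against f_ref with n = position
    coverage (exact binomial fallback when f_ref is 0 or 1); with a
    reference *sequence set* a two-proportion pooled z-test is used, a
    statistic symmetric under swapping the two sets. No multiple-testing
    correction by default; Bonferroni across tested cells on request.
    """
    if not exp_sequences:
        raise ValueError("empty experimental set")
    exp = positional_frequencies(exp_sequences, anchor, span)
    exp_piv = {(r.position, r.residue): (r.count, r.coverage)
               for r in exp.itertuples(index=False)}
    exp_cov = dict(zip(exp["position"], exp["coverage"]))

    two_sample = not isinstance(reference, Mapping)
    if two_sample:
        ref = positional_frequencies(list(reference), anchor, span)
        ref_piv = {(r.position, r.residue): (r.count, r.coverage)
                   for r in ref.itertuples(index=False)}
        ref_cov = dict(zip(ref["position"], ref["coverage"]))

    cells: list[tuple[int, str, float, float, float, float]] = []
    for pos in _positions(anchor, span):
        n1 = exp_cov.get(pos, 0)
        if n1 == 0:
            continue
        if two_sample:
            n2 = ref_cov.get(pos, 0)
            if n2 == 0:
                continue
        residues = {res for (p, res) in exp_piv if p == pos}
        if two_sample:
            residues |= {res for (p, res) in ref_piv if p == pos}
        for res in sorted(residues):
            c1 = exp_piv.get((pos, res), (0, n1))[0]
            f1 = c1 / n1
            if two_sample:
                c2 = ref_piv.get((pos, res), (0, n2))[0]
                f2 = c2 / n2
                pooled = (c1 + c2) / (n1 + n2)
                se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
                if se == 0:
                    z, p = 0.0, 1.0
                else:
                    z = (f1 - f2) / se
                    p = 2 * stats.norm.sf(abs(z))
            else:
                f2 = reference.get(res, 0.0)
                if f2 in (0.0, 1.0):
                    # degenerate reference: exact binomial
                    p = float(stats.binomtest(c1, n1, f2).pvalue)
                    z = float("inf") if (f1 - f2) > 0 else (
                        float("-inf") if (f1 - f2) < 0 else 0.0)
                else:
                    z = (f1 - f2) / np.sqrt(f2 * (1 - f2) / n1)
                    p = 2 * stats.norm.sf(abs(z))
            cells.append((pos, res, f1, f2, float(z), float(p)))

    threshold = alpha / len(cells) if (bonferroni and cells) else alpha
    return [LogoCell(pos, res, f1, f2, f1 - f2, z, p, p < threshold)
            for pos, res, f1, f2, z, p in cells]


def logo_to_frame(cells: Sequence[LogoCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"position": c.position, "residue": c.residue, "f_exp": c.f_exp,
          "f_ref": c.f_ref, "diff": c.diff, "z": c.z,
          "p_value": c.p_value, "significant": c.significant}
         for c in cells],
        columns=["position", "residue", "f_exp", "f_ref", "diff", "z",
                 "p_value", "significant"])
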