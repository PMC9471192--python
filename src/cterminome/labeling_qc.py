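"""Derivatization quality control from PSM evidence.

2-PCA condenses with the free alpha-amine at a peptide N-terminus; an
N-terminally acetylated peptide or one with proline at position 2 cannot
react. NHS-biotin acylates lysine epsilon-amines. This module estimates
the stoichiometry of both labels by spectral counting — the fraction of
PSMs of a peptide that carry the label — and provides the stratified
comparisons (length, hydropathy, first residues, retention time, score)
used to characterize what drives labeling efficiency.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psm_model import N_TERM, PsmRecord
from .terminal_annotation import TerminalAnnotation

CATEGORY_FULL = "full"
CATEGORY_PARTIAL = "partial"
CATEGORY_NONE = "none"

#: Spectral-count efficiency strata reported alongside categories.
DEFAULT_EFFICIENCY_BREAKPOINTS = (0.5, 0.9)


@dataclass
class LabelingSummary:
    """Per-peptide 2-PCA labeling stoichiometry by spectral counting."""

    sequence: str
    psm_total: int
    psm_pca: int
    efficiency: float
    category: str            # full / partial / none
    eligible: bool           # False when acetylated or position-2 proline
    acetylated: bool
    p2_proline: bool


@dataclass
class LabelingReport:
    summaries: list[LabelingSummary]
    category_fractions: dict[str, float]
    category_counts: dict[str, int]
    #: among category "none": fraction acetylated / with P at position 2
    none_acetylated_fraction: float
    none_p2_proline_fraction: float
    #: among partial: fraction with efficiency > 0.9 and in [0.5, 0.9]
    stratum_fractions: dict[str, float] = field(default_factory=dict)


def labeling_efficiency(psms: Sequence[PsmRecord],
                        breakpoints: tuple[float, float] =
                        DEFAULT_EFFICIENCY_BREAKPOINTS) -> LabelingReport:
    """Spectral-counting 2-PCA stoichiometry per bare peptide sequence.

    PSMs are pooled by sequence regardless of label status; efficiency is
    labeled-PSMs / total-PSMs. Category: full (1.0), none (0.0), partial
    (otherwise). Eligibility marks peptides that cannot react at all —
    N-terminal acetylation evidence or proline at position 2.
    """
    if not psms:
        raise ValueError("no PSMs")
    by_seq: dict[str, list[PsmRecord]] = defaultdict(list)
    for p in psms:
        by_seq[p.sequence].append(p)
    summaries = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        total = len(members)
        n_pca = sum(1 for m in members if m.pca_labeled)
        acet = any(m.acetylated for m in members)
        p2p = len(seq) >= 2 and seq[1] == "P"
        eff = n_pca / total
        category = (CATEGORY_FULL if eff == 1.0
                    else CATEGORY_NONE if eff == 0.0
                    else CATEGORY_PARTIAL)
        summaries.append(LabelingSummary(
            sequence=seq, psm_total=total, psm_pca=n_pca, efficiency=eff,
            category=category, eligible=not (acet or p2p),
            acetylated=acet, p2_proline=p2p))
    n = len(summaries)
    counts = Counter(s.category for s in summaries)
    fractions = {c: counts.get(c, 0) / n
                 for c in (CATEGORY_FULL, CATEGORY_PARTIAL, CATEGORY_NONE)}
    none_set = [s for s in summaries if s.category == CATEGORY_NONE]
    lo, hi = breakpoints
    partial = [s for s in summaries if s.category == CATEGORY_PARTIAL]
    strata = {}
    if partial:
        strata[f">{hi:g}"] = sum(s.efficiency > hi for s in partial) / len(partial)
        strata[f"{lo:g}-{hi:g}"] = (
            sum(lo <= s.efficiency <= hi for s in partial) / len(partial))
        strata[f"<{lo:g}"] = sum(s.efficiency < lo for s in partial) / len(partial)
    return LabelingReport(
        summaries=summaries,
        category_fractions=fractions,
        category_counts={c: counts.get(c, 0) for c in fractions},
        none_acetylated_fraction=(
            sum(s.acetylated for s in none_set) / len(none_set)
            if none_set else float("nan")),
        none_p2_proline_fraction=(
            sum(s.p2_proline for s in none_set) / len(none_set)
            if none_set else float("nan")),
        stratum_fractions=strata,
    )


@dataclass
class SiteBlockingReport:
    """Amine blocking fractions over PSM-level site occurrences.

    alpha: N-termini carrying 2-PCA or endogenous acetyl (both leave no
    free alpha-amine). epsilon: lysine occurrences carrying biotin. The
    epsilon fraction is NaN when no K occurs anywhere (undefined, not 0).
    """

    alpha_blocked_fraction: float
    epsilon_blocked_fraction: float
    n_psms: int
    n_k_occurrences: int
    per_replicate: dict[str, tuple[float, float]] = field(
        default_factory=dict)  # replicate -> (alpha, epsilon)


def site_blocking(psms: Sequence[PsmRecord]) -> SiteBlockingReport:
    """PSM-level alpha- and epsilon-amine blocking fractions."""
    if not psms:
        raise ValueError("no PSMs")

    def _fractions(members: Sequence[PsmRecord]) -> tuple[float, float, int]:
        alpha_blocked = sum(1 for p in members
                            if p.pca_labeled or p.acetylated)
        k_total = 0
        k_biotin = 0
        for p in members:
            biotin_sites = {m.site for m in p.modifications
                            if m.name == "Biotin" and isinstance(m.site, int)}
            for pos, aa in enumerate(p.sequence, start=1):
                if aa == "K":
                    k_total += 1
                    if pos in biotin_sites:
                        k_biotin += 1
        alpha = alpha_blocked / len(members)
        eps = k_biotin / k_total if k_total else float("nan")
        return alpha, eps, k_total

    alpha, eps, k_total = _fractions(psms)
    per_rep = {}
    for rep in sorted({p.replicate for p in psms}):
        members = [p for p in psms if p.replicate == rep]
        a, e, _ = _fractions(members)
        per_rep[rep] = (a, e)
    return SiteBlockingReport(
        alpha_blocked_fraction=alpha,
        epsilon_blocked_fraction=eps,
        n_psms=len(psms),
        n_k_occurrences=k_total,
        per_replicate=per_rep,
    )


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    paired: bool
    skipped_reason: str | None = None


def stratified_compare(values_by_group: Mapping[str, Mapping[str, float]],
                       paired: bool | None = None) -> list[GroupComparison]:
    """Two-sided Student t-tests between all group pairs of an attribute.

    ``values_by_group`` maps group label -> {item key (e.g. sequence):
    value}. The paired variant is used when both groups cover the same
    item keys 1:1 (e.g. the same peptide with and without label); Welch's
    unpaired test otherwise. Pass ``paired`` to force either. Pairs where
    a group has fewer than 2 observations are reported with a skip reason.
    """
    out = []
    for (la, da), (lb, db) in itertools.combinations(
            sorted(values_by_group.items()), 2):
        if len(da) < 2 or len(db) < 2:
            out.append(GroupComparison(
                la, lb, len(da), len(db), float("nan"), float("nan"),
                float("nan"), float("nan"), float("nan"), False,
                skipped_reason="group with < 2 observations"))
            continue
        use_paired = (set(da) == set(db)) if paired is None else paired
        if use_paired:
            keys = sorted(set(da) & set(db))
            if len(keys) < 2:
                out.append(GroupComparison(
                    la, lb, len(da), len(db), float("nan"), float("nan"),
                    float("nan"), float("nan"), float("nan"), True,
                    skipped_reason="fewer than 2 matched items"))
                continue
            x = np.array([da[k] for k in keys])
            y = np.array([db[k] for k in keys])
            t, p = stats.ttest_rel(x, y)
        else:
            x = np.array(list(da.values()))
            y = np.array(list(db.values()))
            t, p = stats.ttest_ind(x, y, equal_var=False)
        out.append(GroupComparison(
            la, lb, len(x), len(y), float(np.mean(x)), float(np.mean(y)),
            float(np.mean(x) - np.mean(y)), float(t), float(p), use_paired))
    return out


def first_residues_profile(summaries: Sequence[LabelingSummary]
                           ) -> pd.DataFrame:
    """Labeling outcome rates by residue at positions 1-3.

    For each (position, residue): peptide count, fully-labeled fraction,
    unlabeled fraction. Peptides shorter than a position do not contribute
    to it.
    """
    rows = []
    for pos in (1, 2, 3):
        contrib = [s for s in summaries if len(s.sequence) >= pos]
        by_res: dict[str, list[LabelingSummary]] = defaultdict(list)
        for s in contrib:
            by_res[s.sequence[pos - 1]].append(s)
        for res in sorted(by_res):
            members = by_res[res]
            n = len(members)
            rows.append({
                "position": pos,
                "residue": res,
                "count": n,
                "full_fraction": sum(
                    s.category == CATEGORY_FULL for s in members) / n,
                "none_fraction": sum(
                    s.category == CATEGORY_NONE for s in members) / n,
            })
    return pd.DataFrame(rows, columns=["position", "residue", "count",
                                       "full_fraction", "none_fraction"])


@dataclass
class PtmDistribution:
    """Modification frequency tables over PSMs and C-terminal peptides."""

    with_ptm_fraction: float            # PSMs with >=1 non-static mod
    on_cterm_peptides: pd.DataFrame     # name, count, frequency
    on_last_residue: pd.DataFrame       # mods sited on the final residue
                                        # of original C-terminal peptides


def ptm_distribution(psms: Sequence[PsmRecord],
                     annotations: Mapping[str, TerminalAnnotation],
                     static_mods: frozenset[str] = frozenset(
                         {"Carbamidomethyl"}),
                     cterm_classes: frozenset[str] = frozenset(
                         {"protein_cterm", "both_termini"})
                     ) -> PtmDistribution:
    """Modification census joined to terminal annotations.

    Static chemistry-wide alkylation (carbamidomethyl) does not count as
    a PTM. Table (ii) counts modification names over PSMs of C-terminal
    peptides; table (iii) restricts to modifications sited on the last
    residue of original protein C-terminal peptides.
    """
    if not psms:
        raise ValueError("no PSMs")
    n_with = sum(
        1 for p in psms
        if any(m.name not in static_mods for m in p.modifications))
    cterm_counts: Counter[str] = Counter()
    last_counts: Counter[str] = Counter()
    for p in psms:
        ann = annotations.get(p.sequence)
        if ann is None or ann.terminal_class not in cterm_classes:
            continue
        for m in p.modifications:
            if m.name in static_mods:
                continue
            cterm_counts[m.name] += 1
            on_last = (m.site == len(p.sequence)
                       or m.site == "C-term")
            if on_last:
                last_counts[m.name] += 1

    def _table(counter: Counter[str]) -> pd.DataFrame:
        total = sum(counter.values())
        rows = [{"modification": name, "count": c,
                 "frequency": c / total}
                for name, c in sorted(counter.items(),
                                      key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows,
                            columns=["modification", "count", "frequency"])

    return PtmDistribution(
        with_ptm_fraction=n_with / len(psms),
        on_cterm_peptides=_table(cterm_counts),
        on_last_residue=_table(last_counts),
    )
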