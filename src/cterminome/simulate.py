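"""Ground-truthed synthetic data emulating a negative-selection
C-terminomics experiment.

The generator walks the full experimental logic: sample a proteome;
plant C-terminal truncation proteoforms (present in the sample, absent
from the database, so their termini are discoverable only as
neo-C-termini); digest with Lys-C/P; assign log-normal peptide
abundances; per replicate, sample detection and spectral counts; per
PSM, draw the alpha-amine label (2-PCA) from a covariate-dependent
logistic model (length, GRAVY, first residue; hard zero for N-terminal
acetylation and position-2 proline) and per-lysine biotinylation; deplete
biotinylated PSMs (streptavidin capture); and emit canonical PSM tables
plus a truth ledger for every draw.

Every random draw comes from one seeded generator in a fixed order, so a
seed pins the complete output byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .digestion import DigestParams, digest
from .metrics import gravy
from .proteome_io import ProteinRecord, write_fasta
from .psm_model import (Modification, N_TERM, PsmRecord, write_psm_table)

CTERM_CLASSES = frozenset({"protein_cterm", "both_termini", "neo_cterm"})


def _default_composition() -> dict[str, float]:
    from .logo import reference_composition
    return reference_composition()


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Probabilities are in [0, 1]; length parameters are natural-log
    moments of the protein length distribution; abundance parameters are
    log10 moments (sigma_between across peptides, sigma_within across
    replicates of one peptide).
    """

    seed: int = 0
    n_proteins: int = 300
    length_log_mu: float = 5.9      # median ~365 aa
    length_log_sigma: float = 0.45
    min_protein_length: int = 60
    max_protein_length: int = 2000
    composition: dict[str, float] | None = None  # None = bundled human

    truncation_probability: float = 0.05
    truncation_site_range: tuple[float, float] = (0.3, 0.9)

    acetylation_probability: float = 0.5   # protein-initial peptides

    # 2-PCA logistic model on the alpha-amine
    pca_intercept: float = 3.0
    pca_beta_length: float = -0.08
    pca_length_center: float = 12.0
    pca_beta_gravy: float = -0.5
    pca_first_residue_offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 1.5, "L": 1.5, "E": 1.5,
                                 "G": -2.5, "K": -1.0})
    #: Optional direct per-first-residue labeling probabilities; when set,
    #: overrides the logistic for those strata (ineligible peptides stay 0).
    pca_probability_override: dict[str, float] | None = None

    biotin_efficiency: float = 0.977       # per K site, per PSM
    apply_depletion: bool = True           # captured iff >=1 biotin-K

    detection_probability: float = 0.8     # per peptide per replicate
    #: "normal": log10 abundance ~ N(mu, sigma_between);
    #: "uniform": log10 abundance ~ U(abundance_log10_range).
    abundance_distribution: str = "normal"
    abundance_log10_mu: float = 6.0
    abundance_log10_range: tuple[float, float] = (3.0, 10.5)
    sigma_between: float = 1.5
    sigma_within: float = 0.25
    psm_extra_poisson_mean: float = 2.0    # PSM count = 1 + Poisson(mean)
    n_replicates: int = 3

    max_missed_cleavages: int = 2
    missed_cleavage_retention: float = 0.3  # keep mc=k w.p. retention**k
    min_peptide_length: int = 6

    oxidation_probability: float = 0.05    # per M occurrence per PSM

    def __post_init__(self) -> None:
        for name in ("truncation_probability", "acetylation_probability",
                     "biotin_efficiency", "detection_probability",
                     "missed_cleavage_retention", "oxidation_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pca_probability_override:
            for k, v in self.pca_probability_override.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"pca_probability_override[{k!r}]={v} outside [0,1]")
        for name in ("length_log_sigma", "sigma_between", "sigma_within",
                     "psm_extra_poisson_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be >= 1")
        lo, hi = self.truncation_site_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("truncation_site_range must satisfy 0<lo<=hi<1")
        if self.abundance_distribution not in ("normal", "uniform"):
            raise ValueError("abundance_distribution must be "
                             "'normal' or 'uniform'")

    # -- labeling model ---------------------------------------------------
    def pca_probability(self, sequence: str, acetylated: bool) -> float:
        """True 2-PCA labeling probability for one peptide species."""
        if acetylated or (len(sequence) >= 2 and sequence[1] == "P"):
            return 0.0
        first = sequence[0]
        if (self.pca_probability_override is not None
                and first in self.pca_probability_override):
            return self.pca_probability_override[first]
        logit = (self.pca_intercept
                 + self.pca_beta_length
                 * (len(sequence) - self.pca_length_center)
                 + self.pca_beta_gravy * gravy(sequence)
                 + self.pca_first_residue_offsets.get(first, 0.0))
        return 1.0 / (1.0 + math.exp(-logit))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncation_site_range"] = list(self.truncation_site_range)
        d["abundance_log10_range"] = list(self.abundance_log10_range)
        return d


@dataclass
class SyntheticTruth:
    """Ground-truth ledger emitted alongside the synthetic tables."""

    truncations: pd.DataFrame   # accession, cut_position (1-based, length
                                # of the truncated proteoform)
    peptides: pd.DataFrame      # per unique peptide species: sequence,
                                # true_class, n_k, acetylated, p2_proline,
                                # pca_probability, abundance_log10
    psms: pd.DataFrame          # per PSM incl. captured flag (pre- and
                                # post-depletion bookkeeping)
    post_depletion_cterm_fraction: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    proteins: list[ProteinRecord]          # the searchable database
    psms_by_replicate: dict[str, list[PsmRecord]]  # post-depletion
    truth: SyntheticTruth

    def all_psms(self) -> list[PsmRecord]:
        out: list[PsmRecord] = []
        for rep in sorted(self.psms_by_replicate):
            out.extend(self.psms_by_replicate[rep])
        return out

    def write(self, outdir: str | Path) -> None:
        """Write FASTA + per-replicate PSM TSVs + truth + config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteome.fasta")
        for rep in sorted(self.psms_by_replicate):
            write_psm_table(self.psms_by_replicate[rep],
                            outdir / f"psms_{rep}.tsv")
        self.truth.truncations.to_csv(
            outdir / "truth_truncations.tsv", sep="\t", index=False)
        self.truth.peptides.to_csv(
            outdir / "truth_peptides.tsv", sep="\t", index=False)
        self.truth.psms.to_csv(
            outdir / "truth_psms.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)


def _sample_proteins(cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[ProteinRecord]:
    comp = cfg.composition or _default_composition()
    residues = sorted(comp)
    probs = np.array([comp[r] for r in residues], dtype=float)
    probs /= probs.sum()
    lengths = np.clip(
        rng.lognormal(cfg.length_log_mu, cfg.length_log_sigma,
                      cfg.n_proteins).astype(int),
        cfg.min_protein_length, cfg.max_protein_length)
    proteins = []
    width = len(str(cfg.n_proteins))
    for i, ln in enumerate(lengths, start=1):
        seq = "".join(rng.choice(residues, size=int(ln), p=probs))
        proteins.append(ProteinRecord(
            accession=f"SYN{i:0{width}d}", sequence=seq))
    return proteins


def _plant_truncations(cfg: SimulationConfig, proteins: list[ProteinRecord],
                       rng: np.random.Generator
                       ) -> list[tuple[str, int]]:
    """Choose truncation cut positions whose neo C-terminal peptide is a
    usable witness: length >= min peptide length and last residue != K."""
    from .digestion import cleavage_sites

    events = []
    lo, hi = cfg.truncation_site_range
    for prot in proteins:
        if rng.random() >= cfg.truncation_probability:
            continue
        n = len(prot.sequence)
        for _ in range(50):
            cut = int(rng.integers(int(lo * n), int(hi * n)) + 1)
            trunc_seq = prot.sequence[:cut]
            if trunc_seq[-1] == "K":
                continue
            sites = [0] + cleavage_sites(trunc_seq) + [cut]
            neo_len = cut - sites[-2]
            if neo_len < cfg.min_peptide_length or neo_len == cut:
                continue  # too short, or spans the whole proteoform
            events.append((prot.accession, cut))
            break
    return events


def _true_class(contexts: list[tuple[str, bool, bool]],
                sequence: str,
                proteins: list[ProteinRecord]) -> str:
    """Source-derived terminal class of one peptide species.

    ``contexts`` holds (source accession, at_source_cterm, at_source_nterm)
    over every digestion context that produced the sequence. Suffix/prefix
    bookkeeping against the canonical database resolves coincidental
    matches at protein ends the same way an annotator observing only the
    database would.
    """
    canonical_cterm = any(p.sequence.endswith(sequence) for p in proteins)
    full = any(p.sequence == sequence for p in proteins)
    if canonical_cterm:
        return "both_termini" if full else "protein_cterm"
    if sequence.endswith("K"):
        if any(p.sequence.startswith(sequence) for p in proteins):
            return "protein_nterm"
        return "internal"
    # ends at a truncation cut (or nowhere canonical): neo evidence
    return "neo_cterm"


def simulate(config: SimulationConfig | None = None,
             outdir: str | Path | None = None) -> SimulationResult:
    """Run the generator; optionally write the file bundle to ``outdir``."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    proteins = _sample_proteins(cfg, rng)
    truncations = _plant_truncations(cfg, proteins, rng)
    by_acc = {p.accession: p for p in proteins}

    # digestion sources: canonical proteins + truncated proteoforms
    sources: list[tuple[str, ProteinRecord]] = [
        ("canonical", p) for p in proteins]
    for acc, cut in truncations:
        sources.append(("truncated", ProteinRecord(
            accession=f"{acc}#1-{cut}",
            sequence=by_acc[acc].sequence[:cut])))

    params = DigestParams(max_missed_cleavages=cfg.max_missed_cleavages,
                          min_length=cfg.min_peptide_length,
                          max_length=None, cleave_before_proline=True)
    # peptide species pool: unique sequences with their source contexts
    contexts: dict[str, list[tuple[str, bool, bool]]] = {}
    for kind, src in sources:
        for pep in digest(src, params):
            if pep.missed_cleavages > 0:
                keep = (rng.random()
                        < cfg.missed_cleavage_retention
                        ** pep.missed_cleavages)
                if not keep:
                    continue
            at_c = pep.end == len(src.sequence)
            at_n = pep.start == 1
            contexts.setdefault(pep.sequence, []).append(
                (src.accession, at_c and kind == "canonical", at_n))

    sequences = sorted(contexts)
    pep_rows = []
    pep_attrs: dict[str, dict] = {}
    for seq in sequences:
        ctx = contexts[seq]
        cls = _true_class(ctx, seq, proteins)
        protein_initial = any(
            at_n and not acc.partition("#")[2] for acc, _, at_n in ctx)
        acet = bool(protein_initial
                    and rng.random() < cfg.acetylation_probability)
        p_pca = cfg.pca_probability(seq, acet)
        if cfg.abundance_distribution == "uniform":
            a_lo, a_hi = cfg.abundance_log10_range
            abundance = float(rng.uniform(a_lo, a_hi))
        else:
            abundance = float(rng.normal(cfg.abundance_log10_mu,
                                         cfg.sigma_between))
        n_k = seq.count("K")
        pep_attrs[seq] = dict(true_class=cls, acetylated=acet,
                              pca_probability=p_pca, abundance=abundance,
                              n_k=n_k, context=ctx[0])
        pep_rows.append({
            "sequence": seq,
            "true_class": cls,
            "n_k": n_k,
            "acetylated": acet,
            "p2_proline": len(seq) >= 2 and seq[1] == "P",
            "pca_probability": p_pca,
            "abundance_log10": abundance,
        })

    psm_truth_rows = []
    psms_by_rep: dict[str, list[PsmRecord]] = {}
    emitted_seqs: set[str] = set()
    for r in range(1, cfg.n_replicates + 1):
        rep = f"rep{r}"
        rep_psms: list[PsmRecord] = []
        serial = 0
        for seq in sequences:
            a = pep_attrs[seq]
            if rng.random() >= cfg.detection_probability:
                continue
            n_psm = 1 + int(rng.poisson(cfg.psm_extra_poisson_mean))
            rep_intensity = 10.0 ** (a["abundance"]
                                     + rng.normal(0.0, cfg.sigma_within))
            k_positions = [i + 1 for i, aa in enumerate(seq) if aa == "K"]
            m_positions = [i + 1 for i, aa in enumerate(seq) if aa == "M"]
            src_acc, _, _ = a["context"]
            src_seq = (by_acc[src_acc].sequence
                       if src_acc in by_acc
                       else by_acc[src_acc.partition("#")[0]].sequence)
            start = src_seq.find(seq)
            prec = src_seq[start - 1] if start > 0 else "-"
            parent_acc = src_acc.partition("#")[0]
            parent_seq = by_acc[parent_acc].sequence
            end = start + len(seq)
            foll = parent_seq[end] if end < len(parent_seq) else "-"
            for _ in range(n_psm):
                serial += 1
                pca = bool(rng.random() < a["pca_probability"])
                biotin_sites = [pos for pos in k_positions
                                if rng.random() < cfg.biotin_efficiency]
                captured = bool(biotin_sites)
                score = float(rng.normal(60.0, 15.0))
                mods: list[Modification] = []
                if pca:
                    mods.append(Modification("PCA", N_TERM))
                if a["acetylated"]:
                    mods.append(Modification("Acetyl", N_TERM))
                mods.extend(Modification("Biotin", pos, "K")
                            for pos in biotin_sites)
                mods.extend(Modification("Carbamidomethyl", pos, "C")
                            for pos, aa in enumerate(seq, start=1)
                            if aa == "C")
                mods.extend(Modification("Oxidation", pos, "M")
                            for pos in m_positions
                            if rng.random() < cfg.oxidation_probability)
                psm_id = f"{rep}:{serial:06d}"
                psm_truth_rows.append({
                    "psm_id": psm_id, "replicate": rep, "sequence": seq,
                    "source": src_acc, "true_class": a["true_class"],
                    "pca": pca, "acetylated": a["acetylated"],
                    "n_biotin": len(biotin_sites),
                    "n_k": a["n_k"], "captured": captured,
                })
                if cfg.apply_depletion and captured:
                    continue
                emitted_seqs.add(seq)
                rep_psms.append(PsmRecord(
                    psm_id=psm_id, replicate=rep, sequence=seq,
                    preceding_obs=prec, following_obs=foll,
                    modifications=tuple(mods),
                    intensity=rep_intensity / n_psm,
                    score=score, charge=2))
        psms_by_rep[rep] = rep_psms

    n_emitted = len(emitted_seqs)
    n_cterm = sum(1 for s in emitted_seqs
                  if pep_attrs[s]["true_class"] in CTERM_CLASSES)
    truth = SyntheticTruth(
        truncations=pd.DataFrame(truncations,
                                 columns=["accession", "cut_position"]),
        peptides=pd.DataFrame(pep_rows),
        psms=pd.DataFrame(psm_truth_rows),
        post_depletion_cterm_fraction=(
            n_cterm / n_emitted if n_emitted else float("nan")),
    )
    result = SimulationResult(config=cfg, proteins=proteins,
                              psms_by_replicate=psms_by_rep, truth=truth)
    if outdir is not None:
        result.write(outdir)
    return result


def analytic_expectations(config: SimulationConfig) -> dict[str, float]:
    """Closed-form expectations implied by a configuration.

    Returns: escape probability of a peptide with k lysines
    ``(1 - biotin_efficiency) ** k`` for k = 1..3; the all-replicates
    detection fraction ``p_det ** n``; and the expected between-replicate
    Pearson correlation of log10 intensities from the variance components
    ``sigma_between**2 / (sigma_between**2 + sigma_within**2)``.
    """
    eps = config.biotin_efficiency
    s2b = config.sigma_between ** 2
    s2w = config.sigma_within ** 2
    out = {
        "all_replicate_fraction":
            config.detection_probability ** config.n_replicates,
        "expected_pearson": s2b / (s2b + s2w) if (s2b + s2w) > 0 else 1.0,
    }
    for k in (1, 2, 3):
        out[f"escape_probability_{k}K"] = (1.0 - eps) ** k
    return out
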