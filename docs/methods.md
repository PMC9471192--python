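# Methods

This note documents the models and numerical conventions implemented in
`cterminome`, the defaults of the synthetic-data generator, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Digestion model

Lys-C cleaves the peptide bond C-terminal to lysine. The default enzyme
mode is **Lys-C/P** — K-P bonds are cleaved too, matching the common
search-engine setting — with strict Lys-C available
(`cleave_before_proline=False`) for sensitivity analysis. Peptides are
1-based inclusive coordinate spans; `missed_cleavages` counts retained
internal cleavage sites, which under Lys-C/P equals the number of K
residues before the last position. Products combine up to
`max_missed_cleavages + 1` consecutive fully-cleaved segments (default
2) and are filtered to a length window (default minimum 6 residues).

The **theoretical C-terminome** statistic takes one peptide per protein:
the zero-missed-cleavage C-terminal product, windowed to 6–50 residues.
Using only mc = 0 products keeps the census at one peptide per protein;
allowing missed-cleavage variants would count the same protein terminus
several times. The headline quantity is the fraction of these peptides
with proline at position 2 — the class invisible to alpha-amine
derivatization (below).

## Terminal classification

Identified peptides are located by exact substring search (a 6-mer
seeded index; I and L are distinct letters, since matching is
database-side). Precedence rules, most conservative first:

1. any match ending at a protein's last residue → `protein_cterm`
   (`both_termini` if that match also starts at residue 1). This wins
   over every other reading so that peptides shared between proteins
   never inflate the truncation census.
2. else a K-terminated peptide is a regular Lys-C product:
   `protein_nterm` if some match starts at residue 1, else `internal`.
3. else `neo_cterm`: truncation evidence. Requiring a non-K last residue
   is deliberate — a K-terminated peptide is always explainable as an
   ordinary digestion product.

`specific_nterm` records whether the preceding database residue is K or
the protein start; a peptide whose preceding residue is neither is
additionally flagged as a neo-N-terminus candidate. The classifier is
deterministic and independent of match enumeration order. A closure
property holds and is tested: every digestion product of a database
protein classifies as an original class, never `neo_*`.

The truncation census counts unique `neo_cterm` sequences and the
distinct proteins they map to (a protein counts once regardless of how
many truncation peptides it carries). On the bundled curated examples
(14 peptides of HSP90AB1 and histone H4) the census is 12 neo + 2
original C-termini: the two peptides whose following residue is the
protein end (`[-]`) are original termini by rule 1, even though they
co-occur with nested truncation series.

## Labeling chemistry model

2-PCA condenses with free peptide N-terminal α-amines; the reaction is
impossible for N-terminally acetylated peptides and for peptides with
proline at position 2 (no productive cyclization). Both classes are
flagged ineligible. "Blocked" α-amines include endogenous acetylation,
since an acetylated N-terminus needs no chemical blocking for the
negative selection to work.

Stoichiometry is estimated by **spectral counting**: per peptide
sequence (pooled over label status), efficiency = labeled PSMs / total
PSMs, categorized full (1.0) / none (0.0) / partial, with configurable
reporting strata (defaults 0.5 and 0.9). Grouping elsewhere treats the
same sequence with and without 2-PCA as two species (the grouping key
includes PCA status) because they are chromatographically and
spectrally distinct.

Site-level blocking is computed over PSM-level occurrences: the α
fraction over PSM N-termini and the ε fraction over individual lysine
occurrences (biotin present at that position). When no lysine occurs the
ε fraction is undefined (NaN), never 0. A peptide-level variant can be
derived from the summaries; PSM-level is the default denominator.

Stratified comparisons (length, GRAVY, retention-type attributes, ion
score) use two-sided Student t-tests: paired when the two groups cover
identical item keys 1:1 (same peptide labeled vs unlabeled), Welch's
unpaired otherwise; the choice is recorded in the output. Groups with
fewer than two observations are skipped with a reason.

## Metrics

- **GRAVY**: mean Kyte–Doolittle hydropathy over the 20 standard
  residues; peptides containing B/Z/X/U/O have no defined value and are
  excluded from hydropathy summaries.
- **Enrichment efficiency**: unique peptides classified C-terminal
  (default class set {protein_cterm, both_termini, neo_cterm}) over all
  unique peptides. Neo termini count as C-terminal evidence by default
  because they are genuine sample C-termini; the class set is a
  parameter, so the stricter reading is one flag away. Unique peptides,
  not PSMs, form the default denominator (a PSM-level variant is
  directly computable from the groups).
- **Replicate overlap**: histogram of "seen in exactly k of n
  replicates" with cumulative ≥k fractions.
- **Replicate correlation**: Pearson on log10 intensities (standard for
  MS intensities; raw scale by flag), per pair, using only peptides
  quantified (> 0) in both members; pairs with fewer than 3 shared
  peptides are undefined.
- **Dynamic range**: log10(max) − log10(min) over positive peptide
  intensities pooled across replicates.

## Positional enrichment statistics

Per (position, residue) the experimental frequency is compared with a
reference. Two modes:

- **background mode** (reference = composition table, e.g. the supplied
  proteome's residue frequencies): one-sample z-test,
  `z = (f_exp − f_ref) / sqrt(f_ref (1 − f_ref) / n)` with n the
  position coverage; exact binomial fallback when f_ref ∈ {0, 1}.
- **two-sample mode** (reference = sequence set): two-proportion pooled
  z-test, symmetric under swapping the sets.

Positions are −span..−1 for C-anchored windows (−1 is the C-terminal
residue) and +1..+span for N-anchored ones; shorter sequences contribute
only to positions they cover. No multiple-testing correction is applied
by default — the convention of consensus-difference logo tools, whose
cells are read jointly rather than as independent discoveries —
with Bonferroni available by flag. The exact internal test is this
package's own definition; calibration is verified empirically (type-I
rate ≈ α under the null) in the test suite.

## Synthetic-data generator

The generator emulates the experiment end to end and is first-class,
tested code: it is the acceptance oracle for every estimator. One seeded
`numpy` generator drives all draws in a fixed documented order
(proteome → truncations → digestion retention → per-peptide attributes
→ per-replicate detection/PSM draws), so a seed pins the output
byte-for-byte.

Pipeline and defaults (all configurable):

- **Proteome**: 300 proteins, i.i.d. residues from a bundled average
  human composition table; lengths log-normal (ln-space μ = 5.9,
  σ = 0.45; median ≈ 365 aa, a realistic proteome median), clipped to
  [60, 2000].
- **Truncation proteoforms**: per protein with probability 0.05
  (comparable to the few-percent prevalence such experiments report),
  one cut uniform in the 30–90 % span of the chain, re-drawn until the
  resulting neo C-terminal peptide is a usable witness (≥ 6 aa, last
  residue ≠ K). Truncated proteoforms are digested but excluded from
  the emitted FASTA, so their termini are discoverable only as
  neo-C-termini — exactly how real truncations appear against a
  canonical database.
- **Digestion**: Lys-C/P, mc ≤ 2, minimum length 6; an mc = k product
  is retained with probability 0.3^k (geometric retention mimicking
  efficient but imperfect digestion).
- **Acetylation**: protein-initial peptides are N-terminally acetylated
  with probability 0.5 (endogenous N-terminal acetylation is common on
  mature protein N-termini).
- **2-PCA labeling**: per PSM, Bernoulli with peptide-level probability
  from a logistic model
  `logit p = 3.0 − 0.08 (len − 12) − 0.5 · GRAVY + offset(first residue)`
  with offsets +1.5 for A/L/E, −2.5 for G, −1.0 for K, and a hard zero
  for acetylated or position-2-proline peptides. The signs encode the
  observed chemistry (shorter and more hydrophilic peptides react
  better; A/L/E N-termini favorable; glycine strongly inhibitory); the
  magnitudes are this package's choices, tuned only to that qualitative
  ordering. An optional per-first-residue override plants exact
  stratum probabilities for estimator-recovery experiments.
- **Biotinylation**: each lysine occurrence in each PSM independently
  with ε = 0.977; **depletion** captures a PSM iff it carries ≥ 1
  biotinylated K. Biotinylation of free α-amines is not modeled.
- **Abundance and sampling**: per-peptide log10 abundance normal
  (μ = 6, σ_between = 1.5) or optionally uniform over a configurable
  span (used to plant an exact dynamic range); per replicate, detection
  with p = 0.8, replicate intensity with log10 noise σ_within = 0.25,
  spectral count 1 + Poisson(2). Replicate intensity is split evenly
  across a peptide's PSM rows so that per-replicate sums reconstruct it
  exactly. Ion scores are normal(60, 15); oxidation is planted on M
  occurrences at 0.05 for modification-census realism.
- **Truth ledger**: per-peptide species (true class, labeling
  probability, abundance), per-PSM draws (label, biotin sites, captured
  flag — capture bookkeeping is conserved: captured + flow-through =
  all), truncation events, and the generator's own post-depletion
  C-terminal fraction. True classes come from source positions plus
  direct prefix/suffix bookkeeping against the canonical proteome, so
  a coincidental match at another protein's terminus is resolved the
  same way an annotator observing only the database would resolve it;
  this makes "measured enrichment = truth fraction" an exact identity.

Closed-form expectations (`analytic_expectations`) accompany the
generator: escape probability (1 − ε)^k for a k-lysine peptide, the
all-replicates fraction p_det^n, and the between-replicate Pearson
σ²_between / (σ²_between + σ²_within) ≈ 0.973 at the defaults.

### What the generator does and does not emulate

It reproduces the experiment's *selection logic* and *sampling
structure*, not mass spectrometry itself: no spectra, no
chromatography, no FDR/decoy structure, no shared-peptide homology
(random sequences make cross-protein collisions vanishingly rare), and
i.i.d. residues rather than real sequence correlation. Passing tests
therefore demonstrate estimator correctness under the stated model —
bookkeeping identities, binomial recovery, calibration — not robustness
to search-engine artifacts in real data.

Because detection and spectral counts are drawn independently of
capture, a peptide whose PSMs are only partially captured keeps a
partial intensity; replicate-structure metrics on enriched data are
therefore computed on the C-terminal peptide set (which is never
captured), mirroring how such experiments report reproducibility.

## Problem sizes and numerics

Tests and the acceptance script use simulations of 25–600 proteins
(roughly 10³–10⁵ PSMs), sizes at which every binomial recovery check has
comfortable margin (e.g. stratum estimates at n ≥ 5,000 PSMs have
standard error < 0.007 against a ±0.02 band). Fractions with empty
denominators are NaN and flagged, never silently 0; file outputs are
plain TSV/JSON with no timestamps, making end-to-end runs byte-for-byte
reproducible; outputs are sorted on stable keys so results are
independent of input order.

## Known limitations

- The classifier cannot see truncation peptides that end in K (rule 3
  requires a non-K last residue); such truncations are indistinguishable
  from ordinary digestion products by design of the chemistry.
- Multi-mapping peptides take the most conservative class; a genuine
  truncation that coincides with another protein's C-terminus is
  reported as an original terminus.
- Site-blocking denominators are PSM-level; strongly heteroscedastic
  spectral counts across peptides weight abundant peptides more.
- The FASTA reader targets UniProt-dialect and plain headers only; no
  isoform/variant expansion.
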