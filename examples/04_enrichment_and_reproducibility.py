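"""Enrichment efficiency and replicate reproducibility.

Simulates the full negative-selection experiment (biotinylated internal
peptides captured, C-terminal peptides flow through) and measures the
selective enrichment efficiency, replicate overlap, intensity
correlation, and abundance dynamic range.
"""

import cterminome as ct

res = ct.simulate(ct.SimulationConfig(seed=4, n_proteins=120))
groups = ct.group_peptides(res.all_psms(), key_mods=set())
index = ct.ProteomeIndex(res.proteins)
ann = ct.annotate_peptides((g.sequence for g in groups), index)

enrich = ct.enrichment_efficiency(ann, groups)
print(f"enrichment efficiency: {100 * enrich.efficiency:.1f}% "
      f"({enrich.n_cterm}/{enrich.n_peptides_total} peptides, "
      f"{enrich.n_proteins_with_cterm} proteins)")
print("   (generator truth: "
      f"{100 * res.truth.post_depletion_cterm_fraction:.1f}%)")

cterm = [g for g in groups
         if ann[g.sequence].terminal_class
         in {"protein_cterm", "both_termini", "neo_cterm"}]
overlap = ct.replicate_overlap(cterm, 3)
print(f"C-terminal peptides in all 3 replicates: "
      f"{100 * overlap.fractions[3]:.1f}%")
for pair in ct.replicate_correlation(cterm):
    print(f"Pearson {pair.replicate_a}-{pair.replicate_b}: "
          f"{pair.pearson:.3f} (n={pair.n_shared})")
pooled = [v for g in cterm for v in g.intensity_by_replicate.values()]
print(f"dynamic range: {ct.dynamic_range(pooled):.1f} orders of "
      "magnitude")
print("-> C-terminal peptides lack lysine, escape capture, and are "
      "quantified reproducibly across replicates.")
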