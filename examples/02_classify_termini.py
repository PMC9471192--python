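"""Terminal classification of identified peptides.

Maps the curated truncation-example peptides (HSP90AB1, histone H4) onto
their full-length parents and classifies each C-terminus: an original
protein C-terminus, a regular Lys-C product, or a neo-C-terminus — the
signature of a truncated proteoform absent from the database.
"""

import cterminome as ct

index = ct.ProteomeIndex(ct.load_fixture_proteins())
rows = ct.load_truncation_examples()

annotations = {}
for ann_seq in rows["annotated_sequence"]:
    prec, seq, foll = ct.parse_annotated_sequence(ann_seq)
    ann = ct.classify_terminal(index.find(seq), seq, index)
    annotations[seq] = ann
    print(f"{ann_seq:55s} -> {ann.terminal_class}")

census = ct.truncation_census(annotations)
print(f"\nTruncation census: {census.n_neo_peptides} neo-C-terminal "
      f"peptides across {census.n_proteins} proteins")
print("-> peptides ending neither in K nor at the annotated protein end "
      "evidence in vivo/in vitro C-terminal proteolysis.")
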