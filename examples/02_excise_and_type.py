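"""Excise the 16S-23S spacer by in-silico PCR and type it.

The forward primer anneals in the conserved 16S tail and the reverse
primer in the 23S head; the spacer strictly between the two footprints
is scanned for cloverleaf tRNA genes and classified into one of the
five arrangement types.
"""

from spacertyper.arrangement import annotate_its, annotation_table_row
from spacertyper.pcr import amplify, extract_its, load_primers
from spacertyper.synth import PanelConfig, generate_panel

seqs, truths = generate_panel(PanelConfig(n_references=3, n_isolates=0, seed=1))
primers = load_primers()
fwd, rev = primers["16S-1511f"], primers["23S-23r"]

for seq in seqs:
    amplicon = amplify(seq, fwd, rev)[0]
    its, interval = extract_its(amplicon, fwd, rev)
    ann = annotate_its(its, interval)
    row = annotation_table_row(ann)
    print(row)
# its_type names the tRNA content in 5'->3' order; trna_positions are
# 1-based inclusive coordinates on the excised spacer; a two-gene
# spacer also reports its ITS-2 length and size group.
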