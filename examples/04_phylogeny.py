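"""JC69 bootstrap-consensus phylogeny of a simulated panel.

Aligns the full spacers, removes every column containing a gap or an
ambiguous base (complete deletion), and runs the distance pipeline:
JC69 distances -> neighbor joining -> ML branch lengths per bootstrap
replicate -> majority-rule consensus with percent supports.
"""

from spacertyper.align import progressive_msa
from spacertyper.phylo import bootstrap_consensus, complete_deletion, leaf_labels, to_newick
from spacertyper.seqcore import NucleotideSequence
from spacertyper.synth import PanelConfig, generate_panel

seqs, truths = generate_panel(PanelConfig(n_references=6, n_isolates=6, seed=3))
its = [
    NucleotideSequence(s.id, s.residues[t.its_interval.start: t.its_interval.end])
    for s, t in zip(seqs, truths)
]
aln = progressive_msa(its)
core = complete_deletion(aln)
print(f"{aln.ncols} aligned columns, {core.ncols} after complete deletion")

consensus, replicates = bootstrap_consensus(core, n_reps=100, seed=3)
print(f"consensus over {len(replicates)} replicates, "
      f"{len(leaf_labels(consensus))} leaves")
print(to_newick(consensus))
# Internal node labels are bootstrap supports: the percentage of
# replicate trees containing that bipartition (majority rule, > 50).
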