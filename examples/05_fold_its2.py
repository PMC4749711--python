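"""Fold ITS-2 sequences into hairpins and rank their stability.

Short ITS-2 regions fold into small hairpins — putative RNase III
processing targets — while the long size group supports long stems
with much greater (more negative) stability scores.
"""

from spacertyper.seqcore import NucleotideSequence
from spacertyper.structure import classify_hairpin, fold_its2
from spacertyper.synth import PanelConfig, generate_panel

seqs, truths = generate_panel(PanelConfig(seed=1))
for s, t in zip(seqs, truths):
    if not t.its2_interval:
        continue
    a, b = t.its2_interval
    if b - a < 8:
        continue
    iv = t.its_interval
    its2 = NucleotideSequence(s.id, s.residues[iv.start + a: iv.start + b])
    st = fold_its2(its2)
    info = classify_hairpin(st)
    print(f"{s.id:6s} len={b - a:3d}  stem={info['stem_len']:2d} bp "
          f"loop={info['loop_len']:2d} nt  stability={info['stability']:6.1f}  "
          f"{info['class']}")
# Stability is a unitless DP score (more negative = more stable);
# classes compare long-stem forms against short RNase-III-style hairpins.
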